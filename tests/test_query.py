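"""Conditional probability queries, bootstrap CIs, EUD-Loc and eligibility."""

import dataclasses

import numpy as np
import pytest

from semioloc import (
    SyntheticCohortConfig,
    bootstrap_ci,
    cohort_weight_matrix,
    eligible_semiologies,
    eud_loc,
    forest_table,
    generate_cohort,
    localizing_probability,
)
from semioloc.query import FOREST_REGIONS, UndefinedProbabilityError

from conftest import make_record


def _units(category, allocs, article="A1", topological="spontaneous"):
    return [
        make_record(
            patient=f"P{i}", article=article, category=category,
            locs=dict(a), topological=topological,
        )
        for i, a in enumerate(allocs)
    ]


class TestLocalizingProbability:
    def test_fully_allocated(self, tree):
        recs = _units("Epigastric", [{"Frontal": 1.0}] * 10)
        wm = cohort_weight_matrix(recs, tree)
        assert localizing_probability(wm, "Epigastric", "Frontal") == 1.0

    def test_hand_sum(self, tree):
        allocs = [{"Temporal": 1.0}] * 3 + [{"Frontal": 0.5, "Temporal": 0.5}]
        wm = cohort_weight_matrix(_units("Epigastric", allocs), tree)
        assert localizing_probability(wm, "Epigastric", "Temporal") == pytest.approx(0.875)

    def test_subregion_rolls_into_lobe(self, tree):
        wm = cohort_weight_matrix(
            _units("Epigastric", [{"Mesial Temporal": 1.0}] * 4), tree
        )
        p_lobe = localizing_probability(wm, "Epigastric", "Temporal")
        p_sub = localizing_probability(wm, "Epigastric", "Mesial Temporal")
        assert p_lobe == p_sub == 1.0

    def test_missing_semiology_raises(self, tree):
        wm = cohort_weight_matrix(_units("Tonic", [{"Frontal": 1.0}]), tree)
        with pytest.raises(UndefinedProbabilityError):
            localizing_probability(wm, "Epigastric", "Frontal")

    def test_partition_sums_to_one(self, tree):
        allocs = [
            {"Temporal": 1.0, "Frontal": 1.0},
            {"Mesial Temporal": 1.0},
            {"Subcallosal cortex": 1.0, "Insula": 1.0},
        ]
        wm = cohort_weight_matrix(_units("Tonic", allocs), tree)
        total = sum(
            localizing_probability(wm, "Tonic", r)
            for r in list(tree.top_level) + list(tree.standalone)
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_lobe_dominates_subregions(self, tree):
        allocs = [{"Mesial Temporal": 1.0}, {"Lateral Temporal": 1.0}, {"Frontal": 1.0}]
        wm = cohort_weight_matrix(_units("Tonic", allocs), tree)
        p_lobe = localizing_probability(wm, "Tonic", "Temporal")
        for sub in tree.children["Temporal"]:
            assert p_lobe >= localizing_probability(wm, "Tonic", sub)


class TestBootstrapCI:
    def test_zero_variance_degenerate_ci(self, tree):
        wm = cohort_weight_matrix(_units("Tonic", [{"Temporal": 1.0}] * 5), tree)
        assert bootstrap_ci(wm, "Tonic", "Temporal", n_boot=200, seed=1) == (1.0, 1.0)

    def test_deterministic_given_seed(self, tree):
        allocs = [{"Temporal": 1.0}] * 6 + [{"Frontal": 1.0}] * 4
        wm = cohort_weight_matrix(_units("Tonic", allocs), tree)
        a = bootstrap_ci(wm, "Tonic", "Temporal", n_boot=500, seed=42)
        b = bootstrap_ci(wm, "Tonic", "Temporal", n_boot=500, seed=42)
        assert a == b

    def test_ci_brackets_point_estimate(self, tree):
        allocs = [{"Temporal": 1.0}] * 7 + [{"Frontal": 1.0}] * 3
        wm = cohort_weight_matrix(_units("Tonic", allocs), tree)
        lo, hi = bootstrap_ci(wm, "Tonic", "Temporal", n_boot=2000, seed=0)
        p = localizing_probability(wm, "Tonic", "Temporal")
        assert 0 <= lo <= p <= hi <= 1

    def test_invalid_n_boot(self, tree):
        wm = cohort_weight_matrix(_units("Tonic", [{"Temporal": 1.0}] * 3), tree)
        with pytest.raises(ValueError):
            bootstrap_ci(wm, "Tonic", "Temporal", n_boot=0)

    def test_width_shrinks_with_n(self, tree):
        rng = np.random.default_rng(7)
        widths = []
        for n in (50, 500, 5000):
            allocs = [
                {"Temporal": 1.0} if rng.random() < 0.6 else {"Frontal": 1.0}
                for _ in range(n)
            ]
            wm = cohort_weight_matrix(_units("Tonic", allocs), tree)
            lo, hi = bootstrap_ci(wm, "Tonic", "Temporal", n_boot=1000, seed=n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestEudLoc:
    def test_all_temporal(self, tree):
        wm = cohort_weight_matrix(_units("Tonic", [{"Temporal": 1.0}] * 5), tree)
        prior = eud_loc(wm, "all_data")
        assert prior["Temporal"] == pytest.approx(1.0)
        assert sum(prior.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_subset_undefined(self, tree):
        wm = cohort_weight_matrix(
            _units("Tonic", [{"Temporal": 1.0}], topological="stimulation"), tree
        )
        with pytest.raises(UndefinedProbabilityError):
            eud_loc(wm, "non_topological")

    def test_recovers_generator_marginal(self):
        from semioloc import default_paper_like_config

        cfg = default_paper_like_config(n_articles=150, seed=11)
        records, truth = generate_cohort(cfg)
        wm = cohort_weight_matrix(records)
        prior = eud_loc(wm, "non_topological")
        for region in ("Temporal", "Frontal"):
            assert prior[region] == pytest.approx(
                truth.region_marginal[region], abs=0.03
            )

    def test_biased_all_data_exceeds_non_topological_for_temporal(self):
        from semioloc import default_paper_like_config

        cfg = default_paper_like_config(n_articles=80, seed=5)
        records, _ = generate_cohort(cfg)
        wm = cohort_weight_matrix(records)
        assert (
            eud_loc(wm, "all_data")["Temporal"]
            > eud_loc(wm, "non_topological")["Temporal"]
        )


class TestEligibility:
    @staticmethod
    def _cohort(n_topo, n_nontopo, category="Tonic"):
        recs = []
        for i in range(n_topo):
            recs.append(
                make_record(
                    patient=f"T{i}", article="A-topo", category=category,
                    locs={"Temporal": 1.0}, topological="epilepsy_topology",
                )
            )
        for i in range(n_nontopo):
            recs.append(
                make_record(
                    patient=f"N{i}", article="A-spont", category=category,
                    locs={"Temporal": 1.0},
                )
            )
        return recs

    @pytest.mark.parametrize(
        "n_topo,n_nontopo,expected",
        [(150, 99, []), (100, 100, ["Tonic"]), (101, 101, ["Tonic"]), (99, 150, [])],
    )
    def test_boundary(self, n_topo, n_nontopo, expected):
        assert eligible_semiologies(self._cohort(n_topo, n_nontopo)) == expected

    def test_threshold_configurable(self):
        recs = self._cohort(10, 10)
        assert eligible_semiologies(recs, min_patients=10) == ["Tonic"]
        assert eligible_semiologies(recs, min_patients=11) == []


class TestForestTable:
    def test_cardinality_and_determinism(self, tree):
        recs = (
            TestEligibility._cohort(5, 5, "Tonic")
            + TestEligibility._cohort(5, 5, "Epigastric")
        )
        wm = cohort_weight_matrix(recs, tree)
        table = forest_table(wm, recs, min_patients=5, n_boot=100, seed=3)
        # 2 semiologies x 12 regions x 2 subsets
        assert len(table) == 2 * len(FOREST_REGIONS) * 2
        again = forest_table(wm, recs, min_patients=5, n_boot=100, seed=3)
        assert table.equals(again)

    def test_empty_when_nothing_eligible(self, tree):
        recs = TestEligibility._cohort(3, 3)
        wm = cohort_weight_matrix(recs, tree)
        assert forest_table(wm, recs, min_patients=100, n_boot=50).empty
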