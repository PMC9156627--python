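"""Weighted contingency tables and relative odds ratios, checked against an
independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from semioloc import (
    cohort_weight_matrix,
    contingency_table,
    odds_ratio,
    or_with_ci,
)
from semioloc.relative import InsufficientDataError

from conftest import make_record

# ---------------------------------------------------------------------------
# independent oracle: plain-python enumeration over units, its own
# descendant map, no shared code with the pipeline

_ORACLE_DESCENDANTS = {
    "Temporal": [
        "Mesial Temporal", "Anterior Temporal", "Lateral Temporal",
        "Posterior Temporal", "Basal Temporal",
    ],
}


def oracle_cells(units, semiology, region):
    """units: list of (category, {node: integer count})."""

    def in_region(node):
        return node == region or node in _ORACLE_DESCENDANTS.get(region, [])

    a = c = 0.0
    n_s = n_rest = 0
    for cat, alloc in units:
        total = sum(alloc.values())
        w = sum(v for node, v in alloc.items() if in_region(node)) / total
        if cat == semiology:
            a += w
            n_s += 1
        else:
            c += w
            n_rest += 1
    return a, n_s - a, c, n_rest - c


def oracle_or(a, b, c, d):
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a * d / (b * c)


def _records(units):
    return [
        make_record(patient=f"P{i}", category=cat, locs={k: float(v) for k, v in alloc.items()})
        for i, (cat, alloc) in enumerate(units)
    ]


class TestContingency:
    def test_hand_count(self, tree):
        units = [
            ("S", {"Temporal": 1}), ("S", {"Temporal": 1}), ("S", {"Frontal": 1}),
            ("X", {"Temporal": 1}),
            ("X", {"Frontal": 1}), ("X", {"Frontal": 1}),
            ("X", {"Parietal": 1}), ("X", {"Occipital": 1}),
        ]
        wm = cohort_weight_matrix(_records(units), tree)
        assert contingency_table(wm, "S", "Temporal") == (2.0, 1.0, 1.0, 4.0)

    def test_degenerate_no_rest(self, tree):
        units = [("S", {"Temporal": 1}), ("S", {"Frontal": 1})]
        wm = cohort_weight_matrix(_records(units), tree)
        a, b, c, d = contingency_table(wm, "S", "Temporal")
        assert c == d == 0.0

    def test_unknown_region_raises(self, tree):
        wm = cohort_weight_matrix(_records([("S", {"Temporal": 1})]), tree)
        with pytest.raises(KeyError):
            contingency_table(wm, "S", "Thalamus of Oz")


class TestOddsRatio:
    def test_closed_form(self):
        assert odds_ratio(4, 1, 2, 8) == pytest.approx(16.0)
        assert odds_ratio(3, 3, 3, 3) == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        assert odds_ratio(0, 5, 5, 5) == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio(0, 0, 0, 0)

    @given(st.tuples(*[st.floats(0.5, 20)] * 4))
    def test_complement_antisymmetry(self, cells):
        a, b, c, d = cells
        assert odds_ratio(a, b, c, d) * odds_ratio(b, a, d, c) == pytest.approx(1.0)

    @given(st.tuples(*[st.floats(0.5, 20)] * 4))
    def test_group_exchange_inverts(self, cells):
        a, b, c, d = cells
        assert odds_ratio(c, d, a, b) == pytest.approx(1.0 / odds_ratio(a, b, c, d))


class TestOracleEquivalence:
    """Pipeline cells and ORs equal brute-force enumeration on small integer cohorts."""

    NODES = [
        "Temporal", "Frontal", "Parietal", "Insula",
        "Mesial Temporal", "Basal Temporal", "Subcallosal cortex",
    ]

    def _random_units(self, rng):
        n = int(rng.integers(4, 21))
        units = []
        for i in range(n):
            cat = rng.choice(["S", "X", "Y"], p=[0.4, 0.4, 0.2])
            k = int(rng.integers(1, 4))
            nodes = rng.choice(self.NODES, size=k, replace=False)
            units.append((str(cat), {str(nd): int(rng.integers(1, 4)) for nd in nodes}))
        if not any(u[0] == "S" for u in units):
            units[0] = ("S", units[0][1])
        if all(u[0] == "S" for u in units):
            units[-1] = ("X", units[-1][1])
        return units

    def test_thousand_random_cohorts(self, tree):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            units = self._random_units(rng)
            region = str(rng.choice(["Temporal", "Frontal", "Mesial Temporal"]))
            wm = cohort_weight_matrix(_records(units), tree)
            got = contingency_table(wm, "S", region)
            want = oracle_cells(units, "S", region)
            assert got == pytest.approx(want, abs=1e-9)
            assert odds_ratio(*got) == pytest.approx(oracle_or(*want), rel=1e-9)


class TestOrWithCI:
    def test_deterministic_given_seed(self, tree):
        units = [("S", {"Temporal": 1})] * 5 + [("S", {"Frontal": 1})] * 3 \
            + [("X", {"Temporal": 1})] * 4 + [("X", {"Parietal": 1})] * 6
        wm = cohort_weight_matrix(_records(units), tree)
        r1 = or_with_ci(wm, "S", "Temporal", n_boot=500, seed=9)
        r2 = or_with_ci(wm, "S", "Temporal", n_boot=500, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_identical_allocations_flagged_degenerate(self, tree):
        # every unit fully in the region: b = d = 0, the corrected point OR is
        # 1 and the table is flagged degenerate; the bootstrap CI straddles 1
        units = [("S", {"Temporal": 1})] * 4 + [("X", {"Temporal": 1})] * 4
        wm = cohort_weight_matrix(_records(units), tree)
        res = or_with_ci(wm, "S", "Temporal", n_boot=300, seed=0)
        assert res.degenerate
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low <= 1.0 <= res.ci_high
        assert not res.significant

    def test_insufficient_data(self, tree):
        units = [("S", {"Temporal": 1}), ("X", {"Frontal": 1})]
        wm = cohort_weight_matrix(_records(units), tree)
        with pytest.raises(InsufficientDataError):
            or_with_ci(wm, "S", "Temporal", n_boot=100)

    def test_true_or_recovered_in_ci(self, tree):
        # S strongly frontal vs rest flat: large-sample OR bracketed by CI
        rng = np.random.default_rng(31)
        units = []
        for i in range(400):
            if i < 150:
                node = "Frontal" if rng.random() < 0.6 else "Temporal"
                units.append(("S", {node: 1}))
            else:
                node = "Frontal" if rng.random() < 0.25 else "Temporal"
                units.append(("X", {node: 1}))
        wm = cohort_weight_matrix(_records(units), tree)
        res = or_with_ci(wm, "S", "Frontal", n_boot=2000, seed=12)
        true_or = (0.6 / 0.4) / (0.25 / 0.75)
        assert res.ci_low < true_or < res.ci_high
        assert res.significant
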