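"""Model/Results interface tying the pipeline together.

``SemiologyLocalizationModel`` is built from patient-semiology records (or a
canonical CSV/TSV/XLSX export); ``fit`` runs classification, non-ictal
stripping, filtering, junction redistribution, per-patient normalization, the
bootstrap probability queries and the relative odds ratios, and returns a
``SemiologyLocalizationResults`` carrying the estimates, their bootstrap CIs,
the estimated unbiased prior of localizations and a printable summary.

Typical use::

    model = SemiologyLocalizationModel.from_csv("cohort.csv")
    res = model.fit(n_boot=10_000, seed=0)
    print(res.summary())
    res.forest          # p(region | semiology) per subset, with CIs
    res.odds_ratios     # relative localizing values
    res.prior           # EUD-Loc per subset
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .normalize import WeightMatrix, cohort_weight_matrix
from .query import (
    FOREST_REGIONS,
    PriorDistribution,
    eligible_semiologies,
    eud_loc,
    forest_table,
)
from .records import DatapointRecord, filter_subset, frame_to_records, read_database
from .regions import RegionTree, default_region_tree
from .relative import or_table
from .taxonomy import Taxonomy, classify_records, default_taxonomy, strip_nonictal

__all__ = ["SemiologyLocalizationModel", "SemiologyLocalizationResults"]


class SemiologyLocalizationModel:
    """Probabilistic semiology-localization model over a literature cohort."""

    def __init__(
        self,
        records: Sequence[DatapointRecord],
        tree: RegionTree | None = None,
        taxonomy: Taxonomy | None = None,
        min_patients: int = 100,
        ground_truth_any_of: Sequence[str] | None = None,
        exclude_children: bool = False,
    ):
        self.tree = tree or default_region_tree()
        self.taxonomy = taxonomy or default_taxonomy()
        self.min_patients = int(min_patients)
        filters = {}
        if ground_truth_any_of is not None:
            filters["ground_truth_any_of"] = list(ground_truth_any_of)
        if exclude_children:
            filters["exclude_age"] = True
        records = classify_records(records, self.taxonomy)
        records = strip_nonictal(records, self.taxonomy)
        if filters:
            records = filter_subset(records, **filters)
        self.records: list[DatapointRecord] = list(records)
        self.filters = filters

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_csv(cls, path, dialect: str | None = None, **kwargs) -> "SemiologyLocalizationModel":
        tree = kwargs.get("tree") or default_region_tree()
        records, report = read_database(path, dialect=dialect, tree=tree)
        model = cls(records, **{**kwargs, "tree": tree})
        model.validation_report = report
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SemiologyLocalizationModel":
        tree = kwargs.get("tree") or default_region_tree()
        records, report = frame_to_records(df, tree=tree)
        model = cls(records, **{**kwargs, "tree": tree})
        model.validation_report = report
        return model

    # -- estimation -------------------------------------------------------
    def weight_matrix(self) -> WeightMatrix:
        return cohort_weight_matrix(self.records, self.tree)

    def fit(
        self,
        n_boot: int = 10_000,
        level: float = 0.95,
        seed: int = 0,
        subsets: Sequence[str] = ("all_data", "non_topological"),
        regions: Sequence[str] = FOREST_REGIONS,
        compute_odds_ratios: bool = True,
    ) -> "SemiologyLocalizationResults":
        weights = self.weight_matrix()
        eligible = eligible_semiologies(self.records, min_patients=self.min_patients)
        forest = forest_table(
            weights,
            self.records,
            min_patients=self.min_patients,
            regions=regions,
            subsets=subsets,
            n_boot=n_boot,
            level=level,
            seed=seed,
        )
        priors = {}
        for label in subsets:
            try:
                priors[label] = eud_loc(weights, subset_label=label)
            except ValueError:
                continue
        ors = (
            or_table(
                weights, eligible, regions, subsets=subsets,
                n_boot=n_boot, level=level, seed=seed,
            )
            if compute_odds_ratios
            else pd.DataFrame()
        )
        return SemiologyLocalizationResults(
            model=self,
            forest=forest,
            odds_ratios=ors,
            prior=priors,
            eligible=eligible,
            n_boot=n_boot,
            level=level,
            seed=seed,
        )


@dataclass
class SemiologyLocalizationResults:
    """Fitted localizing values, relative odds ratios and the regional prior."""

    model: SemiologyLocalizationModel
    forest: pd.DataFrame
    odds_ratios: pd.DataFrame
    prior: Mapping[str, PriorDistribution]
    eligible: list
    n_boot: int
    level: float
    seed: int

    def probability(self, semiology: str, region: str, subset: str = "non_topological"):
        row = self.forest[
            (self.forest.semiology == semiology)
            & (self.forest.region == region)
            & (self.forest.subset_label == subset)
        ]
        if row.empty:
            raise KeyError((semiology, region, subset))
        r = row.iloc[0]
        return float(r.p_hat), (float(r.ci_low), float(r.ci_high))

    def summary(self) -> str:
        lines = []
        lines.append("Semiology localization results")
        lines.append("=" * 64)
        lines.append(f"records (units): {len(self.model.records)}")
        lines.append(f"eligible semiologies (>= {self.model.min_patients} patients/subset): "
                     f"{len(self.eligible)}")
        lines.append(f"bootstrap resamples: {self.n_boot}   CI level: {self.level:.0%}   seed: {self.seed}")
        for label, prior in self.prior.items():
            ordered = sorted(prior.probabilities.items(), key=lambda kv: -kv[1])
            pretty = ", ".join(f"{r}: {p:.1%}" for r, p in ordered if p > 0.0005)
            lines.append(f"prior ({label}, n={prior.n_units}): {pretty}")
        if not self.forest.empty:
            lines.append("-" * 64)
            lines.append("p(region | semiology), non-topological subset:")
            sub = self.forest[self.forest.subset_label == "non_topological"]
            for semiology in self.eligible:
                rows = sub[sub.semiology == semiology].sort_values("p_hat", ascending=False)
                top = rows.head(3)
                cells = ", ".join(
                    f"{r.region} {r.p_hat:.0%} ({r.ci_low:.0%}, {r.ci_high:.0%})"
                    for r in top.itertuples()
                )
                lines.append(f"  {semiology}: {cells}")
        return "\n".join(lines)

    # -- export -----------------------------------------------------------
    def to_csv(self, forest_path=None, or_path=None) -> None:
        if forest_path is not None:
            self.forest.to_csv(forest_path, index=False)
        if or_path is not None:
            self.odds_ratios.to_csv(or_path, index=False)

    def plot_forest(self, semiology: str, ax=None):
        from .plotting import forest_plot

        return forest_plot(self.forest, semiology, ax=ax)
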