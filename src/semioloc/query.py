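"""Conditional localization probabilities with bootstrap uncertainty.

The central quantity is ``p(localizing to region | semiology)``: the mean,
over (patient, semiology) units in a data subset, of each unit's normalized
weight rolled up to the region.  Confidence intervals are percentile intervals
over bootstrap resamples of the units (10,000 resamples by default).

Comparing the all-data estimate with the non-topological estimate quantifies
publication bias: topological studies preselect patients by brain region
(predominantly temporal), so pooling them inflates temporal localizations.
Pooling all semiologies over the non-topological subset yields the estimated
unbiased prior distribution of localizations (EUD-Loc).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalize import WeightMatrix
from .records import DatapointRecord
from .regions import RegionTree, TEMPORAL_SUBREGIONS

__all__ = [
    "LocalizationResult",
    "PriorDistribution",
    "UndefinedProbabilityError",
    "localizing_probability",
    "bootstrap_ci",
    "eud_loc",
    "eligible_semiologies",
    "forest_table",
    "FOREST_REGIONS",
]

# the seven top-level regions shown in forest reports plus the five temporal
# subregions nested within Temporal
FOREST_TOP_REGIONS = (
    "Temporal",
    "Frontal",
    "Parietal",
    "Occipital",
    "Cingulate",
    "Insula",
    "Hypothalamus",
)
FOREST_REGIONS = FOREST_TOP_REGIONS + TEMPORAL_SUBREGIONS

SUBSET_LABELS = ("all_data", "non_topological", "topological")


class UndefinedProbabilityError(ValueError):
    """Raised when a probability is requested for an empty unit set."""


@dataclass(frozen=True)
class LocalizationResult:
    semiology: str
    region: str
    p_hat: float
    ci_low: float
    ci_high: float
    n_patients_all: int
    n_patients_subset: int
    subset_label: str
    seed: int | None = None


@dataclass(frozen=True)
class PriorDistribution:
    """Regional prior over the seven forest regions plus an 'other' remainder."""

    probabilities: dict
    subset_label: str
    n_units: int

    def __getitem__(self, region: str) -> float:
        return self.probabilities[region]


def localizing_probability(weights: WeightMatrix, semiology: str, region: str) -> float:
    """Point estimate of p(region | semiology) over the matrix's units."""
    sub = weights.for_semiology(semiology)
    if sub.n_units == 0:
        raise UndefinedProbabilityError(f"no units for semiology {semiology!r}")
    return float(sub.rollup_values(region).mean())


def _percentile_ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def bootstrap_ci(
    weights: WeightMatrix,
    semiology: str,
    region: str,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for p(region | semiology).

    Units are resampled with replacement; deterministic given *seed*.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    values = weights.for_semiology(semiology).rollup_values(region)
    n = values.size
    if n < 2:
        raise UndefinedProbabilityError(
            f"need >= 2 units for a bootstrap CI of {semiology!r}"
        )
    rng = np.random.default_rng(seed)
    # resampling n units with replacement is a multinomial draw over the
    # distinct per-unit values; this keeps cost at O(n_boot * k) for k
    # distinct values instead of O(n_boot * n)
    classes, counts = np.unique(values, return_counts=True)
    draws = rng.multinomial(n, counts / n, size=n_boot)
    means = draws @ classes / n
    return _percentile_ci(means, level)


def eud_loc(weights: WeightMatrix, subset_label: str = "non_topological") -> PriorDistribution:
    """Estimated prior distribution of localizations, all semiologies pooled.

    Probability per top-level region is its total rolled-up weight divided by
    the total weight over the eight top-level regions plus the standalone
    subcallosal cortex.  The seven forest regions are reported explicitly and
    the remainder (cerebellum + standalone nodes) as ``other``, so the output
    sums to 1.
    """
    sub = weights.subset(subset_label)
    if sub.n_units == 0:
        raise UndefinedProbabilityError(f"no units in subset {subset_label!r}")
    tree = weights.tree
    totals = {top: float(sub.rollup_values(top).sum()) for top in tree.top_level}
    for node in tree.standalone:
        totals[node] = float(sub.rollup_values(node).sum())
    grand = sum(totals.values())
    if grand <= 0:
        raise UndefinedProbabilityError("subset carries no localizing weight")
    probs = {r: totals[r] / grand for r in FOREST_TOP_REGIONS}
    probs["other"] = 1.0 - sum(probs.values())
    return PriorDistribution(probabilities=probs, subset_label=subset_label, n_units=sub.n_units)


def eligible_semiologies(
    records: Sequence[DatapointRecord], min_patients: int = 100
) -> list[str]:
    """Categories with at least *min_patients* patients in BOTH the topological
    and the non-topological subset."""
    counts: dict[str, dict[str, set]] = {}
    for rec in records:
        cat = rec.semiology_category
        if not cat:
            continue
        bucket = "topological" if rec.is_topological else "non_topological"
        counts.setdefault(cat, {"topological": set(), "non_topological": set()})
        counts[cat][bucket].add(rec.patient_key)
    return sorted(
        cat
        for cat, buckets in counts.items()
        if len(buckets["topological"]) >= min_patients
        and len(buckets["non_topological"]) >= min_patients
    )


def forest_table(
    weights: WeightMatrix,
    records: Sequence[DatapointRecord],
    min_patients: int = 100,
    regions: Sequence[str] = FOREST_REGIONS,
    subsets: Sequence[str] = ("all_data", "non_topological"),
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Forest-report table: one row per eligible semiology x region x subset.

    Seeds for the per-cell bootstraps are derived deterministically from
    *seed*, so a rerun with the same seed is bit-identical.
    """
    eligible = eligible_semiologies(records, min_patients=min_patients)
    rows = []
    master = np.random.default_rng(seed)
    for semiology in eligible:
        n_all = weights.for_semiology(semiology).n_units
        for subset_label in subsets:
            sub = weights.subset(subset_label)
            n_subset = sub.for_semiology(semiology).n_units
            for region in regions:
                cell_seed = int(master.integers(0, 2**31 - 1))
                if n_subset >= 2:
                    p = localizing_probability(sub, semiology, region)
                    lo, hi = bootstrap_ci(
                        sub, semiology, region, n_boot=n_boot, level=level, seed=cell_seed
                    )
                elif n_subset == 1:
                    p = localizing_probability(sub, semiology, region)
                    lo = hi = p
                else:
                    p = lo = hi = np.nan
                rows.append(
                    asdict(
                        LocalizationResult(
                            semiology=semiology,
                            region=region,
                            p_hat=p,
                            ci_low=lo,
                            ci_high=hi,
                            n_patients_all=n_all,
                            n_patients_subset=n_subset,
                            subset_label=subset_label,
                            seed=cell_seed,
                        )
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "semiology",
            "region",
            "p_hat",
            "ci_low",
            "ci_high",
            "n_patients_all",
            "n_patients_subset",
            "subset_label",
            "seed",
        ],
    )
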