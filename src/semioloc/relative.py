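"""Intrinsic localizing value of a semiology relative to all others.

For a semiology S and region R a weighted 2x2 contingency table is formed over
normalized (patient, semiology) units:

    a = weight of S units rolled up to R        b = S weight outside R
    c = weight of all other units in R          d = non-S weight outside R

The odds ratio (a*d)/(b*c) measures how much knowing S shifts the odds of R
relative to the prior regional distribution implied by all other semiologies.
Cells are continuous because data points are normalized to patients; a
Haldane-Anscombe 0.5 correction is applied to all four cells when any cell is
zero.  CIs are percentile intervals over pooled bootstrap resamples of all
units (S and non-S together); significance means the 95% CI excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .normalize import WeightMatrix

__all__ = [
    "ContingencyResult",
    "InsufficientDataError",
    "contingency_table",
    "odds_ratio",
    "or_with_ci",
    "or_table",
]


class InsufficientDataError(ValueError):
    """Fewer than two units in the semiology or its complement."""


@dataclass(frozen=True)
class ContingencyResult:
    semiology: str
    region: str
    a: float
    b: float
    c: float
    d: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    significant: bool
    subset_label: str
    degenerate: bool = False
    seed: int | None = None


def contingency_table(
    weights: WeightMatrix, semiology: str, region: str
) -> tuple[float, float, float, float]:
    """Weighted (a, b, c, d) cells for semiology-vs-rest by region-vs-rest."""
    if region not in weights.tree:
        raise KeyError(f"unknown region node {region!r}")
    mask = weights.semiology_mask(semiology)
    if not mask.any():
        raise InsufficientDataError(f"no units for semiology {semiology!r}")
    values = weights.rollup_values(region)
    n_s = float(mask.sum())
    n_rest = float((~mask).sum())
    a = float(values[mask].sum())
    b = n_s - a
    c = float(values[~mask].sum())
    d = n_rest - c
    return a, b, c, d


def odds_ratio(a: float, b: float, c: float, d: float, correction: float = 0.5) -> float:
    """(a*d)/(b*c), adding *correction* to every cell if any cell is zero."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("contingency cells must be non-negative")
    if np.all(cells == 0):
        raise ValueError("odds ratio undefined for an all-zero table")
    if np.any(cells == 0):
        cells = cells + correction
    a, b, c, d = cells
    return float((a * d) / (b * c))


def _boot_ors(
    s_mask: np.ndarray,
    values: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    correction: float,
) -> np.ndarray:
    """Odds ratios over pooled resamples of all units with replacement.

    Units are collapsed into equivalence classes of (group, region weight);
    resampling n units is then a multinomial draw over the classes, which is
    distributionally identical to unit-level resampling at a fraction of the
    cost.
    """
    n = values.size
    keyed = np.column_stack([s_mask.astype(float), values])
    classes, counts = np.unique(keyed, axis=0, return_counts=True)
    draws = rng.multinomial(n, counts / n, size=n_boot).astype(float)
    cls_s = classes[:, 0]
    cls_v = classes[:, 1]
    n_s = draws @ cls_s
    a = draws @ (cls_s * cls_v)
    total_v = draws @ cls_v
    c = total_v - a
    n_rest = n - n_s
    b = n_s - a
    d = n_rest - c
    cells = np.stack([a, b, c, d], axis=1)
    zero = (cells == 0).any(axis=1)
    cells[zero] += correction
    a, b, c, d = cells.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ors = (a * d) / (b * c)
    # resamples that drew no S units (or only S units) carry no information
    return ors[np.isfinite(ors)]


def or_with_ci(
    weights: WeightMatrix,
    semiology: str,
    region: str,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = 0,
    correction: float = 0.5,
    subset_label: str = "all_data",
) -> ContingencyResult:
    """Point OR with pooled-bootstrap percentile CI and alpha=0.05 significance."""
    a, b, c, d = contingency_table(weights, semiology, region)
    mask = weights.semiology_mask(semiology)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise InsufficientDataError(
            f"need >= 2 units in both {semiology!r} and its complement"
        )
    degenerate = (c == 0 and d == 0) or (b == 0 and d == 0)
    point = odds_ratio(a, b, c, d, correction=correction)
    values = weights.rollup_values(region)
    rng = np.random.default_rng(seed)
    ors = _boot_ors(mask, values, n_boot, rng, correction)
    if ors.size == 0:
        lo = hi = point
        degenerate = True
    else:
        alpha = (1.0 - level) / 2.0
        lo, hi = (float(q) for q in np.quantile(ors, [alpha, 1.0 - alpha]))
    significant = not (lo <= 1.0 <= hi)
    return ContingencyResult(
        semiology=semiology,
        region=region,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=point,
        ci_low=lo,
        ci_high=hi,
        significant=significant,
        subset_label=subset_label,
        degenerate=degenerate,
        seed=seed,
    )


def or_table(
    weights: WeightMatrix,
    semiologies: Sequence[str],
    regions: Sequence[str],
    subsets: Sequence[str] = ("all_data", "non_topological"),
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """OR results for each semiology x region x subset; deterministic in *seed*.

    The contingency complement uses all other semiologies present in the
    matrix, including the infrequent ones.
    """
    rows = []
    master = np.random.default_rng(seed)
    for semiology in semiologies:
        for subset_label in subsets:
            sub = weights.subset(subset_label)
            for region in regions:
                cell_seed = int(master.integers(0, 2**31 - 1))
                try:
                    res = or_with_ci(
                        sub,
                        semiology,
                        region,
                        n_boot=n_boot,
                        level=level,
                        seed=cell_seed,
                        subset_label=subset_label,
                    )
                except InsufficientDataError:
                    continue
                rows.append(_asrow(res))
    return pd.DataFrame(
        rows,
        columns=[
            "semiology", "region", "a", "b", "c", "d", "odds_ratio",
            "ci_low", "ci_high", "significant", "subset_label", "degenerate", "seed",
        ],
    )


def _asrow(res: ContingencyResult) -> dict:
    return {
        "semiology": res.semiology,
        "region": res.region,
        "a": res.a,
        "b": res.b,
        "c": res.c,
        "d": res.d,
        "odds_ratio": res.odds_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "significant": res.significant,
        "subset_label": res.subset_label,
        "degenerate": res.degenerate,
        "seed": res.seed,
    }
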