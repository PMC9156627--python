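"""Flow-count export and sensitivity comparisons.

``flow_counts`` is the data backbone of a publication-bias flow diagram: for
each analysis unit it walks the layers year -> ground truth -> study design ->
top-level region -> semiology and accumulates (fractional) unit mass, with an
explicit ``missing`` bucket so every layer conserves the unit total exactly.

``sensitivity_compare`` aligns two result tables cell by cell (semiology,
region, subset) and reports CI overlap plus point-estimate differences, the
robustness check used when swapping ground-truth or age filters.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .normalize import cohort_weight_matrix
from .records import DatapointRecord
from .regions import RegionTree, default_region_tree

__all__ = ["flow_counts", "flow_frame", "sensitivity_compare"]

MISSING = "missing"

# a unit with several true ground-truth flags is binned once, by strength
_GT_PRIORITY = (
    ("gt_seizure_free", "seizure_free"),
    ("gt_concordance", "concordance"),
    ("gt_invasive", "invasive"),
)


def _gt_bucket(rec: DatapointRecord) -> str:
    for attr, label in _GT_PRIORITY:
        if getattr(rec, attr):
            return label
    return MISSING


def flow_frame(
    records: Sequence[DatapointRecord], tree: RegionTree | None = None
) -> pd.DataFrame:
    """Long-format flow table: one row per unit x top-level region with mass.

    Each unit carries total mass 1, split over top-level regions (and the
    standalone/missing bucket) according to its normalized, junction-
    redistributed allocation.
    """
    tree = tree or default_region_tree()
    wm = cohort_weight_matrix(records, tree)
    rows = []
    region_targets = list(tree.top_level) + list(tree.standalone)
    rollups = {r: wm.rollup_values(r) for r in region_targets}
    for i, rec in enumerate(records):
        year = str(rec.year) if rec.year is not None else MISSING
        gt = _gt_bucket(rec)
        design = "topological" if rec.is_topological else "non_topological"
        semiology = rec.semiology_category or MISSING
        assigned = 0.0
        for r in region_targets:
            w = float(rollups[r][i])
            if w > 0:
                rows.append((year, gt, design, r, semiology, w))
                assigned += w
        leftover = 1.0 - assigned
        if leftover > 1e-12:
            rows.append((year, gt, design, MISSING, semiology, leftover))
    return pd.DataFrame(
        rows, columns=["year", "ground_truth", "design", "region", "semiology", "mass"]
    )


def flow_counts(
    records: Sequence[DatapointRecord], tree: RegionTree | None = None
) -> dict:
    """Nested mass counts year -> ground truth -> design -> region -> semiology."""
    df = flow_frame(records, tree)
    nested: dict = {}
    for row in df.itertuples(index=False):
        d = nested.setdefault(row.year, {}) \
                  .setdefault(row.ground_truth, {}) \
                  .setdefault(row.design, {}) \
                  .setdefault(row.region, {})
        d[row.semiology] = d.get(row.semiology, 0.0) + row.mass
    return nested


def sensitivity_compare(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Cell-wise CI overlap between two forest tables.

    Both tables must carry semiology/region/subset_label/p_hat/ci_low/ci_high
    and cover the same cells; the returned frame has one row per cell plus
    ``attrs['overlap_fraction']``.
    """
    keys = ["semiology", "region", "subset_label"]
    a = results_a.set_index(keys)
    b = results_b.set_index(keys)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("result sets share no (semiology, region, subset) cells")
    if len(common) != len(a) or len(common) != len(b):
        missing = len(a.index.symmetric_difference(b.index))
        raise ValueError(f"result sets are misaligned on {missing} cell(s)")
    rows = []
    for key in common:
        ra, rb = a.loc[key], b.loc[key]
        overlap = (ra.ci_low <= rb.ci_high) and (rb.ci_low <= ra.ci_high)
        rows.append(
            {
                "semiology": key[0],
                "region": key[1],
                "subset_label": key[2],
                "p_a": float(ra.p_hat),
                "p_b": float(rb.p_hat),
                "abs_diff": abs(float(ra.p_hat) - float(rb.p_hat)),
                "ci_overlap": bool(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["overlap_fraction"] = float(out["ci_overlap"].mean())
    return out
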