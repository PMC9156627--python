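"""Per-patient-semiology normalization.

The unit of analysis is a single patient-semiology.  Raw multi-one-hot
allocations are divided by their total so each unit's weights sum to one,
which (a) penalizes reports localizing one semiology to several regions
inversely to the number of regions, and (b) makes the total weight carried by
a semiology equal to the number of patients reported with it.

Normalization runs *after* interlobar-junction redistribution, so a junction
allocation counts as its constituent lobes, not as one region of its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DatapointRecord, META_COLUMNS
from .regions import RegionTree, default_region_tree, redistribute_junctions

__all__ = ["DegenerateAllocationError", "normalize_patient_semiology", "cohort_weight_matrix", "WeightMatrix"]

_ATOL = 1e-9


class DegenerateAllocationError(ValueError):
    """An allocation vector with no positive weight cannot be normalized."""


def normalize_patient_semiology(vector: Mapping[str, float]) -> dict[str, float]:
    """Divide every weight by the vector total; the output sums to 1 (±1e-9)."""
    total = float(sum(vector.values()))
    if total <= 0:
        raise DegenerateAllocationError("allocation vector has no positive weight")
    return {k: float(v) / total for k, v in vector.items() if v != 0}


@dataclass
class WeightMatrix:
    """Normalized unit-level weights with their metadata.

    ``data`` holds one row per (patient, semiology) unit: the record metadata
    columns followed by one column per allocation node of the tree (junction
    weight has already been redistributed).  Each row's region weights sum
    to 1.
    """

    data: pd.DataFrame
    tree: RegionTree

    @property
    def region_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def n_units(self) -> int:
        return len(self.data)

    def subset(self, label: str) -> "WeightMatrix":
        """Restrict to a data subset: all_data, non_topological or topological."""
        if label == "all_data":
            df = self.data
        elif label == "non_topological":
            df = self.data[self.data["topological"] == "spontaneous"]
        elif label == "topological":
            df = self.data[self.data["topological"] != "spontaneous"]
        else:
            raise ValueError(f"unknown subset label {label!r}")
        return WeightMatrix(data=df, tree=self.tree)

    def for_semiology(self, semiology: str) -> "WeightMatrix":
        return WeightMatrix(
            data=self.data[self.data["semiology_category"] == semiology], tree=self.tree
        )

    def rollup_values(self, node: str) -> np.ndarray:
        """Per-unit rolled-up weight at *node* (node plus its descendants)."""
        if node not in self.tree:
            raise KeyError(f"unknown region node {node!r}")
        cols = [c for c in (node, *self.tree.descendants(node)) if c in self.data.columns]
        if not cols:
            return np.zeros(self.n_units)
        return self.data[cols].to_numpy(dtype=float).sum(axis=1)

    def semiology_mask(self, semiology: str) -> np.ndarray:
        return (self.data["semiology_category"] == semiology).to_numpy()

    @property
    def semiologies(self) -> list[str]:
        return sorted(self.data["semiology_category"].dropna().unique())

    def patient_count(self, semiology: str | None = None) -> int:
        df = self.data
        if semiology is not None:
            df = df[df["semiology_category"] == semiology]
        return df.groupby(["article_id", "patient_id"]).ngroups

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def cohort_weight_matrix(
    records: Sequence[DatapointRecord], tree: RegionTree | None = None
) -> WeightMatrix:
    """Build the normalized unit-by-region weight matrix for a cohort.

    Each record must be classified (carry a semiology category) and have at
    least one positive allocation; degenerate records raise with the record
    identity attached.
    """
    tree = tree or default_region_tree()
    alloc_nodes = list(tree.allocation_nodes)
    meta_rows = []
    weights = np.zeros((len(records), len(alloc_nodes)))
    col_index = {c: i for i, c in enumerate(alloc_nodes)}
    for i, rec in enumerate(records):
        redistributed = redistribute_junctions(rec.localizations, tree)
        try:
            norm = normalize_patient_semiology(redistributed)
        except DegenerateAllocationError as exc:
            raise DegenerateAllocationError(
                f"record {rec.patient_key} ({rec.semiology_category!r}): {exc}"
            ) from exc
        for node, w in norm.items():
            weights[i, col_index[node]] = w
        meta_rows.append({c: getattr(rec, c) for c in META_COLUMNS if c != "semiology_category"}
                         | {"semiology_category": rec.semiology_category})
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    wdf = pd.DataFrame(weights, columns=alloc_nodes)
    data = pd.concat([meta.reset_index(drop=True), wdf], axis=1)
    return WeightMatrix(data=data, tree=tree)
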