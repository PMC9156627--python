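"""Hierarchical brain-region inventory.

The anatomy used for localization is a small tree: eight fixed top-level
regions (temporal, frontal, parietal, occipital, cingulate, insula,
hypothalamus, cerebellum), five named temporal subregions, and arbitrary
further descendants.  Two kinds of non-hierarchical nodes exist alongside the
tree: *junctions* (interlobar categories such as "Temporo-parietal" used as a
data-entry shorthand, whose weight is redistributed equally over their
constituent lobes before analysis) and *standalone* nodes (the subcallosal
cortex), which are kept in place.

Probabilities at a region are always computed by rolling allocations up the
tree: the weight at a node plus everything below it.  Allocations themselves
are stored at the most specific node only, so roll-up never double counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "RegionTree",
    "RegionDefinitionError",
    "load_region_tree",
    "default_region_tree",
    "redistribute_junctions",
    "rollup",
]

TOP_LEVEL = (
    "Temporal",
    "Frontal",
    "Parietal",
    "Occipital",
    "Cingulate",
    "Insula",
    "Hypothalamus",
    "Cerebellum",
)

TEMPORAL_SUBREGIONS = (
    "Mesial Temporal",
    "Anterior Temporal",
    "Lateral Temporal",
    "Posterior Temporal",
    "Basal Temporal",
)


class RegionDefinitionError(ValueError):
    """Raised when a region-tree definition violates its structural invariants."""


@dataclass(frozen=True)
class RegionTree:
    """Immutable region hierarchy with junction and standalone side-tables."""

    top_level: tuple[str, ...]
    parent: Mapping[str, str]          # child -> parent, top-level nodes absent
    children: Mapping[str, tuple[str, ...]]
    junctions: Mapping[str, tuple[str, ...]]
    standalone: tuple[str, ...]
    _descendants: dict = field(default_factory=dict, repr=False, compare=False)

    # -- membership -------------------------------------------------------
    @property
    def hierarchy_nodes(self) -> tuple[str, ...]:
        out = list(self.top_level)
        for top in self.top_level:
            out.extend(self.descendants(top))
        return tuple(out)

    @property
    def allocation_nodes(self) -> tuple[str, ...]:
        """Nodes on which analysis weight may sit (hierarchy + standalone)."""
        return self.hierarchy_nodes + self.standalone

    @property
    def nodes(self) -> tuple[str, ...]:
        """All known node names, including junctions."""
        return self.allocation_nodes + tuple(self.junctions)

    def __contains__(self, name: str) -> bool:
        return name in set(self.nodes)

    def descendants(self, node: str) -> tuple[str, ...]:
        if node in self._descendants:
            return self._descendants[node]
        out: list[str] = []
        stack = list(self.children.get(node, ()))
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children.get(n, ()))
        result = tuple(out)
        self._descendants[node] = result
        return result

    def is_junction(self, name: str) -> bool:
        return name in self.junctions

    def top_level_of(self, node: str) -> str:
        """Return the top-level ancestor of a hierarchy node (identity on top level)."""
        seen = set()
        while node in self.parent:
            if node in seen:  # pragma: no cover - construction forbids cycles
                raise RegionDefinitionError(f"cycle through {node!r}")
            seen.add(node)
            node = self.parent[node]
        return node

    def validate_vector_keys(self, vector: Mapping[str, float]) -> None:
        known = set(self.nodes)
        unknown = [k for k in vector if k not in known]
        if unknown:
            raise KeyError(f"unknown region node(s): {sorted(unknown)}")


def _build_tree(spec: Mapping) -> RegionTree:
    top = tuple(spec.get("top_level", ()))
    if sorted(top) != sorted(TOP_LEVEL):
        raise RegionDefinitionError(
            f"top-level region set is fixed to {sorted(TOP_LEVEL)}; got {sorted(top)}"
        )
    children_raw = spec.get("children") or {}
    parent: dict[str, str] = {}
    children: dict[str, tuple[str, ...]] = {}
    for par, kids in children_raw.items():
        children[par] = tuple(kids)
        for kid in kids:
            if kid in parent:
                raise RegionDefinitionError(f"node {kid!r} has more than one parent")
            if kid in top:
                raise RegionDefinitionError(f"top-level node {kid!r} cannot be a child")
            parent[kid] = par
    # every non-top node must be reachable from a top-level root (no orphans/cycles)
    reachable: set[str] = set()
    for root in top:
        stack = list(children.get(root, ()))
        while stack:
            n = stack.pop()
            if n in reachable:
                raise RegionDefinitionError(f"cycle or duplicate path through {n!r}")
            reachable.add(n)
            stack.extend(children.get(n, ()))
    orphans = set(parent) - reachable
    if orphans:
        raise RegionDefinitionError(f"orphan node(s) not attached to a lobe: {sorted(orphans)}")

    temporal_kids = set(children.get("Temporal", ()))
    if not set(TEMPORAL_SUBREGIONS) <= temporal_kids:
        raise RegionDefinitionError(
            "Temporal must carry its five named subregions "
            f"{list(TEMPORAL_SUBREGIONS)}; got {sorted(temporal_kids)}"
        )

    junctions_raw = spec.get("junctions") or {}
    junctions: dict[str, tuple[str, ...]] = {}
    for name, constituents in junctions_raw.items():
        constituents = tuple(constituents)
        if not constituents:
            raise RegionDefinitionError(f"junction {name!r} has no constituents")
        bad = [c for c in constituents if c not in top]
        if bad:
            raise RegionDefinitionError(
                f"junction {name!r} constituents must be top-level regions; got {bad}"
            )
        junctions[name] = constituents

    standalone = tuple(spec.get("standalone") or ())
    return RegionTree(
        top_level=tuple(TOP_LEVEL),
        parent=parent,
        children=children,
        junctions=junctions,
        standalone=standalone,
    )


def load_region_tree(path=None) -> RegionTree:
    """Load a region tree from a YAML definition (the shipped default if *path* is None)."""
    if path is None:
        text = resources.files("semioloc.data").joinpath("regions.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    spec = yaml.safe_load(text)
    if not isinstance(spec, Mapping):
        raise RegionDefinitionError("region definition must be a mapping")
    return _build_tree(spec)


def default_region_tree() -> RegionTree:
    return load_region_tree(None)


def redistribute_junctions(
    vector: Mapping[str, float], tree: RegionTree
) -> dict[str, float]:
    """Replace junction weight by equal shares on the constituent lobes.

    A junction allocation of weight ``w`` over ``k`` constituents becomes
    ``w / k`` on each constituent top-level node; all other weight (including
    standalone nodes) is untouched.  Total weight is conserved exactly.
    """
    tree.validate_vector_keys(vector)
    out: dict[str, float] = {}
    for node, w in vector.items():
        if tree.is_junction(node):
            constituents = tree.junctions[node]
            share = w / len(constituents)
            for c in constituents:
                out[c] = out.get(c, 0.0) + share
        else:
            out[node] = out.get(node, 0.0) + float(w)
    return out


def rollup(vector: Mapping[str, float], node: str, tree: RegionTree) -> float:
    """Weight at *node* plus the weight of all its descendants."""
    if node not in tree:
        raise KeyError(f"unknown region node {node!r}")
    total = float(vector.get(node, 0.0))
    for d in tree.descendants(node):
        total += float(vector.get(d, 0.0))
    return total


def rollup_columns(tree: RegionTree, node: str) -> tuple[str, ...]:
    """Column names whose sum gives the rolled-up weight at *node*."""
    return (node, *tree.descendants(node))
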