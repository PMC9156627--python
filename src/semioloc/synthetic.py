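"""Synthetic literature-like cohorts with known ground truth.

The generator emulates the structure of a patient-level semiology-localization
literature database: articles with a study-design label, patients with 1-3
semiology categories, multi-one-hot localization allocations over a
hierarchical region tree, ground-truth flags, and — crucially — the selection
mechanism behind topological publication bias:

* a **non-topological** article samples each patient-semiology unit's category
  from the literature-wide semiology marginal and its region from the true
  conditional matrix P(region | semiology);
* a **topological** article first draws a focus region from a focus
  distribution (predominantly temporal), then samples each unit's category
  from the Bayes inversion P(semiology | focus) of the same truth and pins the
  unit's localization to the focus.

Because both arms share one conditional matrix, the non-topological subset is
an unbiased sample of the truth while the pooled data over-represent whatever
the focus distribution favours, letting every bias-mitigation stage of the
pipeline be tested against known parameters.

The default configuration reproduces the headline study conditions: a
non-topological regional marginal of 44% temporal / 31% frontal, a semiology
marginal matching the published frequencies of the twelve most common
categories (9.8% tonic, ..., 2.9% somatosensory, 34.5% spread over 23 rarer
categories), 75% of topological units localizing to the temporal lobe, and a
topological share of 71% so that the pooled temporal share is 66% by mixture
arithmetic (0.29*0.44 + 0.71*0.75 = 0.66).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import DatapointRecord

__all__ = [
    "SyntheticCohortConfig",
    "GeneratorTruth",
    "generate_cohort",
    "default_paper_like_config",
    "TRUE_REGIONS",
    "TABLE_CATEGORIES",
]

TRUE_REGIONS = (
    "Temporal",
    "Frontal",
    "Parietal",
    "Occipital",
    "Cingulate",
    "Insula",
    "Hypothalamus",
)

# the twelve most common ictal categories with their share of non-topological
# data, plus the mass carried by all rarer categories together
TABLE_CATEGORIES: dict[str, float] = {
    "Tonic": 0.098,
    "Oral and manual automatisms": 0.097,
    "Dialeptic-LOA-LOC": 0.083,
    "Epigastric": 0.061,
    "Vocalization": 0.055,
    "Autonomic": 0.047,
    "Olfactory": 0.046,
    "Head version": 0.043,
    "Dystonic": 0.034,
    "Other automatisms": 0.031,
    "Mimetic automatisms": 0.031,
    "Somatosensory": 0.029,
}
OTHER_MASS = 0.345
N_OTHER_CATEGORIES = 23

# true conditional rows P(region | semiology) for the twelve categories,
# columns ordered as TRUE_REGIONS; shaped after the published non-topological
# forest estimates, each row summing to 1
_TABLE_CONDITIONALS: dict[str, tuple[float, ...]] = {
    "Tonic":                       (0.20, 0.54, 0.08, 0.05, 0.07, 0.03, 0.03),
    "Oral and manual automatisms": (0.47, 0.31, 0.05, 0.04, 0.10, 0.02, 0.01),
    "Dialeptic-LOA-LOC":           (0.42, 0.28, 0.08, 0.09, 0.03, 0.02, 0.08),
    "Epigastric":                  (0.83, 0.05, 0.03, 0.02, 0.00, 0.05, 0.02),
    "Vocalization":                (0.36, 0.44, 0.05, 0.03, 0.09, 0.02, 0.01),
    "Autonomic":                   (0.58, 0.13, 0.04, 0.03, 0.02, 0.05, 0.15),
    "Olfactory":                   (0.40, 0.21, 0.28, 0.02, 0.02, 0.06, 0.01),
    "Head version":                (0.46, 0.33, 0.08, 0.06, 0.04, 0.02, 0.01),
    "Dystonic":                    (0.27, 0.53, 0.08, 0.04, 0.05, 0.02, 0.01),
    "Other automatisms":           (0.35, 0.11, 0.04, 0.03, 0.05, 0.01, 0.41),
    "Mimetic automatisms":         (0.20, 0.40, 0.06, 0.04, 0.26, 0.03, 0.01),
    "Somatosensory":               (0.31, 0.23, 0.38, 0.03, 0.01, 0.04, 0.00),
}

# unbiased regional marginal: temporal and frontal pinned at 44% / 31%, the
# remainder split over the other five regions (hypothalamus needs >= ~3.5%
# for the rare-category conditional row to stay non-negative, because the
# hypothalamus-heavy "other automatisms" row contributes strongly)
_REGION_MARGINAL: dict[str, float] = {
    "Temporal": 0.44,
    "Frontal": 0.31,
    "Parietal": 0.07,
    "Occipital": 0.06,
    "Cingulate": 0.05,
    "Insula": 0.03,
    "Hypothalamus": 0.04,
}

_TEMPORAL_SUBREGION_DIST: dict[str, float] = {
    "Mesial Temporal": 0.45,
    "Anterior Temporal": 0.20,
    "Lateral Temporal": 0.15,
    "Posterior Temporal": 0.12,
    "Basal Temporal": 0.08,
}

_TEXT_TEMPLATES: dict[str, str] = {
    "Tonic": "tonic stiffening of one or more limbs",
    "Oral and manual automatisms": "lip smacking and chewing",
    "Dialeptic-LOA-LOC": "blank stare with loss of awareness",
    "Epigastric": "epigastric rising sensation",
    "Vocalization": "unintelligible noises and grunting",
    "Autonomic": "autonomic features with flushing",
    "Olfactory": "ictal smell of burning",
    "Head version": "forced head deviation over the shoulder",
    "Dystonic": "dystonic posturing of the hand",
    "Other automatisms": "gelastic laughter",
    "Mimetic automatisms": "grimacing facial expressions",
    "Somatosensory": "tingling sensation of the arm",
}

_ATOL = 1e-9


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_articles: int
    patients_per_article: tuple[int, int]
    pi_topological: float
    focus_distribution: Mapping[str, float]
    true_conditional: Mapping[str, Mapping[str, float]]  # semiology -> region -> p
    semiology_marginal: Mapping[str, float]
    semiologies_per_patient: tuple[int, int] = (1, 3)
    p_multiregion: float = 0.2
    ground_truth_probs: Mapping[str, float] = field(
        default_factory=lambda: {"seizure_free": 0.5, "concordance": 0.5, "invasive": 0.3}
    )
    p_child_under_7: float = 0.05
    p_age_unknown: float = 0.20
    p_stimulation: float = 0.5          # split within topological articles
    p_temporal_subregion: float = 0.6   # chance a temporal allocation names a subregion
    temporal_subregion_distribution: Mapping[str, float] = field(
        default_factory=lambda: dict(_TEMPORAL_SUBREGION_DIST)
    )
    seed: int = 0

    def __post_init__(self):
        for name, lo_hi in (
            ("patients_per_article", self.patients_per_article),
            ("semiologies_per_patient", self.semiologies_per_patient),
        ):
            lo, hi = lo_hi
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range {lo_hi} is empty or invalid")
        if not 0.0 <= self.pi_topological <= 1.0:
            raise ValueError("pi_topological must be a probability")
        _check_dist("focus_distribution", self.focus_distribution)
        _check_dist("semiology_marginal", self.semiology_marginal)
        _check_dist(
            "temporal_subregion_distribution", self.temporal_subregion_distribution
        )
        for s, row in self.true_conditional.items():
            _check_dist(f"true_conditional[{s!r}]", row)
        missing = set(self.semiology_marginal) - set(self.true_conditional)
        if missing:
            raise ValueError(f"semiologies without a conditional row: {sorted(missing)}")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.semiology_marginal)

    @property
    def regions(self) -> tuple[str, ...]:
        first = next(iter(self.true_conditional.values()))
        return tuple(first)

    def region_marginal(self) -> dict[str, float]:
        """Unbiased (non-topological) regional marginal implied by the mixture."""
        out = {r: 0.0 for r in self.regions}
        for s, p_s in self.semiology_marginal.items():
            for r, p_r in self.true_conditional[s].items():
                out[r] += p_s * p_r
        return out


def _check_dist(name: str, dist: Mapping[str, float]) -> None:
    vals = np.array(list(dist.values()), dtype=float)
    if vals.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any(vals < -_ATOL):
        raise ValueError(f"{name} has negative entries")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} sums to {vals.sum():.8f}, expected 1")


@dataclass(frozen=True)
class GeneratorTruth:
    true_conditional: pd.DataFrame       # categories x regions
    region_marginal: dict                # unbiased marginal over regions
    pooled_region_marginal: dict         # expected all-data marginal
    focus_distribution: dict
    pi_topological: float
    category_unit_counts: dict           # realized units per category
    n_patients: int
    n_articles: int
    seed: int

    def to_json(self) -> str:
        payload = {
            "true_conditional": {
                s: dict(row) for s, row in self.true_conditional.iterrows()
            },
            "region_marginal": self.region_marginal,
            "pooled_region_marginal": self.pooled_region_marginal,
            "focus_distribution": self.focus_distribution,
            "pi_topological": self.pi_topological,
            "category_unit_counts": self.category_unit_counts,
            "n_patients": self.n_patients,
            "n_articles": self.n_articles,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)


def default_paper_like_config(n_articles: int = 222, seed: int = 0) -> SyntheticCohortConfig:
    """Study-condition defaults; ~5,000 patients at the default article count.

    The conditional row shared by the 23 rarer categories is solved from the
    constraint that the semiology mixture reproduce the unbiased regional
    marginal exactly: row_other = (marginal - sum_12 P(s) row_s) / 0.345.
    """
    contrib = {r: 0.0 for r in TRUE_REGIONS}
    for s, p_s in TABLE_CATEGORIES.items():
        for r, p_r in zip(TRUE_REGIONS, _TABLE_CONDITIONALS[s]):
            contrib[r] += p_s * p_r
    other_row = {}
    for r in TRUE_REGIONS:
        v = (_REGION_MARGINAL[r] - contrib[r]) / OTHER_MASS
        if v < -_ATOL:
            raise ValueError(
                f"infeasible residual conditional for region {r!r} ({v:.4f} < 0)"
            )
        other_row[r] = max(v, 0.0)
    total = sum(other_row.values())
    other_row = {r: v / total for r, v in other_row.items()}  # exact renormalization

    marginal: dict[str, float] = dict(TABLE_CATEGORIES)
    conditional: dict[str, dict[str, float]] = {
        s: dict(zip(TRUE_REGIONS, row)) for s, row in _TABLE_CONDITIONALS.items()
    }
    for i in range(1, N_OTHER_CATEGORIES + 1):
        name = f"Other semiology {i:02d}"
        marginal[name] = OTHER_MASS / N_OTHER_CATEGORIES
        conditional[name] = dict(other_row)

    focus = {
        "Temporal": 0.75,
        "Frontal": 0.10,
        "Parietal": 0.02,
        "Occipital": 0.05,
        "Cingulate": 0.01,
        "Insula": 0.05,
        "Hypothalamus": 0.02,
    }
    return SyntheticCohortConfig(
        n_articles=n_articles,
        patients_per_article=(5, 40),
        pi_topological=0.71,
        focus_distribution=focus,
        true_conditional=conditional,
        semiology_marginal=marginal,
        seed=seed,
    )


def _bayes_invert(
    config: SyntheticCohortConfig, focus: str, cats: Sequence[str]
) -> np.ndarray:
    """P(semiology | focus) proportional to P(focus | semiology) * P(semiology)."""
    w = np.array(
        [config.true_conditional[s].get(focus, 0.0) * config.semiology_marginal[s] for s in cats]
    )
    total = w.sum()
    if total <= 0:
        raise ValueError(f"Bayes inversion infeasible: no semiology localizes to {focus!r}")
    return w / total


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[DatapointRecord], GeneratorTruth]:
    """Draw a full cohort; deterministic given config (which carries the seed)."""
    rng = np.random.default_rng(config.seed)
    cats = list(config.categories)
    regions = list(config.regions)
    cond_rows = {
        s: np.array([config.true_conditional[s].get(r, 0.0) for r in regions])
        for s in cats
    }
    marginal_vec = np.array([config.semiology_marginal[s] for s in cats])
    marginal_vec = marginal_vec / marginal_vec.sum()
    focus_names = [r for r, p in config.focus_distribution.items() if p > 0]
    focus_vec = np.array([config.focus_distribution[r] for r in focus_names])
    focus_vec = focus_vec / focus_vec.sum()
    inverted = {f: _bayes_invert(config, f, cats) for f in focus_names}
    sub_names = list(config.temporal_subregion_distribution)
    sub_vec = np.array([config.temporal_subregion_distribution[s] for s in sub_names])
    sub_vec = sub_vec / sub_vec.sum()
    gt_p = config.ground_truth_probs
    age_p = np.array(
        [1.0 - config.p_child_under_7 - config.p_age_unknown,
         config.p_child_under_7, config.p_age_unknown]
    )
    age_labels = ["adult", "child_under_7", "unknown"]

    records: list[DatapointRecord] = []
    counts: dict[str, int] = {}
    n_patients = 0

    def refine(region: str) -> str:
        if region == "Temporal" and rng.random() < config.p_temporal_subregion:
            return sub_names[rng.choice(len(sub_names), p=sub_vec)]
        return region

    for a in range(config.n_articles):
        article_id = f"A{a:04d}"
        year = int(rng.integers(1954, 2022))
        is_topo = rng.random() < config.pi_topological
        if is_topo:
            focus = focus_names[rng.choice(len(focus_names), p=focus_vec)]
            label = "stimulation" if rng.random() < config.p_stimulation else "epilepsy_topology"
            cat_probs = inverted[focus]
        else:
            focus = None
            label = "spontaneous"
            cat_probs = marginal_vec
        lo, hi = config.patients_per_article
        n_pat = int(rng.integers(lo, hi + 1))
        for p in range(n_pat):
            n_patients += 1
            patient_id = f"P{p:03d}"
            k_lo, k_hi = config.semiologies_per_patient
            k = int(rng.integers(k_lo, min(k_hi, len(cats)) + 1))
            chosen = rng.choice(len(cats), size=k, replace=False, p=cat_probs)
            # ground truths: independent flags, redrawn until at least one holds
            while True:
                gts = {
                    "seizure_free": rng.random() < gt_p["seizure_free"],
                    "concordance": rng.random() < gt_p["concordance"],
                    "invasive": rng.random() < gt_p["invasive"],
                }
                if any(gts.values()):
                    break
            age = age_labels[rng.choice(3, p=age_p)]
            for ci in chosen:
                s = cats[ci]
                counts[s] = counts.get(s, 0) + 1
                if is_topo:
                    alloc_regions = [refine(focus)]
                else:
                    r1 = regions[rng.choice(len(regions), p=cond_rows[s])]
                    alloc_regions = [refine(r1)]
                    if rng.random() < config.p_multiregion:
                        r2 = regions[rng.choice(len(regions), p=cond_rows[s])]
                        alloc_regions.append(refine(r2))
                locs: dict[str, float] = {}
                for node in alloc_regions:
                    locs[node] = locs.get(node, 0.0) + 1.0
                records.append(
                    DatapointRecord(
                        patient_id=patient_id,
                        article_id=article_id,
                        year=year,
                        semiology_text=_TEXT_TEMPLATES.get(s, "unlisted ictal phenomenon"),
                        semiology_category=s,
                        localizations=locs,
                        gt_seizure_free=gts["seizure_free"],
                        gt_concordance=gts["concordance"],
                        gt_invasive=gts["invasive"],
                        topological=label,
                        age_label=age,
                    )
                )

    region_marginal = config.region_marginal()
    pooled = {
        r: (1.0 - config.pi_topological) * region_marginal.get(r, 0.0)
        + config.pi_topological * config.focus_distribution.get(r, 0.0)
        for r in regions
    }
    truth = GeneratorTruth(
        true_conditional=pd.DataFrame(
            {s: cond_rows[s] for s in cats}, index=regions
        ).T,
        region_marginal=region_marginal,
        pooled_region_marginal=pooled,
        focus_distribution=dict(config.focus_distribution),
        pi_topological=config.pi_topological,
        category_unit_counts=counts,
        n_patients=n_patients,
        n_articles=config.n_articles,
        seed=config.seed,
    )
    return records, truth
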