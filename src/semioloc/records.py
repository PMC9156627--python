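"""Canonical patient-semiology record schema and tabular IO.

One record is a single patient-semiology observation extracted from the
literature: free text plus (optionally pre-assigned) category, raw multi-one-hot
localization allocations over region nodes, ground-truth flags, the study-design
label used for publication-bias filtering, and age/laterality metadata.

Canonical storage is one row per (patient, semiology) with wide region columns;
CSV and TSV are first-class, XLSX is accepted through the same logical schema.

Inclusion rule: a record must carry at least one of the three ground truths
(postsurgical seizure-freedom, imaging/neurophysiology concordance, invasive
SEEG/stimulation).  Rows failing the rule are collected as validation errors,
not accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import RegionTree, default_region_tree

__all__ = [
    "DatapointRecord",
    "ValidationReport",
    "SchemaError",
    "read_database",
    "write_database",
    "records_to_frame",
    "frame_to_records",
    "validate_records",
    "filter_subset",
]

TOPOLOGICAL_LABELS = ("epilepsy_topology", "stimulation", "spontaneous")
AGE_LABELS = ("adult", "child_under_7", "unknown")
LATERALITY_SEMIOLOGY = ("ipsilateral", "contralateral", "unknown")
LATERALITY_DOMINANCE = ("dominant", "non_dominant", "unknown")

META_COLUMNS = [
    "patient_id",
    "article_id",
    "year",
    "semiology_text",
    "semiology_category",
    "topological",
    "gt_seizure_free",
    "gt_concordance",
    "gt_invasive",
    "age_label",
    "laterality_semiology",
    "laterality_dominance",
]


class SchemaError(ValueError):
    """Input table does not match the canonical schema."""


@dataclass(frozen=True)
class DatapointRecord:
    patient_id: str
    article_id: str
    semiology_text: str = ""
    semiology_category: str | None = None
    year: int | None = None
    localizations: Mapping[str, float] = field(default_factory=dict)
    gt_seizure_free: bool = False
    gt_concordance: bool = False
    gt_invasive: bool = False
    topological: str = "spontaneous"
    age_label: str = "unknown"
    laterality_semiology: str = "unknown"
    laterality_dominance: str = "unknown"

    def __post_init__(self):
        if self.topological not in TOPOLOGICAL_LABELS:
            raise ValueError(f"unknown topological label {self.topological!r}")
        if self.age_label not in AGE_LABELS:
            raise ValueError(f"unknown age label {self.age_label!r}")

    @property
    def is_topological(self) -> bool:
        return self.topological != "spontaneous"

    @property
    def has_ground_truth(self) -> bool:
        return self.gt_seizure_free or self.gt_concordance or self.gt_invasive

    @property
    def patient_key(self) -> tuple[str, str]:
        """Patients are unique within an article only."""
        return (self.article_id, self.patient_id)

    @property
    def total_allocation(self) -> float:
        return float(sum(self.localizations.values()))


@dataclass
class ValidationReport:
    n_records: int = 0
    n_patients: int = 0
    n_articles: int = 0
    errors: list = field(default_factory=list)    # (row, rule, message)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# frame conversion

_BOOL_TRUE = {"true", "1", "yes", "y", "t"}


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in _BOOL_TRUE


def records_to_frame(records: Sequence[DatapointRecord], tree: RegionTree | None = None) -> pd.DataFrame:
    tree = tree or default_region_tree()
    region_cols = [n for n in tree.nodes]
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "article_id": rec.article_id,
            "year": rec.year,
            "semiology_text": rec.semiology_text,
            "semiology_category": rec.semiology_category or "",
            "topological": rec.topological,
            "gt_seizure_free": rec.gt_seizure_free,
            "gt_concordance": rec.gt_concordance,
            "gt_invasive": rec.gt_invasive,
            "age_label": rec.age_label,
            "laterality_semiology": rec.laterality_semiology,
            "laterality_dominance": rec.laterality_dominance,
        }
        for col in region_cols:
            row[col] = rec.localizations.get(col, 0.0)
        rows.append(row)
    return pd.DataFrame(rows, columns=META_COLUMNS + region_cols)


def frame_to_records(
    df: pd.DataFrame, tree: RegionTree | None = None
) -> tuple[list[DatapointRecord], ValidationReport]:
    """Convert a canonical wide table to records, applying inclusion rules.

    Rows with no true ground-truth flag are rejected into the report's error
    list.  Duplicate (patient, semiology) rows are merged by summing their
    allocations, with a warning.
    """
    tree = tree or default_region_tree()
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    known_regions = set(tree.nodes)
    region_cols = [c for c in df.columns if c not in META_COLUMNS]
    unknown = [c for c in region_cols if c not in known_regions]
    if unknown:
        raise SchemaError(f"unknown region column(s): {unknown}")

    report = ValidationReport()
    by_key: dict[tuple, DatapointRecord] = {}
    for idx, row in df.iterrows():
        gt = (_as_bool(row["gt_seizure_free"]), _as_bool(row["gt_concordance"]), _as_bool(row["gt_invasive"]))
        if not any(gt):
            report.errors.append(
                (int(idx), "ground_truth", "record carries none of the three ground truths")
            )
            continue
        year_val = row["year"]
        year = None if pd.isna(year_val) or year_val == "" else int(year_val)
        cat = row["semiology_category"]
        cat = None if (pd.isna(cat) or str(cat).strip() == "") else str(cat)
        locs = {}
        for col in region_cols:
            v = row[col]
            if pd.notna(v) and float(v) != 0.0:
                if float(v) < 0:
                    report.errors.append((int(idx), "allocation", f"negative allocation on {col!r}"))
                locs[col] = float(v)
        rec = DatapointRecord(
            patient_id=str(row["patient_id"]),
            article_id=str(row["article_id"]),
            year=year,
            semiology_text="" if pd.isna(row["semiology_text"]) else str(row["semiology_text"]),
            semiology_category=cat,
            localizations=locs,
            gt_seizure_free=gt[0],
            gt_concordance=gt[1],
            gt_invasive=gt[2],
            topological=str(row["topological"]),
            age_label=str(row["age_label"]),
            laterality_semiology=str(row["laterality_semiology"]),
            laterality_dominance=str(row["laterality_dominance"]),
        )
        key = (rec.article_id, rec.patient_id, rec.semiology_category, rec.semiology_text)
        if key in by_key:
            prev = by_key[key]
            merged = dict(prev.localizations)
            for k, v in rec.localizations.items():
                merged[k] = merged.get(k, 0.0) + v
            by_key[key] = DatapointRecord(
                **{**_record_kwargs(prev), "localizations": merged}
            )
            report.warnings.append(
                (int(idx), "duplicate", f"duplicate (patient, semiology) row merged: {key[:3]}")
            )
        else:
            by_key[key] = rec
    records = list(by_key.values())
    report.n_records = len(records)
    report.n_patients = len({r.patient_key for r in records})
    report.n_articles = len({r.article_id for r in records})
    return records, report


def _record_kwargs(rec: DatapointRecord) -> dict:
    d = asdict(rec)
    return d


# ---------------------------------------------------------------------------
# file IO

_DIALECTS = ("csv", "tsv", "xlsx")


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "tab"):
        return "tsv"
    if suffix in ("xlsx", "xls"):
        return "xlsx"
    return "csv"


def read_database(
    path, dialect: str | None = None, tree: RegionTree | None = None
) -> tuple[list[DatapointRecord], ValidationReport]:
    """Read a database export; returns accepted records plus the validation report."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    if dialect == "xlsx":
        df = pd.read_excel(path)
    else:
        sep = "\t" if dialect == "tsv" else ","
        df = pd.read_csv(path, sep=sep, comment="#")
    return frame_to_records(df, tree=tree)


def write_database(
    records: Sequence[DatapointRecord], path, dialect: str | None = None,
    tree: RegionTree | None = None,
) -> None:
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    df = records_to_frame(records, tree=tree)
    if dialect == "xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, sep="\t" if dialect == "tsv" else ",", index=False)


# ---------------------------------------------------------------------------
# validation & filtering

def validate_records(records: Sequence[DatapointRecord]) -> ValidationReport:
    """Report-only audit: counts plus localization / consistency checks."""
    report = ValidationReport(
        n_records=len(records),
        n_patients=len({r.patient_key for r in records}),
        n_articles=len({r.article_id for r in records}),
    )
    seen: set[tuple] = set()
    article_labels: dict[str, set[str]] = {}
    for i, rec in enumerate(records):
        if rec.total_allocation <= 0:
            report.errors.append((i, "no_localization", f"record {rec.patient_key} has no localization"))
        if not rec.has_ground_truth:
            report.errors.append((i, "ground_truth", f"record {rec.patient_key} has no ground truth"))
        key = (rec.article_id, rec.patient_id, rec.semiology_category)
        if key in seen:
            report.warnings.append((i, "duplicate", f"duplicated (patient, semiology): {key}"))
        seen.add(key)
        article_labels.setdefault(rec.article_id, set()).add(
            "topological" if rec.is_topological else "non_topological"
        )
    for article, labels in article_labels.items():
        if len(labels) > 1:
            report.warnings.append(
                (None, "mixed_topology", f"article {article!r} mixes topological and non-topological labels")
            )
    return report


_FILTER_KEYS = {"topological_in", "ground_truth_any_of", "exclude_age"}
_GT_FLAGS = {"seizure_free": "gt_seizure_free", "concordance": "gt_concordance", "invasive": "gt_invasive"}


def filter_subset(records: Iterable[DatapointRecord], **filters) -> list[DatapointRecord]:
    """Keep records satisfying all provided filters.

    ``topological_in``: iterable of study-design labels to keep.
    ``ground_truth_any_of``: disjunction over {'seizure_free','concordance','invasive'}.
    ``exclude_age``: drop records labelled child_under_7 (unknown ages retained).
    """
    unknown = set(filters) - _FILTER_KEYS
    if unknown:
        raise ValueError(f"unknown filter key(s): {sorted(unknown)}")
    topological_in = filters.get("topological_in")
    if topological_in is not None:
        topological_in = set(topological_in)
        bad = topological_in - set(TOPOLOGICAL_LABELS)
        if bad:
            raise ValueError(f"unknown topological label(s): {sorted(bad)}")
    gt_any = filters.get("ground_truth_any_of")
    if gt_any is not None:
        gt_any = list(gt_any)
        bad = [g for g in gt_any if g not in _GT_FLAGS]
        if bad:
            raise ValueError(f"unknown ground-truth flag(s): {bad}")
    exclude_age = bool(filters.get("exclude_age", False))

    out = []
    for rec in records:
        if topological_in is not None and rec.topological not in topological_in:
            continue
        if gt_any is not None and not any(getattr(rec, _GT_FLAGS[g]) for g in gt_any):
            continue
        if exclude_age and rec.age_label == "child_under_7":
            continue
        out.append(rec)
    return out
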