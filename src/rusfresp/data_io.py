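"""Typed sample-by-feature tables, readers/writers, and pre-model filtering.

Tables are thin wrappers around :class:`pandas.DataFrame` keyed by a
``(subject_id, timepoint)`` MultiIndex.  Time points are the study's four
nominal stool-collection ages in months (9 pre-intervention; 12, 13 and 18
post-intervention); real visit ages are snapped to the nearest nominal age
within a configurable tolerance.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    EmptyAfterFilterError,
    KeyedDuplicateError,
    ValidationError,
)

NOMINAL_TIMEPOINTS: tuple[int, ...] = (9, 12, 13, 18)
TAXONOMIC_RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

_KEY_NAMES = ("subject_id", "timepoint")


class SampleKey(NamedTuple):
    subject_id: str
    timepoint: int


@dataclass(frozen=True)
class GroupLabel:
    """Study-arm label: well-nourished control, RUSF responder or nonresponder.

    ``inflamed`` marks the systemically inflamed nonresponder subgroup and is
    only meaningful for nonresponders.
    """

    value: Literal["control", "responder", "nonresponder"]
    inflamed: bool = False

    def __post_init__(self) -> None:
        if self.value not in ("control", "responder", "nonresponder"):
            raise ValidationError(f"unknown group label: {self.value!r}")
        if self.inflamed and self.value != "nonresponder":
            raise ValidationError("inflamed flag is only valid for nonresponders")


def snap_timepoint(age_months: float, tolerance: float = 1.0) -> int:
    """Map a real visit age to the nearest nominal time point within tolerance."""
    nominal = min(NOMINAL_TIMEPOINTS, key=lambda t: abs(t - age_months))
    if abs(nominal - age_months) > tolerance:
        raise ValidationError(
            f"visit age {age_months} months is not within {tolerance} months of "
            f"any nominal time point {NOMINAL_TIMEPOINTS}"
        )
    return int(nominal)


def _validate_keyed_index(df: pd.DataFrame) -> None:
    if list(df.index.names) != list(_KEY_NAMES):
        raise ValidationError(
            f"index must be a (subject_id, timepoint) MultiIndex, got {df.index.names}"
        )
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise KeyedDuplicateError(f"duplicate (subject, timepoint) keys: {dupes}")
    if df.columns.duplicated().any():
        raise ValidationError("feature names must be unique")


class _KeyedTable:
    """Shared behaviour for sample-keyed feature tables."""

    def __init__(self, data: pd.DataFrame):
        _validate_keyed_index(data)
        self.data = data

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey(str(s), int(t)) for s, t in self.data.index]

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(str(s) for s, _ in self.data.index))

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def at_timepoint(self, timepoint: int):
        sub = self.data.xs(timepoint, level="timepoint", drop_level=False)
        return type(self)(sub)

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.n_samples} samples x {len(self.data.columns)} features)"


class BiomarkerTable(_KeyedTable):
    """Samples x named biomarkers; real-valued, missing values allowed pre-filter."""

    def __init__(self, data: pd.DataFrame):
        data = data.astype(float)
        super().__init__(data)

    @property
    def markers(self) -> list[str]:
        return self.features


class AsvCountTable(_KeyedTable):
    """Samples x ASV (or aggregated-taxon) non-negative integer counts."""

    def __init__(self, data: pd.DataFrame):
        arr = data.to_numpy()
        if not np.issubdtype(np.asarray(arr).dtype, np.number):
            raise ValidationError("ASV counts must be numeric")
        if np.isnan(arr.astype(float)).any():
            raise ValidationError("ASV counts must not be missing")
        if (arr.astype(float) % 1 != 0).any():
            raise ValidationError("ASV counts must be integers")
        if (arr < 0).any():
            raise ValidationError("ASV counts must be non-negative")
        super().__init__(data.astype(np.int64))

    @property
    def total_reads(self) -> pd.Series:
        return self.data.sum(axis=1)


class TaxonomyMap:
    """ASV id -> (phylum, class, order, family, genus); any level may be unassigned."""

    def __init__(self, data: pd.DataFrame):
        missing = [r for r in TAXONOMIC_RANKS if r not in data.columns]
        if missing:
            raise ValidationError(f"taxonomy table lacks rank columns: {missing}")
        data = data[list(TAXONOMIC_RANKS)].astype(str)
        data = data.replace({"": UNASSIGNED, "nan": UNASSIGNED, "NA": UNASSIGNED})
        if data.index.duplicated().any():
            raise KeyedDuplicateError("duplicate ASV ids in taxonomy")
        self.data = data

    def rank_labels(self, asv_ids: Iterable[str], rank: str) -> pd.Series:
        """Rank label per ASV; ids absent from the map come back unassigned."""
        if rank not in TAXONOMIC_RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {TAXONOMIC_RANKS}")
        ids = list(asv_ids)
        out = self.data[rank].reindex(ids).fillna(UNASSIGNED)
        out.index = ids
        return out

    def covers(self, asv_ids: Iterable[str]) -> bool:
        return set(asv_ids) <= set(self.data.index)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonomyMap) and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# Readers / writers (TSV or CSV, sniffed from the extension)


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_table(
    path: str | Path, kind: Literal["biomarker", "asv"]
) -> BiomarkerTable | AsvCountTable:
    """Read a delimited feature table whose first two columns are the sample key.

    Biomarker tables record unparsable numeric cells as missing; ASV tables
    reject missing, negative or non-integer values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), dtype={0: str})
    if df.shape[1] < 3:
        raise ValidationError("expected subject id, timepoint, and >=1 feature column")
    df = df.rename(columns={df.columns[0]: "subject_id", df.columns[1]: "timepoint"})
    df["timepoint"] = df["timepoint"].astype(float).round().astype(int)
    df = df.set_index(["subject_id", "timepoint"])
    if kind == "biomarker":
        df = df.apply(pd.to_numeric, errors="coerce")
        return BiomarkerTable(df)
    if kind == "asv":
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric ASV count: {exc}") from exc
        return AsvCountTable(df)
    raise ValidationError(f"unknown table kind {kind!r}")


def write_feature_table(table: _KeyedTable, path: str | Path) -> None:
    table.data.to_csv(path, sep=_sep_for(path))


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return TaxonomyMap(df)


def write_taxonomy(taxonomy: TaxonomyMap, path: str | Path) -> None:
    df = taxonomy.data.copy()
    df.index.name = "asv_id"
    df.to_csv(path, sep=_sep_for(path))


# ---------------------------------------------------------------------------
# Complete-case filtering (applied before biomarker modeling)


@dataclass
class FilterReport:
    dropped_markers: list[str] = field(default_factory=list)
    dropped_samples: list[SampleKey] = field(default_factory=list)


def filter_complete_cases(
    table: BiomarkerTable,
    max_missing_frac_per_marker: float = 0.2,
    max_missing_frac_per_sample: float = 0.1,
) -> tuple[BiomarkerTable, FilterReport]:
    """Two-pass complete-case filter.

    First drops markers missing in more than the marker-level fraction of
    samples, then samples missing more than the sample-level fraction of the
    surviving markers, then any residual incomplete rows.  The result has no
    missing values.
    """
    for frac in (max_missing_frac_per_marker, max_missing_frac_per_sample):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("missingness thresholds must lie in [0, 1]")
    df = table.data
    marker_missing = df.isna().mean(axis=0)
    keep_markers = marker_missing[marker_missing <= max_missing_frac_per_marker].index
    report = FilterReport(dropped_markers=[m for m in df.columns if m not in set(keep_markers)])
    df = df[list(keep_markers)]
    if df.shape[1] == 0:
        raise EmptyAfterFilterError("all markers exceeded the missingness threshold")

    sample_missing = df.isna().mean(axis=1)
    keep = sample_missing <= max_missing_frac_per_sample
    # residual incomplete rows go too: the model requires complete cases
    keep &= df.notna().all(axis=1)
    report.dropped_samples = [SampleKey(str(s), int(t)) for s, t in df.index[~keep]]
    df = df[keep]
    if df.shape[0] == 0:
        raise EmptyAfterFilterError("all samples exceeded the missingness threshold")
    return BiomarkerTable(df), report


# ---------------------------------------------------------------------------
# Sample alignment across data modalities


@dataclass
class AlignedData:
    biomarkers: BiomarkerTable
    asv: AsvCountTable
    growth: dict[str, "object"]
    subjects: list[str]
    dropped_biomarker_subjects: list[str]
    dropped_asv_subjects: list[str]
    dropped_growth_subjects: list[str]
    timepoint: int


def align_samples(
    biomarkers: BiomarkerTable,
    asv: AsvCountTable,
    growth: dict[str, "object"],
    timepoint: int,
) -> AlignedData:
    """Inner-join the three data modalities on subject at one time point."""

    def _subjects_at(table: _KeyedTable) -> set[str]:
        idx = table.data.index
        mask = idx.get_level_values("timepoint") == timepoint
        return {str(s) for s in idx.get_level_values("subject_id")[mask]}

    bio_subj = _subjects_at(biomarkers)
    asv_subj = _subjects_at(asv)
    growth_subj = set(growth)
    shared = sorted(bio_subj & asv_subj & growth_subj)
    if not shared:
        raise AlignmentError(f"no subjects shared across tables at {timepoint} months")

    def _take(table, cls):
        df = table.data
        mask = (df.index.get_level_values("timepoint") == timepoint) & df.index.get_level_values(
            "subject_id"
        ).isin(shared)
        return cls(df[mask].sort_index())

    return AlignedData(
        biomarkers=_take(biomarkers, BiomarkerTable),
        asv=_take(asv, AsvCountTable),
        growth={s: growth[s] for s in shared},
        subjects=shared,
        dropped_biomarker_subjects=sorted(bio_subj - set(shared)),
        dropped_asv_subjects=sorted(asv_subj - set(shared)),
        dropped_growth_subjects=sorted(growth_subj - set(shared)),
        timepoint=timepoint,
    )
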