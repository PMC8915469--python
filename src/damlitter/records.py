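"""Isolation records, sample metadata and binary genus-pattern encoding.

Culture-based microbiota profiling yields, per sample, a list of bacterial
genera (optionally species) identified from colonies, each with a coarse
CFU growth class. The analysis operates on the *codified pattern*: a binary
vector over the dataset-wide genus universe, 1 where the genus was isolated
at least once in that sample. Species strings and growth classes are kept
as metadata but never enter the pattern.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DamlitterError(Exception):
    """Base class for package errors."""


class ValidationError(DamlitterError, ValueError):
    """Invalid value or violated invariant."""


class ParseError(DamlitterError, ValueError):
    """Malformed input table; message names the offending row."""


class SubjectRole(str, Enum):
    DAM = "dam"
    PUPPY = "puppy"


class MatrixType(str, Enum):
    """Sampling matrix. Colostrum (T0) and milk (T2) are one category,
    ``mammary_secretion``, distinguished by time point."""

    RECTAL = "rectal"
    MECONIUM = "meconium"
    VAGINAL = "vaginal"
    MAMMARY_SECRETION = "mammary_secretion"


class TimePoint(str, Enum):
    """Sampling occasions: birth and days 2, 30 and 60 post-partum."""

    T0 = "T0"
    T2 = "T2"
    T30 = "T30"
    T60 = "T60"


#: Chronological order of the sampling occasions.
TIME_ORDER: tuple[TimePoint, ...] = (
    TimePoint.T0,
    TimePoint.T2,
    TimePoint.T30,
    TimePoint.T60,
)

#: Time points compared against birth by the convergence statistics.
POST_BIRTH: tuple[TimePoint, ...] = (TimePoint.T2, TimePoint.T30, TimePoint.T60)


class GrowthClass(str, Enum):
    """Semi-quantitative CFU classification of first-isolation plates."""

    NO_GROWTH = "no_growth"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    UNCLASSIFIED = "unclassified"


def classify_growth(cfu_count: int) -> GrowthClass:
    """Classify a colony count per 10 uL of plated suspension.

    0 colonies -> no_growth; 1-10 -> low; 11-30 -> moderate; >=31 -> high.
    """
    if isinstance(cfu_count, bool) or not isinstance(cfu_count, (int, np.integer)):
        raise ValidationError(f"cfu_count must be an integer, got {cfu_count!r}")
    if cfu_count < 0:
        raise ValidationError(f"cfu_count must be non-negative, got {cfu_count}")
    if cfu_count == 0:
        return GrowthClass.NO_GROWTH
    if cfu_count <= 10:
        return GrowthClass.LOW
    if cfu_count <= 30:
        return GrowthClass.MODERATE
    return GrowthClass.HIGH


_SPP_SUFFIX = re.compile(r"\s+(spp?\.?)$", re.IGNORECASE)


def canonicalize_genus(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a genus string: trim, collapse whitespace, strip a trailing
    ``spp.``/``sp.``, capitalize. An optional synonym map (applied to the
    trimmed input, e.g. ``{"E. coli": "Escherichia"}``) takes precedence."""
    raw = " ".join(str(name).split())
    if not raw:
        raise ValidationError("genus name is empty")
    if synonyms and raw in synonyms:
        raw = synonyms[raw]
    raw = _SPP_SUFFIX.sub("", raw).strip()
    if not raw:
        raise ValidationError(f"genus name {name!r} empty after normalization")
    return raw[0].upper() + raw[1:].lower()


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one bacteriological sample.

    A *family* is a dam-litter unit: the mother plus her puppies, the
    grouping level of every statistic downstream.
    """

    sample_id: str
    family_id: str
    subject_id: str
    subject_role: SubjectRole
    matrix: MatrixType
    time_point: TimePoint

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if self.matrix is MatrixType.MECONIUM and not (
            self.subject_role is SubjectRole.PUPPY and self.time_point is TimePoint.T0
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: meconium is only valid for a puppy at T0"
            )
        if self.matrix in (MatrixType.VAGINAL, MatrixType.MAMMARY_SECRETION) and not (
            self.subject_role is SubjectRole.DAM
            and self.time_point in (TimePoint.T0, TimePoint.T2)
        ):
            raise ValidationError(
                f"sample {self.sample_id!r}: {self.matrix.value} is only valid "
                "for a dam at T0 or T2"
            )


@dataclass(frozen=True)
class IsolationRecord:
    """One identified isolate in one sample."""

    sample_id: str
    genus: str
    species: str | None = None
    growth: GrowthClass = GrowthClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.genus:
            raise ValidationError("genus must be non-empty")


@dataclass
class PresenceMatrix:
    """Samples x genus-universe binary table (the codified 1/0 patterns)."""

    sample_ids: list[str]
    genera: list[str]
    values: np.ndarray  # shape (n_samples, n_genera), dtype int8, entries 0/1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, g = self.values.shape
        if n != len(self.sample_ids) or g != len(self.genera):
            raise ValidationError("matrix shape does not match labels")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample_id in presence matrix")
        if len(set(self.genera)) != g:
            raise ValidationError("duplicate genus in presence matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("presence matrix cells must be 0 or 1")

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.genera)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


#: Default column names of the long-format isolation table.
DEFAULT_SCHEMA: dict[str, str] = {
    "sample_id": "sample_id",
    "family_id": "family_id",
    "subject_id": "subject_id",
    "subject_role": "subject_role",
    "matrix": "matrix",
    "time_point": "time_point",
    "genus": "genus",
    "species": "species",
    "growth": "growth",
}

_REQUIRED_COLUMNS = ("sample_id", "family_id", "subject_id", "subject_role",
                     "matrix", "time_point", "genus")


def _parse_enum(enum_cls, value: str, row: int, what: str):
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise ParseError(
            f"row {row}: unknown {what} {value!r} (allowed: {allowed})"
        ) from None


def read_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str | None = None,
    genus_synonyms: Mapping[str, str] | None = None,
) -> tuple[list[SampleMeta], list[IsolationRecord]]:
    """Read a long-format isolation table (CSV or TSV).

    One row per (sample, genus) isolation; a row with a blank genus declares
    a sample with no growth (metadata only, yielding an all-zero pattern).
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                             keep_default_na=False)
        else:
            df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed table
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    missing = [colmap[k] for k in _REQUIRED_COLUMNS if colmap[k] not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {', '.join(missing)}")

    samples: dict[str, SampleMeta] = {}
    records: list[IsolationRecord] = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, raw))
        sid = rowd[colmap["sample_id"]].strip()
        if not sid:
            raise ParseError(f"row {i}: empty sample_id")
        try:
            meta = SampleMeta(
                sample_id=sid,
                family_id=rowd[colmap["family_id"]].strip(),
                subject_id=rowd[colmap["subject_id"]].strip(),
                subject_role=_parse_enum(
                    SubjectRole, rowd[colmap["subject_role"]].strip(), i, "subject_role"),
                matrix=_parse_enum(
                    MatrixType, rowd[colmap["matrix"]].strip(), i, "matrix"),
                time_point=_parse_enum(
                    TimePoint, rowd[colmap["time_point"]].strip(), i, "time_point"),
            )
        except ValidationError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        if sid in samples:
            if samples[sid] != meta:
                raise ParseError(
                    f"row {i}: sample_id {sid!r} repeated with conflicting metadata")
        else:
            samples[sid] = meta

        genus_raw = rowd.get(colmap["genus"], "").strip()
        if not genus_raw:
            continue  # metadata-only row (no growth)
        species = rowd.get(colmap.get("species", "species"), "").strip() or None
        growth_raw = rowd.get(colmap.get("growth", "growth"), "").strip()
        growth = (
            _parse_enum(GrowthClass, growth_raw, i, "growth")
            if growth_raw else GrowthClass.UNCLASSIFIED
        )
        try:
            genus = canonicalize_genus(genus_raw, genus_synonyms)
        except ValidationError as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        records.append(IsolationRecord(sid, genus, species, growth))

    return list(samples.values()), records


def write_records(
    samples: Sequence[SampleMeta],
    records: Sequence[IsolationRecord],
    path: str | Path,
    delimiter: str = ",",
) -> None:
    """Write the long-format table consumed by :func:`read_records`.

    Samples without any isolation get one metadata-only row (blank genus),
    so the presence pattern round-trips bit-exactly."""
    by_sample: dict[str, list[IsolationRecord]] = {s.sample_id: [] for s in samples}
    for r in records:
        if r.sample_id not in by_sample:
            raise ValidationError(f"record references unknown sample {r.sample_id!r}")
        by_sample[r.sample_id].append(r)
    rows = []
    for s in samples:
        recs = by_sample[s.sample_id]
        base = {
            "sample_id": s.sample_id, "family_id": s.family_id,
            "subject_id": s.subject_id, "subject_role": s.subject_role.value,
            "matrix": s.matrix.value, "time_point": s.time_point.value,
        }
        if not recs:
            rows.append({**base, "genus": "", "species": "", "growth": ""})
        for r in recs:
            rows.append({**base, "genus": r.genus, "species": r.species or "",
                         "growth": r.growth.value})
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def encode_presence(
    records: Iterable[IsolationRecord],
    samples: Sequence[SampleMeta],
    genus_universe: Sequence[str] | None = None,
) -> PresenceMatrix:
    """Encode isolation records as the binary samples x genera matrix.

    Every sample gets a row (all-zero if nothing was isolated). The genus
    universe defaults to the sorted union of observed genera across the whole
    dataset, so patterns are comparable across families; a fixed external
    list may be supplied for cross-dataset comparability.
    """
    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample_id in metadata")
    index = {sid: i for i, sid in enumerate(sample_ids)}

    records = list(records)
    orphans = sorted({r.sample_id for r in records if r.sample_id not in index})
    if orphans:
        raise ValidationError(
            f"records reference sample_id(s) absent from metadata: {', '.join(orphans)}")

    observed = {r.genus for r in records}
    if genus_universe is None:
        genera = sorted(observed)
    else:
        genera = list(genus_universe)
        missing = sorted(observed - set(genera))
        if missing:
            raise ValidationError(
                f"genus_universe lacks observed genera: {', '.join(missing)}")
    gindex = {g: j for j, g in enumerate(genera)}

    values = np.zeros((len(sample_ids), len(genera)), dtype=np.int8)
    for r in records:
        values[index[r.sample_id], gindex[r.genus]] = 1
    return PresenceMatrix(sample_ids, genera, values)


def isolation_frequency(
    matrix: PresenceMatrix,
    samples: Sequence[SampleMeta],
    group_filter: Callable[[SampleMeta], bool] | None = None,
) -> pd.DataFrame:
    """Per-genus isolation count and percent within a sample group.

    Returns a DataFrame indexed by genus with columns ``count`` and
    ``percent`` (one decimal), e.g. the colostrum or meconium frequency
    summaries. ``group_filter`` defaults to all samples."""
    meta = {s.sample_id: s for s in samples}
    selected = [
        i for i, sid in enumerate(matrix.sample_ids)
        if sid in meta and (group_filter is None or group_filter(meta[sid]))
    ]
    if not selected:
        raise ValidationError("group_filter selects no samples")
    counts = matrix.values[selected].sum(axis=0)
    n = len(selected)
    return pd.DataFrame(
        {"count": counts.astype(int),
         "percent": np.round(100.0 * counts / n, 1)},
        index=pd.Index(matrix.genera, name="genus"),
    )
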