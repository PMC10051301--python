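"""Data model and I/O for antigen-array autoantibody profiling.

The pipeline operates on three tables:

* an intensity matrix (samples in rows, antigens in columns) holding raw
  median fluorescence intensities (MFI),
* a sample-metadata table with clinical group, disease subtype, skin-score
  and clinical-antibody information,
* an antigen panel table mapping each antigen (protein fragment) to the
  protein it represents and recording how it entered the panel.

Matrices are plain :class:`pandas.DataFrame` objects validated on read;
metadata and panels are lists of frozen dataclass records.  All percentages
reported anywhere in the pipeline are rounded half-up to the nearest
integer via :func:`pct_half_up`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("seroprofile")

GROUPS = ("case", "control")
SUBTYPES = ("limited", "diffuse", "no_sclerosis", "not_applicable")
SEXES = ("F", "M")
ANTIGEN_SOURCES = ("planar_selected", "literature")

#: clinical manifestations tracked per patient (each possibly missing)
CLINICAL_FLAGS = (
    "calcinosis",
    "digital_ulcers",
    "dysphagia",
    "lung_fibrosis",
    "pah",
    "raynaud",
    "reflux",
    "sicca",
)

#: routinely assayed clinical autoantibody statuses (each possibly missing)
CLINICAL_ANTIBODIES = ("scl70", "centromere", "ssa", "rnp_sm")

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no"}
_MISSING_TOKENS = {"", "na", "nan", "none", "missing", "-"}


class ParseError(ValueError):
    """Malformed input table: the message names the offending row/column."""


class ValidationError(ValueError):
    """Inconsistent dataset (duplicate ids, unmatched ids, bad values)."""


def pct_half_up(numerator: int, denominator: int) -> int:
    """Percentage ``numerator / denominator`` rounded half-up to an integer.

    Uses exact rational arithmetic so that e.g. 41/55 -> 75 and 3/8 -> 38
    regardless of binary floating-point representation.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(Fraction(100 * numerator, denominator) + Fraction(1, 2)))


@dataclass(frozen=True)
class AntigenRecord:
    """One antigen (protein fragment) of a targeted panel.

    Several antigens may represent the same protein; ``source`` records
    whether the antigen entered the panel from the untargeted planar screen
    or from the literature, and ``fibrosis_related`` flags antigens whose
    protein is known to participate in fibrotic processes.
    """

    antigen_id: str
    protein_id: str
    source: str = "literature"
    fibrosis_related: bool = False

    def __post_init__(self) -> None:
        if self.source not in ANTIGEN_SOURCES:
            raise ValidationError(
                f"antigen {self.antigen_id!r}: unknown source {self.source!r}"
            )


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one plasma sample.

    ``clinical_flags`` and ``clinical_antibodies`` map names to True/False
    or ``None`` when the status was not assessed; missing is a distinct
    state and is never coerced to False.  Controls carry subtype
    ``not_applicable`` and a missing skin score.
    """

    sample_id: str
    group: str
    subtype: str
    age: int
    sex: str
    mrss: int | None = None
    clinical_flags: Mapping[str, bool | None] = field(default_factory=dict)
    clinical_antibodies: Mapping[str, bool | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ParseError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if self.subtype not in SUBTYPES:
            raise ParseError(
                f"sample {self.sample_id!r}: unknown subtype {self.subtype!r}"
            )
        if self.sex not in SEXES:
            raise ParseError(f"sample {self.sample_id!r}: unknown sex {self.sex!r}")
        if self.age <= 0:
            raise ParseError(f"sample {self.sample_id!r}: non-positive age")
        if self.group == "control":
            if self.subtype != "not_applicable":
                raise ValidationError(
                    f"control {self.sample_id!r} must have subtype not_applicable"
                )
            if self.mrss is not None:
                raise ValidationError(
                    f"control {self.sample_id!r} must have missing mRSS"
                )
        if self.mrss is not None and self.mrss < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative mRSS")

    def flag(self, name: str) -> bool | None:
        return self.clinical_flags.get(name)

    def antibody(self, name: str) -> bool | None:
        return self.clinical_antibodies.get(name)


@dataclass
class BinaryReactivityMatrix:
    """0/1 reactivity calls per sample x antigen (or protein).

    ``provenance`` records the cutoff rule and realized per-column cutoffs
    so every call is reproducible from the stored parameters.
    """

    calls: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValidationError("reactivity calls must be 0 or 1")
        self.calls = self.calls.astype("int8")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def target_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class Dataset:
    """Aligned intensity matrix + metadata + panel, produced by join_dataset."""

    matrix: pd.DataFrame
    metadata: dict[str, SampleRecord]
    panel: list[AntigenRecord]

    @property
    def n_cases(self) -> int:
        return sum(r.group == "case" for r in self.metadata.values())

    @property
    def n_controls(self) -> int:
        return sum(r.group == "control" for r in self.metadata.values())

    def summary(self) -> str:
        return f"{self.n_cases} cases / {self.n_controls} controls"

    def case_mask(self) -> pd.Series:
        return pd.Series(
            [self.metadata[s].group == "case" for s in self.matrix.index],
            index=self.matrix.index,
        )


def _sep(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def _dialect_from_path(path: str | Path) -> str:
    return "csv" if str(path).lower().endswith(".csv") else "tsv"


def read_intensity_matrix(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a samples x antigens MFI matrix from TSV/CSV.

    First row holds antigen ids, first column holds sample ids; the body
    must be numeric and non-negative with no missing cells.
    """
    dialect = dialect or _dialect_from_path(path)
    # pandas mangles duplicate header names; check the raw header first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep(dialect))[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ParseError(f"{path}: duplicated antigen id(s): {dups}")
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return validate_intensity_matrix(df, name=str(path))


def validate_intensity_matrix(df: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ParseError(f"{name}: duplicated sample id(s): {dups}")
    if df.columns.duplicated().any():
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ParseError(f"{name}: duplicated antigen id(s): {dups}")
    for col in df.columns:
        series = pd.to_numeric(df[col], errors="coerce")
        if series.isna().any():
            bad = df.index[series.isna()][0]
            raise ParseError(
                f"{name}: non-numeric or missing value at sample {bad!r}, antigen {col!r}"
            )
        df[col] = series
    if (df.to_numpy() < 0).any():
        stacked = df.stack()
        sid, aid = stacked.index[stacked.to_numpy() < 0][0]
        raise ParseError(
            f"{name}: negative MFI at sample {sid!r}, antigen {aid!r}"
        )
    return df.astype(float)


def write_intensity_matrix(
    df: pd.DataFrame,
    path: str | Path,
    dialect: str | None = None,
    float_format: str = "%.6f",
) -> None:
    """Write a matrix with fixed decimal formatting (round-trips bit-exactly)."""
    dialect = dialect or _dialect_from_path(path)
    df.to_csv(path, sep=_sep(dialect), float_format=float_format)


def _parse_bool(token: str, where: str) -> bool | None:
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise ParseError(f"{where}: cannot parse boolean token {token!r}")


def _parse_int(token: str, where: str) -> int | None:
    t = token.strip().lower()
    if t in _MISSING_TOKENS:
        return None
    try:
        return int(float(token))
    except ValueError as exc:
        raise ParseError(f"{where}: cannot parse integer token {token!r}") from exc


def read_metadata(path: str | Path, dialect: str | None = None) -> list[SampleRecord]:
    """Read sample metadata; blanks in optional columns stay missing."""
    dialect = dialect or _dialect_from_path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str).fillna("")
    required = {"sample_id", "group", "subtype", "age", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata column(s): {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # +2: header line + 1-based
        sid = row["sample_id"].strip()
        if not sid:
            raise ParseError(f"{where}: empty sample id")
        age = _parse_int(row["age"], where)
        if age is None:
            raise ParseError(f"{where}: age is required")
        flags = {
            name: _parse_bool(row.get(name, ""), where) for name in CLINICAL_FLAGS
        }
        abs_ = {
            name: _parse_bool(row.get(name, ""), where)
            for name in CLINICAL_ANTIBODIES
        }
        records.append(
            SampleRecord(
                sample_id=sid,
                group=row["group"].strip(),
                subtype=row["subtype"].strip(),
                age=age,
                sex=row["sex"].strip(),
                mrss=_parse_int(row.get("mrss", ""), where),
                clinical_flags=flags,
                clinical_antibodies=abs_,
            )
        )
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({s for s in ids if ids.count(s) > 1})
        raise ParseError(f"{path}: duplicated sample id(s): {dups}")
    return records


def metadata_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabular view of SampleRecords (missing values as pandas NA)."""
    rows = []
    for r in records:
        row: dict = {
            "sample_id": r.sample_id,
            "group": r.group,
            "subtype": r.subtype,
            "age": r.age,
            "sex": r.sex,
            "mrss": r.mrss,
        }
        row.update({k: r.clinical_flags.get(k) for k in CLINICAL_FLAGS})
        row.update({k: r.clinical_antibodies.get(k) for k in CLINICAL_ANTIBODIES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def write_metadata(
    records: Sequence[SampleRecord], path: str | Path, dialect: str | None = None
) -> None:
    df = metadata_to_frame(records)
    df.to_csv(path, sep=_sep(dialect or _dialect_from_path(path)))


def read_panel(path: str | Path, dialect: str | None = None) -> list[AntigenRecord]:
    dialect = dialect or _dialect_from_path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str).fillna("")
    required = {"antigen_id", "protein_id", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing panel column(s): {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        fib = _parse_bool(row.get("fibrosis_related", "0"), f"{path} row {i + 2}")
        records.append(
            AntigenRecord(
                antigen_id=row["antigen_id"].strip(),
                protein_id=row["protein_id"].strip(),
                source=row["source"].strip(),
                fibrosis_related=bool(fib),
            )
        )
    ids = [r.antigen_id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({a for a in ids if ids.count(a) > 1})
        raise ParseError(f"{path}: duplicated antigen id(s): {dups}")
    return records


def write_panel(
    panel: Sequence[AntigenRecord], path: str | Path, dialect: str | None = None
) -> None:
    df = pd.DataFrame(
        {
            "antigen_id": [a.antigen_id for a in panel],
            "protein_id": [a.protein_id for a in panel],
            "source": [a.source for a in panel],
            "fibrosis_related": [int(a.fibrosis_related) for a in panel],
        }
    )
    df.to_csv(path, sep=_sep(dialect or _dialect_from_path(path)), index=False)


def join_dataset(
    matrix: pd.DataFrame,
    metadata: Iterable[SampleRecord],
    panel: Iterable[AntigenRecord],
) -> Dataset:
    """Align matrix, metadata and panel into one validated dataset.

    Every matrix sample must appear in the metadata and every column in the
    panel; metadata rows without a matrix sample are allowed (warned).
    """
    if matrix.shape[0] == 0:
        raise ValidationError("no samples in intensity matrix")
    meta = {r.sample_id: r for r in metadata}
    panel = list(panel)
    panel_ids = {a.antigen_id for a in panel}
    missing_samples = [s for s in matrix.index if s not in meta]
    if missing_samples:
        raise ValidationError(
            f"matrix sample(s) absent from metadata: {missing_samples}"
        )
    missing_antigens = [a for a in matrix.columns if a not in panel_ids]
    if missing_antigens:
        raise ValidationError(
            f"matrix antigen(s) absent from panel: {missing_antigens}"
        )
    extra = sorted(set(meta) - set(matrix.index))
    if extra:
        logger.warning("metadata sample(s) without matrix rows: %s", extra)
    ds = Dataset(
        matrix=matrix,
        metadata={s: meta[s] for s in matrix.index},
        panel=panel,
    )
    logger.info("joined dataset: %s, %d antigens", ds.summary(), matrix.shape[1])
    return ds
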