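"""Patient-level cohort data model and CSV input/output.

A cohort is an ordered collection of primary-care patients with an acute
respiratory tract infection, each carrying symptoms/signs, vital signs,
biomarker measurements and the chest X-ray outcome (consolidation, the
operational definition of pneumonia). Missingness is explicit: an empty
CSV cell maps to a missing value and back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class CohortError(Exception):
    """Base class for cohort data errors."""


class SchemaError(CohortError):
    """The CSV header does not match the documented cohort schema."""


class CohortParseError(CohortError):
    """A cell could not be parsed to its semantic type."""


class CohortValidationError(CohortError):
    """A record violates a cohort invariant."""


ID_FIELD = "patient_id"
OUTCOME_FIELD = "consolidation"

#: Binary indicator fields; stored as 0/1 integers, empty cell = missing.
#: Indicator direction follows the prediction equations: 1 means the runny
#: nose is ABSENT and 1 means the patient feels ill.
BINARY_FIELDS = (
    "runny_nose_absent",
    "feels_ill",
    "current_smoker",
    "confusion_new_onset",
    "consolidation",
    "antibiotics_after_xray",
    "hospital_referral",
)

#: Continuous fields with (lower, upper) plausibility bounds (inclusive);
#: None means unbounded on that side.
FLOAT_FIELDS: Mapping[str, tuple[Optional[float], Optional[float]]] = {
    "respiratory_rate_per_min": (0.0, None),
    "systolic_bp_mmHg": (0.0, None),
    "diastolic_bp_mmHg": (0.0, None),
    "oxygen_saturation_pct": (50.0, 100.0),
    "crp_mg_per_l": (0.0, None),
    "pct": (0.0, None),  # units not standardised; stored as given
    "mr_proadm_nmol_per_l": (0.0, None),
}

INT_FIELDS: Mapping[str, tuple[Optional[float], Optional[float]]] = {
    "age_years": (0, None),
}

#: Canonical column order of the cohort CSV schema.
SCHEMA_COLUMNS = (
    ID_FIELD,
    "age_years",
    "runny_nose_absent",
    "feels_ill",
    "current_smoker",
    "confusion_new_onset",
    "respiratory_rate_per_min",
    "systolic_bp_mmHg",
    "diastolic_bp_mmHg",
    "oxygen_saturation_pct",
    "crp_mg_per_l",
    "pct",
    "mr_proadm_nmol_per_l",
    "consolidation",
    "antibiotics_after_xray",
    "hospital_referral",
)

DATA_COLUMNS = tuple(c for c in SCHEMA_COLUMNS if c != ID_FIELD)


@dataclass
class PatientRecord:
    """One patient's covariates, biomarkers, outcome and follow-up fields.

    ``None`` encodes a missing value. Binary fields take values 0/1/None.
    """

    patient_id: str
    consolidation: int
    age_years: Optional[int] = None
    runny_nose_absent: Optional[int] = None
    feels_ill: Optional[int] = None
    current_smoker: Optional[int] = None
    confusion_new_onset: Optional[int] = None
    respiratory_rate_per_min: Optional[float] = None
    systolic_bp_mmHg: Optional[float] = None
    diastolic_bp_mmHg: Optional[float] = None
    oxygen_saturation_pct: Optional[float] = None
    crp_mg_per_l: Optional[float] = None
    pct: Optional[float] = None
    mr_proadm_nmol_per_l: Optional[float] = None
    antibiotics_after_xray: Optional[int] = None
    hospital_referral: Optional[int] = None


def _empty_frame(n: int) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n))
    df[ID_FIELD] = pd.array([pd.NA] * n, dtype="string")
    for col in INT_FIELDS:
        df[col] = pd.array([pd.NA] * n, dtype="Int64")
    for col in BINARY_FIELDS:
        df[col] = pd.array([pd.NA] * n, dtype="Int64")
    for col in FLOAT_FIELDS:
        df[col] = pd.array([pd.NA] * n, dtype="Float64")
    return df[list(SCHEMA_COLUMNS)]


@dataclass
class Cohort:
    """Ordered patient records plus a provenance label.

    ``data`` uses pandas nullable dtypes (``Int64``/``Float64``/``string``)
    so that missingness survives a CSV round trip exactly.
    """

    data: pd.DataFrame
    provenance: str = "user"
    #: records dropped per required field by :func:`complete_case_subset`
    exclusions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping[str, object]],
        provenance: str = "user",
    ) -> "Cohort":
        """Build a cohort from dict-like records; absent keys become missing."""
        records = list(records)
        raw = pd.DataFrame.from_records(records)
        unknown = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
        if unknown:
            raise SchemaError(f"unknown field(s) {unknown}")
        df = _empty_frame(len(records))
        for col in raw.columns:
            if col == ID_FIELD:
                df[col] = raw[col].astype("string")
            elif col in BINARY_FIELDS or col in INT_FIELDS:
                df[col] = raw[col].astype("Float64").astype("Int64")
            else:
                df[col] = raw[col].astype("Float64")
        if df[ID_FIELD].isna().any():
            auto = pd.Series(
                [f"row{i + 1}" for i in range(len(df))], dtype="string"
            )
            df[ID_FIELD] = df[ID_FIELD].fillna(auto)
        return cls(df, provenance=provenance)

    @property
    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self.data.iterrows():
            kwargs = {}
            for col in SCHEMA_COLUMNS:
                v = row[col]
                if pd.isna(v):
                    kwargs[col] = None
                elif col == ID_FIELD:
                    kwargs[col] = str(v)
                elif col in BINARY_FIELDS or col in INT_FIELDS:
                    kwargs[col] = int(v)
                else:
                    kwargs[col] = float(v)
            out.append(PatientRecord(**kwargs))
        return out

    @property
    def n_events(self) -> int:
        return int((self.data[OUTCOME_FIELD] == 1).sum())

    def validate(self, strict: bool = True) -> None:
        """Check cohort invariants; raise in strict mode, warn otherwise."""
        problems: list[str] = []
        if len(self.data) < 1:
            raise CohortValidationError("cohort must contain at least one record")
        ids = self.data[ID_FIELD]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique().tolist()
            problems.append(f"duplicate patient_id values: {dupes}")
        if self.data[OUTCOME_FIELD].isna().any():
            n = int(self.data[OUTCOME_FIELD].isna().sum())
            problems.append(f"{n} record(s) with missing outcome '{OUTCOME_FIELD}'")
        for col in BINARY_FIELDS:
            bad = self.data[col].dropna().isin([0, 1])
            if not bad.all():
                problems.append(f"column {col!r} contains non-binary values")
        sbp = self.data["systolic_bp_mmHg"]
        dbp = self.data["diastolic_bp_mmHg"]
        both = sbp.notna() & dbp.notna()
        if bool((dbp[both] >= sbp[both]).any()):
            rows = self.data.index[both & (dbp >= sbp)].tolist()
            problems.append(f"diastolic >= systolic blood pressure in rows {rows}")
        for col, (lo, hi) in {**FLOAT_FIELDS, **INT_FIELDS}.items():
            vals = self.data[col].dropna()
            if lo is not None and bool((vals < lo).any()):
                problems.append(f"column {col!r} has values below {lo}")
            if hi is not None and bool((vals > hi).any()):
                problems.append(f"column {col!r} has values above {hi}")
        if problems:
            msg = "; ".join(problems)
            if strict:
                raise CohortValidationError(msg)
            warnings.warn(msg, stacklevel=2)


def _parse_binary(raw: str, row: int, col: str):
    s = raw.strip()
    if s == "":
        return pd.NA
    low = s.lower()
    if low in ("true", "yes"):
        return 1
    if low in ("false", "no"):
        return 0
    try:
        v = float(s)
    except ValueError:
        raise CohortParseError(
            f"row {row}, column {col!r}: cannot parse {raw!r} as binary"
        ) from None
    if v in (0.0, 1.0):
        return int(v)
    raise CohortParseError(f"row {row}, column {col!r}: {raw!r} is not 0/1")


def _parse_number(raw: str, row: int, col: str, as_int: bool):
    s = raw.strip()
    if s == "":
        return pd.NA
    try:
        v = float(s)
    except ValueError:
        raise CohortParseError(
            f"row {row}, column {col!r}: cannot parse {raw!r} as a number"
        ) from None
    if as_int:
        if v != int(v):
            raise CohortParseError(
                f"row {row}, column {col!r}: {raw!r} is not an integer"
            )
        return int(v)
    return v


def read_cohort(path, strict: bool = True, provenance: str = "user") -> Cohort:
    """Read a cohort CSV.

    Empty cells become missing values; ``true``/``false`` are accepted for
    binary fields; extra columns are ignored with a warning. With
    ``strict=True`` validation failures raise, otherwise they warn.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    extra = [c for c in raw.columns if c not in SCHEMA_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns {extra}", stacklevel=2)
    if OUTCOME_FIELD not in raw.columns:
        raise SchemaError(f"required outcome column {OUTCOME_FIELD!r} is missing")
    missing_cols = [c for c in DATA_COLUMNS if c not in raw.columns]
    if missing_cols:
        warnings.warn(
            f"columns {missing_cols} absent; treated as all-missing", stacklevel=2
        )

    df = _empty_frame(len(raw))
    if ID_FIELD in raw.columns:
        df[ID_FIELD] = pd.array(
            [s.strip() for s in raw[ID_FIELD]], dtype="string"
        )
    else:
        df[ID_FIELD] = pd.array(
            [f"row{i + 1}" for i in range(len(raw))], dtype="string"
        )
    for col in BINARY_FIELDS:
        if col in raw.columns:
            df[col] = pd.array(
                [_parse_binary(v, i + 1, col) for i, v in enumerate(raw[col])],
                dtype="Int64",
            )
    for col in INT_FIELDS:
        if col in raw.columns:
            df[col] = pd.array(
                [_parse_number(v, i + 1, col, True) for i, v in enumerate(raw[col])],
                dtype="Int64",
            )
    for col in FLOAT_FIELDS:
        if col in raw.columns:
            df[col] = pd.array(
                [_parse_number(v, i + 1, col, False) for i, v in enumerate(raw[col])],
                dtype="Float64",
            )
    cohort = Cohort(df, provenance=provenance)
    cohort.validate(strict=strict)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV; reading it back reproduces the cohort exactly.

    Missing values are written as empty cells (not "NA" strings); binary
    fields as 0/1 integers; floats at full round-trip precision.
    """
    path = Path(path)
    cohort.data[list(SCHEMA_COLUMNS)].to_csv(path, index=False, na_rep="")


def complete_case_subset(
    cohort: Cohort, required_fields: Sequence[str]
) -> Cohort:
    """Records with all ``required_fields`` non-missing, order preserved.

    The returned cohort's ``exclusions`` maps each required field to the
    number of dropped records missing that field (a record missing several
    fields counts towards each).
    """
    for f in required_fields:
        if f not in SCHEMA_COLUMNS or f == ID_FIELD:
            raise SchemaError(f"unknown field {f!r}")
    if not required_fields:
        return Cohort(cohort.data.copy(), provenance=cohort.provenance)
    mask = cohort.data[list(required_fields)].notna().all(axis=1)
    dropped = cohort.data[~mask]
    exclusions = {f: int(dropped[f].isna().sum()) for f in required_fields}
    return Cohort(
        cohort.data[mask].copy(),
        provenance=cohort.provenance,
        exclusions=exclusions,
    )
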