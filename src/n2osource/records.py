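"""Typed records for pipeline inputs/outputs plus CSV readers/writers.

Three tabular schemas flow between pipeline stages:

``profiles.csv``
    one row per station/depth with dissolved N2O concentration and
    isotope signals (:class:`IsotopomerRecord`);
``incubations.csv``
    one row per incubation bottle with the 15N bookkeeping needed to
    compute rates (:class:`IncubationRecord`);
``rates.csv``
    one row per bottle with derived rates, yield and detection-limit
    flags (:class:`RateRecord`).

All files are UTF-8, comma-separated, ``.`` decimal, one header row with
the exact field names of the corresponding dataclass.  Numeric values
round-trip losslessly (written with 17 significant digits).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Optional, Sequence, Type, TypeVar, Union

import pandas as pd

__all__ = [
    "IsotopomerRecord",
    "IncubationRecord",
    "RateRecord",
    "ValidationError",
    "SchemaError",
    "read_profile_csv",
    "read_incubation_csv",
    "read_rates_csv",
    "read_records_csv",
    "write_records_csv",
]

LAYERS = ("surface", "subsurface")
SUBSTRATES = ("ammonium", "urea")
TREATMENTS = ("control", "acidified")

#: default per-signal analytical precision (permil) for
#: d15n_bulk / d18o / sp respectively
DEFAULT_SIGMAS = {"sigma_d15n_bulk": 0.2, "sigma_d18o": 0.5, "sigma_sp": 1.0}

_SP_TOL = 1e-9


class ValidationError(ValueError):
    """One or more records violate a stated invariant.

    ``messages`` lists every violation found (not only the first).
    """

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class SchemaError(ValueError):
    """CSV header does not match the documented schema."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class IsotopomerRecord:
    """One depth's dissolved N2O concentration and isotope signals.

    ``sp`` may be given directly or derived as ``d15n_alpha - d15n_beta``;
    when all three are present they must be mutually consistent.
    """

    station_id: str
    depth: float  # m, positive downward, 0 = surface
    layer: str  # surface | subsurface
    c_n2o: float  # nmol N2O L-1
    d15n_bulk: float  # permil vs air-N2
    d18o: float  # permil vs VSMOW
    d15n_alpha: Optional[float] = None  # permil
    d15n_beta: Optional[float] = None  # permil
    sp: Optional[float] = None  # permil, alpha - beta
    sigma_d15n_bulk: float = DEFAULT_SIGMAS["sigma_d15n_bulk"]
    sigma_d18o: float = DEFAULT_SIGMAS["sigma_d18o"]
    sigma_sp: float = DEFAULT_SIGMAS["sigma_sp"]

    def __post_init__(self):
        if _is_missing(self.sp) and not (
            _is_missing(self.d15n_alpha) or _is_missing(self.d15n_beta)
        ):
            self.sp = self.d15n_alpha - self.d15n_beta

    def validate(self) -> list[str]:
        errs = []
        if self.layer not in LAYERS:
            errs.append(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if not self.depth >= 0:
            errs.append(f"depth must be >= 0, got {self.depth}")
        if not self.c_n2o > 0:
            errs.append(f"c_n2o must be > 0, got {self.c_n2o}")
        if not (
            _is_missing(self.sp)
            or _is_missing(self.d15n_alpha)
            or _is_missing(self.d15n_beta)
        ):
            if abs(self.sp - (self.d15n_alpha - self.d15n_beta)) > _SP_TOL:
                errs.append(
                    f"sp={self.sp} inconsistent with "
                    f"alpha-beta={self.d15n_alpha - self.d15n_beta}"
                )
        for name in ("sigma_d15n_bulk", "sigma_d18o", "sigma_sp"):
            if not getattr(self, name) > 0:
                errs.append(f"{name} must be > 0, got {getattr(self, name)}")
        return errs


@dataclass
class IncubationRecord:
    """One bottle's 15N tracer bookkeeping.

    Small negative concentration differences from instrument noise are
    retained as-is; downstream detection-limit censoring flags the
    resulting rates instead of clipping the inputs.
    """

    station_id: str
    depth: float  # m
    substrate: str  # ammonium | urea
    treatment: str  # control | acidified
    replicate: int
    f_substrate: float  # 15N atom fraction of the substrate N pool, (0, 1]
    delta_t: float  # incubation time, hours
    c0_nox15: float  # 15NOx- at t=0, nmol N L-1
    ct_nox15: float  # 15NOx- at t=dt, nmol N L-1
    dc45: float  # increase in 45N2O, pmol molecules L-1
    dc46: float  # increase in 46N2O, pmol molecules L-1

    def validate(self) -> list[str]:
        errs = []
        if self.substrate not in SUBSTRATES:
            errs.append(f"substrate must be one of {SUBSTRATES}, got {self.substrate!r}")
        if self.treatment not in TREATMENTS:
            errs.append(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if not 0 < self.f_substrate <= 1:
            errs.append(f"f_substrate must be in (0, 1], got {self.f_substrate}")
        if not self.delta_t > 0:
            errs.append(f"delta_t must be > 0, got {self.delta_t}")
        return errs


@dataclass
class RateRecord:
    """Per-bottle derived rates with detection-limit flags.

    ``r_n2o`` is on an N-atom basis (the 45/46 bookkeeping counts
    labeled N atoms, one per 45N2O and two per 46N2O molecule).
    ``yield_n2o`` is NaN when undefined (both rates non-positive).
    """

    station_id: str
    depth: float
    substrate: str
    treatment: str
    replicate: int
    r_nitr: float  # nmol N L-1 d-1
    r_n2o: float  # pmol N L-1 d-1
    yield_n2o: float  # dimensionless fraction
    below_lod_nitr: bool = False
    below_lod_n2o: bool = False

    def validate(self) -> list[str]:
        errs = []
        if self.substrate not in SUBSTRATES:
            errs.append(f"substrate must be one of {SUBSTRATES}, got {self.substrate!r}")
        if self.treatment not in TREATMENTS:
            errs.append(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if (
            not _is_missing(self.yield_n2o)
            and self.r_nitr >= 0
            and self.r_n2o >= 0
            and not 0 <= self.yield_n2o < 1
        ):
            errs.append(f"yield_n2o must be in [0, 1), got {self.yield_n2o}")
        return errs


Record = Union[IsotopomerRecord, IncubationRecord, RateRecord]
R = TypeVar("R", IsotopomerRecord, IncubationRecord, RateRecord)

_OPTIONAL_FLOATS = {"d15n_alpha", "d15n_beta", "sp", "yield_n2o"}
_STR_FIELDS = {"station_id", "layer", "substrate", "treatment"}
_BOOL_FIELDS = {"below_lod_nitr", "below_lod_n2o"}
_INT_FIELDS = {"replicate"}


def _coerce_cell(name: str, raw, row: int, errors: list[str]):
    if name in _STR_FIELDS:
        return str(raw)
    if name in _BOOL_FIELDS:
        if isinstance(raw, (bool,)):
            return raw
        s = str(raw).strip().lower()
        if s in ("true", "1"):
            return True
        if s in ("false", "0"):
            return False
        errors.append(f"row {row}: column {name!r}: cannot parse boolean {raw!r}")
        return False
    if _is_missing(raw) or (isinstance(raw, str) and raw.strip() == ""):
        if name in _OPTIONAL_FLOATS:
            return None
        errors.append(f"row {row}: column {name!r}: missing required value")
        return math.nan
    try:
        if name in _INT_FIELDS:
            return int(float(raw))
        return float(raw)
    except (TypeError, ValueError):
        errors.append(f"row {row}: column {name!r}: non-numeric value {raw!r}")
        return math.nan


def read_records_csv(path, record_type: Type[R]) -> list[R]:
    """Read and validate a CSV of homogeneous records.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ValidationError` listing *every* offending row otherwise.
    Row numbers in messages refer to 1-based data rows (header excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=object, keep_default_na=True)
    field_defs = {f.name: f for f in fields(record_type)}
    required = {
        n
        for n, f in field_defs.items()
        if f.default is dataclasses.MISSING and n not in _OPTIONAL_FLOATS
    }
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(sorted(missing_cols))}"
        )
    errors: list[str] = []
    records: list[R] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        kwargs = {}
        for name in field_defs:
            if name not in row_d:
                continue  # optional column absent entirely
            kwargs[name] = _coerce_cell(name, row_d[name], i, errors)
        n_before = len(errors)
        try:
            rec = record_type(**kwargs)
        except Exception as exc:  # constructor-level failure
            errors.append(f"row {i}: {exc}")
            continue
        for msg in rec.validate():
            errors.append(f"row {i}: {msg}")
        if len(errors) == n_before:
            records.append(rec)
    if errors:
        raise ValidationError(errors)
    return records


def read_profile_csv(path) -> list[IsotopomerRecord]:
    """Read ``profiles.csv`` into validated :class:`IsotopomerRecord` rows."""
    return read_records_csv(path, IsotopomerRecord)


def read_incubation_csv(path) -> list[IncubationRecord]:
    """Read ``incubations.csv`` into validated :class:`IncubationRecord` rows."""
    return read_records_csv(path, IncubationRecord)


def read_rates_csv(path) -> list[RateRecord]:
    """Read ``rates.csv`` into validated :class:`RateRecord` rows."""
    return read_records_csv(path, RateRecord)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return format(value, ".17g")
    return str(value)


def write_records_csv(records: Sequence[Record], path) -> Path:
    """Write a homogeneous record list to CSV; returns the path written.

    An empty list is not writable (the record type, hence the header,
    would be unknown); mixed record types raise ``TypeError``.  Use the
    ``record_type`` forms of the readers to round-trip.
    """
    path = Path(path)
    if len(records) == 0:
        raise ValueError("cannot infer a header from an empty record list; "
                         "use write_empty_csv(record_type, path)")
    rec_type = type(records[0])
    if any(type(r) is not rec_type for r in records):
        raise TypeError("mixed record types in write_records_csv")
    cols = [f.name for f in fields(rec_type)]
    rows = [[_fmt(getattr(r, c)) for c in cols] for r in records]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def write_empty_csv(record_type: Type[R], path) -> Path:
    """Write a header-only CSV for ``record_type``."""
    path = Path(path)
    cols = [f.name for f in fields(record_type)]
    pd.DataFrame(columns=cols).to_csv(path, index=False)
    return path
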