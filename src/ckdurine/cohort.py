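"""Cohort domain types and delimited-text I/O.

The on-disk representation is long format: one CSV row per patient visit,
with patient-level fields repeated on every row.  Column names carry their
units; the reader performs no unit inference.  Rows that violate an invariant
or fail to parse are collected into a rejection report with row provenance —
never silently dropped — so ``n_accepted_rows + n_rejected_rows`` always
equals the number of data rows in the file.

Missing optional analytes are represented as ``None`` (empty CSV cell),
never 0.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import SchemaError

MAX_SPOT_PERIODS = 6


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass
class SpotPeriod:
    """One timed spot-urine clearance period (typically 30 min)."""

    duration_min: float
    urine_volume_ml: float
    urine_creatinine_umol_l: float
    serum_creatinine_umol_l: Optional[float] = None  # falls back to visit serum


@dataclass
class ClearanceStudy:
    """Measured GFR plus the spot-urine periods of one workup session."""

    mgfr_indexed: float  # mL/min/1.73 m2
    periods: list[SpotPeriod] = field(default_factory=list)


@dataclass
class SerumPanel:
    """Serum biology of one visit; creatinine is mandatory, the rest optional."""

    creatinine_umol_l: float
    sodium_mmol_l: Optional[float] = None
    potassium_mmol_l: Optional[float] = None
    hemoglobin_g_dl: Optional[float] = None
    bicarbonate_mmol_l: Optional[float] = None
    phosphorus_mmol_l: Optional[float] = None
    ionized_calcium_mmol_l: Optional[float] = None
    pth_pg_ml: Optional[float] = None
    vitd_25oh_ng_ml: Optional[float] = None
    calcitriol_pg_ml: Optional[float] = None


@dataclass
class UrineCollection24h:
    """The 24-h urine ionogram: volume plus daily solute amounts."""

    volume_ml: float           # mL/day
    creatinine_mmol: float     # mmol/day
    sodium_mmol: Optional[float] = None
    urea_mmol: Optional[float] = None
    calcium_mmol: Optional[float] = None
    phosphate_mmol: Optional[float] = None
    ammonium_mmol: Optional[float] = None
    osmolarity_mosm_l: Optional[float] = None
    protein_mg: Optional[float] = None
    albumin_mg: Optional[float] = None


@dataclass
class VisitRecord:
    patient_id: str
    visit_index: int
    years_since_baseline: float
    weight_kg: float
    systolic_bp: Optional[float]
    diastolic_bp: Optional[float]
    serum: SerumPanel
    clearance: Optional[ClearanceStudy] = None
    urine24h: Optional[UrineCollection24h] = None


@dataclass
class PatientRecord:
    patient_id: str
    sex: Sex
    ethnicity_black: bool
    height_m: float
    baseline_age_y: float
    diabetes: Optional[bool] = None
    hypertension: Optional[bool] = None
    visits: list[VisitRecord] = field(default_factory=list)

    def age_at(self, visit: VisitRecord) -> float:
        """Age at a visit = baseline age + years since baseline (no calendar math)."""
        return self.baseline_age_y + visit.years_since_baseline


@dataclass
class RejectedRow:
    line: int        # physical line number in the file (header = line 1)
    field: str
    raw_value: str
    reason: str


@dataclass
class ReadResult:
    patients: list[PatientRecord]
    rejections: list[RejectedRow]
    n_rows: int

    @property
    def n_accepted_rows(self) -> int:
        return sum(len(p.visits) for p in self.patients)

    @property
    def n_rejected_rows(self) -> int:
        return len({r.line for r in self.rejections})


# ---------------------------------------------------------------------------
# Canonical column schema (units in the names; order is the file order)
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = [
    "patient_id", "sex", "ethnicity_black", "height_m", "baseline_age_y",
    "diabetes", "hypertension",
]
VISIT_COLUMNS = [
    "visit_index", "years_since_baseline", "weight_kg",
    "systolic_bp_mmhg", "diastolic_bp_mmhg", "mgfr_ml_min_1p73m2",
]
SERUM_COLUMNS = {
    "serum_creatinine_umol_l": "creatinine_umol_l",
    "serum_sodium_mmol_l": "sodium_mmol_l",
    "serum_potassium_mmol_l": "potassium_mmol_l",
    "hemoglobin_g_dl": "hemoglobin_g_dl",
    "bicarbonate_mmol_l": "bicarbonate_mmol_l",
    "phosphorus_mmol_l": "phosphorus_mmol_l",
    "ionized_calcium_mmol_l": "ionized_calcium_mmol_l",
    "pth_pg_ml": "pth_pg_ml",
    "vitd_25oh_ng_ml": "vitd_25oh_ng_ml",
    "calcitriol_pg_ml": "calcitriol_pg_ml",
}
URINE_COLUMNS = {
    "u24_volume_ml_day": "volume_ml",
    "u24_creatinine_mmol_day": "creatinine_mmol",
    "u24_sodium_mmol_day": "sodium_mmol",
    "u24_urea_mmol_day": "urea_mmol",
    "u24_calcium_mmol_day": "calcium_mmol",
    "u24_phosphate_mmol_day": "phosphate_mmol",
    "u24_ammonium_mmol_day": "ammonium_mmol",
    "u24_osmolarity_mosm_l": "osmolarity_mosm_l",
    "u24_protein_mg_day": "protein_mg",
    "u24_albumin_mg_day": "albumin_mg",
}


def _spot_columns(i: int) -> list[str]:
    return [
        f"spot{i}_duration_min",
        f"spot{i}_urine_volume_ml",
        f"spot{i}_urine_creatinine_umol_l",
        f"spot{i}_serum_creatinine_umol_l",
    ]


SPOT_COLUMNS = [c for i in range(1, MAX_SPOT_PERIODS + 1) for c in _spot_columns(i)]

ALL_COLUMNS = (
    PATIENT_COLUMNS + VISIT_COLUMNS + list(SERUM_COLUMNS) + list(URINE_COLUMNS) + SPOT_COLUMNS
)

#: Columns that must be present in the header for a file to be readable.
REQUIRED_COLUMNS = [
    "patient_id", "sex", "ethnicity_black", "height_m", "baseline_age_y",
    "visit_index", "years_since_baseline", "weight_kg", "serum_creatinine_umol_l",
]

_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


def load_schema(path: str) -> dict[str, str]:
    """Load a canonical-name -> file-column mapping from a YAML file.

    The YAML holds a single ``columns:`` mapping; canonical names absent from
    it are assumed to appear under their own name.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    mapping = doc.get("columns", doc)
    if not isinstance(mapping, dict):
        raise SchemaError("schema file must contain a 'columns' mapping")
    unknown = set(mapping) - set(ALL_COLUMNS)
    if unknown:
        raise SchemaError(f"schema maps unknown canonical column(s): {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


class _RowError(Exception):
    def __init__(self, field_name: str, raw: str, reason: str) -> None:
        super().__init__(reason)
        self.field_name = field_name
        self.raw = raw
        self.reason = reason


def _get(row: Mapping[str, str], col: str) -> str:
    v = row.get(col, "")
    return v.strip() if isinstance(v, str) else ("" if v is None else str(v).strip())


def _parse_float(row: Mapping[str, str], col: str, required: bool = False) -> Optional[float]:
    raw = _get(row, col)
    if raw == "":
        if required:
            raise _RowError(col, raw, "required value missing")
        return None
    try:
        return float(raw)
    except ValueError:
        raise _RowError(col, raw, "unparseable numeric") from None


def _parse_bool(row: Mapping[str, str], col: str, required: bool = False) -> Optional[bool]:
    raw = _get(row, col).lower()
    if raw == "":
        if required:
            raise _RowError(col, raw, "required value missing")
        return None
    if raw in _TRUE_TOKENS:
        return True
    if raw in _FALSE_TOKENS:
        return False
    raise _RowError(col, _get(row, col), "unparseable boolean")


def _check(cond: bool, field_name: str, raw: object, reason: str) -> None:
    if not cond:
        raise _RowError(field_name, str(raw), f"invariant violated: {reason}")


def _parse_row(row: Mapping[str, str]) -> tuple[PatientRecord, VisitRecord]:
    """Parse one long-format row into patient-level fields + a visit.

    Raises ``_RowError`` on the first parse failure or invariant violation.
    """
    pid = _get(row, "patient_id")
    if pid == "":
        raise _RowError("patient_id", "", "required value missing")
    sex_raw = _get(row, "sex").lower()
    if sex_raw not in (Sex.MALE.value, Sex.FEMALE.value):
        raise _RowError("sex", sex_raw, "sex must be 'male' or 'female'")
    sex = Sex(sex_raw)
    height = _parse_float(row, "height_m", required=True)
    _check(1.2 < height < 2.2, "height_m", height, "height must be in (1.2, 2.2) m")
    age0 = _parse_float(row, "baseline_age_y", required=True)
    ethnicity = _parse_bool(row, "ethnicity_black", required=True)
    diabetes = _parse_bool(row, "diabetes")
    hypertension = _parse_bool(row, "hypertension")

    visit_index_f = _parse_float(row, "visit_index", required=True)
    visit_index = int(visit_index_f)
    _check(visit_index == visit_index_f and visit_index >= 1,
           "visit_index", visit_index_f, "visit_index must be an integer >= 1")
    years = _parse_float(row, "years_since_baseline", required=True)
    _check(years >= 0, "years_since_baseline", years, "must be >= 0")
    age = age0 + years
    _check(18 <= age <= 110, "baseline_age_y", age, "age at visit must be in [18, 110]")
    weight = _parse_float(row, "weight_kg", required=True)
    _check(30 < weight < 250, "weight_kg", weight, "weight must be in (30, 250) kg")

    serum_kwargs = {}
    for col, attr in SERUM_COLUMNS.items():
        v = _parse_float(row, col, required=(col == "serum_creatinine_umol_l"))
        if v is not None:
            _check(v > 0, col, v, "serum values must be > 0")
        serum_kwargs[attr] = v
    serum = SerumPanel(**serum_kwargs)

    urine: Optional[UrineCollection24h] = None
    uvals = {attr: _parse_float(row, col) for col, attr in URINE_COLUMNS.items()}
    if any(v is not None for v in uvals.values()):
        _check(uvals["volume_ml"] is not None, "u24_volume_ml_day", "",
               "24-h collection requires volume")
        _check(uvals["creatinine_mmol"] is not None, "u24_creatinine_mmol_day", "",
               "24-h collection requires creatinine")
        _check(uvals["volume_ml"] >= 0, "u24_volume_ml_day", uvals["volume_ml"], "volume >= 0")
        _check(uvals["creatinine_mmol"] > 0, "u24_creatinine_mmol_day",
               uvals["creatinine_mmol"], "creatinine > 0")
        for attr, v in uvals.items():
            if v is not None and attr not in ("volume_ml", "creatinine_mmol"):
                _check(v >= 0, attr, v, "urine amounts must be >= 0")
        urine = UrineCollection24h(**uvals)

    clearance: Optional[ClearanceStudy] = None
    mgfr = _parse_float(row, "mgfr_ml_min_1p73m2")
    periods: list[SpotPeriod] = []
    for i in range(1, MAX_SPOT_PERIODS + 1):
        dcol, vcol, ucol, scol = _spot_columns(i)
        dur = _parse_float(row, dcol)
        if dur is None:
            continue
        _check(dur > 0, dcol, dur, "spot period duration must be > 0")
        vol = _parse_float(row, vcol, required=True)
        ucr = _parse_float(row, ucol, required=True)
        _check(vol >= 0, vcol, vol, "spot volume >= 0")
        _check(ucr >= 0, ucol, ucr, "spot urine creatinine >= 0")
        scr = _parse_float(row, scol)
        if scr is not None:
            _check(scr > 0, scol, scr, "spot serum creatinine > 0")
        periods.append(SpotPeriod(dur, vol, ucr, scr))
    if mgfr is not None or periods:
        _check(mgfr is not None, "mgfr_ml_min_1p73m2", "", "clearance study requires mGFR")
        _check(mgfr > 0, "mgfr_ml_min_1p73m2", mgfr, "mGFR must be > 0")
        _check(len(periods) <= MAX_SPOT_PERIODS, "spot_periods", len(periods),
               "at most 6 spot periods")
        clearance = ClearanceStudy(mgfr_indexed=mgfr, periods=periods)

    patient = PatientRecord(pid, sex, ethnicity, height, age0, diabetes, hypertension)
    visit = VisitRecord(pid, visit_index, years, weight,
                        _parse_float(row, "systolic_bp_mmhg"),
                        _parse_float(row, "diastolic_bp_mmhg"),
                        serum, clearance, urine)
    return patient, visit


def read_cohort(path, schema: Mapping[str, str] | str | None = None) -> ReadResult:
    """Read a long-format cohort CSV into typed patient records.

    Parameters
    ----------
    path : str or file-like
        CSV file, UTF-8, RFC-4180, '.' decimal separator.
    schema : mapping or str, optional
        Canonical-name -> file-column mapping (or path to a YAML file with a
        ``columns:`` mapping) used to adapt real-world exports.

    Returns a :class:`ReadResult` whose ``rejections`` carry line-level
    provenance for every row that failed to parse or violated an invariant.
    """
    if isinstance(schema, str):
        schema = load_schema(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        missing_src = [v for v in schema.values() if v not in df.columns]
        if missing_src:
            raise SchemaError(f"schema names column(s) absent from file: {missing_src}")
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    patients: dict[str, PatientRecord] = {}
    rejections: list[RejectedRow] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        line = i + 2  # header is line 1
        try:
            patient, visit = _parse_row(row)
        except _RowError as e:
            rejections.append(RejectedRow(line, e.field_name, e.raw, e.reason))
            continue
        existing = patients.get(patient.patient_id)
        if existing is None:
            patients[patient.patient_id] = patient
            existing = patient
        else:
            same = (existing.sex == patient.sex
                    and existing.ethnicity_black == patient.ethnicity_black
                    and existing.height_m == patient.height_m
                    and existing.baseline_age_y == patient.baseline_age_y
                    and existing.diabetes == patient.diabetes
                    and existing.hypertension == patient.hypertension)
            if not same:
                rejections.append(RejectedRow(
                    line, "patient_id", patient.patient_id,
                    "patient-level fields inconsistent with earlier row"))
                continue
            if existing.visits and visit.visit_index <= existing.visits[-1].visit_index:
                rejections.append(RejectedRow(
                    line, "visit_index", str(visit.visit_index),
                    "invariant violated: visit_index must be strictly increasing per patient"))
                continue
        existing.visits.append(visit)
    return ReadResult(list(patients.values()), rejections, len(df))


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, Sex):
        return v.value
    if isinstance(v, float):
        return repr(v)  # shortest exact round-trip representation
    return str(v)


def _visit_to_row(p: PatientRecord, v: VisitRecord) -> dict[str, str]:
    row = {
        "patient_id": p.patient_id, "sex": _fmt(p.sex),
        "ethnicity_black": _fmt(p.ethnicity_black), "height_m": _fmt(p.height_m),
        "baseline_age_y": _fmt(p.baseline_age_y), "diabetes": _fmt(p.diabetes),
        "hypertension": _fmt(p.hypertension),
        "visit_index": str(v.visit_index),
        "years_since_baseline": _fmt(v.years_since_baseline),
        "weight_kg": _fmt(v.weight_kg),
        "systolic_bp_mmhg": _fmt(v.systolic_bp),
        "diastolic_bp_mmhg": _fmt(v.diastolic_bp),
        "mgfr_ml_min_1p73m2": _fmt(v.clearance.mgfr_indexed if v.clearance else None),
    }
    for col, attr in SERUM_COLUMNS.items():
        row[col] = _fmt(getattr(v.serum, attr))
    for col, attr in URINE_COLUMNS.items():
        row[col] = _fmt(getattr(v.urine24h, attr) if v.urine24h else None)
    for i in range(1, MAX_SPOT_PERIODS + 1):
        dcol, vcol, ucol, scol = _spot_columns(i)
        per = (v.clearance.periods[i - 1]
               if v.clearance and len(v.clearance.periods) >= i else None)
        row[dcol] = _fmt(per.duration_min if per else None)
        row[vcol] = _fmt(per.urine_volume_ml if per else None)
        row[ucol] = _fmt(per.urine_creatinine_umol_l if per else None)
        row[scol] = _fmt(per.serum_creatinine_umol_l if per else None)
    return row


def write_cohort(patients: Sequence[PatientRecord], path) -> None:
    """Write a cohort as long-format CSV; ``read_cohort`` round-trips it exactly."""
    rows = [_visit_to_row(p, v) for p in patients for v in p.visits]
    df = pd.DataFrame(rows, columns=ALL_COLUMNS, dtype=str) if rows else \
        pd.DataFrame(columns=ALL_COLUMNS)
    df.to_csv(path, index=False)


def write_rejections(rejections: Iterable[RejectedRow], path) -> None:
    """Write the rejection report: columns (line, field, raw_value, reason)."""
    df = pd.DataFrame(
        [(r.line, r.field, r.raw_value, r.reason) for r in rejections],
        columns=["line", "field", "raw_value", "reason"],
    )
    df.to_csv(path, index=False)


def cohort_to_csv_string(patients: Sequence[PatientRecord]) -> str:
    buf = io.StringIO()
    write_cohort(patients, buf)
    return buf.getvalue()
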