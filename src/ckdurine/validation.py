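"""24-h urine collection validity assessment.

A collection is checked by comparing a measured quantity against a reference
that does not depend on collection completeness, under a relative-delta
threshold (default 30%, stringent variant 15%):

* ``fractional_clearance`` — measured 24-h creatinine clearance vs the mean
  fractional creatinine clearance from the same-day timed spot-urine periods.
* ``egfr_mdrd`` — measured 24-h creatinine clearance vs the MDRD estimated
  GFR (by default de-indexed to absolute mL/min via Du Bois BSA, since the
  24-h clearance is an absolute quantity).
* ``expected_creatinine`` — measured 24-h urinary creatinine per kg body
  weight vs an expected-median normogram keyed on sex, age and GFR level.

The signed relative delta is ``(measured - reference) / reference``: below
``-threshold`` the collection is classified *incomplete* (missed voids),
above ``+threshold`` *excess* (e.g. two nights included), otherwise *valid*.
The boundary is inclusive: |delta| == threshold counts as valid.  A visit
lacking the inputs a criterion needs raises
:class:`~ckdurine.errors.CriterionUnavailableError` — a distinct outcome,
never coerced to invalid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import pandas as pd

from .cohort import PatientRecord, Sex, VisitRecord
from .constants import DEFAULT_CONSTANTS, StudyConstants
from .errors import ConfigError, CriterionUnavailableError, DomainError
from .renal import (bsa_dubois, crcl_24h_from_visit, deindex_gfr, egfr_mdrd,
                    fractional_crcl)


class ValidityCriterion(str, enum.Enum):
    FRACTIONAL_CLEARANCE = "fractional"
    EGFR_MDRD = "egfr"
    EXPECTED_CREATININE = "expected"

    @classmethod
    def parse(cls, token: "ValidityCriterion | str") -> "ValidityCriterion":
        if isinstance(token, cls):
            return token
        try:
            return cls(str(token).lower())
        except ValueError:
            raise ConfigError(
                f"unknown validity criterion {token!r}; "
                f"expected one of {[c.value for c in cls]}") from None


class ValidityStatus(str, enum.Enum):
    VALID = "valid"
    INCOMPLETE = "incomplete"
    EXCESS = "excess"


@dataclass(frozen=True)
class ValidityAssessment:
    criterion: ValidityCriterion
    measured: float
    reference: float
    relative_delta: float
    threshold: float
    status: ValidityStatus


def classify(measured: float, reference: float, threshold: float,
             criterion: ValidityCriterion = ValidityCriterion.FRACTIONAL_CLEARANCE,
             ) -> ValidityAssessment:
    """Classify a measured/reference pair; the three statuses partition all outcomes."""
    if reference <= 0:
        raise DomainError("reference must be > 0")
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    delta = (measured - reference) / reference
    if delta < -threshold:
        status = ValidityStatus.INCOMPLETE
    elif delta > threshold:
        status = ValidityStatus.EXCESS
    else:
        status = ValidityStatus.VALID
    return ValidityAssessment(criterion, measured, reference, delta, threshold, status)


# ---------------------------------------------------------------------------
# Expected-creatinine normogram
# ---------------------------------------------------------------------------

class ExpectedCreatinineTable:
    """Expected median 24-h urinary creatinine (µmol/kg/day) by sex/age/GFR band.

    Bands are half-open ``[min, max)`` and must tile their domain without
    overlap.  The packaged default table is a synthetic placeholder with
    plausible magnitudes (healthy males excrete roughly 180-230 µmol/kg/day,
    females ~22% less, declining with age and GFR); it is **not** an
    authoritative normogram and should be replaced with published reference
    values for real-cohort use.
    """

    COLUMNS = ["sex", "age_min", "age_max", "gfr_min", "gfr_max", "median_umol_per_kg_day"]

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigError(f"expected-creatinine table missing column(s): {missing}")
        self._frame = frame[self.COLUMNS].copy()
        self._frame["sex"] = self._frame["sex"].str.lower()
        for c in self.COLUMNS[1:]:
            self._frame[c] = self._frame[c].astype(float)
        self._validate()
        self._rows = list(self._frame.itertuples(index=False))

    def _validate(self) -> None:
        if (self._frame["median_umol_per_kg_day"] <= 0).any():
            raise ConfigError("all normogram medians must be positive")
        for sex, grp in self._frame.groupby("sex"):
            rows = grp.to_dict(orient="records")
            for i, a in enumerate(rows):
                for b in rows[i + 1:]:
                    age_overlap = a["age_min"] < b["age_max"] and b["age_min"] < a["age_max"]
                    gfr_overlap = a["gfr_min"] < b["gfr_max"] and b["gfr_min"] < a["gfr_max"]
                    if age_overlap and gfr_overlap:
                        raise ConfigError(
                            f"overlapping normogram bands for sex={sex}: {a} vs {b}")

    @classmethod
    def from_csv(cls, path) -> "ExpectedCreatinineTable":
        return cls(pd.read_csv(path))

    def lookup(self, sex: Sex, age_y: float, gfr: float) -> float:
        """Expected median µmol/kg/day for a (sex, age, GFR) cell."""
        sex_v = sex.value if isinstance(sex, Sex) else str(sex).lower()
        for row in self._rows:
            if (row.sex == sex_v and row.age_min <= age_y < row.age_max
                    and row.gfr_min <= gfr < row.gfr_max):
                return float(row.median_umol_per_kg_day)
        raise CriterionUnavailableError(
            f"normogram does not cover sex={sex_v}, age={age_y}, gfr={gfr}")

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


def default_table() -> ExpectedCreatinineTable:
    """The packaged synthetic placeholder normogram."""
    ref = resources.files("ckdurine.data") / "expected_creatinine_synthetic.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return ExpectedCreatinineTable(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# Criterion-specific assessments
# ---------------------------------------------------------------------------

def _require_collection(visit: VisitRecord) -> None:
    if visit.urine24h is None:
        raise CriterionUnavailableError("visit has no 24-h urine collection")


def assess_fractional(visit: VisitRecord, threshold: float) -> ValidityAssessment:
    """24-h creatinine clearance vs mean fractional creatinine clearance."""
    _require_collection(visit)
    if visit.clearance is None or not visit.clearance.periods:
        raise CriterionUnavailableError("visit has no spot-urine clearance study")
    measured = crcl_24h_from_visit(visit)
    reference = fractional_crcl(visit.clearance, visit.serum.creatinine_umol_l)
    if reference <= 0:
        raise CriterionUnavailableError("fractional clearance is not positive")
    return classify(measured, reference, threshold, ValidityCriterion.FRACTIONAL_CLEARANCE)


def assess_egfr(patient: PatientRecord, visit: VisitRecord, threshold: float,
                deindex: bool = True, mdrd_coefficient: float = 175.0,
                ) -> ValidityAssessment:
    """24-h creatinine clearance vs MDRD eGFR.

    With ``deindex=True`` (default) the eGFR is converted from
    mL/min/1.73 m2 to absolute mL/min via Du Bois BSA before comparison,
    so both sides of the delta are unindexed quantities.
    """
    _require_collection(visit)
    measured = crcl_24h_from_visit(visit)
    reference = egfr_mdrd(visit.serum.creatinine_umol_l, patient.age_at(visit),
                          patient.sex, patient.ethnicity_black, mdrd_coefficient)
    if deindex:
        if patient.height_m is None:
            raise CriterionUnavailableError("height needed to de-index eGFR")
        reference = deindex_gfr(reference, bsa_dubois(visit.weight_kg, patient.height_m))
    return classify(measured, reference, threshold, ValidityCriterion.EGFR_MDRD)


def assess_expected_creatinine(patient: PatientRecord, visit: VisitRecord,
                               table: ExpectedCreatinineTable, threshold: float,
                               ) -> ValidityAssessment:
    """Measured urinary creatinine per kg vs the expected-median normogram.

    The GFR level keying the normogram is the measured GFR when a clearance
    study is present, else the MDRD estimate.
    """
    _require_collection(visit)
    if visit.weight_kg is None or visit.weight_kg <= 0:
        raise CriterionUnavailableError("weight needed for per-kg creatinine")
    if visit.clearance is not None:
        gfr = visit.clearance.mgfr_indexed
    else:
        gfr = egfr_mdrd(visit.serum.creatinine_umol_l, patient.age_at(visit),
                        patient.sex, patient.ethnicity_black)
    reference = table.lookup(patient.sex, patient.age_at(visit), gfr)
    measured = visit.urine24h.creatinine_mmol * 1000.0 / visit.weight_kg  # µmol/kg/day
    return classify(measured, reference, threshold, ValidityCriterion.EXPECTED_CREATININE)


def assess_visit(patient: PatientRecord, visit: VisitRecord,
                 criterion: ValidityCriterion | str,
                 constants: StudyConstants = DEFAULT_CONSTANTS,
                 table: Optional[ExpectedCreatinineTable] = None,
                 threshold: Optional[float] = None,
                 deindex: bool = True) -> ValidityAssessment:
    """Dispatch to the criterion-specific assessment.

    ``threshold`` defaults to ``constants.validity_threshold``.
    """
    criterion = ValidityCriterion.parse(criterion)
    t = constants.validity_threshold if threshold is None else threshold
    if criterion is ValidityCriterion.FRACTIONAL_CLEARANCE:
        return assess_fractional(visit, t)
    if criterion is ValidityCriterion.EGFR_MDRD:
        return assess_egfr(patient, visit, t, deindex=deindex,
                           mdrd_coefficient=constants.mdrd_coefficient)
    if table is None:
        table = default_table()
    return assess_expected_creatinine(patient, visit, table, t)


def assess_cohort(patients: Sequence[PatientRecord],
                  criterion: ValidityCriterion | str,
                  constants: StudyConstants = DEFAULT_CONSTANTS,
                  table: Optional[ExpectedCreatinineTable] = None,
                  threshold: Optional[float] = None,
                  deindex: bool = True) -> pd.DataFrame:
    """Assess every visit of a cohort.

    Returns a tidy frame with one row per visit: patient_id, visit_index,
    criterion, threshold, measured, reference, relative_delta, status, and —
    for unassessable visits — status NA with the reason in ``unavailable``.
    """
    criterion = ValidityCriterion.parse(criterion)
    if table is None and criterion is ValidityCriterion.EXPECTED_CREATININE:
        table = default_table()
    rows = []
    for p in patients:
        for v in p.visits:
            rec = {"patient_id": p.patient_id, "visit_index": v.visit_index,
                   "criterion": criterion.value,
                   "threshold": constants.validity_threshold if threshold is None else threshold,
                   "measured": None, "reference": None, "relative_delta": None,
                   "status": None, "unavailable": None}
            try:
                a = assess_visit(p, v, criterion, constants, table, threshold, deindex)
                rec.update(measured=a.measured, reference=a.reference,
                           relative_delta=a.relative_delta, status=a.status.value)
            except CriterionUnavailableError as e:
                rec["unavailable"] = str(e)
            rows.append(rec)
    return pd.DataFrame(rows)
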