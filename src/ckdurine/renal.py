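"""Renal function computations.

24-h creatinine clearance, mean fractional creatinine clearance from timed
spot-urine periods, the 4-variable MDRD estimated GFR, Du Bois body surface
area and de-indexing of BSA-indexed GFR values.

Clearance is U.V/P throughout: urinary excretion rate divided by the plasma
concentration.  A day is fixed at 1440 min; incomplete collection durations
are modelled by the completeness error process, not by rescaling time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .cohort import ClearanceStudy, PatientRecord, Sex, UrineCollection24h, VisitRecord
from .errors import DomainError

MIN_PER_DAY = 1440.0
#: Serum creatinine normalisation of the MDRD equation, µmol/L per mg/dL.
_MDRD_SCR_NORM = 88.4


@dataclass(frozen=True)
class ClearanceResult:
    """All clearance quantities of one visit, absolute and indexed."""

    crcl_24h: Optional[float]            # mL/min
    fractional_crcl_mean: Optional[float]  # mL/min
    egfr_mdrd_indexed: float             # mL/min/1.73 m2
    egfr_mdrd_absolute: float            # mL/min
    bsa: float                           # m2


def crcl_24h(urine_creatinine_mmol_day: float, serum_creatinine_umol_l: float) -> float:
    """24-h creatinine clearance in mL/min.

    U.V is the daily urinary creatinine amount (mmol/day -> µmol/day via
    x1000), P the serum creatinine (µmol/L); dividing by 1440 min and
    converting L to mL collapses to ``amount*1000 / (serum*1.440)``.
    """
    if serum_creatinine_umol_l <= 0:
        raise DomainError("serum creatinine must be > 0")
    if urine_creatinine_mmol_day <= 0:
        raise DomainError("24-h urine creatinine must be > 0")
    return urine_creatinine_mmol_day * 1000.0 / (serum_creatinine_umol_l * 1.440)


def crcl_24h_from_visit(visit: VisitRecord) -> float:
    if visit.urine24h is None:
        raise DomainError("visit has no 24-h urine collection")
    return crcl_24h(visit.urine24h.creatinine_mmol, visit.serum.creatinine_umol_l)


def fractional_crcl(study: ClearanceStudy,
                    default_serum_creatinine: Optional[float] = None) -> float:
    """Mean creatinine clearance over the available spot-urine periods (mL/min).

    Each period contributes U.V/P = urine_creatinine x urine_volume /
    (serum_creatinine x duration); periods lacking their own serum creatinine
    use ``default_serum_creatinine`` (the visit value).
    """
    if not study.periods:
        raise DomainError("clearance study has no spot periods")
    clearances = []
    for per in study.periods:
        if per.duration_min <= 0:
            raise DomainError("spot period duration must be > 0")
        scr = per.serum_creatinine_umol_l
        if scr is None:
            scr = default_serum_creatinine
        if scr is None or scr <= 0:
            raise DomainError("spot period needs a positive serum creatinine")
        clearances.append(
            per.urine_creatinine_umol_l * per.urine_volume_ml / (scr * per.duration_min))
    return sum(clearances) / len(clearances)


def egfr_mdrd(serum_creatinine_umol_l: float, age_y: float, sex: Sex,
              ethnicity_black: bool, coefficient: float = 175.0) -> float:
    """MDRD estimated GFR, mL/min/1.73 m2.

    ``coefficient * (Scr/88.4)^-1.154 * age^-0.203 * 0.742[female] * 1.212[black]``
    with serum creatinine in µmol/L.  ``coefficient`` 175 is the
    IDMS-traceable re-expression; 186 the original.  Not validated below
    18 years.
    """
    if serum_creatinine_umol_l <= 0:
        raise DomainError("serum creatinine must be > 0")
    if age_y < 18:
        raise DomainError("MDRD equation is not validated for age < 18")
    value = (coefficient
             * (serum_creatinine_umol_l / _MDRD_SCR_NORM) ** -1.154
             * age_y ** -0.203)
    if sex == Sex.FEMALE:
        value *= 0.742
    if ethnicity_black:
        value *= 1.212
    return value


def bsa_dubois(weight_kg: float, height_m: float) -> float:
    """Du Bois body surface area, m2: 0.007184 * W^0.425 * (100H)^0.725."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("weight and height must be > 0")
    return 0.007184 * weight_kg ** 0.425 * (height_m * 100.0) ** 0.725


def deindex_gfr(gfr_indexed: float, bsa: float) -> float:
    """Convert mL/min/1.73 m2 to absolute mL/min for a given BSA."""
    return gfr_indexed * bsa / 1.73


def clearance_result(patient: PatientRecord, visit: VisitRecord,
                     mdrd_coefficient: float = 175.0) -> ClearanceResult:
    """Compute every clearance quantity available for a visit."""
    bsa = bsa_dubois(visit.weight_kg, patient.height_m)
    egfr_idx = egfr_mdrd(visit.serum.creatinine_umol_l, patient.age_at(visit),
                         patient.sex, patient.ethnicity_black, mdrd_coefficient)
    crcl = crcl_24h_from_visit(visit) if visit.urine24h is not None else None
    frac = (fractional_crcl(visit.clearance, visit.serum.creatinine_umol_l)
            if visit.clearance is not None and visit.clearance.periods else None)
    return ClearanceResult(crcl, frac, egfr_idx, deindex_gfr(egfr_idx, bsa), bsa)
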