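"""Dietary intake estimation from a validated 24-h urine ionogram.

All estimators assume steady state: daily excretion equals daily intake for
the solute considered.

* Salt: NaCl intake [g/day] = 24-h natriuresis [mmol/day] / 17.
* Protein: intake [g/kg/day] = 24-h urea [mmol/day] x 0.2 / weight [kg];
  additionally normalised to the ideal weight of a 22 kg/m2 BMI
  (22 x height^2) so follow-up comparisons are insensitive to weight change.
  The simplified urea-only coefficient is the default; the full Maroni
  formula (6.25 x [urea nitrogen + 0.031 x weight]) is available for
  comparison via ``use_maroni``.
* Osmoles: excretion [mosm/day] = osmolarity [mosm/L] x volume [mL/day]/1000;
  diuresis itself serves as the water-intake proxy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .cohort import PatientRecord, Sex, VisitRecord
from .constants import DEFAULT_CONSTANTS, StudyConstants
from .errors import DomainError

#: g of nitrogen per mmol urea (MW of the two N atoms, 28 g/mol).
UREA_N_G_PER_MMOL = 0.028
#: Maroni non-urea nitrogen term, g N per kg body weight per day.
MARONI_NON_UREA_N = 0.031
#: Classical protein-to-nitrogen mass ratio.
PROTEIN_PER_G_N = 6.25


@dataclass(frozen=True)
class DietEstimate:
    nacl_intake: Optional[float]            # g/day
    protein_intake_raw: Optional[float]     # g/kg actual weight/day
    protein_intake_bmi22: Optional[float]   # g/kg ideal (BMI 22) weight/day
    osmole_excretion: Optional[float]       # mosm/day
    water_proxy_diuresis: Optional[float]   # mL/day
    calcium_excretion: Optional[float]      # mmol/day
    phosphate_excretion: Optional[float]    # mmol/day
    ammonium_excretion: Optional[float]     # mmol/day


@dataclass(frozen=True)
class ClinicalFlags:
    """Complication/compliance indicators; ``None`` when inputs are missing."""

    anemia: Optional[bool]
    secondary_hpt: Optional[bool]
    bp_above_target: Optional[bool]
    protein_compliant: Optional[bool]
    salt_compliant: Optional[bool]


def nacl_intake(urine_sodium_mmol_day: float,
                constants: StudyConstants = DEFAULT_CONSTANTS) -> float:
    """Estimated salt intake, g/day, from 24-h natriuresis."""
    if urine_sodium_mmol_day < 0:
        raise DomainError("urinary sodium must be >= 0")
    return urine_sodium_mmol_day / constants.na_mmol_per_g_nacl


def protein_intake(urea_mmol_day: float, weight_kg: float, height_m: float,
                   constants: StudyConstants = DEFAULT_CONSTANTS,
                   use_maroni: bool = False) -> tuple[float, float]:
    """Estimated protein intake as (per actual kg, per BMI-22 ideal kg), g/kg/day."""
    if weight_kg <= 0 or height_m <= 0:
        raise DomainError("weight and height must be > 0")
    if urea_mmol_day < 0:
        raise DomainError("urinary urea must be >= 0")
    ideal_weight = constants.reference_bmi * height_m ** 2
    if use_maroni:
        grams = PROTEIN_PER_G_N * (urea_mmol_day * UREA_N_G_PER_MMOL
                                   + MARONI_NON_UREA_N * weight_kg)
    else:
        grams = urea_mmol_day * constants.urea_to_protein_coeff
    return grams / weight_kg, grams / ideal_weight


def osmole_excretion(osmolarity_mosm_l: float, volume_ml_day: float) -> float:
    """Daily osmole excretion, mosm/day."""
    if osmolarity_mosm_l < 0 or volume_ml_day < 0:
        raise DomainError("osmolarity and volume must be >= 0")
    return osmolarity_mosm_l * volume_ml_day / 1000.0


def diet_estimate(patient: PatientRecord, visit: VisitRecord,
                  constants: StudyConstants = DEFAULT_CONSTANTS,
                  use_maroni: bool = False) -> DietEstimate:
    """Per-visit diet estimate; missing analytes propagate as ``None``."""
    u = visit.urine24h
    if u is None:
        return DietEstimate(*([None] * 8))
    nacl = nacl_intake(u.sodium_mmol, constants) if u.sodium_mmol is not None else None
    if u.urea_mmol is not None:
        raw, bmi22 = protein_intake(u.urea_mmol, visit.weight_kg, patient.height_m,
                                    constants, use_maroni)
    else:
        raw = bmi22 = None
    osm = (osmole_excretion(u.osmolarity_mosm_l, u.volume_ml)
           if u.osmolarity_mosm_l is not None else None)
    return DietEstimate(nacl, raw, bmi22, osm, u.volume_ml,
                        u.calcium_mmol, u.phosphate_mmol, u.ammonium_mmol)


def clinical_flags(patient: PatientRecord, visit: VisitRecord, diet: DietEstimate,
                   constants: StudyConstants = DEFAULT_CONSTANTS) -> ClinicalFlags:
    """Derive complication and compliance flags from one visit.

    Anemia: Hb < 13 g/dL (males) / < 12 g/dL (females).  Secondary
    hyperparathyroidism: PTH above the assay upper normal.  Blood pressure
    above target: systolic > 130 or diastolic > 80 mmHg (strict, matching a
    'BP > 130/80' prevalence).  Protein compliance: raw intake below the
    g/kg/day target; salt compliance: NaCl intake at or below the target.
    """
    hb = visit.serum.hemoglobin_g_dl
    hb_cut = (constants.hb_threshold_male if patient.sex == Sex.MALE
              else constants.hb_threshold_female)
    anemia = None if hb is None else hb < hb_cut
    pth = visit.serum.pth_pg_ml
    shpt = None if pth is None else pth > constants.pth_upper_normal
    if visit.systolic_bp is None or visit.diastolic_bp is None:
        bp = None
    else:
        bp = (visit.systolic_bp > constants.bp_target_sys
              or visit.diastolic_bp > constants.bp_target_dia)
    prot = (None if diet.protein_intake_raw is None
            else diet.protein_intake_raw < constants.protein_target)
    salt = (None if diet.nacl_intake is None
            else diet.nacl_intake <= constants.salt_target)
    return ClinicalFlags(anemia, shpt, bp, prot, salt)
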