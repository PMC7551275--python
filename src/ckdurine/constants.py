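"""Study constants: thresholds, conversion coefficients and clinical targets.

Single source of truth for every tunable number in the analysis.  Units are
fixed here and never inferred from data:

* ``validity_threshold`` / ``stringent_threshold`` — maximum acceptable
  relative delta between the measured 24-h creatinine clearance (or excretion)
  and its reference, as a fraction (0.30 and 0.15).
* ``urea_to_protein_coeff`` — g of dietary protein per mmol of 24-h urinary
  urea (0.2), i.e. protein intake [g/day] = urea [mmol/day] x 0.2.
* ``na_mmol_per_g_nacl`` — 17 mmol sodium per g NaCl; salt intake [g/day] =
  natriuresis [mmol/day] / 17.
* ``reference_bmi`` — 22 kg/m2, the body-mass index used to normalise protein
  intake to an ideal weight so intakes are comparable across weight change.
* ``mdrd_coefficient`` — 175 selects the IDMS-traceable 4-variable MDRD
  equation; set 186 for the original calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

from .errors import ConfigError


@dataclass(frozen=True)
class StudyConstants:
    validity_threshold: float = 0.30
    stringent_threshold: float = 0.15
    urea_to_protein_coeff: float = 0.2   # g protein / mmol urea
    na_mmol_per_g_nacl: float = 17.0
    reference_bmi: float = 22.0          # kg/m2
    protein_target: float = 1.0          # g/kg/day, compliance cut-off
    salt_target: float = 6.0             # g NaCl/day, guideline default
    bp_target_sys: float = 130.0         # mmHg
    bp_target_dia: float = 80.0          # mmHg
    hb_threshold_male: float = 13.0      # g/dL
    hb_threshold_female: float = 12.0    # g/dL
    pth_upper_normal: float = 65.0       # pg/mL (assay upper normal)
    mdrd_coefficient: float = 175.0      # 175 = IDMS-traceable, 186 = original

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ConfigError(f"constant {f.name!r} must be a positive number, got {v!r}")
        if not self.stringent_threshold < self.validity_threshold:
            raise ConfigError("stringent_threshold must be smaller than validity_threshold")

    def with_overrides(self, overrides: Mapping[str, float] | None) -> "StudyConstants":
        if not overrides:
            return self
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigError(f"unknown constant(s): {sorted(unknown)}")
        return dataclasses.replace(self, **dict(overrides))


DEFAULT_CONSTANTS = StudyConstants()
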