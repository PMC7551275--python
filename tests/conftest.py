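import dataclasses

import pytest

from ckdurine import (ClearanceStudy, DEFAULT_CONSTANTS, GeneratorConfig,
                      PatientRecord, SerumPanel, Sex, SpotPeriod,
                      UrineCollection24h, VisitRecord, default_table)


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def expected_table():
    return default_table()


def make_spot_periods(clearance_ml_min, serum_creatinine, n=6, duration=30.0,
                      volume=100.0):
    """Periods whose per-period clearance is exactly `clearance_ml_min`."""
    conc = clearance_ml_min * serum_creatinine * duration / volume
    return [SpotPeriod(duration, volume, conc, serum_creatinine) for _ in range(n)]


def make_visit(patient_id="P1", visit_index=1, years=0.0, weight=70.0,
               serum_creatinine=134.0, mgfr=42.3, spot_clearance=56.9,
               urine_creatinine=13.1, urine_volume=2175.0, **urine_kwargs):
    serum = SerumPanel(creatinine_umol_l=serum_creatinine)
    clearance = ClearanceStudy(
        mgfr, make_spot_periods(spot_clearance, serum_creatinine))
    urine = UrineCollection24h(volume_ml=urine_volume,
                               creatinine_mmol=urine_creatinine, **urine_kwargs)
    return VisitRecord(patient_id, visit_index, years, weight, 132.0, 77.0,
                       serum, clearance, urine)


def make_patient(patient_id="P1", sex=Sex.MALE, height=1.70, age=60.8,
                 n_visits=0, **visit_kwargs):
    p = PatientRecord(patient_id, sex, False, height, age, False, True)
    for i in range(n_visits):
        p.visits.append(make_visit(patient_id, visit_index=i + 1, years=float(i),
                                   **visit_kwargs))
    return p


def noisefree_config(seed, n_patients, **overrides):
    """Generator configuration with all noise off; error processes stay on."""
    return dataclasses.replace(GeneratorConfig(seed=seed, n_patients=n_patients),
                               **overrides)


def perfect_config(seed, n_patients, **overrides):
    """Noise off and completeness factor exactly 1 everywhere."""
    return noisefree_config(seed, n_patients, p_incomplete=0.0, p_excess=0.0,
                            completeness_valid_range=(1.0, 1.0), **overrides)
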