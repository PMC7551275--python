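"""Generate a synthetic CKD cohort with planted collection errors.

The generator plants a completeness factor f on each 24-h collection
(f < 0.7 incomplete, f > 1.3 excess) and records it in a truth table, so
every downstream stage can be checked against ground truth.
"""

from ckdurine import generate, paper_preset

patients, truth = generate(paper_preset(seed=42, n_patients=50))

print(f"patients: {len(patients)}, visits: {sum(len(p.visits) for p in patients)}")
print("\nplanted collection statuses (truth table):")
print(truth["planted_status"].value_counts().to_string())

p = patients[0]
v = p.visits[0]
print(f"\nfirst patient: {p.patient_id}, {p.sex.value}, "
      f"{p.baseline_age_y:.0f} y, {p.height_m:.2f} m")
print(f"  visit 1: mGFR {v.clearance.mgfr_indexed:.1f} mL/min/1.73m2, "
      f"serum creatinine {v.serum.creatinine_umol_l:.0f} µmol/L")
print(f"  24-h urine: {v.urine24h.volume_ml:.0f} mL, "
      f"creatinine {v.urine24h.creatinine_mmol:.1f} mmol, "
      f"sodium {v.urine24h.sodium_mmol:.0f} mmol")
print("\nEach visit carries a full serum panel, six spot-urine clearance "
      "periods and the 24-h ionogram the validation step needs.")
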