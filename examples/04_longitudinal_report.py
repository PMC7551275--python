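"""Longitudinal monitoring of patients with valid collections at every visit.

Restricts the cohort to the valid-at-all-visits subset, then reports
per-visit medians (IQR) with a Friedman test across the three visits —
the repeated-measures view a nephrology team would use to track renal
function decline and dietary compliance.
"""

from ckdurine import (assess_cohort, cohort_flow, generate, longitudinal_table,
                      paper_preset)
from ckdurine.report import DEFAULT_LONGITUDINAL_DIET

patients, _ = generate(paper_preset(seed=11, n_patients=300))

flow = cohort_flow(patients, "fractional", 0.30)
print(f"cohort flow: {flow.n_total} patients, "
      f"{flow.n_valid_all_visits} valid at all visits, "
      f"{flow.n_valid_none} valid at none")

df = assess_cohort(patients, "fractional", threshold=0.30)
ok = df.assign(valid=df["status"] == "valid").groupby("patient_id")["valid"].all()
validated = [p for p in patients if ok.get(p.patient_id, False)]

tab = longitudinal_table(validated, [("mgfr", "c"), ("protein_intake", "c"),
                                     ("nacl_intake", "c"),
                                     ("protein_compliant", "b")])
print("\nvariable            v1 median   v2 median   v3 median   Friedman p")
for row in tab.itertuples(index=False):
    if row.kind == "c":
        cells = f"{row.v1_median:>9.2f}   {row.v2_median:>9.2f}   {row.v3_median:>9.2f}"
    else:
        cells = f"{row.v1_pct:>8.1f}%   {row.v2_pct:>8.1f}%   {row.v3_pct:>8.1f}%"
    print(f"{row.variable:<18}{cells}   {row.p_value:.2g}")

print("\nmGFR declines and protein intake falls over follow-up (planted "
      "trends); salt intake is stable — the Friedman p-values reflect this.")
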