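"""Report assembly: prevalence, flow, group comparison, longitudinal tables."""

import numpy as np
import pytest

from ckdurine import (DEFAULT_CONSTANTS, assess_cohort, cohort_flow, generate,
                      group_comparison_table, longitudinal_table,
                      validity_prevalence, visit_table)
from ckdurine.errors import DomainError
from ckdurine.report import (DEFAULT_LONGITUDINAL_DIET, prevalence_frame,
                             render_markdown)

from conftest import noisefree_config, perfect_config


def _scale_collection(visit, factor):
    u = visit.urine24h
    for attr in ("volume_ml", "creatinine_mmol", "sodium_mmol", "urea_mmol",
                 "calcium_mmol", "phosphate_mmol", "ammonium_mmol",
                 "protein_mg", "albumin_mg"):
        v = getattr(u, attr)
        if v is not None:
            setattr(u, attr, v * factor)


class TestValidityPrevalence:
    def test_perfect_cohort_fully_valid(self):
        patients, _ = generate(perfect_config(71, 20))
        for prev in validity_prevalence(patients, "fractional", 0.30):
            assert prev.pct_valid == 100.0
            assert prev.n_valid == prev.n_assessed

    def test_planted_twenty_percent_invalid(self):
        """Scaling exactly 20% of collections by 0.5 yields 80% valid."""
        patients, _ = generate(perfect_config(73, 30))
        visits = [v for p in patients for v in p.visits]
        for v in visits[::5]:  # exactly 18 of 90
            _scale_collection(v, 0.5)
        prevs = validity_prevalence(patients, "fractional", 0.30)
        total_valid = sum(p.n_valid for p in prevs)
        total = sum(p.n_assessed for p in prevs)
        assert total == 90 and total_valid == 72

    def test_partition_counts_sum(self):
        patients, _ = generate(noisefree_config(79, 40))
        for prev in validity_prevalence(patients, "fractional", 0.30):
            assert prev.n_valid + prev.n_incomplete + prev.n_excess == prev.n_assessed

    def test_stringent_prevalence_nested(self):
        patients, _ = generate(noisefree_config(83, 60))
        loose = validity_prevalence(patients, "fractional", 0.30)
        strict = validity_prevalence(patients, "fractional", 0.15)
        for l, s in zip(loose, strict):
            assert s.pct_valid <= l.pct_valid

    def test_recount_equality_with_assessments(self):
        patients, _ = generate(noisefree_config(89, 30))
        df = assess_cohort(patients, "fractional", threshold=0.30)
        prevs = validity_prevalence(patients, "fractional", 0.30)
        for prev in prevs:
            sub = df[df["visit_index"] == prev.visit_index]
            assert prev.n_valid == int((sub["status"] == "valid").sum())


class TestCohortFlow:
    def test_all_valid_everyone(self):
        patients, _ = generate(perfect_config(97, 15))
        flow = cohort_flow(patients, "fractional", 0.30)
        assert flow.n_valid_all_visits == flow.n_total == 15
        assert flow.n_valid_none == 0

    def test_counts_match_planted_patterns(self):
        patients, truth = generate(noisefree_config(101, 80))
        flow = cohort_flow(patients, "fractional", 0.30)
        per = truth.assign(valid=truth["planted_status"] == "valid") \
                   .groupby("patient_id")["valid"]
        assert flow.n_valid_all_visits == int(per.all().sum())
        assert flow.n_valid_none == int((~per.any()).sum())

    def test_mixed_single_patient_in_neither_extreme(self):
        patients, _ = generate(perfect_config(103, 1))
        _scale_collection(patients[0].visits[0], 0.5)  # 1 invalid, 2 valid
        flow = cohort_flow(patients, "fractional", 0.30)
        assert flow.n_valid_all_visits == 0 and flow.n_valid_none == 0

    def test_unequal_visit_counts_rejected_naming_offender(self):
        patients, _ = generate(perfect_config(107, 3))
        patients[1].visits.pop()
        with pytest.raises(DomainError, match=patients[1].patient_id):
            cohort_flow(patients, "fractional", 0.30)


class TestGroupComparison:
    @staticmethod
    def _cohort_with_groups(seed=109, n=60):
        """Cohort where ~1/4 of patients have all collections scaled to 0.5."""
        patients, _ = generate(perfect_config(seed, n))
        for p in patients[::4]:
            for v in p.visits:
                _scale_collection(v, 0.5)
        return patients

    def test_group_sizes(self):
        patients = self._cohort_with_groups()
        df = group_comparison_table(patients, "fractional", 0.30)
        row = df[df["variable"] == "mgfr"].iloc[0]
        assert row["valid_all_n"] == 45 and row["valid_none_n"] == 15

    def test_identical_variable_not_significant(self):
        patients = self._cohort_with_groups()
        for p in patients:  # make natremia identical across everyone
            for i, v in enumerate(p.visits):
                v.serum.sodium_mmol_l = 141.0 + i
        df = group_comparison_table(patients, "fractional", 0.30)
        row = df[df["variable"] == "natremia"].iloc[0]
        assert row["p_value"] > 0.8

    def test_planted_three_sd_shift_detected(self):
        patients = self._cohort_with_groups(seed=113, n=320)
        invalid_ids = {p.patient_id for p in patients[::4]}
        rng = np.random.default_rng(0)
        for p in patients:  # hemoglobin: N(10,1) vs N(13,1) between groups
            shift = 3.0 if p.patient_id in invalid_ids else 0.0
            for v in p.visits:
                v.serum.hemoglobin_g_dl = 10.0 + shift + rng.normal(0, 1)
        df = group_comparison_table(patients, "fractional", 0.30)
        row = df[df["variable"] == "hemoglobin"].iloc[0]
        assert row["p_value"] < 0.001

    def test_variable_missing_in_one_group_flagged(self):
        patients = self._cohort_with_groups()
        invalid_ids = {p.patient_id for p in patients[::4]}
        for p in patients:
            if p.patient_id in invalid_ids:
                for v in p.visits:
                    v.serum.calcitriol_pg_ml = None
        df = group_comparison_table(patients, "fractional", 0.30,
                                    variables=[("calcitriol", "c")])
        row = df.iloc[0]
        assert np.isnan(row["p_value"]) and "missing" in row["note"]

    def test_empty_group_rejected(self):
        patients, _ = generate(perfect_config(127, 10))  # nobody invalid
        with pytest.raises(DomainError):
            group_comparison_table(patients, "fractional", 0.30)


class TestLongitudinalTable:
    def test_time_constant_variable_not_significant(self):
        patients, _ = generate(perfect_config(131, 30))
        for p in patients:
            for v in p.visits:
                v.serum.bicarbonate_mmol_l = 26.0  # constant -> fully tied
        df = longitudinal_table(patients, [("bicarbonate", "c")])
        assert df.iloc[0]["p_value"] == 1.0

    def test_planted_gfr_decline_detected(self):
        """-2.6 mL/min/year decline at n = 168: Friedman p far below 0.001."""
        patients, _ = generate(perfect_config(137, 168))
        df = longitudinal_table(patients, [("mgfr", "c")])
        assert df.iloc[0]["p_value"] < 0.001

    def test_row_order_follows_configuration(self):
        patients, _ = generate(perfect_config(139, 10))
        variables = [("pth", "c"), ("weight_kg", "c"), ("mgfr", "c")]
        df = longitudinal_table(patients, variables)
        assert list(df["variable"]) == ["pth", "weight_kg", "mgfr"]

    def test_binary_variable_reported_as_percentage(self):
        patients, _ = generate(perfect_config(149, 40))
        df = longitudinal_table(patients, [("protein_compliant", "b")])
        row = df.iloc[0]
        assert 0.0 <= row["v1_pct"] <= 100.0
        assert np.isfinite(row["p_value"])

    def test_single_visit_rejected(self):
        patients, _ = generate(perfect_config(151, 5, n_visits=1))
        with pytest.raises(DomainError):
            longitudinal_table(patients, [("mgfr", "c")])


def test_load_variables_from_yaml(tmp_path):
    from ckdurine.report import load_variables
    cfg = tmp_path / "vars.yaml"
    cfg.write_text("variables:\n- {column: mgfr, kind: c}\n- {column: anemia, kind: b}\n")
    assert load_variables(str(cfg)) == [("mgfr", "c"), ("anemia", "b")]
    bad = tmp_path / "bad.yaml"
    bad.write_text("variables:\n- {column: mgfr, kind: x}\n")
    from ckdurine.errors import ConfigError
    with pytest.raises(ConfigError):
        load_variables(str(bad))


def test_visit_table_maroni_option_changes_protein_only():
    patients, _ = generate(perfect_config(163, 5))
    a = visit_table(patients)
    b = visit_table(patients, use_maroni=True)
    # maroni = 0.175*urea/w + 0.19375 vs simple = 0.2*urea/w: differs everywhere
    # except at exactly 1.55 g/kg/day, and leaves non-protein columns untouched
    assert (b["protein_intake"] != a["protein_intake"]).all()
    assert (a["nacl_intake"] == b["nacl_intake"]).all()


def test_render_markdown_smoke():
    patients, _ = generate(noisefree_config(157, 20))
    prevs = validity_prevalence(patients, "fractional", 0.30)
    flow = cohort_flow(patients, "fractional", 0.30)
    text = render_markdown(flow, prevs)
    assert "Cohort flow" in text and "% valid" in text
    assert prevalence_frame(prevs).shape[0] == len(prevs)
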