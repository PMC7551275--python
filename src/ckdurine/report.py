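"""Cohort-level result surfaces.

Builds the analysis outputs of a 24-h urine validation study: per-visit
validity prevalence under a chosen criterion/threshold, the patient flow
(valid at every visit vs at none), a two-group comparison of baseline
characteristics between those extremes (Mann-Whitney for continuous
variables, chi-square for binary ones), and longitudinal per-visit
median/IQR tables with Friedman p-values across visits.

Binary variables in the longitudinal table are reported as per-visit
percentages and tested with the Friedman statistic applied to the 0/1
indicators, which for binary data is the Cochran Q test under another name.

Everything operates on a tidy per-visit feature frame (``visit_table``)
combining raw measurements with derived clearances, diet estimates and
clinical flags, so report content is configuration (column name + kind),
not code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, Sex
from .constants import DEFAULT_CONSTANTS, StudyConstants
from .diet import clinical_flags, diet_estimate
from .errors import DomainError
from .renal import clearance_result
from .stats import SummaryStat, chi_square, friedman, mann_whitney, summarize
from .validation import (ExpectedCreatinineTable, ValidityCriterion,
                         ValidityStatus, assess_cohort)


@dataclass(frozen=True)
class ValidityPrevalence:
    visit_index: int
    criterion: str
    threshold: float
    n_assessed: int
    n_valid: int
    n_incomplete: int
    n_excess: int

    @property
    def pct_valid(self) -> float:
        return 100.0 * self.n_valid / self.n_assessed if self.n_assessed else float("nan")


@dataclass(frozen=True)
class CohortFlow:
    n_total: int
    n_valid_all_visits: int
    n_valid_none: int
    per_visit_valid: dict[int, int]


def _flag(value: Optional[bool]) -> float:
    return float("nan") if value is None else float(value)


def _num(value: Optional[float]) -> float:
    return float("nan") if value is None else float(value)


def visit_table(patients: Sequence[PatientRecord],
                constants: StudyConstants = DEFAULT_CONSTANTS,
                use_maroni: bool = False) -> pd.DataFrame:
    """Tidy per-visit feature frame: raw, derived and flag columns (NaN = missing)."""
    rows = []
    for p in patients:
        for v in p.visits:
            cr = clearance_result(p, v, constants.mdrd_coefficient)
            d = diet_estimate(p, v, constants, use_maroni)
            fl = clinical_flags(p, v, d, constants)
            u = v.urine24h
            ucr = u.creatinine_mmol if u else None
            rows.append({
                "patient_id": p.patient_id, "visit_index": v.visit_index,
                "sex_male": float(p.sex == Sex.MALE),
                "age_y": p.age_at(v), "height_m": p.height_m,
                "weight_kg": v.weight_kg,
                "bmi": v.weight_kg / p.height_m ** 2,
                "diabetes": _flag(p.diabetes), "hypertension": _flag(p.hypertension),
                "systolic_bp": _num(v.systolic_bp), "diastolic_bp": _num(v.diastolic_bp),
                "bp_above_target": _flag(fl.bp_above_target),
                "mgfr": _num(v.clearance.mgfr_indexed if v.clearance else None),
                "serum_creatinine": v.serum.creatinine_umol_l,
                "natremia": _num(v.serum.sodium_mmol_l),
                "serum_potassium": _num(v.serum.potassium_mmol_l),
                "hemoglobin": _num(v.serum.hemoglobin_g_dl),
                "bicarbonate": _num(v.serum.bicarbonate_mmol_l),
                "phosphorus": _num(v.serum.phosphorus_mmol_l),
                "ionized_calcium": _num(v.serum.ionized_calcium_mmol_l),
                "pth": _num(v.serum.pth_pg_ml),
                "vitd_25oh": _num(v.serum.vitd_25oh_ng_ml),
                "calcitriol": _num(v.serum.calcitriol_pg_ml),
                "anemia": _flag(fl.anemia), "secondary_hpt": _flag(fl.secondary_hpt),
                "crcl_24h": _num(cr.crcl_24h),
                "fractional_crcl": _num(cr.fractional_crcl_mean),
                "egfr_mdrd": cr.egfr_mdrd_indexed,
                "urine_volume": _num(u.volume_ml if u else None),
                "urine_creatinine": _num(ucr),
                "urine_creatinine_per_kg": _num(
                    ucr / v.weight_kg if ucr is not None else None),
                "proteinuria_mg_mmol": _num(
                    u.protein_mg / ucr if u and u.protein_mg is not None else None),
                "acr_mg_mmol": _num(
                    u.albumin_mg / ucr if u and u.albumin_mg is not None else None),
                "nacl_intake": _num(d.nacl_intake),
                "protein_intake": _num(d.protein_intake_raw),
                "protein_intake_bmi22": _num(d.protein_intake_bmi22),
                "osmole_excretion": _num(d.osmole_excretion),
                "calcium_excretion": _num(d.calcium_excretion),
                "phosphate_excretion": _num(d.phosphate_excretion),
                "ammonium_excretion": _num(d.ammonium_excretion),
                "protein_compliant": _flag(fl.protein_compliant),
                "salt_compliant": _flag(fl.salt_compliant),
            })
    return pd.DataFrame(rows)


#: (column, kind) pairs; kind 'c' = continuous (median/IQR + Mann-Whitney or
#: Friedman), 'b' = binary 0/1 (percentage + chi-square or Friedman-on-indicators).
DEFAULT_GROUP_VARIABLES: list[tuple[str, str]] = [
    ("age_y", "c"), ("sex_male", "b"), ("bmi", "c"),
    ("diabetes", "b"), ("hypertension", "b"),
    ("mgfr", "c"), ("fractional_crcl", "c"), ("serum_creatinine", "c"),
    ("natremia", "c"), ("serum_potassium", "c"), ("hemoglobin", "c"),
    ("ionized_calcium", "c"), ("pth", "c"),
    ("urine_volume", "c"), ("proteinuria_mg_mmol", "c"), ("acr_mg_mmol", "c"),
    ("urine_creatinine", "c"), ("urine_creatinine_per_kg", "c"),
]

DEFAULT_LONGITUDINAL_CLINICAL: list[tuple[str, str]] = [
    ("bp_above_target", "b"), ("weight_kg", "c"),
    ("mgfr", "c"), ("fractional_crcl", "c"), ("serum_creatinine", "c"),
    ("hemoglobin", "c"), ("serum_potassium", "c"), ("bicarbonate", "c"),
    ("phosphorus", "c"), ("ionized_calcium", "c"), ("pth", "c"),
    ("secondary_hpt", "b"), ("vitd_25oh", "c"), ("calcitriol", "c"),
    ("proteinuria_mg_mmol", "c"), ("acr_mg_mmol", "c"),
    ("urine_creatinine_per_kg", "c"), ("anemia", "b"),
]

DEFAULT_LONGITUDINAL_DIET: list[tuple[str, str]] = [
    ("urine_volume", "c"), ("nacl_intake", "c"), ("protein_intake", "c"),
    ("protein_intake_bmi22", "c"), ("osmole_excretion", "c"),
    ("phosphate_excretion", "c"), ("calcium_excretion", "c"),
    ("ammonium_excretion", "c"), ("protein_compliant", "b"), ("salt_compliant", "b"),
]


def load_variables(path: str) -> list[tuple[str, str]]:
    """Load a report variable configuration from YAML.

    The file holds a ``variables:`` list of ``{column, kind}`` entries with
    kind 'c' (continuous) or 'b' (binary), in the order rows should appear.
    """
    import yaml

    from .errors import ConfigError
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    entries = doc.get("variables", doc if isinstance(doc, list) else None)
    if not isinstance(entries, list):
        raise ConfigError("report config must contain a 'variables' list")
    out = []
    for e in entries:
        if not isinstance(e, dict) or "column" not in e or e.get("kind") not in ("c", "b"):
            raise ConfigError(f"bad report variable entry: {e!r}")
        out.append((str(e["column"]), str(e["kind"])))
    return out


def validity_prevalence(patients: Sequence[PatientRecord],
                        criterion: ValidityCriterion | str, threshold: float,
                        constants: StudyConstants = DEFAULT_CONSTANTS,
                        table: Optional[ExpectedCreatinineTable] = None,
                        deindex: bool = True) -> list[ValidityPrevalence]:
    """Per-visit partition counts and percentage of valid collections.

    Visits where the criterion is unavailable are excluded from the
    denominator (they are unassessable, not invalid).
    """
    df = assess_cohort(patients, criterion, constants, table, threshold, deindex)
    out = []
    for vi, grp in df.groupby("visit_index", sort=True):
        assessed = grp[grp["status"].notna()]
        counts = assessed["status"].value_counts()
        out.append(ValidityPrevalence(
            int(vi), ValidityCriterion.parse(criterion).value, float(threshold),
            int(len(assessed)),
            int(counts.get(ValidityStatus.VALID.value, 0)),
            int(counts.get(ValidityStatus.INCOMPLETE.value, 0)),
            int(counts.get(ValidityStatus.EXCESS.value, 0))))
    return out


def prevalence_frame(prevalences: Sequence[ValidityPrevalence]) -> pd.DataFrame:
    return pd.DataFrame([{
        "visit_index": p.visit_index, "criterion": p.criterion,
        "threshold": p.threshold, "n_assessed": p.n_assessed,
        "n_valid": p.n_valid, "n_incomplete": p.n_incomplete,
        "n_excess": p.n_excess, "pct_valid": p.pct_valid,
    } for p in prevalences])


def _patient_validity(patients, criterion, threshold, constants, table, deindex):
    """Per patient: (all visits valid, no visit valid) based on assessed statuses."""
    df = assess_cohort(patients, criterion, constants, table, threshold, deindex)
    valid = df["status"] == ValidityStatus.VALID.value
    per = df.assign(valid=valid).groupby("patient_id")["valid"]
    return per.all(), per.any()


def cohort_flow(patients: Sequence[PatientRecord],
                criterion: ValidityCriterion | str, threshold: float,
                constants: StudyConstants = DEFAULT_CONSTANTS,
                table: Optional[ExpectedCreatinineTable] = None,
                deindex: bool = True) -> CohortFlow:
    """Study-flow counts: patients valid at every visit and at none."""
    counts = {p.patient_id: len(p.visits) for p in patients}
    expected = max(counts.values()) if counts else 0
    offenders = sorted(pid for pid, c in counts.items() if c != expected)
    if offenders:
        raise DomainError(f"patients with unequal visit counts: {offenders}")
    all_valid, any_valid = _patient_validity(
        patients, criterion, threshold, constants, table, deindex)
    df = assess_cohort(patients, criterion, constants, table, threshold, deindex)
    per_visit = {
        int(vi): int((grp["status"] == ValidityStatus.VALID.value).sum())
        for vi, grp in df.groupby("visit_index", sort=True)}
    return CohortFlow(len(patients), int(all_valid.sum()),
                      int((~any_valid).sum()), per_visit)


def _summary_cols(prefix: str, s: SummaryStat) -> dict:
    return {f"{prefix}_median": s.median, f"{prefix}_q1": s.q1,
            f"{prefix}_q3": s.q3, f"{prefix}_n": s.n}


def group_comparison_table(patients: Sequence[PatientRecord],
                           criterion: ValidityCriterion | str, threshold: float,
                           constants: StudyConstants = DEFAULT_CONSTANTS,
                           table: Optional[ExpectedCreatinineTable] = None,
                           variables: Optional[Sequence[tuple[str, str]]] = None,
                           baseline_visit: int = 1,
                           deindex: bool = True) -> pd.DataFrame:
    """Baseline comparison of valid-at-all-visits vs valid-at-none patients.

    Continuous variables: median (IQR) per group + Mann-Whitney p.  Binary
    variables: percentage per group + chi-square p.  A variable entirely
    missing in a group is flagged and not tested.
    """
    all_valid, any_valid = _patient_validity(
        patients, criterion, threshold, constants, table, deindex)
    g1_ids = set(all_valid[all_valid].index)
    g2_ids = set(any_valid[~any_valid].index)
    if not g1_ids or not g2_ids:
        raise DomainError("both comparison groups must be non-empty")
    vt = visit_table(patients, constants)
    base = vt[vt["visit_index"] == baseline_visit]
    g1 = base[base["patient_id"].isin(g1_ids)]
    g2 = base[base["patient_id"].isin(g2_ids)]

    rows = []
    for col, kind in (variables or DEFAULT_GROUP_VARIABLES):
        a = g1[col].to_numpy(dtype=float)
        b = g2[col].to_numpy(dtype=float)
        a_ok, b_ok = a[~np.isnan(a)], b[~np.isnan(b)]
        row: dict = {"variable": col, "kind": kind, "note": ""}
        if kind == "c":
            row.update(_summary_cols("valid_all", summarize(a)))
            row.update(_summary_cols("valid_none", summarize(b)))
            if a_ok.size == 0 or b_ok.size == 0:
                row.update(statistic=float("nan"), p_value=float("nan"),
                           test="", note="variable missing in one group")
            else:
                res = mann_whitney(a_ok, b_ok)
                row.update(statistic=res.statistic, p_value=res.p_value,
                           test=res.method.value)
        else:
            row.update(valid_all_pct=100.0 * a_ok.mean() if a_ok.size else float("nan"),
                       valid_all_n=int(a_ok.size),
                       valid_none_pct=100.0 * b_ok.mean() if b_ok.size else float("nan"),
                       valid_none_n=int(b_ok.size))
            tab = [[int(a_ok.sum()), int(a_ok.size - a_ok.sum())],
                   [int(b_ok.sum()), int(b_ok.size - b_ok.sum())]]
            try:
                res = chi_square(tab)
                row.update(statistic=res.statistic, p_value=res.p_value,
                           test=res.method.value)
            except DomainError as e:
                row.update(statistic=float("nan"), p_value=float("nan"),
                           test="", note=str(e))
        rows.append(row)
    return pd.DataFrame(rows)


def longitudinal_table(patients: Sequence[PatientRecord],
                       variables: Optional[Sequence[tuple[str, str]]] = None,
                       constants: StudyConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Per-visit medians (IQR) / percentages with Friedman p across visits.

    Callers pass the cohort restricted to the valid-at-all-visits subset.
    Rows (patients) with a missing value at any visit are dropped listwise
    for the test; row order of the output equals the configured variable
    order.  Requires at least two visits.
    """
    vt = visit_table(patients, constants)
    visits = sorted(vt["visit_index"].unique())
    if len(visits) < 2:
        raise DomainError("longitudinal table needs at least 2 visits")
    rows = []
    for col, kind in (variables or DEFAULT_LONGITUDINAL_CLINICAL):
        wide = vt.pivot(index="patient_id", columns="visit_index", values=col)
        wide = wide.reindex(columns=visits)
        row: dict = {"variable": col, "kind": kind}
        for vi in visits:
            vals = wide[vi].to_numpy(dtype=float)
            ok = vals[~np.isnan(vals)]
            if kind == "c":
                row.update(_summary_cols(f"v{vi}", summarize(vals)))
            else:
                row[f"v{vi}_pct"] = 100.0 * ok.mean() if ok.size else float("nan")
                row[f"v{vi}_n"] = int(ok.size)
        try:
            res = friedman(wide.to_numpy(dtype=float))
            row.update(statistic=res.statistic, p_value=res.p_value,
                       n_complete=res.n[0], n_dropped=res.n_dropped)
        except DomainError as e:
            row.update(statistic=float("nan"), p_value=float("nan"),
                       n_complete=0, note=str(e))
        rows.append(row)
    return pd.DataFrame(rows)


def render_markdown(flow: CohortFlow,
                    prevalences: Sequence[ValidityPrevalence],
                    group_table: Optional[pd.DataFrame] = None,
                    longitudinal: Optional[dict[str, pd.DataFrame]] = None) -> str:
    """Plain-text/markdown report; percentages rounded to one decimal."""
    lines = ["# 24-h urine collection validity report", ""]
    lines.append("## Cohort flow")
    lines.append(f"- patients: {flow.n_total}")
    lines.append(f"- valid collection at every visit: {flow.n_valid_all_visits}")
    lines.append(f"- valid collection at no visit: {flow.n_valid_none}")
    lines.append("")
    lines.append("## Validity prevalence")
    lines.append("| visit | criterion | threshold | n | valid | incomplete | excess | % valid |")
    lines.append("|---|---|---|---|---|---|---|---|")
    for p in prevalences:
        lines.append(
            f"| {p.visit_index} | {p.criterion} | {p.threshold:g} | {p.n_assessed} "
            f"| {p.n_valid} | {p.n_incomplete} | {p.n_excess} | {p.pct_valid:.1f} |")
    lines.append("")
    def _table_text(df: pd.DataFrame) -> str:
        return "```\n" + df.to_string(
            index=False, float_format=lambda x: f"{x:.3g}") + "\n```"

    if group_table is not None:
        lines.append("## Baseline comparison: valid at all visits vs at none")
        lines.append(_table_text(group_table))
        lines.append("")
    for title, tab in (longitudinal or {}).items():
        lines.append(f"## {title}")
        lines.append(_table_text(tab))
        lines.append("")
    return "\n".join(lines)
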