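"""End-to-end study orchestration.

Runs the full design on a clinical table with activity summaries: QC,
dichotomization, imputation, two-cluster phenotyping, per-cluster MVPA
quartiles, Kaplan-Meier and Cox models (unadjusted and adjusted), a pooled
Poisson spline dose-response with threshold extraction, and a flow log of
every exclusion.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dose_response as dr
from . import phenotyping as ph
from . import survival as sv

__all__ = ["RunConfig", "StudyReport", "run_study", "characteristics_table", "percentage_summary"]

SUBGROUP_MODES = ("primary", "rhythm_control", "sensitivity_no_procedure")


@dataclass
class RunConfig:
    censoring: sv.CensoringPolicy = field(default_factory=sv.CensoringPolicy)
    dichotomization: ph.DichotomizationRules = field(default_factory=ph.DichotomizationRules)
    spline: dr.SplineSpec = field(default_factory=dr.SplineSpec)
    threshold_rule: dr.ThresholdRule = field(default_factory=dr.ThresholdRule)
    adjustment_set: str = "standard"
    subgroup_mode: str = "primary"
    n_clusters: int = 2
    min_wear_days: float = 3.0
    use_offset: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subgroup_mode not in SUBGROUP_MODES:
            raise ValueError(f"subgroup_mode must be one of {SUBGROUP_MODES}")
        if self.adjustment_set not in sv.ADJUSTMENT_SETS:
            raise ValueError(f"unknown adjustment set '{self.adjustment_set}'")


@dataclass
class StudyReport:
    flow_log: dict
    cluster_sizes: dict
    cluster_labels: np.ndarray
    quartile_tables: dict  # cluster -> characteristics DataFrame
    quartile_fits: dict  # cluster -> {'unadjusted': CoxFit, 'adjusted': CoxFit}
    cluster_contrast: sv.CoxFit | None
    cluster_comparison: pd.DataFrame | None
    dose_fit: dr.DoseResponseFit | None
    irr_curve: dr.IRRCurve | None
    thresholds: dr.ThresholdReport | None
    wald_linearity: tuple[float, float] | None
    km_curves: dict

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = {
            "flow_log": self.flow_log,
            "cluster_sizes": self.cluster_sizes,
            "quartile_hr_tables": {
                str(c): {k: json.loads(f.to_json()) for k, f in fits.items()}
                for c, fits in self.quartile_fits.items()
            },
            "cluster_contrast": json.loads(self.cluster_contrast.to_json())
            if self.cluster_contrast
            else None,
            "thresholds": self.thresholds.to_dict() if self.thresholds else None,
            "wald_linearity": list(self.wald_linearity) if self.wald_linearity else None,
        }
        return json.dumps(payload, indent=2, default=conv)


def percentage_summary(count: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    frac = 100.0 * count / denominator
    return int(math.floor(frac + 0.5)) if frac >= 0 else int(math.ceil(frac - 0.5))


def reconcile_flow(identified: int, exclusions: dict) -> dict:
    """Flow-diagram bookkeeping: analysed n = identified - sum(exclusions)."""
    analysed = identified - sum(exclusions.values())
    return {"identified": identified, "exclusions": dict(exclusions), "analysed": analysed}


def characteristics_table(data: pd.DataFrame, groups, continuous=(), binary=()) -> pd.DataFrame:
    """Median [IQR] / n (%) per group with ANOVA, chi-square and post-hoc flags.

    Continuous rows: per-group median [IQR] and a one-way ANOVA p-value, with
    pairwise t-test flags when the ANOVA is significant at 0.05. Binary rows:
    per-group n (%) and a chi-square p-value. Constant columns report a
    missing p-value.
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for col in continuous:
        vals = [data.loc[groups == g, col].dropna().to_numpy() for g in levels]
        cells = {}
        for g, v in zip(levels, vals):
            q1, med, q3 = np.percentile(v, [25, 50, 75]) if len(v) else (np.nan,) * 3
            cells[f"group_{g}"] = f"{med:.1f} [{q1:.1f}, {q3:.1f}]"
        if all(len(v) > 1 for v in vals) and np.concatenate(vals).std() > 0:
            p = float(stats.f_oneway(*vals).pvalue)
        else:
            p = np.nan
        flags = []
        if np.isfinite(p) and p < 0.05:
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    pij = float(stats.ttest_ind(vals[i], vals[j], equal_var=False).pvalue)
                    if pij < 0.05:
                        flags.append((int(levels[i]), int(levels[j])))
        rows.append({"variable": col, "type": "continuous", **cells, "p": p, "pairwise": flags})
    for col in binary:
        counts = []
        cells = {}
        for g in levels:
            v = data.loc[groups == g, col].dropna().to_numpy()
            k, m = int(np.nansum(v)), len(v)
            pct = percentage_summary(k, m) if m else np.nan
            cells[f"group_{g}"] = f"{k} ({pct})"
            counts.append([k, m - k])
        table = np.asarray(counts)
        if table[:, 0].sum() in (0, table.sum()) or np.any(table.sum(axis=1) == 0):
            p = np.nan  # constant column
        else:
            p = float(stats.chi2_contingency(table).pvalue)
        rows.append({"variable": col, "type": "binary", **cells, "p": p, "pairwise": []})
    return pd.DataFrame(rows)


_TABLE_CONTINUOUS = ["age", "bmi", "egfr", "haematocrit", "ggt", "mvpa_min_week",
                     "lpa_min_week", "sedentary_min_week"]
_TABLE_BINARY = ["sex_male", "heart_failure", "t2d", "hypertension", "heart_disease",
                 "stroke", "smoking_current", "alcohol_daily"]


def run_study(clinical: pd.DataFrame, config: RunConfig | None = None) -> StudyReport:
    """Execute the full analysis on a clinical table carrying activity columns.

    The table must provide the clinical/comorbidity columns consumed by
    :func:`afmvpa.phenotyping.dichotomize`, the date columns consumed by
    :func:`afmvpa.survival.build_survival_records`, ``mvpa_min_week`` and
    (for adjusted models) ``sedentary_min_week``; an optional boolean
    ``qc_pass`` column marks failed accelerometer QC.
    """
    config = config or RunConfig()
    identified = len(clinical)
    exclusions = {}

    if "qc_pass" in clinical:
        qc_fail = ~clinical["qc_pass"].astype(bool)
        exclusions["qc_failed"] = int(qc_fail.sum())
        clinical = clinical.loc[~qc_fail].reset_index(drop=True)
    else:
        exclusions["qc_failed"] = 0

    # rows missing every clustering variable cannot be imputed
    matrix = ph.dichotomize(clinical, config.dichotomization)
    all_missing = matrix.values.isna().all(axis=1).to_numpy()
    exclusions["missing_variables"] = int(all_missing.sum())
    if all_missing.any():
        clinical = clinical.loc[~all_missing].reset_index(drop=True)
        matrix = ph.dichotomize(clinical, config.dichotomization)

    matrix, n_imputed = ph.impute_missing(matrix)
    tree = ph.ward_linkage(matrix)
    labels = ph.cut_clusters(tree, config.n_clusters, matrix)
    clinical = clinical.copy()
    clinical["cluster"] = labels

    if "sedentary_min_week" not in clinical:
        clinical["sedentary_min_week"] = 0.0

    policy = config.censoring
    if config.subgroup_mode == "rhythm_control":
        policy = sv.CensoringPolicy(
            policy.max_followup_years, policy.exclude_event_on_diagnosis_day, "procedure"
        )
        clinical = clinical.loc[clinical["rhythm_control"] == 1.0].reset_index(drop=True)
    elif config.subgroup_mode == "sensitivity_no_procedure":
        clinical = clinical.loc[clinical["rhythm_control"] != 1.0].reset_index(drop=True)

    records, exc_log = sv.build_survival_records(clinical, policy)
    exclusions["event_before_index"] = exc_log.event_before_index
    flow = reconcile_flow(identified, exclusions)
    flow["n_imputed_cells"] = n_imputed

    cluster_sizes = {}
    quartile_tables = {}
    quartile_fits = {}
    km_curves = {}
    adj_terms = [t for t in sv.ADJUSTMENT_SETS[config.adjustment_set] if t in records]
    for c in sorted(records["cluster"].unique()):
        sub = records.loc[records["cluster"] == c].reset_index(drop=True).copy()
        cluster_sizes[int(c)] = len(sub)
        if len(sub) < 8:
            continue
        q_labels, _ = sv.assign_quartiles(sub["mvpa_min_week"])
        sub["quartile"] = q_labels
        q_cols = sv.quartile_indicators(sub)
        cont = [v for v in _TABLE_CONTINUOUS if v in sub]
        binv = [v for v in _TABLE_BINARY if v in sub]
        quartile_tables[int(c)] = characteristics_table(sub, q_labels, cont, binv)
        km_curves[int(c)] = {
            int(q): sv.kaplan_meier(
                sub.loc[sub["quartile"] == q, "time_days"],
                sub.loc[sub["quartile"] == q, "event"],
            )
            for q in (1, 2, 3, 4)
        }
        fits = {}
        if sub["event"].sum() > 0:
            fits["unadjusted"] = sv.fit_cox(sub, q_cols, [])
            usable_adj = [t for t in adj_terms if sub[t].nunique() > 1]
            fits["adjusted"] = sv.fit_cox(sub, q_cols, usable_adj)
        quartile_fits[int(c)] = fits

    contrast = None
    comparison = None
    if records["cluster"].nunique() == 2 and records["event"].sum() > 0:
        rec = records.copy()
        rec["high_risk"] = (rec["cluster"] == 1).astype(float)
        contrast = sv.fit_cox(rec, ["high_risk"], [])
        if all("adjusted" in quartile_fits.get(c, {}) for c in (0, 1)):
            a = quartile_fits[0]["adjusted"]
            b = quartile_fits[1]["adjusted"]
            if list(a.terms) == list(b.terms):
                comparison = sv.compare_clusters(a, b)

    dose_fit = curve = thresholds = wald = None
    if records["event"].sum() > 0:
        counts = records["event"].astype(int).to_numpy()
        doses = np.clip(records["mvpa_min_week"].to_numpy(), *config.spline.dose_range)
        person_years = records["time_days"].to_numpy() / sv.DAYS_PER_YEAR
        dose_fit = dr.fit_poisson_rcs(
            counts, doses, person_years, config.spline, use_offset=config.use_offset
        )
        curve = dr.irr_curve(dose_fit, spec=config.spline)
        thresholds = dr.find_thresholds(dose_fit, config.threshold_rule, config.spline)
        wald = dr.wald_linearity_test(dose_fit)

    return StudyReport(
        flow_log=flow,
        cluster_sizes=cluster_sizes,
        cluster_labels=labels,
        quartile_tables=quartile_tables,
        quartile_fits=quartile_fits,
        cluster_contrast=contrast,
        cluster_comparison=comparison,
        dose_fit=dose_fit,
        irr_curve=curve,
        thresholds=thresholds,
        wald_linearity=wald,
        km_curves=km_curves,
    )
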