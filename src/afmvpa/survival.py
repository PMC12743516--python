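"""Follow-up construction, quartile exposure, Kaplan-Meier and Cox models.

The Cox solver maximises the Efron-tie-corrected partial likelihood by
Newton iteration with step halving; convergence is declared when every
score component is below 1e-8.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CensoringPolicy",
    "CoxFit",
    "assign_quartiles",
    "build_survival_records",
    "kaplan_meier",
    "fit_cox",
    "compare_clusters",
]

DAYS_PER_YEAR = 365.25

ADJUSTMENT_SETS = {
    # primary text set
    "standard": [
        "age", "sex_male", "sedentary_min_week", "bmi", "smoking_current",
        "heart_failure", "heart_disease", "t2d", "hypertension",
    ],
    # figure-caption variant adds ethnicity and alcohol
    "extended": [
        "age", "sex_male", "sedentary_min_week", "bmi", "smoking_current",
        "heart_failure", "heart_disease", "t2d", "hypertension",
        "ethnicity_white", "alcohol_daily",
    ],
}


@dataclass(frozen=True)
class CensoringPolicy:
    max_followup_years: float = 6.0
    exclude_event_on_diagnosis_day: bool = True
    index_rule: str = "primary"  # 'primary' (later of diagnosis/accelerometry) or 'procedure'

    def __post_init__(self) -> None:
        if self.max_followup_years <= 0:
            raise ValueError("max_followup_years must be positive")
        if self.index_rule not in ("primary", "procedure"):
            raise ValueError("index_rule must be 'primary' or 'procedure'")

    @property
    def max_followup_days(self) -> int:
        return int(np.floor(self.max_followup_years * DAYS_PER_YEAR))


def assign_quartiles(mvpa) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Rank individuals by MVPA into four groups of near-equal size.

    When n is not divisible by 4 the remainder goes to the lowest quartiles,
    so Quartile 1 is never smaller than Quartile 4. Ties keep input order
    (stable sort). Returns 1-based quartile labels and the group sizes.
    """
    values = np.asarray(mvpa, dtype=float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 individuals to form quartiles")
    if np.any(~np.isfinite(values)):
        raise ValueError("MVPA values must be finite (QC-passed)")
    base, rem = divmod(n, 4)
    sizes = tuple(base + (1 if q < rem else 0) for q in range(4))
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return labels, sizes


@dataclass
class ExclusionLog:
    qc_failed: int = 0
    missing_variables: int = 0
    event_before_index: int = 0
    details: list = field(default_factory=list)

    def total(self) -> int:
        return self.qc_failed + self.missing_variables + self.event_before_index


def build_survival_records(
    clinical: pd.DataFrame,
    policy: CensoringPolicy | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Derive (time, event) follow-up records from dated clinical rows.

    Expects day-valued columns ``af_diagnosis_day``, ``accelerometry_day``,
    optional ``procedure_day``, ``event_day`` (NaN if event-free) and
    ``dropout_day``. Index is the later of diagnosis and accelerometry
    (primary) or the procedure day (subgroup). Follow-up is capped at the
    policy maximum; events on the diagnosis day are dropped as events;
    individuals whose first event precedes the index are excluded and logged.
    """
    policy = policy or CensoringPolicy()
    log = ExclusionLog()
    rows = []
    for _, r in clinical.iterrows():
        diag = r["af_diagnosis_day"]
        accel = r["accelerometry_day"]
        if policy.index_rule == "procedure":
            if not np.isfinite(r.get("procedure_day", np.nan)):
                continue  # not in the subgroup
            index = r["procedure_day"]
        else:
            index = max(diag, accel)
        event_day = r.get("event_day", np.nan)
        has_event = np.isfinite(event_day)
        if has_event and event_day < diag:
            log.event_before_index += 1
            log.details.append((r.get("id"), "event_before_diagnosis"))
            continue
        if has_event and policy.exclude_event_on_diagnosis_day and event_day == diag:
            has_event = False  # day-of-diagnosis outcome does not count
            event_day = np.nan
        if has_event and event_day <= index:
            log.event_before_index += 1
            log.details.append((r.get("id"), "event_before_index"))
            continue
        dropout = r.get("dropout_day", np.inf)
        if not np.isfinite(dropout):
            dropout = np.inf
        cap = index + policy.max_followup_days
        end = min(event_day if has_event else np.inf, dropout, cap)
        event = bool(has_event and event_day <= min(dropout, cap))
        time = end - index
        if time <= 0:
            log.event_before_index += 1
            log.details.append((r.get("id"), "nonpositive_followup"))
            continue
        out = dict(r)
        out["time_days"] = float(time)
        out["event"] = event
        rows.append(out)
    records = pd.DataFrame(rows).reset_index(drop=True)
    return records, log


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table with one row per distinct event time: columns
    ``time``, ``at_risk``, ``events``, ``survival``. Curves start at 1 and
    are non-increasing.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("no records")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = len(t)
    rows = [(0.0, n, 0, 1.0)]
    surv = 1.0
    for ut in np.unique(t[e]):
        at_risk = int(np.sum(t >= ut))
        d = int(np.sum((t == ut) & e))
        surv *= 1.0 - d / at_risk
        rows.append((float(ut), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


@dataclass
class CoxFit:
    terms: list
    coefficients: np.ndarray
    covariance: np.ndarray
    n: int
    n_events: int
    ties: str = "efron"
    n_iter: int = 0
    max_score: float = np.nan

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))

    def hazard_ratios(self) -> pd.DataFrame:
        z = 1.959963984540054
        with np.errstate(over="ignore"):
            hr = np.exp(self.coefficients)
            lo = np.exp(self.coefficients - z * self.se)
            hi = np.exp(self.coefficients + z * self.se)
        wald = self.coefficients / self.se
        p = 2.0 * stats.norm.sf(np.abs(wald))
        return pd.DataFrame(
            {"term": self.terms, "coef": self.coefficients, "hr": hr, "lower95": lo,
             "upper95": hi, "p": p}
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": list(self.terms),
                "coefficients": self.coefficients.tolist(),
                "covariance": self.covariance.tolist(),
                "n": self.n,
                "n_events": self.n_events,
                "ties": self.ties,
                "hr_table": self.hazard_ratios().to_dict(orient="records"),
            },
            indent=2,
        )


def _cox_loglik(beta, X, times, events):
    """Efron partial log-likelihood, score and information (negative Hessian)."""
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    eta = Xs @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    # reverse cumulative sums: risk set of t_i is {j : t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ev_idx = np.where(es)[0]
    if ev_idx.size == 0:
        raise ValueError("no events; Cox model undefined")
    ev_times = ts[ev_idx]
    uniq, first = np.unique(ev_times, return_index=True)
    # group boundaries over event indices
    starts = first
    ends = np.append(first[1:], ev_idx.size)
    G = len(uniq)

    # per-group sums over tied events
    d = (ends - starts).astype(float)
    grp_first = ev_idx[starts]  # first record index with that time (events sorted within ties?)
    # risk-set sums at each unique event time: first record with t >= uniq
    risk_pos = np.searchsorted(ts, uniq, side="left")
    S0r = S0[risk_pos]
    S1r = S1[risk_pos]
    S2r = S2[risk_pos]

    S0d = np.add.reduceat(w[ev_idx], starts)
    S1d = np.add.reduceat(wx[ev_idx], starts, axis=0)
    S2d = np.add.reduceat(wxx[ev_idx], starts, axis=0)
    xsum = np.add.reduceat(Xs[ev_idx], starts, axis=0)
    etasum = np.add.reduceat(eta[ev_idx], starts)

    loglik = float(etasum.sum())
    score = xsum.sum(axis=0)
    info = np.zeros((p, p))
    max_d = int(d.max())
    for l in range(max_d):
        mask = d > l
        frac = (l / d[mask])[:, None]
        denom = S0r[mask] - frac[:, 0] * S0d[mask]
        num1 = S1r[mask] - frac * S1d[mask]
        num2 = S2r[mask] - frac[:, :, None] * S2d[mask]
        loglik -= float(np.sum(np.log(denom)))
        ebar = num1 / denom[:, None]
        score -= ebar.sum(axis=0)
        info += np.sum(num2 / denom[:, None, None], axis=0) - np.einsum("gi,gj->ij", ebar, ebar)
    return loglik, score, info


def fit_cox(
    records: pd.DataFrame | None = None,
    exposure_terms: list | None = None,
    covariates: list | None = None,
    *,
    times=None,
    events=None,
    X=None,
    terms=None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton-Raphson).

    Either pass a records frame with ``time_days``/``event`` columns plus the
    exposure/covariate column names, or raw ``times``, ``events``, ``X``
    arrays. Quartile exposure columns should be indicator-coded with
    Quartile 1 absent (the reference).
    """
    if records is not None:
        exposure_terms = list(exposure_terms or [])
        covariates = list(covariates or [])
        terms = exposure_terms + covariates
        X = records[terms].to_numpy(dtype=float)
        times = records["time_days"].to_numpy(dtype=float)
        events = records["event"].to_numpy(dtype=bool)
    else:
        X = np.asarray(X, dtype=float)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=bool)
        terms = list(terms or [f"x{j}" for j in range(X.shape[1])])

    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if events.sum() == 0:
        raise ValueError("zero events; cannot fit Cox model")
    for j, t in enumerate(terms):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate '{t}' is constant; remove it before fitting")

    # centre columns for conditioning; shift-invariant partial likelihood
    centre = X.mean(axis=0)
    Xc = X - centre

    beta = np.zeros(p)
    loglik, score, info = _cox_loglik(beta, Xc, times, events)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < score_tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("singular information matrix in Cox fit") from exc
        # step halving to guarantee ascent (slack scaled to |loglik| fp noise)
        for _ in range(30):
            cand = beta + step
            new_ll, new_score, new_info = _cox_loglik(cand, Xc, times, events)
            if new_ll >= loglik - 1e-9 * (abs(loglik) + 1.0):
                break
            step = step / 2.0
        beta, loglik, score, info = cand, new_ll, new_score, new_info
    else:
        raise FloatingPointError(f"Cox fit did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    return CoxFit(
        terms=terms,
        coefficients=beta,
        covariance=cov,
        n=n,
        n_events=int(events.sum()),
        n_iter=it,
        max_score=float(np.max(np.abs(score))),
    )


def quartile_indicators(records: pd.DataFrame, column: str = "quartile") -> list[str]:
    """Add Q2..Q4 indicator columns (Quartile 1 = reference); returns their names."""
    names = []
    for q in (2, 3, 4):
        name = f"quartile_{q}"
        records[name] = (records[column] == q).astype(float)
        names.append(name)
    return names


def compare_clusters(fit_a: CoxFit, fit_b: CoxFit) -> pd.DataFrame:
    """Per-term 95% CI overlap between two fits with matching terms."""
    if list(fit_a.terms) != list(fit_b.terms):
        raise ValueError("fits have different terms; cannot compare")
    ta = fit_a.hazard_ratios()
    tb = fit_b.hazard_ratios()
    rows = []
    for (_, ra), (_, rb) in zip(ta.iterrows(), tb.iterrows()):
        lo = max(ra["lower95"], rb["lower95"])
        hi = min(ra["upper95"], rb["upper95"])
        overlap = lo <= hi
        gap = 0.0 if overlap else lo - hi
        rows.append({"term": ra["term"], "overlap": bool(overlap), "gap": float(gap)})
    return pd.DataFrame(rows)
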