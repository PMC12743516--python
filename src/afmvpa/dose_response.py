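"""Poisson dose-response modelling of event counts on weekly MVPA.

Fits a log-linear Poisson model on a restricted cubic spline basis of the
activity dose, produces incidence-rate-ratio (IRR) curves with delta-method
confidence bands, tests linearity, and scans the curve for the minimal and
optimal activity doses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SplineSpec",
    "DoseResponseFit",
    "IRRCurve",
    "ThresholdRule",
    "ThresholdReport",
    "rcs_basis",
    "fit_poisson_rcs",
    "poisson_irls",
    "wald_linearity_test",
    "irr_curve",
    "find_thresholds",
]


@dataclass(frozen=True)
class SplineSpec:
    """Configuration of the restricted-cubic-spline dose axis."""

    knot_percentiles: tuple[float, float, float] = (10.0, 50.0, 90.0)
    dose_range: tuple[float, float] = (0.0, 300.0)
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        lo, mid, hi = self.knot_percentiles
        if not (0.0 < lo < mid < hi < 100.0):
            raise ValueError("knot percentiles must be strictly increasing in (0, 100)")
        if not self.dose_range[0] < self.dose_range[1]:
            raise ValueError("dose_range lower bound must be below upper bound")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")

    def grid(self) -> np.ndarray:
        lo, hi = self.dose_range
        n = int(np.floor((hi - lo) / self.grid_step)) + 1
        return lo + self.grid_step * np.arange(n)


@dataclass
class DoseResponseFit:
    """Fitted Poisson spline model: coefficients are (intercept, linear, nonlinear)."""

    knots: np.ndarray
    coefficients: np.ndarray
    covariance: np.ndarray
    offset_used: bool
    reference_dose: float
    deviance: float = np.nan
    n_obs: int = 0
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.knots.size == 3 and self.coefficients.size != 3:
            raise ValueError("3 knots imply intercept + 2 spline coefficients")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    def linear_predictor(self, doses: np.ndarray) -> np.ndarray:
        X = _design(np.asarray(doses, dtype=float), self.knots)
        return X @ self.coefficients

    def to_json(self) -> str:
        return json.dumps(
            {
                "knots": self.knots.tolist(),
                "coefficients": self.coefficients.tolist(),
                "covariance": self.covariance.tolist(),
                "offset_used": self.offset_used,
                "reference_dose": self.reference_dose,
                "deviance": self.deviance,
                "n_obs": self.n_obs,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DoseResponseFit":
        d = json.loads(text)
        return cls(
            knots=np.asarray(d["knots"]),
            coefficients=np.asarray(d["coefficients"]),
            covariance=np.asarray(d["covariance"]),
            offset_used=d["offset_used"],
            reference_dose=d["reference_dose"],
            deviance=d.get("deviance", np.nan),
            n_obs=d.get("n_obs", 0),
        )


@dataclass
class IRRCurve:
    doses: np.ndarray
    irr: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray
    reference_dose: float = 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"dose": self.doses, "irr": self.irr, "lower95": self.lower95, "upper95": self.upper95}
        )


@dataclass(frozen=True)
class ThresholdRule:
    """Scan rule: minimal dose compares to the reference, optimal to dose - step."""

    comparison_step: float = 30.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.comparison_step <= 0:
            raise ValueError("comparison_step must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ThresholdReport:
    minimal_dose: float | None = None
    minimal_irr: float | None = None
    minimal_ci: tuple[float, float] | None = None
    optimal_dose: float | None = None
    optimal_irr: float | None = None
    optimal_ci: tuple[float, float] | None = None
    minimal_found: bool = False
    optimal_found: bool = False
    rule: ThresholdRule = field(default_factory=ThresholdRule)

    def to_dict(self) -> dict:
        return {
            "minimal_dose": self.minimal_dose,
            "minimal_irr": self.minimal_irr,
            "minimal_ci": list(self.minimal_ci) if self.minimal_ci else None,
            "optimal_dose": self.optimal_dose,
            "optimal_irr": self.optimal_irr,
            "optimal_ci": list(self.optimal_ci) if self.optimal_ci else None,
            "minimal_found": self.minimal_found,
            "optimal_found": self.optimal_found,
        }


def rcs_basis(doses: np.ndarray, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form) for three knots.

    Returns an (n, 2) matrix: column 0 is the dose itself, column 1 the single
    nonlinear term. The resulting function is linear below the first and above
    the last knot by construction.
    """
    x = np.asarray(doses, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.size != 3:
        raise ValueError("exactly three knots required")
    if np.unique(t).size != 3:
        raise ValueError("knots must be distinct")
    t1, t2, t3 = np.sort(t)

    def pos3(v):
        return np.where(v > 0.0, v, 0.0) ** 3

    b2 = (
        pos3(x - t1)
        - pos3(x - t2) * (t3 - t1) / (t3 - t2)
        + pos3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, b2])


def _design(doses: np.ndarray, knots: np.ndarray) -> np.ndarray:
    basis = rcs_basis(doses, knots)
    return np.column_stack([np.ones(len(basis)), basis])


def fit_poisson_rcs(
    counts,
    doses,
    person_time=None,
    spec: SplineSpec | None = None,
    *,
    use_offset: bool = True,
    knots=None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> DoseResponseFit:
    """Fit a Poisson regression of event counts on the spline basis by IRLS.

    Parameters
    ----------
    counts, doses : array-like
        Per-unit event counts (non-negative integers) and activity doses.
    person_time : array-like, optional
        Exposure time per unit; used as a log offset when ``use_offset``.
    spec : SplineSpec
        Knot percentiles and dose range; knots are placed at the empirical
        percentiles of ``doses`` unless explicit ``knots`` are passed.
    """
    spec = spec or SplineSpec()
    y = np.asarray(counts, dtype=float)
    x = np.asarray(doses, dtype=float)
    if y.ndim != 1 or y.shape != x.shape:
        raise ValueError("counts and doses must be 1-d arrays of equal length")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    if not np.any(y > 0):
        raise ValueError("all counts are zero; Poisson fit is degenerate")

    if use_offset:
        if person_time is None:
            raise ValueError("person_time required when use_offset is True")
        pt = np.asarray(person_time, dtype=float)
        if np.any(pt <= 0):
            raise ValueError("person_time must be strictly positive")
        offset = np.log(pt)
    else:
        offset = np.zeros_like(y)

    if knots is None:
        knots = np.percentile(x, spec.knot_percentiles)
    knots = np.asarray(knots, dtype=float)
    X = _design(x, knots)
    beta, cov, dev, n_iter = poisson_irls(y, X, offset, max_iter=max_iter, tol=tol)
    return DoseResponseFit(
        knots=knots,
        coefficients=beta,
        covariance=cov,
        offset_used=use_offset,
        reference_dose=float(np.min(x)),
        deviance=float(dev),
        n_obs=len(y),
        n_iter=n_iter,
    )


def poisson_irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Log-link Poisson GLM by iteratively reweighted least squares.

    Returns (coefficients, covariance, deviance, iterations). Convergence is
    declared when the deviance change drops below ``tol`` (relative).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    p = X.shape[1]
    beta = np.zeros(p)
    if np.allclose(X[:, 0], 1.0):
        beta[0] = np.log(y.sum() / np.exp(offset).sum())  # pooled log-rate start
    dev = _poisson_deviance(y, X @ beta + offset)
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta + offset
        mu = np.exp(eta)
        if not np.all(np.isfinite(mu)):
            raise FloatingPointError("Poisson IRLS diverged (non-finite fitted means)")
        z = eta - offset + (y - mu) / mu
        XtW = X.T * mu
        try:
            beta = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError("singular weighted design in Poisson IRLS") from exc
        new_dev = _poisson_deviance(y, X @ beta + offset)
        if abs(dev - new_dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise FloatingPointError(f"Poisson IRLS did not converge in {max_iter} iterations")

    mu = np.exp(X @ beta + offset)
    info = (X.T * mu) @ X
    cov = np.linalg.inv(info)
    cov = 0.5 * (cov + cov.T)
    return beta, cov, float(dev), n_iter


def _poisson_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def wald_linearity_test(fit: DoseResponseFit) -> tuple[float, float]:
    """Wald chi-square test (1 df) of the nonlinear spline coefficient being zero."""
    var_nl = fit.covariance[2, 2]
    if not np.isfinite(var_nl) or var_nl <= 0:
        raise ValueError("covariance of nonlinear term is singular or invalid")
    stat = fit.coefficients[2] ** 2 / var_nl
    pvalue = float(stats.chi2.sf(stat, df=1))
    return float(stat), pvalue


def irr_curve(
    fit: DoseResponseFit,
    reference_dose: float | None = None,
    spec: SplineSpec | None = None,
) -> IRRCurve:
    """IRR of each grid dose relative to the reference, with 95% delta-method bands."""
    spec = spec or SplineSpec()
    ref = fit.reference_dose if reference_dose is None else float(reference_dose)
    grid = spec.grid()
    Xg = _design(grid, fit.knots)
    Xr = _design(np.array([ref]), fit.knots)
    G = Xg - Xr  # basis difference; intercept cancels
    log_irr = G @ fit.coefficients
    var = np.einsum("ij,jk,ik->i", G, fit.covariance, G)
    var = np.clip(var, 0.0, None)
    se = np.sqrt(var)
    z = stats.norm.ppf(0.975)
    return IRRCurve(
        doses=grid,
        irr=np.exp(log_irr),
        lower95=np.exp(log_irr - z * se),
        upper95=np.exp(log_irr + z * se),
        reference_dose=ref,
    )


def _irr_vs(fit: DoseResponseFit, dose: float, other: float, alpha: float):
    """Point IRR of `dose` vs `other` with a (1-alpha) CI."""
    Xd = _design(np.array([dose]), fit.knots)
    Xo = _design(np.array([other]), fit.knots)
    g = (Xd - Xo)[0]
    log_irr = float(g @ fit.coefficients)
    var = float(g @ fit.covariance @ g)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(over="ignore"):
        return np.exp(log_irr), (np.exp(log_irr - z * se), np.exp(log_irr + z * se))


def find_thresholds(
    fit: DoseResponseFit,
    rule: ThresholdRule | None = None,
    spec: SplineSpec | None = None,
    reference_dose: float | None = None,
    *,
    optimal_vs_reference: bool = False,
) -> ThresholdReport:
    """Scan the dose grid for the minimal and optimal activity doses.

    The minimal dose is the first grid dose above the reference whose IRR
    versus the reference has a CI excluding 1. The optimal dose is the first
    dose at least ``comparison_step`` above the reference whose IRR versus
    (dose - step) has a CI including 1 — i.e. where a further step stops
    buying a detectable reduction. ``optimal_vs_reference`` switches the
    second comparison to reference-anchored doses stepped by the step size.
    """
    rule = rule or ThresholdRule()
    spec = spec or SplineSpec()
    ref = fit.reference_dose if reference_dose is None else float(reference_dose)
    grid = spec.grid()
    report = ThresholdReport(rule=rule)

    for d in grid:
        if d <= ref:
            continue
        irr, ci = _irr_vs(fit, d, ref, rule.alpha)
        if ci[0] > 1.0 or ci[1] < 1.0:
            report.minimal_dose = float(d)
            report.minimal_irr = float(irr)
            report.minimal_ci = (float(ci[0]), float(ci[1]))
            report.minimal_found = True
            break

    step = rule.comparison_step
    for d in grid:
        if d < ref + step:
            continue
        anchor = ref if optimal_vs_reference else d - step
        if optimal_vs_reference and (d - ref) % step != 0:
            continue
        irr, ci = _irr_vs(fit, d, anchor, rule.alpha)
        if ci[0] <= 1.0 <= ci[1]:
            report.optimal_dose = float(d)
            report.optimal_irr = float(irr)
            report.optimal_ci = (float(ci[0]), float(ci[1]))
            report.optimal_found = True
            break

    return report
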