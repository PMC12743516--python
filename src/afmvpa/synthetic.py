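"""Synthetic cohort, survival and raw-signal generators with known ground truth.

Every downstream stage of the pipeline can be exercised without external
data: a two-phenotype comorbidity cohort, exponential proportional-hazards
event times whose hazard depends on the phenotype and on a smooth function
of weekly MVPA, and tri-axial accelerometer signals with planted activity
bouts and non-wear episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .accelerometry import GRAVITY_MG, AccelRecording
from .dose_response import rcs_basis
from .phenotyping import PHENOTYPE_COLUMNS, DichotomizationRules

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_survival",
    "simulate_recording",
]

N_VARS = len(PHENOTYPE_COLUMNS)  # 31
DAYS_PER_YEAR = 365.25


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    seed: int = 0
    phenotype_prevalence: float = 0.5  # P(high risk)
    prevalence_low: np.ndarray = field(default_factory=lambda: np.full(N_VARS, 0.15))
    prevalence_high: np.ndarray = field(default_factory=lambda: np.full(N_VARS, 0.45))
    mvpa_log_mean: float = np.log(110.0)
    mvpa_log_sd: float = 0.55
    mvpa_log_shift_high: float = -0.25  # high-risk phenotype is less active
    baseline_hazard: float = 0.02  # events per person-year
    log_hr_cluster: float = np.log(3.81)
    dose_effect: tuple[float, float] = (0.0, 0.0)  # coefficients on the spline basis
    dose_knots: tuple[float, float, float] | None = None  # default: 10/50/90 pct of MVPA
    dropout_rate: float = 0.02  # exponential censoring per year
    admin_censor_years: float = 6.0
    rhythm_control_prob: float = 0.28
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        self.prevalence_low = np.asarray(self.prevalence_low, dtype=float)
        self.prevalence_high = np.asarray(self.prevalence_high, dtype=float)
        for name, vec in (("prevalence_low", self.prevalence_low), ("prevalence_high", self.prevalence_high)):
            if vec.shape != (N_VARS,):
                raise ValueError(f"{name} must have length {N_VARS}")
            if np.any((vec < 0) | (vec > 1)):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        for name in ("phenotype_prevalence", "rhythm_control_prob", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mvpa_log_sd <= 0:
            raise ValueError("mvpa_log_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_individuals < 8:
            raise ValueError("n_individuals must be at least 8")


@dataclass
class GroundTruth:
    true_labels: np.ndarray  # 0 = low risk, 1 = high risk
    true_mvpa: np.ndarray  # min/week
    true_event_time: np.ndarray  # years from index
    true_censor_time: np.ndarray  # years from index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_label": self.true_labels,
                "true_mvpa": self.true_mvpa,
                "true_event_time": self.true_event_time,
                "true_censor_time": self.true_censor_time,
            }
        )


# continuous variables behind dichotomized indicators: (column, clinical name,
# SD, direction) where direction 'ge' means abnormal side is >= the cut.
_CONTINUOUS = {
    "age_ge60": ("age", 8.0, "ge"),
    "bmi_ge25": ("bmi", 4.5, "ge"),
    "egfr_lt90": ("egfr", 15.0, "lt"),
    "liver_abnormal": ("ggt", 25.0, "gt"),
}


def _gaussian_mean_for_prevalence(cut, sd, p, direction):
    """Mean of a Gaussian whose tail past `cut` (on the abnormal side) is p."""
    p = np.clip(np.asarray(p, dtype=float), 1e-6, 1.0 - 1e-6)
    if direction in ("ge", "gt"):
        return cut - sd * stats.norm.ppf(1.0 - p)
    return cut - sd * stats.norm.ppf(p)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a clinical table with latent two-phenotype structure.

    Continuous variables (age, BMI, eGFR, GGT, haematocrit) are Gaussian per
    phenotype with means probit-inverted so their dichotomized versions hit
    the configured prevalences; the remaining indicators are direct Bernoulli
    draws. Dates are days since an arbitrary epoch; accelerometry falls
    uniformly within 5 years after AF diagnosis. Event times are attached by
    :func:`simulate_survival`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    rules = DichotomizationRules()
    labels = (rng.random(n) < config.phenotype_prevalence).astype(int)
    prev = np.where(labels[:, None] == 1, config.prevalence_high, config.prevalence_low)
    col_idx = {c: i for i, c in enumerate(PHENOTYPE_COLUMNS)}

    clinical = pd.DataFrame({"id": np.arange(n)})

    cuts = {"age": rules.age_cut, "bmi": rules.bmi_cut, "egfr": rules.egfr_cut, "ggt": rules.ggt_cut}
    for col, (name, sd, direction) in _CONTINUOUS.items():
        p = prev[:, col_idx[col]]
        mu = _gaussian_mean_for_prevalence(cuts[name], sd, p, direction)
        clinical[name] = mu + sd * rng.standard_normal(n)

    sex = (rng.random(n) < prev[:, col_idx["sex_male"]]).astype(float)
    clinical["sex_male"] = sex
    # haematocrit: anaemia prevalence via sex-specific cut
    hct_sd = 3.0
    hct_cut = np.where(sex == 1.0, rules.haematocrit_cut_male, rules.haematocrit_cut_female)
    p_an = prev[:, col_idx["anaemia"]]
    hct_mu = _gaussian_mean_for_prevalence(hct_cut, hct_sd, p_an, "lt")
    clinical["haematocrit"] = hct_mu + hct_sd * rng.standard_normal(n)

    direct = [
        c
        for c in PHENOTYPE_COLUMNS
        if c not in _CONTINUOUS and c not in ("sex_male", "anaemia")
    ]
    for col in direct:
        clinical[col] = (rng.random(n) < prev[:, col_idx[col]]).astype(float)

    # weekly MVPA, right-skewed, lower in the high-risk phenotype
    log_mu = config.mvpa_log_mean + config.mvpa_log_shift_high * labels
    mvpa = np.exp(log_mu + config.mvpa_log_sd * rng.standard_normal(n))

    # dates (days since arbitrary epoch)
    diag = np.floor(rng.uniform(0, 3 * DAYS_PER_YEAR, n))
    accel = diag + np.floor(rng.uniform(0, 5 * DAYS_PER_YEAR, n)) + 1.0
    clinical["af_diagnosis_day"] = diag
    clinical["accelerometry_day"] = accel
    rc = rng.random(n) < config.rhythm_control_prob
    proc_day = diag + np.floor(rng.uniform(0, 1, n) * np.maximum(accel - diag, 1.0))
    clinical["rhythm_control"] = rc.astype(float)
    clinical["procedure_day"] = np.where(rc, proc_day, np.nan)

    if config.missing_rate > 0:
        maskable = ["bmi", "egfr", "ggt", "haematocrit", "alcohol_daily", "smoking_current",
                    "cardioversion", "catheter_ablation", "pci", "cabg", "pacemaker",
                    "rrt_transplant"]
        for col in maskable:
            mask = rng.random(n) < config.missing_rate
            clinical.loc[mask, col] = np.nan

    event_t, censor_t = simulate_survival(clinical, mvpa, config, labels=labels, rng=rng)
    clinical["event_day"] = np.where(
        event_t <= censor_t, accel + np.floor(event_t * DAYS_PER_YEAR) + 1.0, np.nan
    )
    clinical["dropout_day"] = accel + np.floor(censor_t * DAYS_PER_YEAR) + 1.0
    clinical["mvpa_min_week"] = mvpa

    truth = GroundTruth(
        true_labels=labels,
        true_mvpa=mvpa,
        true_event_time=event_t,
        true_censor_time=censor_t,
    )
    return clinical, truth


def dose_log_hazard(mvpa, config: SimulationConfig) -> np.ndarray:
    """The true smooth log-hazard contribution f(MVPA) on the spline basis."""
    mvpa = np.asarray(mvpa, dtype=float)
    b = np.asarray(config.dose_effect, dtype=float)
    if np.all(b == 0):
        return np.zeros_like(mvpa)
    knots = config.dose_knots
    if knots is None:
        knots = np.percentile(mvpa, (10, 50, 90))
    basis = rcs_basis(mvpa, knots)
    return basis @ b


def simulate_survival(
    clinical: pd.DataFrame,
    true_mvpa,
    config: SimulationConfig,
    *,
    labels=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-with-covariates event times and independent censoring.

    hazard_i = baseline_hazard * exp(log_hr_cluster * I[high_i] + f(MVPA_i));
    the censoring time is min(exponential dropout, administrative cap).
    Returns (event_time_years, censor_time_years) from index.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(clinical)
    if labels is None:
        labels = clinical["true_label"].to_numpy()
    labels = np.asarray(labels)
    hazard = config.baseline_hazard * np.exp(
        config.log_hr_cluster * labels + dose_log_hazard(true_mvpa, config)
    )
    event_t = rng.exponential(1.0, n) / hazard
    if config.dropout_rate > 0:
        dropout = rng.exponential(1.0 / config.dropout_rate, n)
    else:
        dropout = np.full(n, np.inf)
    censor_t = np.minimum(dropout, config.admin_censor_years)
    return event_t, censor_t


# ---------------------------------------------------------------------------
# raw signal generator

# per intensity class: (target ENMO level mg, magnitude jitter SD, lateral noise SD)
_CLASS_PARAMS = {
    "sedentary": (0.0, 3.0, 20.0),
    "light": (65.0, 8.0, 20.0),
    "mvpa": (150.0, 10.0, 25.0),
    "nonwear": (0.0, 2.0, 2.0),
}


def simulate_recording(
    profile,
    nonwear_intervals=(),
    seed: int = 0,
    *,
    sample_rate_hz: float = 100.0,
    epoch_mode: bool = False,
    offsets=(0.0, 0.0, 0.0),
    gains=(1.0, 1.0, 1.0),
) -> AccelRecording:
    """Build a tri-axial recording from (duration_s, intensity_class) segments.

    Gravity sits on the z axis; each class plants a magnitude component so
    epoch ENMO lands in the class band (MVPA >= 120 mg, light 40-90 mg,
    sedentary <= 20 mg) while lateral noise keeps wear segments above the
    13 mg non-wear SD threshold. Non-wear segments (class 'nonwear' or extra
    ``nonwear_intervals`` in seconds) have all-axis SD below 5 mg.
    ``epoch_mode`` generates one sample per 5-s epoch for fast tests.
    Optional offsets/gains corrupt the output for calibration tests.
    """
    if not profile:
        raise ValueError("profile must contain at least one segment")
    for dur, cls in profile:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        if cls not in _CLASS_PARAMS:
            raise ValueError(f"unknown intensity class '{cls}'")

    rng = np.random.default_rng(seed)
    rate = 0.2 if epoch_mode else sample_rate_hz
    total_s = sum(d for d, _ in profile)
    n = int(round(total_s * rate))
    t = np.arange(n) / rate

    classes = np.empty(n, dtype=object)
    pos = 0.0
    for dur, cls in profile:
        seg = (t >= pos) & (t < pos + dur)
        classes[seg] = cls
        pos += dur
    for a, b in nonwear_intervals:
        classes[(t >= a) & (t < b)] = "nonwear"

    x = np.empty(n)
    y = np.empty(n)
    z = np.empty(n)
    for cls, (level, mag_sd, lat_sd) in _CLASS_PARAMS.items():
        seg = classes == cls
        m = int(seg.sum())
        if m == 0:
            continue
        x[seg] = lat_sd * rng.standard_normal(m)
        y[seg] = lat_sd * rng.standard_normal(m)
        if level > 0:
            z[seg] = GRAVITY_MG + np.maximum(level + mag_sd * rng.standard_normal(m), 0.0)
        else:  # sedentary / nonwear stay centred at gravity
            z[seg] = GRAVITY_MG + mag_sd * rng.standard_normal(m)

    gx, gy, gz = gains
    ox, oy, oz = offsets
    return AccelRecording(
        timestamps=t,
        x=(x - ox) / gx,
        y=(y - oy) / gy,
        z=(z - oz) / gz,
        sample_rate_hz=rate,
    )


def write_cohort_csv(clinical: pd.DataFrame, truth: GroundTruth, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clinical.to_csv(out / "clinical.csv", index=False)
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
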