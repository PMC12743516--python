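"""Raw tri-axial acceleration to QC'd weekly activity minutes.

Processing chain: gravity calibration -> 5-s epoch vector magnitude (ENMO)
-> non-wear detection on the raw axes -> intensity classification -> weekly
summary with a minimum-wear QC rule.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AccelRecording",
    "EpochSeries",
    "NonwearParams",
    "IntensityThresholds",
    "ActivitySummary",
    "CalibrationResult",
    "calibrate_to_gravity",
    "epoch_vector_magnitude",
    "detect_nonwear",
    "classify_intensity",
    "summarise_week",
    "summarise_recording",
    "read_recording_csv",
    "write_recording_csv",
    "write_epochs_csv",
    "read_epochs_csv",
]

GRAVITY_MG = 1000.0
DEVICE_RANGE_MG = 8000.0

SEDENTARY, LIGHT, MVPA, NONWEAR = "sedentary", "light", "mvpa", "nonwear"


@dataclass
class AccelRecording:
    """Tri-axial acceleration in milligravity on a strictly increasing time axis."""

    timestamps: np.ndarray  # seconds from recording start
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("axis arrays must match timestamp length")
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if np.any(np.abs(arr) > DEVICE_RANGE_MG):
                raise ValueError(f"axis {name} exceeds the +/-8 g device range")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.sample_rate_hz

    def vector_magnitude(self) -> np.ndarray:
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass
class EpochSeries:
    """Per-epoch mean ENMO (vector magnitude minus gravity, floored at zero)."""

    epoch_start_s: np.ndarray
    mean_vm_mg: np.ndarray
    wear: np.ndarray | None = None
    epoch_length_s: float = 5.0

    def __post_init__(self) -> None:
        self.epoch_start_s = np.asarray(self.epoch_start_s, dtype=float)
        self.mean_vm_mg = np.asarray(self.mean_vm_mg, dtype=float)
        if np.any(self.mean_vm_mg < 0):
            raise ValueError("epoch vector magnitudes must be non-negative")
        if self.wear is None:
            self.wear = np.ones(len(self.mean_vm_mg), dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)

    def __len__(self) -> int:
        return len(self.mean_vm_mg)


@dataclass(frozen=True)
class NonwearParams:
    sd_threshold_mg: float = 13.0
    min_episode_min: float = 60.0
    window_min: float = 60.0
    window_step_min: float = 15.0

    def __post_init__(self) -> None:
        if self.window_step_min > self.window_min:
            raise ValueError("window step must not exceed window length")
        if min(self.sd_threshold_mg, self.min_episode_min, self.window_min, self.window_step_min) <= 0:
            raise ValueError("non-wear parameters must be positive")


@dataclass(frozen=True)
class IntensityThresholds:
    mvpa_mg: float = 100.0
    light_lower_mg: float = 30.0  # conventional companion of the 100 mg cut; configurable

    def __post_init__(self) -> None:
        if not 0.0 < self.light_lower_mg < self.mvpa_mg:
            raise ValueError("need 0 < light_lower_mg < mvpa_mg")


@dataclass
class ActivitySummary:
    mvpa_min_week: float
    lpa_min_week: float
    sedentary_min_week: float
    valid_wear_days: float
    qc_pass: bool
    calibration_ok: bool = True
    scale_to_week: bool = True

    def to_dict(self) -> dict:
        return {
            "mvpa_min_week": self.mvpa_min_week,
            "lpa_min_week": self.lpa_min_week,
            "sedentary_min_week": self.sedentary_min_week,
            "valid_wear_days": self.valid_wear_days,
            "qc_pass": self.qc_pass,
            "calibration_ok": self.calibration_ok,
        }


@dataclass
class CalibrationResult:
    offsets_mg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    n_stationary_windows: int = 0
    calibrated: bool = False


def _windowed_stats(values: np.ndarray, starts: np.ndarray, length: int):
    """Mean and SD of `values` over windows [s, s+length) via cumulative sums."""
    c1 = np.concatenate([[0.0], np.cumsum(values)])
    c2 = np.concatenate([[0.0], np.cumsum(values**2)])
    ends = starts + length
    s1 = c1[ends] - c1[starts]
    s2 = c2[ends] - c2[starts]
    mean = s1 / length
    var = np.maximum(s2 / length - mean**2, 0.0)
    return mean, np.sqrt(var)


def _stationary_windows(rec: AccelRecording, window_s: float, step_s: float, sd_mg: float):
    """Start indices, per-axis window means, and stationarity flags on a step grid."""
    n = len(rec)
    wlen = int(round(window_s * rec.sample_rate_hz))
    step = max(int(round(step_s * rec.sample_rate_hz)), 1)
    if wlen <= 1 or n < wlen:
        return np.empty(0, dtype=int), np.empty((0, 3)), np.empty(0, dtype=bool), wlen
    starts = np.arange(0, n - wlen + 1, step)
    means = np.empty((len(starts), 3))
    sds = np.empty((len(starts), 3))
    for j, axis in enumerate((rec.x, rec.y, rec.z)):
        means[:, j], sds[:, j] = _windowed_stats(axis, starts, wlen)
    stationary = np.all(sds < sd_mg, axis=1)
    return starts, means, stationary, wlen


def calibrate_to_gravity(
    rec: AccelRecording,
    *,
    window_s: float = 10.0,
    sd_threshold_mg: float = 13.0,
    min_windows: int = 10,
    max_iter: int = 20,
) -> tuple[AccelRecording, CalibrationResult]:
    """Estimate per-axis offset/gain from stationary windows and correct the signal.

    Stationary window mean vectors should lie on the 1000-mg gravity sphere;
    offset and gain are found by iteratively regressing each window vector's
    sphere projection on its observed value. With too little orientation
    diversity the gain is unidentifiable and only offsets are fitted; with
    fewer than ``min_windows`` stationary windows the recording is returned
    unchanged with ``calibrated=False`` for QC to record.
    """
    starts, means, stationary, _ = _stationary_windows(rec, window_s, window_s, sd_threshold_mg)
    pts = means[stationary]
    result = CalibrationResult(n_stationary_windows=int(stationary.sum()))
    if len(pts) < min_windows:
        warnings.warn(
            f"only {len(pts)} stationary windows found (<{min_windows}); recording left uncalibrated",
            stacklevel=2,
        )
        return rec, result

    spread = pts.std(axis=0)
    fit_gain = np.all(spread > 50.0)  # gain needs multiple orientations per axis

    offsets = np.zeros(3)
    gains = np.ones(3)
    for _ in range(max_iter):
        adj = pts * gains + offsets
        norms = np.linalg.norm(adj, axis=1)
        target = adj / norms[:, None] * GRAVITY_MG
        new_off = np.empty(3)
        new_gain = np.empty(3)
        for j in range(3):
            if fit_gain:
                A = np.column_stack([pts[:, j], np.ones(len(pts))])
                coef, *_ = np.linalg.lstsq(A, target[:, j], rcond=None)
                new_gain[j], new_off[j] = coef
            else:
                new_gain[j] = 1.0
                new_off[j] = float(np.mean(target[:, j] - pts[:, j]))
        if np.allclose(new_off, offsets, atol=1e-9) and np.allclose(new_gain, gains, atol=1e-12):
            offsets, gains = new_off, new_gain
            break
        offsets, gains = new_off, new_gain

    corrected = AccelRecording(
        timestamps=rec.timestamps,
        x=np.clip(rec.x * gains[0] + offsets[0], -DEVICE_RANGE_MG, DEVICE_RANGE_MG),
        y=np.clip(rec.y * gains[1] + offsets[1], -DEVICE_RANGE_MG, DEVICE_RANGE_MG),
        z=np.clip(rec.z * gains[2] + offsets[2], -DEVICE_RANGE_MG, DEVICE_RANGE_MG),
        sample_rate_hz=rec.sample_rate_hz,
    )
    result.offsets_mg = offsets
    result.gains = gains
    result.calibrated = True
    return corrected, result


def epoch_vector_magnitude(rec: AccelRecording, epoch_length_s: float = 5.0) -> EpochSeries:
    """Mean ENMO per epoch: mean over samples of max(0, |a| - 1000 mg).

    A trailing partial epoch is dropped.
    """
    if len(rec) == 0:
        raise ValueError("empty recording")
    enmo = np.maximum(rec.vector_magnitude() - GRAVITY_MG, 0.0)
    per_epoch = int(round(epoch_length_s * rec.sample_rate_hz))
    if per_epoch < 1:
        raise ValueError("epoch shorter than one sample")
    n_epochs = len(rec) // per_epoch
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    trimmed = enmo[: n_epochs * per_epoch].reshape(n_epochs, per_epoch)
    t0 = rec.timestamps[0]
    return EpochSeries(
        epoch_start_s=t0 + epoch_length_s * np.arange(n_epochs),
        mean_vm_mg=trimmed.mean(axis=1),
        epoch_length_s=epoch_length_s,
    )


def detect_nonwear(
    rec: AccelRecording,
    params: NonwearParams | None = None,
    epochs: EpochSeries | None = None,
) -> tuple[list[tuple[float, float]], EpochSeries | None]:
    """Flag non-wear: stationary episodes of at least ``min_episode_min``.

    Sliding windows of ``window_min`` are evaluated every ``window_step_min``
    on the raw axes; a window is stationary when all three per-axis SDs fall
    below the threshold. Overlapping stationary windows are merged and merged
    spans of sufficient length become non-wear intervals (in seconds from
    recording start). If an epoch series is supplied, its wear flags are set.
    """
    params = params or NonwearParams()
    starts, _, stationary, wlen = _stationary_windows(
        rec, params.window_min * 60.0, params.window_step_min * 60.0, params.sd_threshold_mg
    )
    if len(starts) == 0:
        warnings.warn("recording shorter than one non-wear window; no non-wear detected", stacklevel=2)
        return [], epochs

    t0 = rec.timestamps[0]
    rate = rec.sample_rate_hz
    intervals: list[tuple[float, float]] = []
    cur: tuple[float, float] | None = None
    for s, flag in zip(starts, stationary):
        if not flag:
            continue
        a = t0 + s / rate
        b = t0 + (s + wlen) / rate
        if cur is not None and a <= cur[1]:
            cur = (cur[0], max(cur[1], b))
        else:
            if cur is not None:
                intervals.append(cur)
            cur = (a, b)
    if cur is not None:
        intervals.append(cur)
    intervals = [iv for iv in intervals if iv[1] - iv[0] >= params.min_episode_min * 60.0]

    if epochs is not None:
        wear = np.ones(len(epochs), dtype=bool)
        mid = epochs.epoch_start_s + epochs.epoch_length_s / 2.0
        for a, b in intervals:
            wear[(mid >= a) & (mid < b)] = False
        epochs = EpochSeries(
            epoch_start_s=epochs.epoch_start_s,
            mean_vm_mg=epochs.mean_vm_mg,
            wear=wear,
            epoch_length_s=epochs.epoch_length_s,
        )
    return intervals, epochs


def classify_intensity(
    epochs: EpochSeries, thresholds: IntensityThresholds | None = None
) -> np.ndarray:
    """Per-epoch class: nonwear, else mvpa iff ENMO > mvpa_mg (strict), else
    light iff light_lower_mg <= ENMO <= mvpa_mg, else sedentary."""
    thresholds = thresholds or IntensityThresholds()
    v = epochs.mean_vm_mg
    classes = np.full(len(epochs), SEDENTARY, dtype=object)
    classes[(v >= thresholds.light_lower_mg) & (v <= thresholds.mvpa_mg)] = LIGHT
    classes[v > thresholds.mvpa_mg] = MVPA
    classes[~epochs.wear] = NONWEAR
    return classes


def summarise_week(
    epochs: EpochSeries,
    classes: np.ndarray,
    *,
    min_wear_days: float = 3.0,
    scale_to_week: bool = True,
    calibration_ok: bool = True,
) -> ActivitySummary:
    """Weekly minutes per intensity class from classified wear epochs.

    Wear days are total wear time / 24 h; minutes per class are epoch counts
    times epoch length, scaled to a 7-day week by ``7 / valid_wear_days``
    (or averaged per valid day * 7 equivalently). QC fails below
    ``min_wear_days`` wear days and the summary is flagged unusable.
    """
    wear = epochs.wear
    epoch_min = epochs.epoch_length_s / 60.0
    wear_days = float(wear.sum() * epoch_min / (24.0 * 60.0))
    qc = wear_days >= min_wear_days
    if wear.sum() == 0:
        return ActivitySummary(np.nan, np.nan, np.nan, 0.0, False, calibration_ok, scale_to_week)

    minutes = {
        cls: float(np.sum((classes == cls) & wear) * epoch_min) for cls in (MVPA, LIGHT, SEDENTARY)
    }
    factor = (7.0 / wear_days) if scale_to_week else 1.0
    return ActivitySummary(
        mvpa_min_week=minutes[MVPA] * factor,
        lpa_min_week=minutes[LIGHT] * factor,
        sedentary_min_week=minutes[SEDENTARY] * factor,
        valid_wear_days=wear_days,
        qc_pass=bool(qc),
        calibration_ok=calibration_ok,
        scale_to_week=scale_to_week,
    )


def summarise_recording(
    rec: AccelRecording,
    *,
    thresholds: IntensityThresholds | None = None,
    nonwear: NonwearParams | None = None,
    min_wear_days: float = 3.0,
    calibrate: bool = True,
) -> ActivitySummary:
    """Full chain: calibrate -> epochs -> non-wear -> classify -> weekly summary."""
    cal_ok = True
    if calibrate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec, cal = calibrate_to_gravity(rec)
        cal_ok = cal.calibrated
    epochs = epoch_vector_magnitude(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, epochs = detect_nonwear(rec, nonwear, epochs)
    classes = classify_intensity(epochs, thresholds)
    return summarise_week(
        epochs, classes, min_wear_days=min_wear_days, calibration_ok=cal_ok
    )


# ---------------------------------------------------------------------------
# text I/O


def write_recording_csv(rec: AccelRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz}\n")
        pd.DataFrame(
            {"timestamp_s": rec.timestamps, "x_mg": rec.x, "y_mg": rec.y, "z_mg": rec.z}
        ).to_csv(fh, index=False)


def read_recording_csv(path) -> AccelRecording:
    with open(path) as fh:
        first = fh.readline()
        rate = 100.0
        if first.startswith("#"):
            rate = float(first.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body))
    return AccelRecording(
        timestamps=df["timestamp_s"].to_numpy(),
        x=df["x_mg"].to_numpy(),
        y=df["y_mg"].to_numpy(),
        z=df["z_mg"].to_numpy(),
        sample_rate_hz=rate,
    )


def write_epochs_csv(epochs: EpochSeries, classes: np.ndarray | None, path) -> None:
    df = pd.DataFrame(
        {"epoch_start_s": epochs.epoch_start_s, "mean_vm_mg": epochs.mean_vm_mg, "wear": epochs.wear}
    )
    if classes is not None:
        df["class"] = classes
    df.to_csv(path, index=False)


def read_epochs_csv(path) -> tuple[EpochSeries, np.ndarray | None]:
    df = pd.read_csv(path)
    epochs = EpochSeries(
        epoch_start_s=df["epoch_start_s"].to_numpy(),
        mean_vm_mg=df["mean_vm_mg"].to_numpy(),
        wear=df["wear"].to_numpy(dtype=bool),
    )
    classes = df["class"].to_numpy(dtype=object) if "class" in df else None
    return epochs, classes


def summary_to_json(summary: ActivitySummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
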