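"""Efficiency metrics for one trial: time, resultant acceleration, path length.

Three quantities summarise economy of motion in endoscopic surgical training:

* procedural time — the recording span in seconds;
* resultant acceleration — the per-sample Euclidean norm |a| of the
  gravity-free acceleration, reported both as a per-sample mean and as the
  per-sample sum (cumulative) over the trial;
* path length — total distance travelled by the hand, estimated as the time
  integral of speed from drift-corrected integration of acceleration.

Double integration of accelerometer noise diverges quadratically, so path
length is computed in velocity space (sum of |v|*dt) after drift correction.
The default correction is ZUPT (zero-velocity updates): surgical hand motion
contains micro-pauses, velocity is pinned to zero there and de-trended
between consecutive still anchors.  A zero-phase high-pass on velocity is
the fallback when no still interval exists.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, sosfiltfilt

from .imu_io import Recording
from .preprocess import PreprocessConfig, PreprocessError, preprocess_recording

__all__ = [
    "MotionMetrics",
    "IntegrationConfig",
    "PathResult",
    "resultant_acceleration",
    "procedural_time",
    "still_mask",
    "integrate_velocity",
    "path_length",
    "compute_metrics",
    "METRIC_COLUMNS",
]


@dataclass
class IntegrationConfig:
    """Drift handling for velocity integration.

    ``zupt_acc_threshold`` (m/s^2) and ``zupt_min_duration`` (s) define a
    still interval; still detection runs on a 5 Hz low-passed |a| so that
    physiological tremor (8–12 Hz) does not mask genuine pauses.
    """

    drift_method: str = "zupt"           # zupt | highpass_velocity | none
    vel_hp_cutoff: float = 0.25          # Hz
    zupt_acc_threshold: float = 0.3      # m/s^2
    zupt_min_duration: float = 0.15      # s
    still_detect_lp_hz: float = 5.0      # Hz, detection-only low-pass
    #: floor (m/s) below which a candidate still's velocity residual from the
    #: local drift trend is always accepted as genuinely still
    zupt_vel_threshold: float = 0.05
    #: half-width (s) of the window used to estimate the local drift trend
    #: when vetting candidate stills
    zupt_drift_window_s: float = 7.5

    def validate(self, rate: float) -> None:
        if self.drift_method not in ("zupt", "highpass_velocity", "none"):
            raise ValueError(f"unknown drift_method {self.drift_method!r}")
        if not (self.zupt_acc_threshold > 0 and self.zupt_min_duration > 0):
            raise ValueError("ZUPT thresholds must be positive")
        if not 0 < self.vel_hp_cutoff < rate / 2:
            raise ValueError("vel_hp_cutoff must lie below Nyquist")


@dataclass
class MotionMetrics:
    """The per-trial efficiency metrics."""

    duration_s: float
    mean_resultant_acc: float
    cum_resultant_acc: float
    path_length_m: float
    displacement_m: float
    n_samples: int
    config_fingerprint: str

    def to_dict(self) -> dict:
        return asdict(self)


class PathResult(NamedTuple):
    path_m: float
    displacement_m: float


METRIC_COLUMNS = (
    "duration_s", "mean_resultant_acc", "cum_resultant_acc",
    "path_length_m", "displacement_m",
)


def resultant_acceleration(rec: Recording) -> np.ndarray:
    """Per-sample magnitude sqrt(ax^2 + ay^2 + az^2)."""
    return np.linalg.norm(rec.acc, axis=1)


def procedural_time(rec: Recording) -> float:
    """Trial duration: last minus first timestamp, in seconds."""
    return rec.duration


def _require_gravity_free(rec: Recording) -> None:
    if not rec.meta.extras.get("gravity_free"):
        raise PreprocessError("operation needs a gravity-free recording (run remove_gravity)")


def _runs(below: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2]) if b - a >= min_len]


def still_mask(rec: Recording, cfg: IntegrationConfig,
               v_raw: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of samples inside detected still intervals.

    Candidate stills are runs where the low-passed |a| stays under the
    threshold for at least ``zupt_min_duration`` (the low-pass sits below the
    tremor band so physiological tremor does not mask genuine pauses; the
    threshold is additionally capped at 60% of the trace's 90th-percentile
    |a| so that very gentle traces are not declared still wholesale).

    |a| also dips through any threshold mid-reach, at the acceleration zero
    crossing, exactly where speed peaks — those dips must never be anchored.
    When the raw integrated velocity is supplied, candidates are vetted
    against it: at a genuine still the integrated velocity equals the
    accumulated drift, a slowly varying trend shared by neighbouring stills,
    while a mid-reach dip sits a full movement speed off that trend.
    Candidates whose velocity residual from the local (median) trend exceeds
    both ``zupt_vel_threshold`` and 3x the lower-quartile residual are
    discarded (the lower quartile estimates the genuine-still scatter even
    when mid-reach dips make up half the candidates).
    """
    rate = rec.rate
    acc = rec.acc
    if 0 < cfg.still_detect_lp_hz < rate / 2:
        # low-pass per axis before taking the norm: rectified tremor has a DC
        # component that would survive any low-pass of the magnitude itself
        sos = butter(2, cfg.still_detect_lp_hz, btype="lowpass", fs=rate, output="sos")
        acc = sosfiltfilt(sos, acc, axis=0)
    mag = np.linalg.norm(acc, axis=1)
    threshold = min(cfg.zupt_acc_threshold, 0.6 * float(np.percentile(mag, 90)))
    below = mag < threshold
    min_len = max(1, int(round(cfg.zupt_min_duration * rate)))
    runs = _runs(below, min_len)

    if v_raw is not None and len(runs) > 1:
        centers = np.array([rec.t[(a + b) // 2] for a, b in runs])
        values = np.array([np.median(v_raw[a:b], axis=0) for a, b in runs])
        # sample-weighted local median of candidate velocities ~ drift trend
        cand_t = np.concatenate([rec.t[a:b] for a, b in runs])
        cand_v = np.concatenate([v_raw[a:b] for a, b in runs])
        order = np.argsort(cand_t)
        cand_t, cand_v = cand_t[order], cand_v[order]
        res = np.empty(len(runs))
        for i, tc in enumerate(centers):
            lo = np.searchsorted(cand_t, tc - cfg.zupt_drift_window_s)
            hi = np.searchsorted(cand_t, tc + cfg.zupt_drift_window_s)
            local = np.median(cand_v[lo:hi], axis=0)
            res[i] = np.linalg.norm(values[i] - local)
        cut = max(cfg.zupt_vel_threshold, 3.0 * float(np.percentile(res, 25)))
        runs = [run for run, r in zip(runs, res) if r <= cut]

    mask = np.zeros(rec.n_samples, dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


def integrate_velocity(rec: Recording, cfg: IntegrationConfig | None = None) -> np.ndarray:
    """Velocity series (n, 3) from trapezoidal integration plus drift correction.

    ZUPT: velocity is anchored to zero throughout detected still intervals
    and the integration error is removed by piecewise-linear interpolation
    between anchors.  Falls back to the high-pass route when no still
    interval is found.
    """
    cfg = cfg or IntegrationConfig()
    _require_gravity_free(rec)
    if not rec.is_uniform(rtol=1e-3):
        raise PreprocessError("velocity integration needs a uniform-rate recording")
    cfg.validate(rec.rate)

    v = cumulative_trapezoid(rec.acc, rec.t, axis=0, initial=0.0)
    method = cfg.drift_method
    if method == "zupt":
        mask = still_mask(rec, cfg, v_raw=v)
        if not mask.any():
            method = "highpass_velocity"
        else:
            # one drift anchor per still run, taken at its centre: velocity
            # is exactly zero mid-pause, whereas run edges still carry a few
            # cm/s which would bias every inter-anchor segment if anchored on
            runs = _runs(mask, 1)
            t_anchor = np.array([rec.t[(a + b) // 2] for a, b in runs])
            v_anchor = np.array([
                np.median(v[a + (b - a) // 4: b - (b - a) // 4 or b], axis=0)
                for a, b in runs
            ])
            drift = np.column_stack([
                np.interp(rec.t, t_anchor, v_anchor[:, j]) for j in range(3)
            ])
            v = v - drift
            v[mask] = 0.0
    if method == "highpass_velocity":
        sos = butter(4, cfg.vel_hp_cutoff, btype="highpass", fs=rec.rate, output="sos")
        v = sosfiltfilt(sos, v, axis=0)
    return v


def path_length(rec: Recording, cfg: IntegrationConfig | None = None) -> PathResult:
    """Total path (integral of speed) and straight-line displacement, in meters."""
    v = integrate_velocity(rec, cfg)
    speed = np.linalg.norm(v, axis=1)
    path = float(np.trapezoid(speed, rec.t))
    pos = cumulative_trapezoid(v, rec.t, axis=0, initial=0.0)
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    return PathResult(path_m=path, displacement_m=displacement)


def _fingerprint(pre_cfg: PreprocessConfig, int_cfg: IntegrationConfig) -> str:
    blob = json.dumps({"preprocess": asdict(pre_cfg), "integration": asdict(int_cfg)},
                      sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def compute_metrics(rec: Recording, pre_cfg: PreprocessConfig | None = None,
                    int_cfg: IntegrationConfig | None = None) -> MotionMetrics:
    """Run the full chain on a raw recording and return its metrics.

    Preprocessing (gravity removal + smoothing) is applied unless the
    recording is already flagged gravity-free.  Acceleration statistics are
    taken on the gravity-free smoothed signal by default; set
    ``pre_cfg.acc_on_raw`` to use raw specific force instead.  Deterministic
    for a fixed input and configuration.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    int_cfg = int_cfg or IntegrationConfig()

    if rec.meta.extras.get("gravity_free"):
        clean = rec
    else:
        clean = preprocess_recording(rec, pre_cfg)

    acc_source = rec if pre_cfg.acc_on_raw else clean
    mag = resultant_acceleration(acc_source)
    n = acc_source.n_samples
    cum = float(mag.sum())
    pr = path_length(clean, int_cfg)
    return MotionMetrics(
        duration_s=procedural_time(rec),
        mean_resultant_acc=cum / n,
        cum_resultant_acc=cum,
        path_length_m=pr.path_m,
        displacement_m=pr.displacement_m,
        n_samples=n,
        config_fingerprint=_fingerprint(pre_cfg, int_cfg),
    )
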