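"""Gravity removal and smoothing of wrist-IMU specific force.

An accelerometer at rest reads +1 g opposing gravity; hand-motion metrics
need the gravity-free linear acceleration instead.  Three removal routes are
provided, mirroring how much information the recording carries:

``static_subtract``
    estimate the gravity vector during a still (neutral-pose) window and
    subtract it sample-wise — the analogue of the study sensors' neutral-pose
    calibration; exact only while the wrist does not rotate.
``orientation``
    rotate nominal gravity by the per-sample roll/pitch angles and subtract;
    exact whenever an orientation stream is present.
``highpass``
    zero-phase high-pass each axis; the robust fallback when neither a still
    window nor orientation is available.

All filtering is zero-phase (forward-backward Butterworth) so that time
metrics downstream are not phase-shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.signal import butter, sosfiltfilt

from .imu_io import GRAVITY_MS2, Recording

__all__ = [
    "CalibrationModel",
    "PreprocessConfig",
    "CalibrationError",
    "PreprocessError",
    "estimate_calibration",
    "find_still_window",
    "gravity_in_sensor_frame",
    "remove_gravity",
    "smooth",
    "preprocess_recording",
]


class CalibrationError(ValueError):
    """The requested calibration window cannot be used."""


class PreprocessError(ValueError):
    """Preprocessing preconditions are violated."""


@dataclass
class CalibrationModel:
    """Static calibration estimated from a still window.

    ``gravity_vector`` is the mean specific force over the window (m/s^2);
    ``bias`` is what remains after removing nominal-magnitude gravity along
    that direction.  ``is_still`` is False when the window was too lively
    (std of |a| above 0.5 m/s^2), signalling the caller to fall back to the
    high-pass route.
    """

    bias: np.ndarray
    gravity_vector: np.ndarray
    still_window: tuple[float, float]
    is_still: bool = True

    @property
    def gravity_magnitude(self) -> float:
        return float(np.linalg.norm(self.gravity_vector))


@dataclass
class PreprocessConfig:
    """Tunables for gravity removal and smoothing.

    ``gravity_method`` 'auto' resolves to 'orientation' when angle channels
    are present, else 'static_subtract' on a detected still window, else
    'highpass'.  Cutoffs are in Hz; defaults bracket the voluntary-movement
    band (hand motion lives well below 20 Hz, drift well below 0.25 Hz).
    """

    gravity_method: str = "auto"
    hp_cutoff: float = 0.25
    lp_cutoff: float = 20.0
    filter_order: int = 4
    #: explicit still window (t0, t1) in seconds; None = auto-detect
    still_window: tuple[float, float] | None = None
    #: compute acceleration metrics on raw specific force instead of the
    #: gravity-free signal (off by default; see kinematics)
    acc_on_raw: bool = False

    def validate(self, rate: float) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff < rate / 2:
            raise PreprocessError(
                f"need 0 < hp_cutoff < lp_cutoff < rate/2, got "
                f"hp={self.hp_cutoff}, lp={self.lp_cutoff}, rate={rate}"
            )
        if self.gravity_method not in ("auto", "static_subtract", "highpass", "orientation"):
            raise PreprocessError(f"unknown gravity_method {self.gravity_method!r}")


_STILL_STD_LIMIT = 0.5   # m/s^2; |a| std above this means "not still"
_MIN_STILL_S = 0.5       # minimum usable still-window length


def _zero_phase(x: np.ndarray, rate: float, cutoff: float, order: int, btype: str) -> np.ndarray:
    sos = butter(order, cutoff, btype=btype, fs=rate, output="sos")
    return sosfiltfilt(sos, x, axis=0)


def estimate_calibration(rec: Recording, still_window: tuple[float, float]) -> CalibrationModel:
    """Estimate gravity direction and residual bias over a neutral-pose window."""
    t0, t1 = still_window
    if t0 < rec.t[0] - 1e-9 or t1 > rec.t[-1] + 1e-9 or not t1 > t0:
        raise CalibrationError("still window lies outside the recording")
    mask = (rec.t >= t0) & (rec.t <= t1)
    if (t1 - t0) < _MIN_STILL_S or mask.sum() < 2:
        raise CalibrationError(f"still window must contain at least {_MIN_STILL_S} s of samples")
    window = rec.acc[mask]
    gravity = window.mean(axis=0)
    mag = np.linalg.norm(gravity)
    bias = gravity - GRAVITY_MS2 * (gravity / mag) if mag > 0 else gravity.copy()
    still = float(np.std(np.linalg.norm(window, axis=1))) <= _STILL_STD_LIMIT
    return CalibrationModel(bias=bias, gravity_vector=gravity,
                            still_window=(float(t0), float(t1)), is_still=still)


def find_still_window(rec: Recording, length_s: float = _MIN_STILL_S) -> tuple[float, float] | None:
    """Locate the quietest window of the given length (lowest std of |a|)."""
    # n samples span (n-1)/rate seconds; +1 so the window covers length_s
    n_win = int(round(length_s * rec.rate)) + 1
    if n_win < 2 or n_win > rec.n_samples:
        return None
    mag = np.linalg.norm(rec.acc, axis=1)
    # rolling std via cumulative sums
    c1 = np.cumsum(np.insert(mag, 0, 0.0))
    c2 = np.cumsum(np.insert(mag**2, 0, 0.0))
    s1 = c1[n_win:] - c1[:-n_win]
    s2 = c2[n_win:] - c2[:-n_win]
    var = np.maximum(s2 / n_win - (s1 / n_win) ** 2, 0.0)
    i = int(np.argmin(var))
    return (float(rec.t[i]), float(rec.t[i + n_win - 1]))


def gravity_in_sensor_frame(roll_deg: np.ndarray, pitch_deg: np.ndarray) -> np.ndarray:
    """Gravity reaction read by an accelerometer at the given roll/pitch.

    Aerospace yaw-pitch-roll convention: a level sensor reads (0, 0, +g);
    yaw does not move gravity.  Returns an (n, 3) array in m/s^2.
    """
    phi = np.deg2rad(np.asarray(roll_deg, dtype=float))
    theta = np.deg2rad(np.asarray(pitch_deg, dtype=float))
    return GRAVITY_MS2 * np.column_stack([
        -np.sin(theta),
        np.cos(theta) * np.sin(phi),
        np.cos(theta) * np.cos(phi),
    ])


def _resolve_method(rec: Recording, cfg: PreprocessConfig) -> str:
    if cfg.gravity_method != "auto":
        return cfg.gravity_method
    if rec.orient is not None:
        return "orientation"
    if find_still_window(rec) is not None:
        return "static_subtract"
    return "highpass"


def remove_gravity(rec: Recording, cal: CalibrationModel | None,
                   cfg: PreprocessConfig) -> Recording:
    """Return a gravity-free copy of the recording.

    Refuses recordings already flagged gravity-free (the operation is not
    idempotent in signal terms, so re-application is treated as a caller
    bug).  Falls back from static_subtract to highpass when the calibration
    window was not still.
    """
    if rec.meta.extras.get("gravity_free"):
        raise PreprocessError("recording is already gravity-free")
    cfg.validate(rec.rate)
    method = _resolve_method(rec, cfg)

    if method == "static_subtract":
        if cal is None:
            window = cfg.still_window or find_still_window(rec)
            if window is None:
                method = "highpass"
            else:
                cal = estimate_calibration(rec, window)
        if cal is not None and not cal.is_still:
            method = "highpass"

    if method == "orientation":
        if rec.orient is None:
            raise PreprocessError("orientation gravity removal needs roll/pitch/yaw channels")
        g = gravity_in_sensor_frame(rec.orient[:, 0], rec.orient[:, 1])
        acc = rec.acc - g
        if cal is not None:
            acc = acc - cal.bias
    elif method == "static_subtract":
        assert cal is not None
        acc = rec.acc - cal.gravity_vector
    else:  # highpass
        if not rec.is_uniform(rtol=1e-3):
            raise PreprocessError("high-pass gravity removal needs a uniform-rate recording")
        acc = _zero_phase(rec.acc, rec.rate, cfg.hp_cutoff, cfg.filter_order, "highpass")

    meta = rec.meta.copy(extras={"gravity_free": True, "gravity_method": method})
    return Recording(meta=meta, t=rec.t.copy(), acc=acc,
                     gyro=None if rec.gyro is None else rec.gyro.copy(),
                     orient=None if rec.orient is None else rec.orient.copy())


def smooth(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase low-pass to strip sensor noise above the movement band."""
    if not rec.is_uniform(rtol=1e-3):
        raise PreprocessError("smoothing needs a uniform-rate recording")
    if cfg.lp_cutoff >= rec.rate / 2:
        raise PreprocessError(
            f"lp_cutoff {cfg.lp_cutoff} Hz is at or above Nyquist ({rec.rate / 2} Hz)"
        )
    acc = _zero_phase(rec.acc, rec.rate, cfg.lp_cutoff, cfg.filter_order, "lowpass")
    meta = rec.meta.copy(extras={"smoothed_lp_hz": cfg.lp_cutoff})
    return Recording(meta=meta, t=rec.t.copy(), acc=acc,
                     gyro=None if rec.gyro is None else rec.gyro.copy(),
                     orient=None if rec.orient is None else rec.orient.copy())


def preprocess_recording(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Full chain: gravity removal (per ``cfg.gravity_method``) then smoothing."""
    cfg = cfg or PreprocessConfig()
    return smooth(remove_gravity(rec, None, cfg), cfg)
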