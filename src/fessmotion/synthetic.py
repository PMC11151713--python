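"""Ground-truthed synthetic wrist-motion recordings and cohorts.

The generator emulates the phenomenology the analysis assumes: skilled hands
move less, slower and for a shorter time.  A trial is a chain of straight
minimum-jerk submovements (the standard model of skilled reaching) between
random waypoints, separated by micro-pauses that give the ZUPT drift
correction its anchors.  The minimum-jerk polynomial has closed-form
velocity and acceleration, so every generated trace carries exact analytic
ground truth (duration, path length, cumulative resultant acceleration).

Given per-cell targets (mean procedural time, path length and cumulative
acceleration for one group x hand x procedure), the builder solves for the
submovement count n and movement time that satisfy all three at once: for n
equal segments of amplitude D = L/n and duration tau = T_m/n, each segment
contributes 3.75*D/tau to the integral of |a|, so

    cum_acc = rate * 3.75 * L * n / T_m.

Skill differences enter only through those targets and the derived segment
structure — there is no separate "skill noise" channel.  On top of the
noise-free trajectory the sensor model adds gravity along a slowly wobbling
orientation (exported, so orientation-based gravity removal is testable),
band-limited physiological tremor, and white sensor noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .imu_io import (GRAVITY_MS2, GROUPS, HANDS, PROCEDURES,
                     Recording, RecordingMeta)
from .preprocess import gravity_in_sensor_frame

__all__ = [
    "ExpertiseProfile",
    "SyntheticTruth",
    "CohortSpec",
    "GenerationError",
    "generate_trace",
    "make_submovement_trace",
    "make_cohort",
    "default_cohort_spec",
    "TRUTH_COLUMNS",
]

#: generation refuses targets implying supra-physiological hand speed
MAX_HAND_SPEED = 5.0  # m/s

#: still padding at both ends of every trace (neutral pose before/after the
#: task); long enough for calibration (>= 0.5 s) and ZUPT anchoring
BOUNDARY_STILL_S = 0.6

#: micro-pause length range between submovements
PAUSE_RANGE_S = (0.08, 0.20)


class GenerationError(ValueError):
    """The requested target combination is physically infeasible."""


@dataclass
class ExpertiseProfile:
    """Targets and sensor-model parameters for one cohort cell.

    The three targets are the cell's mean procedural time (s), path length
    (m) and cumulative resultant acceleration (m/s^2 summed per sample at
    ``rate``).  ``between_subject_cv`` is the coefficient of variation of
    the per-participant skill multiplier applied to all three targets.
    """

    group: str
    hand: str
    procedure: str
    target_duration_s: float
    target_path_m: float
    target_cum_acc: float
    between_subject_cv: float = 0.10
    tremor_amp: float = 0.15            # m/s^2 per axis
    tremor_band: tuple[float, float] = (8.0, 12.0)   # Hz
    sensor_noise_sd: float = 0.05       # m/s^2 per axis
    gravity: float = GRAVITY_MS2
    rate: float = 128.0                 # Hz
    pause_fraction: float = 0.10        # nominal share of time spent still
    orientation_wobble_deg: float = 15.0
    workspace_halfwidth: float = 0.315  # m; soft attraction scale for waypoints
    micro_pauses: bool = True           # False = stress mode without ZUPT anchors
    include_orientation: bool = True

    def __post_init__(self) -> None:
        if min(self.target_duration_s, self.target_path_m, self.target_cum_acc) <= 0:
            raise GenerationError("all targets must be positive")
        if not 0 <= self.between_subject_cv < 1:
            raise GenerationError("between_subject_cv must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Analytic ground truth attached to one generated recording."""

    true_duration_s: float
    true_path_m: float
    true_cum_acc: float
    submovement_count: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


TRUTH_COLUMNS = ("participant_id", "group", "hand", "procedure",
                 "true_duration_s", "true_path_m", "true_cum_acc",
                 "submovement_count", "seed")


def _solve_structure(T: float, L: float, C: float, rate: float,
                     pause_fraction: float, micro_pauses: bool
                     ) -> tuple[int, float, float]:
    """Solve (submovement count, movement time, pause budget) for the targets."""
    pad = 2 * BOUNDARY_STILL_S if micro_pauses else 0.0
    if T <= pad + 4 / rate:
        raise GenerationError(f"duration target {T:.3f} s is too short")
    t_move_nominal = min((1 - pause_fraction) * T, T - pad)
    n = max(1, round(C * t_move_nominal / (3.75 * rate * L)))
    # movement time that makes the cumulative-acceleration identity exact
    t_move = 3.75 * rate * L * n / C
    while n > 1 and t_move > T - pad:
        n -= 1
        t_move = 3.75 * rate * L * n / C
    if t_move > T - pad:
        raise GenerationError(
            "targets are infeasible: cumulative acceleration too small for the "
            f"requested path within {T:.1f} s")
    if 1.875 * L / t_move > MAX_HAND_SPEED:
        raise GenerationError(
            f"targets imply a peak hand speed above {MAX_HAND_SPEED} m/s")
    if t_move / n < 4 / rate:
        raise GenerationError("submovements would be shorter than 4 samples")
    return n, t_move, T - pad - t_move


def _minimum_jerk_acc(tau_hat: np.ndarray, D: float, tau: float) -> np.ndarray:
    """Closed-form acceleration of a minimum-jerk reach of amplitude D, time tau."""
    return (D / tau**2) * (60 * tau_hat - 180 * tau_hat**2 + 120 * tau_hat**3)


def _synthesize(rng: np.random.Generator, T: float, L: float, C: float,
                p: ExpertiseProfile) -> tuple[dict, dict]:
    """Build one trace hitting (T, L, C); returns channel arrays and truth fields."""
    rate = p.rate
    n, t_move, pause_budget = _solve_structure(T, L, C, rate,
                                               p.pause_fraction, p.micro_pauses)
    D, tau = L / n, t_move / n

    # schedule interior micro-pauses at random junctions
    gaps = np.zeros(max(n - 1, 0))
    if p.micro_pauses and pause_budget > 0 and n > 1:
        lo, hi = PAUSE_RANGE_S
        n_pauses = min(n - 1, max(1, round(pause_budget / np.mean(PAUSE_RANGE_S))))
        lengths = rng.uniform(lo, hi, size=n_pauses)
        lengths *= pause_budget / lengths.sum()
        where = rng.choice(n - 1, size=n_pauses, replace=False)
        gaps[where] = lengths
    elif not p.micro_pauses:
        # stress mode: stretch first segment start so total span still equals T
        pass

    # waypoint walk: random directions with soft attraction toward the origin
    pos = np.zeros(3)
    directions = np.empty((n, 3))
    for i in range(n):
        raw = rng.standard_normal(3) - 0.5 * pos / p.workspace_halfwidth
        directions[i] = raw / np.linalg.norm(raw)
        pos = pos + D * directions[i]

    lead = BOUNDARY_STILL_S if p.micro_pauses else 0.0
    starts = lead + np.concatenate(([0.0], np.cumsum(tau + gaps)))[:n]

    n_samp = int(round(T * rate)) + 1
    t = np.arange(n_samp) / rate
    a_lin = np.zeros((n_samp, 3))
    for i in range(n):
        i0 = int(np.searchsorted(t, starts[i], side="left"))
        i1 = int(np.searchsorted(t, starts[i] + tau, side="right"))
        tau_hat = (t[i0:i1] - starts[i]) / tau
        tau_hat = np.clip(tau_hat, 0.0, 1.0)
        a_lin[i0:i1] += directions[i][None, :] * \
            _minimum_jerk_acc(tau_hat, D, tau)[:, None]

    # final rescale: make the discrete noise-free cumulative resultant hit C
    # exactly (discretisation leaves it ~0.1% off the analytic identity)
    cum_raw = float(np.linalg.norm(a_lin, axis=1).sum())
    k = C / cum_raw
    a_lin *= k

    # sensor model: gravity along a slowly wobbling orientation, tremor, noise
    wobble_amp = rng.uniform(0.3, 1.0, size=3) * p.orientation_wobble_deg
    wobble_f = rng.uniform(0.02, 0.08, size=3)
    wobble_phase = rng.uniform(0, 2 * np.pi, size=3)
    angles = wobble_amp * np.sin(2 * np.pi * wobble_f * t[:, None] + wobble_phase)
    rates_dps = wobble_amp * 2 * np.pi * wobble_f * np.cos(
        2 * np.pi * wobble_f * t[:, None] + wobble_phase)
    g_sensor = gravity_in_sensor_frame(angles[:, 0], angles[:, 1]) * (p.gravity / GRAVITY_MS2)

    tremor_f = rng.uniform(*p.tremor_band, size=3)
    tremor_phase = rng.uniform(0, 2 * np.pi, size=3)
    tremor = p.tremor_amp * np.sin(2 * np.pi * tremor_f * t[:, None] + tremor_phase)

    noise = rng.normal(0.0, p.sensor_noise_sd, size=(n_samp, 3))

    measured = a_lin + g_sensor + tremor + noise
    channels = {"t": t, "acc": measured,
                "gyro": rates_dps if p.include_orientation else None,
                "orient": angles if p.include_orientation else None}
    truth = {"true_duration_s": float(t[-1] - t[0]),
             "true_path_m": k * L,
             "true_cum_acc": float(np.linalg.norm(a_lin, axis=1).sum()),
             "submovement_count": n}
    return channels, truth


def generate_trace(profile: ExpertiseProfile, seed: int,
                   participant_id: str = "sim",
                   skill_scale: float | None = None
                   ) -> tuple[Recording, SyntheticTruth]:
    """Generate one trial for the given cell profile.

    The three targets are jointly scaled by a per-trace skill multiplier,
    drawn as Normal(1, between_subject_cv) unless ``skill_scale`` pins it
    (the cohort builder passes standardized multipliers).  Deterministic for
    a fixed (profile, seed).
    """
    rng = np.random.default_rng(seed)
    scale = rng.normal(1.0, profile.between_subject_cv) if skill_scale is None \
        else float(skill_scale)
    if scale <= 0:
        raise GenerationError("skill multiplier draw is non-positive; lower the CV")
    channels, truth_fields = _synthesize(
        rng,
        scale * profile.target_duration_s,
        scale * profile.target_path_m,
        scale * profile.target_cum_acc,
        profile,
    )
    meta = RecordingMeta(
        participant_id=participant_id, group=profile.group, hand=profile.hand,
        procedure=profile.procedure, nominal_rate=profile.rate,
        acc_units_in="m_s2",
        extras={"synthetic": True, "seed": int(seed)},
    )
    rec = Recording(meta=meta, **channels)
    truth = SyntheticTruth(seed=int(seed), **truth_fields)
    return rec, truth


def make_submovement_trace(amplitude_m: float, move_time_s: float,
                           rate: float = 128.0, *, sensor_noise_sd: float = 0.0,
                           tremor_amp: float = 0.0, orientation_wobble_deg: float = 0.0,
                           seed: int = 0) -> tuple[Recording, SyntheticTruth]:
    """One isolated minimum-jerk submovement with still padding at both ends.

    Convenience wrapper used in tests and examples: targets are chosen so the
    structure solver returns exactly one segment of the requested amplitude.
    """
    total = move_time_s + 2 * BOUNDARY_STILL_S
    profile = ExpertiseProfile(
        group="senior", hand="DH", procedure="foreign_body_removal",
        target_duration_s=total, target_path_m=amplitude_m,
        target_cum_acc=rate * 3.75 * amplitude_m / move_time_s,
        between_subject_cv=0.0, tremor_amp=tremor_amp,
        sensor_noise_sd=sensor_noise_sd, rate=rate,
        orientation_wobble_deg=orientation_wobble_deg,
        pause_fraction=2 * BOUNDARY_STILL_S / total,
    )
    return generate_trace(profile, seed, skill_scale=1.0)


# --------------------------------------------------------------------------
# cohorts

@dataclass
class CohortSpec:
    """Cell targets and generation parameters for a full study cohort."""

    group_sizes: dict[str, int]
    #: procedure -> group -> mean procedural time (s); shared by both hands
    duration_s: dict[str, dict[str, float]]
    #: procedure -> group -> hand -> set point
    cum_acc: dict[str, dict[str, dict[str, float]]]
    path_m: dict[str, dict[str, dict[str, float]]]
    between_subject_cv: float = 0.0025
    rate_hz: float = 128.0
    sensor_noise_sd: float = 0.05
    tremor_amp: float = 0.15
    tremor_band: tuple[float, float] = (8.0, 12.0)
    orientation_wobble_deg: float = 15.0
    micro_pauses: bool = True

    @property
    def procedures(self) -> tuple[str, ...]:
        return tuple(self.duration_s)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown cohort spec keys: {sorted(extra)}")
        kwargs = dict(d)
        if "tremor_band" in kwargs:
            kwargs["tremor_band"] = tuple(kwargs["tremor_band"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def profile(self, group: str, procedure: str, hand: str) -> ExpertiseProfile:
        return ExpertiseProfile(
            group=group, hand=hand, procedure=procedure,
            target_duration_s=self.duration_s[procedure][group],
            target_path_m=self.path_m[procedure][group][hand],
            target_cum_acc=self.cum_acc[procedure][group][hand],
            between_subject_cv=self.between_subject_cv,
            tremor_amp=self.tremor_amp, tremor_band=self.tremor_band,
            sensor_noise_sd=self.sensor_noise_sd, rate=self.rate_hz,
            orientation_wobble_deg=self.orientation_wobble_deg,
            micro_pauses=self.micro_pauses,
        )


def default_cohort_spec() -> CohortSpec:
    """The shipped default cohort: 24 participants (10/10/4), five procedures,
    two hands, cell set points from the published group means."""
    with resources.files("fessmotion.data").joinpath("default_cohort.yaml").open() as fh:
        return CohortSpec.from_dict(yaml.safe_load(fh))


def _standardized_multipliers(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Skill multipliers with realized mean exactly 1 and SD exactly ``cv``.

    Variance-matched sampling: a standard-normal draw is re-standardized so
    that even a 4-participant group realizes the configured mean and spread
    (the cohort's cell means then sit on the set points by construction).
    """
    if n == 1 or cv == 0:
        return np.ones(n)
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std()
    return 1.0 + cv * z


def make_cohort(spec: CohortSpec, master_seed: int
                ) -> tuple[list[Recording], list[SyntheticTruth], pd.DataFrame]:
    """Generate the full cohort: every participant x procedure x hand trial.

    Per-participant random effects scale all of a participant's targets by
    one multiplier; a participant's two hands share the same duration draw
    (one trial, two sensors).  Pure function of (spec, master_seed).
    """
    ss = np.random.SeedSequence(master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    prefixes = {"resident": "RES", "specialist": "SPE", "senior": "SEN"}

    recordings: list[Recording] = []
    truths: list[SyntheticTruth] = []
    rows: list[dict] = []
    n_trials = sum(spec.group_sizes.values()) * len(spec.procedures) * len(HANDS)
    trace_seeds = (np.random.SeedSequence(master_seed).generate_state(n_trials + 8)
                   % np.int64(2**31 - 1))
    k = 0
    for group in GROUPS:
        size = spec.group_sizes.get(group, 0)
        mult = _standardized_multipliers(rng, size, spec.between_subject_cv)
        for i in range(size):
            pid = f"{prefixes[group]}{i + 1:02d}"
            for procedure in spec.procedures:
                for hand in HANDS:
                    profile = spec.profile(group, procedure, hand)
                    seed = int(trace_seeds[k]); k += 1
                    rec, truth = generate_trace(profile, seed, participant_id=pid,
                                                skill_scale=float(mult[i]))
                    recordings.append(rec)
                    truths.append(truth)
                    rows.append({
                        "path": f"{pid}_{procedure}_{hand}.csv",
                        "participant_id": pid, "group": group,
                        "hand": hand, "procedure": procedure,
                        **truth.to_dict(),
                    })
    manifest = pd.DataFrame(rows)
    return recordings, truths, manifest
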