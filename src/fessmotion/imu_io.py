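"""Reading, writing and normalising wrist-IMU recordings.

A trial is one (participant, hand, procedure) recording from a wrist-mounted
triaxial accelerometer (optionally with gyroscope and orientation channels),
exported as CSV.  Vendors disagree on column names and units, so ingestion is
driven by an explicit column mapping and a declared input unit; after
ingestion every recording stores acceleration in m/s^2 on a monotone time
base, ready for the preprocessing and kinematics stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY_MS2",
    "GROUPS",
    "HANDS",
    "PROCEDURES",
    "ImuSample",
    "RecordingMeta",
    "Recording",
    "ColumnMapping",
    "ConfigurationError",
    "EmptyRecordingError",
    "FormatError",
    "read_recording_csv",
    "write_recording_csv",
    "read_manifest",
    "resample_uniform",
]

#: standard gravity, used for g <-> m/s^2 conversion everywhere in the package
GRAVITY_MS2 = 9.80665

GROUPS = ("resident", "specialist", "senior")
HANDS = ("DH", "NDH")
PROCEDURES = (
    "foreign_body_removal",
    "septoplasty",
    "turbinoplasty",
    "maxillary_antrostomy",
    "ethmoidectomy",
)

OPTIONAL_CHANNELS = ("wx", "wy", "wz", "roll", "pitch", "yaw")


class ConfigurationError(ValueError):
    """A column mapping or metadata declaration is unusable."""


class EmptyRecordingError(ValueError):
    """Fewer than two valid samples survived ingestion."""


class FormatError(ValueError):
    """The file content violates the recording format beyond repair."""


@dataclass(frozen=True)
class ImuSample:
    """One time-stamped IMU reading in the sensor frame.

    Acceleration is in m/s^2 (after unit normalisation), angular rate in
    deg/s, orientation angles in degrees.  Optional channels are ``None``
    when the recording does not carry them.
    """

    t: float
    ax: float
    ay: float
    az: float
    wx: float | None = None
    wy: float | None = None
    wz: float | None = None
    roll: float | None = None
    pitch: float | None = None
    yaw: float | None = None


@dataclass
class RecordingMeta:
    """Labels and acquisition parameters for one trial."""

    participant_id: str
    group: str
    hand: str
    procedure: str
    nominal_rate: float = 128.0
    acc_units_in: str = "g"
    #: processing flags and provenance (gravity_free, resampled_to, dropped_rows, ...)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.hand not in HANDS:
            raise ConfigurationError(f"unknown hand {self.hand!r}; expected one of {HANDS}")
        if self.procedure not in PROCEDURES:
            raise ConfigurationError(
                f"unknown procedure {self.procedure!r}; expected one of {PROCEDURES}"
            )
        if not self.nominal_rate > 0:
            raise ConfigurationError("nominal_rate must be positive")
        if self.acc_units_in not in ("g", "m_s2"):
            raise ConfigurationError("acc_units_in must be 'g' or 'm_s2'")

    def copy(self, **updates) -> "RecordingMeta":
        new = dataclasses.replace(self)
        new.extras = dict(self.extras)
        for k, v in updates.items():
            if k == "extras":
                new.extras.update(v)
            else:
                setattr(new, k, v)
        return new

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class Recording:
    """An ordered trial: timestamps plus channel arrays.

    ``acc`` is (n, 3) in m/s^2; ``gyro`` (deg/s) and ``orient``
    (roll/pitch/yaw, deg) are either (n, 3) arrays or ``None`` — optional
    channels are all-present or all-absent per recording.
    """

    meta: RecordingMeta
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray | None = None
    orient: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise FormatError("t must be 1-D and acc must be (n, 3)")
        if self.t.size < 2:
            raise EmptyRecordingError("a recording needs at least 2 samples")
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.acc)):
            raise FormatError("timestamps and accelerations must be finite")
        if self.t[0] < 0:
            raise FormatError("timestamps must be non-negative")
        if not np.all(np.diff(self.t) > 0):
            raise FormatError("timestamps must be strictly increasing")
        for name in ("gyro", "orient"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.t.size, 3):
                    raise FormatError(f"{name} must be (n, 3) when present")
                setattr(self, name, arr)

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def rate(self) -> float:
        """Mean sampling rate over the recording span."""
        return (self.n_samples - 1) / self.duration

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        dt = np.diff(self.t)
        return bool(np.all(np.abs(dt - dt.mean()) <= rtol * dt.mean() + 1e-12))

    def samples(self) -> Iterator[ImuSample]:
        """Iterate rows as :class:`ImuSample` (convenience view; arrays are primary)."""
        for i in range(self.n_samples):
            yield ImuSample(
                t=float(self.t[i]),
                ax=float(self.acc[i, 0]),
                ay=float(self.acc[i, 1]),
                az=float(self.acc[i, 2]),
                wx=float(self.gyro[i, 0]) if self.gyro is not None else None,
                wy=float(self.gyro[i, 1]) if self.gyro is not None else None,
                wz=float(self.gyro[i, 2]) if self.gyro is not None else None,
                roll=float(self.orient[i, 0]) if self.orient is not None else None,
                pitch=float(self.orient[i, 1]) if self.orient is not None else None,
                yaw=float(self.orient[i, 2]) if self.orient is not None else None,
            )


@dataclass
class ColumnMapping:
    """Maps export column names to channel roles.

    ``t`` may be ``None`` when the export carries no timestamp column; a time
    base is then synthesised as ``index / nominal_rate``.
    """

    t: str | None
    ax: str
    ay: str
    az: str
    wx: str | None = None
    wy: str | None = None
    wz: str | None = None
    roll: str | None = None
    pitch: str | None = None
    yaw: str | None = None

    @classmethod
    def default(cls) -> "ColumnMapping":
        return cls(t="t", ax="ax", ay="ay", az="az",
                   wx="wx", wy="wy", wz="wz",
                   roll="roll", pitch="pitch", yaw="yaw")

    @classmethod
    def from_dict(cls, d: Mapping[str, str | None]) -> "ColumnMapping":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown column roles: {sorted(unknown)}")
        missing = {"ax", "ay", "az"} - set(d)
        if missing:
            raise ConfigurationError(f"mapping must name columns for {sorted(missing)}")
        return cls(t=d.get("t"), **{k: d[k] for k in d if k != "t"})


# fraction of rows that may be dropped / reordered before the file is refused
_MAX_BAD_ROW_FRACTION = 0.01


def read_recording_csv(path: str | Path, mapping: ColumnMapping, meta: RecordingMeta) -> Recording:
    """Read one trial CSV and normalise it into a :class:`Recording`.

    Rows whose required fields fail to parse are dropped and counted in
    ``meta.extras['dropped_rows']``; duplicate timestamps collapse to the
    first occurrence; out-of-order timestamps are repaired by a stable sort.
    More than 1% affected rows (dropped or reordered) aborts with
    :class:`FormatError`.  Acceleration declared in g is converted to m/s^2.
    """
    path = Path(path)
    df = pd.read_csv(path)

    required = {"ax": mapping.ax, "ay": mapping.ay, "az": mapping.az}
    if mapping.t is not None:
        required["t"] = mapping.t
    for role, col in required.items():
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} (role {role}) missing from {path.name}")

    optional_cols = {ch: getattr(mapping, ch) for ch in OPTIONAL_CHANNELS if getattr(mapping, ch)}
    present_opt = {ch: col for ch, col in optional_cols.items() if col in df.columns}
    gyro_ok = all(ch in present_opt for ch in ("wx", "wy", "wz"))
    orient_ok = all(ch in present_opt for ch in ("roll", "pitch", "yaw"))

    cols = dict(required)
    if gyro_ok:
        cols.update({ch: present_opt[ch] for ch in ("wx", "wy", "wz")})
    if orient_ok:
        cols.update({ch: present_opt[ch] for ch in ("roll", "pitch", "yaw")})

    data = {role: pd.to_numeric(df[col], errors="coerce") for role, col in cols.items()}
    frame = pd.DataFrame(data)
    n_raw = len(frame)
    required_roles = list(required)
    frame = frame.dropna(subset=required_roles)
    dropped = n_raw - len(frame)
    if len(frame) < 2:
        raise EmptyRecordingError(f"{path.name}: fewer than 2 valid rows after parsing")

    if mapping.t is None:
        t = np.arange(len(frame), dtype=float) / meta.nominal_rate
        frame = frame.assign(t=t)
    else:
        t = frame["t"].to_numpy(dtype=float)
        n_disorder = int(np.sum(np.diff(t) < 0))
        if n_disorder:
            if n_disorder > _MAX_BAD_ROW_FRACTION * len(frame):
                raise FormatError(
                    f"{path.name}: {n_disorder} out-of-order timestamps exceed the 1% repair budget"
                )
            frame = frame.sort_values("t", kind="stable")
        n_dup = int(frame["t"].duplicated().sum())
        if n_dup > _MAX_BAD_ROW_FRACTION * len(frame):
            raise FormatError(f"{path.name}: {n_dup} duplicate timestamps exceed the 1% budget")
        frame = frame[~frame["t"].duplicated(keep="first")]
        if len(frame) < 2:
            raise EmptyRecordingError(f"{path.name}: fewer than 2 rows after de-duplication")

    acc = frame[["ax", "ay", "az"]].to_numpy(dtype=float)
    if meta.acc_units_in == "g":
        acc = acc * GRAVITY_MS2
    gyro = frame[["wx", "wy", "wz"]].to_numpy(dtype=float) if gyro_ok else None
    orient = frame[["roll", "pitch", "yaw"]].to_numpy(dtype=float) if orient_ok else None

    out_meta = meta.copy(acc_units_in="m_s2", extras={"dropped_rows": dropped})
    return Recording(meta=out_meta, t=frame["t"].to_numpy(dtype=float),
                     acc=acc, gyro=gyro, orient=orient)


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    """Write a normalised trial CSV plus a sidecar metadata JSON.

    Column order is fixed (t, ax, ay, az, then gyro, then orientation);
    acceleration is always written in m/s^2 and the sidecar
    ``<path>.meta.json`` documents units and labels.
    """
    path = Path(path)
    cols = {"t": rec.t, "ax": rec.acc[:, 0], "ay": rec.acc[:, 1], "az": rec.acc[:, 2]}
    if rec.gyro is not None:
        cols.update({"wx": rec.gyro[:, 0], "wy": rec.gyro[:, 1], "wz": rec.gyro[:, 2]})
    if rec.orient is not None:
        cols.update({"roll": rec.orient[:, 0], "pitch": rec.orient[:, 1], "yaw": rec.orient[:, 2]})
    df = pd.DataFrame(cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9f")

    meta = rec.meta.to_dict()
    meta["units"] = {"t": "s", "acc": "m_s2", "gyro": "deg_s", "orient": "deg"}
    meta["n_samples"] = rec.n_samples
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_sidecar_meta(path: str | Path) -> RecordingMeta:
    """Load the metadata sidecar written by :func:`write_recording_csv`."""
    d = json.loads(Path(path).read_text())
    extras = d.get("extras", {})
    return RecordingMeta(
        participant_id=d["participant_id"], group=d["group"], hand=d["hand"],
        procedure=d["procedure"], nominal_rate=d["nominal_rate"],
        acc_units_in=d.get("units", {}).get("acc", d.get("acc_units_in", "m_s2")),
        extras=extras,
    )


MANIFEST_COLUMNS = ("path", "participant_id", "group", "hand", "procedure")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV listing one trial file per row."""
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"manifest is missing columns {sorted(missing)}")
    return df


def resample_uniform(rec: Recording, target_hz: float) -> Recording:
    """Linearly interpolate all channels onto a uniform grid at ``target_hz``.

    The grid spans [t_first, t_last]; total duration is preserved to within
    one sample period.  The resampling is recorded in ``meta.extras``.
    """
    if not target_hz > 0:
        raise ConfigurationError("target_hz must be positive")
    n_new = int(np.floor(rec.duration * target_hz)) + 1
    if n_new < 2:
        raise EmptyRecordingError("target_hz yields fewer than 2 samples")
    t_new = rec.t[0] + np.arange(n_new) / target_hz

    def interp_block(block: np.ndarray) -> np.ndarray:
        return np.column_stack([np.interp(t_new, rec.t, block[:, j]) for j in range(3)])

    meta = rec.meta.copy(nominal_rate=float(target_hz),
                         extras={"resampled_to": float(target_hz)})
    return Recording(
        meta=meta, t=t_new, acc=interp_block(rec.acc),
        gyro=interp_block(rec.gyro) if rec.gyro is not None else None,
        orient=interp_block(rec.orient) if rec.orient is not None else None,
    )
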