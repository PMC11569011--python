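"""File formats and validated in-memory containers.

Units are fixed package-wide: accelerations in g, lengths in meters,
angles in degrees, time in seconds.

Dialects
--------
IMU CSV   : header ``time_s,C7_ax,C7_ay,C7_az,L5_ax,...,SH_az`` — twelve
            acceleration columns in g, one row per sample, comma-separated.
Marker TSV: header ``time_s`` then ``C7_x C7_y C7_z L5_x ... LM_z`` —
            twelve coordinate columns in meters, z vertical up,
            tab-separated.
Segments  : ``label<TAB>t_start<TAB>t_end`` per line, hand-editable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical sensor order: cervical, lumbar, thigh, shank.
SENSORS = ("C7", "L5", "TH", "SH")
#: Canonical marker order: C7/L5 on the trunk, iliac crest, lateral malleolus.
MARKERS = ("C7", "L5", "IC", "LM")

AXES = ("x", "y", "z")

#: Activity labels used for segment annotation and per-activity evaluation.
ACTIVITY_LABELS = (
    "standing_upright",
    "standing_forward_lean",
    "walking",
    "parkinsonian_gait",
    "other",
)


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class AccelRecording:
    """Synchronized tri-axial acceleration streams for the four sensors.

    ``channels[sensor]`` is an (n_samples, 3) float array of (a_x, a_y, a_z)
    in units of g.  All four sensors must be present with equal lengths and
    no NaNs; gaps in a recording are an error, not a maskable condition.
    """

    sample_rate: float
    channels: dict[str, np.ndarray]
    start_time: float = 0.0
    #: Sensors this recording must carry; a two-sensor perpendicular-only
    #: recording passes ("C7", "L5").
    sensors: tuple[str, ...] = SENSORS

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        unknown = [s for s in self.sensors if s not in SENSORS]
        if unknown:
            raise FormatError(f"unknown sensor(s): {unknown}")
        if not {"C7", "L5"} <= set(self.sensors):
            raise FormatError("recording must at least carry the C7 and L5 sensors")
        missing = [s for s in self.sensors if s not in self.channels]
        if missing:
            raise FormatError(f"missing sensor block(s): {missing}")
        lengths = set()
        for s in self.sensors:
            arr = np.asarray(self.channels[s], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"sensor {s}: expected (n, 3) array, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise FormatError(f"sensor {s}: non-finite sample at row {bad[0]}")
            self.channels[s] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise FormatError(f"unequal channel lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return self.channels[self.sensors[0]].shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n_samples / sample_rate)."""
        return self.n_samples / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class ActivitySegments:
    """Ordered, non-overlapping labeled time intervals."""

    segments: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        for label, t0, t1 in self.segments:
            if label not in ACTIVITY_LABELS:
                raise FormatError(
                    f"unknown activity label {label!r}; expected one of {ACTIVITY_LABELS}"
                )
            if not t0 < t1:
                raise FormatError(f"segment {label!r}: t_start {t0} must be < t_end {t1}")
        ordered = sorted(self.segments, key=lambda s: s[1])
        for (la, _, e_a), (lb, s_b, _) in zip(ordered, ordered[1:]):
            if s_b < e_a - 1e-12:
                raise FormatError(f"segments {la!r} and {lb!r} overlap")
        self.segments = ordered

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def labels(self) -> list[str]:
        return [s[0] for s in self.segments]


@dataclass
class MarkerTrajectory:
    """Time-indexed 3D positions of the C7, L5, IC and LM markers.

    Positions are in meters in a ground frame with the z-axis vertical up.
    The constraint z(L5) > z(LM), z(IC) > z(LM) needed by the leg reference
    is a *downstream* precondition checked where the angles are computed,
    not an I/O-level invariant.
    """

    sample_rate: float
    positions: dict[str, np.ndarray]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        missing = [m for m in MARKERS if m not in self.positions]
        if missing:
            raise FormatError(f"missing marker(s): {missing}")
        lengths = set()
        for m in MARKERS:
            arr = np.asarray(self.positions[m], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise FormatError(f"marker {m}: expected (n, 3) array, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr))[0][0])
                raise FormatError(f"marker {m}: non-finite coordinate at frame {bad}")
            self.positions[m] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise FormatError(f"unequal marker lengths: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        return self.positions[MARKERS[0]].shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.sample_rate


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths: thigh ``u`` and shank ``l``, in meters."""

    u: float
    l: float

    def __post_init__(self) -> None:
        if not 0 < self.u < 1.0:
            raise ValueError(f"thigh length u must be in (0, 1) m, got {self.u}")
        if not 0 < self.l < 1.0:
            raise ValueError(f"shank length l must be in (0, 1) m, got {self.l}")


def _accel_columns() -> list[str]:
    return [f"{s}_a{ax}" for s in SENSORS for ax in AXES]


def _marker_columns() -> list[str]:
    return [f"{m}_{ax}" for m in MARKERS for ax in AXES]


def read_accel_csv(path: str | Path, sensors: Sequence[str] = SENSORS) -> AccelRecording:
    """Read a wide-format IMU CSV into an :class:`AccelRecording`.

    All column blocks for ``sensors`` must be present (pass
    ``("C7", "L5")`` for a two-sensor perpendicular-only file).  The
    sample rate is inferred from the time column, which must be strictly
    monotonic and uniformly spaced.
    """
    df = pd.read_csv(path)
    expected = ["time_s"] + [f"{s}_a{ax}" for s in sensors for ax in AXES]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise FormatError(f"{path}: non-uniform sampling interval")
    channels = {
        s: df[[f"{s}_a{ax}" for ax in AXES]].to_numpy(dtype=float) for s in sensors
    }
    return AccelRecording(
        sample_rate=1.0 / dt[0], channels=channels, start_time=t[0], sensors=tuple(sensors)
    )


def write_accel_csv(path: str | Path, rec: AccelRecording) -> None:
    data = {"time_s": rec.time}
    for s in rec.sensors:
        for j, ax in enumerate(AXES):
            data[f"{s}_a{ax}"] = rec.channels[s][:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_markers_tsv(path: str | Path) -> MarkerTrajectory:
    """Read a marker TSV into a :class:`MarkerTrajectory`.

    NaN coordinates are rejected with the offending frame index; gap
    filling is out of scope.
    """
    df = pd.read_csv(path, sep="\t")
    expected = ["time_s"] + _marker_columns()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    positions = {
        m: df[[f"{m}_{ax}" for ax in AXES]].to_numpy(dtype=float) for m in MARKERS
    }
    return MarkerTrajectory(sample_rate=1.0 / dt[0], positions=positions, start_time=t[0])


def write_markers_tsv(path: str | Path, traj: MarkerTrajectory) -> None:
    data = {"time_s": traj.time}
    for m in MARKERS:
        for j, ax in enumerate(AXES):
            data[f"{m}_{ax}"] = traj.positions[m][:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_segments_tsv(path: str | Path) -> ActivitySegments:
    segments: list[tuple[str, float, float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}:{lineno}: expected label<TAB>t_start<TAB>t_end")
        label, t0, t1 = parts
        try:
            segments.append((label, float(t0), float(t1)))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return ActivitySegments(segments)


def write_segments_tsv(path: str | Path, segs: ActivitySegments) -> None:
    lines = [f"{label}\t{t0:.6g}\t{t1:.6g}" for label, t0, t1 in segs]
    Path(path).write_text("\n".join(lines) + "\n")


def resample_markers(traj: MarkerTrajectory, target_rate: float) -> MarkerTrajectory:
    """Linearly interpolate each coordinate onto a uniform grid at target_rate.

    The duration is preserved within one target sample period.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if traj.n_frames < 2:
        raise ValueError("resampling needs at least 2 frames")
    t_old = traj.time
    n_new = int(np.floor((t_old[-1] - t_old[0]) * target_rate)) + 1
    t_new = t_old[0] + np.arange(n_new) / target_rate
    positions = {
        m: np.column_stack(
            [np.interp(t_new, t_old, traj.positions[m][:, j]) for j in range(3)]
        )
        for m in MARKERS
    }
    return MarkerTrajectory(sample_rate=target_rate, positions=positions, start_time=t_old[0])


# ---------------------------------------------------------------------------
# Run configuration

_CONFIG_KEYS = {
    "sample_rate",
    "u_m",
    "l_m",
    "marker_time_offset_s",
    "sg_window_s",
    "sg_order",
    "calibration",
    "axis_convention",
}

_CALIBRATION_KEYS = {"method", "window", "photo_ca_per", "photo_ca_mal"}

_CONFIG_DEFAULTS = {
    "sample_rate": 128.0,
    "marker_time_offset_s": 0.0,
    "sg_window_s": 1.0,
    "sg_order": 3,
}


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML run configuration.

    Unknown keys are rejected so that typos fail loudly before any
    computation starts.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config key(s): {sorted(unknown)}")
    cal = raw.get("calibration")
    if cal is not None:
        if not isinstance(cal, dict):
            raise FormatError(f"{path}: calibration block must be a mapping")
        bad = set(cal) - _CALIBRATION_KEYS
        if bad:
            raise FormatError(f"{path}: unknown calibration key(s): {sorted(bad)}")
        method = cal.get("method", "zero")
        if method not in ("zero", "patient_specific", "none"):
            raise FormatError(f"{path}: invalid calibration method {method!r}")
    cfg = dict(_CONFIG_DEFAULTS)
    cfg.update(raw)
    return cfg
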