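"""Data model and I/O for multi-sensor IMU home recordings.

A recording session consists of five body-worn inertial sensors (chest,
both thighs, both shanks), each logging tri-axial accelerometer and
gyroscope data (optionally magnetometer) at a nominal 100 Hz.  Activity
annotations are ordered, non-overlapping labeled intervals on the same
session-relative time base.

File dialects
-------------
IMU log:     CSV with header ``t,ax,ay,az,gx,gy,gz[,mx,my,mz]``;
             ``t`` in seconds, accelerometer in m/s^2, gyroscope in rad/s.
             An HDF5 mirror stores one group per sensor placement.
Annotations: CSV with header ``start,end,label``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

GRAVITY = 9.81  # m/s^2

__all__ = [
    "GRAVITY",
    "Placement",
    "ActivityClass",
    "CLASS_ORDER",
    "ImuSample",
    "ImuTrace",
    "SessionRecording",
    "AnnotationEvent",
    "EventStream",
    "ParseError",
    "EmptyInputError",
    "AlignmentError",
    "ConfigurationError",
    "ValidationError",
    "read_imu_log",
    "write_imu_log",
    "assemble_session",
    "read_annotations",
    "write_annotations",
    "read_session_h5",
    "write_session_h5",
]


class ParseError(ValueError):
    """A malformed row in an input file."""


class EmptyInputError(ValueError):
    """An input file contained no data rows."""


class AlignmentError(ValueError):
    """Traces share no common time interval after clock correction."""


class ConfigurationError(ValueError):
    """The sensor set does not match the required 5-placement array."""


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class Placement(str, enum.Enum):
    """Body location of one IMU in the 5-sensor configuration."""

    CHEST = "chest"
    THIGH_L = "thigh_L"
    THIGH_R = "thigh_R"
    SHANK_L = "shank_L"
    SHANK_R = "shank_R"


class ActivityClass(str, enum.Enum):
    """The ten daily-living activity classes, in canonical order.

    The order is fixed: it is the tie-breaking order used when a
    classifier emits equal posterior probabilities.
    """

    STAND = "stand"
    WALK = "walk"
    STAND_TO_SIT = "stand_to_sit"
    SIT = "sit"
    SIT_TO_STAND = "sit_to_stand"
    TURN = "turn"
    LIE_DOWN = "lie_down"
    BEND = "bend"
    NEAR_FALL = "near_fall"
    FALL = "fall"


CLASS_ORDER: tuple[ActivityClass, ...] = tuple(ActivityClass)

_IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
_MAG_COLUMNS = ["mx", "my", "mz"]


@dataclass(frozen=True)
class ImuSample:
    """One timestamped IMU sample (convenience view; traces store arrays)."""

    t: float
    accel: np.ndarray  # (3,) m/s^2
    gyro: np.ndarray  # (3,) rad/s
    mag: np.ndarray | None = None


@dataclass
class ImuTrace:
    """One sensor's stream: time-sorted accel/gyro (and optional mag) arrays.

    Attributes
    ----------
    placement : Placement
    t : (n,) seconds since session start, strictly increasing
    accel : (n, 3) m/s^2
    gyro : (n, 3) rad/s
    mag : (n, 3) or None, arbitrary units
    nominal_rate : nominal sampling rate in Hz (default 100)
    """

    placement: Placement
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float).reshape(-1, 3)
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")
        n = self.t.size
        if self.accel.shape[0] != n or self.gyro.shape[0] != n:
            raise ValidationError("t, accel and gyro must have equal length")
        if n and not np.all(np.isfinite(self.t)):
            raise ValidationError("timestamps must be finite")
        if n and (np.any(self.t < 0) or np.any(np.diff(self.t) <= 0)):
            raise ValidationError("timestamps must be non-negative and strictly increasing")
        if n and not (np.all(np.isfinite(self.accel)) and np.all(np.isfinite(self.gyro))):
            raise ValidationError("accel/gyro values must be finite")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def samples(self) -> Iterable[ImuSample]:
        for i in range(len(self)):
            yield ImuSample(
                t=float(self.t[i]),
                accel=self.accel[i],
                gyro=self.gyro[i],
                mag=None if self.mag is None else self.mag[i],
            )

    def accel_magnitude(self) -> np.ndarray:
        """Euclidean norm of the specific force at each sample, m/s^2."""
        return np.linalg.norm(self.accel, axis=1)

    def shifted(self, offset: float) -> "ImuTrace":
        """Return a copy with ``offset`` seconds added to every timestamp."""
        return replace(self, t=self.t + offset)


@dataclass
class SessionRecording:
    """Five synchronized traces on a common uniform grid plus metadata."""

    subject_id: str
    day_index: int
    traces: dict[Placement, ImuTrace]
    clock_offsets: dict[Placement, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = {Placement(k): v for k, v in self.traces.items()}
        missing = set(Placement) - set(self.traces)
        if missing:
            raise ConfigurationError(
                f"session requires all 5 placements; missing: {sorted(p.value for p in missing)}"
            )

    @property
    def grid(self) -> np.ndarray:
        return self.traces[Placement.CHEST].t

    @property
    def rate(self) -> float:
        return self.traces[Placement.CHEST].nominal_rate

    @property
    def duration(self) -> float:
        return self.traces[Placement.CHEST].duration


@dataclass(frozen=True)
class AnnotationEvent:
    """One labeled activity interval, ``end > start``, session-relative s."""

    start: float
    end: float
    label: ActivityClass

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", float(self.start))
        object.__setattr__(self, "end", float(self.end))
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValidationError("event bounds must be finite")
        if self.end <= self.start:
            raise ValidationError(f"event end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EventStream:
    """Time-ordered, non-overlapping labeled activity events for one session."""

    events: list[AnnotationEvent]

    def __post_init__(self) -> None:
        evs = sorted(self.events, key=lambda e: e.start)
        for a, b in zip(evs, evs[1:]):
            if b.start < a.end - 1e-9:
                raise ValidationError(
                    f"overlapping events: [{a.start}, {a.end}) {a.label.value} and "
                    f"[{b.start}, {b.end}) {b.label.value}"
                )
        self.events = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def span(self) -> tuple[float, float]:
        if not self.events:
            return (0.0, 0.0)
        return (self.events[0].start, self.events[-1].end)

    def total_time(self) -> float:
        return sum(e.duration for e in self.events)

    def of_class(self, *labels: ActivityClass) -> list[AnnotationEvent]:
        wanted = {ActivityClass(l) for l in labels}
        return [e for e in self.events if e.label in wanted]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [e.start for e in self.events],
                "end": [e.end for e in self.events],
                "label": [e.label.value for e in self.events],
            }
        )


# ---------------------------------------------------------------------------
# CSV I/O


def read_imu_log(path: str | Path, placement: Placement | str) -> ImuTrace:
    """Read one sensor log from CSV.

    Rows are sorted by timestamp; duplicate timestamps keep the first
    occurrence.  A non-numeric cell raises :class:`ParseError` naming the
    offending line (1-based, counting the header as line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no samples")
    missing = [c for c in _IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has_mag = all(c in df.columns for c in _MAG_COLUMNS)
    cols = _IMU_COLUMNS + (_MAG_COLUMNS if has_mag else [])
    num = df[cols].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: non-numeric value on line {row + 2}")
    num = num.sort_values("t", kind="stable").drop_duplicates("t", keep="first")
    arr = num.to_numpy(dtype=float)
    return ImuTrace(
        placement=Placement(placement),
        t=arr[:, 0],
        accel=arr[:, 1:4],
        gyro=arr[:, 4:7],
        mag=arr[:, 7:10] if has_mag else None,
    )


def write_imu_log(trace: ImuTrace, path: str | Path) -> None:
    """Write a trace to CSV; ``read_imu_log`` round-trips within 1e-9."""
    cols = {"t": trace.t}
    for i, c in enumerate(("ax", "ay", "az")):
        cols[c] = trace.accel[:, i] if len(trace) else np.array([])
    for i, c in enumerate(("gx", "gy", "gz")):
        cols[c] = trace.gyro[:, i] if len(trace) else np.array([])
    if trace.mag is not None:
        for i, c in enumerate(_MAG_COLUMNS):
            cols[c] = trace.mag[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_annotations(path: str | Path) -> EventStream:
    """Read an annotation CSV (``start,end,label``) into an event stream.

    Labels must belong to the ten activity classes; unknown labels raise
    :class:`ValidationError` listing the allowed values.  Overlapping
    events are rejected by the :class:`EventStream` invariant.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    allowed = {c.value for c in ActivityClass}
    events = []
    for i, row in df.iterrows():
        label = str(row["label"]).strip()
        if label not in allowed:
            raise ValidationError(
                f"{path} line {i + 2}: unknown label {label!r}; "
                f"allowed: {sorted(allowed)}"
            )
        events.append(
            AnnotationEvent(float(row["start"]), float(row["end"]), ActivityClass(label))
        )
    return EventStream(events)


def write_annotations(stream: EventStream, path: str | Path) -> None:
    stream.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# HDF5 mirror


def write_session_h5(session: SessionRecording, path: str | Path) -> None:
    """Store a session as HDF5: one group per placement, array datasets."""
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = session.subject_id
        f.attrs["day_index"] = session.day_index
        for p, tr in session.traces.items():
            g = f.create_group(p.value)
            g.attrs["nominal_rate"] = tr.nominal_rate
            g.attrs["clock_offset"] = session.clock_offsets.get(p, 0.0)
            g.create_dataset("t", data=tr.t)
            g.create_dataset("accel", data=tr.accel)
            g.create_dataset("gyro", data=tr.gyro)
            if tr.mag is not None:
                g.create_dataset("mag", data=tr.mag)


def read_session_h5(path: str | Path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        traces = {}
        offsets = {}
        for p in Placement:
            g = f[p.value]
            traces[p] = ImuTrace(
                placement=p,
                t=g["t"][...],
                accel=g["accel"][...],
                gyro=g["gyro"][...],
                mag=g["mag"][...] if "mag" in g else None,
                nominal_rate=float(g.attrs["nominal_rate"]),
            )
            offsets[p] = float(g.attrs.get("clock_offset", 0.0))
        return SessionRecording(
            subject_id=str(f.attrs["subject_id"]),
            day_index=int(f.attrs["day_index"]),
            traces=traces,
            clock_offsets=offsets,
        )


# ---------------------------------------------------------------------------
# Session assembly


def assemble_session(
    traces: Mapping[Placement | str, ImuTrace],
    clock_offsets: Mapping[Placement | str, float] | None = None,
    subject_id: str = "unknown",
    day_index: int = 0,
    rate: float | None = None,
) -> SessionRecording:
    """Synchronize five traces onto a common uniform grid.

    Each trace's timestamps are corrected by adding its declared clock
    offset, all traces are restricted to the common overlap interval, and
    every channel is linearly interpolated onto a uniform grid at ``rate``
    (default: the chest trace's nominal rate).  The output time base is
    session-relative: t = 0 at the start of the overlap.
    """
    traces = {Placement(k): v for k, v in traces.items()}
    missing = set(Placement) - set(traces)
    if missing:
        raise ConfigurationError(
            f"missing placements: {sorted(p.value for p in missing)}"
        )
    offsets = {Placement(k): float(v) for k, v in (clock_offsets or {}).items()}
    corrected = {p: tr.shifted(offsets.get(p, 0.0)) for p, tr in traces.items()}

    start = max(tr.t[0] for tr in corrected.values())
    end = min(tr.t[-1] for tr in corrected.values())
    if end - start <= 0:
        raise AlignmentError(
            f"no common overlap after clock correction (start {start:.3f} >= end {end:.3f})"
        )
    if rate is None:
        rate = traces[Placement.CHEST].nominal_rate
    dt = 1.0 / rate
    n = int(np.floor((end - start) / dt)) + 1
    grid = start + dt * np.arange(n)

    out: dict[Placement, ImuTrace] = {}
    for p, tr in corrected.items():
        def interp(block: np.ndarray) -> np.ndarray:
            return np.column_stack(
                [np.interp(grid, tr.t, block[:, j]) for j in range(block.shape[1])]
            )

        out[p] = ImuTrace(
            placement=p,
            t=grid - start,  # session-relative: t=0 at overlap start
            accel=interp(tr.accel),
            gyro=interp(tr.gyro),
            mag=interp(tr.mag) if tr.mag is not None else None,
            nominal_rate=rate,
        )
    return SessionRecording(
        subject_id=subject_id,
        day_index=day_index,
        traces=out,
        clock_offsets=offsets,
    )
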