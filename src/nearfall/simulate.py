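"""Synthetic 5-sensor IMU sessions with ground-truth activity labels.

The simulator emulates the home-recording setup: five IMUs (chest, both
thighs, both shanks) sampled at 100 Hz while a subject performs scripted
daily-living activities, including near-falls and falls.  Body motion is
modeled in the sagittal plane: each segment carries a pitch (tilt)
trajectory, turns superimpose a yaw-rate pulse, and dynamic activities add
a gravity-aligned linear-acceleration envelope.  Sensor output is then

    accel = (g + lin) * (sin(theta), 0, cos(theta)) + noise
    gyro  = (0, dtheta/dt, yaw_rate) + bias + noise

so a static, noise-free posture always reads exactly 9.81 m/s^2 of
specific force, and the pitch gyro integrates back to the tilt trajectory.

The generator is seed-deterministic end to end: scripts draw all of their
stochastic kinematic parameters (cadence, turn direction, ...) at script
time, so a script maps to one and only one kinematic profile.

Simulated near-falls follow the working definition of a balance
perturbation recovered without ground impact: a rapid chest-pitch
excursion (peak rate >= 2 rad/s) returning to baseline within 2 s,
accompanied by a chest specific-force transient >= 5 m/s^2 above gravity.
These thresholds are simulator conventions for generating recognizable
events, not claims about real near-fall kinematics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io_core import (
    GRAVITY,
    ActivityClass,
    AnnotationEvent,
    EventStream,
    ImuTrace,
    Placement,
    SessionRecording,
    ValidationError,
)

__all__ = [
    "ScriptSegment",
    "ActivityScript",
    "NoiseModel",
    "SessionKinematics",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_MEAN_DURATIONS",
    "generate_random_script",
    "script_to_kinematics",
    "kinematics_to_imu",
    "tilt_to_imu",
    "simulate_session",
]

_TRANSFERS = {ActivityClass.STAND_TO_SIT, ActivityClass.SIT_TO_STAND}

# Posture level: 0 = upright, 1 = seated, 2 = lying.
_LEVEL = {
    ActivityClass.STAND: 0,
    ActivityClass.WALK: 0,
    ActivityClass.TURN: 0,
    ActivityClass.BEND: 0,
    ActivityClass.NEAR_FALL: 0,
    ActivityClass.SIT: 1,
    ActivityClass.LIE_DOWN: 2,
    ActivityClass.FALL: 2,  # ends lying
    ActivityClass.STAND_TO_SIT: 0,
    ActivityClass.SIT_TO_STAND: 1,
}

# Base pitch (rad) per posture level, per segment kind.
_BASE_PITCH = {
    "chest": {0: 0.0, 1: 0.0, 2: np.pi / 2},
    "thigh": {0: 0.0, 1: np.pi / 2, 2: np.pi / 2},
    "shank": {0: 0.0, 1: 0.0, 2: np.pi / 2},
}

_SEGMENT_KIND = {
    Placement.CHEST: "chest",
    Placement.THIGH_L: "thigh",
    Placement.THIGH_R: "thigh",
    Placement.SHANK_L: "shank",
    Placement.SHANK_R: "shank",
}

# Class mix (per drawn segment) for the default study conditions.  Rare
# classes are enriched relative to unconstrained daily life, mirroring a
# validation protocol in which subjects deliberately perform detectable
# activities; transfers are inserted by the posture grammar, not drawn.
DEFAULT_CLASS_MIX: dict[ActivityClass, float] = {
    ActivityClass.STAND: 0.19,
    ActivityClass.WALK: 0.24,
    ActivityClass.TURN: 0.16,
    ActivityClass.SIT: 0.12,
    ActivityClass.BEND: 0.09,
    ActivityClass.LIE_DOWN: 0.04,
    ActivityClass.NEAR_FALL: 0.12,
    ActivityClass.FALL: 0.04,
}

DEFAULT_MEAN_DURATIONS: dict[ActivityClass, float] = {
    ActivityClass.STAND: 8.0,
    ActivityClass.WALK: 12.0,
    ActivityClass.TURN: 3.0,
    ActivityClass.SIT: 15.0,
    ActivityClass.BEND: 3.0,
    ActivityClass.LIE_DOWN: 15.0,
    ActivityClass.NEAR_FALL: 2.0,
    ActivityClass.FALL: 3.0,
    ActivityClass.STAND_TO_SIT: 1.5,
    ActivityClass.SIT_TO_STAND: 1.5,
}


@dataclass(frozen=True)
class ScriptSegment:
    activity: ActivityClass
    duration: float
    params: dict = field(default_factory=dict)


@dataclass
class ActivityScript:
    """Ordered activity segments with per-segment kinematic parameters."""

    segments: list[ScriptSegment]

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg.duration <= 0:
                raise ValidationError(f"non-positive duration for {seg.activity.value}")
            if seg.activity in _TRANSFERS and not (0.5 <= seg.duration <= 5.0):
                raise ValidationError(
                    f"transfer {seg.activity.value} duration {seg.duration} outside [0.5, 5] s"
                )

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def to_events(self) -> EventStream:
        events, t = [], 0.0
        for s in self.segments:
            events.append(AnnotationEvent(t, t + s.duration, s.activity))
            t += s.duration
        return EventStream(events)


@dataclass
class NoiseModel:
    """Additive white sensor noise and a constant per-axis gyro bias.

    ``gyro_bias`` may be given explicitly (rad/s, one 3-vector per
    placement); when None, each axis draws a constant bias uniformly from
    ``[-gyro_bias_limit, +gyro_bias_limit]`` at synthesis time.
    """

    accel_noise_sd: float = 0.3  # m/s^2
    gyro_noise_sd: float = 0.02  # rad/s
    gyro_bias_limit: float = 0.05  # rad/s
    gyro_bias: Mapping[Placement, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")


@dataclass
class SessionKinematics:
    """Sampled ground-truth kinematics on a uniform grid."""

    t: np.ndarray
    rate: float
    pitch: dict[Placement, np.ndarray]  # rad
    yaw_rate: dict[Placement, np.ndarray]  # rad/s
    lin_acc: dict[Placement, np.ndarray]  # gravity-aligned, m/s^2
    events: EventStream


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_random_script(
    total_duration: float,
    seed: int,
    class_mix: Mapping[ActivityClass, float] | None = None,
    mean_durations: Mapping[ActivityClass, float] | None = None,
) -> ActivityScript:
    """Draw a random activity script obeying the posture grammar.

    Segments are drawn from ``class_mix``; whenever consecutive segments
    imply a posture change between upright and seated, a
    ``sit_to_stand``/``stand_to_sit`` transfer is inserted (lying is
    entered from sitting and exited through a transfer as well).  The
    script is truncated so its total duration equals ``total_duration``
    up to a minimum final-segment length.
    """
    mix = {ActivityClass(k): float(v) for k, v in (class_mix or DEFAULT_CLASS_MIX).items()}
    means = dict(DEFAULT_MEAN_DURATIONS)
    if mean_durations:
        means.update({ActivityClass(k): float(v) for k, v in mean_durations.items()})
    if any(v < 0 for v in means.values()):
        raise ValidationError("mean durations must be positive")
    if any(v < 0 for v in mix.values()):
        raise ValidationError("class mix probabilities must be >= 0")
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValidationError("class mix probabilities must sum to 1")

    rng = np.random.default_rng(seed)
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])

    def draw_duration(c: ActivityClass) -> float:
        d = means[c] * rng.uniform(0.7, 1.3)
        if c in _TRANSFERS:
            d = float(np.clip(d, 0.5, 5.0))
        return float(d)

    segments: list[ScriptSegment] = []
    level = 0  # start upright
    total = 0.0
    prev: ActivityClass | None = None
    while total < total_duration:
        c = classes[rng.choice(len(classes), p=probs)]
        if len(classes) > 1 and c is prev:
            continue  # avoid degenerate back-to-back repeats
        target = _LEVEL[c]
        # insert transfers along the posture ladder
        while level != target and c is not ActivityClass.FALL:
            if level < target:
                if level == 0:
                    seg = ScriptSegment(ActivityClass.STAND_TO_SIT, draw_duration(ActivityClass.STAND_TO_SIT))
                    segments.append(seg)
                    total += seg.duration
                level += 1  # seated -> lying needs no labeled transfer segment
            else:
                if level == 1:
                    seg = ScriptSegment(ActivityClass.SIT_TO_STAND, draw_duration(ActivityClass.SIT_TO_STAND))
                    segments.append(seg)
                    total += seg.duration
                level -= 1
        params: dict = {}
        if c is ActivityClass.WALK:
            params["cadence"] = float(rng.uniform(0.8, 1.2))
        elif c is ActivityClass.TURN:
            params["yaw_peak"] = float(rng.choice([-1.0, 1.0]) * rng.uniform(1.4, 2.2))
        d = draw_duration(c)
        segments.append(ScriptSegment(c, d, params))
        total += d
        level = _LEVEL[c]
        prev = c

    # trim the tail so total ~= total_duration
    excess = total - total_duration
    if segments and excess > 0:
        last = segments[-1]
        keep = last.duration - excess
        min_keep = 1.5 if last.activity in (ActivityClass.NEAR_FALL, ActivityClass.FALL) else 0.5
        if last.activity in _TRANSFERS:
            min_keep = max(min_keep, 0.5)
        if keep >= min_keep:
            segments[-1] = ScriptSegment(last.activity, keep, last.params)
    return ActivityScript(segments)


def _posture(kind: str, activity: ActivityClass) -> float:
    return _BASE_PITCH[kind][_LEVEL[activity]]


def script_to_kinematics(script: ActivityScript, rate: float = 100.0) -> SessionKinematics:
    """Render a script into per-segment pitch/yaw/linear-acceleration tracks.

    Canonical postures: standing has every segment vertical (pitch 0);
    sitting folds the thighs to pi/2 with shanks vertical; lying puts all
    segments at pi/2.  Walking oscillates thigh and shank pitch at the
    scripted cadence (shank amplitude > thigh amplitude, left/right in
    anti-phase); turns superimpose a yaw-rate pulse over low-amplitude
    stepping; bends take the chest to ~pi/4 and back; near-falls are fast
    chest excursions with full recovery; falls end in a sustained lying
    posture.  Posture baselines are low-pass blended so trajectories stay
    continuous across segment boundaries.
    """
    T = script.total_duration
    dt = 1.0 / rate
    n = int(round(T * rate)) + 1
    t = dt * np.arange(n)

    pitch = {p: np.zeros(n) for p in Placement}
    yaw = {p: np.zeros(n) for p in Placement}
    lin = {p: np.zeros(n) for p in Placement}

    segs = script.segments
    bounds = np.concatenate([[0.0], np.cumsum([s.duration for s in segs])])
    idx = [
        (int(round(bounds[i] * rate)), min(int(round(bounds[i + 1] * rate)) + 1, n))
        for i in range(len(segs))
    ]

    # --- posture baseline (step functions; transfers interpolate) ---------
    for p in Placement:
        kind = _SEGMENT_KIND[p]
        base = np.zeros(n)
        for i, s in enumerate(segs):
            i0, i1 = idx[i]
            if s.activity in _TRANSFERS:
                before = _posture(kind, segs[i - 1].activity) if i > 0 else _BASE_PITCH[kind][0]
                after = _posture(kind, segs[i + 1].activity) if i + 1 < len(segs) else _BASE_PITCH[kind][_LEVEL[s.activity]]
                tau = (t[i0:i1] - bounds[i]) / s.duration
                base[i0:i1] = before + (after - before) * _smoothstep(tau)
            else:
                base[i0:i1] = _posture(kind, s.activity)
        # blend residual steps (e.g. sit -> lie_down, fall onset)
        pitch[p] = gaussian_filter1d(base, sigma=0.2 * rate, mode="nearest")

    # --- per-activity dynamic components ----------------------------------
    def envelope(i0: int, i1: int, ramp: float = 0.3) -> np.ndarray:
        tt = t[i0:i1] - t[i0]
        dur = tt[-1] if len(tt) > 1 else dt
        r = min(ramp, dur / 2)
        return _smoothstep(tt / r) * _smoothstep((dur - tt) / r) if r > 0 else np.ones_like(tt)

    for i, s in enumerate(segs):
        i0, i1 = idx[i]
        tt = t[i0:i1] - bounds[i]
        if i1 - i0 < 2:
            continue
        env = envelope(i0, i1)
        if s.activity is ActivityClass.WALK:
            f = s.params.get("cadence", 1.0)
            w = 2 * np.pi * f
            for side, sign in ((Placement.THIGH_L, 1.0), (Placement.THIGH_R, -1.0)):
                pitch[side][i0:i1] += sign * 0.30 * np.sin(w * tt) * env
            for side, sign in ((Placement.SHANK_L, 1.0), (Placement.SHANK_R, -1.0)):
                pitch[side][i0:i1] += sign * 0.55 * np.sin(w * tt - 0.4) * env
            pitch[Placement.CHEST][i0:i1] += 0.03 * np.sin(2 * w * tt) * env
            lin[Placement.CHEST][i0:i1] += 0.9 * np.sin(2 * w * tt) * env
            for side, ph in ((Placement.SHANK_L, 0.0), (Placement.SHANK_R, np.pi),
                             (Placement.THIGH_L, 0.0), (Placement.THIGH_R, np.pi)):
                lin[side][i0:i1] += 1.3 * np.sin(2 * w * tt + ph) * env
        elif s.activity is ActivityClass.TURN:
            peak = s.params.get("yaw_peak", 1.8)
            # ramp-plateau-ramp: yaw rate is sustained through the turn
            bump = envelope(i0, i1, ramp=0.5)
            for p in Placement:
                yaw[p][i0:i1] += peak * bump
            ws = 2 * np.pi * 1.6  # low-amplitude stepping while turning
            for side, sign in ((Placement.THIGH_L, 1.0), (Placement.THIGH_R, -1.0)):
                pitch[side][i0:i1] += sign * 0.08 * np.sin(ws * tt) * env
            for side, sign in ((Placement.SHANK_L, 1.0), (Placement.SHANK_R, -1.0)):
                pitch[side][i0:i1] += sign * 0.12 * np.sin(ws * tt - 0.4) * env
            lin[Placement.CHEST][i0:i1] += 0.5 * np.sin(ws * tt) * env
        elif s.activity is ActivityClass.BEND:
            half = np.sin(np.pi * tt / s.duration) ** 2
            pitch[Placement.CHEST][i0:i1] += (np.pi / 4) * half
            for side in (Placement.THIGH_L, Placement.THIGH_R):
                pitch[side][i0:i1] += -0.08 * half
        elif s.activity is ActivityClass.NEAR_FALL:
            # rapid excursion + recovery, then a spike in specific force
            te = min(0.7, max(0.4, 0.35 * s.duration))
            t_on = 0.1
            tau = np.clip((tt - t_on) / te, 0.0, 1.0)
            exc = 0.5 * np.sin(np.pi * tau) ** 2  # peak rate 0.5*pi/te >= 2.2 rad/s
            pitch[Placement.CHEST][i0:i1] += exc
            for side in (Placement.THIGH_L, Placement.THIGH_R):
                pitch[side][i0:i1] += 0.3 * exc
            for side in (Placement.SHANK_L, Placement.SHANK_R):
                pitch[side][i0:i1] += 0.15 * exc
            ts = t_on + te / 2  # impact-arrest transient at the excursion peak
            taus = np.clip((tt - (ts - 0.175)) / 0.35, 0.0, 1.0)
            lin[Placement.CHEST][i0:i1] += 7.0 * np.sin(np.pi * taus) ** 2
        elif s.activity is ActivityClass.FALL:
            taus = np.clip((tt - 0.45) / 0.25, 0.0, 1.0)
            lin[Placement.CHEST][i0:i1] += 9.0 * np.sin(np.pi * taus) ** 2
            for side in (Placement.THIGH_L, Placement.THIGH_R, Placement.SHANK_L, Placement.SHANK_R):
                lin[side][i0:i1] += 4.0 * np.sin(np.pi * taus) ** 2

    for p in Placement:
        np.clip(pitch[p], -np.pi, np.pi, out=pitch[p])

    return SessionKinematics(t=t, rate=rate, pitch=pitch, yaw_rate=yaw, lin_acc=lin,
                             events=script.to_events())


def tilt_to_imu(
    theta: np.ndarray,
    rate: float,
    placement: Placement = Placement.CHEST,
    yaw_rate: np.ndarray | None = None,
    lin_acc: np.ndarray | None = None,
    accel_noise_sd: float = 0.0,
    gyro_noise_sd: float = 0.0,
    gyro_bias: Sequence[float] = (0.0, 0.0, 0.0),
    rng: np.random.Generator | None = None,
) -> ImuTrace:
    """Synthesize one sensor trace from a sampled tilt trajectory.

    ``lin_acc`` is a gravity-aligned linear-acceleration envelope: the
    specific-force magnitude equals ``g + lin_acc`` exactly before noise.
    The pitch gyro channel is the discrete time-derivative of ``theta``
    plus bias and noise.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.size
    dt = 1.0 / rate
    t = dt * np.arange(n)
    mag = GRAVITY + (np.zeros(n) if lin_acc is None else np.asarray(lin_acc, dtype=float))
    accel = np.column_stack([mag * np.sin(theta), np.zeros(n), mag * np.cos(theta)])
    omega = np.gradient(theta, dt)
    gyro = np.column_stack([
        np.zeros(n),
        omega,
        np.zeros(n) if yaw_rate is None else np.asarray(yaw_rate, dtype=float),
    ])
    gyro += np.asarray(gyro_bias, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    if accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, accel_noise_sd, accel.shape)
    if gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sd, gyro.shape)
    return ImuTrace(placement=placement, t=t, accel=accel, gyro=gyro, nominal_rate=rate)


def kinematics_to_imu(
    kin: SessionKinematics,
    noise: NoiseModel | None = None,
    subject_id: str = "sim",
    day_index: int = 0,
) -> tuple[SessionRecording, EventStream]:
    """Turn ground-truth kinematics into a noisy 5-sensor session.

    All stochastic draws (noise and, when not given explicitly, the
    constant per-axis gyro bias) flow from ``noise.seed``, so output is
    bitwise-reproducible for a fixed seed.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed)
    traces = {}
    for p in Placement:  # fixed iteration order keeps draws reproducible
        if noise.gyro_bias is not None:
            bias = np.asarray(noise.gyro_bias[p], dtype=float)
        else:
            bias = rng.uniform(-noise.gyro_bias_limit, noise.gyro_bias_limit, 3)
        traces[p] = tilt_to_imu(
            kin.pitch[p],
            kin.rate,
            placement=p,
            yaw_rate=kin.yaw_rate[p],
            lin_acc=kin.lin_acc[p],
            accel_noise_sd=noise.accel_noise_sd,
            gyro_noise_sd=noise.gyro_noise_sd,
            gyro_bias=bias,
            rng=rng,
        )
    session = SessionRecording(
        subject_id=subject_id, day_index=day_index, traces=traces,
        clock_offsets={p: 0.0 for p in Placement},
    )
    return session, kin.events


def simulate_session(
    total_duration: float,
    seed: int,
    class_mix: Mapping[ActivityClass, float] | None = None,
    mean_durations: Mapping[ActivityClass, float] | None = None,
    noise: NoiseModel | None = None,
    rate: float = 100.0,
    subject_id: str = "sim",
) -> tuple[SessionRecording, EventStream, ActivityScript]:
    """One-call simulation: script -> kinematics -> noisy 5-sensor session."""
    rng = np.random.default_rng(seed)
    script_seed, noise_seed = (int(x) for x in rng.integers(0, 2**31 - 1, 2))
    script = generate_random_script(total_duration, script_seed, class_mix, mean_durations)
    kin = script_to_kinematics(script, rate)
    if noise is None:
        noise = NoiseModel(seed=noise_seed)
    session, events = kinematics_to_imu(kin, noise, subject_id=subject_id)
    return session, events, script
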