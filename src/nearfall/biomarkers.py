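"""Per-subject behavioral biomarkers from labeled home-monitoring streams.

From a subject's labeled event stream and chest IMU trace, the module
computes the home-monitoring feature set used for fall-risk modeling:
near-fall count and weekly frequency, number of ambulatory bouts,
activity time fractions (sitting, walking, lying down), the mean daily
peak chest perturbation, and the power-law exponent of the
ambulatory-bout duration distribution above 8 s (``alpha_8``).  Clinical
covariates (MDS-UPDRS pull-test score, total pull-test failures) and the
fall-diary outcome (falls per week) join these in one feature table.

Missing inputs yield NaN markers, never silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    GRAVITY,
    ActivityClass,
    EventStream,
    ImuTrace,
    ValidationError,
)

__all__ = [
    "AmbulatoryBout",
    "SubjectData",
    "FEATURE_COLUMNS",
    "ambulatory_bouts",
    "alpha_exponent",
    "activity_frequencies",
    "peak_chest_acceleration",
    "near_fall_metrics",
    "compile_feature_table",
]

_LOCOMOTION = (ActivityClass.WALK, ActivityClass.TURN)

FEATURE_COLUMNS = [
    "Nfall_Count_h",
    "Nfall_Freq_h",
    "Tot_Num_Abs",
    "Sit_Freq_h",
    "walk_freq_h",
    "lie_down_freq_h",
    "peak_acc_h",
    "alpha_8",
    "updrs",
    "tot_failures",
    "fall_freq",
]


@dataclass(frozen=True)
class AmbulatoryBout:
    """A maximal contiguous locomotion interval (walking and turning)."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("bout end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


def ambulatory_bouts(events: EventStream, merge_gap: float = 2.0) -> list[AmbulatoryBout]:
    """Merge walk/turn events separated by gaps <= ``merge_gap`` into bouts."""
    loco = events.of_class(*_LOCOMOTION)
    bouts: list[AmbulatoryBout] = []
    for ev in loco:
        if bouts and ev.start - bouts[-1].end <= merge_gap:
            bouts[-1] = AmbulatoryBout(bouts[-1].start, ev.end)
        else:
            bouts.append(AmbulatoryBout(ev.start, ev.end))
    return bouts


def alpha_exponent(durations: Sequence[float], d_min: float = 8.0) -> float:
    """Continuous maximum-likelihood power-law exponent over ``d > d_min``.

    For the n durations strictly above ``d_min``::

        alpha = 1 + n / sum_i ln(d_i / d_min)

    (the Hill-type estimator for a continuous power law with lower cutoff
    ``d_min``).  Returns NaN when fewer than 10 qualifying durations
    exist — too few bouts to characterize a tail.
    """
    d = np.asarray(list(durations), dtype=float)
    d = d[d > d_min]
    if d.size < 10:
        return float("nan")
    return float(1.0 + d.size / np.sum(np.log(d / d_min)))


def activity_frequencies(events: EventStream, total_time: float) -> dict[ActivityClass, float]:
    """Per-class fraction of total time; fractions sum to <= 1."""
    if total_time <= 0:
        raise ValidationError("total_time must be positive")
    out = {c: 0.0 for c in ActivityClass}
    for ev in events:
        out[ev.label] += ev.duration / total_time
    return out


def peak_chest_acceleration(
    chest: ImuTrace | None,
    day_bounds: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Mean over days of the daily peak chest perturbation, m/s^2.

    The perturbation at a sample is ``| ||accel|| - g |``, i.e. the
    deviation of the specific-force magnitude from gravity, so a
    motionless trace scores 0.  ``day_bounds`` splits the trace into
    recording days; by default the whole trace is one day.  Returns NaN
    when no day contains samples.
    """
    if chest is None or len(chest) == 0:
        return float("nan")
    dev = np.abs(chest.accel_magnitude() - GRAVITY)
    if day_bounds is None:
        day_bounds = [(float(chest.t[0]), float(chest.t[-1]))]
    maxima = []
    for lo, hi in day_bounds:
        mask = (chest.t >= lo) & (chest.t <= hi)
        if np.any(mask):
            maxima.append(float(dev[mask].max()))
    return float(np.mean(maxima)) if maxima else float("nan")


def near_fall_metrics(events: EventStream, observation_weeks: float) -> tuple[int, float]:
    """Near-fall count and per-week frequency over the observation period."""
    if observation_weeks <= 0:
        raise ValidationError("observation_weeks must be positive")
    count = len(events.of_class(ActivityClass.NEAR_FALL))
    return count, count / observation_weeks


@dataclass
class SubjectData:
    """One subject's raw inputs for the feature table.

    Any missing component (None) propagates NaN into the derived
    features rather than a silent zero.
    """

    subject_id: str
    events: EventStream | None = None
    chest: ImuTrace | None = None
    day_bounds: Sequence[tuple[float, float]] | None = None
    observation_weeks: float = 1.0
    monitored_time: float | None = None  # seconds of labeled home time
    updrs_pull: float | None = None  # MDS-UPDRS pull test, 0-4
    tot_failures: float | None = None  # pull-test failures in clinic
    diary_falls: float | None = None  # prospective fall count
    diary_weeks: float | None = None  # diary follow-up length


def compile_feature_table(
    subjects: Sequence[SubjectData],
    merge_gap: float = 2.0,
    alpha_d_min: float = 8.0,
) -> pd.DataFrame:
    """Build the per-subject feature table (one row per subject).

    Columns follow the home-monitoring naming convention (``*_h`` marks
    features measured at home).  The outcome ``fall_freq`` is
    diary falls / diary weeks.  Duplicate subject ids are rejected.
    """
    ids = [s.subject_id for s in subjects]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"duplicate subject ids: {sorted(dupes)}")
    nan = float("nan")
    rows = []
    for s in subjects:
        row = dict.fromkeys(FEATURE_COLUMNS, nan)
        if s.events is not None:
            count, freq = near_fall_metrics(s.events, s.observation_weeks)
            row["Nfall_Count_h"] = count
            row["Nfall_Freq_h"] = freq
            bouts = ambulatory_bouts(s.events, merge_gap)
            row["Tot_Num_Abs"] = len(bouts)
            row["alpha_8"] = alpha_exponent([b.duration for b in bouts], alpha_d_min)
            total = s.monitored_time if s.monitored_time is not None else s.events.total_time()
            if total and total > 0:
                fr = activity_frequencies(s.events, total)
                row["Sit_Freq_h"] = fr[ActivityClass.SIT]
                row["walk_freq_h"] = fr[ActivityClass.WALK]
                row["lie_down_freq_h"] = fr[ActivityClass.LIE_DOWN]
        row["peak_acc_h"] = peak_chest_acceleration(s.chest, s.day_bounds)
        if s.updrs_pull is not None:
            row["updrs"] = float(s.updrs_pull)
        if s.tot_failures is not None:
            row["tot_failures"] = float(s.tot_failures)
        if s.diary_falls is not None and s.diary_weeks:
            row["fall_freq"] = float(s.diary_falls) / float(s.diary_weeks)
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
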