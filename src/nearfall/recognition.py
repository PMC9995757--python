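"""Activity recognition: windowing, classifiers, and event segmentation.

The recognition pipeline slides fixed-length windows over the estimated
tilt streams, classifies every window into one of the ten activity
classes, and merges the per-window labels back into a labeled event
stream.  Window channels are the five estimated segment tilts plus two
chest channels (specific-force magnitude and yaw rate) that expose
near-fall transients and turning, which are invisible in sagittal tilt
alone.

Four classifier kinds are supported: the sequence model (``lstm``:
temporal convolutions -> LSTM -> softmax, trained on the raw window
sequences) and three conventional baselines (``log``, ``svm``, ``dt``)
fitted on per-channel summary features (mean, sd, min, max, dominant
frequency), since none of them is a sequence model.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .io_core import (
    ActivityClass,
    AnnotationEvent,
    CLASS_ORDER,
    EventStream,
    Placement,
    SessionRecording,
    ValidationError,
)
from .nn import ConvLSTMNet
from .tilt import TiltSeries

__all__ = [
    "CHANNEL_NAMES",
    "WindowSet",
    "ActivityClassifier",
    "DataInsufficiencyError",
    "window_session",
    "train_classifier",
    "predict",
    "smooth_and_segment",
    "save_model",
    "load_model",
]

_MODEL_FORMAT_VERSION = 1

CHANNEL_NAMES: tuple[str, ...] = (
    "tilt_chest",
    "tilt_thigh_L",
    "tilt_thigh_R",
    "tilt_shank_L",
    "tilt_shank_R",
    "chest_accel_mag",
    "chest_yaw_rate",
)

_TILT_ORDER = (
    Placement.CHEST,
    Placement.THIGH_L,
    Placement.THIGH_R,
    Placement.SHANK_L,
    Placement.SHANK_R,
)


class DataInsufficiencyError(ValueError):
    """A class has too few training windows to fit a classifier."""


@dataclass
class WindowSet:
    """Fixed-length windows of multichannel time series.

    ``x`` has shape ``(n_windows, n_steps, n_channels)``; ``t_start``
    gives each window's start on the session clock.  ``labels`` (when
    annotations were supplied) holds one :class:`ActivityClass` per
    window, assigned by majority time-overlap.
    """

    x: np.ndarray
    t_start: np.ndarray
    window_len: float
    stride: float
    rate: float
    labels: np.ndarray | None = None  # dtype=object of ActivityClass
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __len__(self) -> int:
        return len(self.x)


def window_session(
    session: SessionRecording,
    tilt: Mapping[Placement, TiltSeries],
    annotations: EventStream | None = None,
    window_len: float = 2.0,
    stride: float = 0.5,
) -> WindowSet:
    """Slide windows over the tilt/IMU channels of one session.

    The number of windows is ``floor((T - window_len)/stride) + 1`` for a
    session of duration ``T``.  When annotations are given, each window
    gets the class covering the largest fraction of it (ties broken by
    canonical class order).  A session shorter than one window yields an
    empty set rather than an error.
    """
    if not (window_len >= stride > 0):
        raise ValidationError("require window_len >= stride > 0")
    rate = session.rate
    grid = session.grid
    n = grid.size
    chest = session.traces[Placement.CHEST]
    channels = np.column_stack(
        [tilt[p].theta for p in _TILT_ORDER]
        + [chest.accel_magnitude(), chest.gyro[:, 2]]
    )

    wl = int(round(window_len * rate)) + 1  # inclusive endpoints
    st = int(round(stride * rate))
    if n < wl:
        return WindowSet(
            x=np.empty((0, wl, channels.shape[1])), t_start=np.empty(0),
            window_len=window_len, stride=stride, rate=rate,
            labels=np.empty(0, dtype=object) if annotations is not None else None,
        )
    n_win = (n - wl) // st + 1
    starts = st * np.arange(n_win)
    x = np.stack([channels[s:s + wl] for s in starts])
    t_start = grid[starts]

    labels = None
    if annotations is not None:
        labels = np.empty(n_win, dtype=object)
        for i, t0 in enumerate(t_start):
            t1 = t0 + window_len
            cover = {c: 0.0 for c in CLASS_ORDER}
            for ev in annotations:
                ov = min(t1, ev.end) - max(t0, ev.start)
                if ov > 0:
                    cover[ev.label] += ov
            # max() over canonical order: first class wins ties
            labels[i] = max(CLASS_ORDER, key=lambda c: cover[c])
    return WindowSet(x=x, t_start=t_start, window_len=window_len, stride=stride,
                     rate=rate, labels=labels)


def _summary_features(x: np.ndarray, rate: float) -> np.ndarray:
    """Flatten windows to per-channel (mean, sd, min, max, dominant freq)."""
    mean = x.mean(axis=1)
    sd = x.std(axis=1)
    mn = x.min(axis=1)
    mx = x.max(axis=1)
    centered = x - mean[:, None, :]
    spec = np.abs(np.fft.rfft(centered, axis=1))
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / rate)
    dom = freqs[np.argmax(spec[:, 1:, :], axis=1) + 1]  # skip DC
    return np.concatenate([mean, sd, mn, mx, dom], axis=1)


@dataclass
class ActivityClassifier:
    """A fitted window classifier of one of the four supported kinds."""

    kind: str  # lstm | log | svm | dt
    classes: list[ActivityClass]
    window_shape: tuple[int, int]
    rate: float
    net: ConvLSTMNet | None = None
    scaler: StandardScaler | None = None
    sk_model: object | None = None
    hyper: dict = field(default_factory=dict)

    def predict_proba(self, windows: WindowSet) -> np.ndarray:
        if len(windows) == 0:
            return np.empty((0, len(self.classes)))
        if windows.x.shape[1:] != self.window_shape:
            raise ValidationError(
                f"window shape {windows.x.shape[1:]} does not match "
                f"training shape {self.window_shape}"
            )
        if self.kind == "lstm":
            return self.net.predict_proba(windows.x)
        feats = self.scaler.transform(_summary_features(windows.x, windows.rate))
        return self.sk_model.predict_proba(feats)

    def predict(
        self, windows: WindowSet, temporal_smooth: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (probabilities, argmax labels); ties go to the earlier class.

        ``temporal_smooth`` (odd width, 0 = off) applies a centered moving
        average over the probability sequence before the argmax.  It is
        meaningful only for stride-contiguous windows, where the activity
        stream is temporally coherent: isolated boundary-window flips are
        damped while multi-window events (a near-fall spans several
        overlapping windows) survive.
        """
        proba = self.predict_proba(windows)
        if temporal_smooth > 1 and len(proba) > temporal_smooth:
            h = temporal_smooth // 2
            kern = np.ones(2 * h + 1)
            norm = np.convolve(np.ones(len(proba)), kern, mode="same")
            proba = np.column_stack([
                np.convolve(proba[:, j], kern, mode="same") / norm
                for j in range(proba.shape[1])
            ])
        labels = np.array([self.classes[i] for i in np.argmax(proba, axis=1)], dtype=object)
        return proba, labels


def train_classifier(
    train: WindowSet,
    kind: str = "lstm",
    hyper: Mapping | None = None,
    seed: int = 0,
) -> ActivityClassifier:
    """Fit a window classifier; training is deterministic for a fixed seed.

    Requires at least two classes and at least 5 windows per present
    class.  Class imbalance is handled with inverse-frequency class
    weights.  ``hyper`` overrides kind-specific defaults (e.g. ``epochs``,
    ``hidden``, ``lr`` for the sequence model; sklearn keyword arguments
    for the baselines).
    """
    kind = kind.lower()
    if kind not in {"lstm", "log", "svm", "dt"}:
        raise ValidationError(f"unknown classifier kind {kind!r}")
    if train.labels is None:
        raise ValidationError("training windows must be labeled")
    hyper = dict(hyper or {})

    lab_vals = np.array([ActivityClass(l).value for l in train.labels])
    present = [c for c in CLASS_ORDER if np.any(lab_vals == c.value)]
    if len(present) < 2:
        raise DataInsufficiencyError("need at least 2 classes in the training set")
    counts = {c: int(np.sum(lab_vals == c.value)) for c in present}
    thin = [c.value for c in present if counts[c] < 5]
    if thin:
        raise DataInsufficiencyError(
            f"classes with fewer than 5 training windows: {thin}"
        )

    class_index = {c.value: i for i, c in enumerate(present)}
    y = np.array([class_index[v] for v in lab_vals])
    n = len(y)
    # sqrt-damped inverse-frequency weights: rare classes (near-falls) are
    # up-weighted without making boundary windows of common classes flip
    inv_freq = np.sqrt(n / (len(present) * np.array([counts[c] for c in present], dtype=float)))

    clf = ActivityClassifier(
        kind=kind, classes=present, window_shape=train.x.shape[1:],
        rate=train.rate, hyper=hyper,
    )
    if kind == "lstm":
        net = ConvLSTMNet(
            n_channels=train.x.shape[2],
            n_classes=len(present),
            conv_filters=tuple(hyper.get("conv_filters", (16, 32))),
            kernel=int(hyper.get("kernel", 5)),
            pool=int(hyper.get("pool", 4)),
            hidden=int(hyper.get("hidden", 64)),
            lr=float(hyper.get("lr", 3e-3)),
            seed=seed,
        )
        net.fit(
            train.x, y, class_weights=inv_freq,
            epochs=int(hyper.get("epochs", 80)),
            batch_size=int(hyper.get("batch_size", 128)),
            patience=int(hyper.get("patience", 15)),
            verbose=bool(hyper.get("verbose", False)),
        )
        clf.net = net
        return clf

    feats = _summary_features(train.x, train.rate)
    scaler = StandardScaler().fit(feats)
    feats = scaler.transform(feats)
    weight_map = {i: w for i, w in enumerate(inv_freq)}
    if kind == "log":
        model = LogisticRegression(
            max_iter=int(hyper.get("max_iter", 2000)),
            C=float(hyper.get("C", 1.0)),
            class_weight=weight_map,
        )
    elif kind == "svm":
        svc = SVC(
            C=float(hyper.get("C", 1.0)),
            kernel=hyper.get("svm_kernel", "rbf"),
            class_weight=weight_map,
            random_state=seed,
        )
        # sigmoid-calibrated decision values stand in for probabilities
        model = CalibratedClassifierCV(svc, ensemble=False)
    else:  # dt
        model = DecisionTreeClassifier(
            max_depth=hyper.get("max_depth"),
            class_weight=weight_map,
            random_state=seed,
        )
    model.fit(feats, y)
    clf.scaler = scaler
    clf.sk_model = model
    return clf


def predict(
    model: ActivityClassifier, windows: WindowSet, temporal_smooth: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window class probabilities and argmax labels (module-level alias)."""
    return model.predict(windows, temporal_smooth=temporal_smooth)


def label_session(
    model: ActivityClassifier,
    session: SessionRecording,
    tilt_series: Mapping[Placement, "TiltSeries"],
    temporal_smooth: int = 3,
    min_event_len: float = 0.0,
) -> tuple[WindowSet, np.ndarray, EventStream]:
    """Full labeling pipeline for one session.

    Windows the session with the model's training geometry, predicts with
    temporal probability smoothing (default width 3), and merges the
    labels into an event stream.  Returns (windows, per-window labels,
    events).
    """
    window_len = (model.window_shape[0] - 1) / model.rate
    windows = window_session(session, tilt_series, None, window_len, 0.5)
    _, labels = model.predict(windows, temporal_smooth=temporal_smooth)
    events = smooth_and_segment(
        labels, windows.stride, min_event_len,
        t0=float(windows.t_start[0]) if len(windows) else 0.0,
    )
    return windows, labels, events


def smooth_and_segment(
    labels: Sequence[ActivityClass],
    stride: float,
    min_event_len: float = 0.0,
    t0: float = 0.0,
) -> EventStream:
    """Merge per-window labels into a labeled event stream.

    A width-3 majority (median) filter removes isolated single-window
    flips, runs of equal labels become events spanning one stride per
    window, and events shorter than ``min_event_len`` are absorbed into
    the longer neighbor.  ``near_fall`` and ``fall`` windows are exempt
    from both the filter and the minimum-length rule: a genuine
    single-window near-fall must survive smoothing.
    """
    labels = [ActivityClass(l) for l in labels]
    n = len(labels)
    if n == 0:
        return EventStream([])
    protected = {ActivityClass.NEAR_FALL, ActivityClass.FALL}

    smoothed = list(labels)
    for i in range(1, n - 1):
        if labels[i] in protected:
            continue
        trio = [labels[i - 1], labels[i], labels[i + 1]]
        for cand in (labels[i - 1], labels[i + 1]):
            if cand not in protected and trio.count(cand) >= 2:
                smoothed[i] = cand
                break

    # merge runs into events: each window contributes one stride of time
    runs: list[tuple[ActivityClass, int]] = []
    for lab in smoothed:
        if runs and runs[-1][0] is lab:
            runs[-1] = (lab, runs[-1][1] + 1)
        else:
            runs.append((lab, 1))

    if min_event_len > 0:
        changed = True
        while changed and len(runs) > 1:
            changed = False
            for i, (lab, cnt) in enumerate(runs):
                if lab in protected or cnt * stride >= min_event_len:
                    continue
                neigh = []
                if i > 0:
                    neigh.append(i - 1)
                if i + 1 < len(runs):
                    neigh.append(i + 1)
                j = max(neigh, key=lambda k: runs[k][1])
                runs[j] = (runs[j][0], runs[j][1] + cnt)
                del runs[i]
                # re-merge adjacent equal labels
                merged: list[tuple[ActivityClass, int]] = []
                for lab2, cnt2 in runs:
                    if merged and merged[-1][0] is lab2:
                        merged[-1] = (lab2, merged[-1][1] + cnt2)
                    else:
                        merged.append((lab2, cnt2))
                runs = merged
                changed = True
                break

    events = []
    t = t0
    for lab, cnt in runs:
        events.append(AnnotationEvent(t, t + cnt * stride, lab))
        t += cnt * stride
    return EventStream(events)


def save_model(model: ActivityClassifier, path: str | Path) -> None:
    """Serialize a fitted classifier to a single versioned file."""
    payload = {"format_version": _MODEL_FORMAT_VERSION, "model": model}
    with open(path, "wb") as f:
        pickle.dump(payload, f)


def load_model(path: str | Path) -> ActivityClassifier:
    with open(path, "rb") as f:
        payload = pickle.load(f)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    return payload["model"]
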