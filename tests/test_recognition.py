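"""Windowing, classifier contracts, and event segmentation."""

import numpy as np
import pytest

from nearfall import recognition
from nearfall.io_core import (
    ActivityClass,
    AnnotationEvent,
    EventStream,
    ValidationError,
)
from nearfall.recognition import (
    ActivityClassifier,
    DataInsufficiencyError,
    WindowSet,
    smooth_and_segment,
    train_classifier,
    window_session,
)
from nearfall.simulate import ActivityScript, ScriptSegment, simulate_session
from nearfall import simulate, tilt


def _session_with_events(segments, seed=0, noise=None):
    script = ActivityScript([ScriptSegment(*s) for s in segments])
    kin = simulate.script_to_kinematics(script)
    session, events = simulate.kinematics_to_imu(
        kin, noise or simulate.NoiseModel(seed=seed)
    )
    series = tilt.estimate_session_tilt(session)
    return session, events, series


def _toy_windows(n_per_class=10, n_steps=20, n_channels=2, shift=2.0, seed=0,
                 classes=(ActivityClass.STAND, ActivityClass.WALK)):
    rng = np.random.default_rng(seed)
    xs, labs = [], []
    for i, c in enumerate(classes):
        x = rng.normal(i * shift, 0.1, (n_per_class, n_steps, n_channels))
        xs.append(x)
        labs += [c] * n_per_class
    return WindowSet(
        x=np.vstack(xs), t_start=np.arange(len(labs)) * 0.5, window_len=2.0,
        stride=0.5, rate=10.0, labels=np.array(labs, dtype=object),
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
    )


class TestWindowing:
    def test_window_count(self):
        session, events, series = _session_with_events([(ActivityClass.STAND, 10.0)])
        ws = window_session(session, series, events, window_len=2.0, stride=1.0)
        assert len(ws) == 9  # floor((10-2)/1) + 1

    def test_majority_label_inside_segment(self):
        session, events, series = _session_with_events(
            [(ActivityClass.STAND, 6.0), (ActivityClass.WALK, 6.0)]
        )
        ws = window_session(session, series, events, window_len=2.0, stride=0.5)
        first = ws.labels[0]
        assert first is ActivityClass.STAND

    def test_majority_rule_on_straddling_window(self):
        # window [5.2, 7.2] over stand ending at 6.4: 60% stand / 40% walk
        stream = EventStream([
            AnnotationEvent(0.0, 6.4, ActivityClass.STAND),
            AnnotationEvent(6.4, 12.0, ActivityClass.WALK),
        ])
        session, _, series = _session_with_events(
            [(ActivityClass.STAND, 6.4), (ActivityClass.WALK, 5.6)]
        )
        ws = window_session(session, series, stream, window_len=2.0, stride=0.4)
        i = int(np.where(np.isclose(ws.t_start, 5.2))[0][0])
        assert ws.labels[i] is ActivityClass.STAND

    def test_short_session_yields_empty_set(self):
        session, events, series = _session_with_events([(ActivityClass.STAND, 1.0)])
        ws = window_session(session, series, events, window_len=2.0, stride=0.5)
        assert len(ws) == 0

    def test_invalid_geometry_rejected(self):
        session, events, series = _session_with_events([(ActivityClass.STAND, 5.0)])
        with pytest.raises(ValidationError):
            window_session(session, series, events, window_len=0.5, stride=1.0)


class TestTraining:
    def test_separable_log_reaches_perfect_training_accuracy(self):
        ws = _toy_windows()
        model = train_classifier(ws, kind="log", seed=0)
        _, labels = model.predict(ws)
        assert np.mean([a is b for a, b in zip(labels, ws.labels)]) == 1.0

    @pytest.mark.parametrize("kind", ["log", "svm", "dt"])
    def test_baselines_fit_and_probabilities_normalize(self, kind):
        ws = _toy_windows()
        model = train_classifier(ws, kind=kind, seed=0)
        proba = model.predict_proba(ws)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_lstm_training_deterministic(self):
        ws = _toy_windows(n_per_class=8)
        hyper = {"epochs": 3, "conv_filters": (4,), "hidden": 6, "pool": 2}
        m1 = train_classifier(ws, kind="lstm", hyper=hyper, seed=5)
        m2 = train_classifier(ws, kind="lstm", hyper=hyper, seed=5)
        for k in m1.net.params:
            np.testing.assert_array_equal(m1.net.params[k], m2.net.params[k])

    def test_insufficient_class_raises_with_name(self):
        ws = _toy_windows(n_per_class=10)
        ws.labels[:3] = ActivityClass.NEAR_FALL
        ws.labels[3:10] = ActivityClass.STAND
        with pytest.raises(DataInsufficiencyError, match="near_fall"):
            train_classifier(ws, kind="dt", seed=0)

    def test_single_class_rejected(self):
        ws = _toy_windows(classes=(ActivityClass.STAND,))
        with pytest.raises(DataInsufficiencyError):
            train_classifier(ws, kind="log", seed=0)


class TestPredict:
    def _stub_model(self, proba_rows, classes):
        class StubNet:
            def predict_proba(self, x, batch_size=256):
                return np.asarray(proba_rows)[: len(x)]

        return ActivityClassifier(
            kind="lstm", classes=list(classes), window_shape=(20, 2), rate=10.0,
            net=StubNet(),
        )

    def test_argmax_picks_higher_probability(self):
        m = self._stub_model([[0.3, 0.7]], [ActivityClass.WALK, ActivityClass.SIT])
        ws = _toy_windows(n_per_class=1, classes=(ActivityClass.STAND,))
        _, labels = m.predict(ws)
        assert labels[0] is ActivityClass.SIT

    def test_exact_tie_goes_to_earlier_class(self):
        # classes stored in canonical order: stand before walk
        m = self._stub_model([[0.5, 0.5]], [ActivityClass.STAND, ActivityClass.WALK])
        ws = _toy_windows(n_per_class=1, classes=(ActivityClass.STAND,))
        _, labels = m.predict(ws)
        assert labels[0] is ActivityClass.STAND

    def test_empty_window_set_gives_empty_output(self):
        m = self._stub_model(np.empty((0, 2)), [ActivityClass.STAND, ActivityClass.WALK])
        ws = WindowSet(x=np.empty((0, 20, 2)), t_start=np.empty(0), window_len=2.0,
                       stride=0.5, rate=10.0)
        proba, labels = m.predict(ws)
        assert proba.shape[0] == 0 and labels.size == 0

    def test_shape_mismatch_rejected(self):
        ws = _toy_windows()
        model = train_classifier(ws, kind="dt", seed=0)
        bad = WindowSet(x=np.zeros((3, 11, 2)), t_start=np.zeros(3), window_len=1.0,
                        stride=0.5, rate=10.0)
        with pytest.raises(ValidationError, match="shape"):
            model.predict(bad)


class TestSmoothAndSegment:
    def test_isolated_flip_removed(self):
        ev = smooth_and_segment(
            [ActivityClass.WALK, ActivityClass.STAND, ActivityClass.WALK], stride=1.0
        )
        assert len(ev) == 1
        assert ev.events[0].label is ActivityClass.WALK

    def test_run_merging_span(self):
        ev = smooth_and_segment([ActivityClass.WALK] * 20, stride=1.0)
        assert len(ev) == 1
        assert ev.events[0].duration == pytest.approx(20.0)

    def test_single_near_fall_window_preserved(self):
        labels = [ActivityClass.WALK] * 5 + [ActivityClass.NEAR_FALL] + [ActivityClass.WALK] * 5
        ev = smooth_and_segment(labels, stride=0.5, min_event_len=2.0)
        assert len(ev.of_class(ActivityClass.NEAR_FALL)) == 1

    def test_short_events_absorbed_into_longer_neighbor(self):
        labels = [ActivityClass.WALK] * 10 + [ActivityClass.SIT] + [ActivityClass.STAND] * 3
        ev = smooth_and_segment(labels, stride=1.0, min_event_len=2.0)
        assert [e.label for e in ev] == [ActivityClass.WALK, ActivityClass.STAND]

    def test_events_partition_span(self):
        rng = np.random.default_rng(0)
        labels = [list(ActivityClass)[i] for i in rng.integers(0, 10, 50)]
        ev = smooth_and_segment(labels, stride=0.5)
        assert ev.span == (0.0, pytest.approx(25.0))
        bounds_ok = all(
            a.end == pytest.approx(b.start) for a, b in zip(ev.events, ev.events[1:])
        )
        assert bounds_ok


def test_sequence_model_auc_dominates_decision_tree():
    """One-vs-rest near-fall AUC: the sequence model beats the decision
    tree in a majority of 5 seeds (statistical tendency, near-fall
    enriched sessions).  The linear baselines are not ranked: on clean
    synthetic kinematics their summary features are far more informative
    than on real recordings, so only the sequence-vs-tree ordering is a
    transferable property."""
    enriched = {
        ActivityClass.STAND: 0.16, ActivityClass.WALK: 0.18,
        ActivityClass.TURN: 0.12, ActivityClass.SIT: 0.08,
        ActivityClass.BEND: 0.10, ActivityClass.LIE_DOWN: 0.04,
        ActivityClass.NEAR_FALL: 0.26, ActivityClass.FALL: 0.06,
    }

    def windows(dur, seed):
        sess, ev, _ = simulate_session(dur, seed=seed, class_mix=enriched)
        series = tilt.estimate_session_tilt(sess)
        return recognition.window_session(sess, series, ev)

    from nearfall.evaluation import roc_curve_auc

    wins = 0
    n_nf_total = 0
    for s in range(5):
        tr = windows(1000.0, seed=300 + s)
        te = windows(1600.0, seed=400 + s)
        truth = np.array([1 if l is ActivityClass.NEAR_FALL else 0 for l in te.labels])
        n_nf_total += int(truth.sum())
        aucs = {}
        for kind in ("lstm", "dt"):
            hyper = {"epochs": 12, "patience": 12} if kind == "lstm" else {}
            m = train_classifier(tr, kind=kind, hyper=hyper, seed=s)
            proba = m.predict_proba(te)
            idx = m.classes.index(ActivityClass.NEAR_FALL)
            _, _, aucs[kind] = roc_curve_auc(proba[:, idx], truth)
        wins += aucs["lstm"] >= aucs["dt"]
    assert n_nf_total / 5 >= 100  # ample near-fall support per seed
    assert wins >= 3


def test_model_serialization_round_trip(tmp_path):
    ws = _toy_windows()
    model = train_classifier(ws, kind="dt", seed=0)
    p = tmp_path / "model.bin"
    recognition.save_model(model, p)
    back = recognition.load_model(p)
    _, l1 = model.predict(ws)
    _, l2 = back.predict(ws)
    assert all(a is b for a, b in zip(l1, l2))
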