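import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsikit.feature_extraction import FeatureVector, Pose
from drowsikit.window_labeling import (
    Dataset,
    LabelingConfig,
    WindowSample,
    centered_windows,
    label_frame,
    session_maxima,
    threshold_sweep,
    window_size_sweep,
)


def fv(ear=0.32, mar=0.1):
    return FeatureVector(ear=ear, mar=mar, nose_x=320.0, nose_y=216.0)


def eye_stream(closed_frames: int, total: int = 60, start: int = 20):
    """An open-eye stream with one closure of the given length."""
    feats, labels = [], []
    for i in range(total):
        closed = start <= i < start + closed_frames
        feats.append(fv(ear=0.05 if closed else 0.32))
        labels.append(label_frame(feats[-1], Pose.NEUTRAL))
    return feats, labels


def brute_force_window_labels(labels, window_len):
    """Oracle: direct enumeration of every window and modality."""
    out = []
    for start in range(len(labels) - window_len + 1):
        win = labels[start : start + window_len]
        drowsy = (
            all(l.eye_closed for l in win)
            or all(l.mouth_open for l in win)
            or all(l.head_drowsy for l in win)
        )
        out.append(int(drowsy))
    return out


class TestLabelFrame:
    @pytest.mark.parametrize(
        "ear,mar,pose,eye,mouth,head",
        [
            (0.35, 0.1, Pose.NEUTRAL, False, False, False),
            (0.19, 0.1, Pose.NEUTRAL, True, False, False),
            (0.2, 0.1, Pose.NEUTRAL, False, False, False),  # EAR cut is strict
            (0.35, 0.5, Pose.NEUTRAL, False, True, False),  # MAR cut is inclusive
            (0.35, 0.49, Pose.NEUTRAL, False, False, False),
            (0.35, 0.1, Pose.DOWN, False, False, True),
        ],
    )
    def test_threshold_semantics(self, ear, mar, pose, eye, mouth, head):
        lab = label_frame(fv(ear, mar), pose)
        assert (lab.eye_closed, lab.mouth_open, lab.head_drowsy) == (eye, mouth, head)
        assert lab.drowsy == (eye or mouth or head)

    @given(
        ear=st.floats(0.0, 0.6),
        t1=st.floats(0.05, 0.5),
        t2=st.floats(0.05, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotone(self, ear, t1, t2):
        """Raising the EAR threshold never un-closes an eye."""
        lo, hi = sorted([t1, t2])
        cfg_lo = LabelingConfig(ear_threshold=lo)
        cfg_hi = LabelingConfig(ear_threshold=hi)
        if label_frame(fv(ear=ear), Pose.NEUTRAL, cfg_lo).eye_closed:
            assert label_frame(fv(ear=ear), Pose.NEUTRAL, cfg_hi).eye_closed


class TestCenteredWindows:
    def test_short_stream_yields_nothing(self):
        feats, labels = eye_stream(0, total=14)
        with pytest.warns(UserWarning, match="shorter"):
            assert centered_windows(feats, labels) == []

    @pytest.mark.parametrize("closed,expected", [(15, 1), (9, 0), (21, 7), (0, 0)])
    def test_event_length_window_count_identity(self, closed, expected):
        """An L-frame closure yields max(0, L - W + 1) drowsy windows."""
        feats, labels = eye_stream(closed)
        wins = centered_windows(feats, labels)
        assert sum(w.label for w in wins) == expected

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        feats, labels = [], []
        for _ in range(120):
            f = fv(
                ear=rng.choice([0.05, 0.32]),
                mar=rng.choice([0.1, 0.7]),
            )
            feats.append(f)
            labels.append(label_frame(f, Pose.NEUTRAL))
        wins = centered_windows(feats, labels)
        assert [w.label for w in wins] == brute_force_window_labels(labels, 15)

    def test_window_shape_and_centering(self):
        feats, labels = eye_stream(0, total=31)
        wins = centered_windows(feats, labels)
        assert len(wins) == 31 - 15 + 1
        assert wins[0].center_index == 7
        assert wins[0].features.shape == (4, 15)

    def test_label_recomputable_from_own_columns(self):
        """No hidden state: a window's label follows from its 15 frames."""
        feats, labels = eye_stream(18)
        wins = centered_windows(feats, labels)
        cfg = LabelingConfig()
        for w in wins:
            ears = w.features[0]
            expected = int(all(e < cfg.ear_threshold for e in ears))
            assert w.label == expected


class TestSweeps:
    def test_single_long_closure_counts(self):
        feats, labels = eye_stream(21)
        table = window_size_sweep(feats, labels, [9, 13, 15, 17, 21])
        assert table.tolist() == [13, 9, 7, 5, 1]

    def test_all_alert_stream_counts_zero(self):
        feats, labels = eye_stream(0)
        table = window_size_sweep(feats, labels, [9, 13, 15, 17, 21])
        assert (table == 0).all()

    def test_even_size_rejected(self):
        feats, labels = eye_stream(0)
        with pytest.raises(ValueError):
            window_size_sweep(feats, labels, [10])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_counts_non_increasing_in_window_size(self, seed):
        rng = np.random.default_rng(seed)
        feats, labels = [], []
        for _ in range(100):
            f = fv(ear=float(rng.choice([0.05, 0.32])))
            feats.append(f)
            labels.append(label_frame(f, Pose.NEUTRAL))
        table = window_size_sweep(feats, labels, [9, 13, 15, 17, 21])
        vals = table.tolist()
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_ear_sweep_saturates_above_all_values(self):
        feats, _ = eye_stream(10)
        table = threshold_sweep(feats, [0.001, 0.2, 0.9], "ear")
        assert table[0.9] == len(feats)  # every frame reads closed
        assert table[0.001] == 0
        assert table.is_monotonic_increasing

    def test_mar_sweep_saturates_above_all_values(self):
        feats = [fv(mar=0.3) for _ in range(20)] + [fv(mar=0.7) for _ in range(5)]
        table = threshold_sweep(feats, [0.1, 0.5, 0.95], "mar")
        assert table[0.95] == 0  # threshold above every MAR: all closed-mouth
        assert table[0.1] == 25
        assert table[0.5] == 5

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([fv()], [], "ear")


class TestSessionMaxima:
    def test_constant_stream(self):
        feats = [fv(ear=0.31, mar=0.22)] * 10
        assert session_maxima(feats) == (0.31, 0.22)

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        feats = [fv(ear=float(e), mar=float(m))
                 for e, m in zip(rng.uniform(0, 0.4, 30), rng.uniform(0, 1, 30))]
        shuffled = list(feats)
        rng.shuffle(shuffled)
        assert session_maxima(feats) == session_maxima(shuffled)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            session_maxima([])


class TestDataset:
    def test_class_counts_track_samples(self):
        wins = [
            WindowSample(7, np.zeros((4, 15)), 0),
            WindowSample(8, np.zeros((4, 15)), 1),
            WindowSample(9, np.zeros((4, 15)), 1),
        ]
        assert Dataset(wins).class_counts == {0: 1, 1: 2}

    def test_flatten_block_order(self):
        feats = np.arange(60).reshape(4, 15)
        flat = WindowSample(7, feats, 0).flatten()
        assert flat[:15].tolist() == list(range(15))  # EAR block first
        assert flat[45:].tolist() == list(range(45, 60))  # Y block last

    def test_csv_round_trip_columns(self, tmp_path):
        import pandas as pd

        ds = Dataset([WindowSample(7, np.random.default_rng(0).uniform(size=(4, 15)), 1)])
        path = tmp_path / "ds.csv"
        ds.to_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns[:15]) == [f"ear_{i}" for i in range(15)]
        assert df.loc[0, "label"] == 1


def test_config_window_consistency():
    with pytest.raises(Exception):
        LabelingConfig(window_len=15, half_span=6)
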