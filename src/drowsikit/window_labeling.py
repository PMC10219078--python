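"""Temporal windowing and the two-step drowsy labeling scheme.

Per-frame states are thresholded first: the eyes count as closed when
EAR < 0.2, the mouth as wide open when MAR >= 0.5, and the head as drowsy
when its pose class is anything but neutral. A frame is drowsy when any of
the three states holds.

A training sample is then a window of 15 consecutive frames centred on
frame N (7 neighbours on each side), stored as a 4x15 matrix with rows
EAR, MAR, nose_x, nose_y. The window's binary label applies a persistence
rule: it is drowsy (1) exactly when at least one modality holds on *every*
frame of the window. This is what separates a genuine drowsiness event —
an eye closure of >= 500 ms spans >= 15 frames at 30 fps, so at least one
window is fully covered — from an ordinary 100-400 ms blink, which cannot
fill a 15-frame window and therefore never produces a drowsy label. A
single uninterrupted event of L frames yields exactly max(0, L - W + 1)
drowsy windows at window length W, so shrinking the window inflates the
drowsy count (short blinks start to qualify) and growing it misses real
events: the calibration sweeps below expose exactly that trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import SchemaError
from .feature_extraction import FeatureVector, HeadPose, Pose

__all__ = [
    "LabelingConfig",
    "FrameStateLabel",
    "WindowSample",
    "Dataset",
    "label_frame",
    "label_frames",
    "centered_windows",
    "window_size_sweep",
    "threshold_sweep",
    "session_maxima",
    "FEATURE_ROW_NAMES",
]

FEATURE_ROW_NAMES = ("ear", "mar", "nose_x", "nose_y")
MODALITIES = ("eye_closed", "mouth_open", "head_drowsy")


@dataclass(frozen=True)
class LabelingConfig:
    """Thresholds and window geometry for the labeling stage.

    Defaults follow the calibrated operating point: a 15-frame window
    (7 frames on each side of the centre), EAR threshold 0.2 (strict <),
    MAR threshold 0.5 (inclusive >=, a minimum), pose threshold 7 degrees,
    at 30 frames/s.
    """

    window_len: int = 15
    half_span: int = 7
    ear_threshold: float = 0.2
    mar_threshold: float = 0.5
    pose_threshold: float = 7.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.window_len != 2 * self.half_span + 1:
            raise SchemaError(
                f"window_len ({self.window_len}) must equal 2*half_span+1 "
                f"({2 * self.half_span + 1})"
            )
        for name in ("ear_threshold", "mar_threshold", "pose_threshold", "fps"):
            if not getattr(self, name) > 0:
                raise SchemaError(f"{name} must be positive")


@dataclass(frozen=True)
class FrameStateLabel:
    """Per-frame modality states and the combined drowsy flag."""

    eye_closed: bool
    mouth_open: bool
    head_drowsy: bool

    @property
    def drowsy(self) -> bool:
        return self.eye_closed or self.mouth_open or self.head_drowsy


@dataclass(frozen=True, eq=False)
class WindowSample:
    """One training sample: a 4 x window_len feature matrix and its label."""

    center_index: int
    features: np.ndarray  # rows: ear, mar, nose_x, nose_y
    label: int  # 0 alert, 1 drowsy

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 2 or feats.shape[0] != 4:
            raise SchemaError(f"features must be 4 x W, got shape {feats.shape}")
        object.__setattr__(self, "features", feats)
        if self.label not in (0, 1):
            raise SchemaError(f"label must be 0 or 1, got {self.label}")

    def flatten(self) -> np.ndarray:
        """Row-major 60-vector: EAR block, MAR block, X block, Y block."""
        return self.features.ravel()


@dataclass
class Dataset:
    """A bag of window samples with per-class bookkeeping."""

    samples: list[WindowSample] = field(default_factory=list)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.samples)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) with X of shape (n, 4*window_len)."""
        if not self.samples:
            return np.empty((0, 0)), np.empty((0,), dtype=int)
        X = np.stack([s.flatten() for s in self.samples])
        y = np.array([s.label for s in self.samples], dtype=int)
        return X, y

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: ear_0..ear_W-1, mar_*, x_*, y_*, center_index, label."""
        if not self.samples:
            return pd.DataFrame()
        w = self.samples[0].features.shape[1]
        cols = (
            [f"ear_{i}" for i in range(w)]
            + [f"mar_{i}" for i in range(w)]
            + [f"x_{i}" for i in range(w)]
            + [f"y_{i}" for i in range(w)]
        )
        X, y = self.to_arrays()
        df = pd.DataFrame(X, columns=cols)
        df["center_index"] = [s.center_index for s in self.samples]
        df["label"] = y
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def label_frame(
    fv: FeatureVector, pose: HeadPose | Pose, cfg: LabelingConfig = LabelingConfig()
) -> FrameStateLabel:
    """Threshold one frame's features into modality states.

    Eye closure is strict (EAR < threshold: an EAR sitting exactly on 0.2
    still counts as open); the MAR threshold is a minimum (MAR >= threshold
    counts as open mouth); any non-neutral pose counts as a drowsy head.
    """
    pose_class = pose.pose if isinstance(pose, HeadPose) else pose
    return FrameStateLabel(
        eye_closed=fv.ear < cfg.ear_threshold,
        mouth_open=fv.mar >= cfg.mar_threshold,
        head_drowsy=pose_class is not Pose.NEUTRAL,
    )


def label_frames(
    features: Sequence[FeatureVector],
    poses: Sequence[HeadPose | Pose],
    cfg: LabelingConfig = LabelingConfig(),
) -> list[FrameStateLabel]:
    """Vectorised convenience: label every frame of an aligned stream."""
    if len(features) != len(poses):
        raise SchemaError("features and poses must be aligned")
    return [label_frame(fv, p, cfg) for fv, p in zip(features, poses)]


def _state_matrix(labels: Sequence[FrameStateLabel]) -> np.ndarray:
    """(3, n) boolean matrix of per-frame modality states."""
    return np.array(
        [
            [lab.eye_closed for lab in labels],
            [lab.mouth_open for lab in labels],
            [lab.head_drowsy for lab in labels],
        ],
        dtype=bool,
    )


def _window_labels(states: np.ndarray, window_len: int) -> np.ndarray:
    """Label each fully-contained window: 1 iff some modality holds on all
    window frames. Uses a sliding all-true test per modality."""
    n = states.shape[1]
    n_windows = n - window_len + 1
    if n_windows <= 0:
        return np.empty((0,), dtype=int)
    out = np.zeros(n_windows, dtype=int)
    for m in range(states.shape[0]):
        run = np.lib.stride_tricks.sliding_window_view(states[m], window_len)
        out |= run.all(axis=1).astype(int)
    return out


def centered_windows(
    features: Sequence[FeatureVector],
    labels: Sequence[FrameStateLabel],
    cfg: LabelingConfig = LabelingConfig(),
) -> list[WindowSample]:
    """Cut a labeled feature stream into centred window samples.

    One sample is produced for every frame N with a full complement of
    ``half_span`` neighbours on each side; edge frames are skipped rather
    than padded. The window label is 1 exactly when one modality persists
    across all ``window_len`` frames.
    """
    if len(features) != len(labels):
        raise SchemaError("features and labels must be aligned")
    n = len(features)
    if n < cfg.window_len:
        warnings.warn(
            f"stream of {n} frames is shorter than the {cfg.window_len}-frame window",
            stacklevel=2,
        )
        return []
    feat = np.array(
        [[fv.ear, fv.mar, fv.nose_x, fv.nose_y] for fv in features], dtype=float
    ).T  # (4, n)
    win_labels = _window_labels(_state_matrix(labels), cfg.window_len)
    samples = []
    for start, lab in enumerate(win_labels):
        center = start + cfg.half_span
        samples.append(
            WindowSample(
                center_index=center,
                features=feat[:, start : start + cfg.window_len],
                label=int(lab),
            )
        )
    return samples


def window_size_sweep(
    features: Sequence[FeatureVector],
    labels: Sequence[FrameStateLabel],
    sizes: Sequence[int] = (9, 13, 15, 17, 21),
    cfg: LabelingConfig = LabelingConfig(),
) -> pd.Series:
    """Count drowsy-labeled windows at each candidate window size.

    Counts are non-increasing in the window size for a fixed stream: longer
    windows demand longer persistence.
    """
    for size in sizes:
        if size % 2 == 0 or size < 3:
            raise ValueError(f"window sizes must be odd and >= 3, got {size}")
    states = _state_matrix(labels)
    counts = {int(size): int(_window_labels(states, size).sum()) for size in sizes}
    return pd.Series(counts, name="drowsy_windows").rename_axis("window_size")


def threshold_sweep(
    features: Sequence[FeatureVector],
    candidate_thresholds: Sequence[float],
    which: str,
    cfg: LabelingConfig = LabelingConfig(),
) -> pd.Series:
    """Count positively-labeled frames at each candidate threshold.

    ``which='ear'`` counts closed-eye frames (EAR < t, non-decreasing in t);
    ``which='mar'`` counts open-mouth frames (MAR >= t, non-increasing in t).
    """
    if len(candidate_thresholds) == 0:
        raise ValueError("candidate threshold list is empty")
    if any(t <= 0 for t in candidate_thresholds):
        raise ValueError("thresholds must be positive")
    if which == "ear":
        vals = np.array([fv.ear for fv in features])
        counts = {float(t): int((vals < t).sum()) for t in candidate_thresholds}
        name = "eye_closed_frames"
    elif which == "mar":
        vals = np.array([fv.mar for fv in features])
        counts = {float(t): int((vals >= t).sum()) for t in candidate_thresholds}
        name = "mouth_open_frames"
    else:
        raise ValueError(f"which must be 'ear' or 'mar', got {which!r}")
    return pd.Series(counts, name=name).rename_axis("threshold")


def session_maxima(features: Sequence[FeatureVector]) -> tuple[float, float]:
    """Per-session (MAX EAR, MAX MAR) — the calibration quantities used to
    place the thresholds relative to a subject's geometry."""
    if len(features) == 0:
        raise ValueError("cannot take maxima of an empty stream")
    return (
        max(fv.ear for fv in features),
        max(fv.mar for fv in features),
    )
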