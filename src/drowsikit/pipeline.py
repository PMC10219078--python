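"""End-to-end orchestration: corpus -> windows -> classifier -> report.

Glue between the synthetic generator (or landmark files on disk) and the
labeling/classification stages. The training workflow mirrors the original
study's order: assemble windows, balance the classes, then split 70/30 and
fit. Balancing before splitting can leak resampled near-duplicates into the
test set; ``split_first=True`` swaps the order for a leakage-free protocol.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classification import (
    BalanceConfig,
    EvalReport,
    ModelSpec,
    SplitConfig,
    TrainedModel,
    balance,
    evaluate,
    split,
    train,
)
from .feature_extraction import (
    DEFAULT_DEPTH_SCALE,
    FeatureVector,
    HeadPose,
    extract_feature_stream,
)
from .landmark_model import DLIB_68_MAP, LandmarkFrame, LandmarkIndexMap
from .synthetic import SyntheticSession
from .window_labeling import (
    Dataset,
    FrameStateLabel,
    LabelingConfig,
    centered_windows,
    label_frames,
)

logger = logging.getLogger("drowsikit")

__all__ = [
    "stream_features",
    "pipeline_frame_labels",
    "frame_label_agreement",
    "sessions_to_dataset",
    "stream_to_dataset",
    "train_and_evaluate",
    "write_truth_csv",
    "read_truth_csv",
]


def stream_features(
    frames: Sequence[LandmarkFrame],
    index_map: LandmarkIndexMap = DLIB_68_MAP,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> tuple[list[FeatureVector], list[HeadPose]]:
    """Extract aligned per-frame features and head poses from a stream."""
    feats: list[FeatureVector] = []
    poses: list[HeadPose] = []
    for fv, pose in extract_feature_stream(frames, index_map, depth_scale=depth_scale):
        feats.append(fv)
        poses.append(pose)
    return feats, poses


def pipeline_frame_labels(
    frames: Sequence[LandmarkFrame],
    cfg: LabelingConfig = LabelingConfig(),
    index_map: LandmarkIndexMap = DLIB_68_MAP,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> list[FrameStateLabel]:
    """Per-frame modality states as the pipeline itself computes them
    (landmarks -> ratios/pose -> thresholds)."""
    feats, poses = stream_features(frames, index_map, depth_scale)
    return label_frames(feats, poses, cfg)


def frame_label_agreement(
    session: SyntheticSession,
    cfg: LabelingConfig = LabelingConfig(),
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> float:
    """Fraction of frames where pipeline-derived states equal ground truth.

    Exactly 1.0 on zero-jitter sessions: the landmark geometry inverts the
    ratio definitions, so the pipeline recovers the target trajectories and
    the same thresholds reproduce the truth.
    """
    derived = pipeline_frame_labels(session.frames, cfg, depth_scale=depth_scale)
    agree = sum(d == t for d, t in zip(derived, session.truth))
    return agree / len(session.truth)


def sessions_to_dataset(
    sessions: Sequence[SyntheticSession],
    cfg: LabelingConfig = LabelingConfig(),
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> Dataset:
    """Cut labeled windows from synthetic sessions.

    Features are the observed (jittered) landmark-derived quadruples; window
    labels apply the persistence rule to each session's ground-truth frame
    states. Windows never cross session boundaries.
    """
    samples = []
    for session in sessions:
        feats, _ = stream_features(session.frames, depth_scale=depth_scale)
        samples.extend(centered_windows(feats, session.truth, cfg))
    return Dataset(samples)


def stream_to_dataset(
    frames: Sequence[LandmarkFrame],
    cfg: LabelingConfig = LabelingConfig(),
    truth: Sequence[FrameStateLabel] | None = None,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> Dataset:
    """Cut labeled windows from one landmark stream.

    Frame states come from the pipeline's own thresholds unless an explicit
    ``truth`` sequence is supplied.
    """
    feats, poses = stream_features(frames, depth_scale=depth_scale)
    labels = list(truth) if truth is not None else label_frames(feats, poses, cfg)
    return Dataset(centered_windows(feats, labels, cfg))


@dataclass
class TrainResult:
    model: TrainedModel
    report: EvalReport
    train_set: Dataset
    test_set: Dataset


def train_and_evaluate(
    dataset: Dataset,
    model_spec: ModelSpec = ModelSpec("rf"),
    balance_cfg: BalanceConfig = BalanceConfig(),
    split_cfg: SplitConfig = SplitConfig(),
    seed: int = 0,
    split_first: bool = False,
) -> TrainResult:
    """Balance, split, fit and score one classifier on a window dataset."""
    logger.info("dataset: %d samples, class counts %s", len(dataset), dataset.class_counts)
    if split_first:
        train_set, test_set = split(dataset, split_cfg)
        train_set = balance(train_set, balance_cfg)
    else:
        balanced = balance(dataset, balance_cfg)
        logger.info("balanced: class counts %s", balanced.class_counts)
        train_set, test_set = split(balanced, split_cfg)
    logger.info("split: %d train / %d test", len(train_set), len(test_set))
    model = train(model_spec, train_set, seed=seed)
    report = evaluate(model, test_set)
    logger.info(
        "%s: accuracy %.4f sensitivity %.4f specificity %.4f",
        model_spec.kind,
        report.accuracy,
        report.sensitivity,
        report.specificity,
    )
    return TrainResult(model=model, report=report, train_set=train_set, test_set=test_set)


_TRUTH_HEADER = ["frame_index", "eye_closed", "mouth_open", "head_drowsy", "drowsy"]


def write_truth_csv(truth: Sequence[FrameStateLabel], path: str | Path) -> None:
    """Serialise per-frame ground-truth states."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TRUTH_HEADER)
        for i, lab in enumerate(truth):
            writer.writerow(
                [i, int(lab.eye_closed), int(lab.mouth_open), int(lab.head_drowsy), int(lab.drowsy)]
            )


def read_truth_csv(path: str | Path) -> list[FrameStateLabel]:
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            FrameStateLabel(
                eye_closed=bool(int(row["eye_closed"])),
                mouth_open=bool(int(row["mouth_open"])),
                head_drowsy=bool(int(row["head_drowsy"])),
            )
            for row in reader
        ]
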