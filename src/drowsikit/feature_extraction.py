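"""Per-frame drowsiness features: EAR, MAR, and head-pose angles.

The eye aspect ratio (EAR) over six eye landmarks p1..p6 (corner p1,
clockwise) is

    EAR = (|p2 - p6| + |p3 - p5|) / (2 |p1 - p4|)

with Euclidean norms: the summed vertical lid distances over twice the
horizontal corner distance. It stays roughly constant while the eye is open
and drops to zero as the lids touch. The mouth aspect ratio (MAR) over the
eight inner-lip landmarks is the analogous

    MAR = (|p2 - p8| + |p3 - p7| + |p4 - p6|) / (2 |p1 - p5|)

and rises as the mouth opens wide (yawning).

Head pose is estimated from the displacement of the mesh nose landmark
relative to its position on the first frame of the session. The paperless
part of the model — how a pixel displacement becomes a rotation angle — is
a fixed-distance arctangent: the head is treated as pivoting about a point
``depth_ref`` pixels behind the image plane, so

    angle_y (yaw)   = atan2(x - x0, depth_ref)
    angle_x (pitch) = atan2(y0 - y, depth_ref)

in degrees, where (x0, y0) is the session-initial nose position in pixels.
Image y grows downward, so the sign flip in pitch makes upward head motion
positive. A pose is classified as up/down/left/right when the corresponding
angle strictly exceeds ±7 degrees; otherwise it is neutral.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import DegenerateGeometryError, SchemaError
from .landmark_model import DLIB_68_MAP, LandmarkFrame, LandmarkIndexMap

POSE_ANGLE_THRESHOLD_DEG = 7.0
DEFAULT_DEPTH_SCALE = 0.5

__all__ = [
    "Pose",
    "HeadPose",
    "PoseReference",
    "FeatureVector",
    "compute_ear",
    "compute_mar",
    "make_pose_reference",
    "estimate_head_pose",
    "classify_pose",
    "extract_features",
    "extract_feature_stream",
    "write_feature_csv",
]


class Pose(str, enum.Enum):
    """Coarse head-pose class relative to the session-initial reference."""

    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class HeadPose:
    """Pitch/yaw rotation angles in degrees plus the discrete pose class."""

    angle_x: float  # pitch; positive = head up
    angle_y: float  # yaw; positive = head right
    pose: Pose


@dataclass(frozen=True)
class PoseReference:
    """Session-initial nose position (pixels/depth) and projection distance."""

    nose0: tuple[float, float, float]
    depth_ref: float

    def __post_init__(self) -> None:
        if not self.depth_ref > 0:
            raise SchemaError(f"depth_ref must be positive, got {self.depth_ref}")


@dataclass(frozen=True)
class FeatureVector:
    """The per-frame quadruple fed to the classifiers.

    ``ear`` and ``mar`` are unitless ratios; ``nose_x``/``nose_y`` are the
    de-normalised nose pixel coordinates.
    """

    ear: float
    mar: float
    nose_x: float
    nose_y: float

    def __post_init__(self) -> None:
        for name in ("ear", "mar", "nose_x", "nose_y"):
            if not math.isfinite(getattr(self, name)):
                raise SchemaError(f"{name} must be finite")


def compute_ear(eye: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Eye aspect ratio of one eye from its six landmarks p1..p6.

    Raises
    ------
    DegenerateGeometryError
        If the horizontal corner pair coincides (zero denominator).
    """
    pts = np.asarray(eye, dtype=float)
    if pts.shape != (6, 2):
        raise SchemaError(f"expected 6 eye points, got shape {pts.shape}")
    p1, p2, p3, p4, p5, p6 = pts
    horiz = np.linalg.norm(p1 - p4)
    if horiz == 0.0:
        raise DegenerateGeometryError("eye corners coincide; EAR undefined")
    return float((np.linalg.norm(p2 - p6) + np.linalg.norm(p3 - p5)) / (2.0 * horiz))


def compute_mar(mouth: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Mouth aspect ratio from the eight inner-lip landmarks p1..p8."""
    pts = np.asarray(mouth, dtype=float)
    if pts.shape != (8, 2):
        raise SchemaError(f"expected 8 mouth points, got shape {pts.shape}")
    p1, p2, p3, p4, p5, p6, p7, p8 = pts
    horiz = np.linalg.norm(p1 - p5)
    if horiz == 0.0:
        raise DegenerateGeometryError("mouth corners coincide; MAR undefined")
    vert = (
        np.linalg.norm(p2 - p8) + np.linalg.norm(p3 - p7) + np.linalg.norm(p4 - p6)
    )
    return float(vert / (2.0 * horiz))


def make_pose_reference(
    first_frame: LandmarkFrame, depth_scale: float = DEFAULT_DEPTH_SCALE
) -> PoseReference:
    """Build the head-pose reference from the first frame of a session.

    The nose landmark's normalised x/y are converted to pixels by the frame
    size; the projection distance is ``depth_scale * frame_width`` pixels.
    """
    xn, yn, z = first_frame.nose_point
    return PoseReference(
        nose0=(xn * first_frame.frame_width, yn * first_frame.frame_height, z),
        depth_ref=depth_scale * first_frame.frame_width,
    )


def classify_pose(
    angle_x: float, angle_y: float, threshold: float = POSE_ANGLE_THRESHOLD_DEG
) -> Pose:
    """Map (pitch, yaw) to a discrete pose class.

    Comparisons are strict (an angle of exactly ±threshold is neutral). When
    both axes exceed the threshold the axis with the larger magnitude wins;
    on an exact tie the pitch (X-axis) pose is reported.
    """
    x_hit = abs(angle_x) > threshold
    y_hit = abs(angle_y) > threshold
    if x_hit and (not y_hit or abs(angle_x) >= abs(angle_y)):
        return Pose.UP if angle_x > 0 else Pose.DOWN
    if y_hit:
        return Pose.RIGHT if angle_y > 0 else Pose.LEFT
    return Pose.NEUTRAL


def estimate_head_pose(
    frame: LandmarkFrame,
    ref: PoseReference,
    threshold: float = POSE_ANGLE_THRESHOLD_DEG,
) -> HeadPose:
    """Rotation angles of the head relative to the session-initial nose."""
    xn, yn, _ = frame.nose_point
    x = xn * frame.frame_width
    y = yn * frame.frame_height
    x0, y0, _ = ref.nose0
    angle_y = math.degrees(math.atan2(x - x0, ref.depth_ref))
    angle_x = math.degrees(math.atan2(y0 - y, ref.depth_ref))
    return HeadPose(angle_x, angle_y, classify_pose(angle_x, angle_y, threshold))


def extract_features(
    frame: LandmarkFrame,
    index_map: LandmarkIndexMap = DLIB_68_MAP,
    ref: PoseReference | None = None,
) -> FeatureVector:
    """Compute the (EAR, MAR, nose_x, nose_y) quadruple of one frame.

    EAR is the mean of the left-eye and right-eye ratios. The pose reference
    is unused here (angles are a separate, derived feature) but accepted for
    interface symmetry with :func:`extract_feature_stream`.
    """
    left, right = index_map.eye_points(frame)
    ear = 0.5 * (compute_ear(left) + compute_ear(right))
    mar = compute_mar(index_map.mouth_points(frame))
    xn, yn, _ = frame.nose_point
    return FeatureVector(
        ear=ear,
        mar=mar,
        nose_x=xn * frame.frame_width,
        nose_y=yn * frame.frame_height,
    )


def extract_feature_stream(
    frames: Iterable[LandmarkFrame | None],
    index_map: LandmarkIndexMap = DLIB_68_MAP,
    ref: PoseReference | None = None,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
    max_carry_forward: int = 5,
) -> Iterator[tuple[FeatureVector, HeadPose]]:
    """Yield (features, head pose) per frame of a stream.

    The pose reference is taken from the first frame when ``ref`` is None.
    ``None`` entries (a detector that lost the face) carry the previous
    frame's features and pose forward, up to ``max_carry_forward``
    consecutive frames, after which the stream errors out.
    """
    carried = 0
    last: tuple[FeatureVector, HeadPose] | None = None
    for frame in frames:
        if frame is None:
            if last is None:
                raise SchemaError("stream begins with a missing-face frame")
            carried += 1
            if carried > max_carry_forward:
                raise SchemaError(
                    f"face missing for more than {max_carry_forward} consecutive frames"
                )
            yield last
            continue
        carried = 0
        if ref is None:
            ref = make_pose_reference(frame, depth_scale)
        fv = extract_features(frame, index_map)
        pose = estimate_head_pose(frame, ref)
        last = (fv, pose)
        yield last


def write_feature_csv(
    rows: Iterable[tuple[int, float, FeatureVector, HeadPose | None]],
    path: str | Path,
) -> None:
    """Serialise a feature stream as CSV.

    ``rows`` yields ``(frame_index, t, features, pose_or_None)``. Pose columns
    are written whenever any row carries a pose.
    """
    rows = list(rows)
    with_pose = any(p is not None for _, _, _, p in rows)
    header = ["frame_index", "t", "ear", "mar", "nose_x", "nose_y"]
    if with_pose:
        header += ["angle_x", "angle_y", "pose"]
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for idx, t, fv, pose in rows:
            row = [idx, repr(t), repr(fv.ear), repr(fv.mar), repr(fv.nose_x), repr(fv.nose_y)]
            if with_pose:
                if pose is None:
                    row += ["", "", ""]
                else:
                    row += [repr(pose.angle_x), repr(pose.angle_y), pose.pose.value]
            writer.writerow(row)
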