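"""Domain types and file I/O for facial-landmark streams.

A stream is an ordered sequence of :class:`LandmarkFrame` objects, one per
video frame: 68 two-dimensional face landmarks in pixel units (the classic
Dlib numbering) plus a single three-dimensional nose landmark from a dense
face mesh, whose x/y are normalised to ``[0, 1]`` by the frame size and whose
z is a unitless depth. Streams round-trip losslessly through JSONL or CSV.

Internal landmark indexing is 0-based; the conventional 1-based numbering of
the 68-point annotation scheme maps to internal indices as ``point k`` ↔
``index k - 1``. Pixel coordinates follow the image convention: origin at the
top-left corner, x growing rightward, y growing downward.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import SchemaError, StreamOrderError, StreamParseError

N_FACE_POINTS = 68

__all__ = [
    "N_FACE_POINTS",
    "LandmarkFrame",
    "LandmarkIndexMap",
    "StreamMeta",
    "DLIB_68_MAP",
    "read_landmark_stream",
    "write_landmark_stream",
]


@dataclass(frozen=True)
class StreamMeta:
    """Stream-level metadata: capture rate, subject, and provenance."""

    fps: float = 30.0
    subject_id: str = ""
    source: str = "file"  # one of {"synthetic", "file", "adapter"}

    def __post_init__(self) -> None:
        if not self.fps > 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        if self.source not in ("synthetic", "file", "adapter"):
            raise SchemaError(f"unknown stream source {self.source!r}")


@dataclass(frozen=True, eq=False)
class LandmarkFrame:
    """One frame's landmark geometry.

    Parameters
    ----------
    frame_index
        Non-negative position of the frame in its stream.
    timestamp_s
        Capture time in seconds (``frame_index / fps`` for a regular stream).
    face_points
        ``(68, 2)`` array of pixel coordinates.
    nose_point
        ``(x_norm, y_norm, z)`` — mesh nose landmark, x/y normalised to
        ``[0, 1]``, z a unitless depth.
    frame_width, frame_height
        Source frame size in pixels.
    """

    frame_index: int
    timestamp_s: float
    face_points: np.ndarray
    nose_point: tuple[float, float, float]
    frame_width: int
    frame_height: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.face_points, dtype=float)
        if pts.shape != (N_FACE_POINTS, 2):
            raise SchemaError(
                f"expected {N_FACE_POINTS} face points, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise SchemaError("face points must be finite")
        object.__setattr__(self, "face_points", pts)
        nose = tuple(float(v) for v in self.nose_point)
        if len(nose) != 3 or not all(np.isfinite(nose)):
            raise SchemaError(f"nose point must be 3 finite numbers, got {nose}")
        if not (0.0 <= nose[0] <= 1.0 and 0.0 <= nose[1] <= 1.0):
            raise SchemaError(
                f"normalised nose x/y must lie in [0, 1], got {nose[:2]}"
            )
        object.__setattr__(self, "nose_point", nose)
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        if self.frame_width <= 0 or self.frame_height <= 0:
            raise SchemaError("frame dimensions must be positive")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LandmarkFrame):
            return NotImplemented
        return (
            self.frame_index == other.frame_index
            and self.timestamp_s == other.timestamp_s
            and np.array_equal(self.face_points, other.face_points)
            and self.nose_point == other.nose_point
            and self.frame_width == other.frame_width
            and self.frame_height == other.frame_height
        )

    def __hash__(self) -> int:  # frames are value objects; hash on identity fields
        return hash((self.frame_index, self.timestamp_s))


@dataclass(frozen=True)
class LandmarkIndexMap:
    """Which of the 68 landmark slots form the eyes and the inner mouth.

    Eye groups are ordered from the eye corner p1 revolving clockwise to p6,
    so that (p2, p6) and (p3, p5) are the vertical lid pairs and (p1, p4) the
    horizontal corner pair. The inner-mouth group is ordered with p1/p5 the
    horizontal corner pair and (p2, p8), (p3, p7), (p4, p6) the vertical lip
    pairs. ``nose_mesh_id`` records which dense-mesh landmark supplies the
    nose reference; it is configuration, never consulted by geometry code
    (the nose arrives pre-extracted on each frame).
    """

    left_eye: tuple[int, ...] = (36, 37, 38, 39, 40, 41)
    right_eye: tuple[int, ...] = (42, 43, 44, 45, 46, 47)
    inner_mouth: tuple[int, ...] = (60, 61, 62, 63, 64, 65, 66, 67)
    nose_mesh_id: int = 1

    def __post_init__(self) -> None:
        if len(self.left_eye) != 6 or len(set(self.left_eye)) != 6:
            raise SchemaError("left_eye must be 6 distinct indices")
        if len(self.right_eye) != 6 or len(set(self.right_eye)) != 6:
            raise SchemaError("right_eye must be 6 distinct indices")
        if len(self.inner_mouth) != 8 or len(set(self.inner_mouth)) != 8:
            raise SchemaError("inner_mouth must be 8 distinct indices")
        for group in (self.left_eye, self.right_eye, self.inner_mouth):
            for i in group:
                if not 0 <= i < N_FACE_POINTS:
                    raise SchemaError(f"landmark index {i} out of range")

    def eye_points(self, frame: LandmarkFrame) -> tuple[np.ndarray, np.ndarray]:
        """Return the (left, right) 6x2 eye point arrays of a frame."""
        return (
            frame.face_points[list(self.left_eye)],
            frame.face_points[list(self.right_eye)],
        )

    def mouth_points(self, frame: LandmarkFrame) -> np.ndarray:
        """Return the 8x2 inner-mouth point array of a frame."""
        return frame.face_points[list(self.inner_mouth)]


#: Default map for the 68-point annotation convention (0-based): left eye
#: occupies slots 36-41, right eye 42-47, inner mouth slots 60-67 (the
#: 1-based points 61-68 of the published landmark chart).
DLIB_68_MAP = LandmarkIndexMap()


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

_CSV_HEADER = (
    ["frame_index", "t"]
    + [f"{a}{i}" for i in range(1, N_FACE_POINTS + 1) for a in ("x", "y")]
    + ["nose_x", "nose_y", "nose_z", "w", "h"]
)


def _frame_to_record(frame: LandmarkFrame) -> dict:
    return {
        "frame_index": frame.frame_index,
        "t": frame.timestamp_s,
        "face": [float(v) for v in frame.face_points.ravel()],
        "nose": list(frame.nose_point),
        "w": frame.frame_width,
        "h": frame.frame_height,
    }


def _record_to_frame(rec: dict, line: int) -> LandmarkFrame:
    try:
        face = np.asarray(rec["face"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise StreamParseError(f"bad 'face' field: {exc}", line) from exc
    if face.size != 2 * N_FACE_POINTS:
        raise StreamParseError(
            f"expected {2 * N_FACE_POINTS} face values, got {face.size}", line
        )
    try:
        return LandmarkFrame(
            frame_index=int(rec["frame_index"]),
            timestamp_s=float(rec["t"]),
            face_points=face.reshape(N_FACE_POINTS, 2),
            nose_point=tuple(float(v) for v in rec["nose"]),
            frame_width=int(rec["w"]),
            frame_height=int(rec["h"]),
        )
    except (KeyError, TypeError, ValueError, SchemaError) as exc:
        raise StreamParseError(str(exc), line) from exc


def _check_order(frames: Sequence[LandmarkFrame]) -> None:
    for prev, cur in zip(frames, frames[1:]):
        if cur.frame_index <= prev.frame_index:
            raise StreamOrderError(
                f"frame_index not strictly increasing at {cur.frame_index}"
            )
        if cur.timestamp_s <= prev.timestamp_s:
            raise StreamOrderError(
                f"timestamps not strictly increasing at frame {cur.frame_index}"
            )
        if cur.frame_index != prev.frame_index + 1:
            warnings.warn(
                f"gap in frame indices between {prev.frame_index} and "
                f"{cur.frame_index}; windows will not span it",
                stacklevel=3,
            )


def read_landmark_stream(
    path: str | Path, meta: StreamMeta | None = None
) -> list[LandmarkFrame]:
    """Read a landmark stream from a ``.jsonl`` or ``.csv`` file.

    Frames are returned in ascending ``frame_index``; gaps in the index
    sequence raise a warning (downstream windowing refuses to span them).
    An empty file yields an empty list.
    """
    path = Path(path)
    frames: list[LandmarkFrame] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                return []
            if header != _CSV_HEADER:
                raise StreamParseError("unrecognised CSV header", 1)
            for lineno, row in enumerate(reader, start=2):
                if len(row) != len(_CSV_HEADER):
                    raise StreamParseError(
                        f"expected {len(_CSV_HEADER)} columns, got {len(row)}", lineno
                    )
                rec = {
                    "frame_index": row[0],
                    "t": row[1],
                    "face": row[2 : 2 + 2 * N_FACE_POINTS],
                    "nose": row[-5:-2],
                    "w": row[-2],
                    "h": row[-1],
                }
                frames.append(_record_to_frame(rec, lineno))
    else:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                raw = raw.strip()
                if not raw:
                    continue
                try:
                    rec = json.loads(raw)
                except json.JSONDecodeError as exc:
                    raise StreamParseError(f"invalid JSON: {exc.msg}", lineno) from exc
                frames.append(_record_to_frame(rec, lineno))
    _check_order(frames)
    return frames


def write_landmark_stream(
    frames: Iterable[LandmarkFrame], path: str | Path
) -> None:
    """Write frames to ``.jsonl`` or ``.csv``; coordinates keep full precision.

    Writing is deterministic: the same frames always produce byte-identical
    files, and ``read(write(x)) == x`` bit-exactly (floats are serialised with
    Python's shortest round-trip repr).
    """
    path = Path(path)
    frames = list(frames)
    _check_order(frames)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_HEADER)
            for f in frames:
                writer.writerow(
                    [f.frame_index, repr(f.timestamp_s)]
                    + [repr(float(v)) for v in f.face_points.ravel()]
                    + [repr(v) for v in f.nose_point]
                    + [f.frame_width, f.frame_height]
                )
    else:
        with open(path, "w") as fh:
            for f in frames:
                fh.write(json.dumps(_frame_to_record(f)) + "\n")
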