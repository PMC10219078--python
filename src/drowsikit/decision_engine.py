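"""Streaming runtime: moving feature window, per-frame labels, alarm logic.

Each incoming frame's feature vector enters a fixed-capacity window (default
15); once full, the oldest vector is evicted on every push and the current
4x15 window is classified, producing one drowsy/alert label per frame. The
label emitted at the moment the window first fills completes the population
phase and is not counted; counting starts with the next frame. The alarm
fires when the required number of consecutive drowsy labels (default 15) has
been counted, so at 30 fps the first alarm-capable decision consumes
15 + 15 = 30 frames — one second — and every later decision arrives with
each new frame, i.e. every 33 ms. A single alert label resets the drowsy
counter. Once raised, the alarm stays active until the same number of
consecutive alert labels is observed (hysteresis symmetric to onset).

The engine consumes feature vectors, not video, so its timing contract is a
deterministic function of the stream; per-frame classifier latency is a
hardware property outside this contract.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ModelLayoutError, SchemaError
from .feature_extraction import (
    DEFAULT_DEPTH_SCALE,
    FeatureVector,
    PoseReference,
    extract_features,
    make_pose_reference,
)
from .landmark_model import DLIB_68_MAP, LandmarkFrame, LandmarkIndexMap

__all__ = [
    "EngineConfig",
    "DecisionEvent",
    "DrowsinessEngine",
    "run_stream",
    "timing_report",
]


@dataclass(frozen=True)
class EngineConfig:
    """Window capacity, consecutive-label requirement and frame rate."""

    window_capacity: int = 15
    consecutive_required: int = 15
    consecutive_reset: int | None = None  # defaults to consecutive_required
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.window_capacity <= 0 or self.consecutive_required <= 0:
            raise SchemaError("window_capacity and consecutive_required must be positive")
        if self.consecutive_reset is not None and self.consecutive_reset <= 0:
            raise SchemaError("consecutive_reset must be positive")
        if not self.fps > 0:
            raise SchemaError("fps must be positive")

    @property
    def reset_count(self) -> int:
        return self.consecutive_reset or self.consecutive_required

    @property
    def first_decision_frames(self) -> int:
        """Frames consumed before the first alarm-capable decision."""
        return self.window_capacity + self.consecutive_required


@dataclass(frozen=True)
class DecisionEvent:
    """One per-frame decision: the window label and the alarm state.

    ``latency_frames`` is the number of frames consumed from stream start up
    to and including this event's frame.
    """

    frame_index: int
    label: str  # "alert" or "drowsy"
    alarm: bool
    latency_frames: int


class DrowsinessEngine:
    """Stateful moving-window classifier with consecutive-label alarm logic."""

    def __init__(self, model, config: EngineConfig = EngineConfig()):
        self.model = model
        self.config = config
        self.window: deque[FeatureVector] = deque(maxlen=config.window_capacity)
        self.frames_seen = 0
        self.consecutive_drowsy = 0
        self.consecutive_alert = 0
        self.alarm_active = False
        self._populated = False  # has the initial (uncounted) label been emitted?

    def _classify_window(self) -> bool:
        mat = np.array(
            [
                [fv.ear for fv in self.window],
                [fv.mar for fv in self.window],
                [fv.nose_x for fv in self.window],
                [fv.nose_y for fv in self.window],
            ]
        )
        flat = mat.ravel()
        if flat.shape[0] != self.model.n_features:
            raise ModelLayoutError(
                f"window of {flat.shape[0]} features does not match model "
                f"({self.model.n_features})"
            )
        return bool(self.model.predict(flat[None, :])[0] == 1)

    def push(self, fv: FeatureVector, frame_index: int | None = None) -> DecisionEvent | None:
        """Feed one feature vector; returns an event once the window is full.

        The oldest vector is evicted automatically at capacity. The first
        emitted event carries the initial label that completes window
        population and does not advance the consecutive counters.
        """
        self.window.append(fv)
        self.frames_seen += 1
        if frame_index is None:
            frame_index = self.frames_seen - 1
        if len(self.window) < self.config.window_capacity:
            return None
        drowsy = self._classify_window()
        if not self._populated:
            self._populated = True
        elif drowsy:
            self.consecutive_drowsy += 1
            self.consecutive_alert = 0
        else:
            self.consecutive_alert += 1
            self.consecutive_drowsy = 0
        if not self.alarm_active and self.consecutive_drowsy >= self.config.consecutive_required:
            self.alarm_active = True
        elif self.alarm_active and self.consecutive_alert >= self.config.reset_count:
            self.alarm_active = False
        return DecisionEvent(
            frame_index=frame_index,
            label="drowsy" if drowsy else "alert",
            alarm=self.alarm_active,
            latency_frames=self.frames_seen,
        )


def run_stream(
    frames: Iterable[LandmarkFrame],
    model,
    config: EngineConfig = EngineConfig(),
    index_map: LandmarkIndexMap = DLIB_68_MAP,
    ref: PoseReference | None = None,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
) -> list[DecisionEvent]:
    """Run the engine over a whole landmark stream.

    Equivalent, event for event, to folding :meth:`DrowsinessEngine.push`
    over the per-frame features; a pure function of (stream, model, config).
    """
    engine = DrowsinessEngine(model, config)
    events: list[DecisionEvent] = []
    for frame in frames:
        if ref is None:
            ref = make_pose_reference(frame, depth_scale)
        fv = extract_features(frame, index_map)
        event = engine.push(fv, frame.frame_index)
        if event is not None:
            events.append(event)
    return events


def timing_report(
    events: Sequence[DecisionEvent], config: EngineConfig = EngineConfig()
) -> tuple[float, int]:
    """Summarise the engine's decision timing.

    Returns ``(first_decision_s, steady_interval_ms)``: the time consumed by
    the first alarm-capable decision (window population plus the consecutive
    label count) and the steady-state interval between decisions — one frame,
    ``floor(1000 / fps)`` milliseconds.
    """
    if len(events) < 2:
        raise ValueError("timing report needs at least 2 events")
    eligible = [e for e in events if e.latency_frames >= config.first_decision_frames]
    if not eligible:
        raise ValueError(
            f"stream too short for a full decision ({config.first_decision_frames} frames)"
        )
    first_decision_s = eligible[0].latency_frames / config.fps
    cadence = events[1].latency_frames - events[0].latency_frames
    steady_interval_ms = int(1000 * cadence // config.fps)
    return first_decision_s, steady_interval_ms
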