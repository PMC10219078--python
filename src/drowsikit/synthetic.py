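"""Synthetic landmark sessions with known ground truth.

Real training data for visual drowsiness detection is video of drivers with
annotated behaviours (slow blinks, yawns, nods, looking aside, talking).
This module emulates the *geometric signal* such video produces after
landmark detection: per-frame 68-point faces plus a mesh nose landmark,
driven by kinematic trajectories of the eye aspect ratio, mouth aspect
ratio and head pose. Each session carries exact per-frame ground-truth
modality states, so the whole feature -> window -> classifier -> alarm
pipeline is testable end to end.

The defaults mirror the statistical regime the pipeline is designed for:
30 frames/s capture; per-subject open-eye EAR maxima drawn uniformly from
[0.23, 0.37] and yawn MAR maxima from [0.55, 0.9] (the observed across-
subject ranges for these ratios); ordinary blinks lasting 100-400 ms,
drowsy blinks >= 500 ms, yawns 4-6 s.

Kinematics are deliberately simple: eye closures are square pulses with a
one-frame "knee" sample just below the closed-eye boundary on each edge
(the lid crosses the open/closed boundary between samples, so every
in-event sample reads closed); yawns are half-cosine rise/plateau/fall
shapes; talking is a sub-threshold mouth oscillation; nods and turns are
square pitch/yaw excursions of the nose landmark. Ground-truth states are
computed by thresholding the *noiseless* target trajectories; observation
jitter (Gaussian, seed-controlled) is added afterwards, giving classifiers
a learnable but non-degenerate task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EventSpecError, SchemaError
from .feature_extraction import DEFAULT_DEPTH_SCALE, PoseReference
from .landmark_model import LandmarkFrame, N_FACE_POINTS
from .window_labeling import FrameStateLabel, LabelingConfig

__all__ = [
    "SubjectProfile",
    "EventSpec",
    "SyntheticSession",
    "draw_profile",
    "ear_profile",
    "mar_profile",
    "pose_profile",
    "geometry_from_ratios",
    "generate_session",
    "generate_corpus",
    "EYE_EVENT_KINDS",
    "MOUTH_EVENT_KINDS",
    "HEAD_EVENT_KINDS",
]

MAX_EAR_RANGE = (0.23, 0.37)
MAX_MAR_RANGE = (0.55, 0.9)
BLINK_DURATION_S = (0.1, 0.4)
DROWSY_BLINK_MIN_S = 0.5
YAWN_DURATION_S = (4.0, 6.0)

EYE_EVENT_KINDS = ("blink", "drowsy_blink")
MOUTH_EVENT_KINDS = ("yawn", "talk")
HEAD_EVENT_KINDS = ("nod", "turn")

#: EAR sample placed on the event edges: the eyelid crosses the open/closed
#: boundary between frames, so edge samples already read closed (< 0.2).
CLOSED_KNEE_EAR = 0.18

#: Default pitch/yaw excursion of nod/turn events, comfortably beyond the
#: 7-degree pose threshold.
DEFAULT_EXCURSION_DEG = 10.0


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject facial geometry: ratio extrema and landmark scales."""

    max_ear: float = 0.32
    max_mar: float = 0.8
    closed_ear: float = 0.05
    rest_mar: float = 0.1
    eye_scale: float = 40.0  # horizontal eye extent, pixels
    mouth_scale: float = 48.0  # inner-mouth width, pixels
    nose_rest: tuple[float, float, float] = (0.5, 0.45, -0.04)

    def __post_init__(self) -> None:
        if not self.closed_ear < 0.2 < self.max_ear:
            raise SchemaError(
                f"need closed_ear < 0.2 < max_ear, got ({self.closed_ear}, {self.max_ear})"
            )
        if not self.rest_mar < 0.5 <= self.max_mar:
            raise SchemaError(
                f"need rest_mar < 0.5 <= max_mar, got ({self.rest_mar}, {self.max_mar})"
            )
        if self.eye_scale <= 0 or self.mouth_scale <= 0:
            raise SchemaError("landmark scales must be positive")


def draw_profile(rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject uniformly from the observed across-subject ranges."""
    return SubjectProfile(
        max_ear=float(rng.uniform(*MAX_EAR_RANGE)),
        max_mar=float(rng.uniform(*MAX_MAR_RANGE)),
        closed_ear=float(rng.uniform(0.03, 0.08)),
        rest_mar=float(rng.uniform(0.05, 0.2)),
    )


@dataclass(frozen=True)
class EventSpec:
    """One scheduled behavioural event.

    Kinds and their admissible durations: ``blink`` 0.1-0.4 s,
    ``drowsy_blink`` >= 0.5 s, ``yawn`` 4-6 s; ``talk``, ``nod`` and
    ``turn`` any positive duration. ``direction`` disambiguates turns
    (+1 right, -1 left) and nod polarity (-1 = head falls forward/down).
    """

    kind: str
    onset_s: float
    duration_s: float
    direction: int = -1

    def __post_init__(self) -> None:
        if self.kind not in EYE_EVENT_KINDS + MOUTH_EVENT_KINDS + HEAD_EVENT_KINDS:
            raise EventSpecError(f"unknown event kind {self.kind!r}")
        if self.onset_s < 0 or self.duration_s <= 0:
            raise EventSpecError("onset must be >= 0 and duration > 0")
        if self.kind == "blink" and not (
            BLINK_DURATION_S[0] <= self.duration_s <= BLINK_DURATION_S[1]
        ):
            raise EventSpecError(
                f"a blink lasts {BLINK_DURATION_S[0]}-{BLINK_DURATION_S[1]} s, "
                f"got {self.duration_s}"
            )
        if self.kind == "drowsy_blink" and self.duration_s < DROWSY_BLINK_MIN_S:
            raise EventSpecError(
                f"a drowsy blink lasts >= {DROWSY_BLINK_MIN_S} s, got {self.duration_s}"
            )
        if self.kind == "yawn" and not (
            YAWN_DURATION_S[0] <= self.duration_s <= YAWN_DURATION_S[1]
        ):
            raise EventSpecError(
                f"a yawn lasts {YAWN_DURATION_S[0]}-{YAWN_DURATION_S[1]} s, "
                f"got {self.duration_s}"
            )
        if self.direction not in (-1, 1):
            raise EventSpecError("direction must be +1 or -1")

    @property
    def modality(self) -> str:
        if self.kind in EYE_EVENT_KINDS:
            return "eye"
        if self.kind in MOUTH_EVENT_KINDS:
            return "mouth"
        return "head"

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def frame_span(self, fps: float) -> tuple[int, int]:
        """Half-open frame range [start, stop) covered by the event."""
        return round(self.onset_s * fps), round(self.end_s * fps)


@dataclass(frozen=True)
class SyntheticSession:
    """A generated landmark stream plus its exact ground truth."""

    frames: list[LandmarkFrame]
    truth: list[FrameStateLabel]
    events: list[EventSpec]
    profile: SubjectProfile
    seed: int
    fps: float = 30.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.truth):
            raise SchemaError("frames and truth must be aligned")


# ---------------------------------------------------------------------------
# Per-event kinematic trajectories
# ---------------------------------------------------------------------------

def _n_frames(event: EventSpec, fps: float) -> int:
    start, stop = event.frame_span(fps)
    return stop - start


def ear_profile(event: EventSpec, profile: SubjectProfile, fps: float = 30.0) -> np.ndarray:
    """EAR trajectory over an eye event's frames.

    A closure pulse: edge frames sit at the closed-side knee (just below the
    open/closed boundary), interior frames at the subject's closed-eye EAR.
    Every in-event sample is therefore below 0.2, so a drowsy blink of
    0.5 s at 30 fps yields >= 15 consecutive closed frames while an
    ordinary <= 400 ms blink can never fill a 15-frame window.
    """
    if event.modality != "eye":
        raise EventSpecError(f"{event.kind!r} is not an eye event")
    n = _n_frames(event, fps)
    if event.kind == "drowsy_blink" and n < 4:
        raise EventSpecError("drowsy blink shorter than 4 frames is degenerate")
    knee = min(CLOSED_KNEE_EAR, 0.5 * (profile.max_ear + profile.closed_ear))
    traj = np.full(n, profile.closed_ear)
    if n >= 3:
        traj[0] = knee
        traj[-1] = knee
    return traj


def mar_profile(event: EventSpec, profile: SubjectProfile, fps: float = 30.0) -> np.ndarray:
    """MAR trajectory over a mouth event's frames.

    A yawn rises from the resting MAR to the subject's maximum along a
    half-cosine, plateaus, and falls symmetrically; the plateau sits at
    ``max_mar`` >= 0.55, well past the 0.5 open-mouth threshold. Talking is
    a rectified oscillation of amplitude <= 0.35 above rest, bounded
    strictly below 0.5 — the behaviour a too-low MAR threshold would
    mislabel as yawning.
    """
    if event.modality != "mouth":
        raise EventSpecError(f"{event.kind!r} is not a mouth event")
    n = _n_frames(event, fps)
    if event.kind == "yawn":
        ramp = min(round(0.8 * fps), max(1, n // 3))
        traj = np.full(n, float(profile.max_mar))
        rise = profile.rest_mar + (profile.max_mar - profile.rest_mar) * 0.5 * (
            1 - np.cos(np.linspace(0, math.pi, ramp, endpoint=False))
        )
        traj[:ramp] = rise
        traj[n - ramp :] = rise[::-1]
        return traj
    # talk: amplitude capped so no sample reaches the 0.5 threshold
    amplitude = min(0.35, 0.5 - profile.rest_mar - 0.05)
    t = np.arange(n) / fps
    return profile.rest_mar + amplitude * np.abs(np.sin(2 * math.pi * 2.5 * t))


def pose_profile(
    event: EventSpec,
    profile: SubjectProfile,
    fps: float = 30.0,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
    frame_width: int = 640,
    frame_height: int = 480,
    excursion_deg: float = DEFAULT_EXCURSION_DEG,
) -> np.ndarray:
    """Normalised nose (x, y, z) trajectory over a head event's frames.

    The excursion is computed by inverting the arctangent pose model: a nod
    displaces the nose vertically by ``depth_ref * tan(excursion)`` pixels
    (head falling forward = image y growing = negative pitch), a turn
    displaces it horizontally. Excursions below the 7-degree threshold
    leave the pose neutral by construction.
    """
    if event.modality != "head":
        raise EventSpecError(f"{event.kind!r} is not a head event")
    n = _n_frames(event, fps)
    x0 = profile.nose_rest[0] * frame_width
    y0 = profile.nose_rest[1] * frame_height
    depth_ref = depth_scale * frame_width
    shift_px = depth_ref * math.tan(math.radians(excursion_deg))
    x, y = x0, y0
    if event.kind == "nod":
        # pitch = atan2(y0 - y, depth); direction -1 (down) means y grows
        y = y0 - event.direction * shift_px
    else:  # turn: yaw = atan2(x - x0, depth)
        x = x0 + event.direction * shift_px
    traj = np.empty((n, 3))
    traj[:, 0] = x / frame_width
    traj[:, 1] = y / frame_height
    traj[:, 2] = profile.nose_rest[2]
    return traj


# ---------------------------------------------------------------------------
# Ratio -> landmark geometry (inverse of the EAR/MAR definitions)
# ---------------------------------------------------------------------------

def _face_template(frame_width: int, frame_height: int) -> np.ndarray:
    """A fixed, plausible 68-point layout; eye/mouth slots are overwritten
    per frame by :func:`geometry_from_ratios`."""
    w, h = frame_width, frame_height
    cx, cy = 0.5 * w, 0.5 * h
    pts = np.zeros((N_FACE_POINTS, 2))
    # jaw line 0-16: half ellipse
    ang = np.linspace(math.pi, 2 * math.pi, 17)
    pts[0:17, 0] = cx + 0.28 * w * np.cos(ang)
    pts[0:17, 1] = cy - 0.30 * h * np.sin(ang)
    # brows 17-26
    for i in range(5):
        pts[17 + i] = (cx - 0.20 * w + i * 0.04 * w, cy - 0.16 * h)
        pts[22 + i] = (cx + 0.04 * w + i * 0.04 * w, cy - 0.16 * h)
    # nose bridge and base 27-35
    for i in range(4):
        pts[27 + i] = (cx, cy - 0.10 * h + i * 0.035 * h)
    for i in range(5):
        pts[31 + i] = (cx - 0.04 * w + i * 0.02 * w, cy + 0.05 * h)
    # outer mouth 48-59: ellipse
    ang = np.linspace(0, 2 * math.pi, 12, endpoint=False)
    pts[48:60, 0] = cx + 0.10 * w * np.cos(ang)
    pts[48:60, 1] = cy + 0.22 * h + 0.05 * h * np.sin(ang)
    return pts


def _eye_points(cx: float, cy: float, width: float, ear: float) -> np.ndarray:
    """Six eye landmarks with horizontal extent ``width`` whose EAR is
    exactly ``ear``: vertical lid pairs separated by ``ear * width``."""
    half_v = 0.5 * ear * width
    x0 = cx - 0.5 * width
    return np.array(
        [
            [x0, cy],                        # p1 corner
            [x0 + width / 3, cy - half_v],   # p2 top
            [x0 + 2 * width / 3, cy - half_v],  # p3 top
            [x0 + width, cy],                # p4 corner
            [x0 + 2 * width / 3, cy + half_v],  # p5 bottom
            [x0 + width / 3, cy + half_v],   # p6 bottom
        ]
    )


def _mouth_points(cx: float, cy: float, width: float, mar: float) -> np.ndarray:
    """Eight inner-lip landmarks whose MAR is exactly ``mar``: three
    vertical pairs each separated by ``2 * width * mar / 3``."""
    v = 2.0 * width * mar / 3.0
    x0 = cx - 0.5 * width
    xs = [x0 + width * f for f in (0.25, 0.5, 0.75)]
    return np.array(
        [
            [x0, cy],               # p1 left corner
            [xs[0], cy - 0.5 * v],  # p2
            [xs[1], cy - 0.5 * v],  # p3
            [xs[2], cy - 0.5 * v],  # p4
            [x0 + width, cy],       # p5 right corner
            [xs[2], cy + 0.5 * v],  # p6
            [xs[1], cy + 0.5 * v],  # p7
            [xs[0], cy + 0.5 * v],  # p8
        ]
    )


def geometry_from_ratios(
    ear_t: np.ndarray,
    mar_t: np.ndarray,
    profile: SubjectProfile,
    frame_width: int = 640,
    frame_height: int = 480,
) -> np.ndarray:
    """Build per-frame 68-point faces realising the given ratio targets.

    Inverts the EAR/MAR definitions: eye and inner-mouth landmark groups are
    placed with fixed horizontal extents and vertical separations scaled so
    that recomputing the ratios recovers the targets to ~1e-9. Remaining
    landmarks come from a static template. Returns ``(n, 68, 2)``.
    """
    ear_t = np.asarray(ear_t, dtype=float)
    mar_t = np.asarray(mar_t, dtype=float)
    if ear_t.shape != mar_t.shape:
        raise ValueError("ear and mar trajectories must be aligned")
    if np.any(ear_t < 0) or np.any(mar_t < 0):
        raise ValueError("target ratios must be non-negative")
    if not (np.all(np.isfinite(ear_t)) and np.all(np.isfinite(mar_t))):
        raise ValueError("target ratios must be finite")
    n = ear_t.shape[0]
    template = _face_template(frame_width, frame_height)
    w, h = frame_width, frame_height
    left_c = (0.5 * w - 0.12 * w, 0.42 * h)
    right_c = (0.5 * w + 0.12 * w, 0.42 * h)
    mouth_c = (0.5 * w, 0.72 * h)
    faces = np.broadcast_to(template, (n, N_FACE_POINTS, 2)).copy()
    for i in range(n):
        faces[i, 36:42] = _eye_points(*left_c, profile.eye_scale, ear_t[i])
        faces[i, 42:48] = _eye_points(*right_c, profile.eye_scale, ear_t[i])
        faces[i, 60:68] = _mouth_points(*mouth_c, profile.mouth_scale, mar_t[i])
    return faces


# ---------------------------------------------------------------------------
# Session and corpus generation
# ---------------------------------------------------------------------------

def _check_schedule(events: Sequence[EventSpec], duration_s: float) -> None:
    for ev in events:
        if ev.end_s > duration_s:
            raise EventSpecError(
                f"{ev.kind} at {ev.onset_s}s runs past the {duration_s}s session"
            )
    by_modality: dict[str, list[EventSpec]] = {}
    for ev in events:
        by_modality.setdefault(ev.modality, []).append(ev)
    for modality, evs in by_modality.items():
        evs = sorted(evs, key=lambda e: e.onset_s)
        for a, b in zip(evs, evs[1:]):
            if b.onset_s < a.end_s:
                raise EventSpecError(
                    f"overlapping {modality} events at {a.onset_s}s and {b.onset_s}s"
                )


def generate_session(
    events: Sequence[EventSpec],
    profile: SubjectProfile,
    duration_s: float = 60.0,
    fps: float = 30.0,
    seed: int = 0,
    jitter_sigma: float = 0.01,
    nose_jitter_px: float = 1.0,
    frame_width: int = 640,
    frame_height: int = 480,
    depth_scale: float = DEFAULT_DEPTH_SCALE,
    labeling: LabelingConfig = LabelingConfig(),
    subject_id: str = "",
) -> SyntheticSession:
    """Compose a full landmark session from an event schedule.

    Target trajectories are the subject's resting values with per-event
    kinematics pasted over each event's frame span. Ground-truth states
    threshold the noiseless targets (EAR < 0.2 closed, MAR >= 0.5 open,
    pose non-neutral via the arctangent model against the first-frame nose
    reference); Gaussian jitter is then added to the observed ratios and
    nose coordinates before the landmark geometry is synthesised.
    Deterministic under a fixed seed.
    """
    _check_schedule(events, duration_s)
    n = round(duration_s * fps)
    if n < 1:
        raise EventSpecError("session must contain at least one frame")
    rng = np.random.default_rng(seed)

    ear_t = np.full(n, float(profile.max_ear))
    mar_t = np.full(n, float(profile.rest_mar))
    nose_t = np.tile(np.asarray(profile.nose_rest, dtype=float), (n, 1))
    for ev in events:
        start, stop = ev.frame_span(fps)
        stop = min(stop, n)
        if ev.modality == "eye":
            ear_t[start:stop] = ear_profile(ev, profile, fps)[: stop - start]
        elif ev.modality == "mouth":
            mar_t[start:stop] = mar_profile(ev, profile, fps)[: stop - start]
        else:
            nose_t[start:stop] = pose_profile(
                ev, profile, fps, depth_scale, frame_width, frame_height
            )[: stop - start]

    # ground truth from the noiseless targets
    ref = PoseReference(
        nose0=(
            nose_t[0, 0] * frame_width,
            nose_t[0, 1] * frame_height,
            nose_t[0, 2],
        ),
        depth_ref=depth_scale * frame_width,
    )
    truth: list[FrameStateLabel] = []
    for i in range(n):
        x = nose_t[i, 0] * frame_width
        y = nose_t[i, 1] * frame_height
        angle_y = math.degrees(math.atan2(x - ref.nose0[0], ref.depth_ref))
        angle_x = math.degrees(math.atan2(ref.nose0[1] - y, ref.depth_ref))
        non_neutral = (
            abs(angle_x) > labeling.pose_threshold
            or abs(angle_y) > labeling.pose_threshold
        )
        truth.append(
            FrameStateLabel(
                eye_closed=bool(ear_t[i] < labeling.ear_threshold),
                mouth_open=bool(mar_t[i] >= labeling.mar_threshold),
                head_drowsy=bool(non_neutral),
            )
        )

    # observed = target + jitter
    ear_obs = np.clip(ear_t + rng.normal(0, jitter_sigma, n) if jitter_sigma else ear_t, 0, None)
    mar_obs = np.clip(mar_t + rng.normal(0, jitter_sigma, n) if jitter_sigma else mar_t, 0, None)
    nose_obs = nose_t.copy()
    if nose_jitter_px:
        nose_obs[:, 0] += rng.normal(0, nose_jitter_px / frame_width, n)
        nose_obs[:, 1] += rng.normal(0, nose_jitter_px / frame_height, n)
    nose_obs[:, 0] = np.clip(nose_obs[:, 0], 0.0, 1.0)
    nose_obs[:, 1] = np.clip(nose_obs[:, 1], 0.0, 1.0)

    faces = geometry_from_ratios(ear_obs, mar_obs, profile, frame_width, frame_height)
    frames = [
        LandmarkFrame(
            frame_index=i,
            timestamp_s=i / fps,
            face_points=faces[i],
            nose_point=tuple(nose_obs[i]),
            frame_width=frame_width,
            frame_height=frame_height,
        )
        for i in range(n)
    ]
    return SyntheticSession(
        frames=frames,
        truth=truth,
        events=list(events),
        profile=profile,
        seed=seed,
        fps=fps,
        subject_id=subject_id,
    )


_DURATION_RANGES = {
    "blink": (0.1, 0.4),
    "drowsy_blink": (0.6, 1.5),
    "yawn": (4.0, 6.0),
    "talk": (1.0, 3.0),
    "nod": (1.0, 3.0),
    "turn": (1.0, 3.0),
}
DROWSY_KINDS = ("drowsy_blink", "yawn", "nod")
ALERT_KINDS = ("blink", "talk")


def sample_schedule(
    rng: np.random.Generator,
    n_events: int,
    duration_s: float,
    drowsy_event_fraction: float = 0.5,
) -> list[EventSpec]:
    """Sample a non-overlapping event schedule.

    The session timeline (past a 1 s neutral lead-in that anchors the pose
    reference) is divided into equal slots, one event per slot, so events
    never overlap in any modality. Each event is drowsy-indicative
    (drowsy blink, yawn, nod) with the given probability, else an
    alert-compatible behaviour (short blink, talking).
    """
    lead_in = 1.0
    slot = (duration_s - lead_in) / n_events
    max_dur = max(hi for _, hi in _DURATION_RANGES.values())
    if slot <= max_dur + 0.2:
        raise EventSpecError(
            f"session too short for {n_events} events (slot {slot:.1f}s)"
        )
    events = []
    for k in range(n_events):
        if rng.uniform() < drowsy_event_fraction:
            kind = DROWSY_KINDS[rng.integers(len(DROWSY_KINDS))]
        else:
            kind = ALERT_KINDS[rng.integers(len(ALERT_KINDS))]
        lo, hi = _DURATION_RANGES[kind]
        dur = float(rng.uniform(lo, hi))
        start_lo = lead_in + k * slot
        onset = float(rng.uniform(start_lo, start_lo + slot - dur - 0.1))
        direction = int(rng.choice([-1, 1])) if kind == "turn" else -1
        events.append(EventSpec(kind=kind, onset_s=onset, duration_s=dur, direction=direction))
    return events


def generate_corpus(
    n_subjects: int,
    events_per_subject: int = 6,
    seed: int = 0,
    duration_s: float = 60.0,
    fps: float = 30.0,
    jitter_sigma: float = 0.01,
    nose_jitter_px: float = 1.0,
    drowsy_event_fraction: float = 0.5,
    labeling: LabelingConfig = LabelingConfig(),
) -> tuple[list[SyntheticSession], list[dict]]:
    """Generate a multi-subject corpus plus a manifest.

    Subject profiles are drawn uniformly from the observed ratio ranges;
    event schedules are sampled per subject. Returns ``(sessions,
    manifest)`` where the manifest records each subject's profile, seed and
    schedule. Deterministic under a fixed seed.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    master = np.random.default_rng(seed)
    sessions: list[SyntheticSession] = []
    manifest: list[dict] = []
    for s in range(n_subjects):
        sub_seed = int(master.integers(2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        profile = draw_profile(rng)
        events = sample_schedule(rng, events_per_subject, duration_s, drowsy_event_fraction)
        session = generate_session(
            events,
            profile,
            duration_s=duration_s,
            fps=fps,
            seed=sub_seed,
            jitter_sigma=jitter_sigma,
            nose_jitter_px=nose_jitter_px,
            labeling=labeling,
            subject_id=f"subject_{s:03d}",
        )
        sessions.append(session)
        manifest.append(
            {
                "subject_id": session.subject_id,
                "seed": sub_seed,
                "max_ear": profile.max_ear,
                "max_mar": profile.max_mar,
                "closed_ear": profile.closed_ear,
                "rest_mar": profile.rest_mar,
                "events": [
                    {
                        "kind": e.kind,
                        "onset_s": e.onset_s,
                        "duration_s": e.duration_s,
                        "direction": e.direction,
                    }
                    for e in events
                ],
            }
        )
    return sessions, manifest
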