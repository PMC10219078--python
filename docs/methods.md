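# Methods

## The detection model

drowsikit implements a frame-rate visual drowsiness detector built on three
facial cues extracted from landmark streams at 30 frames/s:

**Eye aspect ratio (EAR).** For the six landmarks of one eye, numbered from
the corner p1 clockwise to p6,

    EAR = (‖p2 − p6‖ + ‖p3 − p5‖) / (2 ‖p1 − p4‖).

The ratio is scale-, rotation- and translation-invariant, roughly constant
while the eye is open, and collapses to 0 as the lids touch. The per-frame
feature is the mean of the left- and right-eye ratios (the single-eye
definition says nothing about combining eyes; averaging is the convention of
the EAR blink-detection literature).

**Mouth aspect ratio (MAR).** Over the eight inner-lip landmarks,

    MAR = (‖p2 − p8‖ + ‖p3 − p7‖ + ‖p4 − p6‖) / (2 ‖p1 − p5‖),

rising as the mouth opens wide (yawning) and staying below ~0.45 during
ordinary talking.

**Head pose.** The mesh nose landmark, de-normalised to pixels, is compared
against its position on the first frame of the session. Pixel displacement
becomes a rotation angle through a fixed-distance arctangent model: the head
pivots about a point `depth_ref = depth_scale × frame_width` pixels behind
the image plane (default `depth_scale = 0.5`, configurable), so

    yaw   = atan2(x − x0, depth_ref),
    pitch = atan2(y0 − y, depth_ref)

in degrees, with the sign flip making upward head motion positive despite
image y growing downward. This model is a design choice — monotone in
displacement, zero at the reference, calibratable through `depth_scale` —
not a claim about any particular camera geometry. A pose is classified
up/down/left/right when the corresponding angle strictly exceeds 7°; when
both axes exceed it, the larger magnitude wins and an exact tie resolves to
the pitch pose. Strictness at the boundary (7.0° is neutral) is deliberate:
it makes neutral the default under ambiguity.

## Labeling

Per-frame states threshold the three cues: eyes closed when EAR < 0.2
(strict, so a subject whose EAR sits exactly at the threshold reads open),
mouth wide open when MAR ≥ 0.5 (the threshold is a minimum), head drowsy for
any non-neutral pose. The 0.2/0.5 operating points are the values at which
per-subject calibration sweeps (`threshold_sweep`) separate open/closed
states across the full observed ranges of subject maxima (MAX EAR 0.23–0.37,
MAX MAR 0.55–0.9) without saturating either label.

A training sample is a 4×15 matrix — EAR, MAR, nose-x, nose-y rows over 15
consecutive frames centred on frame N (7 neighbours per side). Edge frames
without a full neighbourhood are skipped, not padded; windows never span
stream gaps or session boundaries. The window label applies a persistence
rule: drowsy (1) exactly when at least one modality holds on **all** 15
frames. At 30 fps this is what separates a drowsy eye closure (≥ 500 ms ≈ 15
frames, so at least one window is fully covered) from an ordinary 100–400 ms
blink, which can never fill a window. The rule also yields the exact
combinatorial identity used throughout the tests: an uninterrupted L-frame
event produces max(0, L − W + 1) drowsy windows at window length W, hence
drowsy counts are non-increasing in W (`window_size_sweep`).

## Classifiers

Windows are flattened row-major (EAR block, MAR block, X block, Y block = 60
features). Nose blocks are standardised with the training-set mean/scale,
stored in the model and re-applied at inference — pixel coordinates are
camera-dependent, the ratios are not and stay raw. Three families are
provided with fixed defaults:

| model | configuration |
|---|---|
| `rf`  | random forest, entropy criterion, 50 trees |
| `svm` | linear kernel, C = 1, probability estimates enabled |
| `nn`  | feed-forward net 60 → 5 → 5 → 5 → 5 → 1, ReLU hidden, sigmoid output, Adam, log-loss, batch 32 |

The training protocol balances classes first (minority oversampled with
replacement and majority undersampled without, meeting at the mean count),
then splits 70/30 stratified. Balancing before splitting mirrors the
original procedure but can leak resampled near-duplicates into the test
set; `train_and_evaluate(split_first=True)` swaps the order for a
leakage-free estimate. Hard labels use a fixed 0.5 probability cut-off.
Evaluation reports accuracy, sensitivity, specificity, macro precision,
macro F1 (computed directly from the confusion matrix), and ROC /
precision–recall curves with trapezoidal AUCs.

## Decision engine

At run time a bounded window (capacity 15) receives one feature vector per
frame, evicting the oldest when full. Once full, every frame's window is
classified, giving one drowsy/alert label per frame. The label produced at
the instant the window first fills completes the population phase and is not
counted; counting starts on the next frame. The alarm fires after 15
consecutive counted drowsy labels — so the first alarm-capable decision
consumes 15 + 15 = 30 frames, one second at 30 fps, and each later decision
arrives with one new frame (33 ms). One alert label resets the drowsy
counter; once raised, the alarm stands until 15 consecutive alert labels are
counted (hysteresis symmetric to onset, configurable via
`EngineConfig.consecutive_reset`).

## Synthetic sessions

The generator emulates the geometric signal landmark detectors produce on
driver video, not the video itself:

* **Subjects.** Open-eye EAR maxima are drawn uniformly from [0.23, 0.37]
  and yawn MAR maxima from [0.55, 0.9] — the observed across-subject ranges
  for these ratios; closed-eye EAR from [0.03, 0.08]; resting MAR from
  [0.05, 0.2].
* **Events.** Blinks 100–400 ms; drowsy blinks ≥ 500 ms (sampled 0.6–1.5 s);
  yawns 4–6 s; talking a rectified mouth oscillation with amplitude capped
  so MAR stays strictly below 0.5; nods/turns square pitch/yaw excursions of
  10° (beyond the 7° threshold) obtained by inverting the arctangent pose
  model. Event schedules place one event per equal timeline slot after a 1 s
  neutral lead-in (which anchors the pose reference), so events of the same
  modality can never overlap. Corpus defaults — 60 s sessions, 6 events per
  subject, drowsy-event probability 0.5 — are package choices of a
  plausibly busy driving session, not measured event rates.
* **Eye kinematics.** Closures are square pulses whose two edge samples sit
  at a knee of EAR 0.18, just below the open/closed boundary: the lid
  crosses the boundary between samples, so every in-event sample reads
  closed. This keeps the defining frame arithmetic exact — a 500 ms closure
  yields exactly 15 closed frames and exactly one drowsy 15-frame window, a
  300 ms blink yields nine closed frames and none. A literal linear descent
  from the open level could leave an edge sample above 0.2 for large-eyed
  subjects and silently shorten events by a frame.
* **Geometry.** Target ratio trajectories are inverted into landmark
  coordinates: eye and inner-mouth groups are placed with fixed horizontal
  extents and vertical separations chosen so recomputing EAR/MAR recovers
  the targets to ~1e−9; the remaining 48 landmarks come from a static
  template. This exercises the full landmark → ratio path rather than
  bypassing it.
* **Truth and noise.** Ground-truth frame states threshold the *noiseless*
  target trajectories. Observation jitter — Gaussian on the ratios
  (default σ = 0.01) and on the nose position (default 1 px) — is added
  afterwards, before geometry synthesis. Zero-jitter sessions therefore
  round-trip exactly (pipeline states equal truth on 100% of frames), and
  jittered sessions give classifiers a learnable but non-degenerate task.
  All randomness flows from a single seed; corpora derive per-subject
  sub-seeds from it.

**What the generator does not model:** detector landmark noise correlated
in time or with pose, occlusion (eyeglasses, hands), illumination effects,
face-detection dropouts beyond the explicit missing-frame carry-forward,
inter-subject kinematic style, or co-articulated behaviours (talking while
turning). Classifier scores on synthetic corpora therefore demonstrate that
the pipeline machinery is correct and the task learnable under the stated
geometry and noise model — they are not performance claims about real
driver video.

## Numerical and degenerate-input choices

* Ratio denominators of zero (coincident eye/mouth corners) raise a
  degenerate-geometry error rather than returning infinity.
* Missing-face frames carry the previous frame's features forward for at
  most 5 consecutive frames (configurable), then error: the real-time
  contract must not silently fabricate long stretches of data.
* Streams shorter than one window yield an empty sample set with a warning;
  single-class test sets report point metrics with curves set to None;
  grid-search ties break in favour of the first grid point in iteration
  order.
* Stream serialisation uses Python's shortest round-trip float repr, making
  write → read bit-exact and repeated writes byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on deliberately compact
corpora chosen to exercise every code path at full fidelity: 10 subjects ×
60 s at 30 fps (18 000 frames, ≈ 17 900 windows) for the end-to-end
classifier checks, and 100 × 22 s sessions for the window-size monotonicity
sweep. These sizes are package choices; all quantities they compute are
reproduced from scratch on every run.
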