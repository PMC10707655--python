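# Methods

## Problem setting

During robot-assisted surgery (the motivating case is robot-assisted
radical prostatectomy), intraoperative bleeding must be noticed and
addressed quickly. `bleedwatch` models a frame-level bleeding detector for
the endoscopic video stream together with the machinery needed to turn its
noisy per-frame confidence into a calm, early, surgeon-facing alert, and to
evaluate that alert against a human reviewer. Because real surgical video
cannot ship with a package, every stage runs against a synthetic scene
generator whose statistics are controlled and documented below.

## Multi-task network

The detector is a U-Net-derived convolutional network with one shared
contracting path and two output branches:

* **Segmentation branch** — the classic U-Net expansive path with skip
  connections from matching encoder levels, ending in a 1-channel sigmoid
  map of instrument pixels. Convolutions are 3×3 with same-padding (the
  original U-Net crops; same-padding keeps the output aligned with the
  input mask and is the dominant modern convention).
* **Classification branch** — global average pooling of the bottleneck
  feature map, one hidden fully connected layer (ReLU, default width 64),
  and a 2-way softmax over {no blood accumulation, blood accumulation}.

Down-sampling is 2×2 max pooling, up-sampling a 2×2 stride-2 transposed
convolution; channel width doubles per level. The default configuration is
depth 3 with 16 base channels at 64×64 input (≈ 4.9 × 10⁵ parameters) —
small enough to train on one CPU core in minutes while leaving the
canonical deeper configuration reachable through `NetConfig`. Batch
normalisation is not used.

The network, including backpropagation, is implemented directly in NumPy
(`bleedwatch._nn`): convolutions evaluate as one BLAS matrix product per
layer through an im2col view, the input gradient as a full correlation with
the transposed kernel. Correctness of every layer's gradient was
established by central-difference checks in float64 (the only disagreements
are at exact ReLU kinks, where the subgradient convention relu′(0) = 0 is
used). He initialisation; all weights derive from a single seed.

Training minimises the unweighted sum

    loss = seg_loss + cls_loss

with `seg_loss` the *pixel-mean* binary cross-entropy against the
instrument mask and `cls_loss` the cross-entropy of the blood label
(whether the cross-entropies are pixel-mean or pixel-sum is a free choice;
mean keeps the two tasks on comparable scales). Probabilities are clamped
at ε = 1e−7 inside the reported losses; gradients are taken on logits, so
the clamp affects reporting only. Optimiser: Adam, learning rate 1e−3,
batch 16, 30 epochs, model selected at epoch 30 — the learning-rate/batch
choices are standard small-U-Net defaults, all configurable. The
train/validation split is 80/20, stratified by class. Event-detection
accuracy is `correct_predictions / samples`, reported overall and per
class; percentages are rounded half-up to two decimals
(`trainer.percent`), matching the usual clinical reporting style.

## Synthetic scenes

`scenegen` renders 64×64 RGB frames (configurable):

* background: pinkish tissue tone with smooth low-frequency mottling and
  per-channel noise;
* instruments: 2 bright, low-saturation capsules (rotated rectangles with
  round caps) that drift slowly across frames — the binary segmentation
  target;
* blood: a union of ellipses with red channel in [0.5, 0.8] and
  green/blue ≤ 0.25, plus σ = 0.02 Gaussian pixel noise. A frame is
  labelled "blood accumulation" iff the rendered blob area is ≥ 1 % of the
  frame pixels, so the label is recomputed from the pixels and can never
  disagree with them.

Temporal scenarios place an optional oozing-precursor window before a
sustained bleeding phase: during the precursor, a small blob appears for 2
consecutive frames every ~300 ms, below the label threshold in most bursts
with every fourth burst briefly above it; from the bleeding onset the blob
is persistent and grows at a configurable rate (default 30 px²/s). All
randomness is drawn from per-frame streams spawned from the scenario seed,
so any frame re-renders bit-identically in isolation.

The confidence-trace generator mirrors the same timeline at the signal
level: uniform(0, 0.1) baseline, 2-frame bursts of 0.5–0.7 confidence every
300 ms for the 6 s before the plateau, then sustained 0.97–1.0.

What the generator does **not** emulate: camera motion, specular
highlights, smoke, blur, occlusion, lighting drift, and class-boundary
ambiguity. Generated classes are separable by a trivial red-excess pixel
heuristic (> 0.95 accuracy, enforced by test), so accuracy floors met here
demonstrate that the pipeline is implemented correctly and can learn its
task — not that the network would reach the same numbers on real surgical
video, where the printed accuracies act as a reference point rather than a
guarantee.

## Alert engine

The per-frame bleeding confidence is smoothed by a causal digital
Butterworth low-pass filter, default cutoff 5 Hz at the video rate
(default 25 fps), order 2 — the minimal order with a meaningful roll-off;
the order is a free parameter because a filter's group delay cannot be
recovered from a cutoff alone, so the spec reports its own *measured*
step-response delay (`nominal_delay_ms`, the 50 % crossing time) instead of
asserting a figure. Filtering is strictly causal (no zero-phase
forward–backward pass): the engine is meant for live streams. Filter state
starts at zero, making the output invariant to prepended silence.

Escalation is a "parking sensor": what matters is that detections keep
recurring, not how confident each one is. Per frame (Δt = 1/fps):

    detection := filtered p ≥ detection_floor        (default 0.30)
    active    := a detection occurred within the trailing hold window
                 (default 300 ms, the precursor recurrence scale)
    w += Δt / escalation_window                      while active
    w −= decay_rate · Δt                             while inactive
    w  = clip(w, 0, 1)

with escalation window 2.2 s (valid band ≈ 2.1–2.3 s) and decay 0.5/s.
Sustained detections therefore saturate the warning level in exactly one
escalation window, and repeated brief low-confidence detections escalate at
the same rate as a continuous high-confidence signal — deliberately: brief
oozing precursors at modest confidence are precisely the pattern that
precedes frank bleeding, so weighting the rise by confidence amplitude
would systematically delay the warning until the frank phase (an
amplitude-weighted integrator calibrated to the same window provably alerts
*after* the sustained phase begins on burst-type precursors, because any
per-sample law monotone in confidence saturates slower at duty < 1 than at
sustained full confidence). The floor guards against noise: a signal that
never reaches 0.30 can never move the warning level.

A *significant bleeding* event is recorded dichotomously (0/1) at each
upward crossing of the warning level through `significant_threshold`,
default 0.94 — the midpoint of the 93–95 % operating band. The threshold is
applied to the escalated warning level, not the raw network confidence
(the alternative reading; applying it to the warning level is what makes
the escalation consequential).

## Evaluation suite

* **Matching** — greedy nearest-in-time one-to-one matching of system
  events to human events within ±10 s (configurable; bleeding episodes are
  sparse relative to this window). Matched pairs are TP, unmatched system
  events FP, unmatched human events FN.
* **Delta time** — delta = system − human detection time, so negative
  deltas mean the system was earlier; the headline statistic is the median
  with IQR (linear-interpolation/type-7 quartiles). Because the sign
  convention invites misreading, the evaluation also reports
  `lead = −delta` explicitly.
* **KDE** — Gaussian-kernel density of the deltas; Silverman's rule
  bandwidth by default, with a flagged fallback to 0.1 s on zero-spread
  data.
* **MCA** — indicator-matrix Multiple Correspondence Analysis, written out
  directly: indicator matrix Z, correspondence matrix P = Z / grand total,
  standardised residuals (P − rcᵀ)/√(rcᵀ), SVD; principal inertias are the
  squared singular values (their sum is exactly (J − Q)/Q, an identity the
  tests enforce to 1e−10), individual principal coordinates follow from
  the left singular vectors, and each variable's per-dimension coordinate
  is its correlation ratio η² with the individual scores. Benzécri's
  inertia correction is available but off by default. Constant variables
  are dropped with a warning — which is also how "system and human agree on
  every event" manifests: the outcome variable collapses to a single
  category and carries no discriminating structure.

## Numerical and degenerate-input choices

* Cross-entropy clamp ε = 1e−7; ReLU subgradient 0 at exactly 0; max-pool
  gradient split evenly across tied maxima.
* Filter design rejects cutoffs at or above Nyquist; the command-line
  `run` caps its default cutoff at 0.4 × fps for low-frame-rate sequences.
* Zero-length event logs: matching degenerates to all-FP/all-FN; delta
  statistics refuse zero pairs.
* MCA requires ≥ 2 non-constant variables and no missing values; dimensions
  with numerically zero inertia are not reported by default.
* All seeds are explicit; no global RNG state is touched anywhere.

## Scale of the shipped experiments

The standard training run uses 500 synthetic frames (400 train / 100
validation) at 64×64 for 30 epochs, chosen so a full from-scratch
reproduction (dataset synthesis, training, evaluation) completes in
minutes on a single CPU core; the lead-time evaluation uses 50 seeded
traces of 14 s at 25 fps. These sizes are the package's study conditions,
not tuning knobs.

## Known limitations

* Synthetic scenes are much easier than surgical video (see above); no
  domain adaptation or photometric augmentation is attempted.
* The network is frame-wise; no temporal architecture is used — temporal
  context enters only through the alert engine's filtering/escalation.
* Bleeding severity grading and bleeding-source localisation are out of
  scope; every detected event carries the same dichotomic weight.
* The NumPy implementation is single-threaded BLAS-bound; it is sized for
  desk-scale experiments, not for training the full-resolution canonical
  U-Net.
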