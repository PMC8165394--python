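# Methods

## Pipeline overview

`rpecg` treats rhythm classification as an image-classification problem.
Multi-lead ECG records carrying a single rhythm label are (1) resampled to
the 200 Hz working rate, (2) cut into 1,000-sample (5 s) single-lead
segments under class-conditional augmentation rules, (3) encoded as color
texture images — un-thresholded recurrence plots by default, CWT scalograms
or raw waveform plots as baselines — and (4) classified by a residual
inception CNN under a stratified hold-out + 5-fold cross-validation
protocol scored with per-class precision/recall/F1 and macro averages.

## Recurrence imaging

A segment x of length N is delay-embedded with dimension m and delay τ
(defaults m = 2, τ = 1, Euclidean norm), giving N − (m−1)τ states; for the
default segment this is a 999-state trajectory and a 999 × 999 distance
matrix R_{i,j} = ‖sᵢ − sⱼ‖₂. Storing raw distances rather than the
binary θ(ε − d) indicator avoids the information loss of binarization and
needs no radius choice; the binary variant remains available
(`threshold_rp`, boundary counts as recurrent: θ(0) = 1).

Rendering choices that pin the image bytes:

- **Normalization** is per-matrix min–max to [0, 1]. A dataset-global
  reference would couple images across records; per-matrix is
  self-contained, and it makes the image exactly invariant to affine
  rescaling a·x + b (a > 0) of the input segment.
- **Colormap** is a fixed 256-entry piecewise-linear
  blue→cyan→green→yellow→red table built in code (low distance = blue,
  high = red), so pixel values are identical across platforms. Any
  blue-to-red map would serve; this one is the package convention.
- **Constant matrices** (e.g. a flat segment) normalize to 0 and render
  uniformly blue, avoiding 0/0.
- **Resize** to the network input (default 299 × 299 × 3) is bilinear,
  anti-aliasing off — chosen for determinism, not fidelity.

## Baseline encoders

CWT scalograms use magnitudes of `pywt.cwt` coefficients over 64
log-spaced scales whose center frequencies span 0.5–40 Hz at 200 Hz — the
band containing clinically relevant ECG energy; the grid is configurable.
Supported mother wavelets: cgau8, cmor, fbsp, gaus8, mexh, morl (the
complex families are instantiated as `cmor1.5-1.0` / `fbsp2-1.5-1.0`).
Waveform images rasterize the amplitude-vs-time polyline with a 1-px
Bresenham renderer, anti-aliasing off, on white, y-limits = min/max ± 5 % —
again fixed for bit-stable outputs; matplotlib rendering would depend on
backend and dpi.

## Segmentation and augmentation rules

Classes are balanced against the largest never-augmented class (RBBB) by
four rules (per lead, windows of L = 1,000 samples):

| rule | classes | windows |
|---|---|---|
| two_if_long | Normal, AF, STD | 2 consecutive from sample 0 if duration ≥ 10 s, else 1 |
| three_if_long | I-AVB, PAC, PVC | 3 if ≥ 15 s, 2 if 10–15 s, else 1 |
| multi_pass | LBBB, STE | per start offset ∈ {0, 200, 400}: consecutive windows, ≤ 8 per pass |
| single | RBBB | 1 from sample 0 |

Interpretation choices: duration thresholds are **inclusive** (a 10.00 s
recording yields two windows — required for 918 recordings with minimum
duration exactly 10 s to produce 1,836 segments); recordings below a
threshold still contribute one window; the middle band of three_if_long
yields two; multi-pass offsets are 0-based; windows within a pass never
overlap. Records shorter than 5 s are rejected.

## Synthetic generator

There is no public micro-dataset small enough for unit tests, so the
generator emulates the study conditions: 12-lead records of 6–60 s at
500 Hz with one rhythm label. Beats are sums of Gaussian bumps (P, QRS as
Q/R/S triplet, T) placed at generated beat times; class morphology is a
small rule table: regular RR (CV 0.02) for Normal; RR CV ≥ 0.25 with
suppressed P and 6.5/8.1 Hz fibrillatory ripple for AF; PR 0.30 s vs
0.16 s for I-AVB; globally wide (or notched) QRS for LBBB/RBBB; ST offset
∓0.15/+0.20 mV for STD/STE. PAC/PVC render **trigeminy**: every third beat
arrives early (coupling 0.65 RR) and is followed by a compensatory pause
(1.35 RR), premature beats being narrow (PAC) or wide without P (PVC).
Trigeminy — the standard presentation of frequent ectopy — guarantees that
every 5 s window expresses the class morphology, which a segment-labeled
classification task requires; sporadic ectopy would make some windows
indistinguishable from normal rhythm and turn segment labels into label
noise. Ground-truth beat times are stored on the record. Leads beyond the
first are fixed scaled/sign-flipped copies of the primary waveform plus
independent noise (default SD 0.01 mV) — adequate because all downstream
stages treat leads independently.

What the generator does **not** emulate: real 12-lead vector
electrocardiography, baseline wander, muscle/powerline artifacts, beat-level
morphology variability, or inter-patient variation. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that RP textures
separate distinct rhythm morphologies; they say nothing about accuracy on
clinical recordings.

The test/demo default is the 3-class toy set (Normal, AF, PVC): regular,
irregular-RR and wide-premature-beat rhythms, chosen to be well separated
so desk-scale training results are meaningful.

## Classifier

The network is written on a small self-contained NumPy layer library
(im2col convolutions, batch normalization, max/global-average pooling,
channel-concatenating branches, scaled residual addition, Adam,
softmax/cross-entropy), with hand-derived backward passes verified against
numerical differentiation in the test suite. Architecture: a stem of nine
'same'-padded convolutions and two max-pools (downsampling ×8), nA
A-blocks (1×1 branches plus two stacked 3×3), reduction-A, nB B-blocks
(1×1 plus 1×7/7×1), reduction-B, nC C-blocks (1×1 plus 1×3/3×1), global
average pooling, linear head, softmax. Block branch outputs are
concatenated, projected by a linear 1×1 convolution back to the block's
input width and added to the input scaled by 0.1 (the customary residual
stabilization for this family), then ReLU.

Defaults: block counts (5, 10, 5) and width scale 1.0 follow the canonical
published family; the full-profile parameter count is reported by
`Network.n_parameters()` but not asserted against any external figure,
since head width and input handling of reference implementations vary.
The `tiny` profile (input 75 px, blocks (1, 2, 1), width 0.25, ≈ 0.66 M
parameters) is the test and demo default.

Training: Adam with default moments, lr 0.001, cross-entropy; batch size
128 by default (32 in desk-scale runs, where the training sets are a few
hundred images). After each epoch the model is scored by macro-F1 on the
validation fold and the best snapshot is kept. Identical seeds give
identical logs to floating-point tolerance. Model selection uses macro-F1
because it is the protocol's reporting metric. An optional
`pretrained_weights` path supports transfer learning; the default is
random (He) initialization — no weights are shipped.

## Evaluation protocol

`split_dataset` draws a stratified 20 % test set per class, then a
stratified k-fold (default 5) partition of the remainder: four fifths
train, one fifth validation, rotating. Stratification defaults to the
**recording** level so that all segments (and leads) of one recording stay
on the same side of every split — segment-level splitting leaks
near-duplicate windows between train and test and inflates scores; segment
level is available via `stratify_level="segment"` for protocol-fidelity
runs. Both per-segment evaluation (default; each lead-segment image is one
sample) and the recording-level view can be derived from the reported
confusion matrices.

Metric conventions: precision/recall/F1 are 0 when their denominator is 0
(warned); report tables round to 3 decimals, half-up; macro scores are
unweighted class means. `run_experiment` chains
resample → segment → encode → split → train → test, embeds a full
configuration fingerprint in the report, and exposes `max_folds` to cap
how many folds are trained in compute-limited runs (the split plan itself
is always complete). `rank_leads` repeats the experiment per single lead
and sorts by test macro-F1.

## Problem sizes of the shipped runs

Desk-scale runs use the tiny profile at 75 px on the 3-class toy set with
200 segments per class (100 ten-second single-lead records per class), 12
epochs, batch 32, one trained fold — about two minutes on one CPU and a
test macro-F1 well above 0.9. These sizes are the package's chosen
demonstration scale; headline-scale replication (thousands of recordings,
299 px, ~50 M parameters, full 5-fold) is supported by the same code paths
via `ArchConfig()` defaults but requires external data and far more
compute.

## Known limitations

- The NumPy network is CPU-only and unoptimized for large inputs; the full
  299-px profile is buildable and runnable but not practically trainable
  here.
- The WFDB dialect is a minimal header+int16 pair (gain 1000/mV), not a
  full implementation of the format family.
- The synthetic generator's realism limits (above) mean reported toy
  F1 scores are upper bounds relative to clinical data.
- Recurrence-plot quantification measures (determinism, laminarity) are
  out of scope; only the imaging path is provided.
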