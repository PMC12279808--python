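# Methods

## Scope and design

The package models a three-part precision-spraying system for row-planted
corn: (1) a lightweight single-class whorl detector, (2) a spray-decision
rule over per-frame detections, and (3) the timing chain that converts a
detection ahead of the release funnel into an on-target granule drop. All
three are implemented as plain Python/numpy so every stage is testable on a
desktop without a GPU; the neural layers run on a small tape-based autodiff
core (`gmacorn.autograd`) written for exactly the operator set the
detectors need.

## Detector architectures

**Baseline.** The reference graph is YOLOv8n at width 0.25 / depth 0.33:
stride-2 stem, four C2f stages, SPPF, FPN+PAN neck, anchor-free decoupled
head with a 16-bin distribution-focal box parameterization. Configured for
a single class it has 3,011,027 learnable parameters and 8.1 GFLOPs at
640×640 (2 FLOPs per multiply-accumulate, convolutions only — the
fused-model convention). Batch-norm scale/shift pairs are counted as
learnable; the fixed expectation kernel of the box decoder is not.

**Lightweight (GMA) variant.** The backbone is a Ghost-HGNetV2: two
stride-2 stem convolutions, then four stages of HGBlocks — each block runs
three GhostConv(s=2) layers, concatenates the input with every
intermediate output, and fuses them with a 1×1 squeeze/excite pair, with a
residual where shapes allow — joined by stride-2 depthwise downsampling.
SPPF and a SimAM gate sit at the P5 position. The neck mirrors the
baseline but every C2f is a CM block: each bottleneck output passes
through an MLCA gate (two 1-D kernels, ≈6 extra weights per block). The
head is identical to the baseline's, so the two variants are drop-in
compatible.

No channel table is published for this design; the printed complexity
figures are treated as the specification of correctness. The default stage
table (stem 32/32; per-stage mid/out widths 12/48, 32/64, 66/128, 114/256;
neck 64/128/256) was selected by an integer search so that the deploy
parameter count, the FLOPs and the parameter reduction against the
baseline land at 2.3M / 6.8G / 23.3% (one-decimal rounding) — the same
numbers `scripts/acceptance.py` re-measures. `ArchConfig.width` scales the
table uniformly for small experiments (tests use width 0.25, ~0.5M
parameters).

Because the MLCA local grid is 5×5, the GMA variant requires inputs of at
least 160×160 (P5 stride 32); smaller inputs raise a pooling error by
design rather than silently changing the attention geometry.

## Attention operators

*GhostConv* produces `n/s` channels with a dense k×k convolution
(BN + SiLU) and the remaining `n − n/s` with per-channel depthwise d×d
transforms (BN, no activation). Compression and FLOP ratios both reduce to
`s·c·k² / (c·k² + (s−1)·d²) → s` for wide layers; defaults s=2, k=d=3.

*SimAM* assigns activation `t` of a channel the minimal energy
`e* = 4(σ̂²+λ) / ((t−μ̂)² + 2σ̂² + 2λ)` and weight `sigmoid(1/e*)`, with
μ̂, σ̂² the spatial mean and variance of the channel (variance uses the
M−1 denominator over M = H·W positions). λ defaults to 1e-4, the value
used in the original parameter-free attention formulation; it is never
stated in the system description this package follows. The closed form is
the exact minimizer of the binary-discrimination energy; tests verify it
against Nelder-Mead minimization to <1e-4 on random problems.
Single-pixel channels return the input unchanged with a warning instead of
dividing by zero.

*MLCA* pools to a g×g local grid (g=5) and to a global descriptor, runs a
1-D convolution across channels on each (kernel from the ECA rule: nearest
odd to log2(C)/2 + 1/2), blends the two sigmoid gates 50/50, and
multiplies the nearest-bin-upsampled gate onto the input.

## Label assignment and loss

The lead head uses task-aligned assignment: candidates are anchors whose
center lies in the ground-truth box, ranked by `score^0.5 · IoU^6`, top-10
per target, conflicts resolved by the higher metric, soft targets
normalized per target. The auxiliary head uses the same rule with the
candidate region enlarged ×2 about the box center and top-k doubled, and
its positive set is defined as the union with the lead positives, so
coarse ⊇ fine holds by construction (lead-claimed anchors keep their fine
mapping). SimOTA (dynamic-k from summed top-q IoUs, lowest-cost picks,
cheapest-claim conflict rule) is available as an alternative assigner.

The loss is the stock composition: BCE classification + CIoU + two-bin
distribution-focal regression, gains 7.5/0.5/1.5, aux weight 0.25 —
conventional values, since the system description names "a new loss
function" without formulas.

## Smoke training

`train_smoke` runs plain SGD (lr 0.01, momentum 0.937, weight decay
5e-4) and returns the per-step total loss; it is bit-deterministic given a
seed. The suite trains a width-0.25 variant on 16 synthetic 160×160
scenes for 50 steps — sizes chosen so the whole loop is a desk-scale
check of gradient flow, not a performance claim. Note that per-step loss
traces are intrinsically noisy even on a single repeated batch: targets
are re-assigned dynamically every step and batch-norm statistics move, so
descent is asserted on 10-step block means (which decrease strictly),
while the end-to-end reduction is large (>10×).

## Decision engine

The trigger test is center-point containment in the configured rectangle,
edges inclusive — the decision routine receives only the detection center,
so box-overlap semantics are deliberately not used. Detections are assumed
NMS-filtered at conf 0.25 / IoU 0.45 (the field operating point). A
refractory window (default 15 frames ≈ 0.5 s at 30 fps) debounces the
region so one plant crossing emits one packet; all detections triggering
in the same frame emit packets (multi-plant frames), after which the
window closes. Packets are ASCII `X<x>,Y<y>,C<round(100·conf)>\n` and
round-trip losslessly through the parser; the serial port is abstracted as
a byte sink.

## Delivery timing and simulation

Free-fall time `T2 = sqrt(2(H1−H2)/g)`, travel time `T3 = L1/V1`, and the
programmed delay `T4 = T3 − T1 − T2`; negative T4 raises an infeasibility
error. Granules are released with zero horizontal velocity relative to the
funnel; drag and wind are omitted (their effect on solid granules is
negligible at these drop heights). Per-plant speed variation is modeled as
a Gaussian perturbation of V1; the controller recomputes T4 from a sensed
speed with a separate estimation-error knob, so perfect sensing gives
exact compensation and estimation error degrades precision. Timing jitter
adds Gaussian noise to the release instant. A plant is *identified* if
detected and *delivered* if the landing point falls within the layout
tolerance, so delivered ⇒ detected and
rate = accuracy × precision holds exactly on every run.

Scenario geometry defaults (L1 = 1 m, H1 = 1 m, H2 ≈ 0.51 m, V1 =
0.5 m/s) are illustrative: the field protocol this mirrors states only
that the camera sits ~0.5 m above the plants, so no calibrated values
exist to adopt.

## Metrics

AP uses greedy confidence-ordered matching (ties by detection index, each
ground truth matched once, IoU ≥ 0.5) and the all-point interpolated
(precision-envelope) integral. Field metrics are percentages rounded
half-up to one decimal. Trial summaries take the mean and sample (n−1) SD
over the per-group values *after* rounding them to one decimal — the
convention that exactly reproduces summaries computed from printed trial
tables; the n−1 denominator is likewise the only choice consistent with
such tables.

## Synthetic scenes

Scenes are flat-shaded procedural geometry: Perlin-like soil noise,
radially arranged elliptical leaves, a bright central whorl per plant, one
YOLO-format box per whorl. Augmentation covers brightness within ±25%,
rotation (boxes as rotated-extent AABBs about the exact image center,
clipped, dropped when fully outside), and directional motion blur; the
augmentation multiplicity per image is a parameter, since published
dataset expansions imply different factors. Detection streams translate
plants through the frame at a configurable px/frame speed with optional
center jitter and dropouts (nominal 30 fps).

What passing tests show — and do not show: the synthetic data exercises
shape contracts, assignment logic, gradient flow and the decision/timing
pipeline end to end. It does not emulate real canopy texture, occlusion
statistics, or lighting, so no conclusion about detection accuracy on
field imagery follows from it; the published mAP figures require the
original field datasets and full-scale training, which are out of scope
here.

## Numerical choices

float32 weights/activations; batch-norm eps 1e-3, momentum 0.03; BCE
probabilities clamped at 1e-7; CIoU's trade-off coefficient detached from
the gradient; DFL targets clamped to reg_max − 1.01. Profiling counts
MACs over convolutions (including depthwise and the 1-D attention
kernels); `size_mb` is a half-precision serialization estimate
(2 bytes/parameter) and is flagged approximate, since container formats
differ.
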