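# Methods

This note records the models, conventions and design choices behind
`shrimpdet`, at the level a maintainer needs to modify the package or
interpret its numbers.

## The detection problem

Residual feed particles on a submerged feeding tray are small (mostly
under 32 px at 640-px scale), dense, frequently elongated, mutually
adherent, and imaged through turbid water over a periodic mesh with
bubbles, glints, feces-like debris and shrimp bodies as distractors.
General-purpose one-stage detectors miss dense clusters, confuse tray
texture with particles, and localize slender particles poorly. The three
components below target those failure modes while *reducing* model size.

## EnSimAM: parameter-free multi-branch attention

Given a feature map X ∈ R^{C×H×W}, three per-channel attention maps are
computed and fused:

* **Global (energy) branch.** Per channel, with spatial mean μ̂ and
  variance σ̂², each neuron t receives `1/e* = (t−μ̂)²/(4(σ̂²+λ)) + 1/2`
  and weight `σ(1/e*)`. This is the closed-form minimizer of the
  linear-separability energy that underlies SimAM; neurons far from their
  channel mean are distinctive and get up-weighted. λ (default 1e-4)
  regularizes flat channels. The variance divisor is M−1 by default
  (matching the reference SimAM implementation); divisor M is available
  via `variance_correction="M"`; a single-element channel defines
  variance 0.
* **Local variance branch.** A 3×3 box filter with the fixed divisor 9
  gives μ_local and σ²_local; the weight is `σ(α·σ²_local)` (α default 1).
  Flat regions settle at exactly 0.5. Borders are zero-padded by default
  (consistent with the fixed divisor); replicate padding is available.
* **Edge branch.** Sobel cross-correlations Gx, Gy per channel (no channel
  mixing); weight `σ(β·√(Gx²+Gy²))` (β default 1).

Fusion weights derive from feature intensity, not learning:
`ω_g = ‖X‖₂/(‖X‖₂+ε)` per channel over spatial positions, with the
remainder split evenly between local and edge. They sum to 1 by
construction. **Known degeneracy:** the literal L2 norm saturates ω_g → 1
for any map that is not near-zero, effectively reducing the mechanism to
SimAM; `fusion_norm="rms"` divides the norm by √(HW) first and keeps the
auxiliary branches active. The literal form remains the default because it
is the published formula; the switch exists for sensitivity analysis.

The fused map modulates the input multiplicatively (X ⊙ A, the SimAM
application convention). The operation carries zero learnable parameters;
in the detector it is inserted after each of the four neck fusion blocks.
Two implementations exist — a plain-NumPy reference API and an autograd
layer — and are tested to agree to 1e-9; the layer adds 1e-12 inside the
edge-magnitude square root so its gradient is finite at zero gradient.

## EnWIoU: orientation-aware weighted IoU loss

For a predicted and a ground-truth box in center format:

* `L_IoU = 1 − IoU` (standard definition).
* Outlier degree `β = d/C`: center distance over the diagonal of the
  minimum enclosing box of the pair; β ∈ [0, 1). A config switch
  `beta_squared` provides the squared reading for sensitivity tests.
* Focusing gain `r = β/(δ·α^{β−δ})` with defaults α = 1.9, δ = 3. r = 1 at
  β = δ; r → 0 at β → 0. Both r and β are treated as constants per step —
  no gradient flows through them (the weighted-IoU "gradient gain"
  convention). Note r = 0 at β = 0 zeroes the loss even for
  size-mismatched concentric boxes; this literal behaviour is kept, with
  an optional `r_min` floor (default 0 = off).
* Orientation modulation γ: with per-box aspect `max(w,h)/min(w,h)`, the
  pair is *elongated* if either aspect exceeds τ = 2.0. Principal
  directions are consistent iff both boxes are wide (w > h) or both tall
  (w ≤ h; squares count as tall). γ = 1−η (consistent), 1+η
  (inconsistent), or 1 (not elongated), with η = 0.1.

The loss is `clamp(r · L_IoU · γ, 0, 1)`; the clamp bounds are fixed.
The batched differentiable form agrees with the scalar formula-literal
implementation to 1e-6 over 1000 random pairs (tested).

## RepGhost: re-parameterizable ghost convolution

A block replacing a dense conv of n output channels: a primary k×k conv
produces m = n/s intrinsic channels; each spawns s−1 ghost channels via a
depthwise d×d transform (d = 3 by default; the cheap transform is
abstract in principle, depthwise-conv + BN is the GhostNet convention);
output is the concatenation [intrinsic, ghosts] (an `add` merge mode
exists). MAC cost falls from `n·c·k²·h·w` to
`m·c·k²·h·w + (s−1)·m·d²·h·w`.

During training each cheap transform may carry a parallel
normalization-only shortcut. `fuse()` folds every BN into its conv
(`w' = w·γ/√(σ²+ε)`, bias from β, μ) and sums same-support branches —
the BN-only branch becomes a centered delta kernel — yielding one conv +
one depthwise conv per path. Equivalence with the training-time graph in
eval mode is ≤ 1e-5 elementwise (tested over strides {1,2}, kernels
{1,3}, 100 random inputs, in float64). Fusing before any forward uses the
initialization statistics; fusing twice warns and is a no-op.

## Detector assembly and variants

Fixed topology, configurable widths: base channel plan (64, 128, 256,
512, 1024) × `width_mult` capped at `max_channels`; repeats scale with
`depth_mult`. The nano scale (0.25 / 0.5) gives channels (16, 32, 64,
128, 256). Backbone: stem and three strided convs, C3k2 stages (split-
transform-merge with bottleneck or C3k inner units), SPPF, and a
position-sensitive attention stage (C2PSA). Neck: PAN with two top-down
and two bottom-up fusions. Head: decoupled anchor-free, three levels at
strides 8/16/32, distribution-focal box regression with `reg_max` = 16
bins, class branch with depthwise separable convs. The baseline variant
reproduces the public nano detector exactly (2,624,064 learnable scalars
at 80 classes, matching the published count once the 16 fixed
distribution-decode weights are added; 2.590 M at 1 class).

**Ghost placement.** The published complexity pair for the lightweight
variant (−19.7 % parameters, −14.6 % GFLOPs) cannot come from replacing
only the C3k2 inner bottlenecks (−3.7 % parameters) nor from ghosting the
whole backbone (−21 % of GFLOPs — too much arithmetic removed). Measuring
per-component savings shows the pair is reproduced by ghosting the *deep*
backbone — the stride-8 C3k2 stage through SPPF — while keeping the
high-resolution stem/early stages (capacity for tiny targets, and most of
the arithmetic) and the attention stage dense. That mapping,
`ghost_scope="deep"`, is the default and yields 2.073 M params / 5.48
GFLOPs against the baseline's 2.590 M / 6.31; the other scopes remain
available in the config.

**Losses and assignment.** Total = λ₁·obj + λ₂·cls + λ₃·loc with defaults
(1.0, 0.5, 7.5). obj is confidence BCE over all anchors and classes
against task-aligned soft targets, normalized by the target-score sum;
cls is softmax cross-entropy at positive anchors (identically zero for a
single class); loc is the mean EnWIoU over positive anchor/target pairs
on decoded pixel boxes. Assignment is task-aligned: candidates are
anchors whose center lies inside a gt box, scored by
`score^0.5 · IoU^6`, top-10 per gt, conflicts resolved by IoU; the
confidence target of a positive is its normalized alignment. This
assigner is standard detector engineering, not part of the method's
contribution. Training is plain Adam (default lr 5e-3), seeded and
reproducible; inference decodes the focal distribution, thresholds
confidence and applies class-aware greedy NMS (defaults conf 0.25, IoU
0.45); arbitrary image sizes are letterboxed.

The whole stack runs on `shrimpdet.nn`, a compact NumPy reverse-mode
autograd (im2col convolutions with grouping, batch norm with running
statistics, pooling/upsampling/softmax/attention primitives, Adam).
Activations default to float32; numerically sensitive tests (fusion
equivalence) build models in float64.

## Complexity conventions

Parameters = learnable scalars (batch-norm affine included; fixed
distribution-decode bin weights excluded). GFLOPs = 2 × multiply-
accumulates of conv/linear layers at a stated square input; normalization,
activations, pooling and the parameter-free attention are excluded, which
matches the dominant profiler convention for this model family. Under this
convention the 1-class baseline measures 6.31 GFLOPs at 640 px (the same
code at 80 classes gives 6.48, matching the published baseline figure).

## Synthetic benchmark

The generator emulates the *statistics* of real tray imagery, not its
appearance. Per scene (pure function of params + seed): dark mesh
background with periodic weave lines and low-frequency mottling; particle
count U{8..32}; sqrt-box-area drawn from U(12, 30) px with probability
0.85 and U(34, 64) otherwise (640-px reference units, so normalized
statistics are resolution-independent); with probability 0.40 a particle
is elongated (shape aspect U(2.8, 5.5), orientation within ±8° of an
image axis — pellets settle aligned, and the margin keeps the *bounding
box* aspect above the 2.0 threshold), otherwise near-round (aspect
U(1, 1.6), free rotation); placement N(0.5, 0.18) per coordinate
(center-biased); with probability 0.35 a particle is placed adhering to
an earlier one; multiplicative linear illumination gradient (±35 %),
Gaussian turbidity blur (σ = 0.8 px), sensor noise. Unlabeled
distractors: bubbles, glints, feces-like debris, and large shrimp
silhouettes drawn *over* the particles; a particle whose visible area
drops below 25 % loses its label. "Small" is operationalized as box area
< (32/640)² normalized (COCO small at the reference scale) and
"elongated" as bounding-box aspect > 2; 200 seeded scenes reproduce the
0.85 / 0.40 targets within ±0.05 (tested).

What the generator does *not* model: photorealistic water optics, real
pellet texture, camera artifacts, or inter-farm domain shift. Passing the
desk-scale training check therefore demonstrates that the training loop,
assignment, losses and decoding work end-to-end — not that the model
would reach any particular accuracy on real farm data.

Augmentations: the *complete* pipeline is random crop (a box survives if
≥ 30 % of its area remains), right-angle rotation, horizontal flip, and
brightness/contrast jitter — rotation is restricted to multiples of 90°
because samples carry boxes, not masks, and right angles keep label
geometry exact. The *local* pipeline crops labeled particles from donor
scenes and pastes them at center-biased free locations (label IoU ≤ 0.1
enforced, feathered alpha blending), appending their labels.

## Evaluation conventions

mAP uses greedy per-image matching (score-descending, one match per gt,
IoU ≥ threshold, class-aware), 101-point interpolated AP (the all-point
variant is kept as a cross-check; they agree within 0.01 on randomized
suites), and mAP@0.5:0.95 as the mean over IoU 0.50:0.05:0.95. P/R are
reported at the max-F1 confidence; a fixed threshold can be passed
instead. Classes without ground truths are excluded from the mean with a
warning.

## Desk-scale experiment sizes

CPU budgets shape the stock experiment sizes: the tiny model variant
(width 1/8, `reg_max` 8, no C2PSA stage, 0.46 M params) trains on 64 easy
synthetic 160-px scenes for 30 epochs in ≈ 4.5 min single-threaded,
reaching validation mAP@0.5 ≈ 0.95 (seed 0) — a sanity floor showing the
pipeline learns, chosen deliberately far above chance but far below
real-data difficulty. The full-scale dataset split check (3461 scenes →
3115/346 at ratio 0.9) renders on a 96-px canvas since the split and
label statistics are resolution-independent.

## Known limitations

* The baseline GFLOPs figure depends on the profiler convention; ours
  counts conv/linear MACs only (documented above).
* The literal fusion-norm degeneracy in the attention (ω_g ≈ 1) means the
  local/edge branches contribute little unless `fusion_norm="rms"`.
* Training at nano scale / 640 px is possible but slow on the NumPy
  backend; the package's training experiments are deliberately tiny.
* NMS and matching are O(n²) per image — adequate for tray scenes
  (tens of objects), not for thousand-object scenes.
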