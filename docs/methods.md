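# Methods

This note records the modelling conventions, parameter choices, and design
decisions behind `mugennet`, and what the synthetic-data experiments do and
do not demonstrate.

## Numerical foundation

The network runs on a small reverse-mode autodiff engine over numpy
(`mugennet.nn`): elementwise ops with broadcasting, batched matmul,
reductions, im2col-based 2-D convolution, 2×2 max pooling, and a
deterministic ×2 bilinear upsampling implemented as a fixed linear map
(half-pixel-center weights; its gradient is the transposed map).  Every
primitive is checked against central-difference derivatives in
`tests/test_nn_core.py`, and convolution additionally against
`scipy.signal.correlate2d`.  Parameters default to float32; float64 is used
in gradient checks and in all metric/loss arithmetic.  Weight
initialisation draws from a single `numpy.random.Generator` seeded from the
model config, and batch order comes from the run seed, so a full training
run is bit-reproducible (the test suite asserts identical first-step losses
and identical checkpoint-roundtrip evaluations).

## Architecture conventions

* Arrays are (batch, channel, H, W), row-major, origin top-left; spatial
  sizes must be divisible by 16.
* Patch size is 16 (the ViT-B/16 convention).  Position codes are fixed 2-D
  sinusoids, so the transformer accepts any divisible input size without
  re-interpolating a learned table.
* Channel dims per fusion level default to (64, 32, 16) in the `desk`
  preset and (256, 128, 64) in the `paper` preset, with a 1/2-scale decoder
  stage of 8 / 32 channels; the squeeze bottleneck ratio r is 4 / 16
  respectively so C/r stays integral at every level.
* The SE block on transformer features uses the standard global average
  squeeze; the CNN-side channel attention uses global max pooling only —
  the explicit modification this architecture makes to CBAM.
* Fusion: `y = learned(concat(t̂, r̂)) + skip(concat(t, r))` with
  learned = 1×1 conv → BN → ReLU → 3×3 conv and skip = 1×1 conv.  Zeroing
  the final learned conv reduces the module to its skip path exactly (the
  residual-identity property asserted in tests).  The "reduce to one
  channel" role of the per-level output stack is carried by the three
  1-channel supervised heads (S_t, S_r, S_z); no additional per-level side
  heads are created, so every parameter receives gradient.
* Decoder ladder: z₁ = up(y₁) at 1/8; the attention gate computes its
  coefficients on the common grid of (zᵢ, yᵢ₊₁) — upsampling the gating map
  first if it is genuinely coarser — multiplies the fused map, and the
  gated result is upsampled ×2 (bilinear + 3×3 conv + BN + ReLU) to the
  next stage, ending at 1/2 scale before the final upsample + 1×1 sigmoid
  head.  This realises both stated contracts: the ladder
  1/8 → 1/4 → 1/2 → 1 and "gate output is 2× the gating map's resolution".
* All upsampling inside the feature path is bilinear ×2 + 3×3 conv
  (checkerboard-free); the only exception is the two 1-channel side-output
  logit maps, which are upsampled by plain bilinear interpolation before
  the sigmoid, since convolving a single logit channel adds nothing.
* Ablations: `backbone` = CNN encoder, plain concat-free fusion, plain
  additive top-down decoder; `backbone+tb` adds the transformer branch
  (attention off); `backbone+cb` adds the max-pool channel attention (no
  transformer); `complete` adds SE + channel attention + attention-gated
  decoding.  This mapping guarantees the complete model strictly dominates
  both single-addition configurations in parameter count.

## Losses

Boundary weights are `w = 1 + gain·|meanpool_k(G) − G|` with k = 31 and
gain = 5; the window mean uses reflective borders so a locally constant
mask keeps w = 1 through the image edge, and w is invariant under mask
complement.  The weighted BCE normalises by Σw (scale-free: a constant
weight map cancels exactly), and the IoU term is the soft differentiable
form 1 − Σw·pg / Σw·(p+g−pg) with an ε-guarded ratio so an empty mask with
an empty prediction scores zero loss.  The combination L = L_IoUʷ + n·L_BCEʷ
uses n = 6/5, weighting the pixel-level constraint slightly above the
global overlap constraint.  The three-output total uses α = β = γ = 1 by
default; all three are exposed in `LossConfig`.

## Metrics

Dice and IoU are set overlaps on the prediction binarised at 0.5; MAE,
F_β^ω, S_α and E_ξ consume the continuous map.  Conventions worth stating:

* F_β^ω uses β = 1/2 and ω = 1; with uniform weighting the weighted
  precision/recall reduce to the soft precision/recall computed from the
  continuous confusion counts TP = ΣDG etc.
* S_α mixes the object term (foreground/background mean-and-spread scores
  2x̄/(x̄²+1+2λσ), population σ) with the region term at α = 0.5.  The
  object mixing weight is fixed at μ = 0.5.  The region term cuts both
  maps into four quadrants at the ground-truth centroid and averages an
  SSIM-style similarity (sample statistics, N−1) weighted by quadrant
  pixel area.  Degenerate masks fall back to 1 − mean(pred) (empty mask)
  or mean(pred) (full mask).
* E_ξ is the mean pixelwise alignment 2φ_G·φ_D/(φ_G²+φ_D²) of the
  mean-centered maps, reported clamped to [0,1], with no additional
  enhancement function applied to the alignment matrix.  A pixel where
  both centered maps vanish contributes 1 (agreement), so identical
  non-constant pairs score exactly 1; two constant maps score 1 when equal
  and 0 otherwise.
* Empty-vs-empty Dice/IoU is defined as 1 (perfect-agreement convention),
  logged at debug level.

Every metric is validated against an independently coded oracle — naive
double loops for Dice/IoU/MAE/F_β^ω/E_ξ, a straight-line transliteration of
the structure-measure recipe for S_α — on hundreds of random pairs.

## Synthetic scenes

The generator emulates what matters to this segmentation task: deformable
blob foregrounds (base radius drawn from `radius_range`, outline perturbed
by harmonics 2–5 with total relative amplitude ≤ 0.35), brighter/redder
than a smoothly mottled mucosa-like background, optionally blurred
boundaries, and additive Gaussian noise.  Default spec: 64×64, one blob of
radius 6–14 px (mean foreground fraction ≈ 8%, within the documented
2–30% small-to-medium band), boundary blur σ = 1, contrast 0.35, noise
σ = 0.03.  Per-sample streams derive from `SeedSequence((base_seed, index))`
so generation is order-independent and byte-reproducible.  The scenes have
no specular highlights, instruments, perspective or motion blur; passing
the desk-scale experiments therefore demonstrates that the architecture,
losses and pipeline are implemented correctly and can fit this family of
shapes, not that the model reaches clinical-grade accuracy on real
colonoscopy data — that claim would require the public polyp datasets and
pretrained encoder weights, which are deliberately outside this package's
test loop.

## Training protocol and problem sizes

The `paper` preset mirrors the published protocol (256×192 inputs, ViT-B/16
geometry, ResNet-34 widths, Adam at 1e-4, batch 16, 30 epochs, 7:2:1
split).  The test suite and acceptance script run the `desk` preset:
width-reduced model (~0.4 M parameters), 64×64 synthetic scenes, Adam at
1e-3 — chosen once as a standard overfitting rate for a model this size —
and full-batch steps on 8 images.  Under these study conditions 200 steps
reach training mDice ≥ 0.95, and the smoke runs show strictly decreasing
epoch losses.  Checkpoints are numpy `.npz` state dicts; best-checkpoint
selection uses validation mDice at threshold 0.5.

## Known limitations

* No pretrained-weight loading is shipped; `load_state_dict` is the hook a
  user would feed converted weights through.
* The attention-gated decoder passes decoder state into the gates only (the
  stated data flow); non-gated ablations use additive top-down aggregation.
* Single-CPU execution only; no multi-GPU, test-time augmentation, CRF
  post-processing, or FPS benchmarking.
* The learning-rate schedule is constant (no decay), matching the stated
  protocol's silence on scheduling.
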