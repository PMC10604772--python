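# Methods

## Problem setting

Histological H&E tiles of osteosarcoma sections carry two obstacles for
automated nucleus segmentation: acquisition/transmission noise
(predominantly Gaussian sensor noise and salt-and-pepper impulses) and
the cost of running large segmentation networks on modest hardware.
The package implements a two-stage answer: an edge-preserving guided
filter as a cheap deterministic denoiser, and a U-shaped transformer
whose attention cost is linear in the pixel count.

## Guided-filter denoiser

The filter assumes the output is locally linear in a guidance image K
within each (2r+1)×(2r+1) window: p = a_k·K + b_k, with
a_k = cov(K,q)/(var(K)+ε) and b_k = mean(q) − a_k·mean(K); per-pixel
output averages the coefficients of all covering windows.  Guidance is
the tile's own BT.601 grayscale (0.299, 0.587, 0.114); color tiles are
filtered per channel with the shared gray guide.

Parameters (on normalized [0,1] intensities):

| parameter | default | meaning |
|---|---|---|
| `radius` r | 4 px | window half-width; larger smooths more |
| `epsilon` ε | 0.01 | variance floor; ε≫var ⇒ box mean, ε≪var ⇒ pass-through |
| bilateral σ_spatial / σ_range | 3 px / 0.1 | optional post-smoothing, disabled by default |

Numerical choices:

* Box means use separable cumulative-sum running windows with
  count-normalized borders, O(N) regardless of r; constant images are
  exact fixed points everywhere including borders.
* Zero-variance windows with ε = 0 are assigned the ε→0⁺ limit
  a = 0, b = mean(q), which still reproduces the input on constant
  regions and keeps the self-guided ε = 0 case an exact identity.
* Analytic limits used as acceptance anchors: K = q, ε = 0 gives
  a ≡ 1, b ≡ 0 (identity); ε ≫ max var gives a → 0 and output →
  box_mean(box_mean(q)).
* The bilateral post-filter (shift-and-accumulate Gaussian
  range/spatial weights, window truncated at 3σ_spatial, edge padding)
  is shipped off by default: the pipeline treats it as an optional
  refinement stage rather than a mandatory step.

## Segmentation network

Layout for input H×W (divisible by 16), base width C:

* overlapping patch embedding: dense projection of 7×7 neighborhoods,
  stride 4, padding 3 → (H/4, W/4, C) tokens;
* encoder stage 1 (2 Dual blocks @ C) → 2×2 merge → stage 2 (2 @ 2C)
  → merge → stage 3 (2 @ 4C) → bottleneck (2 @ 4C, at H/16);
* decoder mirrors with patch expanding (linear to 2d + pixel-shuffle,
  halving channels), skip fusion, and Dual blocks; a final 4× expansion
  (to d/4 channels) feeds the linear class head.

A Dual Transformer block applies, post-residually: efficient attention
+ x; LayerNorm→Mix-FFN + x; transposed attention + x; LayerNorm→
Mix-FFN + x.  The Mix-FFN is FC → 3×3 depthwise conv on the grid →
GELU → FC with expansion 4 (the depthwise step supplies implicit
positional mixing, so the attentions themselves are position-free and
permutation-equivariant).

Attention conventions (the formulas leave the normalization axes open;
these choices make every factor a convex weight and keep cost linear in
token count N):

* efficient attention: ρ_q = softmax over the channel axis per token,
  ρ_k = softmax over the token axis per channel; the d_k×d_v context
  ρ_k(K)ᵀV is formed first.
* transposed attention: queries/keys L2-normalized per channel column
  (over tokens); the d×d map softmax(KᵀQ/τ) is normalized over its
  key-channel axis; τ is a learnable positive scalar per head (stored
  as log τ, initialized to 1).
* skip fusion (SCA): decoder tokens are linearly rescaled to the
  encoder width, projected to K and V; encoder tokens are projected to
  Q; the attention message is E = ρ_v(V)·(ρ_k(K)ᵀQ) with ρ_v, ρ_k over
  the token axis.  The module output is x1′ + x2 + E: the printed
  message alone has ~1/N token-mixing weights at initialization, which
  empirically starves the decoder of spatial detail (training collapses
  to all-background); the additive form keeps the skip's purpose —
  handing the decoder the encoder's spatial detail — while the global
  message is learned.

Initialization: Xavier-normal weights, zero biases, and — decisively —
zero-initialized output projections on every residual branch (attention
output and Mix-FFN second FC).  Each Dual block is therefore the exact
identity at initialization; without this the published optimizer
settings (lr 0.05, momentum 0.9) diverge within a few steps on the
post-residual stack.  All weight draws come from one config seed
(default 42).

Defaults: C = 64 full-size, C = 16 desk-scale; heads (1, 2, 4); class
decision at probability 0.5; foreground = nucleus.  The spec's
`dropout` field is validated but reserved: the reference training
regime runs with rate 0, and no stochastic regularization is applied.

## Loss and training

Total loss is 0.6·softDice + 0.4·BCE on the foreground probability
(two-class scores are collapsed to one logit, z = s₁ − s₀, so the BCE
is computed stably from logits).  Dice smoothing constant is 1.0 pixel.
Optimizer: SGD, base lr 0.05, momentum 0.9, weight decay 1e-4,
batch 4.  The kept checkpoint is the best validation-DSC epoch; early
stopping after 20 epochs without improvement replaces by-eye
convergence monitoring.  Denoising is applied to both training and
inference inputs by default (flag-controlled).  Runs are deterministic:
same config and seed reproduce identical losses and masks.

## Synthetic data

The generator emulates what matters for this pipeline: elliptical
nuclei in hematoxylin-like purple (RGB ≈ 0.35, 0.25, 0.55) on an
eosin-like pink background (≈ 0.90, 0.75, 0.85), a smooth low-frequency
sinusoid texture (amplitude 0.03 — smooth rather than white, so
denoising tests can separate texture preservation from noise removal),
Gaussian noise (σ = 0.05), salt-and-pepper impulses (2% of pixels) and
integer-translation augmentation.  Nuclei are placed without overlap by
rejection sampling (≤ 1000 retries), giving exact masks whose
connected-component count equals the nucleus count.  Defaults describe
512 px tiles; `SyntheticSpec.desk()` scales nucleus geometry down for
small tiles.

What the generator does **not** emulate: chromatin texture within
nuclei, touching/overlapping nuclei, stain variability across slides,
out-of-focus regions, or scanner compression artifacts.  Passing tests
therefore demonstrate that the implementation is correct and that the
pipeline learns and denoises under controlled conditions — not that the
reported clinical-data scores transfer.

## Problem sizes used by the test suite

Chosen as the package's own desk-scale regime: training acceptance runs
the C = 16 model on 20 training / 5 validation noisy 64 px tiles for 30
epochs (seed 42, a few minutes on one CPU); the single-tile overfit
check runs 200 steps; denoising utility is measured on 50 seeded 128 px
tiles; attention oracles use N ≤ 16, d ≤ 8; the guided-filter window
oracle uses images up to 32×32.

## Known limitations

* Pure-numpy training is practical at desk scale; the full-size
  regime (C = 64, 512 px, 500 epochs) is supported by the same code but
  is slow without accelerator-backed linear algebra.
* Only binary (nucleus/background) heads; no pretrained weights; no
  FLOPs accounting beyond parameter counts; no ROC/AUC reporting.
* PSNR uses the 8-bit convention (MAX = 255) regardless of internal
  normalization; identical images report +inf.
* Empty-mask conventions: both masks empty ⇒ overlap scores 1; exactly
  one empty ⇒ 0.
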