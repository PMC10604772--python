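# nucleoseg

Nucleus segmentation for H&E-stained pathology tiles, built for the
setting where images arrive noisy (older scanners, lossy transmission)
and compute is scarce: a fast edge-preserving **guided-filter denoiser**
followed by a **dual-attention U-shaped transformer** that segments cell
nuclei with attention costs *linear* in the number of pixels.

The package is aimed at computational-pathology researchers and
method developers.  Everything runs on CPU with numpy — the network,
its backpropagation and the SGD training loop are implemented on a
small, gradient-checked reverse-mode autodiff core — and every stage is
exercisable end-to-end on synthetic H&E-like tiles with exact
ground-truth masks, so no clinical data is required to use or test it.

## The method

**Stage 1 — guided denoising.**  The guided filter writes the output as
a local linear transform of a guidance image K (here: the tile's own
grayscale).  Per window ω_k of half-width r,

    a_k = cov(K, q) / (var(K) + ε),    b_k = mean(q) − a_k · mean(K),

and each output pixel averages the linear models of all windows that
cover it: p_i = ā_i·K_i + b̄_i.  High-variance (edge) windows get
a ≈ 1 (pass-through), flat noisy windows get a ≈ 0 (box-mean), so
Gaussian and salt-and-pepper noise is suppressed while nuclear
boundaries stay sharp.  All box means are O(N) running sums, so cost is
independent of the radius.

**Stage 2 — segmentation.**  A pure-transformer U-Net: an overlapping
patch embedding (7×7, stride 4) tokenizes the tile; encoder stages of
*Dual Transformer* blocks — efficient (spatial) attention
`ρ_q(Q)·(ρ_k(K)ᵀV)` followed by transposed (channel) attention
`V·softmax(KᵀQ/τ)` on L2-normalized queries/keys — alternate with 2×2
patch merging; a symmetric decoder upsamples with patch expanding and
fuses each skip through cross-attention (encoder tokens query the
decoder stream); a final 4× expansion and linear head give per-pixel
scores.  Neither attention ever materializes an N×N token map: both
work through d×d channel contexts.  Training minimizes
`0.6·Dice + 0.4·BCE` with SGD (lr 0.05, momentum 0.9, weight decay
1e-4, batch 4).

## Worked example

```bash
python examples/denoise_tile.py
```

```
noisy    PSNR:  20.08 dB
filtered PSNR:  24.44 dB  (gain +4.36 dB)
```

A synthetic 128 px tile corrupted with Gaussian noise (σ = 0.05) and 2%
salt-and-pepper impulses gains 4.4 dB of color PSNR from one pass of
the guided filter (r = 4, ε = 0.01): most impulse and sensor noise is
gone while nuclear edges survive.

```bash
python examples/train_and_evaluate.py
```

```
best validation DSC 0.9407 at epoch 29 (39 s)
mean over all tiles:
  Ac 0.9893  Pr 0.9396  Re 0.9671  DSC 0.9529  F1 0.9529  IoU 0.9104
```

This trains the desk-scale model (C = 16) for 30 epochs on 20 noisy
64 px synthetic tiles, then denoises and segments the whole set.  DSC
(Dice similarity) is the overlap between predicted and true nucleus
masks; 0.94 on held-out tiles means the model recovers nearly all
nucleus pixels despite the injected noise.  `examples/make_dataset.py`
and `examples/attention_complexity.py` demonstrate the generator and
the linear-complexity attention operators.

The same pipeline is scriptable from the shell:

```bash
nucleoseg simulate --n 100 --size 256 --out data --seed 42
nucleoseg denoise  --in data/images --out data/denoised --clean data/clean
nucleoseg train    --train-manifest data/train.txt --val-manifest data/val.txt --out run
nucleoseg predict  --checkpoint run/checkpoint.npz --in data/images --out run/pred
nucleoseg evaluate --pred run/pred --truth data/masks
```

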