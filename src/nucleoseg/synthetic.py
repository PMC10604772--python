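"""Synthetic H&E-like tiles with paired nucleus masks.

Real osteosarcoma pathology tiles are not redistributable, so the test
bed emulates their salient structure: hematoxylin-stained (purple)
elliptical nuclei on an eosin-tinted (pink) background with a smooth
low-frequency texture, corrupted by Gaussian and salt-and-pepper noise
and augmented by integer translations.  The generator is fully seeded
and deterministic; the paired mask is exact by construction.

The smooth sinusoid texture (instead of white noise) lets denoising
tests distinguish texture preservation from noise removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticSpec",
    "generate_tile",
    "add_gaussian_noise",
    "add_salt_pepper",
    "corrupt",
    "translate_pair",
    "augment_translate",
    "make_dataset",
]

#: hematoxylin-like nucleus and eosin-like background colors (R, G, B)
NUCLEUS_COLOR = (0.35, 0.25, 0.55)
BACKGROUND_COLOR = (0.90, 0.75, 0.85)


@dataclass
class SyntheticSpec:
    """Tile-generation parameters.

    The defaults describe the full-size regime (512 px tiles, as the
    real sub-images are cut); :meth:`desk` scales nucleus geometry down
    proportionally for small test tiles.
    """

    tile_size: int = 512
    n_nuclei: tuple = (10, 30)
    axis_range: tuple = (12.0, 32.0)  # semi-axis lengths, px
    nucleus_color: tuple = NUCLEUS_COLOR
    nucleus_sigma: float = 0.03
    background_color: tuple = BACKGROUND_COLOR
    background_sigma: float = 0.02
    texture_amplitude: float = 0.03
    gaussian_sigma: float = 0.05
    salt_pepper_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.tile_size % 16:
            raise ValueError("tile_size must be divisible by 16")
        if not (0.0 <= self.salt_pepper_fraction <= 1.0):
            raise ValueError("salt_pepper_fraction must be in [0, 1]")

    @classmethod
    def desk(cls, tile_size: int = 64, **kw) -> "SyntheticSpec":
        """Small-tile spec with nucleus geometry scaled by tile size."""
        f = tile_size / 512.0
        kw.setdefault("n_nuclei", (3, 8) if tile_size >= 64 else (1, 3))
        kw.setdefault("axis_range", (max(3.0, 12.0 * f * 2), max(5.0, 32.0 * f * 2)))
        return cls(tile_size=tile_size, **kw)


def _texture(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency sinusoid mixture on [-amplitude, amplitude]."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    tex = np.zeros((size, size))
    for _ in range(3):
        fy, fx = rng.uniform(1.0, 4.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        tex += np.sin(2 * np.pi * fy * yy + phase[0]) * np.sin(2 * np.pi * fx * xx + phase[1])
    tex /= max(1e-12, np.abs(tex).max())
    return amplitude * tex


def generate_tile(spec: SyntheticSpec, seed: int | None = None):
    """One clean tile plus its binary nucleus mask.

    Nuclei are filled, randomly oriented ellipses placed without overlap
    by rejection sampling (<= 1000 retries per nucleus); the mask's
    connected-component count equals the number placed.

    Returns ``(image (H, W, 3) in [0, 1], mask (H, W) in {0, 1})``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    size = spec.tile_size
    img = np.empty((size, size, 3))
    for c in range(3):
        img[:, :, c] = np.clip(
            rng.normal(spec.background_color[c], spec.background_sigma), 0, 1
        )
    img += _texture(size, spec.texture_amplitude, rng)[..., None]

    n = int(rng.integers(spec.n_nuclei[0], spec.n_nuclei[1] + 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    placed = 0
    for _ in range(n):
        ok = False
        for _ in range(1000):
            a = rng.uniform(*spec.axis_range)
            b_ax = rng.uniform(*spec.axis_range)
            theta = rng.uniform(0, np.pi)
            margin = max(a, b_ax) + 1.0
            if 2 * margin >= size:
                continue
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            w = -(xx - cx) * st + (yy - cy) * ct
            ell = (u / a) ** 2 + (w / b_ax) ** 2 <= 1.0
            # keep a 1-px moat so components stay separable
            u2 = u / (a + 2.0)
            w2 = w / (b_ax + 2.0)
            dilated = u2 ** 2 + w2 ** 2 <= 1.0
            if not (dilated & (mask > 0)).any():
                color = np.clip(
                    [rng.normal(m, spec.nucleus_sigma) for m in spec.nucleus_color], 0, 1
                )
                # radial shading toward the rim for a hint of chromatin texture
                rad = np.sqrt((u / a) ** 2 + (w / b_ax) ** 2)
                shade = 1.0 - 0.15 * rad[ell]
                for c in range(3):
                    img[:, :, c][ell] = color[c] * shade
                mask[ell] = 1
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place nucleus {placed + 1}/{n} without overlap; "
                "reduce n_nuclei or axis_range"
            )
        placed += 1
    return np.clip(img, 0.0, 1.0), mask


def add_gaussian_noise(img: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """I.i.d. zero-mean Gaussian per channel, clipped to [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.asarray(img, dtype=np.float64).copy()
    rng = np.random.default_rng(seed)
    return np.clip(img + rng.normal(0.0, sigma, size=np.shape(img)), 0.0, 1.0)


def add_salt_pepper(img: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Impulse noise: a ``fraction`` share of pixels set to 0 or 1 (all
    channels of a hit pixel are driven to the same extreme)."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    img = np.asarray(img, dtype=np.float64).copy()
    if fraction == 0:
        return img
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    hit = rng.random((h, w)) < fraction
    salt = rng.random((h, w)) < 0.5
    img[hit & salt] = 1.0
    img[hit & ~salt] = 0.0
    return img


def corrupt(img: np.ndarray, spec: SyntheticSpec, seed: int) -> np.ndarray:
    """Apply the default noise model: Gaussian then salt-and-pepper."""
    noisy = add_gaussian_noise(img, spec.gaussian_sigma, seed)
    return add_salt_pepper(noisy, spec.salt_pepper_fraction, seed + 1)


def translate_pair(img: np.ndarray, mask: np.ndarray, dy: int, dx: int):
    """Shift image and mask by the same integer offset (dy, dx).

    The vacated strip is filled with the background color (image) and
    zeros (mask); the mask stays binary.
    """
    out_img = np.empty_like(img)
    out_img[..., :] = BACKGROUND_COLOR
    out_mask = np.zeros_like(mask)
    h, w = mask.shape

    def sl(shift, n):
        if shift >= 0:
            return slice(shift, n), slice(0, n - shift)
        return slice(0, n + shift), slice(-shift, n)

    dys, sys_ = sl(dy, h)
    dxs, sxs = sl(dx, w)
    out_img[dys, dxs] = img[sys_, sxs]
    out_mask[dys, dxs] = mask[sys_, sxs]
    return out_img, out_mask


def augment_translate(img: np.ndarray, mask: np.ndarray, max_shift: int, seed: int):
    """Seeded random translation augmentation of an image/mask pair.

    Draws one integer offset with ``|dy|, |dx| <= max_shift`` and applies
    it to both arrays.  Returns (image, mask, (dy, dx)).
    """
    rng = np.random.default_rng(seed)
    dy, dx = (int(v) for v in rng.integers(-max_shift, max_shift + 1, size=2))
    out_img, out_mask = translate_pair(img, mask, dy, dx)
    return out_img, out_mask, (dy, dx)


def make_dataset(
    n_tiles: int,
    spec: SyntheticSpec,
    out_dir,
    split_fraction: float = 0.8,
    noisy: bool = True,
    translate: int = 0,
):
    """Write a seeded tile dataset and disjoint train/val manifests.

    Layout: ``clean/`` (noise-free tiles), ``images/`` (noise-injected
    inputs if ``noisy`` else copies of clean), ``masks/`` ({0,255} PNGs),
    ``train.txt`` / ``val.txt`` listing ``images/NNN.png masks/NNN.png``
    per line.  Returns (train_manifest_path, val_manifest_path).
    """
    from .io import write_mask, write_rgb

    if n_tiles < 2:
        raise ValueError("need at least 2 tiles to split")
    if not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must be in (0, 1)")
    out_dir = Path(out_dir)
    for sub in ("clean", "images", "masks"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(spec.seed)
    names = []
    for i in range(n_tiles):
        tile_seed = int(rng.integers(0, 2 ** 31 - 1))
        img, mask = generate_tile(spec, seed=tile_seed)
        if translate > 0:
            img, mask, _ = augment_translate(img, mask, translate, tile_seed + 7)
        name = f"{i:04d}.png"
        write_rgb(out_dir / "clean" / name, img)
        inp = corrupt(img, spec, tile_seed + 3) if noisy else img
        write_rgb(out_dir / "images" / name, inp)
        write_mask(out_dir / "masks" / name, mask)
        names.append(name)

    order = rng.permutation(n_tiles)
    n_train = max(1, min(n_tiles - 1, int(round(split_fraction * n_tiles))))
    train_idx = sorted(order[:n_train])
    val_idx = sorted(order[n_train:])
    train_path = out_dir / "train.txt"
    val_path = out_dir / "val.txt"
    for path, idx in ((train_path, train_idx), (val_path, val_idx)):
        with open(path, "w") as fh:
            for i in idx:
                fh.write(f"images/{names[i]} masks/{names[i]}\n")
    return train_path, val_path
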