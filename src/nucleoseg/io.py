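"""Image and mask I/O: 8-bit PNG/TIFF/JPEG in, [0, 1] float arrays out."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_rgb", "write_rgb", "read_mask", "write_mask"]


def read_rgb(path) -> np.ndarray:
    """Load an 8-bit image as an (H, W, 3) float array on [0, 1]."""
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ValueError(f"{path}: expected 3 channels, got {arr.shape[2]}")
    return arr.astype(np.float64) / 255.0


def write_rgb(path, img: np.ndarray) -> None:
    """Write a [0, 1] float RGB array as 8-bit."""
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Load a {0, 255} mask PNG as a {0, 1} integer array."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a {0, 1} mask as a {0, 255} single-channel PNG."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    iio.imwrite(Path(path), arr)
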