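"""Image-quality and segmentation metrics.

PSNR follows the 8-bit convention (MAX = 255): images stored on [0, 1]
are rescaled by 255 before the squared error is taken, so reported dB
values are comparable to standard image-processing practice.  The
segmentation metrics are pixel-wise confusion-count ratios; on binary
masks the Dice similarity coefficient (DSC) coincides with F1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "mse",
    "psnr_from_mse",
    "psnr_gray",
    "psnr_color",
    "confusion",
    "seg_metrics",
    "evaluate_mask_dirs",
]

#: reported when the compared images are identical (MSE = 0)
PSNR_IDENTICAL = np.inf

_MAX_I = 255.0


@dataclass
class ConfusionCounts:
    """Pixel tallies: foreground (1) = nucleus."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mse(i: np.ndarray, k: np.ndarray) -> float:
    """Mean squared difference over all pixels (no rescaling)."""
    i = np.asarray(i, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if i.shape != k.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {k.shape}")
    d = i - k
    return float(np.mean(d * d))


def psnr_from_mse(m: float) -> float:
    """10*log10(255^2 / MSE) in dB; +inf for MSE = 0."""
    if m < 0:
        raise ValueError("MSE must be non-negative")
    if m == 0:
        return PSNR_IDENTICAL
    return float(10.0 * np.log10(_MAX_I * _MAX_I / m))


def psnr_gray(i: np.ndarray, k: np.ndarray) -> float:
    """Grayscale PSNR of two [0, 1] images, on the 8-bit scale."""
    return psnr_from_mse(mse(np.asarray(i) * _MAX_I, np.asarray(k) * _MAX_I))


def psnr_color(i: np.ndarray, k: np.ndarray) -> float:
    """Color PSNR: squared error summed over R, G, B and averaged over 3mn."""
    i = np.asarray(i, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    if i.shape != k.shape:
        raise ValueError(f"shape mismatch: {i.shape} vs {k.shape}")
    if i.ndim != 3 or i.shape[2] != 3:
        raise ValueError("psnr_color expects (H, W, 3) images")
    return psnr_from_mse(mse(i * _MAX_I, k * _MAX_I))


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return mask.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts between a predicted and a reference mask."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def seg_metrics(c: ConfusionCounts) -> dict:
    """Accuracy, recall, precision, IoU, DSC and F1 from confusion counts.

    Empty-foreground conventions: if both masks are empty (tp+fp+fn = 0)
    the overlap scores are 1; if exactly one is empty they are 0.  Ratios
    with an empty denominator follow the same rule componentwise.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = tp + tn + fp + fn

    def ratio(num, den, empty=0.0):
        return num / den if den > 0 else empty

    both_empty = (tp + fp + fn) == 0
    acc = ratio(tp + tn, total)
    recall = ratio(tp, tp + fn, 1.0 if both_empty else 0.0)
    precision = ratio(tp, tp + fp, 1.0 if both_empty else 0.0)
    iou = 1.0 if both_empty else ratio(tp, tp + fp + fn)
    dsc = 1.0 if both_empty else ratio(2 * tp, 2 * tp + fp + fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else (1.0 if both_empty else 0.0)
    )
    return {
        "accuracy": acc,
        "recall": recall,
        "precision": precision,
        "iou": iou,
        "dsc": dsc,
        "f1": f1,
    }


def evaluate_mask_dirs(pred_dir, truth_dir, out_csv=None) -> pd.DataFrame:
    """Per-image and mean metrics for matching mask files in two directories.

    Masks are {0, 255} PNGs.  Files present in only one directory are
    skipped with a warning column; an empty intersection raises.
    """
    from .io import read_mask

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    pred_files = {p.name: p for p in sorted(pred_dir.glob("*.png"))}
    truth_files = {p.name: p for p in sorted(truth_dir.glob("*.png"))}
    common = sorted(set(pred_files) & set(truth_files))
    if not common:
        raise ValueError("no matching mask filenames between the two directories")
    skipped = sorted(set(pred_files) ^ set(truth_files))
    if skipped:
        import warnings

        warnings.warn(f"unmatched mask files skipped: {skipped}")
    rows = []
    for name in common:
        m = seg_metrics(confusion(read_mask(pred_files[name]), read_mask(truth_files[name])))
        rows.append({"image": name, **m})
    df = pd.DataFrame(rows)
    mean_row = {"image": "mean", **df.drop(columns="image").mean().to_dict()}
    df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
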