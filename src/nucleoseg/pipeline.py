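"""Denoise -> train/predict -> evaluate pipeline.

Training follows the published recipe: SGD with base learning rate
0.05, momentum 0.9, weight decay 1e-4, batch size 4, composite
``0.6*Dice + 0.4*BCE`` loss.  Runs are fully seeded and CPU-bound; the
checkpoint kept is the epoch with the best validation DSC, with early
stopping after 20 epochs without improvement.  By default the guided
filter is applied to inputs both at training and at inference (the
denoise-first pipeline order).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import SGD
from .guided import DenoiseParams, guided_filter_rgb
from .io import read_mask, read_rgb, write_mask, write_rgb
from .metrics import confusion, evaluate_mask_dirs, seg_metrics
from .model import LossWeights, ModelSpec, NucleusSegmenter, composite_loss

__all__ = ["TrainConfig", "train", "predict", "evaluate", "load_checkpoint", "save_checkpoint"]


@dataclass
class TrainConfig:
    """Optimizer and run settings (published defaults; small test epochs)."""

    base_lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 0.0001
    batch_size: int = 4
    epochs: int = 30
    seed: int = 42
    patience: int = 20
    denoise: bool = True
    denoise_params: DenoiseParams = field(default_factory=DenoiseParams)
    loss: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _load_manifest(manifest_path) -> list[tuple[Path, Path]]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    pairs = []
    for line in manifest_path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        img_rel, mask_rel = line.split()
        img_p, mask_p = root / img_rel, root / mask_rel
        if not img_p.exists() or not mask_p.exists():
            raise FileNotFoundError(f"manifest entry missing on disk: {line}")
        pairs.append((img_p, mask_p))
    if not pairs:
        raise ValueError(f"empty manifest: {manifest_path}")
    return pairs


def _load_pairs(pairs, denoise: bool, dp: DenoiseParams):
    imgs, masks = [], []
    for img_p, mask_p in pairs:
        img = read_rgb(img_p)
        if denoise:
            img = guided_filter_rgb(img, dp)
        imgs.append(img)
        masks.append(read_mask(mask_p))
    return np.stack(imgs), np.stack(masks)


def _val_dsc(model: NucleusSegmenter, imgs: np.ndarray, masks: np.ndarray) -> float:
    scores = []
    for img, mask in zip(imgs, masks):
        pred = model.predict_mask(img)
        scores.append(seg_metrics(confusion(pred, mask))["dsc"])
    return float(np.mean(scores))


def save_checkpoint(path, model: NucleusSegmenter):
    state = model.state_dict()
    np.savez(path, __spec__=np.frombuffer(model.spec_obj.to_json().encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> NucleusSegmenter:
    with np.load(path) as data:
        spec = ModelSpec.from_json(bytes(data["__spec__"]).decode())
        model = NucleusSegmenter(spec)
        model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model


def train(
    train_manifest,
    val_manifest,
    model_spec: ModelSpec,
    cfg: TrainConfig,
    out_dir,
) -> dict:
    """Train a segmenter; returns the run manifest (also written to disk).

    Writes ``checkpoint.npz`` (best validation DSC), ``curves.csv``
    (per-epoch train loss and val DSC) and ``run.json`` under
    ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    train_imgs, train_masks = _load_pairs(
        _load_manifest(train_manifest), cfg.denoise, cfg.denoise_params
    )
    val_imgs, val_masks = _load_pairs(
        _load_manifest(val_manifest), cfg.denoise, cfg.denoise_params
    )

    rng = np.random.default_rng(cfg.seed)
    model = NucleusSegmenter(model_spec, np.random.default_rng(cfg.seed))
    opt = SGD(model.parameters(), lr=cfg.base_lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)

    n = len(train_imgs)
    best_dsc, best_state, best_epoch = -1.0, model.state_dict(), 0
    curves = []
    if cfg.epochs == 0:
        best_dsc = _val_dsc(model, val_imgs, val_masks)
        curves.append({"epoch": 0, "train_loss": float("nan"), "val_dsc": best_dsc})
    since_best = 0
    final_loss = float("nan")
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            scores = model(train_imgs[idx])
            loss = composite_loss(scores, train_masks[idx], cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}; aborting"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        train_loss = float(np.mean(losses))
        final_loss = train_loss
        dsc = _val_dsc(model, val_imgs, val_masks)
        curves.append({"epoch": epoch, "train_loss": train_loss, "val_dsc": dsc})
        if dsc > best_dsc:
            best_dsc, best_state, best_epoch = dsc, model.state_dict(), epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    model.load_state_dict(best_state)
    ckpt_path = out_dir / "checkpoint.npz"
    save_checkpoint(ckpt_path, model)
    pd.DataFrame(curves).to_csv(out_dir / "curves.csv", index=False)

    manifest = {
        "config": {
            "train": {k: v for k, v in asdict(cfg).items()},
            "model": json.loads(model_spec.to_json()),
        },
        "version": "nucleoseg-0.1.0",
        "seed": cfg.seed,
        "best_val_dsc": best_dsc,
        "best_epoch": best_epoch,
        "final_train_loss": final_loss,
        "epochs_run": len(curves),
        "wall_seconds": time.time() - t0,
        "checkpoint": str(ckpt_path),
        "curves": curves,
    }
    tmp = out_dir / "run.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.rename(out_dir / "run.json")
    return manifest


def _pad_to_16(img: np.ndarray):
    h, w = img.shape[:2]
    ph = (-h) % 16
    pw = (-w) % 16
    if ph == 0 and pw == 0:
        return img, (h, w)
    img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return img, (h, w)


def predict(
    checkpoint,
    image_dir,
    out_dir,
    denoise: DenoiseParams | None = None,
    save_proba: bool = False,
) -> list[Path]:
    """Segment every image in a directory; one {0,255} PNG mask each.

    ``denoise=None`` skips the filtering stage.  Inputs whose sides are
    not divisible by 16 are reflect-padded, then the mask is cropped
    back.  With ``save_proba`` a float probability map (.npy) is written
    alongside each mask.
    """
    model = load_checkpoint(checkpoint)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    files = sorted(
        p for p in Path(image_dir).iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    )
    if not files:
        raise ValueError(f"no images found in {image_dir}")
    for path in files:
        img = read_rgb(path)
        if denoise is not None:
            img = guided_filter_rgb(img, denoise)
        img, (h, w) = _pad_to_16(img)
        proba = model.predict_proba(img)[:h, :w]
        mask = (proba >= 0.5).astype(np.uint8)
        out_path = out_dir / (path.stem + ".png")
        write_mask(out_path, mask)
        if save_proba:
            np.save(out_dir / (path.stem + "_proba.npy"), proba)
        written.append(out_path)
    return written


def evaluate(pred_dir, truth_dir, out_csv=None) -> pd.DataFrame:
    """Per-image and mean Ac/Pr/Re/DSC/F1/IoU for matching mask files."""
    return evaluate_mask_dirs(pred_dir, truth_dir, out_csv=out_csv)


def denoise_dir(
    in_dir,
    out_dir,
    params: DenoiseParams,
    clean_dir=None,
    report_csv=None,
) -> pd.DataFrame | None:
    """Batch guided filtering over a directory of tiles.

    When a directory of clean references is given, a per-image PSNR
    report (noisy vs filtered) is returned and optionally written.
    """
    from .metrics import psnr_color

    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    files = sorted(
        p for p in in_dir.iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff", ".jpg", ".jpeg")
    )
    if not files:
        raise ValueError(f"no images found in {in_dir}")
    for path in files:
        img = read_rgb(path)
        out = guided_filter_rgb(img, params)
        write_rgb(out_dir / path.name, out)
        if clean_dir is not None:
            clean = read_rgb(Path(clean_dir) / path.name)
            rows.append({
                "image": path.name,
                "psnr_noisy": psnr_color(img, clean),
                "psnr_filtered": psnr_color(out, clean),
            })
    if rows:
        df = pd.DataFrame(rows)
        if report_csv is not None:
            df.to_csv(report_csv, index=False)
        return df
    return None
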