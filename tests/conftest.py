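"""Shared fixtures: seeded RNGs, a desk-scale synthetic dataset, and a
single session-wide training run reused by the learning-based tests."""

import numpy as np
import pytest

from nucleoseg import ModelSpec, SyntheticSpec, make_dataset
from nucleoseg.pipeline import TrainConfig, train


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """25 noisy 64x64 tiles (20 train / 5 val) with masks and manifests."""
    out = tmp_path_factory.mktemp("desk_ds")
    spec = SyntheticSpec.desk(tile_size=64, seed=42)
    train_m, val_m = make_dataset(25, spec, out)
    return {"dir": out, "train": train_m, "val": val_m, "spec": spec}


@pytest.fixture(scope="session")
def trained_run(desk_dataset, tmp_path_factory):
    """The desk-scale reference training run: tiny model, 30 epochs, seed 42."""
    out = tmp_path_factory.mktemp("run")
    manifest = train(
        desk_dataset["train"],
        desk_dataset["val"],
        ModelSpec.tiny(),
        TrainConfig(epochs=30, seed=42),
        out,
    )
    return {"dir": out, "manifest": manifest, "dataset": desk_dataset}
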