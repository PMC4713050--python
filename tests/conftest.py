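"""Shared fixtures: small synthetic gel datasets and toy feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from geltexture import gelsim
from geltexture.dataset import build_table, feature_columns, standardize


def random_roi(rng: np.random.Generator, size: int = 16, full_mask: bool = True):
    """A random uint8 ROI; optionally with an irregular (but connected) mask."""
    pixels = rng.integers(0, 256, size=(size, size)).astype(np.uint8)
    if full_mask:
        mask = np.ones((size, size), dtype=bool)
    else:
        mask = np.ones((size, size), dtype=bool)
        # carve notches from the corners to make the mask irregular
        k = size // 4
        mask[:k, :k] = False
        mask[-k:, -k:] = False
    return pixels, mask


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160113)


@pytest.fixture(scope="session")
def strong_signal_table():
    """Standardized feature table from a strong-amplitude simulation (n=100)."""
    cfg = gelsim.GelSimConfig(
        n_images=2, height=384, width=384,
        spots_per_image=25, noise_per_image=25,
        amplitude_range=(120.0, 200.0), sigma_range=(2.5, 5.0),
        n_cracks=2, n_noise_patches=2,
        noise_roi_size=(16, 28),
    )
    _, rois = gelsim.generate_dataset(cfg, seed=11)
    table = build_table(rois)
    ztable, _ = standardize(table)
    return ztable


@pytest.fixture(scope="session")
def null_signal_table():
    """Feature table with amplitude 0 and background-only noise ROIs (n=200).

    With invisible spots and a homogeneous noise class there is no signal
    relating features to labels beyond sampling noise.
    """
    # noise ROI size fixed to the invisible-spot fallback box and shading off,
    # so ROI geometry and position carry no label information either
    cfg = gelsim.GelSimConfig(
        n_images=4, height=256, width=256,
        spots_per_image=25, noise_per_image=25,
        amplitude_range=(0.0, 0.0), sigma_range=(2.5, 5.0),
        n_cracks=0, n_noise_patches=0, shading_amplitude=0.0,
        noise_mix={"background": 1.0},
        noise_roi_size=(16, 16),
    )
    _, rois = gelsim.generate_dataset(cfg, seed=7)
    table = build_table(rois)
    ztable, _ = standardize(table)
    return ztable


def split_xy(ztable: pd.DataFrame):
    feats = feature_columns(ztable)
    return ztable[feats], ztable["label"].to_numpy()


@pytest.fixture()
def planted_table(rng):
    """Toy standardized table: one informative feature in group A, noise
    elsewhere, three groups of four features each (n=200)."""
    n = 200
    y = np.array([0, 1] * (n // 2))
    X = pd.DataFrame(
        np.random.default_rng(42).normal(size=(n, 12)),
        columns=[f"f{i}" for i in range(12)],
    )
    X["f0"] = y + 0.05 * np.random.default_rng(43).normal(size=n)
    X = (X - X.mean()) / X.std()
    groups = {f"f{i}": ("A" if i < 4 else "B" if i < 8 else "C") for i in range(12)}
    return X, y, groups
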