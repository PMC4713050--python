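"""Feature-table assembly and standardization.

The table is a pandas DataFrame with index columns ``image_id``/``roi_id``, a
binary ``label`` column (0 = noise, 1 = spot), and one column per inventoried
feature. Standardization z-scores each feature column, either globally (the
default: the dataset is preprocessed as a whole before any split) or per
cross-validation fold (statistics fitted on training rows only, avoiding any
leakage of test-fold statistics).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .textures import FeatureInventory, TextureConfig, default_inventory, extract_all

__all__ = ["build_table", "standardize", "feature_columns", "write_table", "read_table"]

META_COLUMNS = ("image_id", "roi_id", "label")
LABEL_CODES = {"noise": 0, "spot": 1}


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def build_table(
    rois,
    inventory: FeatureInventory | None = None,
    config: TextureConfig | None = None,
) -> pd.DataFrame:
    """One row of texture features per ROI, ordered by (image_id, roi_id)."""
    inventory = inventory or default_inventory(config)
    rows = []
    for roi in sorted(rois, key=lambda r: (r.image_id, r.roi_id)):
        values = extract_all(roi, inventory, config)
        row = {
            "image_id": roi.image_id,
            "roi_id": roi.roi_id,
            "label": LABEL_CODES[roi.label],
        }
        row.update(values)
        rows.append(row)
    columns = list(META_COLUMNS) + inventory.names
    table = pd.DataFrame(rows, columns=columns)
    if len(table) and table[inventory.names].isna().any().any():
        bad = [c for c in inventory.names if table[c].isna().any()]
        raise ValueError(f"missing values after assembly in columns {bad[:5]}...")
    return table


def standardize(
    table: pd.DataFrame,
    mode: str = "global",
    train_index: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score every feature column.

    ``global`` fits (mean, sd) on all rows; ``per-fold`` fits on
    ``train_index`` rows only and applies to everything. Zero-variance
    columns map to 0 with a warning. Returns (table, stats) where ``stats``
    has one row per feature with its mean and sd.
    """
    feats = feature_columns(table)
    out = table.copy()
    if mode == "global":
        fit_rows = out.index
    elif mode == "per-fold":
        if train_index is None:
            raise ValueError("per-fold mode requires train_index")
        fit_rows = train_index
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    X = out.loc[fit_rows, feats].to_numpy(dtype=np.float64)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance feature column(s) mapped to 0",
            stacklevel=2,
        )
    sd_safe = np.where(zero, 1.0, sd)
    Z = (out[feats].to_numpy(dtype=np.float64) - mean) / sd_safe
    Z[:, zero] = 0.0
    out[feats] = Z
    stats = pd.DataFrame({"feature": feats, "mean": mean, "sd": sd}).set_index("feature")
    return out, stats


def write_table(table: pd.DataFrame, path, inventory: FeatureInventory | None = None,
                config: TextureConfig | None = None) -> None:
    """CSV plus a JSON provenance sidecar (inventory + extraction config)."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = {
        "inventory": (inventory or default_inventory(config)).entries,
        "config": asdict(config or TextureConfig()),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_table(path) -> pd.DataFrame:
    """Read a feature-table CSV (ours, or an external label + features layout)."""
    table = pd.read_csv(path)
    if "label" not in table.columns:
        raise ValueError("feature table must contain a 'label' column")
    if table["label"].dtype == object:
        table["label"] = table["label"].map(LABEL_CODES)
    for col in ("image_id", "roi_id"):
        if col not in table.columns:
            table[col] = np.arange(len(table))
    cols = list(META_COLUMNS) + [c for c in table.columns if c not in META_COLUMNS]
    return table[cols]
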