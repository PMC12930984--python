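"""Per-pair feature extraction: normalize, mask, render, measure.

This ties the I/O, volumetric and similarity modules into the row format the
classifier consumes. One row per original/defaced pair:

scan_id, subject_id, method, fsim, ssim, rmse, psnr, head_impacted_pct,
head_removed_pct, brain_impacted_pct, brain_removed_pct, bhr
(+ label columns when ground truth is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import SimilarityConfig, similarity_features
from .phantom import (
    DEFACING_METHODS,
    phantom_for_row,
    sim_from_row,
    simulate_defacing,
)
from .render import render_all_views
from .volume_io import Mask, PreprocessConfig, Volume, head_mask, normalize
from .volumetric import volumetric_features

__all__ = [
    "SIMILARITY_COLUMNS",
    "VOLUMETRIC_COLUMNS",
    "extract_pair_features",
    "phantom_feature_table",
    "modeling_table",
]

SIMILARITY_COLUMNS = ("fsim", "ssim", "rmse", "psnr")
VOLUMETRIC_COLUMNS = (
    "head_impacted_pct",
    "head_removed_pct",
    "brain_impacted_pct",
    "brain_removed_pct",
    "bhr",
)


def extract_pair_features(
    orig: Volume,
    defaced: Volume,
    brain: Mask,
    pre_cfg: PreprocessConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
    resolution: int = 256,
) -> dict:
    """Compute all similarity and volumetric features for one pair.

    Both volumes are min-max normalized independently; the head mask is
    thresholded from the normalized original and used as region and
    denominator for all head-relative measures and for both renders, so the
    rendered surfaces are directly comparable.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    sim_cfg = sim_cfg or SimilarityConfig()
    if orig.shape != defaced.shape:
        raise ValueError(
            f"pair grids differ: {orig.shape} vs {defaced.shape}"
        )
    orig_n = normalize(orig)
    defaced_n = normalize(defaced)
    head = head_mask(orig_n, pre_cfg)

    vol = volumetric_features(
        orig_n, defaced_n, head, brain, eps=pre_cfg.altered_tolerance
    )
    views_o = render_all_views(orig_n, head, resolution)
    views_d = render_all_views(defaced_n, head, resolution)
    sim = similarity_features(views_o, views_d, sim_cfg)

    row = {"scan_id": orig.scan_id, "subject_id": orig.subject_id}
    row.update(sim.as_dict())
    row.update(vol.as_dict())
    return row


def phantom_feature_table(
    manifest: pd.DataFrame,
    grid_size: int | None = None,
    noise_sigma: float | None = None,
    master_seed: int | None = None,
    resolution: int = 128,
    pre_cfg: PreprocessConfig | None = None,
    sim_cfg: SimilarityConfig | None = None,
) -> pd.DataFrame:
    """Extract features for every pair of a synthetic cohort manifest.

    Phantoms are rebuilt deterministically from the manifest, defaced per
    the recorded simulation parameters, and run through the full feature
    pipeline. Grid size, noise level and master seed default to the values
    recorded on the manifest.
    """
    grid_size = grid_size or manifest.attrs.get("grid_size", 96)
    noise_sigma = (
        noise_sigma
        if noise_sigma is not None
        else manifest.attrs.get("noise_sigma", 0.02)
    )
    master_seed = (
        master_seed
        if master_seed is not None
        else manifest.attrs.get("master_seed", 0)
    )

    rows = []
    cache_key, cached = None, None
    for _, mrow in manifest.iterrows():
        if mrow["scan_id"] != cache_key:  # phantoms shared across methods
            cached = phantom_for_row(
                mrow, grid_size, noise_sigma, master_seed
            )
            cache_key = mrow["scan_id"]
        ph = cached
        defaced = simulate_defacing(ph, sim_from_row(mrow))
        row = extract_pair_features(
            ph.volume, defaced, ph.brain,
            pre_cfg=pre_cfg, sim_cfg=sim_cfg, resolution=resolution,
        )
        row["method"] = mrow["method"]
        row["label_strict"] = int(mrow["label_strict"])
        row["label_lenient"] = int(mrow["label_lenient"])
        rows.append(row)
    return pd.DataFrame(rows)


def modeling_table(
    features: pd.DataFrame,
    criterion: str = "lenient",
    include_methods: bool = True,
    volumetric_subset: tuple = ("head_removed_pct", "brain_removed_pct", "bhr"),
) -> pd.DataFrame:
    """Shape a feature table into the default modeling layout.

    Emits the four similarity metrics, the configured volumetric subset and,
    optionally, one-hot defacing-method indicators (the default 4+3+4 = 11
    feature layout), plus ``label``, ``criterion``, ``subject_id`` and
    ``scan_id`` bookkeeping columns.
    """
    if criterion not in ("strict", "lenient"):
        raise ValueError("criterion must be 'strict' or 'lenient'")
    label_col = f"label_{criterion}"
    if label_col not in features.columns:
        raise ValueError(f"feature table lacks {label_col!r}")
    out = features[
        ["scan_id", "subject_id", *SIMILARITY_COLUMNS, *volumetric_subset]
    ].copy()
    if include_methods:
        for method in DEFACING_METHODS:
            out[f"method_{method}"] = (
                (features["method"] == method).astype(int)
            )
    out["criterion"] = criterion
    out["label"] = features[label_col].astype(int)
    return out


def feature_columns(table: pd.DataFrame) -> list:
    """The model-input columns of a modeling table."""
    reserved = {"scan_id", "subject_id", "criterion", "label", "method"}
    return [
        c for c in table.columns
        if c not in reserved and np.issubdtype(table[c].dtype, np.number)
    ]
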