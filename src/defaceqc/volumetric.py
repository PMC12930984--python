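"""Volumetric defacing-impact measures from an original/defaced pair.

All measures are percentages of mask voxels, computed on normalized
intensities. The head mask is always the ORIGINAL scan's mask: the defaced
scan's own head mask is itself altered by defacing and would bias the
denominator.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volume_io import Mask, Volume

__all__ = [
    "VolumetricFeatures",
    "impacted_voxels",
    "removed_voxels",
    "brain_impact",
    "brain_to_head_ratio",
    "volumetric_features",
]

#: volumetric columns used by the default 11-feature modeling layout
DEFAULT_MODEL_SUBSET = ("head_removed_pct", "brain_removed_pct", "bhr")


@dataclasses.dataclass
class VolumetricFeatures:
    """Per-pair 3D impact measures.

    head_impacted_pct / head_removed_pct
        Percent of head-mask voxels altered / completely zeroed ("head loss").
    brain_impacted_pct / brain_removed_pct
        Same relative to the brain mask ("brain loss").
    bhr
        Brain-to-head voxel-count ratio; anomaly indicator for mask quality.
    """

    head_impacted_pct: float
    head_removed_pct: float
    brain_impacted_pct: float
    brain_removed_pct: float
    bhr: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _check_pair(orig: Volume, defaced: Volume, mask: Mask) -> None:
    if orig.shape != defaced.shape:
        raise ValueError(
            f"original/defaced grid shapes differ: {orig.shape} vs "
            f"{defaced.shape} (pairs must share one acquisition grid)"
        )
    if mask.shape != orig.shape:
        raise ValueError("mask shape does not match volume shape")


def impacted_voxels(
    orig: Volume, defaced: Volume, head: Mask, eps: float = 0.0
) -> float:
    """Percent of head voxels whose intensity changed by more than ``eps``."""
    _check_pair(orig, defaced, head)
    n_head = head.count
    if n_head == 0:
        raise ValueError("empty head mask: impacted percentage undefined")
    diff = np.abs(orig.intensities - defaced.intensities)
    altered = int(np.count_nonzero(diff[head.voxels] > eps))
    return 100.0 * altered / n_head


def removed_voxels(orig: Volume, defaced: Volume, head: Mask) -> float:
    """Percent of head voxels nonzero in the original and zero after defacing."""
    _check_pair(orig, defaced, head)
    n_head = head.count
    if n_head == 0:
        raise ValueError("empty head mask: removed percentage undefined")
    o = orig.intensities[head.voxels]
    d = defaced.intensities[head.voxels]
    removed = int(np.count_nonzero((o != 0) & (d == 0)))
    return 100.0 * removed / n_head


def brain_impact(
    orig: Volume, defaced: Volume, brain: Mask, eps: float = 0.0
) -> tuple[float, float]:
    """(altered %, completely removed %) within the brain mask."""
    _check_pair(orig, defaced, brain)
    if brain.count == 0:
        raise ValueError("empty brain mask: brain impact undefined")
    return (
        impacted_voxels(orig, defaced, brain, eps),
        removed_voxels(orig, defaced, brain),
    )


def brain_to_head_ratio(brain: Mask, head: Mask) -> float:
    """Brain-mask voxel count over head-mask voxel count."""
    n_head = head.count
    if n_head == 0:
        raise ValueError("empty head mask: BHR undefined")
    return brain.count / n_head


def volumetric_features(
    orig: Volume,
    defaced: Volume,
    head: Mask,
    brain: Mask,
    eps: float = 0.0,
) -> VolumetricFeatures:
    """All five volumetric measures for one original/defaced pair."""
    b_imp, b_rem = brain_impact(orig, defaced, brain, eps)
    return VolumetricFeatures(
        head_impacted_pct=impacted_voxels(orig, defaced, head, eps),
        head_removed_pct=removed_voxels(orig, defaced, head),
        brain_impacted_pct=b_imp,
        brain_removed_pct=b_rem,
        bhr=brain_to_head_ratio(brain, head),
    )
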