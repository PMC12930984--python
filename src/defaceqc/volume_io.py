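"""NIfTI volume I/O, canonical reorientation, intensity normalization and head masking.

All downstream feature computation assumes volumes in a fixed RAS+ axis
convention (x: left->right, y: posterior->anterior, z: inferior->superior) so
that the five rendering perspectives (frontal = looking at the face from +y)
are well defined. ``load_volume`` enforces that convention on read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "PreprocessConfig",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "normalize",
    "head_mask",
]


@dataclasses.dataclass
class Volume:
    """A 3D intensity grid with spatial metadata.

    Parameters
    ----------
    intensities : ndarray
        3D array of finite intensities (arbitrary scanner units, or [0, 1]
        after :func:`normalize`).
    affine : ndarray
        4x4 invertible voxel-to-world transform.
    scan_id : str
        Identifier of the acquisition.
    subject_id : str
        Identifier of the participant the scan belongs to (group key for
        cross-validation).
    """

    intensities: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4)
    )
    scan_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"volume must be 3D, got {self.intensities.ndim} axes"
            )
        if min(self.intensities.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape


@dataclasses.dataclass
class Mask:
    """A boolean 3D grid aligned to a :class:`Volume`."""

    voxels: np.ndarray
    kind: str = "head"  # {"head", "brain"}
    source_scan_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.kind not in ("head", "brain"):
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclasses.dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    head_threshold
        Intensity threshold on normalized data above which a voxel counts as
        head tissue; removes low-intensity background noise. Default 0.03.
    altered_tolerance
        Absolute intensity difference above which a voxel counts as altered
        by defacing. Default 0 (any nonzero change counts); exposed because
        float round-trips through disk can introduce spurious tiny diffs.
    canonical_orientation
        Axis convention every volume is reoriented to on load.
    """

    head_threshold: float = 0.03
    altered_tolerance: float = 0.0
    canonical_orientation: str = "RAS"

    def __post_init__(self) -> None:
        if not 0.0 < self.head_threshold < 1.0:
            raise ValueError("head_threshold must lie in (0, 1)")
        if self.altered_tolerance < 0:
            raise ValueError("altered_tolerance must be >= 0")


def _ids_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def load_volume(path, scan_id: str | None = None, subject_id: str = "") -> Volume:
    """Load a single-frame NIfTI volume and reorient it to RAS+.

    Reorientation permutes/flips axes only; intensity values are unchanged.

    Raises
    ------
    ValueError
        If the file holds a 4D series or its affine is not invertible.
    """
    path = Path(path)
    img = nib.load(str(path))
    if img.ndim == 4 and img.shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
    if img.ndim != 3:
        raise ValueError(
            f"{path}: expected a single 3D volume, got shape {img.shape}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    return Volume(
        intensities=data,
        affine=np.asarray(img.affine, dtype=float),
        scan_id=scan_id if scan_id is not None else _ids_from_path(path),
        subject_id=subject_id,
    )


def save_volume(volume: Volume, path) -> None:
    """Write a volume to NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(
        np.asarray(volume.intensities, dtype=np.float64), volume.affine
    )
    nib.save(img, str(path))


def load_mask(path, kind: str = "head") -> Mask:
    """Load a 0/1-coded NIfTI mask."""
    vol = load_volume(path)
    return Mask(
        voxels=vol.intensities > 0.5, kind=kind, source_scan_id=vol.scan_id
    )


def save_mask(mask: Mask, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        mask.voxels.astype(np.uint8),
        np.eye(4) if affine is None else np.asarray(affine, dtype=float),
    )
    nib.save(img, str(path))


def normalize(volume: Volume) -> Volume:
    """Min-max normalize intensities to [0, 1].

    A constant volume maps to all zeros (degenerate range) rather than
    erroring, so empty fixtures flow through with empty head masks.
    """
    x = np.asarray(volume.intensities, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot normalize non-finite intensities")
    lo = x.min()
    hi = x.max()
    if hi == lo:
        out = np.zeros_like(x)
    else:
        out = (x - lo) / (hi - lo)
    return Volume(
        intensities=out,
        affine=volume.affine,
        scan_id=volume.scan_id,
        subject_id=volume.subject_id,
    )


def head_mask(volume: Volume, cfg: PreprocessConfig | None = None) -> Mask:
    """Threshold a normalized volume into a head mask.

    A voxel belongs to the head exactly when its normalized intensity
    exceeds ``cfg.head_threshold`` (default 0.03), removing low-intensity
    background voxels.
    """
    cfg = cfg or PreprocessConfig()
    return Mask(
        voxels=np.asarray(volume.intensities) > cfg.head_threshold,
        kind="head",
        source_scan_id=volume.scan_id,
    )
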