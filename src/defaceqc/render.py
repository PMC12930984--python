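"""Deterministic orthographic surface rendering of head volumes.

Five standardized perspectives of the face — frontal, left and right
profiles, and left and right 45-degree views — are produced by first-hit ray
casting: parallel rays traverse the volume along the view direction and each
pixel takes the intensity of the first head-mask voxel the ray meets
(trilinear sampling at sub-voxel steps), 0 where no surface is hit. The image
plane is scaled to the volume bounding box and letterboxed to keep square
pixels, so views of one scan pair are directly comparable.

Volumes are assumed to be in canonical RAS+ order (see ``volume_io``): the
face points along +y, the superior axis is +z. Azimuth is measured about the
superior axis, positive toward the subject's right.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import Mask, Volume

__all__ = [
    "ViewSpec",
    "ViewImage",
    "ViewSet",
    "CANONICAL_VIEWS",
    "render_view",
    "render_all_views",
    "export_png",
]

_VIEW_AZIMUTHS = {
    "frontal": 0.0,
    "left_profile": -90.0,
    "right_profile": 90.0,
    "left_45": -45.0,
    "right_45": 45.0,
}


@dataclasses.dataclass(frozen=True)
class ViewSpec:
    """One standardized perspective.

    azimuth: degrees about the superior (+z) axis relative to the facing
    direction (+y); 0 = frontal, +90 = right profile, -90 = left profile.
    """

    name: str
    azimuth: float
    resolution: int = 256

    def __post_init__(self) -> None:
        if self.resolution < 16:
            raise ValueError("resolution must be >= 16")
        expected = _VIEW_AZIMUTHS.get(self.name)
        if expected is not None and expected != self.azimuth:
            raise ValueError(
                f"view {self.name!r} must have azimuth {expected}"
            )


def CANONICAL_VIEWS(resolution: int = 256) -> tuple[ViewSpec, ...]:
    """The five canonical view specs in fixed order."""
    return tuple(
        ViewSpec(name, az, resolution) for name, az in _VIEW_AZIMUTHS.items()
    )


@dataclasses.dataclass
class ViewImage:
    """A rendered 2D view; pixel values in [0, 1], background 0."""

    pixels: np.ndarray
    view: ViewSpec
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("view image must be 2D")


@dataclasses.dataclass
class ViewSet:
    """The five canonical renders of one scan, in fixed order."""

    images: tuple

    def __post_init__(self) -> None:
        self.images = tuple(self.images)
        if len(self.images) != 5:
            raise ValueError("a ViewSet holds exactly 5 views")

    def __iter__(self):
        return iter(self.images)

    def __getitem__(self, key):
        if isinstance(key, str):
            for im in self.images:
                if im.view.name == key:
                    return im
            raise KeyError(key)
        return self.images[key]

    @property
    def names(self) -> tuple:
        return tuple(im.view.name for im in self.images)


def _view_basis(azimuth_deg: float):
    """Ray direction and image-plane basis for an azimuth about +z."""
    theta = np.deg2rad(azimuth_deg)
    # observer direction: +y rotated toward +x for positive azimuth
    observer = np.array([np.sin(theta), np.cos(theta), 0.0])
    ray = -observer
    up = np.array([0.0, 0.0, 1.0])  # superior is up in every image
    u = np.cross(up, observer)  # image columns, left to right
    u /= np.linalg.norm(u)
    return ray, u, up


def render_view(volume: Volume, mask: Mask, spec: ViewSpec) -> ViewImage:
    """Orthographic first-hit ray casting of one view.

    An empty mask yields an all-background (zero) image rather than an error.
    """
    vol = np.asarray(volume.intensities, dtype=np.float64)
    if mask.shape != vol.shape:
        raise ValueError("mask shape does not match volume shape")
    mvox = mask.voxels.astype(np.float64)
    res = spec.resolution

    if mask.count == 0:
        return ViewImage(np.zeros((res, res)), spec, volume.scan_id)

    ray, u, v = _view_basis(spec.azimuth)
    shape = np.array(vol.shape, dtype=float)
    center = (shape - 1.0) / 2.0

    # half-extent of the bounding box projected on the image axes;
    # letterbox with the larger one so pixels stay square
    corners = (
        np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
        * (shape - 1.0)
    )
    rel = corners - center
    extent = max(np.abs(rel @ u).max(), np.abs(rel @ v).max())
    extent = max(extent, 1e-9)

    # ray start plane outside the volume; march across the full diagonal
    radius = float(np.linalg.norm((shape - 1.0) / 2.0)) + 1.0
    step = 0.5  # half the voxel edge (unit voxels in canonical index space)
    n_steps = int(np.ceil(2.0 * radius / step)) + 1

    px = (np.arange(res) + 0.5) / res * 2.0 - 1.0  # [-1, 1]
    cols = px * extent
    rows = -px * extent  # top of the image is superior
    origin = (
        center
        + rows[:, None, None] * v
        + cols[None, :, None] * u
        - radius * ray
    )  # (res, res, 3)

    ts = np.arange(n_steps) * step
    # sample points: (res*res, n_steps, 3)
    pts = origin.reshape(-1, 1, 3) + ts[None, :, None] * ray
    coords = pts.reshape(-1, 3).T

    inside = map_coordinates(
        mvox, coords, order=1, mode="constant", cval=0.0
    ).reshape(res * res, n_steps)
    hit = inside >= 0.5
    first = np.argmax(hit, axis=1)
    any_hit = hit.any(axis=1)

    pixels = np.zeros(res * res)
    if any_hit.any():
        idx = np.nonzero(any_hit)[0]
        # sample half a voxel beyond the detected crossing so the pixel
        # reads the surface voxel's intensity, not the interpolation ramp
        hit_pts = pts[idx, first[idx], :] + 0.5 * ray
        vals = map_coordinates(
            vol, hit_pts.T, order=1, mode="constant", cval=0.0
        )
        pixels[idx] = np.clip(vals, 0.0, 1.0)
    return ViewImage(pixels.reshape(res, res), spec, volume.scan_id)


def render_all_views(
    volume: Volume, mask: Mask, resolution: int = 256
) -> ViewSet:
    """Render the five canonical views in fixed order."""
    return ViewSet(
        tuple(
            render_view(volume, mask, spec)
            for spec in CANONICAL_VIEWS(resolution)
        )
    )


def export_png(image: ViewImage, path) -> None:
    """Write an 8-bit grayscale PNG (value = round(255 * pixel))."""
    import imageio.v3 as iio

    data = np.round(255.0 * np.clip(image.pixels, 0.0, 1.0)).astype(np.uint8)
    iio.imwrite(str(path), data)
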