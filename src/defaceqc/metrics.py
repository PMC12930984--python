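"""Full-reference image similarity metrics between rendered view pairs.

RMSE, PSNR, SSIM and FSIM are computed per corresponding view of the
original and defaced renders and aggregated (arithmetic mean by default)
into one scalar feature each.

All metrics operate on float images in [0, 1] (dynamic range L = 1), so the
classical constants are rescaled from their 8-bit defaults:

* SSIM (Wang et al. 2004): Gaussian window sigma = 1.5 truncated at 11x11,
  C1 = (K1 L)^2, C2 = (K2 L)^2 with K1 = 0.01, K2 = 0.03.
* FSIM (Zhang et al. 2011): phase congruency from a 4-scale x 4-orientation
  log-Gabor bank (Kovesi's construction), gradient magnitude from the Scharr
  operator, per-pixel similarity S_PC * S_G pooled with max(PC1, PC2)
  weights; T1 = 0.85 on the (scale-invariant) phase congruency, T2 = 160
  rescaled by (1/255)^2 for unit dynamic range. Luminance only — the renders
  are grayscale, so the chrominance extension is omitted.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import correlate

from .render import ViewImage, ViewSet

__all__ = [
    "SimilarityConfig",
    "SimilarityFeatures",
    "rmse",
    "psnr",
    "ssim",
    "fsim",
    "phase_congruency",
    "similarity_features",
]


@dataclasses.dataclass
class SimilarityConfig:
    dynamic_range: float = 1.0
    psnr_cap: float = 100.0
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_sigma: float = 1.5
    ssim_win: int = 11
    fsim_t1: float = 0.85          # on phase congruency (scale-invariant)
    fsim_t2: float = 160.0 / 255.0 ** 2  # on gradient, rescaled to L = 1
    fsim_scales: int = 4
    fsim_orientations: int = 4
    aggregation: str = "mean"  # {"mean", "min"} over the 5 views

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic range must be > 0")
        for name in ("ssim_k1", "ssim_k2", "ssim_sigma", "fsim_t1", "fsim_t2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.aggregation not in ("mean", "min"):
            raise ValueError("aggregation must be 'mean' or 'min'")


@dataclasses.dataclass
class SimilarityFeatures:
    """Per-pair similarity feature vector (aggregated over the 5 views)."""

    rmse: float
    psnr: float
    ssim: float
    fsim: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pixels(a) -> np.ndarray:
    if isinstance(a, ViewImage):
        a = a.pixels
    return np.asarray(a, dtype=np.float64)


def _check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")


def rmse(a, b) -> float:
    """Root mean squared pixel error."""
    x, y = _pixels(a), _pixels(b)
    _check_same_shape(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def psnr(a, b, cfg: SimilarityConfig | None = None) -> float:
    """Peak signal-to-noise ratio in dB, capped so features stay finite."""
    cfg = cfg or SimilarityConfig()
    e = rmse(a, b)
    if e == 0.0:
        return cfg.psnr_cap
    return float(min(20.0 * np.log10(cfg.dynamic_range / e), cfg.psnr_cap))


def _gaussian_kernel1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _local_mean(img: np.ndarray, k1d: np.ndarray, pad: int) -> np.ndarray:
    # separable Gaussian, then crop to the window-valid interior
    out = correlate(img, k1d[None, :], mode="nearest")
    out = correlate(out, k1d[:, None], mode="nearest")
    return out[pad:-pad, pad:-pad]


def ssim(a, b, cfg: SimilarityConfig | None = None) -> float:
    """Mean structural similarity with a Gaussian-weighted local window."""
    cfg = cfg or SimilarityConfig()
    x, y = _pixels(a), _pixels(b)
    _check_same_shape(x, y)
    if min(x.shape) < cfg.ssim_win:
        raise ValueError(
            f"image smaller than SSIM window ({cfg.ssim_win}): {x.shape}"
        )
    pad = (cfg.ssim_win - 1) // 2
    k = _gaussian_kernel1d(cfg.ssim_sigma, pad)
    L = cfg.dynamic_range
    c1 = (cfg.ssim_k1 * L) ** 2
    c2 = (cfg.ssim_k2 * L) ** 2

    ux = _local_mean(x, k, pad)
    uy = _local_mean(y, k, pad)
    uxx = _local_mean(x * x, k, pad)
    uyy = _local_mean(y * y, k, pad)
    uxy = _local_mean(x * y, k, pad)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy

    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    )
    return float(s.mean())


def _log_gabor_bank(
    shape: tuple, n_scales: int, n_orient: int
) -> list:
    """Frequency-domain log-Gabor filters (Kovesi's construction).

    Returns ``filters[s][o]`` ready to multiply with an fft2 of the image.
    """
    rows, cols = shape
    min_wavelength = 6.0
    mult = 2.0
    sigma_on_f = 0.55
    d_theta_on_sigma = 1.2

    fy = np.fft.fftfreq(rows)  # cycles per pixel, unshifted layout
    fx = np.fft.fftfreq(cols)
    x, y = np.meshgrid(fx, fy)
    radius = np.sqrt(x ** 2 + y ** 2)
    radius[0, 0] = 1.0  # avoid log(0) at DC; filter is zeroed there anyway
    theta = np.arctan2(-y, x)
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    # 15th-order Butterworth low-pass at 0.45 cycles/pixel tames boundary
    # ringing at the highest filter scale
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    radial = []
    for s in range(n_scales):
        f0 = 1.0 / (min_wavelength * mult ** s)
        lg = np.exp(
            -(np.log(radius / f0)) ** 2 / (2.0 * np.log(sigma_on_f) ** 2)
        )
        lg *= lowpass
        lg[0, 0] = 0.0
        radial.append(lg)

    theta_sigma = np.pi / n_orient / d_theta_on_sigma
    spreads = []
    for o in range(n_orient):
        angle = o * np.pi / n_orient
        ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
        dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spreads.append(np.exp(-(dtheta ** 2) / (2.0 * theta_sigma ** 2)))

    return [[radial[s] * spreads[o] for o in range(n_orient)]
            for s in range(n_scales)]


def phase_congruency(
    img: np.ndarray, n_scales: int = 4, n_orient: int = 4
) -> np.ndarray:
    """Phase-congruency map summed over orientations, in [0, 1].

    Follows the noise-compensated formulation used with log-Gabor banks:
    per orientation the local energy (projection of the filter responses on
    the mean phase vector) is noise-thresholded with an estimate from the
    smallest-scale amplitude median, and the orientation-summed energy is
    normalized by the summed response amplitude.
    """
    img = np.asarray(img, dtype=np.float64)
    bank = _log_gabor_bank(img.shape, n_scales, n_orient)
    fimg = np.fft.fft2(img)
    eps = 1e-4
    k_noise = 2.0
    mult = 2.0

    energy_all = np.zeros(img.shape)
    an_all = np.zeros(img.shape)
    for o in range(n_orient):
        eo = [np.fft.ifft2(fimg * bank[s][o]) for s in range(n_scales)]
        an = [np.abs(e) for e in eo]
        sum_an = np.sum(an, axis=0)
        sum_e = np.sum([e.real for e in eo], axis=0)
        sum_o = np.sum([e.imag for e in eo], axis=0)

        x_energy = np.sqrt(sum_e ** 2 + sum_o ** 2) + eps
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        energy = np.zeros(img.shape)
        for e in eo:
            energy += (
                e.real * mean_e
                + e.imag * mean_o
                - np.abs(e.real * mean_o - e.imag * mean_e)
            )

        # Rayleigh noise estimate from the smallest-scale amplitude median
        tau = np.median(an[0]) / np.sqrt(np.log(4.0))
        total_tau = tau * (1.0 - (1.0 / mult) ** n_scales) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        threshold = (noise_mean + k_noise * noise_sigma) / 1.7

        energy_all += np.maximum(energy - threshold, 0.0)
        an_all += sum_an

    return energy_all / (an_all + eps)


_SCHARR_X = np.array(
    [[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]
) / 16.0


def _gradient_magnitude(img: np.ndarray) -> np.ndarray:
    gx = correlate(img, _SCHARR_X, mode="nearest")
    gy = correlate(img, _SCHARR_X.T, mode="nearest")
    return np.sqrt(gx ** 2 + gy ** 2)


def fsim(a, b, cfg: SimilarityConfig | None = None) -> float:
    """Feature similarity index in [0, 1].

    Constant inputs carry no phase congruency anywhere; the pooled value is
    then defined as 1.0 for identical images and the unweighted mean of the
    per-pixel similarity otherwise.
    """
    cfg = cfg or SimilarityConfig()
    x, y = _pixels(a), _pixels(b)
    _check_same_shape(x, y)
    if min(x.shape) < 32:
        raise ValueError(f"image too small for FSIM (min side 32): {x.shape}")

    pc1 = phase_congruency(x, cfg.fsim_scales, cfg.fsim_orientations)
    pc2 = phase_congruency(y, cfg.fsim_scales, cfg.fsim_orientations)
    g1 = _gradient_magnitude(x)
    g2 = _gradient_magnitude(y)

    t1, t2 = cfg.fsim_t1, cfg.fsim_t2
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    s_l = s_pc * s_g
    pcm = np.maximum(pc1, pc2)

    denom = pcm.sum()
    if denom <= 0.0:
        if np.array_equal(x, y):
            return 1.0
        return float(np.clip(s_l.mean(), 0.0, 1.0))
    return float(np.clip((s_l * pcm).sum() / denom, 0.0, 1.0))


_METRICS = ("rmse", "psnr", "ssim", "fsim")


def similarity_features(
    views_orig: ViewSet,
    views_defaced: ViewSet,
    cfg: SimilarityConfig | None = None,
) -> SimilarityFeatures:
    """Aggregate the four metrics over corresponding view pairs."""
    cfg = cfg or SimilarityConfig()
    if views_orig.names != views_defaced.names:
        raise ValueError(
            "view sets do not match: "
            f"{views_orig.names} vs {views_defaced.names}"
        )
    per_view = {m: [] for m in _METRICS}
    for vo, vd in zip(views_orig, views_defaced):
        per_view["rmse"].append(rmse(vo, vd))
        per_view["psnr"].append(psnr(vo, vd, cfg))
        per_view["ssim"].append(ssim(vo, vd, cfg))
        per_view["fsim"].append(fsim(vo, vd, cfg))
    agg = np.mean if cfg.aggregation == "mean" else np.min
    return SimilarityFeatures(
        **{m: float(agg(per_view[m])) for m in _METRICS}
    )
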