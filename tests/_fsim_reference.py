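"""Independent reference implementation of the feature similarity index.

Follows the published algorithm directly — log-Gabor filter bank built on
centered, fft-shifted frequency grids, phase congruency with Rayleigh noise
compensation, Scharr gradients via explicit 2D convolution — structured
independently of the package implementation so the two can cross-check each
other.
"""

import numpy as np
from scipy.signal import convolve2d


def _shifted_freq_grids(rows, cols):
    # centered grids in cycles/pixel, then shifted to FFT layout
    if cols % 2:
        xr = np.arange(-(cols - 1) / 2, (cols - 1) / 2 + 1) / (cols - 1)
    else:
        xr = np.arange(-cols / 2, cols / 2) / cols
    if rows % 2:
        yr = np.arange(-(rows - 1) / 2, (rows - 1) / 2 + 1) / (rows - 1)
    else:
        yr = np.arange(-rows / 2, rows / 2) / rows
    x, y = np.meshgrid(xr, yr)
    return np.fft.ifftshift(x), np.fft.ifftshift(y)


def reference_phase_congruency(im, nscale=4, norient=4):
    im = np.asarray(im, float)
    rows, cols = im.shape
    x, y = _shifted_freq_grids(rows, cols)
    radius = np.hypot(x, y)
    radius[0, 0] = 1.0
    theta = np.arctan2(-y, x)

    min_wl, mult, sigma_onf = 6.0, 2.0, 0.55
    dtheta_on_sigma, k, eps = 1.2, 2.0, 1e-4
    lp = 1.0 / (1.0 + (radius / 0.45) ** (2 * 15))

    imfft = np.fft.fft2(im)
    energy_total = np.zeros((rows, cols))
    an_total = np.zeros((rows, cols))
    theta_sigma = np.pi / norient / dtheta_on_sigma

    for o in range(norient):
        angl = o * np.pi / norient
        ds = np.sin(theta) * np.cos(angl) - np.cos(theta) * np.sin(angl)
        dc = np.cos(theta) * np.cos(angl) + np.sin(theta) * np.sin(angl)
        spread = np.exp(-np.arctan2(ds, dc) ** 2 / (2 * theta_sigma ** 2))

        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        responses = []
        tau = None
        for s in range(nscale):
            fo = 1.0 / (min_wl * mult ** s)
            log_gabor = np.exp(
                -np.log(radius / fo) ** 2 / (2 * np.log(sigma_onf) ** 2)
            ) * lp
            log_gabor[0, 0] = 0.0
            eo = np.fft.ifft2(imfft * log_gabor * spread)
            responses.append(eo)
            an = np.abs(eo)
            sum_an += an
            sum_e += eo.real
            sum_o += eo.imag
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4))

        x_energy = np.hypot(sum_e, sum_o) + eps
        me, mo = sum_e / x_energy, sum_o / x_energy
        energy = np.zeros((rows, cols))
        for eo in responses:
            energy += eo.real * me + eo.imag * mo - np.abs(
                eo.real * mo - eo.imag * me
            )
        total_tau = tau * (1 - (1 / mult) ** nscale) / (1 - 1 / mult)
        t = (
            total_tau * np.sqrt(np.pi / 2)
            + k * total_tau * np.sqrt((4 - np.pi) / 2)
        ) / 1.7
        energy_total += np.maximum(energy - t, 0.0)
        an_total += sum_an
    return energy_total / (an_total + eps)


def _scharr(im):
    kx = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]], float) / 16.0
    padded = np.pad(im, 1, mode="edge")
    gx = convolve2d(padded, kx[::-1, ::-1], mode="valid")
    gy = convolve2d(padded, kx.T[::-1, ::-1], mode="valid")
    return np.hypot(gx, gy)


def reference_fsim(a, b, t1=0.85, t2=160.0 / 255.0 ** 2):
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pc1 = reference_phase_congruency(a)
    pc2 = reference_phase_congruency(b)
    g1, g2 = _scharr(a), _scharr(b)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1 ** 2 + pc2 ** 2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1 ** 2 + g2 ** 2 + t2)
    pcm = np.maximum(pc1, pc2)
    if pcm.sum() <= 0:
        if np.array_equal(a, b):
            return 1.0
        return float(np.clip((s_pc * s_g).mean(), 0, 1))
    return float(np.clip((s_pc * s_g * pcm).sum() / pcm.sum(), 0, 1))
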