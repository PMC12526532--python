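"""Full-reference image-quality metrics, implemented natively.

MS-SSIM, FSIM, VSI, GMSD and NLPD are computed from their defining
formulas on numpy/scipy; the learned-feature metrics DISTS and LPIPS
require a pretrained backbone and are exposed through a pluggable backend
registry — with no backend registered they raise
:class:`MetricUnavailableError` rather than silently falling back.

All metrics take same-shape HWC RGB images with values in [0, 1].
Similarity metrics (MS-SSIM, FSIM, VSI) equal 1 for identical images;
distance metrics (GMSD, NLPD, and conventionally DISTS/LPIPS) equal 0.
"""

from __future__ import annotations

import math
from typing import Callable, Dict

import numpy as np
from scipy import ndimage

__all__ = [
    "METRIC_NAMES", "MetricUnavailableError", "register_backend",
    "compute_raw_metric", "ms_ssim", "ssim", "fsim", "vsi", "gmsd", "nlpd",
]

METRIC_NAMES = ("DISTS", "LPIPS", "VSI", "MS-SSIM", "FSIM", "GMSD", "NLPD")

#: learned metrics needing a pretrained feature backbone
LEARNED_METRICS = ("DISTS", "LPIPS")

_BACKENDS: Dict[str, Callable] = {}


class MetricUnavailableError(RuntimeError):
    """Raised when a learned metric is requested without a backend."""


def register_backend(name: str, fn: Callable[[np.ndarray, np.ndarray], float]):
    """Register (or clear, with ``fn=None``) a learned-metric backend."""
    key = name.upper()
    if key not in LEARNED_METRICS:
        raise ValueError(f"{name} is not a pluggable learned metric")
    if fn is None:
        _BACKENDS.pop(key, None)
    else:
        _BACKENDS[key] = fn


def _check_pair(ref, test):
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    if ref.ndim != 3 or ref.shape[2] != 3:
        raise ValueError("expected HWC RGB images")
    return ref, test


def _luma(img: np.ndarray) -> np.ndarray:
    """ITU-R BT.601 luma from an RGB image (same value range as input)."""
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


# ---------------------------------------------------------------------------
# SSIM / MS-SSIM
# ---------------------------------------------------------------------------

_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


def _gauss_filt(x: np.ndarray, sigma: float, radius: int) -> np.ndarray:
    return ndimage.gaussian_filter(x, sigma, truncate=radius / sigma, mode="reflect")


def _ssim_cs(x: np.ndarray, y: np.ndarray, win: int = 11, sigma: float = 1.5,
             k1: float = 0.01, k2: float = 0.03):
    """Mean SSIM and mean contrast-structure term for one (luma) scale."""
    win = min(win, min(x.shape) if min(x.shape) % 2 else min(x.shape) - 1)
    win = max(win, 3)
    radius = win // 2
    c1, c2 = k1**2, k2**2
    mx = _gauss_filt(x, sigma, radius)
    my = _gauss_filt(y, sigma, radius)
    sxx = _gauss_filt(x * x, sigma, radius) - mx * mx
    syy = _gauss_filt(y * y, sigma, radius) - my * my
    sxy = _gauss_filt(x * y, sigma, radius) - mx * my
    cs_map = (2 * sxy + c2) / (sxx + syy + c2)
    ssim_map = (2 * mx * my + c1) / (mx * mx + my * my + c1) * cs_map
    return float(ssim_map.mean()), float(cs_map.mean())


def ssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Single-scale SSIM on luma (utility; not part of the composite)."""
    ref, test = _check_pair(ref, test)
    return _ssim_cs(_luma(ref), _luma(test))[0]


def _downsample2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
    x = x[:h, :w]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(ref: np.ndarray, test: np.ndarray, levels: int = 5) -> float:
    """Multi-scale SSIM with the standard five level weights.

    The 11-pixel Gaussian window shrinks automatically on scales smaller
    than the window so that small fixtures remain scorable; images must be
    at least ``2**(levels-1)`` pixels on a side.
    """
    ref, test = _check_pair(ref, test)
    x, y = _luma(ref), _luma(test)
    if min(x.shape) < 2 ** (levels - 1):
        raise ValueError(
            f"image too small for {levels}-level pyramid: {x.shape}")
    weights = _MSSSIM_WEIGHTS[:levels]
    vals = []
    for lev in range(levels):
        s, cs = _ssim_cs(x, y)
        vals.append(s if lev == levels - 1 else cs)
        if lev < levels - 1:
            x, y = _downsample2(x), _downsample2(y)
    out = 1.0
    for v, w in zip(vals, weights):
        out *= max(v, 1e-6) ** w
    return float(out)


# ---------------------------------------------------------------------------
# GMSD
# ---------------------------------------------------------------------------

def gmsd(ref: np.ndarray, test: np.ndarray, c: float = 0.0026) -> float:
    """Gradient-magnitude similarity deviation (distance; 0 = identical).

    Prewitt gradients on 2x-downsampled luma; ``c`` is the published
    stabilizer rescaled to the [0, 1] intensity range.
    """
    ref, test = _check_pair(ref, test)
    x, y = _downsample2(_luma(ref)), _downsample2(_luma(test))
    hx = np.array([[1, 0, -1]] * 3) / 3.0
    gx = np.hypot(ndimage.convolve(x, hx, mode="nearest"),
                  ndimage.convolve(x, hx.T, mode="nearest"))
    gy = np.hypot(ndimage.convolve(y, hx, mode="nearest"),
                  ndimage.convolve(y, hx.T, mode="nearest"))
    gms = (2 * gx * gy + c) / (gx**2 + gy**2 + c)
    return float(gms.std())


# ---------------------------------------------------------------------------
# phase congruency (log-Gabor), used by FSIM
# ---------------------------------------------------------------------------

def _log_gabor_grid(h, w):
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0
    theta = np.arctan2(-fy, fx)
    return radius, theta


def _phase_congruency(img: np.ndarray, nscale: int = 4, norient: int = 4,
                      min_wavelength: float = 6.0, mult: float = 2.0,
                      sigma_onf: float = 0.55, k_noise: float = 2.0,
                      epsilon: float = 1e-4) -> np.ndarray:
    """2-D phase congruency via log-Gabor quadrature filters.

    Follows the standard formulation (energy normalized by total amplitude,
    with a median-based noise threshold); returns a map in [0, 1].
    """
    h, w = img.shape
    F = np.fft.fft2(img)
    radius, theta = _log_gabor_grid(h, w)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    sigma_theta = math.pi / norient / 1.2

    pc_sum = np.zeros((h, w))
    for o in range(norient):
        angl = o * math.pi / norient
        ds = sintheta * math.cos(angl) - costheta * math.sin(angl)
        dc = costheta * math.cos(angl) + sintheta * math.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * sigma_theta**2))

        sum_e = np.zeros((h, w))
        sum_o = np.zeros((h, w))
        sum_amp = np.zeros((h, w))
        tau = None
        for s in range(nscale):
            wavelength = min_wavelength * mult**s
            fo = 1.0 / wavelength
            log_gabor = np.exp(-(np.log(radius / fo))**2 /
                               (2 * math.log(sigma_onf)**2))
            log_gabor[0, 0] = 0.0
            eo = np.fft.ifft2(F * log_gabor * spread)
            e, od = eo.real, eo.imag
            amp = np.hypot(e, od)
            sum_e += e
            sum_o += od
            sum_amp += amp
            if s == 0:
                tau = np.median(amp) / math.sqrt(math.log(4))
        x_energy = np.hypot(sum_e, sum_o) + epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        # re-accumulate projected energy
        energy = np.zeros((h, w))
        for s in range(nscale):
            wavelength = min_wavelength * mult**s
            fo = 1.0 / wavelength
            log_gabor = np.exp(-(np.log(radius / fo))**2 /
                               (2 * math.log(sigma_onf)**2))
            log_gabor[0, 0] = 0.0
            eo = np.fft.ifft2(F * log_gabor * spread)
            e, od = eo.real, eo.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # expected noise energy from the smallest-scale amplitude estimate
        total_tau = tau * (1 - (1 / mult)**nscale) / (1 - 1 / mult)
        noise_mean = total_tau * math.sqrt(math.pi / 2)
        noise_sigma = total_tau * math.sqrt((4 - math.pi) / 2)
        threshold = noise_mean + k_noise * noise_sigma
        energy = np.maximum(energy - threshold, 0.0)
        pc_sum += energy / (sum_amp + epsilon)
    return pc_sum / norient


_SCHARR = np.array([[3, 0, -3], [10, 0, -10], [3, 0, -3]]) / 16.0


def _scharr_mag(x: np.ndarray) -> np.ndarray:
    return np.hypot(ndimage.convolve(x, _SCHARR, mode="nearest"),
                    ndimage.convolve(x, _SCHARR.T, mode="nearest"))


def _iqa_downsample(x: np.ndarray) -> np.ndarray:
    """Published FSIM/VSI pre-processing: average filter + decimation so the
    shorter side is near 256 pixels."""
    f = max(1, int(round(min(x.shape[:2]) / 256)))
    if f == 1:
        return x
    x = ndimage.uniform_filter(x, size=(f, f) + (0,) * (x.ndim - 2), mode="nearest")
    return x[::f, ::f]


def fsim(ref: np.ndarray, test: np.ndarray, t1: float = 0.85,
         t2: float = 160.0) -> float:
    """Feature similarity index on luma (phase congruency + gradient).

    ``S = S_PC * S_G`` pooled with the elementwise maximum phase congruency
    as weight; gradient term on a [0, 255] scale with Scharr filters.
    """
    ref, test = _check_pair(ref, test)
    x = _iqa_downsample(_luma(ref) * 255.0)
    y = _iqa_downsample(_luma(test) * 255.0)
    pc1 = _phase_congruency(x)
    pc2 = _phase_congruency(y)
    g1, g2 = _scharr_mag(x), _scharr_mag(y)
    s_pc = (2 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pcm = np.maximum(pc1, pc2)
    return float((s_pc * s_g * pcm).sum() / (pcm.sum() + 1e-12))


# ---------------------------------------------------------------------------
# VSI (visual-saliency-induced index)
# ---------------------------------------------------------------------------

def _sdsp_saliency(rgb255: np.ndarray, sigma_f: float = 6.2,
                   omega0: float = 0.002, sigma_d: float = 114.0,
                   sigma_c: float = 0.25) -> np.ndarray:
    """SDSP saliency: band-passed CIELAB frequency prior x center prior x
    warm-color prior."""
    from skimage.color import rgb2lab

    lab = rgb2lab(np.clip(rgb255 / 255.0, 0, 1))
    h, w = lab.shape[:2]
    radius, _ = _log_gabor_grid(h, w)
    lg = np.exp(-((np.log(radius / omega0))**2) / (2 * math.log(sigma_f)**2)) \
        if sigma_f != 1 else np.zeros((h, w))
    lg[0, 0] = 0.0
    sf_sq = np.zeros((h, w))
    for c in range(3):
        band = np.fft.ifft2(np.fft.fft2(lab[..., c]) * lg)
        sf_sq += np.abs(band) ** 2
    s_f = np.sqrt(sf_sq)

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    s_d = np.exp(-((yy - cy)**2 + (xx - cx)**2) / sigma_d**2)

    a, b = lab[..., 1], lab[..., 2]
    an = (a - a.min()) / (a.max() - a.min() + 1e-12)
    bn = (b - b.min()) / (b.max() - b.min() + 1e-12)
    s_c = 1.0 - np.exp(-(an**2 + bn**2) / sigma_c**2)
    return s_f * s_d * s_c


def vsi(ref: np.ndarray, test: np.ndarray, c1: float = 1.27, c2: float = 386.0,
        c3: float = 130.0, alpha: float = 0.40, beta: float = 0.02) -> float:
    """Visual-saliency-induced index with SDSP saliency, Scharr gradients
    and LMN color-opponent chrominance."""
    ref, test = _check_pair(ref, test)
    r255 = _iqa_downsample(ref * 255.0)
    t255 = _iqa_downsample(test * 255.0)
    vs1 = _sdsp_saliency(r255)
    vs2 = _sdsp_saliency(t255)

    def lmn(img):
        r, g, b = img[..., 0], img[..., 1], img[..., 2]
        l = 0.06 * r + 0.63 * g + 0.27 * b
        m = 0.30 * r + 0.04 * g - 0.35 * b
        n = 0.34 * r - 0.60 * g + 0.17 * b
        return l, m, n

    l1, m1, n1 = lmn(r255)
    l2, m2, n2 = lmn(t255)
    g1, g2 = _scharr_mag(l1), _scharr_mag(l2)

    s_vs = (2 * vs1 * vs2 + c1) / (vs1**2 + vs2**2 + c1)
    s_g = (2 * g1 * g2 + c2) / (g1**2 + g2**2 + c2)
    s_m = (2 * m1 * m2 + c3) / (m1**2 + m2**2 + c3)
    s_n = (2 * n1 * n2 + c3) / (n1**2 + n2**2 + c3)
    s_c = np.clip(s_m * s_n, 1e-12, None)
    s = s_vs * np.clip(s_g, 0, None) ** alpha * s_c ** beta
    vsm = np.maximum(vs1, vs2)
    return float((s * vsm).sum() / (vsm.sum() + 1e-12))


# ---------------------------------------------------------------------------
# NLPD (normalized Laplacian pyramid distance)
# ---------------------------------------------------------------------------

_BINOM5 = np.outer([1, 4, 6, 4, 1], [1, 4, 6, 4, 1]) / 256.0


def _nlp_transform(x: np.ndarray, levels: int, sigma: float = 0.17):
    """Laplacian pyramid with divisive normalization by local amplitude."""
    bands = []
    cur = x
    for _ in range(levels - 1):
        low = ndimage.convolve(cur, _BINOM5, mode="reflect")
        down = low[::2, ::2]
        up = np.zeros_like(cur)
        up[::2, ::2] = down
        up = ndimage.convolve(up, 4 * _BINOM5, mode="reflect")
        band = cur - up
        bands.append(band)
        cur = down
    bands.append(cur - cur.mean())
    out = []
    for band in bands:
        denom = sigma + ndimage.uniform_filter(np.abs(band), size=5, mode="reflect")
        out.append(band / denom)
    return out


def nlpd(ref: np.ndarray, test: np.ndarray, levels: int = 6) -> float:
    """Root-mean distance between normalized Laplacian pyramids (0 = same).

    This follows the published transform's structure (Laplacian pyramid +
    local divisive normalization) with a fixed binomial pyramid filter and
    a 5x5 amplitude pool standing in for the optimized normalization
    filters, which are not reproduced here.
    """
    ref, test = _check_pair(ref, test)
    x, y = _luma(ref), _luma(test)
    levels = min(levels, max(1, int(math.log2(min(x.shape))) - 2))
    zx = _nlp_transform(x, levels)
    zy = _nlp_transform(y, levels)
    per_level = [np.sqrt(np.mean((a - b) ** 2)) for a, b in zip(zx, zy)]
    return float(np.sqrt(np.mean(np.square(per_level))))


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_NATIVE = {"MS-SSIM": ms_ssim, "FSIM": fsim, "VSI": vsi,
           "GMSD": gmsd, "NLPD": nlpd}


def compute_raw_metric(name: str, ref: np.ndarray, test: np.ndarray) -> float:
    """Raw value of one of the seven metrics (learned ones need a backend)."""
    key = name.upper()
    if key in _NATIVE:
        return _NATIVE[key](ref, test)
    if key in LEARNED_METRICS:
        backend = _BACKENDS.get(key)
        if backend is None:
            raise MetricUnavailableError(
                f"{key} requires a pretrained feature backend; none registered "
                "(use register_backend)")
        ref, test = _check_pair(ref, test)
        return float(backend(ref, test))
    raise ValueError(f"unknown metric {name!r}; expected one of {METRIC_NAMES}")
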