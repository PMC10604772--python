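"""Edge-preserving guided (directed) filtering for pathology tiles.

The denoiser expresses its output as a local linear transform of a
guidance image: within each square window the output is ``a*K + b`` where
the slope ``a`` and offset ``b`` come from window variance/covariance
statistics of the guide ``K`` and the noisy input ``q``.  Using the
grayscale of the tile itself as guidance removes Gaussian and
salt-and-pepper noise while keeping nuclear boundaries sharp: high-variance
(edge) windows get ``a ~ 1`` (pass-through), flat windows get ``a ~ 0``
and are replaced by their window mean.

All images are float arrays on [0, 1]; grayscale images are 2-D, RGB
images are (H, W, 3).  Box means are separable running sums, so the cost
is O(N) regardless of the window radius, and border windows are
normalized by their in-bounds pixel count (constant images are exact
fixed points everywhere, including borders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DenoiseParams",
    "FilterCoefficients",
    "to_grayscale",
    "box_mean",
    "guided_filter",
    "guided_filter_rgb",
    "bilateral_post",
]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class DenoiseParams:
    """Guided-filter configuration.

    radius
        Window half-width r in pixels; the window is (2r+1) x (2r+1).
    epsilon
        Regularizer on the squared normalized-intensity scale. Larger
        values push the filter toward a plain box mean; 0 makes it an
        exact identity when the guide equals the input.
    """

    radius: int = 4
    epsilon: float = 0.01
    bilateral_enabled: bool = False
    bilateral_sigma_spatial: float = 3.0
    bilateral_sigma_range: float = 0.1

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.bilateral_sigma_spatial <= 0 or self.bilateral_sigma_range <= 0:
            raise ValueError("bilateral sigmas must be positive")


@dataclass
class FilterCoefficients:
    """Per-pixel linear coefficients of the guided filter."""

    a: np.ndarray
    b: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray


def _check_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"{name} must be a 2-D grayscale array, got shape {img.shape}")
    return img


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an RGB image on [0, 1]."""
    img = _check_rgb(img)
    return img @ _LUMA


def _sliding_sum_1d(x: np.ndarray, radius: int, axis: int) -> np.ndarray:
    """Windowed sum over ``[i-radius, i+radius]`` along one axis, O(N)."""
    n = x.shape[axis]
    c = np.cumsum(x, axis=axis)
    zeros_shape = list(x.shape)
    zeros_shape[axis] = 1
    c = np.concatenate([np.zeros(zeros_shape), c], axis=axis)
    hi = np.minimum(np.arange(n) + radius + 1, n)
    lo = np.maximum(np.arange(n) - radius, 0)
    return np.take(c, hi, axis=axis) - np.take(c, lo, axis=axis)


def box_mean(img: np.ndarray, radius: int) -> np.ndarray:
    """Count-normalized box mean over (2r+1)^2 windows, O(N) in total work."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = _check_gray(img)
    s = _sliding_sum_1d(_sliding_sum_1d(img, radius, 0), radius, 1)
    ones = np.ones_like(img)
    counts = _sliding_sum_1d(_sliding_sum_1d(ones, radius, 0), radius, 1)
    return s / counts


def guided_filter(
    q: np.ndarray,
    guide: np.ndarray,
    params: DenoiseParams,
    return_coeffs: bool = False,
):
    """Filter ``q`` steered by guidance image ``guide``.

    Implements the standard box-statistics form: per window,
    ``a_k = cov(K, q) / (var(K) + eps)`` and ``b_k = mean(q) - a_k*mean(K)``;
    each output pixel averages the linear models of every window covering
    it, giving ``p_i = mean_a_i * K_i + mean_b_i``.

    Zero-variance windows with ``eps == 0`` take the limit from eps -> 0+:
    ``a = 0``, ``b = mean(q)``, which reproduces the input exactly on
    constant regions.
    """
    q = _check_gray(q, "q")
    guide = _check_gray(guide, "guide")
    if q.shape != guide.shape:
        raise ValueError(f"shape mismatch: q {q.shape} vs guide {guide.shape}")
    r, eps = params.radius, params.epsilon

    mean_k = box_mean(guide, r)
    mean_q = box_mean(q, r)
    corr_k = box_mean(guide * guide, r)
    corr_kq = box_mean(guide * q, r)
    var_k = corr_k - mean_k * mean_k
    cov_kq = corr_kq - mean_k * mean_q

    denom = var_k + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, cov_kq / np.where(denom > 0, denom, 1.0), 0.0)
    b = mean_q - a * mean_k

    mean_a = box_mean(a, r)
    mean_b = box_mean(b, r)
    out = mean_a * guide + mean_b
    if return_coeffs:
        return out, FilterCoefficients(a=a, b=b, mean_a=mean_a, mean_b=mean_b)
    return out


def guided_filter_rgb(img: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Denoise an RGB tile: each channel is guided by the shared grayscale.

    Output is clipped to [0, 1].  When ``params.bilateral_enabled`` the
    bilateral post-filter is applied afterwards.
    """
    img = _check_rgb(img)
    guide = to_grayscale(img)
    out = np.stack(
        [guided_filter(img[:, :, c], guide, params) for c in range(3)], axis=-1
    )
    out = np.clip(out, 0.0, 1.0)
    if params.bilateral_enabled:
        out = bilateral_post(out, params)
    return out


def bilateral_post(img: np.ndarray, params: DenoiseParams) -> np.ndarray:
    """Gaussian range/spatial bilateral smoothing, per channel.

    The window is truncated at 3 sigma_spatial; weights are
    ``exp(-d^2/(2*ss^2)) * exp(-(I_p - I_q)^2/(2*sr^2))`` normalized per
    pixel.  As sigma_range grows this converges to a plain (normalized,
    truncated) Gaussian blur.
    """
    if params.bilateral_sigma_spatial <= 0 or params.bilateral_sigma_range <= 0:
        raise ValueError("bilateral sigmas must be positive")
    img = _check_rgb(img)
    ss, sr = params.bilateral_sigma_spatial, params.bilateral_sigma_range
    radius = int(np.ceil(3.0 * ss))
    h, w, _ = img.shape
    pad = np.pad(img, ((radius, radius), (radius, radius), (0, 0)), mode="edge")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            w_s = np.exp(-(dy * dy + dx * dx) / (2.0 * ss * ss))
            shifted = pad[radius + dy:radius + dy + h, radius + dx:radius + dx + w, :]
            diff = shifted - img
            w_r = np.exp(-(diff * diff) / (2.0 * sr * sr))
            num += w_s * w_r * shifted
            den += w_s * w_r
    return num / den
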