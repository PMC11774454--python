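"""Traditional (non-task-based) image-quality metrics: RMSE and SSIM.

SSIM here uses a pinned, fully specified convention so that results are
exactly reproducible: local statistics are computed with a normalized
Gaussian window (default sigma 1.5 px, truncated at 3 sigma), edge-replicate
padding, and population (not sample) moments; the score is the mean of the
local SSIM map over all pixels.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.ndimage import correlate


__all__ = ["rmse", "ssim", "gaussian_window"]

ArrayLike = Union[np.ndarray, "object"]


def _pixels(x) -> np.ndarray:
    """Accept ObjectImage / ReconImage / plain arrays."""
    if hasattr(x, "pixels"):
        x = x.pixels
    return np.asarray(x, dtype=float)


def rmse(x, ref) -> float:
    """Root-mean-squared pixel error between an image and a reference."""
    xp, rp = _pixels(x), _pixels(ref)
    if xp.shape != rp.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((xp - rp) ** 2)))


def gaussian_window(sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian window truncated at 3 sigma."""
    radius = int(np.ceil(3.0 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    w = np.outer(g1, g1)
    return w / w.sum()


def ssim(x, ref, window_sigma: float = 1.5, K1: float = 0.01,
         K2: float = 0.03, dynamic_range: float | None = None) -> float:
    """Mean structural-similarity index between two images.

    ``dynamic_range`` (the constant L in C1=(K1 L)^2, C2=(K2 L)^2) defaults
    to ``ref.max() - ref.min()`` and must be positive.
    """
    xp, rp = _pixels(x), _pixels(ref)
    if xp.shape != rp.shape:
        raise ValueError("shape mismatch")
    if dynamic_range is None:
        dynamic_range = float(rp.max() - rp.min())
    if not (dynamic_range > 0):
        raise ValueError("dynamic_range must be positive")
    C1 = (K1 * dynamic_range) ** 2
    C2 = (K2 * dynamic_range) ** 2
    w = gaussian_window(window_sigma)

    def local_mean(img: np.ndarray) -> np.ndarray:
        return correlate(img, w, mode="nearest")

    mu_x, mu_y = local_mean(xp), local_mean(rp)
    var_x = local_mean(xp * xp) - mu_x**2
    var_y = local_mean(rp * rp) - mu_y**2
    cov = local_mean(xp * rp) - mu_x * mu_y
    ssim_map = ((2 * mu_x * mu_y + C1) * (2 * cov + C2)) / (
        (mu_x**2 + mu_y**2 + C1) * (var_x + var_y + C2))
    return float(ssim_map.mean())
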