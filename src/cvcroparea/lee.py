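"""Enhanced Lee adaptive speckle filter.

Speckle in L-look SAR intensity is multiplicative with coefficient of
variation C_u = 1/sqrt(L).  The enhanced Lee filter compares the local
window coefficient of variation C_i = s/m (window mean m, window standard
deviation s) with C_u and the point-target bound C_max = sqrt(1 + 2/L)
and blends accordingly:

* homogeneous  (C_i <= C_u):     output = m        (pure averaging)
* heterogeneous (C_u < C_i < C_max):
      output = m + W * (center - m),
      W = exp(-damping * (C_i - C_u) / (C_max - C_i))
* point target (C_i >= C_max):   output = center   (preserved exactly)

Invalid (NaN) pixels propagate and are excluded from window statistics;
windows shrink at the raster edges.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["enhanced_lee_filter"]


def _window_stats(image: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware local mean and population std with shrinking edge windows."""
    valid = np.isfinite(image)
    filled = np.where(valid, image, 0.0).astype(np.float64)
    area = float(size * size)
    count = ndimage.uniform_filter(valid.astype(np.float64), size, mode="constant") * area
    count = np.round(count)
    total = ndimage.uniform_filter(filled, size, mode="constant") * area
    total_sq = ndimage.uniform_filter(filled * filled, size, mode="constant") * area
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(count > 0, total / count, np.nan)
        var = np.where(count > 0, total_sq / count - m * m, np.nan)
    s = np.sqrt(np.clip(var, 0.0, None))
    return m, s


def enhanced_lee_filter(
    image: np.ndarray,
    window_size: int = 7,
    looks_L: float = 9.0,
    damping: float = 1.0,
) -> np.ndarray:
    """Despeckle a single linear-power intensity image.

    Parameters
    ----------
    image:
        2-D intensity image in linear power units; NaN marks invalid pixels.
    window_size:
        Odd window side length, default 7.
    looks_L:
        Equivalent number of looks of the speckle, default 9.
    damping:
        Damping factor of the heterogeneous-branch weight, default 1.
    """
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    if not looks_L >= 1:
        raise ValueError("looks_L must be >= 1")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("enhanced_lee_filter expects a single 2-D image")

    c_u = 1.0 / np.sqrt(looks_L)
    c_max = np.sqrt(1.0 + 2.0 / looks_L)

    m, s = _window_stats(image, window_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_i = np.where(m > 0, s / m, 0.0)

    out = np.where(c_i <= c_u, m, np.nan)
    hetero = (c_i > c_u) & (c_i < c_max)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        w = np.exp(-damping * (c_i - c_u) / (c_max - c_i))
    out = np.where(hetero, m + w * (image - m), out)
    out = np.where(c_i >= c_max, image, out)
    out[~np.isfinite(image)] = np.nan
    return out
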