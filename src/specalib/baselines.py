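"""Model-based illuminant estimators from the color-constancy literature,
extended to multispectral cubes.

All four pool a per-band statistic over the image and L1-normalize the
result: max-RGB (per-band maximum), gray-world (per-band mean),
shades-of-gray (Minkowski mean of order ``p``, default 6, which
interpolates between the two) and gray-edge (Minkowski mean of the
Gaussian-smoothed gradient magnitude).  They serve as comparison baselines
for the specular-highlight method and accept the same optional valid-pixel
mask; by default the whole image is used, as is conventional in the
color-constancy literature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import IlluminantSpectrum, SpectralCube, l1_normalize
from .errors import ConfigurationError, DegenerateInputError, DimensionError

__all__ = [
    "max_rgb",
    "gray_world",
    "shades_of_gray",
    "gray_edge",
    "minkowski_mean",
]

DEFAULT_P = 6.0
DEFAULT_SIGMA = 2.0


def _resolve_mask(cube: SpectralCube, mask) -> np.ndarray:
    if mask is None:
        return np.ones(cube.data.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.data.shape[:2]:
        raise DimensionError("mask shape does not match the cube")
    if not mask.any():
        raise DegenerateInputError("mask selects no pixels")
    return mask


def minkowski_mean(values: np.ndarray, p: float) -> float:
    """``(mean |x|^p)^(1/p)``; ``p = inf`` gives the maximum.

    Computed with max-scaling so large orders do not overflow.
    """
    if not (p >= 1 or math.isinf(p)):
        raise ConfigurationError(f"Minkowski order must be >= 1 or inf; got {p}")
    values = np.abs(np.asarray(values, dtype=float).ravel())
    m = values.max(initial=0.0)
    if math.isinf(p) or m == 0.0:
        return float(m)
    return float(m * np.mean((values / m) ** p) ** (1.0 / p))


def max_rgb(cube: SpectralCube, mask=None) -> IlluminantSpectrum:
    """Per-band maximum over the considered pixels (white-patch assumption)."""
    mask = _resolve_mask(cube, mask)
    scores = cube.data[mask].max(axis=0)
    return IlluminantSpectrum(l1_normalize(scores), normalized=True)


def gray_world(cube: SpectralCube, mask=None) -> IlluminantSpectrum:
    """Per-band mean over the considered pixels (achromatic-average assumption)."""
    mask = _resolve_mask(cube, mask)
    scores = cube.data[mask].mean(axis=0)
    return IlluminantSpectrum(l1_normalize(scores), normalized=True)


def shades_of_gray(cube: SpectralCube, mask=None, p: float = DEFAULT_P) -> IlluminantSpectrum:
    """Per-band Minkowski mean of order ``p``: reduces to gray-world at
    ``p = 1`` and to max-RGB at ``p = inf``."""
    mask = _resolve_mask(cube, mask)
    pixels = cube.data[mask]
    scores = np.array([minkowski_mean(pixels[:, k], p) for k in range(pixels.shape[1])])
    return IlluminantSpectrum(l1_normalize(scores), normalized=True)


def gray_edge(
    cube: SpectralCube,
    mask=None,
    p: float = DEFAULT_P,
    sigma: float = DEFAULT_SIGMA,
) -> IlluminantSpectrum:
    """Minkowski mean of the smoothed gradient magnitude, per band.

    Each band is smoothed with an isotropic Gaussian (std ``sigma`` px,
    reflection padding); the gradient is taken with central differences. A
    border of ``ceil(3 * sigma) + 1`` pixels is excluded from the pooling
    so padding artefacts never enter the statistic.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    mask = _resolve_mask(cube, mask)
    rows, cols, n_bands = cube.data.shape
    border = int(math.ceil(3.0 * sigma)) + 1
    if rows <= 2 * border or cols <= 2 * border:
        raise ConfigurationError(
            f"image too small for gray-edge with sigma={sigma} (needs > {2 * border} px)"
        )
    interior = np.zeros_like(mask)
    interior[border:-border, border:-border] = True
    pool_mask = mask & interior
    if not pool_mask.any():
        raise DegenerateInputError("mask selects no interior pixels")

    scores = np.empty(n_bands)
    for k in range(n_bands):
        smoothed = gaussian_filter(cube.data[:, :, k], sigma, mode="reflect")
        gi, gj = np.gradient(smoothed)
        magnitude = np.hypot(gi, gj)
        scores[k] = minkowski_mean(magnitude[pool_mask], p)
    if np.all(scores**2 < 1e-12):
        raise DegenerateInputError(
            "gradient energy is zero in every band (uniform image?)"
        )
    return IlluminantSpectrum(l1_normalize(scores), normalized=True)
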