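"""Illuminant recovery from specular highlights in low-exposure images.

The method rests on the dichromatic reflection model: in a specular
highlight the reflected spectrum is a scaled copy of the illuminant,
independent of the tissue underneath.  Because highlights saturate the
sensor at normal exposure times, dedicated low-exposure calibration
images are used instead.  The pipeline is:

1. *Valid-pixel mask* -- discard pixels that are underexposed (below the
   dark-current level ``i_min``) or overexposed (above the nonlinearity
   ceiling ``i_max``, default 950 counts) in any band.
2. *Highlight selection* -- among valid pixels take the ``n_p`` (default
   100) of greatest lightness (mean intensity over bands).
3. *Estimation* -- L1-normalize each selected pixel's band vector and
   average; the mean, re-normalized, is the illuminant estimate.
4. *Exposure selection* -- repeat over a bracketed exposure series and
   keep the exposure maximizing the goodness metric
   ``G = median((I_L - Dbar) / Dbar)``, the median relative excess of
   highlight lightness over the mean dark lightness ``Dbar``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import IlluminantSpectrum, SpectralCube, l1_normalize, lightness
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    DimensionError,
    NoHighlightsError,
)

__all__ = [
    "ValidityThresholds",
    "HighlightSelection",
    "ExposureSeries",
    "GoodnessProfile",
    "CalibrationResult",
    "compute_valid_mask",
    "select_highlight_pixels",
    "estimate_illuminant",
    "goodness",
    "select_exposure",
    "calibrate",
]

DEFAULT_I_MAX = 950.0
DEFAULT_N_P = 100
#: ``i_min = dark mean + DARK_SIGMA_FACTOR * dark std`` at the given exposure.
DARK_SIGMA_FACTOR = 3.0


@dataclass(frozen=True)
class ValidityThresholds:
    """Intensity window (in ADC counts) for a pixel to count as valid."""

    i_min: float
    i_max: float = DEFAULT_I_MAX

    def __post_init__(self) -> None:
        if not 0 <= self.i_min < self.i_max:
            raise ConfigurationError(
                f"need 0 <= i_min < i_max; got ({self.i_min}, {self.i_max})"
            )

    @classmethod
    def from_dark_statistics(
        cls,
        dark_mean: float,
        dark_std: float,
        i_max: float = DEFAULT_I_MAX,
        sigma_factor: float = DARK_SIGMA_FACTOR,
    ) -> "ValidityThresholds":
        """Lower threshold at the dark-current level for this exposure."""
        return cls(i_min=max(0.0, dark_mean + sigma_factor * dark_std), i_max=i_max)


@dataclass(frozen=True)
class HighlightSelection:
    """The highlight pixels chosen from one cube."""

    indices: np.ndarray  # (n, 2) array of (row, col), ordered
    n_p: int
    lightness_values: np.ndarray  # lightness at the selected pixels, same order

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        lv = np.asarray(self.lightness_values, dtype=float)
        if idx.ndim != 2 or idx.shape[1] != 2 or idx.shape[0] != lv.shape[0]:
            raise DimensionError("indices must be (n, 2) aligned with lightness values")
        if idx.shape[0] == 0:
            raise DegenerateInputError("empty highlight selection")
        if idx.shape[0] > self.n_p:
            raise ConfigurationError("selection larger than requested n_p")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "lightness_values", lv)

    def __len__(self) -> int:
        return self.indices.shape[0]


@dataclass(frozen=True)
class ExposureSeries:
    """Bracketed cubes plus dark statistics, ordered by exposure time."""

    entries: tuple[tuple[float, SpectralCube], ...]
    dark_lightness_mean: np.ndarray  # Dbar(T_exp), one per entry
    dark_lightness_std: np.ndarray

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ConfigurationError("exposure series must not be empty")
        times = np.array([t for t, _ in self.entries], dtype=float)
        if np.any(times <= 0) or not np.all(np.diff(times) > 0):
            raise ConfigurationError("exposure times must be strictly increasing and > 0")
        mean = np.asarray(self.dark_lightness_mean, dtype=float)
        std = np.asarray(self.dark_lightness_std, dtype=float)
        if mean.shape != times.shape or std.shape != times.shape:
            raise DimensionError("dark statistics must be present for every entry")
        object.__setattr__(self, "dark_lightness_mean", mean)
        object.__setattr__(self, "dark_lightness_std", std)

    @property
    def exposures(self) -> np.ndarray:
        return np.array([t for t, _ in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GoodnessProfile:
    """Per-exposure goodness ``G``; exposures with no valid highlight pixel
    carry ``-inf`` and are never selected."""

    exposures: np.ndarray
    values: np.ndarray

    def best(self) -> tuple[float, float]:
        """(exposure, G) of the maximum; ties resolved to the shorter exposure."""
        if not np.any(np.isfinite(self.values)):
            raise NoHighlightsError("no exposure in the series has valid highlight pixels")
        best = np.flatnonzero(self.values == self.values.max())[0]
        return float(self.exposures[best]), float(self.values[best])


@dataclass(frozen=True)
class CalibrationResult:
    """Estimate plus diagnostics of the winning exposure."""

    illuminant: IlluminantSpectrum
    exposure_ms: float
    goodness_profile: GoodnessProfile
    selection: HighlightSelection
    valid_mask: np.ndarray
    thresholds: ValidityThresholds


def compute_valid_mask(cube: SpectralCube, thresholds: ValidityThresholds) -> np.ndarray:
    """Boolean (rows, cols) mask: a pixel is valid iff every band intensity
    lies strictly inside ``(i_min, i_max)``."""
    data = cube.data
    return np.all((data > thresholds.i_min) & (data < thresholds.i_max), axis=2)


def select_highlight_pixels(
    lightness_image: np.ndarray,
    mask: np.ndarray,
    n_p: int = DEFAULT_N_P,
) -> HighlightSelection:
    """The ``n_p`` valid pixels of greatest lightness.

    Fewer than ``n_p`` valid pixels is not an error (all are returned);
    zero valid pixels is.  Order and ties are deterministic: descending
    lightness, then ascending row, then ascending column.
    """
    lightness_image = np.asarray(lightness_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if lightness_image.shape != mask.shape:
        raise DimensionError("lightness image and mask shapes differ")
    if n_p < 1:
        raise ConfigurationError("n_p must be >= 1")
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoHighlightsError("no valid pixel in this cube")
    values = lightness_image[rows, cols]
    # lexsort: last key is primary -> (-lightness, row, col)
    order = np.lexsort((cols, rows, -values))[: min(n_p, rows.size)]
    idx = np.column_stack([rows[order], cols[order]])
    return HighlightSelection(indices=idx, n_p=n_p, lightness_values=values[order])


def estimate_illuminant(cube: SpectralCube, selection: HighlightSelection) -> IlluminantSpectrum:
    """Mean of the L1-normalized band vectors of the selected pixels,
    re-normalized to sum exactly one."""
    pixels = cube.data[selection.indices[:, 0], selection.indices[:, 1], :]
    sums = pixels.sum(axis=1)
    if np.any(sums <= 0):
        raise DegenerateInputError("a selected highlight pixel has all-zero bands")
    normalized = pixels / sums[:, None]
    return IlluminantSpectrum(l1_normalize(normalized.mean(axis=0)), normalized=True)


def goodness(selection: HighlightSelection, dark_lightness_mean: float) -> float:
    """Goodness ``G``: median over the selected pixels of the relative excess
    of lightness over the mean dark lightness ``Dbar``."""
    if not dark_lightness_mean > 0:
        raise ConfigurationError(
            "dark statistics required: mean dark lightness must be > 0"
        )
    return float(
        np.median((selection.lightness_values - dark_lightness_mean) / dark_lightness_mean)
    )


def _per_exposure(
    series: ExposureSeries,
    i_max: float,
    n_p: int,
    sigma_factor: float,
):
    """Valid mask, selection (or None) and G for every exposure."""
    out = []
    for k, (t, cube) in enumerate(series.entries):
        thresholds = ValidityThresholds.from_dark_statistics(
            series.dark_lightness_mean[k],
            series.dark_lightness_std[k],
            i_max=i_max,
            sigma_factor=sigma_factor,
        )
        mask = compute_valid_mask(cube, thresholds)
        try:
            selection = select_highlight_pixels(lightness(cube), mask, n_p)
        except NoHighlightsError:
            out.append((t, cube, thresholds, mask, None, -np.inf))
            continue
        g = goodness(selection, series.dark_lightness_mean[k])
        out.append((t, cube, thresholds, mask, selection, g))
    return out


def select_exposure(
    series: ExposureSeries,
    i_max: float = DEFAULT_I_MAX,
    n_p: int = DEFAULT_N_P,
    sigma_factor: float = DARK_SIGMA_FACTOR,
) -> tuple[float, GoodnessProfile]:
    """Exposure with maximal goodness ``G`` (ties: shorter exposure)."""
    rows = _per_exposure(series, i_max, n_p, sigma_factor)
    profile = GoodnessProfile(
        exposures=np.array([r[0] for r in rows]),
        values=np.array([r[5] for r in rows]),
    )
    best_exposure, _ = profile.best()
    return best_exposure, profile


def calibrate(
    series: ExposureSeries,
    i_max: float = DEFAULT_I_MAX,
    n_p: int = DEFAULT_N_P,
    sigma_factor: float = DARK_SIGMA_FACTOR,
) -> CalibrationResult:
    """End-to-end light source calibration on an exposure series.

    Per exposure: lower threshold from the dark statistics, valid mask,
    highlight selection, goodness; then the estimate is computed from the
    exposure with maximal ``G``.
    """
    rows = _per_exposure(series, i_max, n_p, sigma_factor)
    profile = GoodnessProfile(
        exposures=np.array([r[0] for r in rows]),
        values=np.array([r[5] for r in rows]),
    )
    best_exposure, _ = profile.best()
    t, cube, thresholds, mask, selection, _g = rows[
        int(np.flatnonzero(profile.exposures == best_exposure)[0])
    ]
    assert selection is not None
    estimate = estimate_illuminant(cube, selection)
    return CalibrationResult(
        illuminant=estimate,
        exposure_ms=t,
        goodness_profile=profile,
        selection=selection,
        valid_mask=mask,
        thresholds=thresholds,
    )
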