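"""Core spectral containers and metrics.

The package works with three elementary objects: a :class:`SpectralCube`
(a rows x cols x bands stack of sensor counts), an
:class:`IlluminantSpectrum` (per-band or per-wavelength relative
irradiance) and a :class:`WavelengthGrid`.  Spectra are compared with the
*angular error* -- the Euclidean angle between two spectra treated as
vectors -- which is invariant to the overall intensity scale and is the
standard dissimilarity for illuminant estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .errors import ConfigurationError, DegenerateInputError, DimensionError

__all__ = [
    "SpectralCube",
    "IlluminantSpectrum",
    "WavelengthGrid",
    "angular_error",
    "l1_normalize",
    "lightness",
    "pca_project",
]


@dataclass(frozen=True)
class SpectralCube:
    """A multispectral image: intensities in ADC counts, axes (row, col, band).

    Parameters
    ----------
    data:
        Array of shape ``(rows, cols, bands)`` with finite, non-negative
        intensities.  Stored as float64 regardless of input dtype so that
        quantized and analog cubes share one container.
    exposure_ms:
        Exposure time in milliseconds, if known.
    band_ids:
        Optional ordered band labels; defaults to ``b00 .. b15`` style names.
    """

    data: np.ndarray
    exposure_ms: float | None = None
    band_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise DimensionError(
                f"cube data must have shape (rows, cols, bands); got ndim={data.ndim}"
            )
        rows, cols, bands = data.shape
        if rows < 1 or cols < 1:
            raise DimensionError("cube must have at least one pixel")
        if bands < 2:
            raise DimensionError(f"cube must have at least 2 bands; got {bands}")
        if not np.all(np.isfinite(data)):
            raise DegenerateInputError("cube intensities must be finite")
        if np.any(data < 0):
            raise DegenerateInputError("cube intensities must be non-negative")
        if self.exposure_ms is not None and not self.exposure_ms > 0:
            raise ConfigurationError(f"exposure_ms must be > 0; got {self.exposure_ms}")
        object.__setattr__(self, "data", data)
        if self.band_ids is not None:
            band_ids = tuple(str(b) for b in self.band_ids)
            if len(band_ids) != bands:
                raise DimensionError(
                    f"{len(band_ids)} band_ids for {bands} bands"
                )
            object.__setattr__(self, "band_ids", band_ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def labels(self) -> tuple[str, ...]:
        """Band labels, generating ``b00``-style defaults when unset."""
        if self.band_ids is not None:
            return self.band_ids
        return tuple(f"b{k:02d}" for k in range(self.n_bands))

    def crop(self, rows: slice, cols: slice) -> "SpectralCube":
        """Spatial crop keeping exposure and band metadata."""
        return SpectralCube(self.data[rows, cols, :], self.exposure_ms, self.band_ids)


@dataclass(frozen=True)
class IlluminantSpectrum:
    """Relative irradiance per band (or per wavelength sample).

    Values are dimensionless and non-negative; for comparison between
    estimates the convention is L1 normalization (values sum to one).
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise DimensionError("illuminant spectrum must be one-dimensional")
        if not np.all(np.isfinite(values)):
            raise DegenerateInputError("illuminant values must be finite")
        if np.any(values < 0):
            raise DegenerateInputError("illuminant values must be non-negative")
        if not np.any(values > 0):
            raise DegenerateInputError("illuminant must have at least one positive value")
        if self.normalized and abs(values.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"normalized illuminant must sum to 1; got {values.sum()!r}"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def from_values(cls, values: np.ndarray) -> "IlluminantSpectrum":
        """Build an L1-normalized spectrum from raw non-negative values."""
        return cls(l1_normalize(np.asarray(values, dtype=float)), normalized=True)

    def as_normalized(self) -> "IlluminantSpectrum":
        if self.normalized:
            return self
        return IlluminantSpectrum.from_values(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength samples in nanometres."""

    wavelengths: np.ndarray
    bounds_nm: tuple[float, float] = field(default=(380.0, 780.0))

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise DimensionError("wavelength grid needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ConfigurationError("wavelengths must be strictly increasing")
        lo, hi = self.bounds_nm
        if wl[0] < lo or wl[-1] > hi:
            raise ConfigurationError(
                f"wavelengths must lie within [{lo}, {hi}] nm; got "
                f"[{wl[0]}, {wl[-1]}]"
            )
        object.__setattr__(self, "wavelengths", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """450-720 nm at 2 nm: covers the 16 visible camera bands with margin."""
        return cls(np.arange(450.0, 720.0 + 1e-9, 2.0))

    @property
    def nm(self) -> np.ndarray:
        return self.wavelengths

    def __len__(self) -> int:
        return len(self.wavelengths)

    def trapezoid_weights(self) -> np.ndarray:
        """Quadrature weights such that ``w @ f`` equals the trapezoidal
        integral of ``f`` over the grid (in nm units)."""
        wl = self.wavelengths
        w = np.zeros_like(wl)
        d = np.diff(wl)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w


def _as_spectrum_vector(v, name: str) -> np.ndarray:
    if isinstance(v, IlluminantSpectrum):
        v = v.values
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise DegenerateInputError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise DegenerateInputError(f"{name} contains non-finite values")
    return arr


def angular_error(u, v) -> float:
    """Euclidean angle between two spectra, in degrees.

    Symmetric, invariant to positive rescaling of either argument, and
    bounded in [0, 180].  Accepts plain arrays or
    :class:`IlluminantSpectrum` objects.
    """
    u = _as_spectrum_vector(u, "u")
    v = _as_spectrum_vector(v, "v")
    if u.shape != v.shape:
        raise DimensionError(f"length mismatch: {u.size} vs {v.size}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("angular error undefined for a zero vector")
    # arctan2 form: numerically exact for near-parallel and near-opposite vectors
    uh, vh = u / nu, v / nv
    angle = 2.0 * np.arctan2(np.linalg.norm(uh - vh), np.linalg.norm(uh + vh))
    return float(np.degrees(angle))


def l1_normalize(s) -> np.ndarray:
    """Scale a non-negative spectrum so its entries sum to one."""
    s = _as_spectrum_vector(s, "spectrum")
    if np.any(s < 0):
        raise DegenerateInputError("spectrum entries must be non-negative")
    total = s.sum()
    if total <= 0:
        raise DegenerateInputError("cannot normalize an all-zero spectrum")
    return s / total


def lightness(cube: SpectralCube) -> np.ndarray:
    """Per-pixel lightness: the mean intensity over all bands."""
    return cube.data.mean(axis=2)


def pca_project(spectra, references) -> np.ndarray:
    """Project spectra onto the first two principal components of a reference set.

    The basis is fitted on the (centered) reference spectra only; query
    spectra are projected into that plane.  The sign of each component is
    fixed by making its largest-magnitude loading positive, so projections
    are fully deterministic.

    Returns an ``(n_query, 2)`` array of coordinates.
    """
    refs = np.atleast_2d(np.asarray(references, dtype=float))
    queries = np.atleast_2d(np.asarray(
        [np.asarray(s.values if isinstance(s, IlluminantSpectrum) else s, dtype=float)
         for s in spectra]
    ))
    if refs.shape[0] < 2:
        raise ConfigurationError("need at least 2 reference spectra to fit a projection")
    if queries.shape[1] != refs.shape[1]:
        raise DimensionError(
            f"query length {queries.shape[1]} != reference length {refs.shape[1]}"
        )
    n_comp = min(2, refs.shape[0], refs.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(refs)
    components = pca.components_
    # deterministic sign: largest-|loading| entry of each component is positive
    for c in range(components.shape[0]):
        idx = np.argmax(np.abs(components[c]))
        if components[c, idx] < 0:
            components[c] = -components[c]
    coords = (queries - pca.mean_) @ components.T
    if coords.shape[1] < 2:  # rank-deficient reference set: pad with zeros
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    return coords
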