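"""Layered tissue optics and the camera image-formation model.

A tissue sample is a three-layer slab described by ten varied quantities:
per layer a thickness (20-2000 um), a blood volume fraction (0-0.3) and a
hemoglobin oxygen saturation ``sox`` (0-1), plus one shared reduced
scattering amplitude at 500 nm.  The scattering power and a small
wavelength-flat background absorption are model constants shared by all
samples (they can be varied through :class:`TissueRanges` if desired).

The diffuse reflectance of a sample is computed with a closed-form layered
model: each layer contributes the semi-infinite diffuse reflectance of its
reduced single-scattering albedo ``a' = mus' / (mua + mus')`` through the
monotone map

    ``R(a') = r_max * a' * exp(-k * (1 - a') / (1 + a'))``

with ``k = 6`` and ``r_max = 0.85``, and the contributions are blended with
weights derived from the two-pass transmission ``exp(-2 (mua + mus') d)``
of the layers above (the bottom layer is treated as semi-infinite, so the
weights always sum to one and a non-absorbing slab reflects ``r_max`` at
every wavelength).  This model is deterministic, monotone in the
absorbers, and fast enough to render tens of thousands of spectra per
second, which is what the calibration and regression experiments need.

Camera measurements are obtained by band-integrating the reflectance
against the illuminant and 16 Gaussian band responses, with a per-pixel
gain ``alpha`` and multiplicative band noise ``w_k ~ N(1, sigma_w)``
(clipped at zero), mirroring shot noise at high intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import IlluminantSpectrum, WavelengthGrid, l1_normalize
from .errors import ConfigurationError, DimensionError

__all__ = [
    "LayerProperties",
    "TissueSample",
    "TissueRanges",
    "ChromophoreTable",
    "ReflectanceSpectrum",
    "CameraModel",
    "NoiseModel",
    "sample_tissue",
    "absorption_coefficient",
    "reflectance_spectrum",
    "reflectance_matrix",
    "band_integrate",
]

# Fixed constants of the layered diffuse-reflectance map.
ALBEDO_MAP_K = 6.0
R_MAX = 0.85


@dataclass(frozen=True)
class LayerProperties:
    """One tissue layer: geometric thickness and blood content."""

    thickness_um: float
    blood_volume_fraction: float
    oxygenation: float

    def __post_init__(self) -> None:
        if not 20.0 <= self.thickness_um <= 2000.0:
            raise ConfigurationError(
                f"layer thickness must be in [20, 2000] um; got {self.thickness_um}"
            )
        if not 0.0 <= self.blood_volume_fraction <= 0.3:
            raise ConfigurationError(
                f"blood volume fraction must be in [0, 0.3]; got {self.blood_volume_fraction}"
            )
        if not 0.0 <= self.oxygenation <= 1.0:
            raise ConfigurationError(
                f"oxygenation must be in [0, 1]; got {self.oxygenation}"
            )


@dataclass(frozen=True)
class TissueSample:
    """Three-layer tissue property vector (see module docstring)."""

    layers: tuple[LayerProperties, LayerProperties, LayerProperties]
    scattering_amplitude: float  # reduced scattering at 500 nm, 1/cm
    scattering_power: float = 1.3  # dimensionless Mie-type exponent
    background_absorption: float = 0.1  # wavelength-flat, 1/cm

    def __post_init__(self) -> None:
        if len(self.layers) != 3:
            raise ConfigurationError("tissue model has exactly 3 layers")
        if not self.scattering_amplitude > 0:
            raise ConfigurationError("scattering amplitude must be > 0")
        if self.background_absorption < 0:
            raise ConfigurationError("background absorption must be >= 0")

    @property
    def oxygenation(self) -> float:
        """The regression target: oxygenation of the shallowest layer."""
        return self.layers[0].oxygenation


@dataclass(frozen=True)
class TissueRanges:
    """Uniform sampling ranges for :func:`sample_tissue`.

    Degenerate ranges (lo == hi) pin a parameter; by default the
    scattering power and background absorption are pinned, so exactly ten
    quantities vary per draw.
    """

    thickness_um: tuple[float, float] = (20.0, 2000.0)
    blood_volume_fraction: tuple[float, float] = (0.0, 0.3)
    oxygenation: tuple[float, float] = (0.0, 1.0)
    scattering_amplitude: tuple[float, float] = (5.0, 50.0)
    scattering_power: tuple[float, float] = (1.3, 1.3)
    background_absorption: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        for name in (
            "thickness_um",
            "blood_volume_fraction",
            "oxygenation",
            "scattering_amplitude",
            "scattering_power",
            "background_absorption",
        ):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass(frozen=True)
class ChromophoreTable:
    """Absorption of fully oxygenated / deoxygenated whole blood vs wavelength.

    ``mua_oxy`` and ``mua_deoxy`` are in 1/cm for whole blood (bvf = 1).
    Values are interpolated onto arbitrary wavelengths with a monotone
    cubic (PCHIP) interpolant; requests outside the tabulated range are a
    configuration error.
    """

    wavelength_nm: np.ndarray
    mua_oxy: np.ndarray
    mua_deoxy: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        oxy = np.asarray(self.mua_oxy, dtype=float)
        deoxy = np.asarray(self.mua_deoxy, dtype=float)
        if not (wl.shape == oxy.shape == deoxy.shape) or wl.ndim != 1:
            raise DimensionError("chromophore table columns must be 1-D and congruent")
        if not np.all(np.diff(wl) > 0):
            raise ConfigurationError("chromophore wavelengths must be strictly increasing")
        if np.any(oxy <= 0) or np.any(deoxy <= 0):
            raise ConfigurationError("blood absorption coefficients must be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "mua_oxy", oxy)
        object.__setattr__(self, "mua_deoxy", deoxy)

    @classmethod
    def from_csv(cls, path) -> "ChromophoreTable":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(data["wavelength_nm"], data["mua_oxy"], data["mua_deoxy"])

    @classmethod
    def default(cls) -> "ChromophoreTable":
        """Packaged coarse tabulation of whole-blood absorption (approximate
        values derived from standard hemoglobin extinction compilations at a
        hemoglobin concentration of 150 g/L)."""
        with resources.as_file(
            resources.files("specalib.data") / "blood_absorption.csv"
        ) as p:
            return cls.from_csv(p)

    @classmethod
    def synthetic(cls) -> "ChromophoreTable":
        """Fully synthetic pseudo-hemoglobin: two Gaussian oxy bands (542 and
        577 nm), one deoxy band (555 nm) and a deoxy red tail.  Useful for
        tests that must not depend on the packaged tabulation."""
        wl = np.arange(440.0, 740.0 + 1e-9, 2.0)

        def g(center, width):
            return np.exp(-0.5 * ((wl - center) / width) ** 2)

        oxy = 5.0 + 280.0 * g(542.0, 12.0) + 300.0 * g(577.0, 10.0) + 250.0 * g(450.0, 25.0)
        deoxy = 5.0 + 290.0 * g(555.0, 18.0) + 420.0 * g(450.0, 30.0) + 40.0 * g(640.0, 60.0)
        return cls(wl, oxy, deoxy)

    def interpolate(self, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelength_nm[0] or wl.max() > self.wavelength_nm[-1]:
            raise ConfigurationError(
                "requested wavelengths outside chromophore table coverage "
                f"[{self.wavelength_nm[0]}, {self.wavelength_nm[-1]}] nm"
            )
        oxy = PchipInterpolator(self.wavelength_nm, self.mua_oxy)(wl)
        deoxy = PchipInterpolator(self.wavelength_nm, self.mua_deoxy)(wl)
        return oxy, deoxy


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Dimensionless diffuse reflectance on a wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.wavelengths.shape:
            raise DimensionError("reflectance values must match the wavelength grid")
        if np.any(values < 0) or np.any(values > 1):
            raise ConfigurationError("reflectance must lie in [0, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class CameraModel:
    """Spectral and electronic model of the multispectral camera.

    Sixteen Gaussian band responses (centres evenly spaced 465-630 nm,
    FWHM 15 nm) stand in for the unpublished responses of snapshot-mosaic
    visible-range sensors.  The electronic chain is a 10-bit ADC with an
    exposure-dependent dark level and Gaussian read noise.
    """

    band_centers_nm: np.ndarray = field(
        default_factory=lambda: np.linspace(465.0, 630.0, 16)
    )
    band_fwhm_nm: float = 15.0
    adc_bits: int = 10
    dark_offset_counts: float = 8.0
    dark_rate_counts_per_ms: float = 0.08
    read_noise_std_counts: float = 2.0
    reference_exposure_ms: float = 40.0
    responses: np.ndarray | None = None  # optional explicit (bands, n_wl) matrix

    def __post_init__(self) -> None:
        centers = np.atleast_1d(np.asarray(self.band_centers_nm, dtype=float))
        if centers.size < 2:
            raise ConfigurationError("camera needs at least 2 bands")
        if self.band_fwhm_nm <= 0:
            raise ConfigurationError("band FWHM must be > 0")
        if self.adc_bits < 1:
            raise ConfigurationError("adc_bits must be >= 1")
        if self.reference_exposure_ms <= 0:
            raise ConfigurationError("reference exposure must be > 0")
        object.__setattr__(self, "band_centers_nm", centers)
        if self.responses is not None:
            resp = np.asarray(self.responses, dtype=float)
            if resp.ndim != 2 or resp.shape[0] != centers.size:
                raise DimensionError("explicit responses must be (n_bands, n_wavelengths)")
            if np.any(resp < 0) or np.any(resp.sum(axis=1) <= 0):
                raise ConfigurationError("band responses must be >= 0 with positive integral")
            object.__setattr__(self, "responses", resp)

    @property
    def n_bands(self) -> int:
        return int(self.band_centers_nm.size)

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    def dark_level(self, exposure_ms: float) -> float:
        """Expected dark signal in counts at the given exposure."""
        return self.dark_offset_counts + self.dark_rate_counts_per_ms * exposure_ms

    def band_responses(self, grid: WavelengthGrid) -> np.ndarray:
        """Band response matrix ``xi`` of shape (n_bands, n_wavelengths)."""
        if self.responses is not None:
            if self.responses.shape[1] != len(grid):
                raise DimensionError("explicit responses do not match the grid")
            return self.responses
        sigma = self.band_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        wl = grid.wavelengths[None, :]
        centers = self.band_centers_nm[:, None]
        return np.exp(-0.5 * ((wl - centers) / sigma) ** 2)

    def noiseless(self) -> "CameraModel":
        """Variant with a minimal deterministic dark chain and no read noise.

        The dark rate stays positive so the goodness metric keeps its
        exposure-time gradient (the dark level is what penalizes long
        exposures); the offset is small enough that the residual flat bias
        on highlight spectra is negligible.
        """
        return replace(
            self,
            dark_offset_counts=0.6,
            dark_rate_counts_per_ms=0.02,
            read_noise_std_counts=0.0,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative band noise ``w_k ~ N(1, sigma_w)``, clipped at zero."""

    sigma_w: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_w < 0:
            raise ConfigurationError("sigma_w must be >= 0")

    def draw(self, shape, rng: np.random.Generator) -> np.ndarray:
        if self.sigma_w == 0:
            return np.ones(shape)
        return np.maximum(rng.normal(1.0, self.sigma_w, size=shape), 0.0)


def sample_tissue(
    n: int,
    rng: np.random.Generator | int,
    ranges: TissueRanges | None = None,
) -> list[TissueSample]:
    """Draw ``n`` independent tissue samples, each parameter uniform on its range."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    r = ranges or TissueRanges()

    def u(lo_hi, size=None):
        lo, hi = lo_hi
        return rng.uniform(lo, hi, size=size) if hi > lo else np.full(size if size else (), lo)

    thickness = u(r.thickness_um, (n, 3))
    bvf = u(r.blood_volume_fraction, (n, 3))
    sox = u(r.oxygenation, (n, 3))
    amp = u(r.scattering_amplitude, (n,))
    power = u(r.scattering_power, (n,))
    background = u(r.background_absorption, (n,))
    samples = []
    for i in range(n):
        layers = tuple(
            LayerProperties(thickness[i, l], bvf[i, l], sox[i, l]) for l in range(3)
        )
        samples.append(
            TissueSample(layers, float(amp[i]), float(power[i]), float(background[i]))
        )
    return samples


def absorption_coefficient(
    bvf: float,
    sox: float,
    wavelengths: np.ndarray,
    table: ChromophoreTable,
    background: float = 0.0,
) -> np.ndarray:
    """Tissue absorption in 1/cm: linear blood mixing plus flat background.

    ``mua = bvf * (sox * mua_oxy + (1 - sox) * mua_deoxy) + background``
    """
    if not 0.0 <= bvf <= 1.0:
        raise ConfigurationError(f"bvf must be in [0, 1]; got {bvf}")
    if not 0.0 <= sox <= 1.0:
        raise ConfigurationError(f"sox must be in [0, 1]; got {sox}")
    oxy, deoxy = table.interpolate(np.asarray(wavelengths, dtype=float))
    return bvf * (sox * oxy + (1.0 - sox) * deoxy) + background


def _semi_infinite_reflectance(albedo: np.ndarray) -> np.ndarray:
    """Monotone map from reduced albedo to semi-infinite diffuse reflectance."""
    return R_MAX * albedo * np.exp(-ALBEDO_MAP_K * (1.0 - albedo) / (1.0 + albedo))


def reflectance_matrix(
    samples: list[TissueSample],
    grid: WavelengthGrid,
    table: ChromophoreTable,
) -> np.ndarray:
    """Reflectance spectra for many samples at once; shape (n_samples, n_wl)."""
    wl = grid.wavelengths
    oxy, deoxy = table.interpolate(wl)
    n = len(samples)
    thickness = np.array([[l.thickness_um for l in s.layers] for s in samples])
    bvf = np.array([[l.blood_volume_fraction for l in s.layers] for s in samples])
    sox = np.array([[l.oxygenation for l in s.layers] for s in samples])
    amp = np.array([s.scattering_amplitude for s in samples])[:, None]
    power = np.array([s.scattering_power for s in samples])[:, None]
    background = np.array([s.background_absorption for s in samples])[:, None]

    mus = amp * (wl[None, :] / 500.0) ** (-power)  # (n, n_wl), reduced scattering
    r = np.zeros((n, wl.size))
    transmission = np.ones((n, wl.size))
    for layer in range(3):
        mua = (
            bvf[:, layer, None] * (sox[:, layer, None] * oxy + (1 - sox[:, layer, None]) * deoxy)
            + background
        )
        albedo = mus / (mua + mus)
        r_layer = _semi_infinite_reflectance(albedo)
        if layer < 2:
            d_cm = thickness[:, layer, None] * 1e-4
            tau = np.exp(-2.0 * (mua + mus) * d_cm)
            weight = transmission * (1.0 - tau)
            transmission = transmission * tau
        else:
            weight = transmission  # bottom layer treated as semi-infinite
        r += weight * r_layer
    return np.clip(r, 0.0, 1.0)


def reflectance_spectrum(
    sample: TissueSample,
    grid: WavelengthGrid,
    table: ChromophoreTable,
) -> ReflectanceSpectrum:
    """Diffuse reflectance of a single sample on the wavelength grid."""
    return ReflectanceSpectrum(reflectance_matrix([sample], grid, table)[0], grid)


def band_illuminant(
    illuminant_spd: np.ndarray,
    grid: WavelengthGrid,
    camera: CameraModel,
) -> IlluminantSpectrum:
    """Band-integrated illuminant: what a perfectly specular (reflectance-flat)
    pixel measures, L1-normalized.  This is the ground truth the calibration
    estimate is compared against."""
    xi = camera.band_responses(grid)
    w = grid.trapezoid_weights()
    b = xi @ (w * np.asarray(illuminant_spd, dtype=float))
    return IlluminantSpectrum(l1_normalize(b), normalized=True)


def band_integrate(
    reflectance,
    illuminant_spd,
    camera: CameraModel,
    grid: WavelengthGrid,
    alpha: float | np.ndarray = 1.0,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render reflectance spectra into analog band measurements.

    ``I_k = alpha * w_k * integral xi_k(lambda) L(lambda) r(lambda) dlambda``
    using trapezoidal quadrature on the grid.  ``reflectance`` may be a
    single spectrum (shape ``(n_wl,)`` or :class:`ReflectanceSpectrum`) or a
    stack ``(..., n_wl)``; ``alpha`` broadcasts against the leading axes.
    With ``sigma_w = 0`` the result is deterministic.
    """
    if isinstance(reflectance, ReflectanceSpectrum):
        reflectance = reflectance.values
    r = np.asarray(reflectance, dtype=float)
    spd = np.asarray(
        illuminant_spd.values if isinstance(illuminant_spd, IlluminantSpectrum) else illuminant_spd,
        dtype=float,
    )
    if r.shape[-1] != len(grid) or spd.shape != (len(grid),):
        raise DimensionError("reflectance/illuminant do not match the wavelength grid")
    xi = camera.band_responses(grid)
    w = grid.trapezoid_weights()
    kernel = (xi * (w * spd)[None, :]).T  # (n_wl, n_bands)
    out = r @ kernel
    out = out * np.asarray(alpha, dtype=float)[..., None] if np.ndim(alpha) else out * float(alpha)
    if noise is not None and noise.sigma_w > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        out = out * noise.draw(out.shape, rng)
    return out
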