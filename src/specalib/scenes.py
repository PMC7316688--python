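"""Dichromatic scene rendering and exposure series.

A scene is a spatial arrangement of diffuse tissue regions and localized
specular highlight blobs under one known illuminant.  Per pixel the analog
band signal follows the dichromatic reflection model,

    ``I_k = alpha * (D_k(tissue) + c * U_k)``,

where ``D_k`` is the band-integrated diffuse tissue term, ``U_k`` the
band-integrated illuminant (flat unit specular reflectance: a specular
highlight is spectrally a scaled copy of the light source) and ``c`` the
specular strength field.  The signal scales linearly with exposure time;
dark counts, read noise, multiplicative band noise, integer quantization
and saturation at the ADC ceiling complete the camera chain.  Highlight
blobs have Gaussian radial profiles, so long exposures saturate their
cores while a rim of valid (unsaturated) pixels survives -- the
phenomenology the calibration method exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .calibration import ExposureSeries
from .core import SpectralCube, WavelengthGrid
from .errors import ConfigurationError, DimensionError
from .tissue import (
    CameraModel,
    NoiseModel,
    TissueSample,
    band_illuminant,
    reflectance_matrix,
    ChromophoreTable,
    sample_tissue,
)

__all__ = [
    "DichromaticScene",
    "SceneGroundTruth",
    "generate_scene",
    "generate_exposure_series",
    "generate_dark_frame",
    "make_surgical_scene",
    "default_exposure_list",
]

#: Factor by which the specular term must exceed the diffuse term for a
#: pixel to count as specular-dominant in the ground-truth bundle.
SPECULAR_DOMINANCE = 10.0


def default_exposure_list() -> np.ndarray:
    """The standard calibration sweep: 5-150 ms in 5 ms steps."""
    return np.arange(5.0, 150.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class DichromaticScene:
    """Full description of a synthetic surgical scene.

    ``photon_scale`` sets the diffuse brightness: it is the analog count
    level of a hypothetical pixel with unit band-integrated radiance at the
    reference exposure, i.e. typical tissue pixels land at
    ``photon_scale * mean-band reflectance`` counts.
    """

    tissue_labels: np.ndarray  # (rows, cols) int indices into tissue_samples
    tissue_samples: tuple[TissueSample, ...]
    specular: np.ndarray  # (rows, cols) >= 0, zero outside highlight blobs
    gain: np.ndarray  # (rows, cols) > 0
    illuminant_spd: np.ndarray  # on `grid`
    grid: WavelengthGrid
    camera: CameraModel
    noise: NoiseModel
    table: ChromophoreTable
    photon_scale: float = 400.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.tissue_labels, dtype=int)
        spec = np.asarray(self.specular, dtype=float)
        gain = np.asarray(self.gain, dtype=float)
        if not (labels.shape == spec.shape == gain.shape):
            raise DimensionError("tissue_labels, specular and gain must be congruent")
        if labels.min() < 0 or labels.max() >= len(self.tissue_samples):
            raise ConfigurationError("tissue label out of range")
        if np.any(spec < 0):
            raise ConfigurationError("specular strength must be >= 0")
        if np.any(gain <= 0):
            raise ConfigurationError("gain field must be > 0")
        spd = np.asarray(self.illuminant_spd, dtype=float)
        if spd.shape != (len(self.grid),):
            raise DimensionError("illuminant SPD must live on the scene grid")
        if self.photon_scale <= 0:
            raise ConfigurationError("photon_scale must be > 0")
        object.__setattr__(self, "tissue_labels", labels)
        object.__setattr__(self, "specular", spec)
        object.__setattr__(self, "gain", gain)
        object.__setattr__(self, "illuminant_spd", spd)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_labels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SceneGroundTruth:
    """What the renderer knows and the estimators must recover."""

    illuminant_bands: np.ndarray  # L1-normalized band-integrated illuminant
    illuminant_spd: np.ndarray
    sox_map: np.ndarray  # first-layer oxygenation per pixel
    specular_dominant: np.ndarray  # boolean mask


def _band_terms(scene: DichromaticScene) -> tuple[np.ndarray, np.ndarray]:
    """Normalized diffuse band vectors per tissue and the specular band vector.

    The specular vector ``u`` is scaled to unit band mean so that
    ``photon_scale`` has the meaning documented on the scene; the diffuse
    vectors share the same normalization factor.
    """
    xi = scene.camera.band_responses(scene.grid)
    w = scene.grid.trapezoid_weights()
    spd = scene.illuminant_spd
    b = xi @ (w * spd)  # specular (flat reflectance) band integrals
    scale = b.mean()
    r = reflectance_matrix(list(scene.tissue_samples), scene.grid, scene.table)
    d = r @ (xi * (w * spd)[None, :]).T  # (n_tissues, n_bands)
    return d / scale, b / scale


def generate_scene(
    scene: DichromaticScene,
    exposure_ms: float,
    rng: np.random.Generator | int | None = None,
    quantize: bool = True,
) -> tuple[SpectralCube, SceneGroundTruth]:
    """Render one cube at the given exposure.

    With ``quantize=False`` the analog signal is returned unrounded and
    unclipped (no saturation), which is what exactness tests need; the
    camera noise sources still apply unless they are zero.
    """
    if exposure_ms <= 0:
        raise ConfigurationError("exposure must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cam = scene.camera
    diffuse_bands, specular_bands = _band_terms(scene)

    diffuse = diffuse_bands[scene.tissue_labels]  # (rows, cols, bands)
    spec = scene.specular[..., None] * specular_bands[None, None, :]
    analog = scene.photon_scale * scene.gain[..., None] * (diffuse + spec)
    analog = analog * (exposure_ms / cam.reference_exposure_ms)
    signal = analog * scene.noise.draw(analog.shape, rng)
    signal = signal + cam.dark_level(exposure_ms)
    if cam.read_noise_std_counts > 0:
        signal = signal + rng.normal(0.0, cam.read_noise_std_counts, size=signal.shape)
    if quantize:
        signal = np.clip(np.rint(signal), 0.0, cam.adc_max)
    else:
        signal = np.maximum(signal, 0.0)

    sox_map = np.array([s.oxygenation for s in scene.tissue_samples])[scene.tissue_labels]
    diffuse_sum = diffuse.sum(axis=2)
    spec_sum = spec.sum(axis=2)
    dominant = spec_sum > SPECULAR_DOMINANCE * diffuse_sum
    truth = SceneGroundTruth(
        illuminant_bands=band_illuminant(scene.illuminant_spd, scene.grid, cam).values,
        illuminant_spd=scene.illuminant_spd,
        sox_map=sox_map,
        specular_dominant=dominant,
    )
    return SpectralCube(signal, exposure_ms=exposure_ms), truth


def generate_dark_frame(
    camera: CameraModel,
    exposure_ms: float,
    shape: tuple[int, int],
    rng: np.random.Generator | int | None = None,
    n_bands: int | None = None,
) -> SpectralCube:
    """A cube with no scene signal: dark counts plus read noise, quantized."""
    if exposure_ms <= 0:
        raise ConfigurationError("exposure must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nb = n_bands or camera.n_bands
    signal = np.full((*shape, nb), camera.dark_level(exposure_ms))
    if camera.read_noise_std_counts > 0:
        signal = signal + rng.normal(0.0, camera.read_noise_std_counts, size=signal.shape)
    signal = np.clip(np.rint(signal), 0.0, camera.adc_max)
    return SpectralCube(signal, exposure_ms=exposure_ms)


def generate_exposure_series(
    scene: DichromaticScene,
    exposures: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    dark_frame_shape: tuple[int, int] = (32, 32),
) -> tuple[ExposureSeries, SceneGroundTruth]:
    """Render one cube per exposure plus rendered-dark-frame statistics.

    Dark statistics (mean and standard deviation of the dark lightness
    image) come from actually rendered dark frames, mirroring the physical
    lights-off calibration step.
    """
    if exposures is None:
        exposures = default_exposure_list()
    exposures = np.asarray(exposures, dtype=float)
    if exposures.size == 0:
        raise ConfigurationError("exposure list must not be empty")
    if np.any(exposures <= 0) or not np.all(np.diff(exposures) > 0):
        raise ConfigurationError("exposures must be strictly increasing and > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    entries = []
    dark_means = []
    dark_stds = []
    truth = None
    for t in exposures:
        cube, truth = generate_scene(scene, float(t), rng)
        dark = generate_dark_frame(scene.camera, float(t), dark_frame_shape, rng)
        dark_lightness = dark.data.mean(axis=2)
        entries.append((float(t), cube))
        dark_means.append(float(dark_lightness.mean()))
        dark_stds.append(float(dark_lightness.std()))
    series = ExposureSeries(
        entries=tuple(entries),
        dark_lightness_mean=np.asarray(dark_means),
        dark_lightness_std=np.asarray(dark_stds),
    )
    assert truth is not None
    return series, truth


def _smooth_field(rng, shape, smooth_px, lo, hi):
    field = gaussian_filter(rng.standard_normal(shape), smooth_px, mode="reflect")
    fmin, fmax = field.min(), field.max()
    if fmax - fmin < 1e-12:
        return np.full(shape, 0.5 * (lo + hi))
    return lo + (hi - lo) * (field - fmin) / (fmax - fmin)


def make_surgical_scene(
    illuminant_spd,
    grid: WavelengthGrid,
    camera: CameraModel,
    rng: np.random.Generator | int,
    table: ChromophoreTable | None = None,
    shape: tuple[int, int] = (128, 128),
    n_tissues: int = 3,
    n_blobs: int = 5,
    blob_sigma_px: float = 4.0,
    specular_peak: float = 30.0,
    photon_scale: float = 400.0,
    noise: NoiseModel | None = None,
    gain_range: tuple[float, float] = (0.7, 1.3),
    tissue_samples: tuple[TissueSample, ...] | None = None,
) -> DichromaticScene:
    """Randomized surgical-like scene: tissue regions, smooth gain, highlight blobs.

    Tissue regions are the nearest-centre cells of ``n_tissues`` random
    seed points; the gain field is a smoothed random field in
    ``gain_range`` (shading / distance variation); specular strength is a
    sum of Gaussian blobs with peaks ``specular_peak`` times a random
    factor in [0.5, 1.5], falling smoothly to zero at the rim.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = table or ChromophoreTable.default()
    spd = np.asarray(
        illuminant_spd.values if hasattr(illuminant_spd, "values") else illuminant_spd,
        dtype=float,
    )
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]

    centers = np.column_stack(
        [rng.uniform(0, rows, n_tissues), rng.uniform(0, cols, n_tissues)]
    )
    dist = (rr[..., None] - centers[:, 0]) ** 2 + (cc[..., None] - centers[:, 1]) ** 2
    labels = np.argmin(dist, axis=2)

    gain = _smooth_field(rng, shape, smooth_px=min(rows, cols) / 8.0, lo=gain_range[0], hi=gain_range[1])

    margin = min(4.0 * blob_sigma_px, 0.25 * min(rows, cols))
    specular = np.zeros(shape)
    for _ in range(n_blobs):
        br = rng.uniform(margin, rows - margin)
        bc = rng.uniform(margin, cols - margin)
        peak = specular_peak * rng.uniform(0.5, 1.5)
        d2 = (rr - br) ** 2 + (cc - bc) ** 2
        specular += peak * np.exp(-0.5 * d2 / blob_sigma_px**2)
    specular[specular < 1e-3 * specular_peak] = 0.0

    samples = tissue_samples or tuple(sample_tissue(n_tissues, rng))
    return DichromaticScene(
        tissue_labels=labels,
        tissue_samples=tuple(samples),
        specular=specular,
        gain=gain,
        illuminant_spd=spd,
        grid=grid,
        camera=camera,
        noise=noise if noise is not None else NoiseModel(0.1),
        table=table,
        photon_scale=photon_scale,
    )


def make_noiseless_highlight_scene(
    illuminant_spd,
    grid: WavelengthGrid,
    camera: CameraModel,
    rng: np.random.Generator | int,
    table: ChromophoreTable | None = None,
    **kwargs,
) -> DichromaticScene:
    """Noise-free validation variant: highlight-dominant scene under a camera
    with a minimal deterministic dark level.

    The diffuse term is rendered at a photometric level far below the dark
    threshold, so the valid highlight rim is essentially pure specular --
    the regime in which exact recovery of the illuminant can be asserted.
    """
    kwargs.setdefault("photon_scale", 2.0)
    kwargs.setdefault("specular_peak", 2000.0)
    kwargs.setdefault("noise", NoiseModel(0.0))
    return make_surgical_scene(
        illuminant_spd,
        grid,
        camera.noiseless(),
        rng,
        table=table,
        **kwargs,
    )
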