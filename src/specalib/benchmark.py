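"""Reproducible study protocols built on the simulator.

Two entry points mirror the validation studies the toolkit is designed
around:

``calibration_study``
    5 illuminants x ``n_poses`` randomized scenes; per scene a full
    exposure series is rendered, the highlight method is calibrated, and
    optionally the four literature baselines and per-exposure highlight
    estimates are evaluated on the same data.

``oxygenation_study``
    The matched / mismatched / calibrated regression experiment, fed with
    the calibration estimates of a ``calibration_study``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import gray_edge, gray_world, max_rgb, shades_of_gray
from .calibration import (
    ValidityThresholds,
    calibrate,
    compute_valid_mask,
    estimate_illuminant,
    select_highlight_pixels,
)
from .core import IlluminantSpectrum, WavelengthGrid, angular_error, lightness
from .errors import NoHighlightsError
from .illuminants import reference_illuminants
from .oxygenation import ExperimentDesign, ExperimentResult, run_illuminant_mismatch_experiment
from .scenes import (
    default_exposure_list,
    generate_exposure_series,
    make_noiseless_highlight_scene,
    make_surgical_scene,
)
from .tissue import CameraModel, NoiseModel, band_illuminant

__all__ = ["CalibrationRun", "CalibrationStudy", "calibration_study", "oxygenation_study"]

BASELINE_EXPOSURES = (20.0, 40.0, 60.0)


@dataclass(frozen=True)
class CalibrationRun:
    """One scene: the calibration result plus optional side evaluations."""

    illuminant_id: str
    pose: int
    estimate: IlluminantSpectrum
    angular_error_deg: float
    exposure_ms: float
    per_exposure_errors: dict = field(default_factory=dict)
    baseline_errors: dict = field(default_factory=dict)  # {(method, exposure): deg}


@dataclass(frozen=True)
class CalibrationStudy:
    runs: tuple[CalibrationRun, ...]

    @property
    def errors(self) -> np.ndarray:
        return np.array([r.angular_error_deg for r in self.runs])

    def estimates(self) -> tuple[tuple[str, IlluminantSpectrum], ...]:
        return tuple((r.illuminant_id, r.estimate) for r in self.runs)

    def baseline_table(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            for t in sorted({e for (_, e) in r.baseline_errors}):
                rows.append(
                    dict(
                        illuminant=r.illuminant_id,
                        pose=r.pose,
                        exposure_ms=t,
                        **{
                            m: r.baseline_errors[(m, t)]
                            for (m, e) in r.baseline_errors
                            if e == t
                        },
                    )
                )
        return pd.DataFrame(rows)


def _baseline_suite(cube, dark_mean, dark_std, truth, n_p):
    thresholds = ValidityThresholds.from_dark_statistics(dark_mean, dark_std)
    out = {
        "max_rgb": max_rgb(cube),
        "gray_world": gray_world(cube),
        "shades_of_gray": shades_of_gray(cube, p=6),
        "gray_edge": gray_edge(cube, p=6, sigma=2.0),
    }
    errors = {m: angular_error(est, truth) for m, est in out.items()}
    try:
        mask = compute_valid_mask(cube, thresholds)
        sel = select_highlight_pixels(lightness(cube), mask, n_p)
        errors["specular_highlights"] = angular_error(
            estimate_illuminant(cube, sel), truth
        )
    except NoHighlightsError:
        errors["specular_highlights"] = np.nan
    return errors


def calibration_study(
    seed: int,
    n_poses: int = 8,
    noiseless: bool = False,
    shape: tuple[int, int] = (128, 128),
    grid: WavelengthGrid | None = None,
    camera: CameraModel | None = None,
    include_baselines: bool = False,
    include_per_exposure: bool = False,
    n_p: int = 100,
) -> CalibrationStudy:
    """Calibrate on ``n_poses`` randomized scenes per reference illuminant.

    Each pose re-randomizes highlight geometry, gain field and tissue,
    emulating different camera positions relative to the light source.
    """
    grid = grid or WavelengthGrid.default()
    camera = camera or CameraModel()
    illuminants = reference_illuminants(grid)
    master = np.random.default_rng(seed)
    exposures = default_exposure_list()
    runs = []
    for name, spd in illuminants.items():
        for pose in range(n_poses):
            rng = np.random.default_rng(master.integers(2**31))
            if noiseless:
                scene = make_noiseless_highlight_scene(spd, grid, camera, rng, shape=shape)
            else:
                scene = make_surgical_scene(spd, grid, camera, rng, shape=shape)
            series, truth = generate_exposure_series(scene, exposures, rng)
            result = calibrate(series, n_p=n_p)
            err = angular_error(result.illuminant, truth.illuminant_bands)

            per_exposure = {}
            if include_per_exposure:
                for k, (t, cube) in enumerate(series.entries):
                    thresholds = ValidityThresholds.from_dark_statistics(
                        series.dark_lightness_mean[k], series.dark_lightness_std[k]
                    )
                    try:
                        mask = compute_valid_mask(cube, thresholds)
                        sel = select_highlight_pixels(lightness(cube), mask, n_p)
                        per_exposure[t] = angular_error(
                            estimate_illuminant(cube, sel), truth.illuminant_bands
                        )
                    except NoHighlightsError:
                        continue
            baseline_errors = {}
            if include_baselines:
                for k, (t, cube) in enumerate(series.entries):
                    if t not in BASELINE_EXPOSURES:
                        continue
                    suite = _baseline_suite(
                        cube,
                        series.dark_lightness_mean[k],
                        series.dark_lightness_std[k],
                        truth.illuminant_bands,
                        n_p,
                    )
                    baseline_errors.update({(m, t): e for m, e in suite.items()})
            runs.append(
                CalibrationRun(
                    illuminant_id=name,
                    pose=pose,
                    estimate=result.illuminant,
                    angular_error_deg=err,
                    exposure_ms=result.exposure_ms,
                    per_exposure_errors=per_exposure,
                    baseline_errors=baseline_errors,
                )
            )
    return CalibrationStudy(runs=tuple(runs))


def oxygenation_study(
    seed: int,
    estimates: tuple[tuple[str, IlluminantSpectrum], ...],
    n_train: int = 10_000,
    n_test: int = 5_000,
    grid: WavelengthGrid | None = None,
    camera: CameraModel | None = None,
    noise: NoiseModel | None = None,
    n_estimators: int = 100,
) -> ExperimentResult:
    """The mismatch experiment under the five reference illuminants."""
    grid = grid or WavelengthGrid.default()
    camera = camera or CameraModel()
    illuminants = reference_illuminants(grid)
    bands = {
        name: band_illuminant(spd.values, grid, camera)
        for name, spd in illuminants.items()
    }
    design = ExperimentDesign(
        illuminants=bands,
        estimates=estimates,
        n_train=n_train,
        n_test=n_test,
        seed=seed,
        noise=noise if noise is not None else NoiseModel(0.1),
        n_estimators=n_estimators,
    )
    return run_illuminant_mismatch_experiment(design, grid=grid, camera=camera)
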