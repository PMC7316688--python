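"""Run configuration: layered defaults < YAML file < explicit overrides."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Defaults for the calibration tool and the simulation bench.

    The thresholds, pixel count, Minkowski order and exposure sweep carry
    the method's standard values; everything is overridable per run.
    """

    # calibration
    i_max: float = 950.0
    n_p: int = 100
    dark_sigma_factor: float = 3.0
    # baselines
    minkowski_p: float = 6.0
    gray_edge_sigma: float = 2.0
    # exposure sweep (ms)
    exposure_start_ms: float = 5.0
    exposure_stop_ms: float = 150.0
    exposure_step_ms: float = 5.0
    # camera / noise
    band_count: int = 16
    adc_bits: int = 10
    sigma_w: float = 0.1
    # scene
    scene_shape: tuple[int, int] = (128, 128)
    n_highlight_blobs: int = 5
    photon_scale: float = 400.0
    # experiment sizes
    n_train: int = 10_000
    n_test: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_step_ms <= 0 or self.exposure_stop_ms < self.exposure_start_ms:
            raise ConfigurationError("invalid exposure sweep")
        if self.n_p < 1:
            raise ConfigurationError("n_p must be >= 1")

    def exposures(self) -> np.ndarray:
        return np.arange(
            self.exposure_start_ms, self.exposure_stop_ms + 1e-9, self.exposure_step_ms
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scene_shape"] = list(self.scene_shape)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a config from defaults, an optional YAML file and overrides."""
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update(overrides)
    if "scene_shape" in values:
        values["scene_shape"] = tuple(values["scene_shape"])
    return RunConfig(**values)
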