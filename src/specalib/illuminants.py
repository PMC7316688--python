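"""Synthetic reference light sources.

Five smooth spectral power distributions emulate common operating-room
illumination: two near-flat xenon-like sources (a near-degenerate pair), a
warm halogen (3200 K Planckian), a line-dominated fluorescent lamp and a
phosphor white LED.  They are constructed so that their pairwise angular
errors in 16-band camera space span roughly one degree (the two xenons) to
the mid-twenties of degrees (xenon vs fluorescent), the regime in which
illuminant mismatch matters for downstream tissue-parameter regression.
"""

from __future__ import annotations

import numpy as np

from .core import IlluminantSpectrum, WavelengthGrid, angular_error, l1_normalize
from .tissue import CameraModel, band_illuminant

__all__ = [
    "reference_illuminants",
    "band_illuminant",
    "pairwise_angular_errors",
]

# Boltzmann/Planck constants folded into a single exponent constant:
# h*c/k_B = 1.4388e7 nm*K (second radiation constant).
_C2_NM_K = 1.4388e7


def _planck(wl_nm: np.ndarray, temperature_k: float) -> np.ndarray:
    x = _C2_NM_K / (wl_nm * temperature_k)
    return wl_nm**-5 / np.expm1(x)


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def reference_illuminants(grid: WavelengthGrid | None = None) -> dict[str, IlluminantSpectrum]:
    """The five reference illuminant SPDs, L1-normalized on the grid.

    Keys (ordered): ``ls1_xenon``, ``ls2_halogen``, ``ls3_fluorescent``,
    ``ls4_xenon``, ``ls5_led``.
    """
    grid = grid or WavelengthGrid.default()
    wl = grid.wavelengths
    span = wl[-1] - wl[0]
    x = (wl - wl.mean()) / span  # in [-0.5, 0.5]

    xenon_a = np.ones_like(wl)
    # second xenon: slight warm tilt, about one degree away in band space
    xenon_b = 1.0 + 0.10 * x
    halogen = _planck(wl, 3200.0)
    fluorescent = (
        0.30
        + 0.45 * _gauss(wl, 487.0, 8.0)
        + 0.85 * _gauss(wl, 545.0, 9.0)
        + 0.65 * _gauss(wl, 611.0, 10.0)
    )
    led = 0.9 * _gauss(wl, 460.0, 12.0) + 1.0 * _gauss(wl, 560.0, 48.0)

    spds = {
        "ls1_xenon": xenon_a,
        "ls2_halogen": halogen,
        "ls3_fluorescent": fluorescent,
        "ls4_xenon": xenon_b,
        "ls5_led": led,
    }
    return {
        name: IlluminantSpectrum(l1_normalize(values), normalized=True)
        for name, values in spds.items()
    }


def pairwise_angular_errors(
    illuminants: dict[str, IlluminantSpectrum],
    grid: WavelengthGrid,
    camera: CameraModel,
) -> dict[tuple[str, str], float]:
    """Angular error between every illuminant pair, in 16-band camera space."""
    bands = {
        name: band_illuminant(spd.values, grid, camera) for name, spd in illuminants.items()
    }
    names = list(bands)
    return {
        (a, b): angular_error(bands[a], bands[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
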