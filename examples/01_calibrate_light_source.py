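"""Recover the illuminant spectrum from specular highlights.

Simulates a surgical-like multispectral scene under a fluorescent lamp,
renders a bracketed low-exposure series (5-150 ms), and runs the
highlight-based calibration: valid-pixel masking, top-lightness highlight
selection, goodness-driven exposure choice, and the final estimate.
"""

import numpy as np

from specalib import (
    CameraModel,
    WavelengthGrid,
    angular_error,
    calibrate,
    make_surgical_scene,
    reference_illuminants,
)
from specalib.scenes import generate_exposure_series

grid = WavelengthGrid.default()
camera = CameraModel()
illuminant = reference_illuminants(grid)["ls3_fluorescent"]

rng = np.random.default_rng(0)
scene = make_surgical_scene(illuminant, grid, camera, rng)
series, truth = generate_exposure_series(scene, rng=rng)

result = calibrate(series)
error = angular_error(result.illuminant, truth.illuminant_bands)

print(f"exposures rendered:        {len(series)} (5-150 ms)")
print(f"selected exposure:         {result.exposure_ms:g} ms (max goodness G)")
print(f"highlight pixels used:     {len(result.selection)}")
g = result.goodness_profile
finite = np.isfinite(g.values)
print(f"goodness range:            {g.values[finite].min():.1f} .. {g.values[finite].max():.1f}")
print(f"angular error vs truth:    {error:.3f} deg")
print()
print("The estimate is the mean L1-normalized spectrum of the brightest")
print("valid (unsaturated) pixels; under the dichromatic model those pixels")
print("are scaled copies of the illuminant, so an error well below the")
print("~1-26 deg separation of typical light sources means the lamp can be")
print("identified reliably from a single low-exposure burst.")
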