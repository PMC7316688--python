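"""Compare the highlight method against classic color-constancy estimators.

Renders the same noisy scenes at a low / normal / high exposure analog
(20 / 40 / 60 ms) and scores max-RGB, gray-world, shades-of-gray (p=6),
gray-edge and the specular-highlight method by their angular error to the
true band-integrated illuminant.
"""

from specalib.benchmark import BASELINE_EXPOSURES, calibration_study

study = calibration_study(
    seed=0, n_poses=2, include_baselines=True  # 5 illuminants x 2 poses
)
table = study.baseline_table()

methods = ["specular_highlights", "max_rgb", "gray_world", "shades_of_gray", "gray_edge"]
print("mean angular error (deg) over", table.pose.nunique() * table.illuminant.nunique(),
      "scenes per exposure:\n")
print(f"{'method':<20}" + "".join(f"{int(t):>8} ms" for t in BASELINE_EXPOSURES))
for m in methods:
    row = "".join(
        f"{table[table.exposure_ms == t][m].mean():>10.2f}" for t in BASELINE_EXPOSURES
    )
    print(f"{m:<20}{row}")
print()
print("Whole-image statistics (the four baselines) are pulled toward the")
print("tissue color and toward saturated highlight cores; the highlight")
print("method reads the illuminant off valid specular pixels and stays")
print("well ahead at every exposure (it degrades gently as rising exposure")
print("brightens the diffuse term under the rims).")
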