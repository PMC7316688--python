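"""Quantify what light source calibration buys for tissue oxygenation.

Trains one random-forest oxygenation regressor per illuminant on simulated
tissue measurements and compares three conditions on held-out samples:
training under the matched illuminant, under a mismatched one, and under
the illuminant estimated by specular-highlight calibration.  Run at a
reduced scale (2,000 train / 500 test, 2 poses per illuminant) so it
finishes in about a minute; the full protocol uses 10,000 / 5,000.
"""

from specalib.benchmark import calibration_study, oxygenation_study

study = calibration_study(seed=0, n_poses=2)
print(f"calibration estimates: {len(study.runs)} "
      f"(max angular error {study.errors.max():.2f} deg)")

result = oxygenation_study(
    seed=0, estimates=study.estimates(), n_train=2000, n_test=500, n_estimators=50
)
s = result.summary
print(f"matched MAE:     {s['matched_mean_pp']:.2f} pp")
print(f"mismatched MAE:  {s['mismatched_mean_pp']:.2f} pp")
print(f"calibrated MAE:  {s['calibrated_mean_pp']:.2f} pp")
print(f"mean error reduction from calibration: {s['mean_reduction_pct']:.1f}%")
print()
print("Normalized band measurements shift with the illuminant, so a")
print("regressor trained under the wrong lamp roughly doubles the")
print("oxygenation error (in percentage points of saturation); selecting a")
print("regressor trained under the calibrated estimate recovers nearly the")
print("matched-illuminant accuracy.")
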