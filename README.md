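# specalib

Light source calibration for multispectral imaging via specular highlight
analysis — with a dichromatic surgical-scene simulator, the classic
color-constancy baselines, and an illuminant-adapted tissue-oxygenation
regression bench.

## The problem

Functional multispectral imaging recovers tissue parameters such as
hemoglobin oxygen saturation from narrow-band reflectance measurements.
The regressors that do this are trained under a specific illuminant
spectrum; in open surgery the effective illuminant changes constantly as
overhead lights, headlamps and endoscopic sources move, and a regressor
trained under the wrong lamp silently degrades. `specalib` implements an
automatic calibration of the light source from the images themselves, for
researchers building multispectral pipelines who need the current
illuminant without touching the lights.

## The method

Under the dichromatic reflection model a pixel splits into a diffuse and a
specular part,

```
I_k = S_k · L_k  +  c · L_k ,        k = 1 … N_s bands,
```

so a pixel dominated by the specular term is a scaled copy of the
illuminant spectrum `L`, independent of the tissue underneath. Specular
highlights saturate the sensor at normal exposures, so calibration uses a
bracketed series of *low-exposure* images (5–150 ms):

1. **Valid mask** — keep pixels whose every band lies strictly inside
   `(I_min, I_max)`, with `I_min` the dark-current level at that exposure
   and `I_max = 950` counts (sensor nonlinearity ceiling).
2. **Highlight selection** — among valid pixels take the `N_P = 100` of
   greatest lightness `I_L` (mean over bands).
3. **Estimate** — L1-normalize each selected pixel's band vector and
   average: `L_k = mean( I_k / ‖I‖₁ )`.
4. **Exposure choice** — pick the exposure maximizing the goodness
   `G(T) = median( (I_L − D̄(T)) / D̄(T) )`, the median relative excess of
   highlight lightness over the mean dark lightness `D̄`.

Spectra are compared by the **angular error**, the Euclidean angle between
two spectra as vectors — invariant to overall intensity. The package also
provides the four standard model-based estimators (max-RGB, gray-world,
shades-of-gray with Minkowski order `p = 6`, gray-edge) extended to
multispectral cubes, a full image-formation simulator (three-layer tissue
optics, 16 Gaussian camera bands, multiplicative band noise, dark current,
10-bit quantization and saturation), and the downstream experiment: one
random-forest oxygenation regressor per illuminant, selected at run time
by angular proximity to the calibration estimate.

## Worked example

```sh
python examples/01_calibrate_light_source.py
```

```
exposures rendered:        30 (5-150 ms)
selected exposure:         5 ms (max goodness G)
highlight pixels used:     100
goodness range:            17.6 .. 59.4
angular error vs truth:    1.876 deg
```

A fluorescent-lamp scene is rendered with band noise, dark current and
partially saturated highlights; max-G picks the shortest exposure (where
highlight rims are valid and tissue is near-dark), and the recovered
spectrum lands within ~2° of the true band-integrated illuminant — small
against the ~1–26° separation between typical OR light sources, so the
lamp is identified reliably. `examples/02_compare_baselines.py` scores the
four literature estimators on the same scenes (they land at 9–20° mean
error versus 2–7° for the highlight method), and
`examples/03_oxygenation_benefit.py` shows calibration recovering nearly
the matched-illuminant oxygenation accuracy (~42% error reduction at
reduced scale).

The same functionality is available as a CLI:
`specalib simulate-series`, `specalib estimate-illuminant`,
`specalib select-exposure`, `specalib compare-baselines`,
`specalib run-experiment`, `specalib show-config`.

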