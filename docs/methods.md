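# Methods

This note documents the models behind `specalib`, the defaults that
matter, and what the synthetic bench does and does not establish.

## Calibration pipeline

The estimator operates on a bracketed exposure series of multispectral
cubes (rows × cols × bands, ADC counts) with dark statistics per exposure.

- **Lower validity threshold.** `I_min = D̄ + 3·σ_D`, where `D̄` and `σ_D`
  are the mean and standard deviation of the dark-frame *lightness* at
  that exposure. The method description pins `I_min` to "the dark-current
  level" without a formula; mean + 3 sigma is the package's reading and is
  configurable (`sigma_factor`).
- **Per-band validity.** A pixel is valid only if *every* band lies
  strictly inside `(I_min, I_max)`. The strict all-bands reading prevents
  a single saturated band from contaminating an otherwise bright pixel.
  `I_max` defaults to 950 counts, just under the 10-bit ceiling of 1023.
- **Selection and ties.** The `N_P = 100` valid pixels of greatest
  lightness; fewer valid pixels clamp rather than fail (robustness to
  `N_P` in 75–200 is the published experience). Ordering is fully
  deterministic: descending lightness, then ascending row, then column.
- **Estimation** uses raw (not dark-subtracted) intensities, matching the
  published estimation equation; the residual flat dark bias at the
  selected exposure is ≲0.05° under the default camera.
- **Goodness / exposure choice.** `G = median((I_L − D̄)/D̄)` over the
  selected pixels, recomputed per exposure; exposures with zero valid
  highlight pixels get `G = −∞`; ties go to the shorter exposure. Because
  highlight lightness is capped by the validity ceiling while `D̄` grows
  with exposure, max-G lands on the shortest exposures that already carry
  bright valid rims — which is also where diffuse contamination (which
  scales with exposure) is smallest.

Angular error is computed with the `2·atan2(‖û−v̂‖, ‖û+v̂‖)` form, exact
for near-parallel spectra where the arccos form loses precision.

## Baseline estimators

Max-RGB, gray-world, shades-of-gray and gray-edge pool a per-band
statistic over the image (Minkowski order `p = 6` where applicable) and
L1-normalize. Gray-edge smooths each band with a Gaussian of `σ = 2` px
(the source literature leaves σ unstated), takes central-difference
gradient magnitudes, and excludes a border of `⌈3σ⌉+1` px from the pooling
so reflection-padding artefacts never enter the statistic. Large Minkowski
orders are computed with max-scaling to avoid overflow. By default the
baselines see the whole image (the literature convention); they accept the
same valid-pixel mask as the highlight method for like-for-like
comparisons.

## Tissue forward model

A tissue sample is a three-layer slab. Ten quantities vary per draw, each
uniform on its range: per layer thickness (20–2000 µm), blood volume
fraction (0–0.3) and oxygenation sox (0–1), plus a shared reduced
scattering amplitude at 500 nm (5–50 cm⁻¹, a standard soft-tissue prior).
The scattering power (1.3) and a flat background absorption (0.1 cm⁻¹)
are model constants (degenerate ranges; both can be varied). Whole-blood
absorption comes from a packaged coarse tabulation (10 nm nodes,
450–720 nm) of approximate standard hemoglobin extinction values at
150 g/L, interpolated monotonically (PCHIP); a fully synthetic
two-Gaussian pseudo-hemoglobin table is available for tests that must not
depend on the fixture.

Reflectance uses a closed-form layered model rather than photon-transport
Monte Carlo: per layer the semi-infinite diffuse reflectance of the
reduced albedo `a' = µs'/(µa+µs')` through the fixed monotone map
`R(a') = 0.85 · a' · exp(−6(1−a')/(1+a'))`, blended with
partition-of-unity weights `w₁ = 1−τ₁`, `w₂ = τ₁(1−τ₂)`, `w₃ = τ₁τ₂`
built from the two-pass transmissions `τ = exp(−2(µa+µs')d)` of the
layers above; the bottom layer is treated as semi-infinite (its sampled
thickness is inert). Consequences worth knowing: a non-absorbing slab
reflects exactly 0.85 at every wavelength; reflectance is monotone
decreasing in every absorber; the model is deterministic and vectorizes
to ~10⁵ spectra/s. It reproduces the *structure* that matters here —
hemoglobin band shapes, layer occlusion, oxygenation-dependent spectral
tilt — but it is smoother and less confounded than radiative-transfer
simulation, so absolute regression errors on this bench are somewhat
lower than what Monte-Carlo-trained pipelines report (see Limitations).

Camera: 16 Gaussian band responses, centres evenly spaced 465–630 nm,
FWHM 15 nm (the real snapshot-mosaic responses are unpublished), on a
450–720 nm grid at 2 nm with trapezoidal quadrature; 10-bit ADC
(ceiling 1023); dark signal 8 + 0.08·T counts at exposure T ms; read
noise 2 counts. Band noise is multiplicative, `w_k ~ N(1, σ_w)` clipped
at zero, `σ_w = 0.1` by default — a deliberately pessimistic shot-noise
surrogate.

## Scene simulator

Scenes are dichromatic: per pixel
`I_k ∝ gain · (D_k(tissue) + c · U_k) · T/T_ref`, with `U` the
band-integrated illuminant (flat unit specular reflectance — the
neutral-interface assumption), `D` the band-integrated tissue term, and
`c ≥ 0` a specular strength field of Gaussian blobs (5 blobs, σ = 4 px on
a 128×128 field) whose cores saturate while rims stay valid. Tissue
regions are nearest-centre cells of three random seeds; the gain field is
a smoothed random field in [0.7, 1.3].

Photometry is the one genuinely free quantity (the real scenes'
specular-to-diffuse contrast is uncharacterized). Defaults:
`photon_scale = 400` (typical tissue lightness ~10–15 % of full range at
the 40 ms reference — dark organ tissue) and `specular_peak = 30`
(highlight cores roughly two orders of magnitude above diffuse radiance,
as for wet-surface Fresnel spikes under directional light). These were
fixed from the contamination analysis: the tissue-vs-illuminant band
angle is 50–60°, so the worst-case calibration error is approximately
`(tissue lightness / highlight ceiling) × 55°` at the selected exposure;
the defaults keep that term near 1° at 5 ms while preserving the
qualitative exposure phenomenology (valid rims at low exposure, saturated
blobs and excluded exposures at high exposure).

The noise-free validation camera (`CameraModel.noiseless()`) keeps a
small deterministic dark chain (0.6 + 0.02·T counts): the dark level is
what gives the goodness metric its exposure gradient, and removing it
entirely lets max-G drift to long exposures where rim contamination
grows.

Dark statistics are measured from rendered 32×32 dark frames rather than
taken from the closed form, mirroring the physical lights-off procedure.

## Oxygenation experiment

Measurements for the regression bench use the narrow-band factorization
`I_k = α · w_k · ℓ_k · ρ_k`, where `ℓ` is the band-space illuminant and
`ρ` the band-averaged tissue reflectance. For 15 nm-wide bands this is an
excellent approximation of the full spectral integral, and it puts
reference illuminants and calibration estimates (which live in band
space) on identical footing: an estimate equal to the truth reproduces
the matched condition bit-for-bit (the per-training-set RNG stream is
keyed by the illuminant values, not by call order). The per-sample gain
`α ~ U(0.1, 10)` cancels under L1 normalization and is included to make
that explicit.

The regressor is a random forest (100 trees, `min_samples_leaf = 5`,
fixed seed, predictions clipped to [0, 1]) mapping normalized 16-band
vectors to first-layer sox. First-layer oxygenation is the documented
label choice: the shallowest layer dominates reflectance in the layered
model. The experiment trains one regressor per reference illuminant and
one per calibration estimate (5 + 40 at full scale), evaluates all on
test sets rendered under each reference illuminant, and reports matched /
mismatched / calibrated MAE in percentage points plus the mean relative
reduction `(1 − MAE_cal/MAE_mis) × 100` per test illuminant. Full scale
is 10,000 / 5,000 train/test rows; examples and most tests run a reduced
2,000 / 500 scale. At run time, `select_regressor` picks the bank entry
angularly closest to a calibration estimate (ties to the lowest id).

## Synthetic illuminants

Five smooth SPDs emulate OR lighting: flat xenon, a second xenon with a
slight warm tilt, a 3200 K Planckian halogen, a three-line fluorescent on
a continuum base, and a blue-peak + phosphor-hump white LED. Their
pairwise band-space angular errors span 1.1–25.2°, covering the
near-degenerate pair (the two xenons) through the strongly separated
xenon/fluorescent pair.

## What the bench shows — and does not

Passing the synthetic studies shows the pipeline is correct and
near-optimal *under this image-formation model*: dichromatic mixing,
neutral specular interface, spatially uniform illumination, Gaussian
bands, multiplicative band noise. It does not establish performance under
real mosaic-sensor crosstalk, geometric shading, inter-reflections,
wavelength-dependent specular reflectance, or spatially mixed
illuminants. Two quantitative caveats: (1) the closed-form reflectance
stand-in makes matched-illuminant oxygenation regression easier than
Monte-Carlo-based benches — matched MAE here is ~7.5–8.5 pp, a few points
below what full radiative transfer yields; relative comparisons (matched
vs mismatched vs calibrated) are the robust quantities. (2) absolute
angular errors depend on the chosen specular-to-diffuse contrast;
worst-case error scales roughly linearly with tissue brightness at the
selected exposure.

## Numerical details

- Ties everywhere are deterministic (documented per operation); all
  randomness flows through explicit seeds or `numpy` Generators.
- L1 normalization rejects all-zero vectors; angular error rejects zero
  vectors and mismatched lengths; degenerate inputs raise typed errors
  (`DegenerateInputError`, `DimensionError`, `ConfigurationError`,
  `NoHighlightsError`) rather than returning NaNs.
- PCA projections fix component signs by making the largest-magnitude
  loading positive, so plots and regression tests are reproducible.
- Quantization is round-to-nearest then clip to [0, adc_max];
  `quantize=False` renders the unclipped analog signal for exactness
  tests.
- Problem sizes: the calibration study renders 5×8 series of 30 cubes at
  128×128×16; the full oxygenation study trains 45 forests on
  10,000×16 matrices. Together they run in about six minutes on one CPU.
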