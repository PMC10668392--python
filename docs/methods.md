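# Methods

This note documents the models, numerical choices and limitations of
`phenotherm`, in the package's own terms.

## Thermographic signal model

The camera's raw digital numbers (DN) are related to blackbody
temperature through the Planck-type calibration curve

    S(T) = R1 / (R2 (exp(B / T_K) − F)) − O,   T_K = T + 273.15,

with the factory constants of the platform's LWIR camera
(R1 = 16963.094, B = 1435.3 K, F = 1, O = −4328, R2 = 0.014514672).
The measured signal of a scene pixel mixes object emission with
reflected, atmospheric and protective-window radiance:

    raw = ε τ τ_w S(T_obj) + τ τ_w (1−ε) S(T_refl)
        + τ_w (1−τ) S(T_a) + (1−τ_w) S(T_win).

`raw_to_temperature` inverts this decomposition per pixel;
`temperature_to_raw` is its exact forward model and is what the scene
generator renders with, so the DN round trip is testable (≤ 0.01 °C over
0–60 °C including integer DN rounding; the DN quantisation step is
~0.006 °C at 25 °C). Leaf emissivity defaults to 0.96 and the reflected
temperature is measured from crumpled aluminium foil in the frame.

Atmospheric transmittance uses the standard two-term exponential model
τ = X·exp[−√d(α₁+β₁√ω)] + (1−X)·exp[−√d(α₂+β₂√ω)] with the
conventional constants (X = 1.9, α₁ = 0.006569, α₂ = 0.01262,
β₁ = −0.002276, β₂ = −0.00667) and the usual cubic water-vapour-content
polynomial ω(T_a, RH). At the 3.5 m indoor path τ ≈ 0.97–1, so this
choice is benign; all constants are exposed.

**Drift correction.** The imaged black plate is compared with its
thermocouple frame by frame (difference d). A frame is adjusted — the
rolling-window median d subtracted from all pixels — only when the
rolling median of |d| exceeds 1 °C, i.e. the discrepancy is consistent
rather than a single-frame glitch. The window is 20 frames (a free
choice; only the consistency idea is fixed), the correction acts in °C
space, and it is idempotent. Frames without a thermocouple reading pass
through flagged.

**Mask alignment.** RGB-derived masks are reprojected with pinhole
intrinsics for both cameras and a depth-dependent extrinsic translation,
using one scalar depth per plant: camera height minus 2/3 of plant
height. A morphological erosion (default radius 1 px, square footprint)
strips mixed border pixels. Invalid pixels are excluded from all
medians.

## Thermal indices and baselines

CTD, CSI, TRI, T_dry−T_p and T_BS−T_p are pure arithmetic; TRI is taken
with both temperatures in °C (Kelvin would change its values — the
convention is documented precisely because it matters). ICWSI and CWSI
normalise against a fully-transpiring anchor predicted by a
non-water-stressed baseline fitted on well-watered plants (T_p ~ VPD for
ICWSI; CTD ~ VPD per development stage, or CTD ~ VPD·T_a, for CWSI) and
a non-transpiring anchor T_max = T_a + 3 °C. The CWSI formula is
implemented exactly as conventionally printed for this baseline variant,
which yields 1 for a fully transpiring plant and 0 at the dry anchor;
because many users expect the opposite orientation (1 = stressed), an
explicit `orientation="conventional"` switch flips it — nothing is
flipped silently. Index values outside [0, 1] are kept, not clipped.
The young/mature development split is a configurable days-after-onset
threshold. Every computed index records which monitoring position's
T_a/VPD it used; recomputation with the same position is bit-identical.

## Hyperspectral processing

Reflectance is calibrated against a white reference at 1.2 m, so plants
at other camera distances show a systematically shifted level. A
broadband distance response h(d) is fitted on a few plants imaged at
several lift heights: each plant's series of broadband mean reflectance
is divided by its own maximum (removing biological level differences
while preserving the multiplicative shape — a min–max scaling would
destroy the ratio structure the correction relies on), the pooled scaled
values are fitted with a quadratic, and the curve is renormalised to
h(1.2 m) = 1. Correction is the scalar ρ/h(d) per pixel, applied before
illumination classification and averaging, and is exactly invertible
(up to one floating-point ulp). The correction is broadband by default
(one curve for all wavelengths); a per-wavelength variant can be built
by fitting per-band tables the same way.

Illumination classification is deliberately simple: pixels ranked by
broadband VNIR brightness, the central order-statistics band (default
25th–75th percentile) retained, the class mean returned. Named index
wavelengths use nearest-band lookup on the native grids (VNIR 400–1000
nm at 3 nm, SWIR 970–2500 nm at 6.3 nm; the merged grid drops VNIR bands
above the SWIR start so it stays strictly increasing). The derivative
index uses central differences (`numpy.gradient`) on the native grid.

## Drought detection statistics

For each day and trait a saturated two-factor cell-means model
(genotype × treatment) is fitted and the within-genotype WW−WD contrast
tested with a t statistic using the pooled residual variance and
df = N − #cells — the classical least-squares-means contrast, which
collapses to a pooled two-sample t test for one genotype, and handles
unbalanced cells through the cell-means parameterisation. Physiological
traits, which are measured sparsely, are binned into consecutive 4-day
groups and split at 13:00 into morning/afternoon (the boundary instant
counts as afternoon — a documented tie rule); index data are tested
daily without a time split. All p values within one trait (all days ×
genotypes) form the Sidak family, p_adj = 1 − (1−p)^m, computed via
`log1p`/`expm1` so small p keep precision. Under a simulated global null
this controls the familywise error near the nominal 0.05.

## Transpiration-rate models

All models train on ordered-quantile-normalised data: values of rank r
map to Φ⁻¹((r−0.5)/n) (average ranks for ties); new values are
transformed by monotone piecewise-linear interpolation of the training
knots with linear extrapolation, and predictions are inverted to the
original E scale **before** any metric is computed — RMSE is therefore
invariant to any rescaling of the score space. Both response and
continuous predictors are transformed by default; flags disable either.

Methods: single-index and multi-column linear models (unpenalised fits
refuse p ≥ n), greedy forward–backward AIC stepwise selection, LASSO
with the penalty chosen by cross-validation under the one-standard-error
rule (the CV-minimum penalty is known to retain many noise variables;
the 1-SE rule is the standard sparser choice), random forest (300 trees;
hyperparameters may be tuned once on the full table and frozen across
bootstraps — tuning inside every resample would be prohibitively slow
and changes little), and PLSR with the component count chosen by K-fold
CV. A likelihood-ratio χ² helper tests whether added terms contribute
to a linear model. The replacement for automated variable-count
selection ranks features by permutation importance and keeps the
smallest prefix within one SE of the best CV error.

Accuracy is the median out-of-bag RMSE, R² and MAPE over bootstrap
resamples (default 100): each resample refits the model *including its
normalisation maps*, scores the out-of-bag rows, and a resample with no
out-of-bag rows is redrawn. The resampling unit is the plant×timepoint
row by default, with plant-level blocking available. R² is reported in
both conventions — squared Pearson correlation (primary) and
1 − SSE/SST — because they diverge for biased predictions. Transfer to
other genotypes applies the frozen final model (transformations
included) to each genotype's rows; a genotype with constant E gets NaN
R² and finite RMSE.

## Energy balance

The dry-reference simplification assumes leaf and reference share the
radiative load and the boundary layer, so the latent flux is read from
the temperature depression: λE = ρ_a c_p (T_dry − T_p)/r_HR, with
r_HR the parallel combination of the radiative resistance
r_R = ρ_a c_p/(4σε T_aK³) and the boundary-layer resistance from the
laminar flat-plate correlation Nu = 0.664 Re^½ Pr^⅓ over
`exchange_sides` = 2 leaf faces (Nusselt number floored at 1 so still
air stays finite). Defaults: leaf characteristic dimension 0.08 m
(maize leaf width), wind speed 0.1 m s⁻¹ (near-free convection inside
an imaging cabin), λ = 44 kJ mol⁻¹. The forward model solves the same
linearised balance for T_p and T_dry given E (or g_s via the diffusion
approximation E = g_s·VPD/P), so forward→inverse is consistent to
machine precision when the parameters match; when they do not, the E
error scales exactly with the resistance ratio — the model's accuracy
is governed by its resistance assumptions, and that sensitivity is a
parameter, not a guess. T_p above T_dry yields a negative E, flagged
rather than clipped.

## Synthetic scene generator

The generator defines the study conditions; its defaults are not tuning
knobs. It emulates:

- **Environment** — clipped-sinusoid diurnal cycles (T_a 22→28 °C
  between 09:00 and 21:00, VPD 1.5→3 kPa realised through RH so the
  Tetens consistency VPD = e_s(T_a)(1−RH/100) holds exactly; 16/8 h
  photoperiod with a PAR plateau of 280 µmol m⁻² s⁻¹ in the growth
  zone), plus constant daytime biases for the three monitoring
  positions (T_a out/in/gz ≈ +2.0/+0.53/0 °C, VPD +0.4/+0.1/0 kPa) so
  position means are ordered out ≥ in ≥ gz. Gaussian sampling noise
  (sd 0.2 °C, 0.05 kPa, 5 µmol) is added before RH is derived.
- **Physiology** — a phenomenological stomatal model
  g_s = g_night + (g_max·f_sw·f_VPD − g_night)·f_PAR with a logistic
  soil-water response normalised to 1 at 2.4 g H2O/g dry soil and
  < 0.5 at 1.4 g/g, a hyperbolic VPD decline and a rectangular-
  hyperbola light response (nocturnal floor g_night = 0.02 mol m⁻²
  s⁻¹). E follows the diffusion approximation; leaf temperature comes
  from the energy-balance forward model with a radiative load coupled
  to PAR (R_ni = 10 + 0.07·PAR W m⁻², sd 5) and per-observation
  boundary-layer variation (lognormal wind jitter, sd 0.15) — these two
  terms are what make single-index models imperfect and multi-feature
  models genuinely better, as in real cabins where radiation and
  ventilation vary. The scene's wind speed defaults to 1.0 m s⁻¹ (a
  ventilated greenhouse) so canopy–air differences stay in the
  few-degree range; the energy-balance module's own default (0.1 m s⁻¹)
  describes the still cabin during imaging. Leaf water potential uses a
  monotone soil-water-content → soil-potential map anchored at the
  treatment definitions plus a hydraulic drawdown that steepens with
  drying; leaf water fraction is an affine clip of ψ. WD soil water
  ramps linearly from 2.4 to the treatment target over 8 days (water
  withheld), then holds. Fresh weight grows logistically, with the WD
  trajectory scaled so the silking mean sits at the configured fraction
  of the WW mean (default 375.3/615.3 ≈ 0.61).
- **Thermal frames** — 640×480 scenes: background and foil at the
  reflected temperature, black plate at T_dry, a centred plant disk at
  T_p (optional texture sd), pushed through the exact DN forward model,
  with optional camera drift and DN noise (sd 2 DN ≈ 0.013 °C).
- **Spectra** — a smooth vegetation baseline (logistic red edge and
  SWIR decline, pigment-scaled green/red features) with Gaussian
  water-absorption troughs near 970/1200/1450/1940 nm that deepen with
  leaf water fraction, plus a broad NIR scattering term that declines
  with hydration; the latter makes the 900/970 ratio (WBI) *fall* and
  ρ1483/ρ1430 (RMP) *rise* with water status, matching the sign of the
  observed index–E correlations. The whole spectrum is multiplied by a
  quadratic distance factor h(d) with h(1.2 m) = 1 declining ~14% by
  3 m.

What the generator does **not** emulate: 3-D canopy geometry and
self-shading, spectral radiative transfer (troughs are Gaussians, not
physics), non-steady-state leaf thermal dynamics, camera optics beyond
the pinhole model, and real gas-exchange instrument error structure.
Passing tests therefore demonstrate that the *processing chain* is
correct and self-consistent, not that the statistical models would reach
the same accuracy on real plants.

## Problem sizes and numerical notes

Tests and the acceptance script use experiments of 2 genotypes × 2
treatments × 4–10 plants × 6–20 days (up to ~800 plant-days), 50–100
bootstrap resamples, 200 baseline-recovery replicates and 1000
null-calibration replicates — sizes chosen so the whole suite runs in a
few minutes on one CPU while keeping Monte-Carlo error well below the
asserted tolerances. Degenerate inputs (zero VPD, T_a = 0 °C, constant
predictors, empty masks, zero index denominators, constant-response
genotypes) produce flagged missing values or named errors, never silent
zeros. Seeded `numpy` Generators drive all randomness; identical
configurations reproduce byte-identical CSVs (fixed float format).

One honest caveat: the baseline coefficient-recovery check asks for
±2·SE coverage in ≥ 95% of replicates while the true coverage of a
2-standard-error interval is ≈ 95.2% (t, 98 df), so the empirical
fraction over 200 replicates sits close to the threshold by
construction; the check verifies that OLS-based baselines are unbiased
with honest standard errors, not that coverage exceeds its nominal
value.
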