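# Methods

`skindrs` models and analyzes near-infrared diffuse reflectance
spectroscopy (DRS) of skin around the two water absorption overtones, with
the goal of quantifying how strongly tissue water is hydrogen-bonded to
macromolecules (bound water) — a proxy for epidermal barrier status that
separates psoriatic lesions from uninvolved and normal skin.

## Forward model: probe-resolved Monte Carlo

The tissue is a homogeneous semi-infinite turbid medium (refractive index
1.45) probed in contact by three aligned fibers (400 µm core, NA 0.22,
1 mm pitch): one source and two detectors at source–detector separations
(SDS) of 1 and 2 mm. Photons are launched uniformly over the source face
with directions uniform over the acceptance cone (half-angle
asin(NA/n_tissue), since the index-matched face preserves the cone);
propagation uses exponential step lengths at rate µt, Henyey–Greenstein
scattering with g = 0.8, and the scattering coefficient µs = µs′/(1−g).
The boundary is index-matched by default (a fused-silica contact probe
nearly matches n = 1.45); an unpolarized-Fresnel mismatched variant is a
`ProbeGeometry` switch.

Detection uses three exact variance-reduction devices:

1. **White Monte Carlo.** One zero-absorption run per µs′ records each
   detected photon's total path length L; reflectance at any µa follows
   from reweighting by exp(−µa·L). This turns the 1000-step µa axis of
   the optical-property grid into an analytic rescaling.
2. **Azimuthal averaging.** The launch ensemble is rotationally symmetric
   about the probe axis, so a flight reaching the surface at radius r
   lands inside a detector face at distance d with probability equal to
   the subtended-arc fraction θ*/π. Every in-band exit contributes a
   fractional weight instead of a rare 0/1 hit.
3. **Next-event estimation.** At each scattering event the kernel tallies
   the expected detected weight of the next flight: one direction sampled
   uniformly in the upward acceptance cone, weighted by the
   Henyey–Greenstein density toward it, the uncollided escape probability
   exp(−µt·z/|cosθ|), and the arc fraction at the exit radius. Terminal
   surface exits are then pure escape, so nothing is double counted. The
   acceptance cone subtends only ~2% of the exit hemisphere, which makes
   terminal-hit detection hopelessly sparse at desk-scale photon budgets;
   the local estimator reduces the reflectance variance by roughly an
   order of magnitude (SE/R ≈ 2% at 10⁵ photons).

Unbiased termination: weight roulette below 10⁻⁴ (survival 0.1, standard
practice), plus a path-length roulette (survival 0.8 per 100 mm of
cumulative path) that tames the heavy first-passage tail of
zero-absorption walks, and a hard cap at 1000 mm whose truncated weight is
tracked in the energy balance. Per-run conservation
(detected + escaped + absorbed + truncated + roulette net = launched)
holds to float precision by construction and is asserted to 10⁻³.

Path records receive record-level roulette (floor 3 × 10⁻⁴) to bound the
buffer; the random stream is consumed identically with recording on or
off, so recorded and unrecorded runs of the same seed agree bit-for-bit.

**Interrogation depth** is the exit-weight-and-Beer–Lambert-weighted mean
(or median/percentile) of detected photons' maximum depths. At the
absorption levels of the water bands (µa ≈ 0.3–0.9 mm⁻¹) it is 0.5–1.0 mm
across the two separations; at weak absorption the mean is dominated by
the heavy tail of deep excursions and exceeds 1 mm — a property of the
statistic, not a transport error.

**Validation** is against the extrapolated-boundary diffusion
approximation for a semi-infinite medium (Farrell-type two-dipole form
with zb = 2AD, A = 1 when index-matched): the simulated R(1 mm)/R(2 mm)
agrees within 15% at µa = 0.01, µs′ = 1.0 mm⁻¹ — about the accuracy the
diffusion approximation itself supports one transport mean free path from
the source.

## Inverse model

The forward database tabulates (R1, R2) over µa ∈ [0.001, 1.00] mm⁻¹
(step 0.001) × µs′ ∈ [0.10, 3.00] mm⁻¹ (step 0.10). The desk-scale
default keeps every 10th µa node (100 × 30 = 3000 rows, built from 30
white-MC runs of 10⁵ photons in a few minutes); the full 30,000-node grid
is a flag away.

The inverse is a feed-forward network, two hidden layers of 16 tanh units
with an L2 penalty, mapping z-scored (log10 R1, log10 R2) to
(log10 µa, log10 µs′). Training uses full-batch L-BFGS (deterministic
given the seed; a plateau-patience schedule would only matter for SGD),
with a 10% held-out split whose loss is stored on the model. Prediction
is explicit matrix algebra over the serialized weights, so a JSON
round-trip reproduces predictions exactly. Each wavelength is inverted
independently (no spectral prior). Reflectance pairs outside the training
cloud's bounding box in log space, or nonpositive, yield NaN plus an
out-of-domain flag — never a silent extrapolation.

Held-out recovery on the desk-scale Monte Carlo database is ~2–4% median
relative error for both properties; the high-µa corner of the 2 mm
channel (R2 attenuated below its own standard error) dominates the error
tails.

## Water-band analysis

The two analysis windows are 940–1000 nm (second O–H stretch overtone,
free-water peak near 970 nm) and 1230–1380 nm (rising shoulder of the
first-overtone complex; the remap pivot is 1380 nm, inside the window).

**Water reference.** The bundled pure-water absorption spectrum is a
synthetic construction — a sum of Gaussian components anchored at
published overtone peak positions and magnitudes (≈0.045 mm⁻¹ at 970 nm,
≈0.1 mm⁻¹ at 1190 nm, ≈2.4 mm⁻¹ at 1450 nm with a broad short-wavelength
wing) sampled at 1 nm from 920–1450 nm. It reproduces the qualitative
overtone structure the method needs; it is not a measured spectrum, and
absolute residual magnitudes therefore are not comparable with values
obtained against a spectrophotometer reference.

**Bound-water perturbation.** Bound water red-shifts the second-overtone
band and blue-shifts/broadens the first. The model resamples the
reference at λ′ = peak + (λ − peak − shift)/width and mixes
(1−f_b)·free + f_b·bound. Remapped wavelengths outside the reference are
clamped to edge values; no renormalization (simplest model consistent
with the observed broadening). Typical magnitudes: a few nm of red shift
at the second overtone; tens of nm of blue shift with 1.2–1.3× width at
the first (the cohort generator defaults to +1 nm and −20 nm/1.3×).

**Residual statistic.** For a recovered absorption spectrum the
nonnegative amplitude c minimizing Σ(µa − c·µa_water)² over the band is
closed-form; the statistic is ρ = 100 × Σresid²/N (units (mm⁻¹)²×100).
Amplitude-only fitting is deliberate — an offset term would absorb
exactly the hemoglobin-like baseline whose interplay with band shape the
statistic exploits; an offset variant exists behind a flag for
diagnostics.

**Scattering power law.** µs′ = a·λ⁻ᵇ (λ in nm) is fitted by nonlinear
least squares initialized at the log–log regression solution. Over a
60–150 nm window, a and b are strongly collinear (log a is the intercept
extrapolated to λ = 1 nm), so percent-level spectral tilt moves (a, b)
wildly along the collinearity ridge while the band-centre value a·λ₀⁻ᵇ
stays pinned. This is why subject-level comparisons use µs′ read at 970
and 1300 nm (linear interpolation of the recovered spectrum) rather than
the raw pair, and why enormous fitted a values on some lesions are
expected behavior rather than failure.

## Synthetic cohort

No patient spectra are published, so the study population is synthetic:
21 psoriasis subjects (lesion, adjacent uninvolved, uninvolved upper
inner arm) and 21 normal subjects (arm), five replicate measurements per
site. Per site the generator draws:

| parameter | lesion | adjacent | arms | meaning |
|---|---|---|---|---|
| f_b | 0.55 ± 0.15 | 0.35 ± 0.10 | 0.25 ± 0.08 | bound-water fraction |
| µs′(970 nm) (mm⁻¹) | 0.93 ± 0.29 | 1.16 ± 0.145 | 1.16 ± 0.145 | scattering level (lesion ~80%, doubled spread) |
| b | 0.85 ± 0.16 | 0.85 ± 0.08 | 0.85 ± 0.08 | scattering exponent |
| offset (mm⁻¹) | 0.020 ± 0.006 | 0.012 ± 0.004 | 0.006 ± 0.003 | hemoglobin-like baseline |

with water volume fraction 0.70 ± 0.04 everywhere. Scattering is
parameterized by the band-level µs′(970) together with b, and
a = µs′(970)·970ᵇ is derived: drawing a and b independently would let the
exponent spread inflate the expected band µs′ (Jensen effect of 970⁻ᵇ)
and scramble the intended group ordering, while the derived a reproduces
the huge lesion-to-lesion span of fitted magnitudes seen clinically. Band-specific
perturbation defaults are deliberately asymmetric: a mild +1 nm red shift
at the second overtone versus −20 nm with 1.3× broadening at the first, so the
bound-water signal is strong where the clinical statistics find it
(first overtone) and weak where they do not.

Each site also receives a smooth group-independent absorption background
(linear + quadratic shapes over the band, coefficient SD 0.012 mm⁻¹)
standing in for unmodeled chromophores and residual inversion structure.
This term sets the group-independent floor of the residual statistic: it
dominates the small second-overtone bound-water differences (reproducing
the null second-band group comparison) while being negligible against the
first-overtone signal. Absorption and scattering spectra are pushed
through the forward database by bilinear interpolation, and multiplicative
lognormal noise (CV 2%, independent per wavelength, mean-preserving) makes
the replicates.

PASI subscores are rounded, clipped linear functions of the lesion
parameters plus noise: erythema tracks the absorption offset, thickness
the (inverted) scattering magnitude with a bound-water component, scaling
the bound-water fraction. Only directions are calibrated; the resulting
Pearson correlations with the first-overtone residual are positive and of
the order a few tenths, like the clinical values.

The five replicates are averaged *before* inversion (the lower-variance
choice; the study protocol does not say which side of the inversion the
averaging happened). µs′ readouts at 970/1300 nm come from the recovered
spectrum by linear interpolation.

What the generator does **not** emulate: layered skin anatomy (stratum
corneum/epidermis/dermis), melanin and visible-band chromophores,
spatial heterogeneity within a site, instrument drift between replicates,
and any treatment-response dynamics. Passing tests therefore demonstrate
that the analysis pipeline recovers the statistical structure it assumes,
not that real psoriatic skin has these effect sizes.

## Statistics

Classical equal-variance one-way ANOVA across the four site groups
(k−1, N−k degrees of freedom); when it rejects, all pairwise contrasts
use the Scheffé procedure: F_pair = (x̄ᵢ−x̄ⱼ)²/(MSW·(1/nᵢ+1/nⱼ)) referred
to (k−1)·F_{k−1,N−k}. Scheffé is conservative by construction (every
pairwise p at least the unadjusted pooled-t p), which the suite checks on
simulated data, along with type-I calibration of the ANOVA at α = 0.05
over 2000 null cohorts. Box-and-whisker summaries use linear-interpolation
quartiles, a 1.5·IQR outlier rule, and whiskers to the most extreme
non-outliers (reconciling "whiskers to the extremes" with separately
plotted outliers). Pearson correlation is the standard product-moment
form.

## Numerical choices and degenerate inputs

* Lengths are mm internally; wavelengths nm; depths reported in µm at the
  CLI.
* Reflectance grids must be complete rectangles for bilinear
  interpolation; out-of-bounds forward queries raise rather than clamp.
* Zero detected photons returns a flagged zero-reflectance result, not an
  exception; empty detector bins in depth statistics give NaN with a
  warning.
* All-equal ANOVA groups give F = 0, p = 1; zero-variance Pearson inputs
  raise.
* Power-law fitting rejects nonpositive µs′ naming the wavelengths;
  degenerate constant spectra give b = 0 exactly.
* Every stochastic artifact (kernel, database, training split, cohort) is
  reproducible bit-for-bit from its integer seed.

## Problem sizes

Default experiment sizes were chosen so the full pipeline runs on a
single CPU in minutes: 10⁵ photons per µs′ node (30 nodes, ~3–4 min
build), 10⁶ photons for the diffusion comparison, 3000-row training
table, 2000 null datasets for calibration, and the 42-subject cohort.
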