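# Methods

`sdexa` simulates and analyses scout-based dual-energy absorptiometry
(SDEXA): estimating areal bone mineral density (aBMD, g/cm²) of the lumbar
spine from a low-dose two-channel spectral scout projection, with
volumetric trabecular BMD (vBMD, mg/mL) from dual-energy CT as the
reference standard for osteoporosis classification.

## Attenuation model

Diagnostic-energy attenuation is modelled in the photoelectric/Compton
basis: `f_ph(E) = (E/E₀)⁻³` and the Klein–Nishina total cross-section
`f_KN(E)`, both normalised to 1 at E₀ = 30 keV. Material basis
coefficients for water and hydroxyapatite (Ca₁₀(PO₄)₆(OH)₂, mixture rule
over H/O/P/Ca) are fitted by relative-error least squares to a shipped
mass-attenuation tabulation (`sdexa/data/mass_attenuation.json`, standard
photon cross-section values on a 30–200 keV grid).

Two deliberate numerical choices:

* **Fit window 40–150 keV.** The tabulated totals include coherent
  scattering, which neither basis function represents; for calcium it is
  appreciable below ~40 keV and caps the achievable two-basis relative
  residual at ~2.6% however the photoelectric exponent is chosen. Over
  40–150 keV the fit residual is 0.2% (water) and 1.2% (hydroxyapatite).
  Photons below 40 keV are also essentially absent from a filtered beam
  behind an adult abdomen.
* **Basis-consistent scout channels.** The scout forward model evaluates
  channel attenuation from the fitted basis representation rather than
  from raw table interpolation. The two-channel system (55/75 keV) is
  poorly conditioned, so a sub-percent inconsistency between forward model
  and decomposition basis would otherwise be amplified into a several-percent
  aBMD bias; with the self-consistent model, the projection-domain
  decomposition is the exact inverse of the noiseless forward model. Raw
  tabulated values at 50 and 200 keV are still used for the image-domain
  2×2 matrix (where forward and inverse share the same matrix by
  construction).

## Phantom and acquisitions

The digital phantom is a soft-tissue ellipse (default semi-axes
110 × 80 mm, 1.0 g/mL water-equivalent) containing 1–4 vertebrae: a
cylindrical body (radius 17 mm, height 27 mm) with a 2.5 mm cortical shell
(600 mg/mL hydroxyapatite), a trabecular core (the vBMD target), and a
posterior spinous-process block (10 mm wide, 25–30 mm long, 350 mg/mL).
The spinous block is what differentiates the views: it overlaps the
vertebral body in AP rays and is laterally separable at 90°. Default grids
are 2 mm isotropic; geometry rasterisation is deterministic.

Monoenergetic CT volumes at 50/200 keV follow
`μ_E = (μ/ρ)_water(E)·ρ_water + (μ/ρ)_bone(E)·ρ_bone` (optionally with
Gaussian noise; the default σ = 0 gives ground-truth vBMD, since CT-domain
noise is not the phenomenon of interest here).

The scout is a fan-beam acquisition (52.5° fan, 512 columns by default,
beam collimated to 4 detector rows; source–isocenter 570 mm,
source–detector 1040 mm — typical clinical values, configurable, and
irrelevant to areal densities, which are ray-path integrals). The
dual-layer detector is reduced to two effective monoenergetic channels at
55 and 75 keV with independent Poisson counts. Expected counts in air
default to 1.7·10⁴ per pixel per channel, chosen once so that the raw
photoelectric soft-tissue EPL map of an abdomen-sized phantom has SNR ≈ 5
— the low-dose regime of a 30 mA scout. Zero counts are clamped to 1 and
the clamped fraction recorded as QC. Measured log line integrals are
decomposed per pixel into photoelectric/Compton coefficients and expressed
as water-equivalent path lengths (EPL, cm). Because the two channels are
close in energy, the decomposition amplifies noise and makes it strongly
anticorrelated between the two maps (Pearson r ≈ −0.92 in a homogeneous
soft-tissue ROI at default fluence).

## Denoising

Three stages, in order:

1. **Minimum-noise image.** The weight minimising the ROI variance of
   `w·ph + (1−w)·co` has the closed form
   `w = (σ_c² − σ_pc)/(σ_p² + σ_c² − 2σ_pc)`, clamped to [0, 1]. The ROI
   is a bone-free box, auto-detected as the lowest-photoelectric window
   inside the body. Per-column means are removed first so smooth anatomy
   does not inflate the covariances (scout phantoms are z-invariant, so
   column means capture all structure).
2. **Dictionary denoising** of the minimum-noise image: 8×8 patches,
   256-atom dictionary initialised from an overcomplete DCT and refined on
   the image itself by alternating OMP sparse coding and least-squares
   atom updates (deterministic for a fixed seed); at denoising time every
   overlapping patch is OMP-coded to a residual tolerance of
   1.1·σ̂·(patch size), with σ̂ the wavelet-MAD noise estimate in the
   reference ROI, and overlapping estimates are averaged. Images with no
   trainable structure (flat noise fields) fall back to the fixed DCT
   dictionary.
3. **Local linear transformation** back to each basis map: per window,
   ridge least squares fits `basis ≈ a·min_noise + b`; the box-averaged
   coefficients are applied to the denoised minimum-noise image (the
   guided-filter construction with the minimum-noise image as guide,
   ε = 10⁻³ of the basis-map variance). The default window radius is
   4 px (9×9, matching the 8×8 patch scale). This is deliberately smaller
   than the dictionary patch overlap region: with much larger windows the
   averaged coefficients become constant across a homogeneous ROI, both
   denoised maps collapse onto scalar functions of the shared guide, and
   their Pearson correlation saturates near +1 — destroying exactly the
   decorrelation the method exists to produce. At radius 4 the
   anticorrelation in soft tissue falls from ≈ −0.92 to ≈ −0.13 and the
   photoelectric SNR rises by an order of magnitude, while mean aBMD
   changes by < 0.1%.

The weighted recombination of the denoised maps reproduces the raw
recombination pixel-by-pixel within a fraction of the local noise — the
invariant that guarantees the denoiser does not move quantitative values.
Local noise σ is computed analytically per pixel by first-order Poisson
propagation through the channel inverse (`projection_noise_sigma`), and
the check is evaluated inside the body (Compton EPL above half its
maximum), the only region aBMD quantification ever reads; boundary table
rows see partial-beam rays and carry no quantitative meaning.

## Projection, registration, quantification

The forward projector integrates trilinearly interpolated volumes along
source→detector-cell rays at half-voxel steps, averaging the collimated
rows per table position; density volumes yield areal density (g/cm²),
binary masks yield path length (cm). The interpolant ramps to zero half a
voxel beyond the outer faces, which makes a constant volume integrate to
its exact face-to-face chord (mass conservation for a centered phantom is
within 1%). 2D vertebra masks are thresholded at 25% of each label's peak
projected path; overlaps resolve toward the larger path.

Projected AP aBMD maps are registered to measured scout aBMD maps by mean
squared difference over a 3-level pyramid, translation stage first
(regular-step gradient descent) and affine refinement second (L-BFGS-B;
first-order regular-step descent stalls on the differently-scaled matrix
parameters — injected 2–5° rotations were recovered as ≈ 0.1° — while the
quasi-Newton stage recovers them to < 0.05°). Accepted transforms must
have determinant in (0.5, 2.0) and a final metric no worse than the
identity. Labels are resampled nearest-neighbour.

vBMD is the mean decomposed hydroxyapatite density over a vertebra's
trabecular voxels; aBMD the mean map value over its registered 2D mask.
Negative noise values are preserved (clipping would bias ROI means) and
flagged when > 20% of mask pixels are negative. Status uses the QCT
thresholds with strict `<`: osteoporotic < 80 mg/mL ≤ osteopenic
< 120 mg/mL ≤ normal. Patient-level values are means over available
vertebrae.

## Statistics

Ordinary least squares (aBMD on vBMD) with 95% CIs from the two-sided
inverse Student-t quantile at n−2 degrees of freedom; two-sided
equal-variance t-test by default; ROC by threshold sweep over unique
scores with trapezoidal AUC and the operating point at minimum Euclidean
distance to (FPR 0, TPR 1), ties toward higher TPR. BMD-like scores
classify disease at *low* values through an explicit `positive_is_low`
orientation, so reported thresholds stay in g/cm². The trapezoidal AUC
equals the pairwise-concordance estimator (half credit for ties) exactly;
tests assert this identity on random instances.

Cohort analysis runs three regressions and three ROCs: projected AP and
lateral aBMD against the osteoporosis threshold (80 mg/mL), measured scout
aBMD against the osteopenia threshold (120 mg/mL), where a noisy
measurement retains adequate class balance. Per-patient aggregate rows are
the default analysis input; per-vertebra rows are also emitted.

## Synthetic cohort: what it does and does not emulate

`generate_cohort` draws per-patient trabecular vBMD uniformly over a
configurable range (default studies use 40–200 mg/mL, spanning
osteoporotic to normal) and jitters anatomy: body size ±10%, vertebral
radius ±10%, cortical thickness and mineralisation ±15%, spinous length
±15% and mineralisation ±25%. All randomness flows from explicit seeds
(`SeedSequence` spawning per stage), so cohorts are bit-reproducible.

The emulation captures the mechanisms the analysis depends on — spinous
overlap biasing AP views, cortical contributions, anticorrelated
decomposition noise at clinical scout dose — and on a 40-patient synthetic
cohort reproduces the qualitative ordering of the view correlations with
vBMD (lateral > projected AP > measured AP). It does not emulate
osteophytes, fractures, degenerative change, contrast agents, scatter,
beam hardening, detector cross-talk or motion, so passing tests support
the internal consistency of the method chain, not clinical performance.

## Problem sizes and defaults in tests

Tests and the acceptance script run scaled-down instances chosen as the
smallest sizes that leave every mechanism intact: 2-mm phantoms of
~112×96×48 voxels with two vertebrae, 128-column scouts (~21×128 maps),
20 noise realizations for denoising statistics, a 40-patient cohort for
the correlation ordering, 2000/5000 Monte-Carlo replicates for CI coverage
and t-test calibration. The full-geometry defaults (512 columns, four
vertebrae) remain the library defaults.

## Known limitations

* Two effective monoenergetic channels stand in for the proprietary
  dual-layer detector response; absolute EPL noise levels are calibrated
  by SNR regime rather than by dose.
* The slope of aBMD-on-vBMD regressions depends on phantom anatomy
  (effective projected thickness), so only its sign and ordering across
  views — not its magnitude — are comparable to clinical values.
* Registration assumes matched acquisition geometry (the projector
  provides it), so recovered transforms are small; large initial
  misalignments are outside the validated capture range.
* No soft-tissue correction factor is applied to aBMD.
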