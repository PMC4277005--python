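# Methods

## Models

Body density D_B (g/mL) is weight (kg) divided by volume (L); with these
units the conversion is exact. The two-component model (2CM) treats the body
as fat (density 0.9007 g/mL) plus fat-free mass (FFM, assumed density
d_FFM), giving by volume balance

    f = (1/D_B − 1/d_FFM) / (1/0.9007 − 1/d_FFM).

The three-component model (3CM) treats the body as fat, water and residual
solids and is used here in its coefficient form

    f = 2.118/D_B − 0.78·TBW/W − 1.354,

which presumes fixed water and residual densities. Matching coefficients
(see `derive_component_densities`) implies water ≈ 0.9937 g/mL and residual
≈ 1.567 g/mL; the published intercept 1.354 differs from the recomputed
2.118/d_residual ≈ 1.3515 by ≈ 0.0025, so the 3CM applied to an exactly
composed body recovers its fat fraction to within 0.0025 — the bound the
noise-free recovery tests use.

A per-subject FFM density comes from inverting the 2CM relation at the 3CM
fat fraction: d_FFM = (1 − f)/(1/D_B − f/0.9007). This round-trips with the
2CM to machine precision; tests assert 1e-9.

Fat fractions outside [0, 1] and body densities outside (0.9, 1.15) g/mL
are flagged with `PhysiologicalRangeWarning` but returned unclamped, so
cohort statistics computed downstream are unbiased by truncation.

Reference FFM densities (g/mL): pre-pregnancy 1.100, gestational week 14
1.099, week 32 1.092, 2 weeks postpartum 1.094, with 1.100 available as a
named postpartum alternative. Unknown stages require an explicit value.

## Error propagation and variance decomposition

The methodological SD of FFM density propagates the three measurement SDs
(weight, TBW, volume) through the composite map (W, TBW, V) → D_B = W/V →
3CM f → inverted d_FFM, evaluated **at the cohort-mean measurement vector**
(one SD per stage is the quantity of interest; per-subject propagation then
averaging is a documented alternative the API permits but does not default
to). Partials are central finite differences with step max(1e-6·|x|, 1e-8)
— the map is smooth and mildly nonlinear, and a Monte-Carlo oracle in the
test suite certifies the first-order result to within 2% at 10^6 Gaussian
draws for every stage/spec combination. Measurement errors are taken as
independent zero-mean Gaussians.

Two precision presets are built in, with weight SD 0.01 kg in both:
`set1` (relative: TBW 1.05% of the stage mean, volume 0.7% of the stage
mean) and `set2` (absolute: TBW 0.331 kg, volume 0.371 L). Volume precision
is the primary input by design: a density precision of 0.0016 g/mL is
sometimes quoted as equivalent to 0.371 L (0.7%) at a 56.6 kg / 53.9 L
reference subject, but the first-order conversion (V²/W)·sd_D gives
≈ 0.082 L there, so the utility `density_precision_to_volume_sd` exists for
completeness and is deliberately not used in the decomposition.

Biological SD is the quadrature remainder sqrt(max(total² − meth², 0)).
When the propagated methodological SD exceeds the observed total — a real
regime at gestational week 32, where biological variability is near zero —
the biological variance clamps at zero, the `clamped` flag is set and the
variance shares are reported as 100/0 so they always sum to 100.

## Agreement statistics

Differences are oriented test − reference (2CM − 3CM). The SD of the
differences uses the n−1 denominator and the limits of agreement are
mean ± 2·SD (the 2-SD convention, not 1.96). The trend regression fits the
difference on the pairwise average; its p-value is the OLS slope t test,
which coincides with the correlation test for simple regression. Paired
t tests are two-sided; on zero-variance differences the p-value is exactly
1.0 when the mean difference is zero and NaN (with a warning) otherwise.

## Synthetic cohort

Bodies are composed from the three components rather than sampling FFM
density directly: latent traits are body weight W, fat fraction f and FFM
hydration h (water mass / FFM mass), composing masses fat = f·W,
water = h·(1−f)·W, residual the remainder. This makes both models
simultaneously meaningful and gives every body an exact volume, density and
FFM density for recovery tests.

Traits are Gaussian per stage. Defaults emulate a 17-woman cohort measured
at four reproductive stages, moment-matched to that study's printed
summaries: weight means/SDs and 3CM fat-fraction means/SDs are taken
directly; hydration means are solved so the latent FFM density hits the
per-stage estimates (1.106 / 1.104 / 1.093 / 1.099 g/mL) — 1/d_FFM is
linear in h, so the inversion is exact — and hydration SDs map the target
biological FFM-density SDs (0.007 / 0.012 / 0.002 / 0.005 g/mL, the
relative-precision decomposition) through the local derivative.

Two correlations shape the cohort. Each trait tracks within subject across
stages with correlation 0.9 (shared-factor construction; the study design
is longitudinal but publishes no value, so a strong-tracking default is
exposed in `CohortSpec`). Weight and fat fraction correlate 0.8 within a
stage: independent draws would give an emitted TBW SD of ≈ 7 kg against the
printed ≈ 4 kg, while 0.8 — heavier women carrying proportionally more
fat, which is physiologically expected — reproduces it. At large n the
emitted weight/TBW/density moments match the printed table closely (the
hydration calibration alone would bias TBW upward by ≈ 0.7 kg, but the
weight-fat covariance term offsets it almost exactly).

Measurement noise is added independently to weight, TBW and volume at the
resolved stage precisions; the noisy density is recomputed as noisy
weight / noisy volume. Subjects implying non-positive masses are redrawn
(cap 1000, then an error). A fixed seed gives bit-identical cohorts.

What the generator does **not** emulate: fetal/placental compartments
(stage specs absorb their net effect on hydration and density), non-Gaussian
or skewed trait distributions, correlated measurement errors, and
within-subject error correlation across stages. Passing recovery tests
therefore show the pipeline is self-consistent under its own assumptions,
not that real cohorts satisfy them.

## Problem sizes and tolerances

Closed-form checks run at the printed cohort means (n = 17 behind each
summary). Simulation-based checks use: 10,000 subjects for distributional
targets (SD within 5%), 200 replicate 17-subject cohorts for the recovery
median (±0.003 g/mL of the generating 0.012) and for the stage-accuracy
ordering (week-32 limits of agreement tighter than week-14 in ≥ 95% of
replicates), and 10^6 Monte-Carlo draws for the propagation oracle. These
sizes keep the full suite under a minute while leaving comfortable margins
on the stochastic assertions.

Worked-example reproductions at printed means carry ±0.1% TBF and
±0.001 g/mL tolerances — except pre-pregnancy (±0.3% TBF, ±0.002 g/mL):
printed cohort statistics average a nonlinear model over subjects, which
differs from the model at the averaged inputs, and the gap is largest
there.

## Limitations

- Raw underwater-weighing or plethysmography processing is out of scope;
  body density is an input.
- No four-component model: no body-mineral input exists in this design.
- Propagation is first-order and mean-level; strongly non-Gaussian errors
  or per-subject heterogeneity in precision are not modelled.
- The calibrated defaults are moment matches to published summaries, not
  reconstructions of individual subjects; individual-level published
  statistics (e.g. per-stage limits of agreement) are reproduced only in
  distribution.
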