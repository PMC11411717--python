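# Methods

This note records the statistical models, numerical conventions and design
choices behind `expolong`, in the order the pipeline runs.

## Study design assumed

A repeated-measures biomonitoring design: N participants (default 46,
balanced sexes) sampled at V visits (default 6), plasma analyzed by
LC-HRMS in both electrospray modes. Inputs are an aligned feature table
(feature id, ionization mode, m/z, retention time, optional annotation;
one peak-area column per sample), sample metadata (participant, visit,
sex, age band, BMI, batch, run order, analyzed volume 50–200 µL), an
internal-standard intensity matrix, and per-analyte MLOQs. Raw spectral
processing, spectral-library annotation and compound-class assignment are
upstream of this package and out of scope.

## Mass arithmetic

Monoisotopic masses for C, H, N, O, S, Cl; proton mass 1.007276 Da with
electron-mass handling folded in (standard 4-decimal (de)protonation
arithmetic). Observed ions are [M+H]⁺ in ESI+ and [M−H]⁻ in ESI−, so
neutral mass = m/z ∓ 1.007276. The formula parser is deliberately flat
(no parentheses or isotopes); it covers the compound classes handled here
and is cross-checked against pyteomics in the test suite.

## Feature reduction

Stages run in a fixed, logged order: blank filter → cross-mode dedup →
IS-PCA drift correction → volume normalization.

**Blank filter.** A feature is kept when mean(sample areas)/mean(blank
areas) ≥ `min_ratio` (default 5, configurable; a zero blank mean always
keeps the feature, and equality keeps it). The ratio-5 default is a
common untargeted-metabolomics convention; the threshold is exposed
because no single value is canonical.

**Cross-mode deduplication.** Two features in opposite modes are
redundant when their adjusted neutral masses differ by ≤ 0.002 Da and
their RTs by ≤ 0.2 min; the lower-mean-area member is discarded. The
0.002 Da tolerance is applied to adjusted neutral masses (the literal
reading), not to raw m/z differences. Chains (A~B~C across modes) are
resolved greedily from the highest mean area downward, re-checking pairs
after each removal: a feature is dropped only when a *surviving*
higher-area partner covers it. This makes the survivor set unique
(order-independent given distinct areas) and guarantees two properties
the tests enforce: the output contains no qualifying pair, and every
removed feature has a surviving partner within both tolerances. Mean-area
ties drop the ESI− member — arbitrary but fixed. An alternative greedy
that repeatedly deletes the globally smallest paired feature violates the
surviving-partner property on chains, which is why it was not used.

**IS-PCA drift correction.** The internal-standard matrix (channels ×
samples) is log10-transformed and unit-variance scaled per channel;
per-sample scores on the first `n_components` principal components
(default 2, configurable) summarize instrumental/batch variation shared
across channels. Each feature's log10 area is regressed on the centered
scores and replaced by residual + mean, then back-transformed — so
corrected areas are strictly positive by construction. Zeros are imputed
at half the feature's smallest nonzero area before logging and restored
as zeros afterwards. Constant IS channels are dropped with a warning; if
none remain the table is returned unchanged (this is also the exact
no-drift limit: with constant IS intensities the correction is the
identity). `n_components` must be below the sample count.

**Volume normalization** divides each sample's areas by its analyzed
volume; samples with missing or non-positive volumes are dropped with a
warning.

## Censoring

Detected-below-MLOQ values are substituted by MLOQ/2 and nondetects by
MLOQ/4, on the concentration scale, before any log transform (the
substitute-then-log order is a package choice; it is configurable by
operating on the series directly). "Detected" for detection-frequency
purposes includes below-MLOQ signals: DF counts presence, not
quantifiability. Substitution is idempotent and preserves statuses.

## ICC and exposure typing

The default estimator is the one-way random-effects, single-measurement
form ICC(1) on log10 substituted concentrations:
ICC = (MSB − MSW)/(MSB + (k − 1)·MSW), matching the
between-over-total-variance definition. For unbalanced data k is the
harmonic mean of per-participant visit counts and participants with
fewer than two visits are excluded. Negative estimates are clamped to 0
with the raw value retained; zero total variance raises. A two-way
absolute-agreement form ICC(2,1) is available behind a switch for
balanced data, since published ICCs computed with other toolkits may use
a two-way model.

Reproducibility bins: < 0.40 poor, 0.40–0.75 fair-to-good, > 0.75
excellent. Exposure types partition the DF × ICC plane with exact,
config-exposed thresholds: DF ≤ 0.20 "rare", DF ≥ 0.80 "common",
ICC ≥ 0.6 "stable", ICC < 0.4 "unstable"; anything between is
`unclassified`. The DF thresholds are inclusive so a substance at
exactly 20 % DF with low ICC lands in the rare-unstable type.

## Coexposure

Pairwise Pearson correlations use pairwise-complete deletion with the
paired n reported; constant vectors are flagged rather than tested.
Bonferroni adjustment is min(1, m·p) over the m testable pairs.
Clustering uses 1 − r as the dissimilarity (a valid symmetric,
zero-self-distance index) with average linkage; substances are
unit-variance scaled first, and columns are either all samples or
per-individual visit means. Log10 + unit-variance is the default value
scale. Leaf order is deterministic (ties broken by input index). Flat
"coexposure groups" via tree cutting at a height are provided as a
convenience only — published group labels of this kind are typically
drawn by hand, not by a cut rule.

## Suspect screening

A candidate (nonannotated) feature is accepted as a metabolite when it
(i) matches, within `ppm_tol`, the theoretical (de)protonated m/z of an
anchor shifted by a transformation mass (shift table: hydroxylation
+15.994915, sulfation +79.956815, glucuronidation +176.032088,
carbamoyl-glucuronidation +220.021918, demethylation −14.015650; each
delta is validated against its elemental composition to 1e-6 Da), and
(ii) correlates with that anchor at Pearson p < `p_threshold` (default
10⁻³). Anchors start at the parent and grow with accepted hits, depth
limited to 2 — enough for the hydroxy → sulfate chain. The default
`ppm_tol` of 5 is a deliberately generous instrument-accuracy window
(observed hits typically fall within 2 ppm); it is configurable. No RT
plausibility constraint is imposed, although conjugates usually elute
earlier than their parents. Output is invariant to candidate order.

## Association models

Sex differences use the Mann–Whitney rank-sum test on all samples of
each substance (DF > 10 % gate), with Shapiro–Wilk normality p-values
recorded and Bonferroni correction over the tested set. A signed-rank
variant on sorted per-individual means is available behind a switch;
published analyses of unpaired sex comparisons sometimes name the
signed-rank test, which strictly applies to paired data, so the
discrepancy is surfaced as an option rather than silently resolved.

Exposure–outcome models are linear mixed models,
log10(outcome) ~ log10(exposure) [+ baseline age + baseline BMI], with
participant random intercepts and slopes, REML estimation via
statsmodels. On a singular or non-converged random-slope fit the model
falls back to random intercepts only (flagged); if the intercept
variance itself collapses to the zero boundary the fit degrades to OLS,
which is the exact limit of the model. Bonferroni correction spans the
exposure panel. Baseline (first-visit) age and BMI are used as
covariates; sex stratification is a flag.

## Synthetic cohorts: what is and is not emulated

Log10 concentration of individual i at visit j is
`log_mean + sex_effect·1[female] + b_i + e_ij`, b_i ~ N(0, σ²_b),
e_ij ~ N(0, σ²_w) — log-normal concentrations, variance components
additive on the log scale, so positivity and multiplicative biology come
for free and the true ICC σ²_b/(σ²_b+σ²_w) is known exactly. Peak areas
are concentration × a per-substance response factor (drawn once, fixed)
× drift. Drift is a per-batch multiplicative factor (log10-normal, sd
0.10) times a smooth monotone run-order trend (default +30 % across the
run), identical for internal standards and analytes of the same mode —
which is exactly what makes the IS-PCA correction identifiable. IS
channels get 5 % multiplicative noise. Censoring: no signal below a
mode-level noise floor or below the substance's detection limit (MDL,
default MLOQ/2 when not stated); detected-but-unquantifiable between MDL
and MLOQ. Blanks carry low-level noise at a configurable fraction
(default 1 %) of mean signal; no specific published blank-filter rule is
encoded, so blank intensity is a free parameter. The default panel
(343 environmental + 162 endogenous substances) spreads detection
frequencies over 2–100 % and draws true ICCs from Beta distributions
with means 0.30 (environmental) and 0.40 (endogenous), matching the
scale of reported exposome vs endogenous ICC distributions.

Planted structure: cross-mode duplicate twins (adjusted-mass gap
< 0.002 Da, ΔRT < 0.2 min, strictly lower mean area), parent–metabolite
families (children at the theoretical shifted m/z ± ≤ 1 ppm jitter,
areas affine in the anchor's with noise sized for a target Pearson r),
decoy features at random m/z with uncorrelated areas (blank-level signal
in blank columns), and an exposure→outcome association with fixed slope
plus participant random intercepts and slopes.

Not emulated: chromatographic peak shapes, isotope patterns, MS2
spectra, adducts beyond ±H, matrix effects, nonlinear response, missing
visits. Consequently, passing parameter-recovery tests shows the
statistical machinery is correct under the stated generative model; it
does not certify performance against annotation errors, RT drift or
nonlinear ionization effects in real data.

## Simulation sizes and numerical conventions

Test simulations are sized for tight-but-fast checks: ICC recovery uses
200 balanced 46×6 cohorts per true-ICC level (bias tolerance 0.05);
dedup is compared against the brute-force oracle on one hundred
500-feature tables; mixed-model slope coverage uses 40 replicates at 23
participants × 6 visits and the permutation null 60 refits. Ties,
degenerate inputs and boundary cases (zero variance, constant vectors,
all-censored series, single-sex data) raise or flag explicitly rather
than returning silent numbers. All randomness flows through
`numpy.random.default_rng` seeds; a fixed seed gives byte-identical
generator output.

## Known limitations

- ICC confidence intervals are not provided (a bootstrap is easy to add
  on top of `icc_oneway`).
- Reference standardization assumes linear response through the pooled
  reference plasma; no matrix-effect or recovery correction.
- The mixed model reports Wald p-values; small-sample corrections
  (Satterthwaite/Kenward–Roger) are not implemented.
- The suspect screen's correlation criterion uses post-correction areas;
  strong censoring in either member attenuates r and can cost
  sensitivity for rarely detected metabolites.
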