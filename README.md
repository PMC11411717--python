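# expolong

Longitudinal analysis of the blood chemical exposome from repeated-measures
LC-HRMS cohorts.

Untargeted chemical exposomics measures hundreds of environmental and
endogenous small molecules in plasma. When the same individuals are sampled
repeatedly, two questions dominate: *is a single sample representative of a
person's exposure* (longitudinal stability), and *which exposures travel
together* (coexposure structure). `expolong` implements the full analysis
path for such a design — 46 participants × 6 visits is the default study
shape — together with a synthetic-cohort generator with known ground truth,
so every stage is testable by parameter recovery.

## What the package computes

**Feature-table reduction** (`expolong.features`). Starting from an aligned
two-mode feature table (the shape of an MS-DIAL alignment export): blank
filtering; removal of redundant cross-mode detections (features whose
(de)protonation-adjusted neutral masses agree within 0.002 Da and retention
times within 0.2 min — the lower-mean-area member is discarded); drift
correction by regressing each feature's log area on the leading PCA scores
of the isotope-labeled internal-standard intensities; and normalization by
analyzed sample volume.

**Censored quantification** (`expolong.quant`). Calibration-curve fitting,
semiquantification by reference standardization against pooled plasma, and
the biomonitoring substitution convention for left-censored values:

- detected below MLOQ → MLOQ/2,
- nondetect → MLOQ/4.

**Longitudinal stability** (`expolong.stability`). For each substance the
one-way random-effects intraclass correlation coefficient on log10
concentrations,

ICC = σ²_b / (σ²_b + σ²_w) — estimated as (MSB − MSW) / (MSB + (k − 1)·MSW),

with detection frequency (DF) as the second axis. Substances are binned
(ICC < 0.40 poor, 0.40–0.75 fair-to-good, > 0.75 excellent) and typed into
four quadrants of the DF × ICC plane: rare-stable, common-stable,
common-unstable, rare-unstable.

**Coexposure clustering** (`expolong.coexposure`). Pairwise Pearson
correlations with Bonferroni control, and average-linkage hierarchical
clustering with 1 − r distance on unit-variance-scaled profiles
(per-sample or per-individual visit means), exported as heatmap-ready
delimited matrices with metadata tracks.

**Suspect metabolite screening** (`expolong.suspects`). Nonannotated
features are screened as metabolites of a parent compound by two joint
criteria: exact-mass match to a biotransformation shift (hydroxylation +O,
sulfate +SO₃, glucuronide +C₆H₈O₆, carbamoyl-glucuronide +CO₂+C₆H₈O₆, …)
within a ppm tolerance, and Pearson correlation with the parent (p below a
threshold). Accepted hits become anchors, so metabolites of metabolites
(e.g. a hydroxylated drug's sulfate conjugate) are found at depth 2.

**Association modeling** (`expolong.assoc`). Rank-based sex-difference
tests with Bonferroni correction, and exposure–outcome linear mixed models
on log10–log10 scale with participant-specific random intercepts and
slopes, optionally adjusted for baseline age and BMI.

**Synthetic cohorts** (`expolong.synth`). The generator draws log10
concentrations from an additive variance-components model (so each
substance's true ICC is known), converts them to peak areas with fixed
response factors, shared multiplicative batch/run-order drift (carried
identically by the internal standards), MLOQ/MDL censoring, blanks, and
plants cross-mode duplicate pairs, correlated parent–metabolite families,
decoy features and an exposure–hormone association with random slopes.

## Worked example

```python
from expolong import chem, suspects

diclofenac = chem.formula_mass("C14H11Cl2NO2")   # 295.016684 Da
mz = suspects.theoretical_mz(diclofenac, "hydroxylation", "ESI-")
print(round(mz, 6), round(suspects.ppm_error(mz, 310.0049), 2))
```

prints `310.004323 1.86`: the theoretical [M−H]⁻ ion of hydroxylated
diclofenac, and the +1.86 ppm error of an observed ion at m/z 310.0049 —
i.e. a convincing exact-mass match for the hydroxy metabolite.

The full analysis lives in `analysis/` as numbered drivers over the
library; run them in order from the repository root:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_process_features.py
python analysis/03_stability_typing.py
python analysis/04_coexposure_clusters.py
python analysis/05_suspect_screen.py
python analysis/06_associations.py
```

With seed 1 the simulated cohort has 276 samples and 735 features; the
reduction removes exactly the 25 planted cross-mode twins; stability typing
recovers per-substance ICCs with median absolute error 0.048 against the
generator's truth and separates the environmental (mean ICC 0.29) from the
endogenous (0.39) class (t = 5.6, p = 4×10⁻⁸); the suspect screen recovers
both planted diclofenac metabolites (hydroxy, then its sulfate anchored to
the hydroxy hit) with zero false hits over 200 decoys; and the planted
PFAS→testosterone slope of 0.5 is estimated at 0.41 (SE 0.055) in the
female stratum. Tables land under `results/`.

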