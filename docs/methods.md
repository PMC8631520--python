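# Methods

This note documents the modeling and numerical choices behind
`phyllotex`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Gray-level normalization

Texture statistics on MR images are meaningless without intensity
normalization, because raw signal units vary with scanner gain and coil
loading.  Each VOI is normalized independently: μ and σ are computed over
the VOI voxels only (σ with the population, divide-by-Np convention, the
same convention the histogram Variance feature uses), intensities are
clipped to [μ − 3σ, μ + 3σ] and binned as

```
level = 1 + floor((x − (μ − 3σ)) / (6σ) · Ng)
```

with the exact upper endpoint assigned to Ng.  Conventions fixed here and
configurable where noted:

* **Ng = 64** (6-bit) by default.  This matches the level scale on which
  histogram statistics such as a Mean near 32 or a 90th percentile near
  43 are natural; it is configurable (`n_levels`).
* **Levels are 1-based** (1..Ng) so that the index arithmetic of the
  co-occurrence and run-length formulas (sums over k, i·j products,
  p_{x+y} on 2..2Ng) matches the classical definitions.
* **σ = 0 degenerates gracefully**: a constant VOI maps every voxel to
  level 1 with a logged warning, so flat phantoms remain usable.
* Voxel coordinates are 0-based array indices; masks are binarized at
  > 0 and used as drawn, with no morphological cleaning and no
  reorientation of the on-disk NIfTI layout.

This windowing makes every downstream feature exactly invariant to
affine intensity maps x → a·x + b (a > 0), which the test suite asserts.

## Feature families

All features operate on the quantized VOI.  The inventory (314 names) is
generated by a single registry module that is the source of truth for
name ↔ (family, statistic, offset/direction, distance) and is exported to
CSV with every study run.

* **Histogram (9).**  Population variance; excess kurtosis; percentile
  q% defined as the smallest level whose cumulative count reaches
  (q/100)·Np.  Skewness/kurtosis of a zero-variance VOI are reported as 0
  and flagged undefined.
* **Co-occurrence (275).**  Five offset families — the three lattice
  axes plus the two in-plane diagonals — each scaled by distances 1..5,
  11 statistics per matrix.  A fifth, through-plane (Z) offset family is
  included because volumetric whole-lesion analysis has no reason to
  privilege the acquisition plane, and the named features of interest
  (e.g. S(0,0,1)AngScMom) require it; 11 × 5 × 5 = 275.  Matrices are
  accumulated symmetrically (both pair orders), pairs count only when
  both voxels are inside the VOI (no padding), and each matrix is
  normalized to sum to 1.  Entropies use the natural logarithm with
  0·ln 0 ≡ 0.  Correlation is flagged undefined (value 0) when a marginal
  standard deviation vanishes.
* **Run-length (25).**  Maximal same-level runs along the lattice lines
  of five directions (Z, horizontal, vertical, and the two in-plane
  diagonals); any non-VOI voxel breaks a run.  Fraction is Nr/Np.  The
  run matrix is stored dense at Ng × (longest observed run).
* **Gradient (5).**  Central differences of the quantized levels,
  evaluated only at voxels whose six axial neighbors are inside the VOI;
  GrNonZeros is the fraction of those voxels with nonzero magnitude.

Degenerate statistics are always reported as *missing-with-reason*
(surfaced as NaN in feature tables) rather than silently zeroed, so the
selection stage can drop them transparently.

A note on scale: the angular second moment of a normalized matrix lies in
(0, 1].  Values quoted for this statistic in parts of the clinical
literature exceed 1 because of undocumented software-specific scaling;
`phyllotex` reports the normalized value and makes no attempt to
reproduce any such scaling.

## Selection cascade

Stage order is variance filter → standardization → univariate screen →
univariate logistic → backward stepwise multivariate.  The variance
threshold (default 0.8, *strictly* smaller removed) is applied to **raw**
features: applying it after z-scoring would be vacuous since standardized
columns all have variance ≈ 1.  The order is configurable
(`variance_on_raw=False`) for anyone who wants the other reading.

* The normality gate applies the Kolmogorov–Smirnov test per group
  against a normal with estimated parameters.  Estimating the parameters
  makes the nominal KS distribution conservative (the Lilliefors
  correction would sharpen it); the gate only routes between t-test and
  Mann–Whitney, so miscalibration here costs power, not validity.
* Perfectly separating features are flagged and **retained** at the
  univariate-logistic stage — in a 47-lesion cohort separation is
  informative, not an artifact to discard.
* Backward elimination uses likelihood-ratio removal tests with a
  retention criterion of p ≤ 0.10, the common statistical-package
  default.  The last surviving feature is itself tested against the
  intercept-only model, so a pure-noise table ends at an intercept-only
  model.
* When survivors approach the sample size, the full starting model is
  unfittable; candidates are capped (default 10) by best
  univariate-logistic p before elimination begins.  The cap is recorded
  in the trace like every other removal.
* Missing (undefined) feature values are dropped listwise per feature at
  the univariate stages and disqualify a feature from the multivariate
  stage.

No multiple-testing correction is applied across the 314 features, and no
regularized selection or cross-validation is performed; the cascade is a
fixed, deterministic function of the table, and the trace replays to the
same final model.

## Evaluation statistics

* **AUC** is the Mann–Whitney concordance estimator (ties ½), exactly
  equal to the exhaustive concordant-pair count; its variance and the
  paired two-model comparison use DeLong structural components.  95% CIs
  are formed on the logit scale (normal-scale CIs clipped to [0, 1] are
  available via `ci_style="normal"`).  The reported operating point
  maximizes Youden's J, ties broken toward higher specificity.
* **Hosmer–Lemeshow** groups by deciles of predicted risk (default
  g = 10; ties kept together; degenerate groups merged), with
  χ² = Σ (O−E)²/(E(1−E/n_g)) and df = g − 2.  The df convention assumes
  the probabilities come from a fitted logistic model; with true
  probabilities the statistic is χ²_g and the test over-rejects, which
  the calibration test demonstrates by fitting first.
* **Categorical findings** use Pearson χ² *without* continuity
  correction — the uncorrected statistic is what reproduces the
  recomputable reference p-values for 2×2 findings tables (e.g. 0.014
  for the cyst-wall table [[17,5],[7,11]]); Fisher's exact test is
  available for 2×2 tables.
* **ICC** is the two-way random-effects, absolute-agreement,
  single-measure ICC(2,1) (via pingouin), banded
  poor/fair/moderate/good/excellent at 0.2/0.4/0.6/0.8 with intervals
  closed on the upper end.
* **The published grading model** is frozen: five printed coefficients
  and intercept −4.552 on z-scored inputs, evaluated as a pure function
  with no fitting path that can alter it.

## Synthetic phantoms

The generator's job is to produce cohorts with the *statistical
structure* the analysis assumes — not realistic MR physics.  Defaults
give 26 benign-like and 21 malignant-like lesions on 30³ voxel grids.

Each lesion is a lobulated ellipsoid (semi-axes 7–10 voxels, radial
perturbation by a smooth random field) filled with a base enhancement
level (350–450 a.u.) plus a Gaussian random field (sd 50–80) plus white
noise (sd 15).  Class contrasts:

* **Malignant-like** lesions receive 2–5 small, very bright "hot-spot"
  blobs (Gaussian bumps, radius 1.1 voxels, amplitude 800–2500) and a
  shorter field correlation length (1–2.5 vs 2–3.5 voxels).  The bright
  outliers inflate the VOI σ, so after μ ± 3σ quantization the tissue
  bulk is squeezed into fewer, lower levels: quantized Mean, Perc.90%
  and Variance drop and run-length GLevNonU rises.  One mechanism thus
  produces all four directional contrasts the grading analysis reports.
  The blobs are kept small so they stay well under a tenth of the VOI —
  otherwise the upper percentiles land inside the hot-spot shoulder and
  the percentile contrast inverts.
* **Cysts** (zero-enhancement cavities, strictly interior to the mask)
  appear in ~85% of lesions in both classes; walls are regular spheres
  in 77% of benign-like cysts and irregular unions of offset spheres in
  61% of malignant-like cysts, mirroring the clinical cohort's
  fractions.  Wall irregularity — measured on the actually generated
  cavity geometry — is the one categorical finding that separates the
  classes, feeding the findings-only model.

Everything is a pure function of (spec, seed); cohort artifacts
(NIfTI pairs, labels/findings CSV, truth manifest) are reproducible
bit-for-bit.

**What passing tests do and do not show.**  The phantom classes separate
more cleanly than clinical cohorts do: the planted contrasts are strong
enough that the cascade's texture model typically reaches AUC ≈ 1 on 47
phantoms, whereas real-world grading sits far lower.  Tests on phantoms
therefore validate the *correctness* of the machinery (features match
brute-force oracles, the cascade recovers planted signal, the statistics
are calibrated) — they say nothing about clinical discrimination, which
only patient data can establish.  The generator also omits MR physics
entirely: no coil profiles, no partial-volume mixing, no pharmacokinetic
enhancement curves, no inter-slice anisotropy.

## Problem sizes

The default test and acceptance runs use 30³ lesion grids, 47-lesion
cohorts, 20 master seeds for the recovery property, 1000 replicates for
the DeLong type-I rate and 500 for the Hosmer–Lemeshow rate; the
brute-force oracle comparisons run on seeded volumes up to 5×5×5 with 2–4
gray levels, where exhaustive enumeration is exact and cheap.  These
sizes were chosen to exercise every code path at desk scale while keeping
the full suite fast.

## Known limitations

* Single-volume analysis: no multi-phase DCE modeling, no DWI/T2
  features, no registration across phases, no DICOM ingestion.
* Manual-mask paradigm: no segmentation, no mask cleaning; a bad mask
  yields bad features by design.
* The backward-stepwise candidate cap is a pragmatic small-cohort
  safeguard; with hundreds of lesions it should be raised or disabled.
* Wald p-values and separation flags from `statsmodels` fits in tiny
  cohorts are approximate; the trace records enough to audit every
  decision.
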