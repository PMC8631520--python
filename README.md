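# phyllotex

Whole-tumor texture analysis of dynamic contrast-enhanced breast MRI for
grading phyllodes tumors.

Phyllodes tumors (PTs) are rare fibroepithelial breast neoplasms whose
surgical management depends on grade: benign PTs are treated by local
excision, borderline/malignant PTs by wide excision or mastectomy.
Conventional MR morphology separates the two groups poorly, and biopsy is
unreliable in these heterogeneous lesions.  `phyllotex` implements a
radiomics pipeline for this problem: quantitative texture statistics of
the whole-lesion volume of interest (VOI) on a contrast-enhanced series,
reduced through a statistical selection cascade into a compact logistic
grading model, with a full evaluation layer.  Because no patient images
are distributed, the package ships a synthetic lesion-phantom generator
that reproduces the statistical structure the analysis assumes, so every
stage is runnable and testable out of the box.

## The method

**Normalization.** For each lesion the VOI intensities are windowed to
μ ± 3σ (μ, σ computed over the VOI voxels; population σ) and mapped
linearly to Ng = 64 discrete gray levels, making every downstream feature
invariant to scanner brightness and contrast.

**Features (314 per lesion).**

| family | count | statistics |
|---|---|---|
| histogram | 9 | Mean, Variance, Skewness, Kurtosis, percentiles 1/10/50/90/99 |
| co-occurrence (GLCM) | 275 | 11 Haralick statistics × 5 offsets {(1,0,0),(0,1,0),(0,0,1),(1,1,0),(1,−1,0)} × distances 1–5 |
| run-length (RLM) | 25 | RLNonUni, GLevNonU, LngREmph, ShrtREmp, Fraction × 5 directions |
| gradient | 5 | GrMean, GrVariance, GrSkewness, GrKurtosis, GrNonZeros |

The histogram mean is Σₖ k·g(k)/Σₖ g(k) over levels k = 1..Ng; the GLCM
angular second moment is Σᵢⱼ p(i,j)²; the run-length gray-level
non-uniformity is Σᵢ (Σⱼ r(i,j))² / Nr.  GLCMs are symmetric, pairs count
only when both voxels lie inside the VOI, and runs break at any non-VOI
voxel.

**Selection cascade.** variance threshold (sample variance < 0.8 removed)
→ z-scoring → univariate screen (Kolmogorov–Smirnov/Levene-gated choice
of pooled t-test vs Mann–Whitney U, keep p < 0.05) → univariate logistic
(Wald p < 0.05) → multivariate logistic regression with backward stepwise
elimination (likelihood-ratio removal p > 0.10).

**Evaluation.** Mann–Whitney AUC with DeLong variance and logit-scale 95%
CIs; paired DeLong comparison of correlated AUCs; Hosmer–Lemeshow
calibration over deciles of risk; uncorrected Pearson χ² / Fisher exact
tests for categorical imaging findings; ICC(2,1) for inter-observer
agreement; and a frozen published grading model
`logit(p) = 0.067·S(0,0,1)AngScMom + 0.001·Z_GLevNonU + 1.944·Perc.90% −
0.301·Variance − 1.994·Mean − 4.552` evaluated on z-scored inputs.

## Worked example

```python
from phyllotex import RunConfig, end_to_end_demo

result = end_to_end_demo(config=RunConfig(seed=7))
print(result.report.render_text())
```

prints (default 26 + 21 synthetic cohort, seed 7):

```
Model                       AUC           95% CI   Sens   Spec
texture                   1.000      1.000-1.000  1.000  1.000
findings                  0.700      0.567-0.806  0.476  0.923
combined                  1.000      1.000-1.000  1.000  1.000
DeLong texture vs findings: z=4.855, p=0.0000
DeLong texture vs combined: z=0.000, p=1.0000
DeLong findings vs combined: z=-4.855, p=0.0000
Hosmer-Lemeshow texture: chi2=0.000, df=1, p=0.9998
Hosmer-Lemeshow findings: chi2=0.000, df=1, p=1.0000
Hosmer-Lemeshow combined: chi2=0.000, df=1, p=0.9996
```

The texture model (the cascade's output, here a single planted-signal
percentile feature) separates the two phantom classes completely, while
the one informative categorical finding (cyst-wall irregularity) alone
reaches AUC 0.70; the paired DeLong rows show the difference is far
beyond sampling noise on 47 lesions.  Synthetic phantoms separate more
cleanly than clinical cohorts — see `docs/methods.md`.

More narrative walk-throughs live in `examples/`: normalization and
extraction of one lesion, the cascade stage by stage, the evaluation
toolbox, and the full study.

A thin CLI wraps the same API:

```bash
phyllotex simulate --seed 3 --out cohort/
phyllotex extract --volume cohort/lesion000_volume.nii.gz \
                  --mask cohort/lesion000_mask.nii.gz --out one.csv
phyllotex run --simulate --seed 7 --out study/
```

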