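"""The evaluation toolbox on small worked inputs.

Shows the DeLong AUC machinery, the uncorrected chi-square on the
reference cyst-wall table, the inter-observer ICC, and the frozen
published grading model evaluated at a few z-score vectors.
"""

import numpy as np

from phyllotex import (
    PUBLISHED_TEXTURE_MODEL,
    auc_delong,
    chi_square_2xk,
    delong_paired_test,
    evaluate_published_model,
    icc_interobserver,
)

rng = np.random.default_rng(0)
labels = np.repeat([0, 1], 25)
good = labels + rng.normal(scale=0.6, size=50)   # informative score
weak = labels + rng.normal(scale=2.5, size=50)   # weakly informative score

r = auc_delong(good, labels)
print(f"informative score: AUC {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}),"
      f" sens {r.sensitivity:.2f} / spec {r.specificity:.2f} at Youden threshold")
z, p = delong_paired_test(good, weak, labels)
print(f"DeLong paired comparison vs the weak score: z = {z:.2f}, p = {p:.4f}")

chi2, df, p = chi_square_2xk([[17, 5], [7, 11]])
print(f"\ncyst-wall 2x2 table: chi2 = {chi2:.3f}, df = {df}, p = {p:.3f}")
print("  (regular vs irregular wall counts; p < 0.05 separates the classes)")

truth = rng.normal(size=60)
ratings = np.column_stack([truth + rng.normal(scale=0.3, size=60),
                           truth + rng.normal(scale=0.3, size=60)])
icc, band = icc_interobserver(ratings)
print(f"\ntwo-rater ICC(2,1) on noisy repeated measurements: {icc:.3f} ({band})")

print("\nfrozen published grading model (inputs are z-scores):")
for z_vec in ({n: 0.0 for n in PUBLISHED_TEXTURE_MODEL.feature_names},
              {"S(0,0,1)AngScMom": 0.5, "Z_GLevNonU": 1.0, "Perc.90%": -1.0,
               "Variance": -0.5, "Mean": -1.0}):
    logit, prob = evaluate_published_model(z_vec)
    print(f"  logit = {logit:+.3f} -> P(malignant-like) = {prob:.4f}")
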