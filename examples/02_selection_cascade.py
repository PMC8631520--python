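"""Run the four-stage feature-selection cascade on a synthetic cohort.

Generates the default 26 benign-like + 21 malignant-like cohort, extracts
the full feature table and shows how the cascade shrinks 314 features to a
small multivariate logistic model, stage by stage.
"""

from phyllotex import CohortSpec, extract_cohort_features, generate_cohort, run_cascade

spec = CohortSpec(master_seed=7)
lesions, labels, findings, _ = generate_cohort(spec)
features = extract_cohort_features(lesions, ids=list(labels.index))
print(f"feature table: {features.shape[0]} lesions x {features.shape[1]} features")

model, trace = run_cascade(features, labels["label"].to_numpy())
for record in trace.stages:
    print(f"  after {record.stage:<20} {len(record.kept):>4} features kept")

print("\nfinal multivariate model (coefficients on the z-scored scale):")
print(f"  intercept = {model.intercept:+.3f}")
for name, coef in model.coefficients.items():
    print(f"  {name:<22} {coef:+.3f}")
print(
    "\nEach surviving coefficient is the log-odds change of the"
    "\nmalignant-like class per one standard deviation of the feature."
)
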