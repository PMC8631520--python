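"""The whole study in one call: simulate, extract, select, evaluate.

Compares the three grading models (texture, conventional findings,
combined) on the default synthetic cohort and prints the report table.
"""

from phyllotex import RunConfig, end_to_end_demo

result = end_to_end_demo(config=RunConfig(seed=7))
print(result.report.render_text())
print(f"\ntexture model features: {result.texture_model.feature_names}")
print(
    "\nThe texture and combined models dominate the single categorical"
    "\nfinding (cyst-wall irregularity); the paired DeLong rows quantify"
    "\nwhether the AUC differences exceed sampling noise on these 47 lesions."
)
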