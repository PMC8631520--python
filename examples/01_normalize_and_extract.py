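"""Normalize one synthetic lesion's VOI and extract its 314 texture features.

Builds a single malignant-like phantom, applies the mu +/- 3*sigma
gray-level windowing (64 levels) and prints a handful of the features that
matter for grading.
"""

from phyllotex import LesionSpec, extract_all, generate_lesion, normalize_voi

lesion, truth = generate_lesion(
    LesionSpec(class_label=1, cyst="irregular", n_hotspots=4, seed=42)
)
quantized, params = normalize_voi(lesion, n_levels=64)
print(f"VOI voxels: {quantized.n_voxels}")
print(f"mu = {params.mu:.1f}, sigma = {params.sigma:.1f} (intensity units)")
print(f"window = [{params.window[0]:.1f}, {params.window[1]:.1f}] -> levels 1..64")

features = extract_all(lesion)
print(f"\nextracted {len(features)} features; a few of interest:")
for name in ("Mean", "Variance", "Perc.90%", "S(0,0,1)AngScMom", "Z_GLevNonU"):
    print(f"  {name:<20} {features[name]:.4f}")
print(
    "\nMean/Perc.90% sit on the 1..64 level scale; the bright hot-spots of"
    "\nthis malignant-like lesion inflate sigma, squeezing the tissue bulk"
    "\ninto few low levels (low Mean/Variance, high GLevNonU)."
)
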