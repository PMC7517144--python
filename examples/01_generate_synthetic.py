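"""Generate a planted high-dimensional dataset and inspect its structure.

The generator emulates small-sample expression matrices: a handful of
class-informative features (some separable by a single threshold, some only
informative as a rotated pair) hidden among pure noise, with imbalanced
classes.
"""

from ccdfs import SyntheticSpec, generate

spec = SyntheticSpec(n_samples=100, n_features=1000, seed=42)
ds, truth = generate(spec)

print(f"dataset: {ds.n_samples} samples x {ds.n_features} features, "
      f"{ds.n_classes} classes, counts {ds.class_counts.tolist()}")
print(f"threshold-informative features: {truth.threshold_idx.tolist()}")
print(f"jointly-informative pairs:      {truth.jointly_idx.tolist()}")
print(f"planted cut for feature {truth.threshold_idx[0]}: "
      f"{truth.planted_thresholds[str(truth.threshold_idx[0])]}")
# The threshold features' class means sit 5 noise-sd apart, so a supervised
# discretizer should recover a cut near each planted midpoint; everything
# outside the listed indices carries no class signal at all.
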