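"""Harmonize a simulated three-center cohort and verify the center
effect is gone.

Generates a 189-sample, 120-feature table from three centers with
injected per-center location and scale effects, fits standard ComBat,
and compares distributional diagnostics before and after.
"""

import combatkit as ck

ds = ck.generate(ck.SyntheticSpec(seed=7, n_features=120))

pre = ck.diagnose(ds.features, ds.batches, alpha=0.01)
model, harmonized = ck.fit_transform(ds.features, ds.batches,
                                     variant="combat", eb="parametric")
post = ck.diagnose(harmonized, ds.batches, alpha=0.01)

print(f"samples: {ds.n_samples}  features: {ds.features.n_features}  "
      f"centers: {ds.batches.registry}")
print(f"ANOVA-significant feature fraction (alpha=0.01): "
      f"{pre.fraction_significant:.3f} before -> "
      f"{post.fraction_significant:.3f} after")
print(f"aggregate COV: {pre.cov_aggregate:.0f} before -> "
      f"{post.cov_aggregate:.0f} after")
print(f"top-2 PC explained variance before: "
      f"{pre.explained_variance.round(3)}, after: "
      f"{post.explained_variance.round(3)}")
# The significant fraction drops to ~0: no feature differs between
# centers any more.  The COV drop shows the removed scale inflation; the
# PC spectrum flattens once the center axis is gone.
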