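"""Generate a synthetic cohort and verify its effect-size calibration.

The generator plants a PGS → brain → intelligence mediation structure with
known paths: designated surface-area regions and connectome hub nodes carry
the genetic effect.  With the default calibration, adding each PGS to a
covariate-only regression of the intelligence score should raise R² by
~3.3% (EA-like score) and ~4.8% (GI-like score).
"""

import numpy as np

from neuromediate import stats, synthetic

config = synthetic.CohortConfig(
    n_subjects=10_000, seed=1, include_structural=False, include_functional=False
)
cohort, truth = synthetic.generate_cohort(config)

print("designed mediators:")
print(synthetic.truth_summary(truth).to_string(index=False))

p = cohort.phenotypes
cov = p[["age", "sex", "pc1", "pc2", "pc3", "pc4"]].to_numpy(dtype=float)
for pgs, col in (("EA", "pgs_ea"), ("GI", "pgs_gi")):
    d = stats.incremental_r2(p["iq"], cov, p[col])
    print(f"incremental R² of the {pgs}-like score: {d:.4f} "
          f"(target {truth.implied_incremental_r2[pgs]:.3f})")
# at n=10,000 the empirical increments sit within Monte-Carlo error of the
# calibration targets recorded in the ground-truth model
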