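"""Quantify domain shift with MMD replicates and PCA compression.

Squared maximum mean discrepancy with a cubic polynomial kernel compares
feature distributions between acquisition domains; a Mann-Whitney U-test on
replicate estimates asks whether one representation aligns domains better
than another.  The PCA analysis counts components needed to retain 90% of
the feature variance — fewer components means a more compressed space.
"""

import numpy as np

from fairgen import MMDConfig, mann_whitney_u, mmd_replicates, pca_components_for_variance

rng = np.random.default_rng(0)
d = 16

# representation A: domains separated by a mean shift; B: well aligned
feats_a = {0: rng.normal(0, 1, (600, d)), 1: rng.normal(0.6, 1, (600, d))}
feats_b = {0: rng.normal(0, 1, (600, d)), 1: rng.normal(0.05, 1, (600, d))}

cfg = MMDConfig(S=30, n=300, seed=1)
rep_a = mmd_replicates(feats_a, cfg).estimates[(0, 1)]
rep_b = mmd_replicates(feats_b, cfg).estimates[(0, 1)]
print(f"mean squared MMD, representation A: {rep_a.mean():.4f}")
print(f"mean squared MMD, representation B: {rep_b.mean():.4f}")

stat, p, reject = mann_whitney_u(rep_a, rep_b)
print(f"Mann-Whitney U={stat:.0f}, p={p:.2e}, significant={reject}")
print("A significant test says the two representations align domains differently.")

X = rng.normal(size=(800, d)) @ np.diag(np.linspace(2.0, 0.2, d))
k = pca_components_for_variance(X, 0.9)
print(f"components needed for 90% variance: {k} of {d}")
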