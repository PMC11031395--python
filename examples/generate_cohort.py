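"""Generate a toy imaging cohort with planted label, attribute and domain structure.

The diagnostic label is encoded in the radius of a centred blob, a binary
sensitive attribute in the hue of a corner marker, and the acquisition site
in an additive colour cast.  The planted rule is recoverable, so we can
check the Bayes-optimal accuracy directly.
"""

import numpy as np

from fairgen import (
    AttributeSpec,
    CohortConfig,
    default_domain_casts,
    generate_cohort,
    skew_dataset,
)

config = CohortConfig(
    n_examples=1000,
    image_size=16,
    n_labels=2,
    label_prevalence=(0.5, 0.5),
    attributes=(AttributeSpec("sex", (0, 1), ((0.9, 0.1), (0.5, 0.5))),),
    n_domains=3,
    domain_effect=default_domain_casts(3, 0.12),
    spurious_strength=0.9,
    noise_sd=0.1,
    seed=0,
)
cohort = generate_cohort(config)
labels = cohort.labels()
attrs = cohort.attribute_values("sex").astype(int)

print(f"{len(cohort)} examples, label prevalence {np.bincount(labels) / len(cohort)}")
print(f"p(sex=1 | y=0) = {attrs[labels == 0].mean():.3f}  (configured 0.1)")
print(f"p(sex=1 | y=1) = {attrs[labels == 1].mean():.3f}  (configured 0.5)")
acc = np.mean(cohort.planted_rule.predict(cohort.images()) == labels)
print(f"planted-rule oracle accuracy: {acc:.3f} (degrades with noise_sd)")

skewed = skew_dataset(cohort, "sex", cap=50, seed=1)
kept = (skewed.attribute_values("sex").astype(int) == 1).sum()
print(f"after capping the minority subgroup at 50: {kept} sex=1 examples remain")
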