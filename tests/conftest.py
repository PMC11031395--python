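import numpy as np
import pytest

from fairgen import AttributeSpec, CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def binary_cohort_config():
    """Small two-label cohort with a skewed binary attribute and two domains."""
    return CohortConfig(
        n_examples=300,
        image_size=16,
        n_labels=2,
        label_prevalence=(0.6, 0.4),
        attributes=(
            AttributeSpec("sex", (0, 1), ((0.8, 0.2), (0.2, 0.8))),
        ),
        n_domains=2,
        domain_effect=((0.05, -0.02, 0.0), (-0.03, 0.04, 0.01)),
        spurious_strength=0.8,
        noise_sd=0.02,
        seed=7,
    )


@pytest.fixture(scope="session")
def binary_cohort(binary_cohort_config):
    return generate_cohort(binary_cohort_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
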