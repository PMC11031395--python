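"""Fair sampling policy and real/synthetic mixture construction.

The fair joint over (attribute, label) factorises as Uniform(attribute) x
p(label): synthetic images are conditioned on attributes drawn uniformly —
so every subgroup is equally represented — while the diagnostic label keeps
its empirical prevalence.  Training data is then a Bernoulli(alpha) mixture:
with probability alpha an example comes from the real labeled set, otherwise
from the synthetic pool.  A perfect generative model plus alpha = 0 recovers
the fair distribution exactly; the two-Gaussian toy at the bottom of this
module makes that property testable in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, CohortConfig, Example, render_example_image

__all__ = [
    "SamplingPolicy",
    "MixtureConfig",
    "draw_conditioning",
    "build_mixture_stream",
    "fair_risk",
    "oracle_generator",
    "TwoGaussianToy",
]


@dataclass(frozen=True)
class SamplingPolicy:
    """Fair joint p(a, y) = Uniform(attribute values) x p(y)."""

    label_distribution: np.ndarray
    attribute_values: tuple

    def __post_init__(self):
        p = np.asarray(self.label_distribution, dtype=float)
        object.__setattr__(self, "label_distribution", p)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("label_distribution must be a probability vector")

    @classmethod
    def from_cohort(cls, cohort: Cohort, attribute_name: str) -> "SamplingPolicy":
        """Empirical p(y) from the labeled examples; attribute support from config."""
        labeled = cohort.labeled_examples()
        if not labeled:
            raise ValueError("cohort has no labeled examples")
        n_labels = cohort.config.n_labels
        counts = np.bincount([e.label for e in labeled], minlength=n_labels)
        spec = next(
            (a for a in cohort.config.attributes if a.name == attribute_name), None
        )
        if spec is None:
            raise KeyError(f"unknown attribute {attribute_name!r}")
        return cls(counts / counts.sum(), tuple(spec.values))


@dataclass(frozen=True)
class MixtureConfig:
    """alpha = probability an example is drawn from the real labeled set."""

    alpha: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


def draw_conditioning(policy: SamplingPolicy, n: int, seed: int) -> list:
    """n i.i.d. (label, attribute value) pairs, label ~ p(y), attribute uniform.

    Label and attribute are independent by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not policy.attribute_values:
        raise ValueError("attribute value set is empty")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(policy.label_distribution), size=n, p=policy.label_distribution)
    attrs = rng.integers(0, len(policy.attribute_values), size=n)
    return [(int(y), policy.attribute_values[a]) for y, a in zip(labels, attrs)]


def build_mixture_stream(
    real: Cohort, synthetic_pool: Cohort, mix: MixtureConfig, n: int, seed: int
) -> list:
    """n training examples: Bernoulli(alpha) choose real, else synthetic.

    Items are drawn uniformly with replacement within the chosen pool.
    """
    rng = np.random.default_rng(seed)
    real_ex = real.labeled_examples() if real is not None else []
    synth_ex = synthetic_pool.labeled_examples() if synthetic_pool is not None else []
    if mix.alpha > 0 and not real_ex:
        raise ValueError("real pool is empty but alpha > 0")
    if mix.alpha < 1 and not synth_ex:
        raise ValueError("synthetic pool is empty but alpha < 1")
    take_real = rng.random(n) < mix.alpha
    out = []
    for r in take_real:
        pool = real_ex if r else synth_ex
        out.append(pool[int(rng.integers(0, len(pool)))])
    return out


def fair_risk(predict, fair_test: Cohort, loss) -> float:
    """Mean loss of a predictor over a fair-distribution test set.

    ``predict``: images -> predictions (batched); ``loss``: (prediction,
    example) -> real.  This is the objective the fair policy targets.
    """
    examples = fair_test.labeled_examples()
    if not examples:
        raise ValueError("empty fair test set")
    preds = predict(np.stack([e.image for e in examples]))
    return float(np.mean([loss(p, e) for p, e in zip(preds, examples)]))


def oracle_generator(cohort_config: CohortConfig):
    """A perfect generative model: samples from the true conditional renderer.

    Returns ``sampler(label, attribute_values_by_name, seed, domain=None)``
    -> Example.  Bypasses any learned model; used to test that a perfect
    generator plus the fair policy recovers fair-distribution performance.
    """

    def sampler(label, attributes=None, seed=0, domain=None) -> Example:
        rng = np.random.default_rng(seed)
        attributes = dict(attributes or {})
        attr_indices = []
        attrs = {}
        for spec in cohort_config.attributes:
            if spec.name in attributes:
                vi = list(spec.values).index(attributes[spec.name])
            else:
                vi = int(rng.integers(0, len(spec.values)))
            attr_indices.append(vi)
            attrs[spec.name] = spec.values[vi]
        if domain is None:
            domain = int(rng.integers(0, cohort_config.n_domains))
        img = render_example_image(cohort_config, int(label), attr_indices, domain, rng)
        return Example(
            image=img,
            label=int(label),
            soft_label=None,
            attributes=attrs,
            domain=domain,
            labeled=True,
            synthetic=True,
            example_id=f"oracle-{seed}",
        )

    return sampler


@dataclass(frozen=True)
class TwoGaussianToy:
    """Closed-form testbed for the perfect-generative-model property.

    Features are 2-D: x | y, a ~ N(mu_y + delta_a, sigma^2 I) with the class
    axis (mu) orthogonal to the attribute axis (delta), so the attribute is
    label-irrelevant under the fair distribution.  A skewed training set
    couples attribute to label (p(a=1|y=1) high), making the attribute axis
    spuriously predictive; the fair distribution draws the attribute uniformly
    and independently of the label.
    """

    class_sep: float = 2.0  # distance between class means along axis 0
    attr_sep: float = 3.0  # distance between attribute means along axis 1
    sigma: float = 1.0
    p_y1: float = 0.5

    def _means(self, y, a):
        mx = np.where(y == 1, self.class_sep / 2, -self.class_sep / 2)
        my = np.where(a == 1, self.attr_sep / 2, -self.attr_sep / 2)
        return np.stack([mx, my], axis=1)

    def sample(self, n: int, p_a1_given_y, rng: np.random.Generator):
        """(X, y, a) with y ~ Bernoulli(p_y1), a | y ~ Bernoulli(p_a1_given_y[y])."""
        p_a1_given_y = np.asarray(p_a1_given_y, dtype=float)
        y = (rng.random(n) < self.p_y1).astype(int)
        a = (rng.random(n) < p_a1_given_y[y]).astype(int)
        X = self._means(y, a) + self.sigma * rng.standard_normal((n, 2))
        return X, y, a

    def sample_fair(self, n: int, rng: np.random.Generator):
        """Fair draw: attribute uniform, independent of the label."""
        return self.sample(n, (0.5, 0.5), rng)

    def sample_fair_mixture(
        self, n: int, alpha: float, skew, rng: np.random.Generator
    ):
        """Eq.-style mixture with a perfect generator for the synthetic branch.

        With probability alpha a point comes from the skewed training
        distribution, otherwise (label, attribute) are drawn from the fair
        policy and x from the true conditional — the oracle generator.
        """
        take_real = rng.random(n) < alpha
        n_real = int(take_real.sum())
        Xr, yr, ar = self.sample(n_real, skew, rng)
        Xs, ys, as_ = self.sample_fair(n - n_real, rng)
        X = np.concatenate([Xr, Xs])
        y = np.concatenate([yr, ys])
        a = np.concatenate([ar, as_])
        perm = rng.permutation(n)
        return X[perm], y[perm], a[perm]

    def bayes_accuracy(self) -> float:
        """Fair-distribution accuracy of the Bayes rule (threshold on axis 0)."""
        from scipy.stats import norm

        return float(norm.cdf(self.class_sep / (2 * self.sigma)))
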