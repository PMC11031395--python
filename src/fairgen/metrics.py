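"""Performance and fairness metrics for subgroup evaluation.

Best-worst subgroup gaps, AUC parity, high-risk sensitivity, top-k and
balanced accuracy, and a Beta-posterior spread that summarises how uncertain
the group-vs-outgroup performance difference is at small sample sizes.
AUC uses the rank-statistic (Mann-Whitney) formulation with ties counted 1/2,
which is exactly the probability that a random positive outscores a random
negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "UndefinedMetricError",
    "SubgroupReport",
    "auc",
    "auc_gap",
    "gap_best_worst",
    "high_risk_sensitivity",
    "balanced_accuracy",
    "topk_accuracy",
    "beta_posterior_spread",
    "subgroup_report",
]


class UndefinedMetricError(ValueError):
    """A metric whose value is mathematically undefined on this input."""


@dataclass(frozen=True)
class SubgroupReport:
    """Per-group metric values with the best-worst gap."""

    metric: str
    per_group: dict
    n_per_group: dict

    @property
    def gap(self) -> float:
        return gap_best_worst(self.per_group)


def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank statistic; ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_gap(scores, labels, attribute) -> float:
    """AUC parity: |AUC(group 1) - AUC(group 0)| for a binary attribute."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    attribute = np.asarray(attribute)
    values = np.unique(attribute)
    if len(values) != 2:
        raise ValueError(f"attribute must be binary, got values {values}")
    aucs = []
    for v in values:
        m = attribute == v
        try:
            aucs.append(auc(scores[m], labels[m]))
        except UndefinedMetricError as e:
            raise UndefinedMetricError(f"subgroup {v!r}: {e}") from None
    return abs(aucs[1] - aucs[0])


def gap_best_worst(per_group: dict) -> float:
    """max - min over a per-group metric map."""
    if len(per_group) < 2:
        raise ValueError("need at least two groups for a gap")
    vals = list(per_group.values())
    return float(max(vals) - min(vals))


def high_risk_sensitivity(predictions, reference, high_risk_set) -> float:
    """True-positive rate pooled over the high-risk conditions (micro average).

    Fraction of examples whose reference label is high-risk and whose top-1
    prediction equals the reference.
    """
    if not high_risk_set:
        raise ValueError("high_risk_set must be non-empty")
    predictions = np.asarray(predictions)
    reference = np.asarray(reference)
    mask = np.isin(reference, list(high_risk_set))
    if not mask.any():
        raise UndefinedMetricError("no high-risk examples present")
    return float(np.mean(predictions[mask] == reference[mask]))


def balanced_accuracy(predictions, reference) -> float:
    """Unweighted mean of per-class recalls over classes present in reference.

    Classes absent from the reference are excluded from the mean and logged.
    """
    predictions = np.asarray(predictions)
    reference = np.asarray(reference)
    recalls = []
    for c in np.unique(reference):
        m = reference == c
        recalls.append(float(np.mean(predictions[m] == c)))
    n_classes = len(np.unique(np.concatenate([predictions, reference])))
    if len(recalls) < n_classes:
        logger.info(
            "balanced_accuracy: %d class(es) absent from reference, excluded",
            n_classes - len(recalls),
        )
    return float(np.mean(recalls))


def topk_accuracy(probabilities, reference, k: int) -> float:
    """Fraction of examples whose reference label is among the k top scores."""
    probs = np.asarray(probabilities, dtype=float)
    reference = np.asarray(reference).astype(int)
    if k > probs.shape[1]:
        raise ValueError("k exceeds the number of classes")
    topk = np.argsort(-probs, axis=1, kind="stable")[:, :k]
    return float(np.mean([r in row for r, row in zip(reference, topk)]))


def beta_posterior_spread(
    group_correct, outgroup_correct, n_samples: int = 100_000, seed: int = 0
) -> float:
    """Spread (sd) of the sampled posterior performance difference.

    Each side gets an independent Beta(1 + successes, 1 + failures) posterior
    under a uniform Beta(1, 1) prior; ``n_samples`` paired differences are
    drawn and their standard deviation returned.  Small samples give wide
    posteriors, so the spread reads as uncertainty in the fairness gap.
    """
    rng = np.random.default_rng(seed)
    draws = []
    for successes, trials in (group_correct, outgroup_correct):
        if trials < 1:
            raise ValueError("trials must be >= 1 on both sides")
        if not (0 <= successes <= trials):
            raise ValueError("successes must lie in [0, trials]")
        draws.append(rng.beta(1 + successes, 1 + trials - successes, size=n_samples))
    return float(np.std(draws[0] - draws[1]))


def subgroup_report(
    metric_name: str, metric_fn, groups, **metric_inputs
) -> SubgroupReport:
    """Evaluate a metric per subgroup and report values, sizes and the gap.

    ``groups`` is an array of group ids aligned with every array in
    ``metric_inputs``; ``metric_fn`` receives the masked arrays as keyword
    arguments.
    """
    groups = np.asarray(groups)
    per_group, n_per_group = {}, {}
    for g in np.unique(groups):
        m = groups == g
        per_group[g] = float(
            metric_fn(**{k: np.asarray(v)[m] for k, v in metric_inputs.items()})
        )
        n_per_group[g] = int(m.sum())
    return SubgroupReport(metric=metric_name, per_group=per_group, n_per_group=n_per_group)
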