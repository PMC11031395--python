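"""Multi-rater soft-label aggregation and high-confidence filtering.

Dermatology-style ground truth: each rater supplies up to three (condition,
confidence) tuples with confidence in 1-5.  Within one rater the conditions
are ranked by descending confidence (rank 1 = most confident), each condition
receives weight 1/rank, weights are summed across raters and normalised to a
probability vector over the full condition set.  Confidence values affect
only the ranking, never the weight magnitude.

Worked example (two raters over conditions {A, B, C, D}):
R1 = [(A,4),(B,3)] gives A weight 1, B weight 1/2; R2 = [(A,3),(D,4)] gives
D weight 1, A weight 1/2; summed {A: 1.5, B: 0.5, D: 1} and normalised:
{A: 0.5, B: 0.167, C: 0, D: 0.333}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RaterAssessment",
    "SoftLabel",
    "aggregate_soft_labels",
    "filter_high_confidence",
    "read_assessments_csv",
]


@dataclass(frozen=True)
class RaterAssessment:
    """One rater's ordered list of 1-3 (condition, confidence 1-5) entries."""

    entries: tuple

    def __post_init__(self):
        entries = tuple((c, int(conf)) for c, conf in self.entries)
        object.__setattr__(self, "entries", entries)
        if not (1 <= len(entries) <= 3):
            raise ValueError("an assessment carries between 1 and 3 entries")
        conds = [c for c, _ in entries]
        if len(set(conds)) != len(conds):
            raise ValueError("conditions within one assessment must be distinct")
        for _, conf in entries:
            if not (1 <= conf <= 5):
                raise ValueError("confidence must lie in 1..5")


@dataclass(frozen=True)
class SoftLabel:
    """Probability vector over an ordered condition set."""

    weights: np.ndarray
    conditions: tuple

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("soft label must be non-negative and sum to 1")

    def __getitem__(self, condition):
        return float(self.weights[self.conditions.index(condition)])


def aggregate_soft_labels(
    assessments, conditions, tie_break: str = "list_order"
) -> SoftLabel:
    """Inverse-rank aggregation of rater assessments into one soft label.

    Per rater, entries are ranked by descending confidence and weighted by
    1/rank; weights are summed across raters and normalised to 1.  Conditions
    never mentioned get exactly 0.  Confidence ties within one rater are
    broken by list order (``tie_break="list_order"``, earlier entry wins) or
    shared via average ranks (``tie_break="average"``).
    """
    conditions = tuple(conditions)
    if not assessments:
        raise ValueError("at least one assessment is required")
    if tie_break not in ("list_order", "average"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    index = {c: i for i, c in enumerate(conditions)}
    weights = np.zeros(len(conditions))
    for a in assessments:
        for c, _ in a.entries:
            if c not in index:
                raise KeyError(f"unknown condition {c!r}")
        confs = np.array([conf for _, conf in a.entries], dtype=float)
        # stable argsort on descending confidence = list-order tie-break
        order = np.argsort(-confs, kind="stable")
        ranks = np.empty(len(confs))
        ranks[order] = np.arange(1, len(confs) + 1)
        if tie_break == "average":
            for v in np.unique(confs):
                tied = confs == v
                ranks[tied] = ranks[tied].mean()
        for (c, _), r in zip(a.entries, ranks):
            weights[index[c]] += 1.0 / r
    return SoftLabel(weights / weights.sum(), conditions)


def filter_high_confidence(cohort, condition, threshold: float):
    """Keep only examples whose soft-label mass on ``condition`` is >= t.

    ``condition`` is an index into the soft-label vector.  Selects the
    "canonical" cases raters agreed on with high confidence.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    soft_labeled = [e for e in cohort.examples if e.soft_label is not None]
    if not soft_labeled:
        raise ValueError("cohort carries no soft labels")
    keep = [
        i
        for i, e in enumerate(cohort.examples)
        if e.soft_label is not None and e.soft_label[condition] >= threshold
    ]
    return cohort.subset(keep)


def read_assessments_csv(path) -> dict:
    """Read rater assessments grouped per case.

    Expected columns: ``rater_id``, ``case_id``, ``condition``, ``confidence``
    and ``rank_position`` (the entry's position in the rater's list, used to
    preserve list order for tie-breaking).  Returns {case_id: [RaterAssessment]}.
    """
    df = pd.read_csv(path)
    required = {"rater_id", "case_id", "condition", "confidence", "rank_position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assessment CSV missing columns: {sorted(missing)}")
    out: dict = {}
    for (case, _rater), grp in df.groupby(["case_id", "rater_id"], sort=True):
        grp = grp.sort_values("rank_position")
        out.setdefault(case, []).append(
            RaterAssessment(tuple(zip(grp["condition"], grp["confidence"])))
        )
    return out
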