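"""Aggregate multi-rater dermatology-style assessments into soft labels.

Each rater lists up to three (condition, confidence) tuples; conditions are
ranked per rater by descending confidence, weighted 1/rank, summed across
raters and normalised.  High-confidence "canonical" cases are then the
examples whose mass on one condition clears a strict threshold.
"""

from fairgen import RaterAssessment, aggregate_soft_labels

conditions = ("A", "B", "C", "D")
r1 = RaterAssessment((("A", 4), ("B", 3)))
r2 = RaterAssessment((("A", 3), ("D", 4)))

soft = aggregate_soft_labels([r1, r2], conditions)
print("conditions :", conditions)
print("soft label :", [round(w, 3) for w in soft.weights])
print(
    "Mass 0.5 on A: both raters mention A (ranks 1 and 2 -> weights 1 and 1/2);"
    " D gets 1/3, B 1/6, C was never mentioned so it gets exactly 0."
)
print("A >= 0.9 ?", soft["A"] >= 0.9, "-> not a canonical case at t=0.9")
print("A >= 0.5 ?", soft["A"] >= 0.5, "-> passes the relaxed t=0.5 filter")
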