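"""The perfect-generative-model property on a closed-form two-Gaussian toy.

Features are 2-D with the class signal on one axis and a label-irrelevant
attribute signal on the other.  A skewed training set (attribute strongly
correlated with the label) makes the attribute axis spuriously predictive;
a classifier trained on it underperforms on the fair distribution and shows
a large subgroup gap.  Replacing the training data with draws from the fair
mixture (alpha = 0, perfect generator) recovers near-Bayes fair accuracy.
"""

import numpy as np
from sklearn.linear_model import LogisticRegression

from fairgen import TwoGaussianToy, gap_best_worst

toy = TwoGaussianToy(class_sep=2.0, attr_sep=3.0, sigma=1.0)
rng = np.random.default_rng(0)
skew = (0.3, 0.95)  # p(a=1 | y): asymmetric, so one subgroup bears the errors

Xf, yf, af = toy.sample_fair(4000, rng)


def fit_and_eval(X, y):
    clf = LogisticRegression().fit(X, y)
    pred = clf.predict(Xf)
    acc = np.mean(pred == yf)
    per_group = {g: np.mean(pred[af == g] == yf[af == g]) for g in (0, 1)}
    return acc, gap_best_worst(per_group)


Xs, ys, _ = toy.sample(2000, skew, rng)
acc_skew, gap_skew = fit_and_eval(Xs, ys)

Xm, ym, _ = toy.sample_fair_mixture(2000, alpha=0.0, skew=skew, rng=rng)
acc_fair, gap_fair = fit_and_eval(Xm, ym)

print(f"Bayes-optimal fair accuracy : {toy.bayes_accuracy():.3f}")
print(f"skewed training set         : acc={acc_skew:.3f}  subgroup gap={gap_skew:.3f}")
print(f"fair mixture (alpha=0)      : acc={acc_fair:.3f}  subgroup gap={gap_fair:.3f}")
print(
    "The fair-mixture classifier approaches the Bayes bound and closes the"
    " subgroup gap; the skewed classifier trades fair accuracy for the"
    " spurious attribute shortcut."
)
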