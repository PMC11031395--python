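"""Augmentation policies, oversampling, focal loss and classifier training."""

import numpy as np
import pytest

from fairgen import (
    ClassifierConfig,
    focal_loss,
    heuristic_augment,
    oversample_even,
    predict_topk,
    train_classifier,
)
from fairgen.classify import _crop_resize
from fairgen.cohort import Cohort, Example


def _examples(n, n_labels=2, dim=8, seed=0, separable=True):
    """Linearly separable toy: label written into the first pixel block."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        y = int(rng.integers(n_labels))
        img = rng.random((dim, dim, 3)).astype(np.float32) * 0.2
        if separable:
            img[:2, :2, :] = y / max(n_labels - 1, 1)
        out.append(
            Example(
                image=img,
                label=y,
                soft_label=None,
                attributes={"g": int(rng.integers(2))},
                domain=0,
                labeled=True,
                example_id=f"{i}",
            )
        )
    return out


class TestHeuristicAugment:
    @pytest.mark.parametrize("policy", ["histopathology", "radiology", "dermatology", "randaugment_lite"])
    def test_output_in_unit_range_and_shape_preserved(self, policy, rng):
        img = rng.random((16, 16, 3))
        out = heuristic_augment(img, policy, seed=0)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_identity_policy(self, rng):
        img = rng.random((16, 16, 3))
        np.testing.assert_array_equal(heuristic_augment(img, "none", 0), img)

    def test_crop_fraction_at_native_scale(self):
        """Radiology crops 202/224 of each side before resizing back."""
        img = np.zeros((224, 224, 3))
        rng = np.random.default_rng(0)
        out = _crop_resize(img, 202.0 / 224.0, rng)
        assert out.shape == (224, 224, 3)
        # the crop window side is exactly round(202/224 * 224) = 202
        assert int(round(202.0 / 224.0 * 224)) == 202

    def test_luminance_shift_bounded(self, rng):
        """Mean-brightness change of the radiology policy stays within the
        printed +/-0.1 shift (plus contrast scaling of a mid-gray image)."""
        img = np.full((16, 16, 3), 0.5)
        shifts = []
        for s in range(1000):
            out = heuristic_augment(img, "radiology", seed=s)
            shifts.append(out.mean() - img.mean())
        # out = (0.5 + delta) * c with |delta| <= 0.1, c in (0.8, 1.2):
        # |mean shift| <= 0.5 * 0.2 + 0.1 * 1.2 = 0.22
        assert max(np.abs(shifts)) <= 0.22 + 1e-9

    def test_unknown_policy_rejected(self, rng):
        with pytest.raises(KeyError):
            heuristic_augment(rng.random((8, 8, 3)), "nope", 0)

    def test_seeded_determinism(self, rng):
        img = rng.random((16, 16, 3))
        a = heuristic_augment(img, "dermatology", seed=5)
        b = heuristic_augment(img, "dermatology", seed=5)
        np.testing.assert_array_equal(a, b)


class TestOversample:
    def _cohort_with_counts(self, counts):
        rng = np.random.default_rng(0)
        examples = []
        i = 0
        for value, count in counts.items():
            for _ in range(count):
                examples.append(
                    Example(
                        image=rng.random((4, 4, 3)).astype(np.float32),
                        label=0,
                        soft_label=None,
                        attributes={"g": value},
                        domain=0,
                        labeled=True,
                        example_id=f"{i}",
                    )
                )
                i += 1
        return Cohort(examples, None, None)

    def test_already_even_unchanged(self):
        cohort = self._cohort_with_counts({"a": 50, "b": 50})
        out = oversample_even(cohort, "g")
        assert len(out.examples) == 100

    def test_two_group_counts(self):
        out = oversample_even(self._cohort_with_counts({"a": 100, "b": 25}), "g")
        vals = [e.attributes["g"] for e in out.examples]
        assert vals.count("a") == 100 and vals.count("b") == 100

    def test_three_group_counts(self):
        out = oversample_even(self._cohort_with_counts({"a": 50, "b": 20, "c": 10}), "g")
        vals = [e.attributes["g"] for e in out.examples]
        assert vals.count("a") == vals.count("b") == vals.count("c") == 50


class TestFocalLoss:
    def test_gamma_zero_is_cross_entropy(self, rng):
        probs = rng.dirichlet(np.ones(4))
        for t in range(4):
            assert focal_loss(probs, t, 0.0) == pytest.approx(
                -np.log(probs[t]), abs=1e-12
            )

    def test_confident_correct_prediction_zero(self):
        assert focal_loss(np.array([0.0, 1.0]), 1, 5.0) == 0.0

    def test_hand_evaluated_value(self):
        # p_t = 0.5, gamma = 2 -> 0.25 * log 2
        assert focal_loss(np.array([0.5, 0.5]), 0, 2.0) == pytest.approx(
            0.25 * np.log(2), abs=1e-12
        )

    def test_monotone_decreasing_in_pt(self):
        grid = np.linspace(0.05, 0.95, 19)
        vals = [focal_loss(np.array([p, 1 - p]), 0, 2.0) for p in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_per_condition_binary_sums_heads(self):
        probs = np.array([0.9, 0.2])
        target = np.array([1.0, 0.0])
        expected = focal_loss(np.array([0.9, 0.1]), 0, 2.0) + focal_loss(
            np.array([0.2, 0.8]), 1, 2.0
        )
        assert focal_loss(probs, target, 2.0) == pytest.approx(expected, abs=1e-12)

    def test_zero_probability_clamped(self):
        assert np.isfinite(focal_loss(np.array([0.0, 1.0]), 0, 2.0))


class TestTrainClassifier:
    def test_separable_toy_reaches_high_train_accuracy(self):
        examples = _examples(200, seed=1)
        clf = train_classifier(
            examples, ClassifierConfig(n_labels=2, steps=500, seed=0)
        )
        images = np.stack([e.image for e in examples])
        labels = np.array([e.label for e in examples])
        assert np.mean(clf.predict(images) == labels) >= 0.95

    def test_same_seed_identical_training(self):
        examples = _examples(50, seed=2)
        cfg = ClassifierConfig(n_labels=2, steps=100, seed=3)
        a = train_classifier(examples, cfg)
        b = train_classifier(examples, cfg)
        assert a.training_log == b.training_log
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa["W"], pb["W"])

    def test_distinct_seeds_distinct_parameters(self):
        examples = _examples(50, seed=2)
        a = train_classifier(examples, ClassifierConfig(n_labels=2, steps=50, seed=0))
        b = train_classifier(examples, ClassifierConfig(n_labels=2, steps=50, seed=1))
        assert not np.allclose(a.params[0]["W"], b.params[0]["W"])
        assert [w["W"].shape for w in a.params] == [w["W"].shape for w in b.params]

    def test_per_condition_binary_head_contract(self):
        examples = _examples(60, n_labels=5, seed=4)
        clf = train_classifier(
            examples,
            ClassifierConfig(n_labels=5, head_mode="per_condition_binary", steps=50, seed=0),
        )
        probs = clf.predict_proba(np.stack([e.image for e in examples[:8]]))
        assert probs.shape == (8, 5)
        assert np.all((probs >= 0) & (probs <= 1))
        assert not np.allclose(probs.sum(axis=1), 1.0)

    def test_multiclass_probabilities_sum_to_one(self):
        examples = _examples(30, n_labels=3, seed=5)
        clf = train_classifier(examples, ClassifierConfig(n_labels=3, steps=30, seed=0))
        probs = clf.predict_proba(np.stack([e.image for e in examples[:5]]))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_soft_labels_train(self):
        examples = _examples(40, seed=6)
        soft = [
            Example(
                image=e.image,
                label=None,
                soft_label=np.array([0.8, 0.2]) if e.label == 0 else np.array([0.2, 0.8]),
                attributes=e.attributes,
                domain=0,
                labeled=True,
                example_id=e.example_id,
            )
            for e in examples
        ]
        clf = train_classifier(soft, ClassifierConfig(n_labels=2, steps=100, seed=0))
        assert np.isfinite(clf.training_log[-1][1])

    def test_focal_training_runs(self):
        examples = _examples(40, seed=7)
        clf = train_classifier(
            examples, ClassifierConfig(n_labels=2, loss="focal", gamma=2.0, steps=50, seed=0)
        )
        assert np.isfinite(clf.training_log[-1][1])

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            train_classifier([], ClassifierConfig(n_labels=2))

    def test_penultimate_features_shape(self):
        examples = _examples(30, seed=8)
        clf = train_classifier(
            examples, ClassifierConfig(n_labels=2, hidden=(32, 12), steps=20, seed=0)
        )
        feats = clf.penultimate_features(np.stack([e.image for e in examples[:6]]))
        assert feats.shape == (6, 12)

    def test_augmentation_does_not_change_labels(self):
        examples = _examples(30, seed=9)
        clf = train_classifier(
            examples,
            ClassifierConfig(
                n_labels=2, augmentation_policy="histopathology", steps=30, seed=0
            ),
        )
        assert all(e.label in (0, 1) for e in examples)
        assert np.isfinite(clf.training_log[-1][1])


class TestPredictTopk:
    def _clf(self):
        return train_classifier(
            _examples(40, n_labels=4, seed=10),
            ClassifierConfig(n_labels=4, steps=30, seed=0),
        )

    def test_full_k_is_permutation(self, rng):
        clf = self._clf()
        out = predict_topk(clf, rng.random((8, 8, 3)), 4)
        assert sorted(out) == [0, 1, 2, 3]

    def test_k1_equals_argmax(self, rng):
        clf = self._clf()
        img = rng.random((8, 8, 3))
        assert predict_topk(clf, img, 1) == [int(clf.predict(img)[0])]

    def test_matches_sort_oracle(self, rng):
        clf = self._clf()
        img = rng.random((8, 8, 3))
        probs = clf.predict_proba(img)[0]
        oracle = sorted(range(4), key=lambda i: (-probs[i], i))
        assert predict_topk(clf, img, 3) == oracle[:3]
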