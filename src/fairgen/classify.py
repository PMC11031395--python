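"""Downstream diagnostic classifiers and the baseline training arms.

Empirical risk minimisation over a (possibly mixed real/synthetic) training
stream, with the comparison arms used throughout the experiments: per-modality
heuristic augmentation policies, attribute-even oversampling, and focal loss.
Heads are either multiclass softmax or independent per-condition sigmoid
heads (radiology-style multilabel).  The backbone is a small fully-connected
net; its last hidden activation is exposed as the penultimate feature map
used by the shift diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy import ndimage

from ._nn import Adam, init_mlp, mlp_backward, mlp_forward
from .cohort import Cohort, Example

__all__ = [
    "ClassifierConfig",
    "TrainedClassifier",
    "heuristic_augment",
    "oversample_even",
    "focal_loss",
    "train_classifier",
    "predict_topk",
    "AUGMENT_POLICIES",
]

_EPS = 1e-7  # probability clamp inside focal/cross-entropy gradients


# ---------------------------------------------------------------------------
# heuristic augmentations
# ---------------------------------------------------------------------------

def _brightness(img, delta):
    return img + delta


def _contrast(img, factor):
    # pixel values multiplied by the factor and clipped afterwards
    return img * factor


def _saturation(img, factor):
    gray = img.mean(axis=2, keepdims=True)
    return gray + factor * (img - gray)


def _hue(img, delta):
    hsv = rgb_to_hsv(np.clip(img, 0.0, 1.0))
    hsv[..., 0] = (hsv[..., 0] + delta) % 1.0
    return hsv_to_rgb(hsv)


def _rotate(img, degrees):
    return ndimage.rotate(
        img, degrees, axes=(1, 0), reshape=False, order=1, mode="nearest"
    )


def _blur(img, sigma):
    return ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0.0))


def _crop_resize(img, frac, rng):
    size = img.shape[0]
    side = max(1, int(round(frac * size)))
    r0 = int(rng.integers(0, size - side + 1))
    c0 = int(rng.integers(0, size - side + 1))
    crop = img[r0 : r0 + side, c0 : c0 + side]
    factor = size / side
    return np.stack(
        [ndimage.zoom(crop[..., c], factor, order=1, grid_mode=True, mode="nearest")
         for c in range(img.shape[2])],
        axis=2,
    )


def _histopathology(img, rng):
    # colour jitter emulating stain variation: brightness, contrast,
    # saturation and hue
    img = _brightness(img, rng.uniform(-0.1, 0.1))
    img = _contrast(img, rng.uniform(0.8, 1.2))
    img = _saturation(img, rng.uniform(0.8, 1.2))
    img = _hue(img, rng.uniform(-0.02, 0.02))
    return img


def _radiology(img, rng):
    if rng.random() < 0.5:
        img = img[:, ::-1]
    img = _crop_resize(img, 202.0 / 224.0, rng)  # crop fraction kept at any size
    img = _rotate(img, rng.uniform(-15.0, 15.0))
    img = _brightness(img, rng.uniform(-0.1, 0.1))  # luminance shift
    img = _contrast(img, rng.uniform(0.8, 1.2))
    return img


_DERM_BLUR_SIGMAS = (0.001, 0.01, 0.1, 1.0, 3.0, 5.0, 7.0)


def _dermatology(img, rng):
    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1, :]
    img = _brightness(img, rng.uniform(-0.1, 0.1))
    img = _saturation(img, rng.uniform(0.8, 1.2))
    img = _hue(img, rng.uniform(-0.02, 0.02))
    img = _contrast(img, rng.uniform(0.8, 1.2))
    img = _rotate(img, rng.uniform(-150.0, 150.0))
    # blur sigmas are stated at 224-pixel scale; rescale to the toy resolution
    sigma = _DERM_BLUR_SIGMAS[int(rng.integers(0, len(_DERM_BLUR_SIGMAS)))]
    img = _blur(img, sigma * img.shape[0] / 224.0)
    return img


def _randaugment_lite(img, rng):
    """Reduced random-op policy: 2 ops per image from the jitter set.

    A stand-in for a learned augmentation-policy search space, not a
    reimplementation of one.
    """
    ops = [
        lambda im: _brightness(im, rng.uniform(-0.15, 0.15)),
        lambda im: _contrast(im, rng.uniform(0.7, 1.3)),
        lambda im: _saturation(im, rng.uniform(0.7, 1.3)),
        lambda im: _hue(im, rng.uniform(-0.05, 0.05)),
        lambda im: _rotate(im, rng.uniform(-30.0, 30.0)),
        lambda im: _blur(im, rng.uniform(0.0, 1.0)),
    ]
    for i in rng.choice(len(ops), size=2, replace=False):
        img = ops[i](img)
    return img


AUGMENT_POLICIES = {
    "none": lambda img, rng: img,
    "histopathology": _histopathology,
    "radiology": _radiology,
    "dermatology": _dermatology,
    "randaugment_lite": _randaugment_lite,
}


def heuristic_augment(image: np.ndarray, policy: str, seed) -> np.ndarray:
    """One seeded draw of a named per-modality augmentation chain.

    ``image`` is H x W x 3 in [0, 1]; output is clipped back to [0, 1].
    ``seed`` may be an integer or a Generator.
    """
    if policy not in AUGMENT_POLICIES:
        raise KeyError(f"unknown augmentation policy {policy!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = AUGMENT_POLICIES[policy](np.asarray(image, dtype=float), rng)
    return np.clip(out, 0.0, 1.0)


def oversample_even(cohort: Cohort, attribute_name: str, seed: int = 0) -> Cohort:
    """Duplicate labeled examples so every attribute value reaches the majority count.

    Upsampling with replacement, seeded; unlabeled examples pass through.
    """
    rng = np.random.default_rng(seed)
    by_value: dict = {}
    indices = []
    for i, e in enumerate(cohort.examples):
        if not e.labeled:
            indices.append(i)
            continue
        if attribute_name not in e.attributes:
            raise KeyError(f"unknown attribute {attribute_name!r}")
        by_value.setdefault(e.attributes[attribute_name], []).append(i)
    if not by_value:
        raise ValueError("cohort has no labeled examples")
    target = max(len(v) for v in by_value.values())
    for v in sorted(by_value, key=str):
        idx = by_value[v]
        indices.extend(idx)
        deficit = target - len(idx)
        if deficit > 0:
            indices.extend(rng.choice(idx, size=deficit, replace=True).tolist())
    return cohort.subset(sorted(indices))


def focal_loss(probs, target, gamma: float) -> float:
    """Focal loss -(1 - p_t)^gamma log p_t, with p_t clamped at 1e-12.

    ``target`` an int selects the target-class probability from a multiclass
    vector; a binary vector of per-condition targets applies the loss per
    sigmoid head and sums.  gamma = 0 reduces exactly to cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    probs = np.asarray(probs, dtype=float)
    if np.isscalar(target) or np.ndim(target) == 0:
        pt = np.clip(probs[int(target)], 1e-12, 1.0)
        return float(-((1.0 - pt) ** gamma) * np.log(pt))
    target = np.asarray(target, dtype=float)
    pt = np.clip(target * probs + (1 - target) * (1 - probs), 1e-12, 1.0)
    return float(np.sum(-((1.0 - pt) ** gamma) * np.log(pt)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    n_labels: int
    head_mode: str = "multiclass"  # or "per_condition_binary"
    loss: str = "cross_entropy"  # or "focal"
    gamma: float = 2.0
    augmentation_policy: str | None = None
    steps: int = 500
    batch_size: int = 32
    learning_rate: float = 1e-3
    hidden: tuple = (128, 64)
    seed: int = 0

    def __post_init__(self):
        if self.head_mode not in ("multiclass", "per_condition_binary"):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.gamma < 0 or self.steps < 1 or self.batch_size < 1:
            raise ValueError("gamma >= 0 and steps, batch_size >= 1 required")


@dataclass
class TrainedClassifier:
    params: list
    config: ClassifierConfig
    image_shape: tuple
    training_log: list = field(default_factory=list)

    def _flat(self, images) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[None]
        return images.reshape(len(images), -1)

    def logits(self, images) -> np.ndarray:
        return mlp_forward(self.params, self._flat(images))

    def predict_proba(self, images) -> np.ndarray:
        """Class probabilities: softmax (multiclass) or per-head sigmoid."""
        z = self.logits(images)
        if self.config.head_mode == "multiclass":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            return e / e.sum(axis=1, keepdims=True)
        return 1.0 / (1.0 + np.exp(-z))

    def penultimate_features(self, images) -> np.ndarray:
        """Activation of the last hidden layer — the shift-diagnostics space."""
        _, cache = mlp_forward(self.params, self._flat(images), return_cache=True)
        return cache["features"]

    def predict(self, images) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=1)


def _target_matrix(examples, n_labels: int) -> np.ndarray:
    t = np.zeros((len(examples), n_labels))
    for i, e in enumerate(examples):
        if e.soft_label is not None:
            t[i] = np.asarray(e.soft_label, dtype=float)
        elif e.label is not None:
            t[i, int(e.label)] = 1.0
        else:
            raise ValueError("training stream yielded an unlabeled example")
    return t


def _dlogits(z, targets, config: ClassifierConfig) -> float | tuple:
    """(loss value, gradient of mean loss wrt logits) for one batch."""
    B = len(z)
    if config.head_mode == "multiclass":
        zs = z - z.max(axis=1, keepdims=True)
        e = np.exp(zs)
        p = e / e.sum(axis=1, keepdims=True)
        if config.loss == "cross_entropy":
            pc = np.clip(p, _EPS, 1.0)
            loss = -np.mean(np.sum(targets * np.log(pc), axis=1))
            return loss, (p - targets) / B
        # focal on the hard target (argmax of a soft target)
        tidx = targets.argmax(axis=1)
        pt = np.clip(p[np.arange(B), tidx], _EPS, 1 - _EPS)
        g = config.gamma
        loss = float(np.mean(-((1 - pt) ** g) * np.log(pt)))
        dl_dpt = g * (1 - pt) ** (g - 1) * np.log(pt) - (1 - pt) ** g / pt
        onehot = np.zeros_like(p)
        onehot[np.arange(B), tidx] = 1.0
        dz = dl_dpt[:, None] * pt[:, None] * (onehot - p) / B
        return loss, dz
    # independent sigmoid heads
    p = 1.0 / (1.0 + np.exp(-z))
    pt = np.clip(targets * p + (1 - targets) * (1 - p), _EPS, 1 - _EPS)
    if config.loss == "cross_entropy":
        loss = float(np.mean(np.sum(-np.log(pt), axis=1)))
        return loss, (p - targets) / B
    g = config.gamma
    loss = float(np.mean(np.sum(-((1 - pt) ** g) * np.log(pt), axis=1)))
    dl_dpt = g * (1 - pt) ** (g - 1) * np.log(pt) - (1 - pt) ** g / pt
    dz = dl_dpt * (2 * targets - 1) * p * (1 - p) / B
    return loss, dz


def train_classifier(stream, config: ClassifierConfig) -> TrainedClassifier:
    """Minibatch ERM on a training stream of Examples; deterministic per seed.

    The stream is materialised; batches are drawn uniformly with replacement.
    Soft labels train with soft-target cross-entropy (or focal on their
    argmax); the optional augmentation policy is applied per drawn example.
    """
    examples = list(stream)
    if not examples:
        raise ValueError("training stream is empty")
    targets = _target_matrix(examples, config.n_labels)
    image_shape = examples[0].image.shape
    images = np.stack([e.image for e in examples]).reshape(len(examples), -1)

    rng = np.random.default_rng(config.seed)
    D = images.shape[1]
    params = init_mlp([D, *config.hidden, config.n_labels], rng)
    opt = Adam(params, lr=config.learning_rate)
    log = []
    policy = config.augmentation_policy
    for step in range(config.steps):
        idx = rng.integers(0, len(examples), size=config.batch_size)
        if policy and policy != "none":
            xb = np.stack(
                [
                    heuristic_augment(
                        images[i].reshape(image_shape), policy, rng
                    ).reshape(-1)
                    for i in idx
                ]
            )
        else:
            xb = images[idx]
        z, cache = mlp_forward(params, xb, return_cache=True)
        loss, dz = _dlogits(z, targets[idx], config)
        grads, _ = mlp_backward(params, cache, dz)
        opt.step(grads)
        if step % 50 == 0 or step == config.steps - 1:
            log.append((step, float(loss)))
    return TrainedClassifier(
        params=params, config=config, image_shape=image_shape, training_log=log
    )


def predict_topk(classifier: TrainedClassifier, image, k: int) -> list:
    """Labels of the k largest probabilities, descending; ties by label index."""
    probs = classifier.predict_proba(image)[0]
    if k > len(probs):
        raise ValueError("k exceeds the number of labels")
    order = np.argsort(-probs, kind="stable")
    return [int(i) for i in order[:k]]
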