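"""Conditional denoising diffusion (DDPM) at toy resolution.

Implements the Gaussian forward process, the noise-prediction training
objective with conditioning dropout, ancestral sampling with classifier-free
guidance, and the cascaded-upsampler degradation pipeline.  Conditioning is
blockwise — a one-hot (or soft) label block plus an optional property block —
and an all-zero block means "unknown", which is how unlabeled examples enter
training and how the unconditional branch of guidance is formed.

The denoiser is a conditional MLP over the flattened image, a sinusoidal
timestep embedding and the conditioning vector.  The conditioning input
columns are zero-initialised, so a block that is identically zero throughout
training provably cannot influence samples (its weight columns receive zero
gradient and stay zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import Adam, init_mlp, mlp_backward, mlp_forward, sinusoidal_embedding

__all__ = [
    "NoiseSchedule",
    "make_noise_schedule",
    "ConditioningVector",
    "DiffusionModel",
    "forward_noise",
    "training_loss",
    "train_diffusion",
    "sample_ddpm",
    "UpsamplerPreprocessConfig",
    "upsampler_preprocess",
    "sample_cascade",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Variance schedule: betas in (0,1), alpha_t = 1-beta_t, abar_t = prod alpha."""

    betas: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 1 or len(b) < 1:
            raise ValueError("betas must be a non-empty 1-D vector")
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("betas must lie strictly in (0, 1)")
        object.__setattr__(self, "betas", b)

    @property
    def T(self) -> int:
        return len(self.betas)

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bar(self) -> np.ndarray:
        return np.cumprod(self.alphas)


def make_noise_schedule(T: int, kind: str = "linear") -> NoiseSchedule:
    """Linear or cosine beta schedule with standard literature endpoints."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if kind == "linear":
        # endpoints scaled by 1000/T so the total noise injected is
        # resolution-independent in T
        scale = 1000.0 / T
        betas = np.linspace(scale * 1e-4, min(scale * 0.02, 0.999), T)
        betas = np.clip(betas, 1e-8, 0.999)
    elif kind == "cosine":
        s = 0.008
        steps = np.arange(T + 1) / T
        abar = np.cos((steps + s) / (1 + s) * np.pi / 2) ** 2
        abar /= abar[0]
        betas = np.clip(1 - abar[1:] / abar[:-1], 1e-8, 0.999)
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(betas=betas)


@dataclass(frozen=True)
class ConditioningVector:
    """Blockwise conditioning: label block + optional property block.

    Each block is either all-zero ("unknown") or a probability vector summing
    to 1.  Unlabeled examples carry an all-zero label block; the unconditional
    branch of classifier-free guidance zeroes every block.
    """

    label_block: np.ndarray
    property_block: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        for name in ("label_block", "property_block"):
            b = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, b)
            if b.size and not (np.allclose(b, 0.0) or np.isclose(b.sum(), 1.0)):
                raise ValueError(f"{name} must be all-zero (unknown) or sum to 1")
            if np.any(b < 0):
                raise ValueError(f"{name} must be non-negative")

    def vector(self) -> np.ndarray:
        return np.concatenate([self.label_block, self.property_block])

    def zeroed(self) -> "ConditioningVector":
        return ConditioningVector(
            np.zeros_like(self.label_block), np.zeros_like(self.property_block)
        )

    @classmethod
    def for_label(cls, label, n_labels, prop_index=None, n_prop=0):
        lb = np.zeros(n_labels)
        if label is not None:
            if np.ndim(label) == 0:
                lb[int(label)] = 1.0
            else:  # soft label
                lb = np.asarray(label, dtype=float)
        pb = np.zeros(n_prop)
        if prop_index is not None and n_prop:
            pb[int(prop_index)] = 1.0
        return cls(lb, pb)


@dataclass
class DiffusionModel:
    """A denoiser plus its schedule; the denoiser maps (x, t, cond) -> eps-hat.

    ``denoiser`` may be a trained network closure or any callable stub with
    the same contract (used heavily for closed-form oracle tests).
    """

    denoiser: object
    schedule: NoiseSchedule
    image_shape: tuple
    cond_dim: int
    guidance_weight: float = 0.0
    params: list | None = None
    config: dict = field(default_factory=dict)

    @property
    def image_dim(self) -> int:
        return int(np.prod(self.image_shape))


def forward_noise(schedule: NoiseSchedule, x0: np.ndarray, t, eps: np.ndarray) -> np.ndarray:
    """Closed-form forward marginal: sqrt(abar_t) x0 + sqrt(1-abar_t) eps.

    ``t`` is 1-indexed (t in [1, T]); scalar or per-sample array.
    """
    t = np.asarray(t)
    if np.any(t < 1) or np.any(t > schedule.T):
        raise ValueError(f"t must lie in [1, {schedule.T}]")
    abar = schedule.alpha_bar[t - 1]
    shape = (-1,) + (1,) * (np.asarray(x0).ndim - 1) if t.ndim else ()
    a = np.asarray(abar).reshape(shape) if t.ndim else abar
    return np.sqrt(a) * x0 + np.sqrt(1.0 - a) * eps


def _as_cond_matrix(conds, n: int, cond_dim: int) -> np.ndarray:
    if conds is None:
        return np.zeros((n, cond_dim))
    if isinstance(conds, ConditioningVector):
        return np.tile(conds.vector(), (n, 1))
    mat = np.asarray(conds, dtype=float)
    return np.tile(mat, (n, 1)) if mat.ndim == 1 else mat


def training_loss(model: DiffusionModel, batch, uncond_prob: float, seed: int) -> float:
    """DDPM noise-prediction MSE at a uniform random timestep per example.

    ``batch`` is a sequence of (image in [-1,1], ConditioningVector).  With
    probability ``uncond_prob`` an example's full conditioning vector is
    zeroed (conditioning dropout for classifier-free guidance; unlabeled
    examples already carry zero label blocks).
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    x0 = np.stack([np.asarray(b[0], dtype=float).reshape(-1) for b in batch])
    cond = np.stack([b[1].vector() for b in batch])
    drop = rng.random(len(batch)) < uncond_prob
    cond[drop] = 0.0
    t = rng.integers(1, model.schedule.T + 1, size=len(batch))
    eps = rng.standard_normal(x0.shape)
    xt = forward_noise(model.schedule, x0, t, eps)
    pred = model.denoiser(xt, t, cond)
    return float(np.mean((pred - eps) ** 2))


def _make_denoiser(params, t_emb_dim, schedule=None, predict_type="eps"):
    """Wrap an MLP as an eps-predicting denoiser.

    With ``predict_type="x0"`` the network outputs a clean-image estimate and
    the returned closure converts it to the equivalent noise prediction
    eps-hat = (x_t - sqrt(abar_t) x0-hat) / sqrt(1 - abar_t).
    """

    def denoiser(x, t, cond):
        x = np.atleast_2d(x)
        cond = np.atleast_2d(cond)
        temb = sinusoidal_embedding(np.broadcast_to(np.asarray(t), (len(x),)), t_emb_dim)
        out = mlp_forward(params, np.concatenate([x, temb, cond], axis=1))
        if predict_type == "eps":
            return out
        abar = schedule.alpha_bar[np.asarray(t) - 1]
        a = np.asarray(abar).reshape(-1, 1) if np.ndim(abar) else abar
        return (x - np.sqrt(a) * out) / np.sqrt(1.0 - a)

    return denoiser


def train_diffusion(
    images,
    conds,
    schedule: NoiseSchedule,
    steps: int = 2000,
    batch_size: int = 64,
    lr: float = 1e-3,
    uncond_prob: float = 0.1,
    hidden=(256, 256),
    t_emb_dim: int = 32,
    predict_type: str = "x0",
    seed: int = 0,
) -> DiffusionModel:
    """Train the conditional MLP denoiser; deterministic given the seed.

    ``images``: (n, H, W, C) in [0, 1]; ``conds``: list of ConditioningVector
    (or an (n, cond_dim) array).  By default the network regresses the clean
    image x0 (uniform training weight across timesteps, which keeps the
    conditioning signal strong at high noise where mode choice happens) and
    is exposed through the standard noise-prediction interface; set
    ``predict_type="eps"`` for the plain noise-regression objective.
    """
    if predict_type not in ("x0", "eps"):
        raise ValueError(f"unknown predict_type {predict_type!r}")
    images = np.asarray(images, dtype=float)
    n = len(images)
    x0 = images.reshape(n, -1) * 2.0 - 1.0
    image_shape = images.shape[1:]
    if isinstance(conds, (list, tuple)):
        cond_mat = np.stack([c.vector() for c in conds])
    else:
        cond_mat = np.asarray(conds, dtype=float)
    cond_dim = cond_mat.shape[1]
    D = x0.shape[1]

    rng = np.random.default_rng(seed)
    in_dim = D + t_emb_dim + cond_dim
    params = init_mlp(
        [in_dim, *hidden, D], rng, zero_input_cols=(D + t_emb_dim, in_dim)
    )
    opt = Adam(params, lr=lr)
    T = schedule.T
    for _ in range(steps):
        idx = rng.integers(0, n, size=batch_size)
        xb = x0[idx]
        cb = cond_mat[idx].copy()
        cb[rng.random(batch_size) < uncond_prob] = 0.0
        t = rng.integers(1, T + 1, size=batch_size)
        eps = rng.standard_normal(xb.shape)
        xt = forward_noise(schedule, xb, t, eps)
        temb = sinusoidal_embedding(t, t_emb_dim)
        inp = np.concatenate([xt, temb, cb], axis=1)
        pred, cache = mlp_forward(params, inp, return_cache=True)
        target = xb if predict_type == "x0" else eps
        dout = 2.0 * (pred - target) / pred.size
        grads, _ = mlp_backward(params, cache, dout)
        opt.step(grads)

    return DiffusionModel(
        denoiser=_make_denoiser(params, t_emb_dim, schedule, predict_type),
        schedule=schedule,
        image_shape=image_shape,
        cond_dim=cond_dim,
        params=params,
        config={
            "hidden": list(hidden),
            "t_emb_dim": t_emb_dim,
            "steps": steps,
            "batch_size": batch_size,
            "lr": lr,
            "uncond_prob": uncond_prob,
            "predict_type": predict_type,
            "seed": seed,
        },
    )


def sample_ddpm(
    model: DiffusionModel,
    cond,
    w: float | None = None,
    seed: int = 0,
    n: int = 1,
    clip_x0: bool = True,
) -> np.ndarray:
    """Ancestral DDPM sampling with classifier-free guidance.

    Guided prediction: eps-hat = (1+w) eps(x,t,cond) - w eps(x,t,0).  With
    w = 0 this is exactly plain conditional sampling.  Deterministic per seed;
    returns (n, *image_shape) in [-1, 1].
    """
    if w is None:
        w = model.guidance_weight
    if w < 0:
        raise ValueError("guidance weight must be >= 0")
    rng = np.random.default_rng(seed)
    sched = model.schedule
    D = model.image_dim
    cond_mat = _as_cond_matrix(cond, n, model.cond_dim)
    x = rng.standard_normal((n, D))
    alphas, betas, abar = sched.alphas, sched.betas, sched.alpha_bar
    for t in range(sched.T, 0, -1):
        eps_c = model.denoiser(x, t, cond_mat)
        if w != 0.0:
            eps_u = model.denoiser(x, t, np.zeros_like(cond_mat))
            eps_hat = (1.0 + w) * eps_c - w * eps_u
        else:
            eps_hat = eps_c
        a_t, b_t, ab_t = alphas[t - 1], betas[t - 1], abar[t - 1]
        ab_prev = abar[t - 2] if t > 1 else 1.0
        x0_hat = (x - np.sqrt(1 - ab_t) * eps_hat) / np.sqrt(ab_t)
        if clip_x0:
            x0_hat = np.clip(x0_hat, -1.0, 1.0)
        mean = (
            np.sqrt(ab_prev) * b_t / (1 - ab_t) * x0_hat
            + np.sqrt(a_t) * (1 - ab_prev) / (1 - ab_t) * x
        )
        if t > 1:
            var = (1 - ab_prev) / (1 - ab_t) * b_t
            x = mean + np.sqrt(var) * rng.standard_normal(x.shape)
        else:
            x = mean
    return np.clip(x, -1.0, 1.0).reshape((n, *model.image_shape))


@dataclass(frozen=True)
class UpsamplerPreprocessConfig:
    """Degradation pipeline applied to the upsampler's conditioning image."""

    antialias_prob: float = 0.5
    noise_prob: float = 0.2
    noise_sd: float = 4.0  # on the 0-255 intensity scale
    blur_kernel: int = 7
    blur_sd_mean: float = 0.0
    blur_sd_sd: float = 0.2
    quantize_bins: int = 256

    def __post_init__(self):
        if not (0 <= self.antialias_prob <= 1 and 0 <= self.noise_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.quantize_bins < 2:
            raise ValueError("quantize_bins must be >= 2")


def _bilinear_upsample(image: np.ndarray, out_size: int) -> np.ndarray:
    factor = out_size / image.shape[0]
    return np.stack(
        [ndimage.zoom(image[..., c], factor, order=1, grid_mode=True, mode="nearest")
         for c in range(image.shape[2])],
        axis=2,
    )


def upsampler_preprocess(
    image_lo: np.ndarray,
    out_size: int,
    cfg: UpsamplerPreprocessConfig = UpsamplerPreprocessConfig(),
    seed: int = 0,
) -> np.ndarray:
    """Upscale-and-degrade a low-resolution sample into upsampler conditioning.

    Steps, in order: (1) bilinear upsample to ``out_size`` with an anti-alias
    smoothing applied with probability ``antialias_prob``; (2) Gaussian pixel
    noise (sd on the 0-255 scale) with probability ``noise_prob``; (3) Gaussian
    blur with a ``blur_kernel`` x ``blur_kernel`` kernel and sigma = |N(mean,
    sd)|; (4) quantisation to ``quantize_bins`` levels; (5) normalisation to
    (-1, 1).  ``image_lo`` is H x W x 3 on the 0-255 scale.
    """
    rng = np.random.default_rng(seed)
    img = np.asarray(image_lo, dtype=float)
    img = _bilinear_upsample(img, out_size)
    if rng.random() < cfg.antialias_prob:
        img = ndimage.gaussian_filter(img, sigma=(0.5, 0.5, 0.0))
    if rng.random() < cfg.noise_prob:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    sigma = abs(rng.normal(cfg.blur_sd_mean, cfg.blur_sd_sd))
    if sigma > 1e-12:
        radius = (cfg.blur_kernel - 1) // 2
        img = ndimage.gaussian_filter(
            img, sigma=(sigma, sigma, 0.0), truncate=radius / sigma
        )
    img = np.clip(img, 0.0, 255.0)
    bins = cfg.quantize_bins
    img = np.round(img / 255.0 * (bins - 1)) / (bins - 1) * 255.0
    return img / 127.5 - 1.0


def sample_cascade(
    base: DiffusionModel,
    upsampler: DiffusionModel | None,
    cond,
    out_size: int,
    cfg: UpsamplerPreprocessConfig = UpsamplerPreprocessConfig(),
    seed: int = 0,
    w: float = 0.0,
) -> np.ndarray:
    """Two-stage cascade: base sample -> degrade -> conditional upsampler.

    The upsampler is conditioned on the degraded upscaled base sample
    concatenated with the same blockwise conditioning vector as the base
    model.  ``upsampler=None`` stubs the second stage as bilinear identity.
    Returns one (out_size, out_size, 3) image in [-1, 1].
    """
    ss = np.random.SeedSequence(seed)
    s_base, s_pre, s_up = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))
    lo = sample_ddpm(base, cond, w=w, seed=s_base, n=1)[0]
    if upsampler is None:
        return np.clip(_bilinear_upsample(lo, out_size), -1.0, 1.0)
    hi_dim = out_size * out_size * lo.shape[2]
    cond_vec = _as_cond_matrix(cond, 1, base.cond_dim)[0]
    if upsampler.cond_dim != hi_dim + len(cond_vec):
        raise ValueError(
            "mismatched conditioning layouts: upsampler expects "
            f"{upsampler.cond_dim}, cascade provides {hi_dim + len(cond_vec)}"
        )
    degraded = upsampler_preprocess((lo + 1.0) * 127.5, out_size, cfg, seed=s_pre)
    full_cond = np.concatenate([degraded.reshape(-1), cond_vec])
    return sample_ddpm(upsampler, full_cond, w=w, seed=s_up, n=1)[0]


def save_model(model: DiffusionModel, path) -> None:
    """Single-file checkpoint: weights plus embedded config and schedule."""
    if model.params is None:
        raise ValueError("only trained models (with params) can be saved")
    arrays = {}
    for i, p in enumerate(model.params):
        arrays[f"W{i}"] = p["W"]
        arrays[f"b{i}"] = p["b"]
    meta = dict(
        model.config,
        image_shape=list(model.image_shape),
        cond_dim=model.cond_dim,
        guidance_weight=model.guidance_weight,
        n_layers=len(model.params),
    )
    np.savez(path, betas=model.schedule.betas, meta=json.dumps(meta), **arrays)


def load_model(path) -> DiffusionModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        params = [
            {"W": z[f"W{i}"], "b": z[f"b{i}"]} for i in range(meta["n_layers"])
        ]
        betas = z["betas"]
    schedule = NoiseSchedule(betas=betas)
    return DiffusionModel(
        denoiser=_make_denoiser(
            params, meta["t_emb_dim"], schedule, meta.get("predict_type", "eps")
        ),
        schedule=schedule,
        image_shape=tuple(meta["image_shape"]),
        cond_dim=meta["cond_dim"],
        guidance_weight=meta["guidance_weight"],
        params=params,
        config=meta,
    )
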