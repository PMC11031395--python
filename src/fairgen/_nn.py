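"""Minimal fully-connected network machinery (forward, backprop, Adam).

Sized for toy 16x16 imagery: a handful of dense layers with ReLU is enough for
both the diffusion denoiser and the downstream classifiers, and keeping the
whole training loop in numpy makes every run a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["init_mlp", "mlp_forward", "mlp_backward", "Adam", "sinusoidal_embedding"]


def init_mlp(sizes, rng: np.random.Generator, zero_input_cols=None):
    """He-initialised dense stack; ``sizes`` = [in, h1, ..., out].

    ``zero_input_cols``: optional (start, stop) slice of first-layer input
    columns initialised to zero.  Used for conditioning inputs so that a block
    the training data never activates provably cannot influence the output.
    """
    params = []
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        W = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
        if i == 0 and zero_input_cols is not None:
            W[zero_input_cols[0] : zero_input_cols[1], :] = 0.0
        params.append({"W": W, "b": np.zeros(b)})
    return params


def mlp_forward(params, x, return_cache=False):
    """Forward pass; ReLU on all layers except the last (linear output).

    With ``return_cache`` also returns per-layer pre-ReLU inputs for backprop
    and the penultimate activation (``cache['features']``).
    """
    h = x
    acts = [x]
    for i, p in enumerate(params):
        z = h @ p["W"] + p["b"]
        h = np.maximum(z, 0.0) if i < len(params) - 1 else z
        acts.append(h)
    if not return_cache:
        return h
    return h, {"acts": acts, "features": acts[-2]}


def mlp_backward(params, cache, dout):
    """Gradients for every parameter given d(loss)/d(output); returns (grads, dx)."""
    acts = cache["acts"]
    grads = [None] * len(params)
    delta = dout
    for i in range(len(params) - 1, -1, -1):
        a_in = acts[i]
        grads[i] = {"W": a_in.T @ delta, "b": delta.sum(axis=0)}
        if i > 0:
            delta = (delta @ params[i]["W"].T) * (acts[i] > 0)
    dx = delta @ params[0]["W"].T if len(params) == 1 else delta
    return grads, dx


class Adam:
    """Adam over a list of {'W','b'} parameter dicts."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]
        self.v = [{k: np.zeros_like(v) for k, v in p.items()} for p in params]

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            for k in p:
                m[k] = self.b1 * m[k] + (1 - self.b1) * g[k]
                v[k] = self.b2 * v[k] + (1 - self.b2) * g[k] ** 2
                p[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)


def sinusoidal_embedding(t, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Transformer-style sinusoidal embedding of (possibly batched) timesteps."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((len(t), 1))], axis=1)
    return emb
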