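"""Conditional GAN baseline for curve prediction.

The generator maps ``(x, c, z)`` (input curve, dose, noise) to a predicted
post-treatment curve; the discriminator receives ``(x, c, y')`` and scores
whether ``y'`` is a measured or generated curve.  Both are sigmoid MLPs
trained adversarially with alternating 1:1 gradient steps (non-saturating
generator loss).  The generator achieving the best validation NRMSE is
returned; evaluation uses ``z = 0`` so predictions are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from . import nn
from .nn import glorot_init, mean_nrmse

__all__ = ["GanConfig", "GanResult", "train_cgan", "generator_predict"]


@dataclass
class GanConfig:
    noise_dim: int = 8
    g_hidden: int = 64
    d_hidden: int = 64
    epochs: int = 200
    batch_size: int = 32
    lr: float = 2.0            # matches the package-wide MSE/BCE gradient scale
    rng_seed: int = 0


@dataclass
class GanResult:
    generator: list            # list of LayerParams
    discriminator: list
    noise_dim: int
    history: list = field(default_factory=list)
    mode_collapse: bool = False
    best_val_nrmse: float = np.inf


def _mlp(dims, rng):
    return [glorot_init(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]


def generator_predict(result: GanResult, X, C, z=None):
    X = np.atleast_2d(np.asarray(X, float))
    C = np.atleast_1d(np.asarray(C, float))
    if z is None:
        z = np.zeros((X.shape[0], result.noise_dim))
    inp = np.concatenate([X, C[:, None], z], axis=1)
    return nn._forward_chain(result.generator, inp)[-1]


def train_cgan(dataset: tuple, cfg: GanConfig, val_data: tuple | None = None) -> GanResult:
    """Adversarial training; returns the best-validation generator.

    ``dataset``/``val_data`` are ``(X, C, Y)``.  A run whose validation
    NRMSE never improves on the untrained generator is flagged as mode
    collapse.
    """
    X, C, Y = (np.asarray(a, float) for a in dataset)
    if X.size == 0:
        raise DataError("train_cgan: empty dataset")
    n, T = Y.shape
    rng = np.random.default_rng(cfg.rng_seed)
    G = _mlp([T + 1 + cfg.noise_dim, cfg.g_hidden, T], rng)
    D = _mlp([2 * T + 1, cfg.d_hidden, 1], rng)
    val = val_data if val_data is not None else dataset
    Xv, Cv, Yv = (np.asarray(a, float) for a in val)

    res = GanResult(generator=[nn.copy_model(l) for l in G],
                    discriminator=D, noise_dim=cfg.noise_dim)
    init_nrmse = mean_nrmse(Yv, generator_predict(res, Xv, Cv))
    res.best_val_nrmse = init_nrmse

    def sgd(layers, grads, lr):
        for layer, (gW, gb) in zip(layers, grads):
            layer.W -= lr * gW
            layer.b -= lr * gb

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, cb, yb = X[idx], C[idx], Y[idx]
            m = len(idx)
            z = rng.normal(size=(m, cfg.noise_dim))
            gin = np.concatenate([xb, cb[:, None], z], axis=1)
            g_acts = nn._forward_chain(G, gin)
            y_fake = g_acts[-1]

            # --- discriminator step: real -> 1, fake -> 0
            d_in = np.concatenate([
                np.concatenate([xb, cb[:, None], yb], axis=1),
                np.concatenate([xb, cb[:, None], y_fake], axis=1),
            ])
            d_acts = nn._forward_chain(D, d_in)
            p = np.clip(d_acts[-1], 1e-12, 1 - 1e-12)
            t = np.concatenate([np.ones((m, 1)), np.zeros((m, 1))])
            # BCE with sigmoid head: d(loss)/d(logit) = p - t; divide out the
            # sigmoid derivative that _backward_chain will multiply back in
            dA = (p - t) / (p * (1 - p)) / (2 * m)
            d_grads, _ = nn._backward_chain(D, d_acts, dA)
            sgd(D, d_grads, cfg.lr)

            # --- generator step: non-saturating, fake -> 1
            d_in_f = np.concatenate([xb, cb[:, None], y_fake], axis=1)
            d_acts_f = nn._forward_chain(D, d_in_f)
            pf = np.clip(d_acts_f[-1], 1e-12, 1 - 1e-12)
            dA_f = (pf - 1.0) / (pf * (1 - pf)) / m
            _, d_input_grad = nn._backward_chain(D, d_acts_f, dA_f)
            dYfake = d_input_grad[:, T + 1:]
            g_grads, _ = nn._backward_chain(G, g_acts, dYfake)
            sgd(G, g_grads, cfg.lr)

        res_epoch = GanResult(generator=G, discriminator=D, noise_dim=cfg.noise_dim)
        v = mean_nrmse(Yv, generator_predict(res_epoch, Xv, Cv))
        res.history.append(v)
        if v < res.best_val_nrmse:
            res.best_val_nrmse = v
            res.generator = [nn.copy_model(l) for l in G]
    res.mode_collapse = res.best_val_nrmse >= init_nrmse
    return res
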