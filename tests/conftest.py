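"""Shared fixtures: tiny synthetic datasets and gradient-check helpers."""

import numpy as np
import pytest

from hemocae import generate_dataset
from hemocae.nn import sigmoid


@pytest.fixture(scope="session")
def tiny_dataset():
    """Very small curve dataset for fast structural tests."""
    return generate_dataset(n_plasmas=(4, 2, 2), doses_per_plasma=5, T=24,
                            rng_seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced-scale study dataset (shared across slower tests)."""
    return generate_dataset(n_plasmas=(20, 6, 6), doses_per_plasma=8, T=60,
                            rng_seed=1)


def latent_factor_data(n, d=10, k=2, master_seed=42, draw_seed=0):
    """d-dimensional observations generated from k uniform latent factors.

    The mixing map is fixed by ``master_seed`` so different draws share one
    generative model; rows are squashed through a sigmoid into (0, 1).
    """
    r0 = np.random.default_rng(master_seed)
    A = r0.uniform(-1, 1, (d, k))
    b = r0.uniform(-0.5, 0.5, d)
    r = np.random.default_rng(draw_seed)
    return sigmoid(r.uniform(0, 1, (n, k)) @ A.T + b)


@pytest.fixture(scope="session")
def factor_data():
    """(train, val) pair of 10-dim observations with 2 latent factors."""
    return latent_factor_data(300, draw_seed=0), latent_factor_data(80, draw_seed=1)


# --------------------------------------------------------------------------
# finite-difference gradient checking
# --------------------------------------------------------------------------

def flat_params(model):
    return np.concatenate([np.r_[l.W.ravel(), l.b] for l in model.layers()])


def set_flat_params(model, vec):
    i = 0
    for l in model.layers():
        n = l.W.size
        l.W[...] = vec[i:i + n].reshape(l.W.shape)
        i += n
        l.b[...] = vec[i:i + l.b.size]
        i += l.b.size


def flat_grads(grads):
    return np.concatenate([np.r_[g[0].ravel(), g[1]] for g in grads])


def gradcheck_rel_error(model, objective, batch, eps=1e-6):
    """Relative error between analytic and central-difference gradients."""
    _, grads = objective.value_and_grads(model, batch)
    g = flat_grads(grads)
    p0 = flat_params(model).copy()
    num = np.zeros_like(g)
    for i in range(p0.size):
        p = p0.copy()
        p[i] += eps
        set_flat_params(model, p)
        jp = objective(model, batch)
        p[i] -= 2 * eps
        set_flat_params(model, p)
        jm = objective(model, batch)
        num[i] = (jp - jm) / (2 * eps)
    set_flat_params(model, p0)
    return float(np.linalg.norm(g - num) / max(np.linalg.norm(num), 1e-12))
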