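"""Dense feed-forward autoencoder primitives.

Everything here is plain NumPy: parameter containers, batched forward
passes, the cost functions (reconstruction MSE, supervised MSE, L1 sparsity
on the code, and their hybrid sum), hand-derived backpropagation for each
model family, Glorot initialization, log-uniform per-unit learning rates
(ALRAO) and a mini-batch gradient-descent loop with early stopping.

Three model families share the same layer type:

* :class:`AEModel` -- encoder/decoder chain reconstructing its input.
* :class:`CAEModel` -- conditional autoencoder: the code ``h`` depends only
  on ``x``; a supervised head maps ``(h, c)`` to a prediction of ``y``.
* :class:`DCAEModel` -- deep CAE: an x-encoder stack producing ``h_x``, a
  mirrored x-decoder, a conditional link ``(h_x, c) -> h_y`` and a
  y-decoder stack producing the prediction.

Per-unit learning rates follow the ALRAO idea: each unit draws its own rate
log-uniformly between two bounds, and the rate is applied to that unit's
incoming weights and bias.  The original method's output-layer model
averaging is not implemented; output units simply draw rates like any other
unit.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import h5py
import numpy as np

from .exceptions import (
    DivergenceError,
    ParameterError,
    ShapeError,
)

__all__ = [
    "LayerParams",
    "AEModel",
    "CAEModel",
    "DCAEModel",
    "AlraoRates",
    "TrainConfig",
    "glorot_init",
    "sigmoid",
    "mse",
    "nrmse",
    "mean_nrmse",
    "sparsity_penalty",
    "sample_alrao",
    "sgd_fit",
    "ae_objective",
    "cae_objective",
    "dcae_objective",
    "copy_model",
    "models_equal",
    "save_model",
    "load_model",
]


# --------------------------------------------------------------------------
# activations and losses
# --------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    # clip keeps exp() finite; saturation error is below float64 resolution
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


_ACTIVATIONS = {
    "sigmoid": sigmoid,
    "linear": lambda z: z,
}


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared difference of two equal-length vectors/arrays."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeError(f"mse: shapes {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def nrmse(x: np.ndarray, xhat: np.ndarray) -> float:
    """Root-mean-square error normalized by the range of the reference ``x``."""
    x = np.asarray(x, float)
    xhat = np.asarray(xhat, float)
    if x.shape != xhat.shape:
        raise ShapeError(f"nrmse: shapes {x.shape} vs {xhat.shape}")
    rng = float(x.max() - x.min())
    if rng <= 0:
        raise ParameterError("nrmse: reference vector has zero range")
    return float(np.sqrt(np.mean((x - xhat) ** 2)) / rng)


def mean_nrmse(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Average per-row NRMSE over a batch of reference/prediction rows."""
    X = np.atleast_2d(np.asarray(X, float))
    Xhat = np.atleast_2d(np.asarray(Xhat, float))
    if X.shape != Xhat.shape:
        raise ShapeError(f"mean_nrmse: shapes {X.shape} vs {Xhat.shape}")
    rng = X.max(axis=1) - X.min(axis=1)
    if np.any(rng <= 0):
        raise ParameterError("mean_nrmse: a reference row has zero range")
    return float(np.mean(np.sqrt(np.mean((X - Xhat) ** 2, axis=1)) / rng))


def sparsity_penalty(h: np.ndarray, lam: float) -> float:
    """L1 penalty ``lam * sum_i |h_i|`` on code activations (batch-averaged)."""
    if lam < 0:
        raise ParameterError("sparsity weight lambda must be >= 0")
    h = np.atleast_2d(np.asarray(h, float))
    return float(lam * np.mean(np.sum(np.abs(h), axis=1)))


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class LayerParams:
    """One dense layer: ``a = act(W @ x + b)`` with W of shape (out, in)."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self):
        self.W = np.asarray(self.W, float)
        self.b = np.asarray(self.b, float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ShapeError("LayerParams: W must be (out, in), b (out,)")
        if self.activation not in _ACTIVATIONS:
            raise ParameterError(f"unknown activation '{self.activation}'")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ParameterError("LayerParams: non-finite entries")

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W.shape[0]

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.in_dim:
            raise ShapeError(f"layer expects dim {self.in_dim}, got {X.shape[1]}")
        return _ACTIVATIONS[self.activation](X @ self.W.T + self.b)


def glorot_init(
    in_dim: int,
    out_dim: int,
    rng_seed: int | np.random.Generator = 0,
    activation: str = "sigmoid",
) -> LayerParams:
    """Glorot/Xavier uniform initialization: W ~ U(+-sqrt(6/(in+out))), b = 0."""
    if in_dim < 1 or out_dim < 1:
        raise ParameterError("glorot_init: dimensions must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    bound = np.sqrt(6.0 / (in_dim + out_dim))
    W = rng.uniform(-bound, bound, size=(out_dim, in_dim))
    return LayerParams(W=W, b=np.zeros(out_dim), activation=activation)


def _check_chain(layers, what: str):
    for a, b in zip(layers, layers[1:]):
        if a.out_dim != b.in_dim:
            raise ShapeError(f"{what}: layer dims {a.out_dim} -> {b.in_dim} "
                             "do not chain")


def _forward_chain(layers, X):
    """Forward through a list of layers; returns all activations, input first."""
    acts = [np.atleast_2d(np.asarray(X, float))]
    for layer in layers:
        acts.append(layer.forward(acts[-1]))
    return acts


def _backward_chain(layers, acts, dA):
    """Backprop a chain; returns per-layer (gW, gb) and gradient wrt input."""
    grads = [None] * len(layers)
    for i in range(len(layers) - 1, -1, -1):
        layer, A_in, A_out = layers[i], acts[i], acts[i + 1]
        if layer.activation == "sigmoid":
            dZ = dA * A_out * (1.0 - A_out)
        else:
            dZ = dA
        grads[i] = (dZ.T @ A_in, dZ.sum(axis=0))
        dA = dZ @ layer.W
    return grads, dA


# --------------------------------------------------------------------------
# model families
# --------------------------------------------------------------------------

@dataclass
class AEModel:
    """Autoencoder: encoder chain to code ``h``, decoder chain back to input."""

    encoder_layers: list[LayerParams]
    decoder_layers: list[LayerParams]

    def __post_init__(self):
        if not self.encoder_layers or not self.decoder_layers:
            raise ShapeError("AEModel needs at least one encoder and decoder layer")
        _check_chain(self.encoder_layers, "encoder")
        _check_chain(self.decoder_layers, "decoder")
        if self.encoder_layers[-1].out_dim != self.decoder_layers[0].in_dim:
            raise ShapeError("encoder output dim must equal decoder input dim")

    @property
    def input_dim(self) -> int:
        return self.encoder_layers[0].in_dim

    @property
    def hidden_dim(self) -> int:
        return self.encoder_layers[-1].out_dim

    def encode(self, X: np.ndarray) -> np.ndarray:
        return _forward_chain(self.encoder_layers, X)[-1]

    def decode(self, H: np.ndarray) -> np.ndarray:
        return _forward_chain(self.decoder_layers, H)[-1]

    def forward(self, X: np.ndarray):
        H = self.encode(X)
        return H, self.decode(H)

    def layers(self) -> list[LayerParams]:
        return list(self.encoder_layers) + list(self.decoder_layers)


@dataclass
class CAEModel:
    """Conditional AE: ``h = enc(x)``, ``r = dec(h)``, ``yhat = head([h, c])``.

    The code is a function of ``x`` alone; the scalar condition enters only
    the supervised head, concatenated to the code.
    """

    encoder: list[LayerParams]
    decoder: list[LayerParams]
    supervised_head: list[LayerParams]

    def __post_init__(self):
        if not (self.encoder and self.decoder and self.supervised_head):
            raise ShapeError("CAEModel blocks must be non-empty")
        for block, name in ((self.encoder, "encoder"), (self.decoder, "decoder"),
                            (self.supervised_head, "supervised head")):
            _check_chain(block, name)
        h = self.encoder[-1].out_dim
        if self.decoder[0].in_dim != h:
            raise ShapeError("decoder input dim must equal hidden dim")
        if self.supervised_head[0].in_dim != h + 1:
            raise ShapeError("supervised head input dim must equal hidden_dim + 1")

    @property
    def input_dim(self) -> int:
        return self.encoder[0].in_dim

    @property
    def hidden_dim(self) -> int:
        return self.encoder[-1].out_dim

    @property
    def output_dim(self) -> int:
        return self.supervised_head[-1].out_dim

    def forward(self, X: np.ndarray, C: np.ndarray):
        """Return ``(h, r, yhat)`` for a batch."""
        X = np.atleast_2d(np.asarray(X, float))
        C = np.atleast_1d(np.asarray(C, float))
        if C.shape[0] != X.shape[0]:
            raise ShapeError("X and C batch sizes differ")
        H = _forward_chain(self.encoder, X)[-1]
        R = _forward_chain(self.decoder, H)[-1]
        HC = np.concatenate([H, C[:, None]], axis=1)
        Yhat = _forward_chain(self.supervised_head, HC)[-1]
        return H, R, Yhat

    def layers(self) -> list[LayerParams]:
        return list(self.encoder) + list(self.decoder) + list(self.supervised_head)


@dataclass
class DCAEModel:
    """Deep conditional AE.

    ``h_x = x_encoder(x)``; ``r_x = x_decoder(h_x)``;
    ``h_y = link([h_x, c])``; ``yhat = y_decoder(h_y)`` (identity when the
    y-decoder stack is empty, i.e. the link maps straight to the output).
    """

    x_encoder: list[LayerParams]
    x_decoder: list[LayerParams]
    link: list[LayerParams]
    y_decoder: list[LayerParams] = field(default_factory=list)

    def __post_init__(self):
        if not (self.x_encoder and self.x_decoder and self.link):
            raise ShapeError("DCAE x-encoder, x-decoder and link must be non-empty")
        for block, name in ((self.x_encoder, "x-encoder"), (self.x_decoder, "x-decoder"),
                            (self.link, "link"), (self.y_decoder, "y-decoder")):
            _check_chain(block, name)
        hx = self.x_encoder[-1].out_dim
        if self.x_decoder[0].in_dim != hx:
            raise ShapeError("x-decoder input dim must equal dim(h_x)")
        if self.link[0].in_dim != hx + 1:
            raise ShapeError("link input dim must equal dim(h_x) + 1")
        if self.y_decoder and self.y_decoder[0].in_dim != self.link[-1].out_dim:
            raise ShapeError("y-decoder input dim must equal dim(h_y)")

    @property
    def input_dim(self) -> int:
        return self.x_encoder[0].in_dim

    @property
    def output_dim(self) -> int:
        return (self.y_decoder[-1] if self.y_decoder else self.link[-1]).out_dim

    def forward(self, X: np.ndarray, C: np.ndarray):
        """Return ``(h_x, r_x, h_y, yhat)`` for a batch."""
        X = np.atleast_2d(np.asarray(X, float))
        C = np.atleast_1d(np.asarray(C, float))
        if C.shape[0] != X.shape[0]:
            raise ShapeError("X and C batch sizes differ")
        Hx = _forward_chain(self.x_encoder, X)[-1]
        Rx = _forward_chain(self.x_decoder, Hx)[-1]
        HxC = np.concatenate([Hx, C[:, None]], axis=1)
        Hy = _forward_chain(self.link, HxC)[-1]
        Yhat = _forward_chain(self.y_decoder, Hy)[-1] if self.y_decoder else Hy
        return Hx, Rx, Hy, Yhat

    def predict(self, X: np.ndarray, C: np.ndarray) -> np.ndarray:
        return self.forward(X, C)[3]

    def layers(self) -> list[LayerParams]:
        return (list(self.x_encoder) + list(self.x_decoder)
                + list(self.link) + list(self.y_decoder))


def copy_model(model):
    return copy.deepcopy(model)


def models_equal(a, b) -> bool:
    """Bitwise equality of two models' parameters."""
    la, lb = a.layers(), b.layers()
    if len(la) != len(lb):
        return False
    return all(
        x.activation == y.activation
        and x.W.shape == y.W.shape
        and np.array_equal(x.W, y.W)
        and np.array_equal(x.b, y.b)
        for x, y in zip(la, lb)
    )


# --------------------------------------------------------------------------
# ALRAO per-unit learning rates
# --------------------------------------------------------------------------

@dataclass
class AlraoRates:
    """Per-unit learning rates, one vector per layer (aligned with out_dim)."""

    eta_min: float
    eta_max: float
    per_unit: list[np.ndarray]

    def __post_init__(self):
        # eta_min == 0 is allowed in the container (frozen / no-op training);
        # sampling via sample_alrao requires strictly positive bounds
        if not (0 <= self.eta_min <= self.eta_max):
            raise ParameterError("need 0 <= eta_min <= eta_max")
        for r in self.per_unit:
            if np.any(r < self.eta_min - 1e-15) or np.any(r > self.eta_max + 1e-15):
                raise ParameterError("a sampled rate violates the ALRAO bounds")

    def scaled(self, factor: float) -> "AlraoRates":
        out = copy.deepcopy(self)
        out.per_unit = [r * factor for r in out.per_unit]
        out.eta_min *= factor
        out.eta_max *= factor
        return out


def sample_alrao(
    layer_widths: list[int],
    eta_min: float,
    eta_max: float,
    rng_seed: int | np.random.Generator = 0,
) -> AlraoRates:
    """Draw one log-uniform rate in [eta_min, eta_max] per unit per layer."""
    if not (0 < eta_min <= eta_max):
        raise ParameterError("need 0 < eta_min <= eta_max")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    lo, hi = np.log(eta_min), np.log(eta_max)
    per_unit = [np.exp(rng.uniform(lo, hi, size=w)) for w in layer_widths]
    return AlraoRates(eta_min=eta_min, eta_max=eta_max, per_unit=per_unit)


def rates_for_model(model, eta_min, eta_max, rng_seed=0) -> AlraoRates:
    return sample_alrao([l.out_dim for l in model.layers()], eta_min, eta_max, rng_seed)


def constant_rates(model, eta: float) -> AlraoRates:
    return AlraoRates(eta, eta, [np.full(l.out_dim, eta) for l in model.layers()])


# --------------------------------------------------------------------------
# objectives (value + analytic gradients)
# --------------------------------------------------------------------------

def _accumulate(dst, src):
    for i, g in enumerate(src):
        if g is None:
            continue
        if dst[i] is None:
            dst[i] = [g[0].copy(), g[1].copy()]
        else:
            dst[i][0] += g[0]
            dst[i][1] += g[1]


def ae_objective(lam: float = 0.0):
    """Sparse-AE cost: MSE(r, x) + lam * mean_i sum|h_i| and its gradients."""

    def value(model: AEModel, batch):
        (X,) = batch
        H, R = model.forward(X)
        return mse(R, X) + sparsity_penalty(H, lam)

    def value_and_grads(model: AEModel, batch):
        (X,) = batch
        X = np.atleast_2d(np.asarray(X, float))
        n = X.shape[0]
        enc_acts = _forward_chain(model.encoder_layers, X)
        H = enc_acts[-1]
        dec_acts = _forward_chain(model.decoder_layers, H)
        R = dec_acts[-1]
        J = mse(R, X) + sparsity_penalty(H, lam)
        dR = 2.0 * (R - X) / (n * X.shape[1])
        dec_grads, dH = _backward_chain(model.decoder_layers, dec_acts, dR)
        if lam > 0:
            dH = dH + lam * np.sign(H) / n
        enc_grads, _ = _backward_chain(model.encoder_layers, enc_acts, dH)
        return J, enc_grads + dec_grads

    value.value_and_grads = value_and_grads
    return value


def cae_objective(lam: float = 0.0, regularized: bool = True):
    """Hybrid CAE cost MSE(r,x) + MSE(yhat,y) [+ lam*sum|h|] and gradients."""
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    lam_eff = lam if regularized else 0.0

    def value(model: CAEModel, batch):
        X, C, Y = batch
        H, R, Yhat = model.forward(X, C)
        return mse(R, X) + mse(Yhat, Y) + sparsity_penalty(H, lam_eff)

    def value_and_grads(model: CAEModel, batch):
        X, C, Y = batch
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        C = np.atleast_1d(np.asarray(C, float))
        n = X.shape[0]
        enc_acts = _forward_chain(model.encoder, X)
        H = enc_acts[-1]
        dec_acts = _forward_chain(model.decoder, H)
        R = dec_acts[-1]
        HC = np.concatenate([H, C[:, None]], axis=1)
        head_acts = _forward_chain(model.supervised_head, HC)
        Yhat = head_acts[-1]
        J = mse(R, X) + mse(Yhat, Y) + sparsity_penalty(H, lam_eff)

        dR = 2.0 * (R - X) / (n * X.shape[1])
        dec_grads, dH_rec = _backward_chain(model.decoder, dec_acts, dR)
        dYhat = 2.0 * (Yhat - Y) / (n * Y.shape[1])
        head_grads, dHC = _backward_chain(model.supervised_head, head_acts, dYhat)
        dH = dH_rec + dHC[:, :-1]  # the condition column is an input, not a parameter
        if lam_eff > 0:
            dH = dH + lam_eff * np.sign(H) / n
        enc_grads, _ = _backward_chain(model.encoder, enc_acts, dH)
        return J, enc_grads + dec_grads + head_grads

    value.value_and_grads = value_and_grads
    return value


def dcae_objective(lam: float = 0.0, regularized: bool = False):
    """DCAE joint cost MSE(r_x,x) + MSE(yhat,y) [+ lam*sum|h_x|] and gradients.

    The default is the unregularized form used for joint fine-tuning after
    pre-training; set ``regularized=True`` to add the L1 code penalty.
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    lam_eff = lam if regularized else 0.0

    def value(model: DCAEModel, batch):
        X, C, Y = batch
        Hx, Rx, _, Yhat = model.forward(X, C)
        return mse(Rx, X) + mse(Yhat, Y) + sparsity_penalty(Hx, lam_eff)

    def value_and_grads(model: DCAEModel, batch):
        X, C, Y = batch
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.atleast_2d(np.asarray(Y, float))
        C = np.atleast_1d(np.asarray(C, float))
        n = X.shape[0]
        xe_acts = _forward_chain(model.x_encoder, X)
        Hx = xe_acts[-1]
        xd_acts = _forward_chain(model.x_decoder, Hx)
        Rx = xd_acts[-1]
        HxC = np.concatenate([Hx, C[:, None]], axis=1)
        ln_acts = _forward_chain(model.link, HxC)
        Hy = ln_acts[-1]
        if model.y_decoder:
            yd_acts = _forward_chain(model.y_decoder, Hy)
            Yhat = yd_acts[-1]
        else:
            yd_acts, Yhat = None, Hy
        J = mse(Rx, X) + mse(Yhat, Y) + sparsity_penalty(Hx, lam_eff)

        dYhat = 2.0 * (Yhat - Y) / (n * Y.shape[1])
        if yd_acts is not None:
            yd_grads, dHy = _backward_chain(model.y_decoder, yd_acts, dYhat)
        else:
            yd_grads, dHy = [], dYhat
        ln_grads, dHxC = _backward_chain(model.link, ln_acts, dHy)
        dRx = 2.0 * (Rx - X) / (n * X.shape[1])
        xd_grads, dHx_rec = _backward_chain(model.x_decoder, xd_acts, dRx)
        dHx = dHx_rec + dHxC[:, :-1]
        if lam_eff > 0:
            dHx = dHx + lam_eff * np.sign(Hx) / n
        xe_grads, _ = _backward_chain(model.x_encoder, xe_acts, dHx)
        return J, xe_grads + xd_grads + ln_grads + yd_grads

    value.value_and_grads = value_and_grads
    return value


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Knobs of the gradient-descent loop.

    ``lambda_sparsity`` weighs the L1 code penalty in regularized
    objectives; ``patience`` is the early-stopping window in epochs.
    """

    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    lambda_sparsity: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 0:
            raise ParameterError("invalid TrainConfig")
        if self.lambda_sparsity < 0:
            raise ParameterError("lambda_sparsity must be >= 0")


def _apply_update(model, grads, rates: AlraoRates):
    for layer, grad, r in zip(model.layers(), grads, rates.per_unit):
        gW, gb = grad
        layer.W -= r[:, None] * gW
        layer.b -= r * gb


def sgd_fit(
    model,
    data: tuple,
    objective,
    rates: AlraoRates,
    cfg: TrainConfig,
    val_data: tuple | None = None,
    val_score=None,
):
    """Mini-batch gradient descent with per-unit rates and early stopping.

    ``data``/``val_data`` are tuples of row-aligned arrays forming batches
    for ``objective`` (``(X,)`` for AEs, ``(X, C, Y)`` for conditional
    models).  After each epoch the validation error is computed -- by
    ``val_score(model, val_data)`` when given, else by the objective on
    ``val_data``, else the training loss.  Training stops at ``max_epochs``
    or when validation fails to improve for ``patience`` consecutive
    epochs; the parameters achieving the best validation error are
    returned, along with the per-epoch history.
    """
    n = len(data[0])
    if n == 0:
        raise ParameterError("sgd_fit: empty training data")
    rng = np.random.default_rng(cfg.rng_seed)
    history = {"train": [], "val": []}

    def current_val():
        if val_score is not None:
            return float(val_score(model, val_data))
        if val_data is not None:
            return float(objective(model, val_data))
        return float(objective(model, data))

    best_err = current_val()
    best = copy_model(model)
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = tuple(a[idx] for a in data)
            loss, grads = objective.value_and_grads(model, batch)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            _apply_update(model, grads, rates)
        train_err = float(objective(model, data))
        if not np.isfinite(train_err):
            raise DivergenceError(epoch)
        val_err = current_val()
        history["train"].append(train_err)
        history["val"].append(val_err)
        if val_err < best_err:
            best_err = val_err
            best = copy_model(model)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    return best, history


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

_MODEL_BLOCKS = {
    "AEModel": ("encoder_layers", "decoder_layers"),
    "CAEModel": ("encoder", "decoder", "supervised_head"),
    "DCAEModel": ("x_encoder", "x_decoder", "link", "y_decoder"),
}
_MODEL_TYPES = {"AEModel": AEModel, "CAEModel": CAEModel, "DCAEModel": DCAEModel}


def save_model(model, path: str, rates: AlraoRates | None = None) -> None:
    """Write a model (and optionally its per-unit rates) as HDF5."""
    kind = type(model).__name__
    blocks = _MODEL_BLOCKS[kind]
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = kind
        for block in blocks:
            grp = f.create_group(block)
            for i, layer in enumerate(getattr(model, block)):
                lg = grp.create_group(f"{i:03d}")
                lg.create_dataset("W", data=layer.W, track_times=False)
                lg.create_dataset("b", data=layer.b, track_times=False)
                lg.attrs["activation"] = layer.activation
        if rates is not None:
            rg = f.create_group("alrao")
            rg.attrs["eta_min"] = rates.eta_min
            rg.attrs["eta_max"] = rates.eta_max
            for i, r in enumerate(rates.per_unit):
                rg.create_dataset(f"{i:03d}", data=r, track_times=False)


def load_model(path: str):
    """Read a model checkpoint; returns ``(model, rates_or_None)``."""
    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        blocks = {}
        for block in _MODEL_BLOCKS[kind]:
            layers = []
            for key in sorted(f[block].keys()):
                lg = f[block][key]
                layers.append(LayerParams(lg["W"][...], lg["b"][...], lg.attrs["activation"]))
            blocks[block] = layers
        rates = None
        if "alrao" in f:
            rg = f["alrao"]
            rates = AlraoRates(
                float(rg.attrs["eta_min"]),
                float(rg.attrs["eta_max"]),
                [rg[k][...] for k in sorted(rg.keys())],
            )
    return _MODEL_TYPES[kind](**blocks), rates
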