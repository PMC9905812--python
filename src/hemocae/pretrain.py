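"""Greedy conditional pre-training of deep conditional autoencoders.

A DCAE is split into three building blocks: the x-side deep AE (modelling
``p(x)``), the y-side deep AE (modelling ``p(y)``; only its decoder
parameters are exported) and the supervised conditional link.  The three
pre-training steps are:

1. **Parallel pre-training** -- greedy layer-wise (Hinton-style) pre-training
   of the x-side and y-side stacks, each layer a sparse single-hidden-layer
   AE trained to reconstruct the code of the previous layer.  The two sides
   are independent, so they may run in either order (or in parallel) with
   identical results.
2. **Supervised conditional link** -- a CAE answering ``p(h_y | h_{x,n-1},
   c)``: its hidden layer is the top code ``h_x``, its decoder is
   initialized from the reconstruction parameters learned in step 1 (so the
   gradient chain into the x-stack stays intact), and its remaining
   parameters start Glorot-random.  Trained on the hybrid cost.
3. **Parameter copy + joint fine-tuning** -- all block parameters are copied
   into a single DCAE, which is then trained jointly on the unregularized
   cost (reconstruction + supervised MSE, no sparsity term: pre-training
   itself acts as the regularizer, so the L1 penalty is kept only inside the
   block-wise steps 1-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AssemblyError, DataError, ParameterError
from . import nn
from .nn import (
    AEModel,
    CAEModel,
    DCAEModel,
    TrainConfig,
    copy_model,
    glorot_init,
    mean_nrmse,
)

__all__ = [
    "PretrainConfig",
    "pretrain_stack",
    "encode_through",
    "parallel_pretrain",
    "train_link",
    "assemble_dcae",
    "finetune_dcae",
    "predict",
    "conditional_pretrain",
]

#: Default ALRAO bounds; see docs/methods.md for the calibration rationale.
DEFAULT_ETA_MIN = 1.0
DEFAULT_ETA_MAX = 30.0


@dataclass
class PretrainConfig:
    """Training configuration shared by all pre-training steps.

    Each step trains with per-unit ALRAO rates drawn log-uniformly in
    ``[eta_min, eta_max]`` and uses the same epoch budget (``base``), a
    deliberate equal-budget split across steps.
    """

    base: TrainConfig = field(default_factory=TrainConfig)
    eta_min: float = DEFAULT_ETA_MIN
    eta_max: float = DEFAULT_ETA_MAX

    def __post_init__(self):
        if not (0 < self.eta_min <= self.eta_max):
            raise ParameterError("need 0 < eta_min <= eta_max")


def _seeded_cfg(cfg: TrainConfig, seed: int) -> TrainConfig:
    return TrainConfig(
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        lambda_sparsity=cfg.lambda_sparsity,
        rng_seed=seed,
    )


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _fit_ae(X, hidden_dim, cfg: PretrainConfig, seed: int, X_val=None) -> AEModel:
    rng = np.random.default_rng(seed)
    d = X.shape[1]
    ae = AEModel([glorot_init(d, hidden_dim, rng)], [glorot_init(hidden_dim, d, rng)])
    rates = nn.rates_for_model(ae, cfg.eta_min, cfg.eta_max, rng)
    obj = nn.ae_objective(lam=cfg.base.lambda_sparsity)
    val = (X_val,) if X_val is not None else None
    best, _ = nn.sgd_fit(ae, (X,), obj, rates, _seeded_cfg(cfg.base, seed), val_data=val)
    return best


def pretrain_stack(
    data: np.ndarray,
    layer_dims: list[int],
    cfg: PretrainConfig,
    val_data: np.ndarray | None = None,
    rng_seed: int | None = None,
) -> list[AEModel]:
    """Greedy layer-wise pre-training: AE ``k`` reconstructs the code of AE ``k-1``."""
    data = np.atleast_2d(np.asarray(data, float))
    if data.size == 0:
        raise DataError("pretrain_stack: empty data")
    if not layer_dims:
        raise ParameterError("pretrain_stack: layer_dims must be non-empty")
    seed = cfg.base.rng_seed if rng_seed is None else rng_seed
    stack: list[AEModel] = []
    codes, codes_val = data, val_data
    for dim, s in zip(layer_dims, _sub_seeds(seed, len(layer_dims))):
        ae = _fit_ae(codes, dim, cfg, s, codes_val)
        stack.append(ae)
        codes = ae.encode(codes)
        codes_val = ae.encode(codes_val) if codes_val is not None else None
    return stack


def encode_through(stack: list[AEModel], data: np.ndarray) -> np.ndarray:
    """Compose the encoders of a stack; an empty stack is the identity."""
    codes = np.atleast_2d(np.asarray(data, float))
    for ae in stack:
        codes = ae.encode(codes)
    return codes


def parallel_pretrain(
    X: np.ndarray,
    Y: np.ndarray,
    x_dims: list[int],
    y_dims: list[int],
    cfg: PretrainConfig,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
):
    """Pre-train the x-side and y-side stacks (independent; order-free)."""
    sx, sy = _sub_seeds(cfg.base.rng_seed, 2)
    x_stack = pretrain_stack(X, x_dims, cfg, val_data=X_val, rng_seed=sx)
    y_stack = pretrain_stack(Y, y_dims, cfg, val_data=Y_val, rng_seed=sy)
    return x_stack, y_stack


def train_link(
    hx_prev_codes: np.ndarray,
    c_values: np.ndarray,
    hy_codes: np.ndarray,
    known_decoder: nn.LayerParams,
    cfg: PretrainConfig,
    val: tuple | None = None,
    rng_seed: int | None = None,
    epochs: int = 0,
) -> CAEModel:
    """Train the supervised conditional link CAE ``p(h_y | h_{x,n-1}, c)``.

    The CAE's hidden layer is ``h_x`` (the dimension of ``known_decoder``'s
    input); its decoder starts as a copy of ``known_decoder`` -- the
    reconstruction parameters of ``h_{x,n-1}`` learned during parallel
    pre-training -- while encoder and head start Glorot-random.  The decoder
    remains trainable during this step.  ``epochs`` overrides the config
    budget when positive; ``epochs=0`` with ``cfg.base.max_epochs=0`` leaves
    the initialization untouched.
    """
    hx_prev_codes = np.atleast_2d(np.asarray(hx_prev_codes, float))
    hy_codes = np.atleast_2d(np.asarray(hy_codes, float))
    if known_decoder.out_dim != hx_prev_codes.shape[1]:
        raise nn.ShapeError("known_decoder must reconstruct the h_{x,n-1} codes")
    hx_dim = known_decoder.in_dim
    seed = cfg.base.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    model = CAEModel(
        encoder=[glorot_init(hx_prev_codes.shape[1], hx_dim, rng)],
        decoder=[nn.LayerParams(known_decoder.W.copy(), known_decoder.b.copy(),
                                known_decoder.activation)],
        supervised_head=[glorot_init(hx_dim + 1, hy_codes.shape[1], rng)],
    )
    base = _seeded_cfg(cfg.base, seed)
    if epochs:
        base.max_epochs = epochs
    if base.max_epochs == 0:
        return model
    rates = nn.rates_for_model(model, cfg.eta_min, cfg.eta_max, rng)
    obj = nn.cae_objective(lam=base.lambda_sparsity, regularized=True)
    best, _ = nn.sgd_fit(model, (hx_prev_codes, c_values, hy_codes), obj, rates,
                         base, val_data=val)
    return best


def assemble_dcae(x_stack: list[AEModel], link: CAEModel,
                  y_stack: list[AEModel]) -> DCAEModel:
    """Copy block parameters into one DCAE.

    The link replaces the last x-side AE (its encoder becomes the final
    x-encoder layer, its decoder the first x-decoder layer); the y-stack
    contributes only its decoders, innermost first.  The assembled forward
    pass equals the block-wise composition exactly.
    """
    if not x_stack or not y_stack:
        raise AssemblyError("x_stack and y_stack must be non-empty")
    body = x_stack[:-1]
    x_encoder = [copy_model(l) for ae in body for l in ae.encoder_layers]
    x_encoder += [copy_model(l) for l in link.encoder]
    x_decoder = [copy_model(l) for l in link.decoder]
    x_decoder += [copy_model(l) for ae in reversed(body) for l in ae.decoder_layers]
    link_layers = [copy_model(l) for l in link.supervised_head]
    y_decoder = [copy_model(l) for ae in reversed(y_stack) for l in ae.decoder_layers]
    try:
        dcae = DCAEModel(x_encoder=x_encoder, x_decoder=x_decoder,
                         link=link_layers, y_decoder=y_decoder)
    except nn.ShapeError as exc:
        raise AssemblyError(str(exc)) from exc
    if dcae.input_dim != x_decoder[-1].out_dim:
        raise AssemblyError("x-decoder does not mirror the x-encoder")
    return dcae


def finetune_dcae(
    dcae: DCAEModel,
    triplets: tuple,
    cfg: PretrainConfig,
    val: tuple | None = None,
    rng_seed: int | None = None,
):
    """Joint fine-tuning of all DCAE parameters, sparsity term dropped.

    Early-stops on validation NRMSE of the prediction when ``val`` is
    given.  Returns ``(model, history)``.
    """
    seed = cfg.base.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    rates = nn.rates_for_model(dcae, cfg.eta_min, cfg.eta_max, rng)
    obj = nn.dcae_objective(regularized=False)

    def val_score(model, vd):
        Xv, Cv, Yv = vd
        return mean_nrmse(Yv, model.predict(Xv, Cv))

    return nn.sgd_fit(dcae, triplets, obj, rates, _seeded_cfg(cfg.base, seed),
                      val_data=val, val_score=val_score if val is not None else None)


def predict(dcae: DCAEModel, x: np.ndarray, c) -> np.ndarray:
    """Predicted post-treatment curve(s) for input curve(s) and dose(s)."""
    one = np.asarray(x).ndim == 1
    X = np.atleast_2d(np.asarray(x, float))
    C = np.atleast_1d(np.asarray(c, float))
    out = dcae.predict(X, C)
    return out[0] if one else out


def conditional_pretrain(
    triplets: tuple,
    x_dims: list[int],
    y_dims: list[int],
    cfg: PretrainConfig,
    val: tuple | None = None,
    finetune: bool = True,
):
    """Full three-step conditional pre-training; returns ``(dcae, history)``.

    ``triplets``/``val`` are ``(X, C, Y)`` tuples; ``x_dims`` ends at the
    ``h_x`` width, ``y_dims`` at the ``h_y`` width.
    """
    X, C, Y = triplets
    Xv, Cv, Yv = val if val is not None else (None, None, None)
    x_stack, y_stack = parallel_pretrain(X, Y, x_dims, y_dims, cfg, X_val=Xv, Y_val=Yv)
    hx_prev = encode_through(x_stack[:-1], X)
    hy = encode_through(y_stack, Y)
    link_val = None
    if val is not None:
        link_val = (encode_through(x_stack[:-1], Xv), Cv, encode_through(y_stack, Yv))
    link_seed = _sub_seeds(cfg.base.rng_seed, 3)[2]
    link = train_link(hx_prev, C, hy, x_stack[-1].decoder_layers[0], cfg,
                      val=link_val, rng_seed=link_seed)
    dcae = assemble_dcae(x_stack, link, y_stack)
    if not finetune:
        return dcae, {"train": [], "val": []}
    return finetune_dcae(dcae, triplets, cfg, val=val)
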