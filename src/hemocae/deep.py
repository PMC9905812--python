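"""Greedy depth growth for deep (conditional) autoencoders.

Two optimization strategies build depth one hidden layer at a time, using
incremental AEs/CAEs (see :mod:`hemocae.incremental`) as building blocks:

* **Unsupervised incremental optimization** (plain deep AEs) -- train an
  incremental AE on the data, then repeatedly: train a new incremental AE
  on the current codes, unfold all layers into a single deep AE, fine-tune
  jointly, and accept the new depth only if the validation error strictly
  decreases.  On the first rejection the previously saved model is
  restored and the search stops.

* **Conditional incremental optimization** (DCAEs) -- phase 0 trains a
  simple incremental CAE whose stopping criterion uses the hybrid cost.
  The x-phase then deepens the x-side: an incremental AE learns a deeper
  code of ``p(x)``, an incremental CAE warm-started from it re-links
  ``(h_x, c)`` to the current ``h_y``, the blocks are unfolded into a DCAE
  and fine-tuned jointly, and the candidate is accepted only if the
  validation NRMSE of the prediction improves.  The y-phase mirrors this on
  the output side: a new incremental AE deepens the ``h_y`` code (its
  decoder joins the y-side stack; its encoder is kept only to produce
  deeper code targets) and the link CAE is retrained to map ``(h_x, c)``
  to the new code.  Every rejection restores the previous DCAE bitwise and
  ends its phase, so accepted validation errors decrease strictly.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .exceptions import AssemblyError
from . import nn
from .incremental import IncrementalConfig, run_incremental
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
    "DeepConfig",
    "DepthSearchState",
    "unfold",
    "run_unsup_incremental",
    "run_cond_incremental",
]


@dataclass
class DeepConfig:
    """Configuration of the depth search.

    ``block`` parametrizes every incremental building block; per-block RNG
    seeds are derived from ``block.rng_seed``.  Joint fine-tuning of each
    unfolded candidate uses a fixed epoch cap with early stopping,
    identical across candidates, with modest ALRAO bounds so the
    pre-trained structure is refined rather than overwritten.
    """

    block: IncrementalConfig = field(default_factory=IncrementalConfig)
    max_depth: int = 4               # per phase, counting added layers
    finetune_epochs: int = 150
    finetune_patience: int = 15
    finetune_eta: tuple[float, float] = (0.5, 5.0)
    code_width: int | None = None    # init_width for deeper blocks; None = block value


@dataclass
class DepthSearchState:
    """Decision log and snapshots of one depth search."""

    accepted: list = field(default_factory=list)   # dicts: phase, depth, val_error
    best_model: object = None
    best_error: float = np.inf
    rejected: list = field(default_factory=list)
    log: list = field(default_factory=list)

    def accept(self, model, error: float, phase: str, depth: int):
        self.best_model = copy_model(model)
        self.best_error = error
        self.accepted.append({"phase": phase, "depth": depth, "val_error": error})
        self.log.append({"event": "accept", "phase": phase, "depth": depth,
                         "val_error": error})

    def reject(self, error: float, phase: str, depth: int):
        self.rejected.append({"phase": phase, "depth": depth, "val_error": error})
        self.log.append({"event": "reject", "phase": phase, "depth": depth,
                         "val_error": error, "restored_error": self.best_error})


def _seed(cfg: DeepConfig, k: int) -> int:
    return int(np.random.SeedSequence((cfg.block.rng_seed, k)).generate_state(1)[0]
               % (2**31))


def _block_cfg(cfg: DeepConfig, seed: int, init_width: int | None = None,
               overcomplete: bool = True) -> IncrementalConfig:
    c = copy.deepcopy(cfg.block)
    c.rng_seed = seed
    if init_width is not None:
        c.init_width = init_width
    c.require_overcomplete = overcomplete
    return c


def unfold(blocks: list[AEModel]) -> AEModel:
    """Export the layers of a chain of AE blocks into one deep AE.

    The forward pass of the unfolded model equals the composition of the
    block forwards exactly (parameters are copied, not retrained).
    """
    if not blocks:
        raise AssemblyError("unfold: need at least one block")
    enc = [copy_model(l) for b in blocks for l in b.encoder_layers]
    dec = [copy_model(l) for b in reversed(blocks) for l in b.decoder_layers]
    try:
        return AEModel(encoder_layers=enc, decoder_layers=dec)
    except nn.ShapeError as exc:
        raise AssemblyError(str(exc)) from exc


def _finetune_ae(model: AEModel, data, val, cfg: DeepConfig, seed: int):
    rng = np.random.default_rng(seed)
    rates = nn.rates_for_model(model, *cfg.finetune_eta, rng)
    tc = TrainConfig(batch_size=cfg.block.batch_size, max_epochs=cfg.finetune_epochs,
                     patience=cfg.finetune_patience, lambda_sparsity=0.0,
                     rng_seed=seed)

    def score(m, _vd):
        return mean_nrmse(val[0], m.forward(val[0])[1])

    best, _ = nn.sgd_fit(model, data, nn.ae_objective(0.0), rates, tc,
                         val_data=val, val_score=score)
    return best, score(best, None)


def run_unsup_incremental(data: tuple, cfg: DeepConfig,
                          val_data: tuple | None = None):
    """Depth search for a plain deep AE; returns ``(model, state)``."""
    val = val_data if val_data is not None else data
    state = DepthSearchState()

    model, _, hist = run_incremental(data, _block_cfg(cfg, _seed(cfg, 0)),
                                     conditional=False, val_data=val)
    model, err = _finetune_ae(model, data, val, cfg, _seed(cfg, 1))
    state.accept(model, err, "unsupervised", 1)

    for depth in range(2, cfg.max_depth + 1):
        current: AEModel = state.best_model
        codes = current.encode(data[0])
        codes_val = current.encode(val[0])
        width = cfg.code_width or max(cfg.block.init_width, codes.shape[1])
        blk_cfg = _block_cfg(cfg, _seed(cfg, 10 * depth), init_width=width,
                             overcomplete=False)
        new_ae, _, _ = run_incremental((codes,), blk_cfg, conditional=False,
                                       val_data=(codes_val,))
        candidate = AEModel(
            encoder_layers=[copy_model(l) for l in current.encoder_layers]
            + [copy_model(l) for l in new_ae.encoder_layers],
            decoder_layers=[copy_model(l) for l in new_ae.decoder_layers]
            + [copy_model(l) for l in current.decoder_layers],
        )
        candidate, cand_err = _finetune_ae(candidate, data, val, cfg,
                                           _seed(cfg, 10 * depth + 1))
        if cand_err < state.best_error:
            state.accept(candidate, cand_err, "unsupervised", depth)
        else:
            state.reject(cand_err, "unsupervised", depth)
            break
    return copy_model(state.best_model), state


# --------------------------------------------------------------------------
# conditional depth search
# --------------------------------------------------------------------------

def _cae_to_dcae(cae: CAEModel) -> DCAEModel:
    """A simple CAE is a depth-1 DCAE whose link maps straight to the output."""
    return DCAEModel(
        x_encoder=[copy_model(l) for l in cae.encoder],
        x_decoder=[copy_model(l) for l in cae.decoder],
        link=[copy_model(l) for l in cae.supervised_head],
        y_decoder=[],
    )


def _finetune_dcae(model: DCAEModel, data, val, cfg: DeepConfig, seed: int):
    rng = np.random.default_rng(seed)
    rates = nn.rates_for_model(model, *cfg.finetune_eta, rng)
    tc = TrainConfig(batch_size=cfg.block.batch_size, max_epochs=cfg.finetune_epochs,
                     patience=cfg.finetune_patience, lambda_sparsity=0.0,
                     rng_seed=seed)

    def score(m, _vd):
        Xv, Cv, Yv = val
        return mean_nrmse(Yv, m.predict(Xv, Cv))

    best, _ = nn.sgd_fit(model, data, nn.dcae_objective(regularized=False),
                         rates, tc, val_data=val, val_score=score)
    return best, score(best, None)


def run_cond_incremental(triplets: tuple, cfg: DeepConfig,
                         val_data: tuple | None = None):
    """Conditional depth search for a DCAE; returns ``(model, state)``.

    ``triplets``/``val_data`` are ``(X, C, Y)`` tuples with plasma-disjoint
    splits.  The returned topology belongs to the family
    ``x -> h_x1 -> ... -> h_x`` (mirrored x-decoder), ``(h_x, c) -> h_y``,
    ``h_y -> ... -> y``.
    """
    X, C, Y = triplets
    val = val_data if val_data is not None else triplets
    Xv, Cv, Yv = val
    state = DepthSearchState()

    # ---- phase 0: simple incremental CAE
    cae, _, _ = run_incremental(triplets, _block_cfg(cfg, _seed(cfg, 0)),
                                conditional=True, val_data=val)
    dcae = _cae_to_dcae(cae)
    dcae, err = _finetune_dcae(dcae, triplets, val, cfg, _seed(cfg, 1))
    state.accept(dcae, err, "phase0", 1)

    # ---- x-phase: deepen the x-side
    for depth in range(2, cfg.max_depth + 1):
        current: DCAEModel = state.best_model
        codes = nn._forward_chain(current.x_encoder, X)[-1]
        codes_val = nn._forward_chain(current.x_encoder, Xv)[-1]
        hy_dim = current.link[-1].out_dim
        width = cfg.code_width or max(cfg.block.init_width, codes.shape[1])
        # step 1: incremental AE learns a deeper code of p(x)
        blk_cfg = _block_cfg(cfg, _seed(cfg, 100 * depth), init_width=width,
                             overcomplete=False)
        new_ae, ae_rates, _ = run_incremental((codes,), blk_cfg, conditional=False,
                                              val_data=(codes_val,))
        # step 2: incremental CAE warm-started from it re-links (h_x, c) -> h_y.
        # The x-phase runs before the y-phase, so the y-side decoder is empty
        # and h_y is the output itself: the link targets are the true curves.
        hy, hy_val = Y, Yv
        rng = np.random.default_rng(_seed(cfg, 100 * depth + 1))
        warm = CAEModel(
            encoder=[copy_model(l) for l in new_ae.encoder_layers],
            decoder=[copy_model(l) for l in new_ae.decoder_layers],
            supervised_head=[glorot_init(new_ae.hidden_dim + 1, hy_dim, rng)],
        )
        warm_rates = nn.AlraoRates(
            ae_rates.eta_min, ae_rates.eta_max,
            [r.copy() for r in ae_rates.per_unit[:2]]
            + [np.exp(rng.uniform(np.log(ae_rates.eta_min),
                                  np.log(ae_rates.eta_max), hy_dim))],
        )
        blk_cfg = _block_cfg(cfg, _seed(cfg, 100 * depth + 2))
        link_cae, _, _ = run_incremental(
            (codes, C, hy), blk_cfg, conditional=True,
            val_data=(codes_val, Cv, hy_val), warm_start=(warm, warm_rates))
        candidate = DCAEModel(
            x_encoder=[copy_model(l) for l in current.x_encoder]
            + [copy_model(l) for l in link_cae.encoder],
            x_decoder=[copy_model(l) for l in link_cae.decoder]
            + [copy_model(l) for l in current.x_decoder],
            link=[copy_model(l) for l in link_cae.supervised_head],
            y_decoder=[copy_model(l) for l in current.y_decoder],
        )
        candidate, cand_err = _finetune_dcae(candidate, triplets, val, cfg,
                                             _seed(cfg, 100 * depth + 3))
        if cand_err < state.best_error:
            state.accept(candidate, cand_err, "x-phase", depth)
        else:
            state.reject(cand_err, "x-phase", depth)
            break

    # ---- y-phase: deepen the y-side decoder
    y_encoders: list = []   # auxiliary stack producing h_y targets from Y
    for depth in range(1, cfg.max_depth + 1):
        current = state.best_model
        ycodes = nn._forward_chain(y_encoders, Y)[-1] if y_encoders else Y
        ycodes_val = nn._forward_chain(y_encoders, Yv)[-1] if y_encoders else Yv
        width = cfg.code_width or max(cfg.block.init_width, ycodes.shape[1])
        blk_cfg = _block_cfg(cfg, _seed(cfg, 1000 * depth), init_width=width,
                             overcomplete=False)
        new_ae, _, _ = run_incremental((ycodes,), blk_cfg, conditional=False,
                                       val_data=(ycodes_val,))
        # deeper code targets for the link
        hy_new = new_ae.encode(ycodes)
        hy_new_val = new_ae.encode(ycodes_val)
        codes = nn._forward_chain(current.x_encoder, X)[-1]
        codes_val = nn._forward_chain(current.x_encoder, Xv)[-1]
        rng = np.random.default_rng(_seed(cfg, 1000 * depth + 1))
        new_link = [glorot_init(codes.shape[1] + 1, new_ae.hidden_dim, rng)]
        link_rates = nn.sample_alrao([new_ae.hidden_dim], *cfg.finetune_eta, rng)
        tc = TrainConfig(batch_size=cfg.block.batch_size,
                         max_epochs=cfg.finetune_epochs,
                         patience=cfg.finetune_patience, lambda_sparsity=0.0,
                         rng_seed=_seed(cfg, 1000 * depth + 2))

        class _LinkObj:
            """Supervised-only training of the new link layer."""

            def __call__(self, layers, batch):
                Xb, Cb, Tb = batch
                out = nn._forward_chain(layers.encoder_layers, np.concatenate(
                    [Xb, Cb[:, None]], axis=1))[-1]
                return nn.mse(out, Tb)

            def value_and_grads(self, layers, batch):
                Xb, Cb, Tb = batch
                inp = np.concatenate([Xb, Cb[:, None]], axis=1)
                acts = nn._forward_chain(layers.encoder_layers, inp)
                out = acts[-1]
                dOut = 2.0 * (out - Tb) / Tb.size
                grads, _ = nn._backward_chain(layers.encoder_layers, acts, dOut)
                return nn.mse(out, Tb), grads

        holder = AEModel(encoder_layers=new_link,
                         decoder_layers=[glorot_init(new_ae.hidden_dim, 1, rng)])
        # only the encoder (the link layer) is trained by the objective; the
        # placeholder decoder receives zero gradients
        obj = _LinkObj()

        def _vg(model, batch, _o=obj):
            J, g = _o.value_and_grads(model, batch)
            return J, g + [(np.zeros_like(model.decoder_layers[0].W),
                            np.zeros_like(model.decoder_layers[0].b))]

        wrapped = lambda model, batch, _o=obj: _o(model, batch)  # noqa: E731
        wrapped.value_and_grads = _vg
        # the placeholder decoder's rate is never used: its gradients are zero
        all_rates = nn.AlraoRates(link_rates.eta_min, link_rates.eta_max,
                                  link_rates.per_unit + [np.full(1, link_rates.eta_min)])
        holder, _ = nn.sgd_fit(holder, (codes, C, hy_new), wrapped, all_rates, tc,
                               val_data=(codes_val, Cv, hy_new_val))
        candidate = DCAEModel(
            x_encoder=[copy_model(l) for l in current.x_encoder],
            x_decoder=[copy_model(l) for l in current.x_decoder],
            link=[copy_model(l) for l in holder.encoder_layers],
            y_decoder=[copy_model(l) for l in new_ae.decoder_layers]
            + [copy_model(l) for l in current.y_decoder],
        )
        candidate, cand_err = _finetune_dcae(candidate, triplets, val, cfg,
                                             _seed(cfg, 1000 * depth + 3))
        if cand_err < state.best_error:
            state.accept(candidate, cand_err, "y-phase", depth)
            y_encoders = y_encoders + [copy_model(l) for l in new_ae.encoder_layers]
        else:
            state.reject(cand_err, "y-phase", depth)
            break

    return copy_model(state.best_model), state
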