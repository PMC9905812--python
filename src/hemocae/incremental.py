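"""Incremental width optimization of a single AE or CAE.

The algorithm jointly adjusts parameters and the hidden-layer width in a
quasi-autonomous loop:

* **Initialization** -- an overcomplete single-hidden-layer model; the two
  ALRAO learning-rate bounds are chosen by a short grid search over
  order-of-magnitude pairs, then the model is trained on the full training
  base with early stopping.
* **Joint training** -- one epoch of mini-batch gradient descent per
  iteration, each unit using its own log-uniform learning rate.
* **Growth (underfitting)** -- when the training cost on the poorly
  discriminated subset ``B`` (samples whose cost exceeds the mean cost)
  stagnates while validation is still improving, a single hidden unit is
  added and trained for one epoch on ``B`` with every other parameter
  frozen; its rate is drawn within the ALRAO bounds.
* **Pruning (overfitting)** -- when validation keeps rising while training
  keeps falling, the per-unit activation degrees (mean ``|h|`` over the
  validation set) are clustered with affinity propagation; the cluster with
  the lowest-activation exemplar is deleted (``1 <= dM <= L-1``), and the
  deletion is reverted bitwise unless validation does not degrade.
* **Early stopping** -- the loop halts once validation has not improved for
  ``patience`` iterations; the best snapshot is returned.

For conditional models (CAEs) the code ``h`` depends only on ``x``, so
over/underfit detection uses the unsupervised reconstruction task, while
the stopping criterion and the selection of ``B`` use the hybrid cost.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation

from .exceptions import DataError, ParameterError
from . import nn
from .nn import AEModel, AlraoRates, CAEModel, copy_model, glorot_init

__all__ = [
    "IncrementalConfig",
    "IncrementalState",
    "init_incremental",
    "select_subset_B",
    "add_unit",
    "activation_degrees",
    "affinity_propagation",
    "prune_units",
    "run_incremental",
    "default_eta_grid",
]


def default_eta_grid() -> list[tuple[float, float]]:
    """Order-of-magnitude pairs ``(10^a, 10^b)`` with ``a < b``."""
    exps = [-2, -1, 0, 1]
    return [(10.0**a, 10.0**b) for i, a in enumerate(exps) for b in exps[i + 1:]]


@dataclass
class IncrementalConfig:
    """Knobs of the incremental loop (defaults chosen for curve data)."""

    init_width: int = 32
    eta_grid: list[tuple[float, float]] = field(default_factory=default_eta_grid)
    grid_epochs: int = 100         # short run per grid candidate
    init_epochs: int = 1000        # completion of training after the grid search
    max_iterations: int = 200      # outer-loop iterations (one epoch each)
    patience: int = 25
    window: int = 12               # stagnation window for the underfit trigger
    improve_tol: float = 0.01      # <1% relative improvement counts as stagnant
    batch_size: int = 32
    lambda_sparsity: float = 1e-5
    damping: float = 0.7
    ap_max_iter: int = 200
    rng_seed: int = 0
    require_overcomplete: bool = True

    def __post_init__(self):
        if not self.eta_grid:
            raise ParameterError("eta_grid must be non-empty")
        if self.init_width < 1 or self.patience < 1 or self.window < 1:
            raise ParameterError("invalid IncrementalConfig")


@dataclass
class IncrementalState:
    """Mutable state of one incremental run."""

    model: AEModel | CAEModel
    rates: AlraoRates
    conditional: bool
    history: list = field(default_factory=list)
    best_model: AEModel | CAEModel | None = None
    best_rates: AlraoRates | None = None
    best_error: float = np.inf
    iteration: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def snapshot_if_better(self, val_error: float) -> bool:
        if val_error < self.best_error:
            self.best_error = val_error
            self.best_model = copy_model(self.model)
            self.best_rates = copy.deepcopy(self.rates)
            return True
        return False

    @property
    def width(self) -> int:
        return self.model.hidden_dim


# --------------------------------------------------------------------------
# per-sample costs
# --------------------------------------------------------------------------

def _per_sample_cost(model, data, lam: float, conditional: bool,
                     supervised: bool = True) -> np.ndarray:
    """Per-sample cost; hybrid for conditional models unless ``supervised=False``."""
    if conditional:
        X, C, Y = data
        H, R, Yhat = model.forward(X, C)
        cost = np.mean((R - X) ** 2, axis=1)
        if supervised:
            cost = cost + np.mean((Yhat - Y) ** 2, axis=1)
    else:
        (X,) = data[:1]
        H, R = model.forward(X)
        cost = np.mean((R - X) ** 2, axis=1)
    return cost + lam * np.sum(np.abs(H), axis=1)


def _total_cost(model, data, lam, conditional, supervised=True) -> float:
    return float(np.mean(_per_sample_cost(model, data, lam, conditional, supervised)))


def _objective(cfg: IncrementalConfig, conditional: bool):
    if conditional:
        return nn.cae_objective(lam=cfg.lambda_sparsity, regularized=True)
    return nn.ae_objective(lam=cfg.lambda_sparsity)


def _build_model(input_dim, width, out_dim, conditional, rng):
    if conditional:
        return CAEModel(
            encoder=[glorot_init(input_dim, width, rng)],
            decoder=[glorot_init(width, input_dim, rng)],
            supervised_head=[glorot_init(width + 1, out_dim, rng)],
        )
    return AEModel([glorot_init(input_dim, width, rng)],
                   [glorot_init(width, input_dim, rng)])


# --------------------------------------------------------------------------
# spec operations
# --------------------------------------------------------------------------

def select_subset_B(per_sample_losses: np.ndarray) -> np.ndarray:
    """Indices of poorly discriminated samples: loss strictly above the mean."""
    losses = np.asarray(per_sample_losses, float)
    if losses.size == 0:
        raise DataError("select_subset_B: empty losses")
    return np.flatnonzero(losses > losses.mean())


def activation_degrees(model, X: np.ndarray) -> np.ndarray:
    """Mean absolute code activation per hidden unit over ``X``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.size == 0:
        raise DataError("activation_degrees: empty data")
    if isinstance(model, CAEModel):
        H = nn._forward_chain(model.encoder, X)[-1]
    else:
        H = model.encode(X)
    return np.mean(np.abs(H), axis=0)


def affinity_propagation(points: np.ndarray, damping: float = 0.7,
                         max_iter: int = 200):
    """Cluster scalars by affinity propagation.

    Similarity is the negative squared distance and the shared preference is
    the median similarity, so the number of clusters is data-driven.
    Returns ``(labels, exemplar_indices, converged)``; on non-convergence
    the result is flagged and collapsed to a single cluster.
    """
    pts = np.asarray(points, float).ravel()
    n = pts.size
    if n == 0:
        raise ParameterError("affinity_propagation: need at least one point")
    if n == 1 or np.ptp(pts) == 0:
        return np.zeros(n, int), np.array([0]), True
    # exact duplicates make the message passing oscillate; cluster the
    # distinct values and propagate labels back
    uniq, inverse = np.unique(pts, return_inverse=True)
    if uniq.size == 1:
        return np.zeros(n, int), np.array([0]), True
    ap = AffinityPropagation(damping=damping, max_iter=max_iter, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels_u = ap.fit_predict(uniq.reshape(-1, 1))
    if np.any(labels_u < 0) or len(ap.cluster_centers_indices_) == 0:
        return np.zeros(n, int), np.array([int(np.argmin(pts))]), False
    exemplars = np.array([int(np.flatnonzero(pts == uniq[u])[0])
                          for u in ap.cluster_centers_indices_])
    return labels_u[inverse], exemplars, True


def _grow_arrays(model, rng, conditional):
    """Append one hidden unit; returns index masks of the new parameters."""
    enc = model.encoder[0] if conditional else model.encoder_layers[0]
    dec = model.decoder[0] if conditional else model.decoder_layers[0]
    bound_in = np.sqrt(6.0 / (enc.in_dim + enc.out_dim + 1))
    enc.W = np.vstack([enc.W, rng.uniform(-bound_in, bound_in, (1, enc.in_dim))])
    enc.b = np.append(enc.b, 0.0)
    bound_out = np.sqrt(6.0 / (dec.in_dim + 1 + dec.out_dim))
    dec.W = np.hstack([dec.W, rng.uniform(-bound_out, bound_out, (dec.out_dim, 1))])
    if conditional:
        head = model.supervised_head[0]
        bh = np.sqrt(6.0 / (head.in_dim + 1 + head.out_dim))
        newcol = rng.uniform(-bh, bh, (head.out_dim, 1))
        # the condition stays in the last column of the head input
        head.W = np.hstack([head.W[:, :-1], newcol, head.W[:, -1:]])


def add_unit(state: IncrementalState, B: np.ndarray, data: tuple,
             cfg: IncrementalConfig) -> IncrementalState:
    """Grow the hidden layer by one unit and train it for one epoch on ``B``.

    All pre-existing parameters are frozen during that epoch; the new
    unit's learning rate is drawn log-uniformly within the ALRAO bounds.
    Empty ``B`` is a warned no-op.
    """
    B = np.asarray(B, int)
    if B.size == 0:
        warnings.warn("add_unit: empty subset B, nothing to train the unit on")
        return state
    model, rng = state.model, state.rng
    conditional = state.conditional
    old = copy_model(model)
    _grow_arrays(model, rng, conditional)
    new_rate = float(np.exp(rng.uniform(np.log(state.rates.eta_min),
                                        np.log(state.rates.eta_max))))
    # rates vectors are aligned with model.layers(): encoder, decoder, (head)
    pu = state.rates.per_unit
    pu[0] = np.append(pu[0], new_rate)

    obj = _objective(cfg, conditional)
    sub = tuple(a[B] for a in data)
    n = len(sub[0])
    order = rng.permutation(n)
    L = model.hidden_dim - 1  # index of the new unit
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        batch = tuple(a[idx] for a in sub)
        _, grads = obj.value_and_grads(model, batch)
        enc_g, dec_g = grads[0], grads[1]
        layers = model.layers()
        layers[0].W[L, :] -= new_rate * enc_g[0][L, :]
        layers[0].b[L] -= new_rate * enc_g[1][L]
        layers[1].W[:, L] -= new_rate * dec_g[0][:, L]
        if conditional:
            head_g = grads[2]
            layers[2].W[:, L] -= new_rate * head_g[0][:, L]
    # freeze contract: everything except the new unit's parameters is intact
    assert np.array_equal(old.layers()[0].W, model.layers()[0].W[:L, :])
    state.history.append({"iteration": state.iteration, "action": "grow",
                          "width": model.hidden_dim, "rate": new_rate,
                          "subset_size": int(B.size)})
    return state


def _delete_units(model, rates: AlraoRates, units: np.ndarray, conditional: bool):
    keep = np.setdiff1d(np.arange(model.hidden_dim), units)
    enc = model.encoder[0] if conditional else model.encoder_layers[0]
    dec = model.decoder[0] if conditional else model.decoder_layers[0]
    enc.W = enc.W[keep, :]
    enc.b = enc.b[keep]
    dec.W = dec.W[:, keep]
    if conditional:
        head = model.supervised_head[0]
        head.W = np.hstack([head.W[:, :-1][:, keep], head.W[:, -1:]])
    rates.per_unit[0] = rates.per_unit[0][keep]


def prune_units(state: IncrementalState, val_data: tuple,
                cfg: IncrementalConfig | None = None) -> IncrementalState:
    """Delete the lowest-activation affinity-propagation cluster if harmless.

    The number of deleted units dM satisfies ``1 <= dM <= L-1``.  The
    validation cost is measured before and after; if it strictly increases
    the deletion is reverted bitwise.  A width-1 model is a no-op.
    """
    cfg = cfg or IncrementalConfig()
    model = state.model
    L = model.hidden_dim
    if L < 2:
        state.history.append({"iteration": state.iteration, "action": "prune_skipped",
                              "reason": "width 1"})
        return state
    Xv = val_data[0]
    degrees = activation_degrees(model, Xv)
    labels, exemplars, converged = affinity_propagation(
        degrees, damping=cfg.damping, max_iter=cfg.ap_max_iter)
    worst = exemplars[np.argmin(degrees[exemplars])]
    units = np.flatnonzero(labels == labels[worst])
    if units.size >= L:  # dM is bounded by L-1: spare the strongest unit
        units = units[units != int(np.argmax(degrees))][: L - 1]
    if units.size == 0:
        state.history.append({"iteration": state.iteration,
                              "action": "prune_skipped", "reason": "empty cluster"})
        return state

    before_model = copy_model(model)
    before_rates = copy.deepcopy(state.rates)
    err_before = _total_cost(model, val_data, cfg.lambda_sparsity, state.conditional)
    _delete_units(model, state.rates, units, state.conditional)
    err_after = _total_cost(model, val_data, cfg.lambda_sparsity, state.conditional)
    if err_after > err_before:
        state.model = before_model
        state.rates = before_rates
        state.history.append({"iteration": state.iteration, "action": "prune_reverted",
                              "delta_m": int(units.size),
                              "val_before": err_before, "val_after": err_after})
    else:
        state.history.append({"iteration": state.iteration, "action": "prune",
                              "delta_m": int(units.size), "width": state.model.hidden_dim,
                              "val_before": err_before, "val_after": err_after,
                              "ap_converged": bool(converged)})
    return state


# --------------------------------------------------------------------------
# initialization and main loop
# --------------------------------------------------------------------------

def init_incremental(data: tuple, cfg: IncrementalConfig,
                     val_data: tuple | None = None,
                     conditional: bool = False,
                     warm_start: tuple | None = None) -> IncrementalState:
    """Grid-search the ALRAO bounds, then complete training on the full base.

    Each candidate pair of bounds gets its own freshly initialized model and
    a short training run; the winner (lowest validation cost) is kept and
    its training is completed on the entire learning base with early
    stopping -- the grid run is part of initialization, not thrown away.

    ``warm_start=(model, rates)`` reuses a previously trained model instead:
    the grid search and the overcompleteness requirement are skipped (the
    prior model's width and rate bounds are trusted) and training is simply
    completed on the full base.
    """
    X = data[0]
    input_dim = X.shape[1]
    obj = _objective(cfg, conditional)
    val = val_data if val_data is not None else data

    if warm_start is not None:
        model, rates = copy_model(warm_start[0]), copy.deepcopy(warm_start[1])
        emin, emax = rates.eta_min, rates.eta_max
    else:
        if cfg.require_overcomplete and cfg.init_width < input_dim:
            raise ParameterError(
                f"init_width {cfg.init_width} < input dim {input_dim}: "
                "the initial architecture must be overcomplete")
        out_dim = data[2].shape[1] if conditional else input_dim
        best, best_score = None, np.inf
        for k, (emin, emax) in enumerate(cfg.eta_grid):
            if not (0 <= emin <= emax):
                raise ParameterError("eta grid entries must satisfy 0 <= min <= max")
            rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, k)))
            model = _build_model(input_dim, cfg.init_width, out_dim, conditional, rng)
            if emin == 0.0 and emax == 0.0:  # degenerate candidate: frozen model
                rates = nn.constant_rates(model, 0.0)
            else:
                rates = nn.rates_for_model(model, emin, emax, rng)
            tc = nn.TrainConfig(batch_size=cfg.batch_size, max_epochs=cfg.grid_epochs,
                                patience=max(cfg.grid_epochs, 1),
                                lambda_sparsity=cfg.lambda_sparsity, rng_seed=cfg.rng_seed)
            trained, _ = nn.sgd_fit(model, data, obj, rates, tc)
            score = _total_cost(trained, val, cfg.lambda_sparsity, conditional)
            if score < best_score:
                best_score, best = score, (trained, rates, (emin, emax))
        model, rates, (emin, emax) = best
    tc = nn.TrainConfig(batch_size=cfg.batch_size, max_epochs=cfg.init_epochs,
                        patience=cfg.patience, lambda_sparsity=cfg.lambda_sparsity,
                        rng_seed=cfg.rng_seed)

    def val_cost(m, _vd):
        return _total_cost(m, val, cfg.lambda_sparsity, conditional)

    model, _ = nn.sgd_fit(model, data, obj, rates, tc, val_data=val, val_score=val_cost)
    state = IncrementalState(model=model, rates=rates, conditional=conditional,
                             rng=np.random.default_rng(
                                 np.random.SeedSequence((cfg.rng_seed, 999979))))
    err = val_cost(model, None)
    state.history.append({"iteration": 0, "action": "init", "eta_min": emin,
                          "eta_max": emax, "width": model.hidden_dim,
                          "val_error": err})
    state.snapshot_if_better(err)
    return state


def _train_one_epoch(state: IncrementalState, data: tuple, cfg: IncrementalConfig):
    obj = _objective(cfg, state.conditional)
    n = len(data[0])
    order = state.rng.permutation(n)
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        batch = tuple(a[idx] for a in data)
        _, grads = obj.value_and_grads(state.model, batch)
        nn._apply_update(state.model, grads, state.rates)


def run_incremental(data: tuple, cfg: IncrementalConfig,
                    conditional: bool = False,
                    val_data: tuple | None = None,
                    warm_start: tuple | None = None):
    """Full incremental loop; returns ``(model, rates, history)``.

    ``data``/``val_data`` are ``(X,)`` for plain AEs or ``(X, C, Y)`` for
    conditional models.  The returned model is the best validation
    snapshot observed during the run.
    """
    state = init_incremental(data, cfg, val_data=val_data, conditional=conditional,
                             warm_start=warm_start)
    val = val_data if val_data is not None else data
    lam = cfg.lambda_sparsity

    # unsupervised traces drive the overfit trigger; the cost on the poorly
    # discriminated subset B drives the underfit (growth) trigger
    train_unsup = [_total_cost(state.model, data, lam, conditional, supervised=False)]
    val_unsup = [_total_cost(state.model, val, lam, conditional, supervised=False)]
    b_trace: list[float] = []
    stale = 0
    last_improved = 0
    last_structural = 0

    for it in range(1, cfg.max_iterations + 1):
        state.iteration = it
        _train_one_epoch(state, data, cfg)
        losses = _per_sample_cost(state.model, data, lam, conditional)
        train_err = float(losses.mean())
        val_err = _total_cost(state.model, val, lam, conditional)
        B = select_subset_B(losses)
        b_trace.append(float(losses[B].mean()) if B.size else 0.0)
        train_unsup.append(_total_cost(state.model, data, lam, conditional, False))
        val_unsup.append(_total_cost(state.model, val, lam, conditional, False))
        improved = state.snapshot_if_better(val_err)
        if improved:
            stale, last_improved = 0, it
        else:
            stale += 1
        state.history.append({"iteration": it, "action": "epoch",
                              "train_error": train_err, "val_error": val_err,
                              "width": state.width})
        if stale >= cfg.patience:
            state.history.append({"iteration": it, "action": "early_stop"})
            break

        overfit_k = max(cfg.patience // 2, 2)
        recent_v = val_unsup[-(overfit_k + 1):]
        recent_t = train_unsup[-(overfit_k + 1):]
        overfitting = (len(recent_v) == overfit_k + 1
                       and all(b > a for a, b in zip(recent_v, recent_v[1:]))
                       and recent_t[-1] < recent_t[0])
        w = cfg.window
        # stagnation is judged only on iterations since the last grow/prune:
        # a fresh unit needs a full window before its effect is measurable
        stagnant = False
        if len(b_trace) > w and (it - last_structural) > w:
            prev, cur = b_trace[-w - 1], b_trace[-1]
            stagnant = prev > 0 and (prev - cur) / prev < cfg.improve_tol
        val_not_rising = (it - last_improved) < w

        if overfitting and state.width >= 2:
            prune_units(state, val, cfg)
            last_structural = it
        elif stagnant and val_not_rising and B.size:
            add_unit(state, B, data, cfg)
            last_structural = it

    state.model = copy_model(state.best_model)
    state.rates = copy.deepcopy(state.best_rates)
    return state.model, state.rates, state.history
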