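"""scikit-learn style estimators wrapping the hemocae training machinery.

All regressors share one data convention so they compose with sklearn
pipelines and model selection: ``X`` is an array of shape ``(n, T + 1)``
whose first ``T`` columns are the pre-treatment curve and whose last
column is the normalized dose ``c``; ``y`` has shape ``(n, T)`` and holds
the post-treatment curve.  ``TripletDataset.sklearn_arrays`` produces
these directly.

Validation data for early stopping can be passed explicitly to ``fit``
(``X_val``, ``y_val``); otherwise a group-aware (or plain random) fraction
of the training data is held out.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.model_selection import GroupShuffleSplit, ShuffleSplit
from sklearn.utils.validation import check_array, check_is_fitted

from . import nn
from .deep import DeepConfig, run_cond_incremental
from .exceptions import ParameterError
from .gan import GanConfig, generator_predict, train_cgan
from .incremental import IncrementalConfig, run_incremental
from .nn import CAEModel, TrainConfig, glorot_init, mean_nrmse
from .pretrain import PretrainConfig, conditional_pretrain

__all__ = [
    "ConditionalAutoencoderRegressor",
    "IncrementalCAERegressor",
    "PretrainedDCAERegressor",
    "IncrementalDCAERegressor",
    "IncrementalAutoencoder",
    "ConditionalGANRegressor",
    "split_Xc",
]


def split_Xc(X):
    """Split the packed design matrix into (curves, doses)."""
    X = check_array(X, dtype=float)
    if X.shape[1] < 2:
        raise ParameterError("X must pack at least one curve sample and a dose")
    return X[:, :-1], X[:, -1]


def _holdout(X, y, groups, val_fraction, seed):
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=1, test_size=val_fraction,
                                     random_state=seed)
        tr, va = next(splitter.split(X, y, groups))
    else:
        splitter = ShuffleSplit(n_splits=1, test_size=val_fraction,
                                random_state=seed)
        tr, va = next(splitter.split(X))
    return tr, va


class _CurveRegressorBase(BaseEstimator, RegressorMixin):
    """Shared fit plumbing: validation handling and packed-X convention."""

    def _triplets(self, X, y):
        Xc, C = split_Xc(X)
        y = check_array(y, dtype=float)
        if y.shape[0] != Xc.shape[0]:
            raise ParameterError("X and y row counts differ")
        return Xc, C, y

    def _resolve_val(self, X, y, X_val, y_val, groups):
        if (X_val is None) != (y_val is None):
            raise ParameterError("pass X_val and y_val together")
        if X_val is not None:
            return (X, y), (X_val, y_val)
        seed = getattr(self, "random_state", 0) or 0
        tr, va = _holdout(X, y, groups, self.val_fraction, seed)
        return (X[tr], y[tr]), (X[va], y[va])

    def predict(self, X):
        check_is_fitted(self, "model_")
        Xc, C = split_Xc(X)
        return self._predict_curves(Xc, C)

    def nrmse_score(self, X, y):
        """Mean per-curve NRMSE of the predictions (lower is better)."""
        return mean_nrmse(check_array(y, dtype=float), self.predict(X))


class ConditionalAutoencoderRegressor(_CurveRegressorBase):
    """Fixed-topology conditional autoencoder trained on the hybrid cost.

    A single-hidden-layer CAE: the code depends on the curve alone, the
    dose is concatenated to the code inside the supervised head.  Training
    is mini-batch SGD with per-unit log-uniform (ALRAO) learning rates and
    early stopping on validation NRMSE.
    """

    def __init__(self, hidden_dim=64, lambda_sparsity=1e-5, eta_min=1.0,
                 eta_max=10.0, max_epochs=300, patience=20, batch_size=32,
                 val_fraction=0.15, random_state=0):
        self.hidden_dim = hidden_dim
        self.lambda_sparsity = lambda_sparsity
        self.eta_min = eta_min
        self.eta_max = eta_max
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        (Xt, yt), (Xv, yv) = self._resolve_val(np.asarray(X, float),
                                               np.asarray(y, float),
                                               X_val, y_val, groups)
        Xc, C, Y = self._triplets(Xt, yt)
        Xcv, Cv, Yv = self._triplets(Xv, yv)
        rng = np.random.default_rng(self.random_state)
        model = CAEModel(
            encoder=[glorot_init(Xc.shape[1], self.hidden_dim, rng)],
            decoder=[glorot_init(self.hidden_dim, Xc.shape[1], rng)],
            supervised_head=[glorot_init(self.hidden_dim + 1, Y.shape[1], rng)],
        )
        rates = nn.rates_for_model(model, self.eta_min, self.eta_max, rng)
        cfg = TrainConfig(batch_size=self.batch_size, max_epochs=self.max_epochs,
                          patience=self.patience,
                          lambda_sparsity=self.lambda_sparsity,
                          rng_seed=self.random_state)

        def score(m, _vd):
            return mean_nrmse(Yv, m.forward(Xcv, Cv)[2])

        self.model_, self.history_ = nn.sgd_fit(
            model, (Xc, C, Y), nn.cae_objective(lam=self.lambda_sparsity),
            rates, cfg, val_data=(Xcv, Cv, Yv), val_score=score)
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_curves(self, Xc, C):
        return self.model_.forward(Xc, C)[2]


class IncrementalCAERegressor(_CurveRegressorBase):
    """Conditional autoencoder with incremental width optimization.

    Wraps the quasi-autonomous loop: ALRAO bound grid search, joint
    training, one-unit growth on the poorly discriminated subset, and
    validated affinity-propagation pruning.
    """

    def __init__(self, init_width=64, grid_epochs=60, init_epochs=400,
                 max_iterations=100, patience=15, lambda_sparsity=1e-5,
                 batch_size=32, val_fraction=0.15, random_state=0):
        self.init_width = init_width
        self.grid_epochs = grid_epochs
        self.init_epochs = init_epochs
        self.max_iterations = max_iterations
        self.patience = patience
        self.lambda_sparsity = lambda_sparsity
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _config(self):
        return IncrementalConfig(
            init_width=self.init_width, grid_epochs=self.grid_epochs,
            init_epochs=self.init_epochs, max_iterations=self.max_iterations,
            patience=self.patience, lambda_sparsity=self.lambda_sparsity,
            batch_size=self.batch_size, rng_seed=self.random_state)

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        (Xt, yt), (Xv, yv) = self._resolve_val(np.asarray(X, float),
                                               np.asarray(y, float),
                                               X_val, y_val, groups)
        train = self._triplets(Xt, yt)
        val = self._triplets(Xv, yv)
        self.model_, self.rates_, self.history_ = run_incremental(
            train, self._config(), conditional=True, val_data=val)
        self.width_ = self.model_.hidden_dim
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_curves(self, Xc, C):
        return self.model_.forward(Xc, C)[2]


class PretrainedDCAERegressor(_CurveRegressorBase):
    """Deep conditional autoencoder initialized by conditional pre-training.

    The x- and y-side stacks are pre-trained greedily, the conditional
    link CAE is trained on their codes, all parameters are copied into the
    DCAE and fine-tuned jointly without the sparsity term.
    """

    def __init__(self, x_dims=(64, 32), y_dims=(32,), lambda_sparsity=1e-5,
                 eta_min=1.0, eta_max=10.0, max_epochs=200, patience=15,
                 batch_size=32, val_fraction=0.15, random_state=0):
        self.x_dims = x_dims
        self.y_dims = y_dims
        self.lambda_sparsity = lambda_sparsity
        self.eta_min = eta_min
        self.eta_max = eta_max
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        (Xt, yt), (Xv, yv) = self._resolve_val(np.asarray(X, float),
                                               np.asarray(y, float),
                                               X_val, y_val, groups)
        train = self._triplets(Xt, yt)
        val = self._triplets(Xv, yv)
        cfg = PretrainConfig(
            base=TrainConfig(batch_size=self.batch_size,
                             max_epochs=self.max_epochs, patience=self.patience,
                             lambda_sparsity=self.lambda_sparsity,
                             rng_seed=self.random_state),
            eta_min=self.eta_min, eta_max=self.eta_max)
        self.model_, self.history_ = conditional_pretrain(
            train, list(self.x_dims), list(self.y_dims), cfg, val=val)
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_curves(self, Xc, C):
        return self.model_.predict(Xc, C)


class IncrementalDCAERegressor(_CurveRegressorBase):
    """DCAE optimized by the conditional incremental depth search."""

    def __init__(self, init_width=64, code_width=48, max_depth=3,
                 grid_epochs=60, init_epochs=400, max_iterations=100,
                 patience=15, finetune_epochs=150, lambda_sparsity=1e-5,
                 batch_size=32, val_fraction=0.15, random_state=0):
        self.init_width = init_width
        self.code_width = code_width
        self.max_depth = max_depth
        self.grid_epochs = grid_epochs
        self.init_epochs = init_epochs
        self.max_iterations = max_iterations
        self.patience = patience
        self.finetune_epochs = finetune_epochs
        self.lambda_sparsity = lambda_sparsity
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        (Xt, yt), (Xv, yv) = self._resolve_val(np.asarray(X, float),
                                               np.asarray(y, float),
                                               X_val, y_val, groups)
        train = self._triplets(Xt, yt)
        val = self._triplets(Xv, yv)
        block = IncrementalConfig(
            init_width=self.init_width, grid_epochs=self.grid_epochs,
            init_epochs=self.init_epochs, max_iterations=self.max_iterations,
            patience=self.patience, lambda_sparsity=self.lambda_sparsity,
            batch_size=self.batch_size, rng_seed=self.random_state)
        cfg = DeepConfig(block=block, max_depth=self.max_depth,
                         finetune_epochs=self.finetune_epochs,
                         finetune_patience=self.patience,
                         code_width=self.code_width)
        self.model_, self.search_ = run_cond_incremental(train, cfg, val_data=val)
        self.topology_ = {
            "x_encoder": [l.out_dim for l in self.model_.x_encoder],
            "link": [l.out_dim for l in self.model_.link],
            "y_decoder": [l.out_dim for l in self.model_.y_decoder],
        }
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_curves(self, Xc, C):
        return self.model_.predict(Xc, C)


class IncrementalAutoencoder(BaseEstimator, TransformerMixin):
    """Plain autoencoder with incremental width optimization.

    ``transform`` returns the learned code, ``inverse_transform`` decodes
    it back to the input space.
    """

    def __init__(self, init_width=32, grid_epochs=100, init_epochs=1000,
                 max_iterations=200, patience=25, lambda_sparsity=1e-5,
                 batch_size=32, val_fraction=0.15, random_state=0):
        self.init_width = init_width
        self.grid_epochs = grid_epochs
        self.init_epochs = init_epochs
        self.max_iterations = max_iterations
        self.patience = patience
        self.lambda_sparsity = lambda_sparsity
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y=None, X_val=None, groups=None):
        X = check_array(np.asarray(X, float))
        if X_val is None:
            tr, va = _holdout(X, None, groups, self.val_fraction,
                              self.random_state or 0)
            Xt, Xv = X[tr], X[va]
        else:
            Xt, Xv = X, check_array(np.asarray(X_val, float))
        cfg = IncrementalConfig(
            init_width=self.init_width, grid_epochs=self.grid_epochs,
            init_epochs=self.init_epochs, max_iterations=self.max_iterations,
            patience=self.patience, lambda_sparsity=self.lambda_sparsity,
            batch_size=self.batch_size, rng_seed=self.random_state)
        self.model_, self.rates_, self.history_ = run_incremental(
            (Xt,), cfg, conditional=False, val_data=(Xv,))
        self.width_ = self.model_.hidden_dim
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "model_")
        return self.model_.encode(check_array(np.asarray(X, float)))

    def inverse_transform(self, H):
        check_is_fitted(self, "model_")
        return self.model_.decode(check_array(np.asarray(H, float)))


class ConditionalGANRegressor(_CurveRegressorBase):
    """Conditional GAN baseline behind the same estimator interface."""

    def __init__(self, noise_dim=8, g_hidden=64, d_hidden=64, epochs=200,
                 batch_size=32, lr=2.0, val_fraction=0.15, random_state=0):
        self.noise_dim = noise_dim
        self.g_hidden = g_hidden
        self.d_hidden = d_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None, groups=None):
        (Xt, yt), (Xv, yv) = self._resolve_val(np.asarray(X, float),
                                               np.asarray(y, float),
                                               X_val, y_val, groups)
        cfg = GanConfig(noise_dim=self.noise_dim, g_hidden=self.g_hidden,
                        d_hidden=self.d_hidden, epochs=self.epochs,
                        batch_size=self.batch_size, lr=self.lr,
                        rng_seed=self.random_state)
        self.result_ = train_cgan(self._triplets(Xt, yt), cfg,
                                  val_data=self._triplets(Xv, yv))
        self.model_ = self.result_.generator
        self.mode_collapse_ = self.result_.mode_collapse
        self.n_features_in_ = X.shape[1]
        return self

    def _predict_curves(self, Xc, C):
        return generator_predict(self.result_, Xc, C)
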