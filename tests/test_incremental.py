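"""Incremental width optimization: subset B, growth, AP pruning, main loop."""

import numpy as np
import pytest

from hemocae import nn
from hemocae.exceptions import ParameterError
from hemocae.incremental import (
    IncrementalConfig,
    IncrementalState,
    activation_degrees,
    add_unit,
    affinity_propagation,
    init_incremental,
    prune_units,
    run_incremental,
    select_subset_B,
)
from hemocae.nn import AEModel, LayerParams, glorot_init, mean_nrmse

from conftest import latent_factor_data


class TestSubsetB:
    @pytest.mark.parametrize("losses, expected", [
        ([1, 1, 1, 9], [3]),
        ([2, 2, 2], []),
        ([0, 10], [1]),
    ])
    def test_strictly_above_mean(self, losses, expected):
        assert list(select_subset_B(np.array(losses, float))) == expected

    def test_empty_losses_rejected(self):
        with pytest.raises(Exception):
            select_subset_B(np.array([]))


class TestActivationDegrees:
    def test_dead_linear_unit_has_zero_degree(self):
        enc = LayerParams(np.array([[1.0, 0.0], [0.0, 0.0]]), np.zeros(2),
                          "linear")
        dec = LayerParams(np.ones((2, 2)), np.zeros(2), "linear")
        ae = AEModel([enc], [dec])
        X = np.random.default_rng(0).uniform(0, 1, (20, 2))
        degrees = activation_degrees(ae, X)
        assert degrees[1] == 0.0
        assert degrees[0] > 0.0

    def test_hand_computed_degrees(self):
        enc = LayerParams(np.eye(2), np.zeros(2), "linear")
        ae = AEModel([enc], [LayerParams(np.eye(2), np.zeros(2), "linear")])
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert np.allclose(activation_degrees(ae, X), [1.0, 0.0])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        ae = AEModel([glorot_init(3, 4, rng)], [glorot_init(4, 3, rng)])
        X = rng.uniform(0, 1, (30, 3))
        d1 = activation_degrees(ae, X)
        d2 = activation_degrees(ae, X[::-1])
        assert np.allclose(d1, d2)


def oracle_affinity_propagation(points, damping=0.7, iters=500):
    """Independent scalar affinity-propagation (plain message passing)."""
    x = np.asarray(points, float)
    n = len(x)
    S = -(x[:, None] - x[None, :]) ** 2
    pref = np.median(S[~np.eye(n, dtype=bool)])
    np.fill_diagonal(S, pref)
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    for _ in range(iters):
        AS = A + S
        idx = np.argsort(AS, axis=1)
        first, second = AS[np.arange(n), idx[:, -1]], AS[np.arange(n), idx[:, -2]]
        Rn = S - first[:, None]
        Rn[np.arange(n), idx[:, -1]] = S[np.arange(n), idx[:, -1]] - second
        R = damping * R + (1 - damping) * Rn
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        An = np.minimum(0, Rp.sum(axis=0)[None, :] - Rp)
        np.fill_diagonal(An, Rp.sum(axis=0) - Rp.diagonal())
        A = damping * A + (1 - damping) * An
    exemplars = np.flatnonzero((A + R).diagonal() > 0)
    labels = np.argmax(S[:, exemplars], axis=1)
    labels[exemplars] = np.arange(len(exemplars))
    return labels, exemplars


class TestAffinityPropagation:
    def test_single_point(self):
        labels, exemplars, ok = affinity_propagation(np.array([0.4]))
        assert list(labels) == [0] and list(exemplars) == [0] and ok

    def test_two_well_separated_pairs_match_oracle(self):
        pts = np.array([0.0, 0.01, 5.0, 5.01])
        labels, exemplars, ok = affinity_propagation(pts)
        o_labels, o_exemplars = oracle_affinity_propagation(pts)
        assert ok
        # same partition: pairs {0,1} and {2,3}
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert o_labels[0] == o_labels[1] and o_labels[2] == o_labels[3]
        assert o_labels[0] != o_labels[2]

    def test_identical_points_collapse_to_one_cluster(self):
        labels, exemplars, ok = affinity_propagation(np.zeros(6))
        assert len(set(labels)) == 1 and ok


def planted_state(n_dead=8, n_live=8, d=6, seed=0):
    """Linear AE with informative units and exactly-dead (zero in/out) units."""
    rng = np.random.default_rng(seed)
    L = n_dead + n_live
    Wenc = np.zeros((L, d))
    Wenc[:n_live] = rng.uniform(0.5, 1.5, (n_live, d))
    Wdec = np.zeros((d, L))
    Wdec[:, :n_live] = rng.uniform(-1, 1, (d, n_live))
    ae = AEModel([LayerParams(Wenc, np.zeros(L), "linear")],
                 [LayerParams(Wdec, np.zeros(d), "linear")])
    rates = nn.AlraoRates(0.1, 1.0, [np.full(L, 0.5), np.full(d, 0.5)])
    return IncrementalState(model=ae, rates=rates, conditional=False,
                            rng=np.random.default_rng(seed))


class TestGrow:
    def _state(self, seed=0):
        rng = np.random.default_rng(seed)
        ae = AEModel([glorot_init(4, 5, rng)], [glorot_init(5, 4, rng)])
        rates = nn.sample_alrao([5, 4], 0.5, 5.0, rng)
        return IncrementalState(model=ae, rates=rates, conditional=False,
                                rng=np.random.default_rng(seed + 1))

    def test_width_increments_by_one_and_freeze_contract(self):
        state = self._state()
        before = nn.copy_model(state.model)
        X = np.random.default_rng(2).uniform(0, 1, (30, 4))
        B = np.arange(10)
        add_unit(state, B, (X,), IncrementalConfig())
        assert state.model.hidden_dim == 6
        # pre-existing parameters are bitwise unchanged
        assert np.array_equal(before.encoder_layers[0].W,
                              state.model.encoder_layers[0].W[:5])
        assert np.array_equal(before.decoder_layers[0].W,
                              state.model.decoder_layers[0].W[:, :5])
        new_rate = state.rates.per_unit[0][-1]
        assert 0.5 <= new_rate <= 5.0

    def test_empty_subset_is_warned_noop(self):
        state = self._state(1)
        before = nn.copy_model(state.model)
        with pytest.warns(UserWarning):
            add_unit(state, np.array([], int),
                     (np.zeros((4, 4)),), IncrementalConfig())
        assert nn.models_equal(state.model, before)

    def test_conditional_growth_keeps_condition_column(self):
        rng = np.random.default_rng(3)
        cae = nn.CAEModel([glorot_init(4, 5, rng)], [glorot_init(5, 4, rng)],
                          [glorot_init(6, 3, rng)])
        rates = nn.sample_alrao([5, 4, 3], 0.5, 5.0, rng)
        state = IncrementalState(model=cae, rates=rates, conditional=True,
                                 rng=np.random.default_rng(4))
        head_before = cae.supervised_head[0].W.copy()
        X = rng.uniform(0, 1, (20, 4))
        C = rng.uniform(0, 1, 20)
        Y = rng.uniform(0, 1, (20, 3))
        add_unit(state, np.arange(5), (X, C, Y), IncrementalConfig())
        head = state.model.supervised_head[0].W
        assert head.shape == (3, 7)
        # dose column preserved as the last input of the head
        assert np.array_equal(head[:, -1], head_before[:, -1])


class TestPrune:
    def test_width_one_is_noop(self):
        rng = np.random.default_rng(0)
        ae = AEModel([glorot_init(3, 1, rng)], [glorot_init(1, 3, rng)])
        state = IncrementalState(model=ae,
                                 rates=nn.AlraoRates(0.1, 1, [np.ones(1) * 0.5,
                                                              np.ones(3) * 0.5]),
                                 conditional=False)
        before = nn.copy_model(ae)
        prune_units(state, (np.random.default_rng(1).uniform(0, 1, (10, 3)),))
        assert nn.models_equal(state.model, before)

    def test_planted_dead_units_are_removed_harmlessly(self):
        state = planted_state()
        X = np.random.default_rng(5).uniform(0, 1, (40, 6))
        _, R_before = state.model.forward(X)
        err_before = nn.mse(R_before, X)
        prune_units(state, (X,))
        assert state.model.hidden_dim == 8  # exactly the dead cluster removed
        _, R_after = state.model.forward(X)
        assert abs(nn.mse(R_after, X) - err_before) < 1e-12
        assert state.history[-1]["action"] == "prune"

    def test_harmful_prune_is_reverted_bitwise(self):
        # every unit informative: removing any cluster hurts validation
        rng = np.random.default_rng(6)
        ae = AEModel([glorot_init(6, 4, rng)], [glorot_init(4, 6, rng)])
        X = rng.uniform(0, 1, (50, 6))
        # train briefly so units matter
        rates = nn.rates_for_model(ae, 1.0, 5.0, rng)
        cfg = nn.TrainConfig(batch_size=10, max_epochs=150, patience=150,
                             rng_seed=0, lambda_sparsity=0.0)
        ae, _ = nn.sgd_fit(ae, (X,), nn.ae_objective(0.0), rates, cfg)
        state = IncrementalState(model=ae, rates=rates, conditional=False,
                                 rng=np.random.default_rng(7))
        before = nn.copy_model(state.model)
        prune_units(state, (X,))
        last = state.history[-1]
        if last["action"] == "prune_reverted":
            assert nn.models_equal(state.model, before)
        else:  # an accepted prune must not have hurt validation
            assert last["val_after"] <= last["val_before"]


class TestInit:
    def _data(self):
        return (latent_factor_data(120, draw_seed=3),), (latent_factor_data(40, draw_seed=4),)

    def test_single_pair_grid_selects_it(self):
        data, val = self._data()
        cfg = IncrementalConfig(init_width=12, eta_grid=[(1.0, 10.0)],
                                grid_epochs=5, init_epochs=5, rng_seed=0)
        state = init_incremental(data, cfg, val_data=val)
        assert state.history[0]["eta_min"] == 1.0
        assert state.history[0]["eta_max"] == 10.0

    def test_undercomplete_init_rejected(self):
        data, val = self._data()
        cfg = IncrementalConfig(init_width=4, grid_epochs=2, init_epochs=2)
        with pytest.raises(ParameterError):
            init_incremental(data, cfg, val_data=val)

    def test_zero_rate_pair_never_wins(self):
        data, val = self._data()
        cfg = IncrementalConfig(init_width=12, eta_grid=[(0.0, 0.0), (1.0, 10.0)],
                                grid_epochs=20, init_epochs=5, rng_seed=0)
        state = init_incremental(data, cfg, val_data=val)
        assert (state.history[0]["eta_min"], state.history[0]["eta_max"]) == (1.0, 10.0)


class TestRunIncremental:
    def test_deterministic_given_seed(self, factor_data):
        Xtr, Xv = factor_data
        cfg = IncrementalConfig(init_width=12, grid_epochs=10, init_epochs=40,
                                max_iterations=20, patience=6, rng_seed=5)
        m1, r1, h1 = run_incremental((Xtr,), cfg, val_data=(Xv,))
        m2, r2, h2 = run_incremental((Xtr,), cfg, val_data=(Xv,))
        assert nn.models_equal(m1, m2)
        assert h1 == h2

    def test_returns_best_snapshot(self, factor_data):
        Xtr, Xv = factor_data
        cfg = IncrementalConfig(init_width=12, grid_epochs=10, init_epochs=40,
                                max_iterations=30, patience=8, rng_seed=2)
        model, _, history = run_incremental((Xtr,), cfg, val_data=(Xv,))
        init_err = history[0]["val_error"]
        epochs = [h for h in history if h["action"] == "epoch"]
        best_seen = min([init_err] + [h["val_error"] for h in epochs])
        from hemocae.incremental import _total_cost
        final_err = _total_cost(model, (Xv,), cfg.lambda_sparsity, False)
        assert final_err == pytest.approx(best_seen)

    def test_width_changes_bounded_per_iteration(self, factor_data):
        Xtr, Xv = factor_data
        cfg = IncrementalConfig(init_width=12, grid_epochs=10, init_epochs=40,
                                max_iterations=40, patience=10, window=4,
                                rng_seed=3)
        _, _, history = run_incremental((Xtr,), cfg, val_data=(Xv,))
        width = 12
        for h in history:
            if h["action"] == "grow":
                assert h["width"] == width + 1
                width = h["width"]
            elif h["action"] == "prune":
                assert 1 <= h["delta_m"] <= width - 1
                width = h["width"]

    def test_recovers_low_rank_structure(self, factor_data):
        Xtr, Xv = factor_data
        cfg = IncrementalConfig(init_width=16, rng_seed=0)
        model, _, _ = run_incremental((Xtr,), cfg, val_data=(Xv,))
        assert mean_nrmse(Xv, model.forward(Xv)[1]) < 0.05
        assert model.hidden_dim <= 16
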