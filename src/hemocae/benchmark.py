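"""Benchmark harness: five optimization approaches plus a GAN baseline.

The protocol compares, on one dataset and over several seeded reruns:

1. incremental CAE optimization (width + rates, quasi-autonomous);
2. random-search over simple CAEs, budget-matched to approach 1;
3. conditional incremental optimization of a DCAE (depth + width + rates);
4. random-search over DCAE topologies, Glorot-initialized, trained on the
   regularized hybrid cost, budget-matched to approach 3;
5. random-search over DCAE topologies, conditionally pre-trained, trained
   on the unregularized cost, budget-matched to approach 3;
gan. a conditional GAN trained once per rerun.

Budgets are either wall-clock seconds (matched to the measured duration of
the incremental reference approach, as in a live comparison) or trial
counts (hardware-independent, reproducible).  Errors are prediction NRMSE
on the train and test splits; summaries are mean +- std over reruns.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError
from . import nn
from .curves import TripletDataset
from .deep import DeepConfig, run_cond_incremental
from .gan import GanConfig, generator_predict, train_cgan
from .incremental import IncrementalConfig, run_incremental
from .nn import CAEModel, DCAEModel, TrainConfig, glorot_init, mean_nrmse
from .pretrain import PretrainConfig, conditional_pretrain

__all__ = [
    "ApproachSpec",
    "BenchmarkResult",
    "default_search_space",
    "run_approach",
    "run_benchmark",
    "report",
]

VALID_APPROACHES = ("1", "2", "3", "4", "5", "gan")


def default_search_space() -> dict:
    """Random-search space spanning under- and overcomplete regimes."""
    return {
        "widths": [int(w) for w in np.unique(np.geomspace(8, 256, 10).astype(int))],
        "depths": [1, 2, 3, 4],
        "lambdas": [0.0] + list(np.geomspace(1e-5, 1e-2, 4)),
        "eta_bounds": (1e-2, 1e1),
        "epochs": 150,
        "patience": 15,
    }


@dataclass
class ApproachSpec:
    """One benchmarked approach.

    ``budget`` is a number of random-search trials (``budget_mode="trials"``)
    or seconds (``budget_mode="seconds"``); for the incremental approaches
    it is ignored.  Approach 4 mandates Glorot init + regularized cost,
    approach 5 conditional pre-training + unregularized cost.
    """

    id: str
    search_space: dict = field(default_factory=default_search_space)
    budget: float = 5
    budget_mode: str = "trials"
    init: str = "glorot"
    objective: str = "regularized"
    incremental: IncrementalConfig = field(default_factory=IncrementalConfig)
    deep: DeepConfig = field(default_factory=DeepConfig)
    gan: GanConfig = field(default_factory=GanConfig)

    def __post_init__(self):
        self.id = str(self.id)
        if self.id not in VALID_APPROACHES:
            raise ParameterError(f"unknown approach id {self.id!r}")
        if self.budget <= 0:
            raise ParameterError("budget must be > 0")
        if self.budget_mode not in ("trials", "seconds"):
            raise ParameterError("budget_mode must be 'trials' or 'seconds'")
        if self.id == "4":
            self.init, self.objective = "glorot", "regularized"
        elif self.id == "5":
            self.init, self.objective = "conditional_pretrain", "unregularized"


@dataclass
class BenchmarkResult:
    """Raw per-rerun errors and recomputable summaries."""

    approach: str
    train_errors: list = field(default_factory=list)
    test_errors: list = field(default_factory=list)
    durations: list = field(default_factory=list)
    topologies: list = field(default_factory=list)

    @property
    def n_reruns(self) -> int:
        return len(self.test_errors)

    def summary(self) -> dict:
        tr = np.asarray(self.train_errors, float)
        te = np.asarray(self.test_errors, float)
        return {
            "approach": self.approach,
            "n_reruns": self.n_reruns,
            "train_mean": float(tr.mean()), "train_std": float(tr.std()),
            "test_mean": float(te.mean()), "test_std": float(te.std()),
        }


def _splits(dataset: TripletDataset):
    return (dataset.arrays("train"), dataset.arrays("val"), dataset.arrays("test"))


def _errors(predict, train, test) -> tuple[float, float]:
    Xtr, Ctr, Ytr = train
    Xte, Cte, Yte = test
    return (mean_nrmse(Ytr, predict(Xtr, Ctr)), mean_nrmse(Yte, predict(Xte, Cte)))


def _seed_of(seed: int, k: int) -> int:
    return int(np.random.SeedSequence((seed, k)).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# individual approaches (one rerun each)
# --------------------------------------------------------------------------

def _run_a1(spec, train, val, test, seed):
    cfg = copy.deepcopy(spec.incremental)
    cfg.rng_seed = seed
    model, _, _ = run_incremental(train, cfg, conditional=True, val_data=val)
    tr, te = _errors(lambda X, C: model.forward(X, C)[2], train, test)
    return tr, te, {"width": model.hidden_dim}


def _run_a3(spec, train, val, test, seed):
    cfg = copy.deepcopy(spec.deep)
    cfg.block = copy.deepcopy(spec.incremental)
    cfg.block.rng_seed = seed
    model, state = run_cond_incremental(train, cfg, val_data=val)
    tr, te = _errors(model.predict, train, test)
    topo = {"x_enc": [l.out_dim for l in model.x_encoder],
            "y_dec": [l.out_dim for l in model.y_decoder],
            "accepted": state.accepted}
    return tr, te, topo


def _sample_cae_trial(space, input_dim, output_dim, rng):
    width = int(rng.choice(space["widths"]))
    lam = float(rng.choice(space["lambdas"]))
    lo, hi = space["eta_bounds"]
    pair = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), 2)))
    return width, lam, (float(pair[0]), float(pair[1]))


def _budget_loop(spec, trial_fn, seed):
    """Run trials under the configured budget; returns best-val trial result.

    A diverging trial counts against the budget but is discarded; if every
    trial diverges the loop keeps drawing until one survives.
    """
    from .exceptions import DivergenceError

    best = None
    t0 = time.monotonic()
    k = 0
    while True:
        if best is not None:
            if spec.budget_mode == "trials" and k >= int(spec.budget):
                break
            if (spec.budget_mode == "seconds"
                    and k > 0 and (time.monotonic() - t0) >= spec.budget):
                break
        try:
            out = trial_fn(_seed_of(seed, k), k)
        except DivergenceError:
            out = None
        if out is not None and (best is None or out["val"] < best["val"]):
            best = out
        k += 1
    return best, k


def _run_a2(spec, train, val, test, seed):
    X, C, Y = train
    space = spec.search_space

    def trial(trial_seed, k):
        rng = np.random.default_rng(trial_seed)
        width, lam, (emin, emax) = _sample_cae_trial(space, X.shape[1], Y.shape[1], rng)
        model = CAEModel(
            encoder=[glorot_init(X.shape[1], width, rng)],
            decoder=[glorot_init(width, X.shape[1], rng)],
            supervised_head=[glorot_init(width + 1, Y.shape[1], rng)],
        )
        rates = nn.rates_for_model(model, emin, emax, rng)
        tc = TrainConfig(batch_size=32, max_epochs=space["epochs"],
                         patience=space["patience"], lambda_sparsity=lam,
                         rng_seed=trial_seed)

        def score(m, _vd):
            Xv, Cv, Yv = val
            return mean_nrmse(Yv, m.forward(Xv, Cv)[2])

        model, _ = nn.sgd_fit(model, train, nn.cae_objective(lam=lam), rates, tc,
                              val_data=val, val_score=score)
        return {"val": score(model, None), "model": model,
                "topo": {"width": width, "lambda": lam, "eta": (emin, emax)}}

    best, k = _budget_loop(spec, trial, seed)
    model = best["model"]
    tr, te = _errors(lambda Xq, Cq: model.forward(Xq, Cq)[2], train, test)
    return tr, te, {**best["topo"], "trials": k}


def _sample_dcae_dims(space, input_dim, output_dim, rng):
    dx = int(rng.choice(space["depths"]))
    dy = int(rng.choice(space["depths"])) - 1
    x_dims = [int(rng.choice(space["widths"])) for _ in range(dx)]
    y_dims = [int(rng.choice(space["widths"])) for _ in range(max(dy, 0))]
    return x_dims, y_dims


def _build_random_dcae(x_dims, y_dims, input_dim, output_dim, rng):
    enc, dec = [], []
    prev = input_dim
    for w in x_dims:
        enc.append(glorot_init(prev, w, rng))
        prev = w
    for w in list(reversed(x_dims[:-1])) + [input_dim]:
        dec.append(glorot_init(prev, w, rng))
        prev = w
    hx = x_dims[-1]
    hy = y_dims[-1] if y_dims else output_dim
    link = [glorot_init(hx + 1, hy, rng)]
    ydec = []
    prev = hy
    for w in list(reversed(y_dims[:-1])) + ([output_dim] if y_dims else []):
        ydec.append(glorot_init(prev, w, rng))
        prev = w
    return DCAEModel(x_encoder=enc, x_decoder=dec, link=link, y_decoder=ydec)


def _run_random_dcae(spec, train, val, test, seed):
    X, C, Y = train
    space = spec.search_space
    pretrained = spec.init == "conditional_pretrain"

    def trial(trial_seed, k):
        rng = np.random.default_rng(trial_seed)
        x_dims, y_dims = _sample_dcae_dims(space, X.shape[1], Y.shape[1], rng)
        lam = float(rng.choice(space["lambdas"]))
        lo, hi = space["eta_bounds"]
        pair = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), 2)))
        emin, emax = float(pair[0]), float(pair[1])

        def score(m, _vd):
            Xv, Cv, Yv = val
            return mean_nrmse(Yv, m.predict(Xv, Cv))

        if pretrained:
            pcfg = PretrainConfig(
                base=TrainConfig(batch_size=32,
                                 max_epochs=max(space["epochs"] // 3, 1),
                                 patience=space["patience"],
                                 lambda_sparsity=lam if lam > 0 else 1e-5,
                                 rng_seed=trial_seed),
                eta_min=emin, eta_max=emax)
            model, _ = conditional_pretrain(train, x_dims, y_dims or [Y.shape[1]],
                                            pcfg, val=val, finetune=False)
            objective = nn.dcae_objective(regularized=False)
        else:
            model = _build_random_dcae(x_dims, y_dims, X.shape[1], Y.shape[1], rng)
            objective = nn.dcae_objective(lam=lam, regularized=True)
        rates = nn.rates_for_model(model, emin, emax, rng)
        tc = TrainConfig(batch_size=32, max_epochs=space["epochs"],
                         patience=space["patience"], lambda_sparsity=lam,
                         rng_seed=trial_seed)
        model, _ = nn.sgd_fit(model, train, objective, rates, tc,
                              val_data=val, val_score=score)
        return {"val": score(model, None), "model": model,
                "topo": {"x_dims": x_dims, "y_dims": y_dims, "lambda": lam,
                         "eta": (emin, emax)}}

    best, k = _budget_loop(spec, trial, seed)
    model = best["model"]
    tr, te = _errors(model.predict, train, test)
    return tr, te, {**best["topo"], "trials": k}


def _run_gan(spec, train, val, test, seed):
    cfg = copy.deepcopy(spec.gan)
    cfg.rng_seed = seed
    res = train_cgan(train, cfg, val_data=val)
    tr, te = _errors(lambda X, C: generator_predict(res, X, C), train, test)
    return tr, te, {"mode_collapse": res.mode_collapse}


_RUNNERS = {"1": _run_a1, "2": _run_a2, "3": _run_a3,
            "4": _run_random_dcae, "5": _run_random_dcae, "gan": _run_gan}


def run_approach(spec: ApproachSpec, dataset: TripletDataset,
                 seeds: list[int]) -> BenchmarkResult:
    """Run one approach once per seed; returns the collected errors."""
    train, val, test = _splits(dataset)
    result = BenchmarkResult(approach=spec.id)
    runner = _RUNNERS[spec.id]
    for seed in seeds:
        t0 = time.monotonic()
        tr, te, topo = runner(spec, train, val, test, int(seed))
        result.durations.append(time.monotonic() - t0)
        result.train_errors.append(tr)
        result.test_errors.append(te)
        result.topologies.append(topo)
    return result


def run_benchmark(dataset: TripletDataset, approaches: list[ApproachSpec],
                  seeds: list[int],
                  match_budgets: bool = True) -> dict[str, BenchmarkResult]:
    """Run several approaches on one dataset with shared rerun seeds.

    In seconds mode with ``match_budgets``, the random-search budgets are
    set to the measured mean duration of the corresponding incremental
    approach (2 matches 1; 4 and 5 match 3), as in a live head-to-head.
    """
    by_id = {spec.id: spec for spec in approaches}
    results: dict[str, BenchmarkResult] = {}
    order = [s for s in ("1", "3") if s in by_id] + \
            [s for s in by_id if s not in ("1", "3")]
    for aid in order:
        spec = by_id[aid]
        if (match_budgets and spec.budget_mode == "seconds"
                and aid in ("2", "4", "5")):
            ref = {"2": "1", "4": "3", "5": "3"}[aid]
            if ref in results and results[ref].durations:
                spec.budget = float(np.mean(results[ref].durations))
        results[aid] = run_approach(spec, dataset, seeds)
    return results


def report(results: dict[str, BenchmarkResult]) -> tuple[str, dict]:
    """Format a results table (mean +- std, scientific notation) + JSON dict.

    Returns ``(text_table, machine_readable)``; the latter also carries the
    raw per-rerun errors for box plots.
    """
    if not results:
        raise ParameterError("report: no results")

    def sci(x: float) -> str:
        m, e = f"{x:.2e}".split("e")
        return f"{m}e{int(e):+d}"

    lines = [f"{'Approach':<10} {'Learning error':<22} {'Test error':<22}"]
    payload = {}
    for aid in sorted(results, key=lambda s: (s.isdigit() is False, s)):
        r = results[aid]
        s = r.summary()
        lines.append(
            f"n.{aid:<8} "
            f"{sci(s['train_mean'])} ± {sci(s['train_std']):<10} "
            f"{sci(s['test_mean'])} ± {sci(s['test_std']):<10}")
        payload[aid] = {**s,
                        "raw_train": list(map(float, r.train_errors)),
                        "raw_test": list(map(float, r.test_errors)),
                        "durations_s": list(map(float, r.durations))}
    return "\n".join(lines), payload


def save_report(results: dict[str, BenchmarkResult], path: str) -> None:
    _, payload = report(results)
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def desk_scale_protocol(data_seed: int = 1):
    """Reduced-scale study configuration for desk-scale reproduction.

    Short curves (T=60), 20/6/6 plasmas with 8 doses each, trial-count
    budgets and tightened epoch caps so the whole five-approach protocol
    runs on one CPU in minutes.  Returns ``(dataset, specs)``; reruns are
    expected to use ten seeds.
    """
    from .curves import generate_dataset

    dataset = generate_dataset(n_plasmas=(20, 6, 6), doses_per_plasma=8,
                               T=60, rng_seed=data_seed)
    block = IncrementalConfig(init_width=64, grid_epochs=40, init_epochs=250,
                              max_iterations=60, patience=12)
    deep = DeepConfig(block=block, max_depth=3, finetune_epochs=120,
                      finetune_patience=12, code_width=48)
    space = default_search_space()
    space.update(epochs=800, patience=40, eta_bounds=(1e-2, 3e1))
    specs = [
        ApproachSpec("1", incremental=block),
        ApproachSpec("2", search_space=space, budget=5),
        ApproachSpec("3", incremental=block, deep=deep),
        ApproachSpec("4", search_space=space, budget=5),
        ApproachSpec("5", search_space=space, budget=5),
        ApproachSpec("gan", gan=GanConfig(epochs=150)),
    ]
    return dataset, specs
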