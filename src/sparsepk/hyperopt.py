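"""Hyperparameter search over the LSTM-ANN architecture and training space.

Two samplers are provided: independent random search and a tree-structured
Parzen estimator (TPE).  TPE splits previous trials into a "good" fraction
(lowest objective, here final-epoch training MSE) and the rest, models each
hyperparameter's density in both groups with Parzen (Gaussian-kernel)
mixtures, draws candidates from the good density and keeps the candidate
with the highest good/bad density ratio — the standard expected-improvement
surrogate for this family of samplers.

Unpromising trials can be terminated early by a successive-halving style
pruner: training loss is reported per epoch, and at rung epochs (10, 20,
40, 80) a trial whose loss is above the median of previously recorded losses
at that rung is stopped.  A trial can never be pruned before epoch 10.

Searchable space (fixed everywhere: ReLU activations, Adam, batch size 1,
time steps 2, dropout 0.1):

============================  ==============
number of LSTM+dropout blocks 1-3
LSTM nodes                    8-256
number of dense+dropout blocks 1-3
dense nodes per block         8-256
learning rate (log-uniform)   0.0001-0.001
epochs                        40-120
============================  ==============
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, FitError, InputError
from .lstm_ann import ArchitectureSpec, TrainConfig, build_model, train

_MAX_DENSE = 3


@dataclass
class HyperparamSpace:
    """Bounds of the searchable hyperparameters."""

    n_lstm_blocks: tuple[int, int] = (1, 3)
    lstm_nodes: tuple[int, int] = (8, 256)
    n_dense_blocks: tuple[int, int] = (1, 3)
    ann_nodes: tuple[int, int] = (8, 256)
    learning_rate: tuple[float, float] = (0.0001, 0.001)
    epochs: tuple[int, int] = (40, 120)

    def validate(self) -> None:
        for name in ("n_lstm_blocks", "lstm_nodes", "n_dense_blocks",
                     "ann_nodes", "learning_rate", "epochs"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name}: lower bound exceeds upper")

    def dimensions(self):
        """(name, low, high, is_int, is_log) tuples; dense widths are sampled
        independently per block."""
        dims = [
            ("n_lstm_blocks", *self.n_lstm_blocks, True, False),
            ("lstm_nodes", *self.lstm_nodes, True, False),
            ("n_dense_blocks", *self.n_dense_blocks, True, False),
        ]
        for k in range(_MAX_DENSE):
            dims.append((f"ann_nodes_{k}", *self.ann_nodes, True, False))
        dims.append(("learning_rate", *self.learning_rate, False, True))
        dims.append(("epochs", *self.epochs, True, False))
        return dims

    def contains(self, config: dict) -> bool:
        for name, lo, hi, is_int, _ in self.dimensions():
            v = config[name]
            if not lo <= v <= hi:
                return False
            if is_int and int(v) != v:
                return False
        return True


def config_to_specs(
    config: dict, seed: int = 0, time_steps: int = 2
) -> tuple[ArchitectureSpec, TrainConfig]:
    """Materialize a sampled point into architecture + training configs."""
    n_dense = int(config["n_dense_blocks"])
    arch = ArchitectureSpec(
        n_lstm_blocks=int(config["n_lstm_blocks"]),
        lstm_nodes=int(config["lstm_nodes"]),
        n_dense_blocks=n_dense,
        dense_nodes=tuple(int(config[f"ann_nodes_{k}"]) for k in range(n_dense)),
        time_steps=time_steps,
    )
    cfg = TrainConfig(
        learning_rate=float(config["learning_rate"]),
        epochs=int(config["epochs"]),
        seed=seed,
    )
    return arch, cfg


def config_parameter_count(config: dict) -> int:
    arch, _ = config_to_specs(config)
    return arch.parameter_count()


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------


class RandomSampler:
    """Independent uniform (log-uniform for the learning rate) sampling."""

    def __init__(self, space: HyperparamSpace, seed: int = 0):
        space.validate()
        self.space = space
        self.rng = np.random.default_rng(seed)

    def _draw_dim(self, lo, hi, is_int, is_log):
        if is_log:
            value = float(np.exp(self.rng.uniform(np.log(lo), np.log(hi))))
            return min(max(value, lo), hi)
        if is_int:
            return int(self.rng.integers(lo, hi + 1))
        return float(self.rng.uniform(lo, hi))

    def suggest(self, history) -> dict:
        return {
            name: self._draw_dim(lo, hi, is_int, is_log)
            for name, lo, hi, is_int, is_log in self.space.dimensions()
        }


class TPESampler(RandomSampler):
    """Univariate tree-structured Parzen estimator.

    The first ``n_startup`` suggestions are random.  Afterwards, per
    dimension, completed trials are split at the ``gamma`` quantile of the
    objective; ``n_candidates`` draws from the good-density mixture are
    scored by log l(x) - log g(x) and the best is kept.
    """

    def __init__(self, space, seed=0, n_startup=10, gamma=0.15, n_candidates=24):
        super().__init__(space, seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    @staticmethod
    def _adaptive_parzen(points, lo, hi):
        """Adaptive Parzen mixture: per-point bandwidths from neighbor gaps,
        plus a broad prior component at the range midpoint.

        Returns (centers, sigmas, weights); the prior keeps a full-range
        bandwidth so exploration never dies out as observations accumulate.
        """
        span = hi - lo
        pts = np.sort(np.asarray(points, float))
        prior_mu = 0.5 * (lo + hi)
        idx = np.searchsorted(pts, prior_mu)
        centers = np.insert(pts, idx, prior_mu)
        n = len(centers)
        if n == 1:
            sigmas = np.array([span])
        else:
            left = np.diff(centers, prepend=centers[0] - (centers[0] - lo))
            right = np.diff(centers, append=centers[-1] + (hi - centers[-1]))
            sigmas = np.maximum(left, right)
        sigmas = np.clip(sigmas, span / min(100.0, 1.0 + n), span)
        sigmas[idx] = span  # the prior component stays broad
        weights = np.full(n, 1.0 / n)
        return centers, sigmas, weights

    @staticmethod
    def _mixture_logpdf(x, centers, sigmas, weights):
        x = np.atleast_1d(x)
        z = (x[:, None] - centers[None, :]) / sigmas[None, :]
        kernel = np.exp(-0.5 * z * z) / (sigmas[None, :] * np.sqrt(2 * np.pi))
        dens = kernel @ weights
        return np.log(np.maximum(dens, 1e-300))

    def _tpe_dim(self, values, objectives, lo, hi, is_int, is_log):
        xs = np.asarray(values, float)
        ys = np.asarray(objectives, float)
        if is_log:
            xs, lo_t, hi_t = np.log(xs), np.log(lo), np.log(hi)
        else:
            lo_t, hi_t = float(lo), float(hi)
        order = np.argsort(ys, kind="stable")
        n_good = max(1, int(np.ceil(self.gamma * len(xs))))
        good, bad = xs[order[:n_good]], xs[order[n_good:]]
        if len(bad) == 0:
            bad = xs
        cg, sg, wg = self._adaptive_parzen(good, lo_t, hi_t)
        cb, sb, wb = self._adaptive_parzen(bad, lo_t, hi_t)
        comp = self.rng.choice(len(cg), size=self.n_candidates, p=wg)
        cands = cg[comp] + self.rng.normal(size=self.n_candidates) * sg[comp]
        cands = np.clip(cands, lo_t, hi_t)
        score = self._mixture_logpdf(cands, cg, sg, wg) - self._mixture_logpdf(
            cands, cb, sb, wb
        )
        best = cands[int(np.argmax(score))]
        if is_log:
            best = float(np.clip(np.exp(best), lo, hi))
        if is_int:
            best = int(np.clip(round(best), lo, hi))
        return best

    def suggest(self, history) -> dict:
        completed = [(c, o) for c, o in history if o is not None]
        if len(completed) < self.n_startup:
            return super().suggest(history)
        objectives = [o for _, o in completed]
        config = {}
        for name, lo, hi, is_int, is_log in self.space.dimensions():
            values = [c[name] for c, _ in completed]
            config[name] = self._tpe_dim(values, objectives, lo, hi, is_int, is_log)
        return config


# ---------------------------------------------------------------------------
# pruner
# ---------------------------------------------------------------------------


class HalvingPruner:
    """Median rule at doubling rung epochs; nothing pruned before epoch 10."""

    def __init__(self, rungs=(10, 20, 40, 80), min_records: int = 4):
        self.rungs = tuple(rungs)
        self.min_records = min_records
        self._records: dict[int, list[float]] = {r: [] for r in self.rungs}

    def report(self, epoch_index: int, loss: float) -> bool:
        """Record an intermediate loss; returns True if the trial should be
        pruned.  ``epoch_index`` is zero-based; rung r fires after r epochs."""
        completed_epochs = epoch_index + 1
        if completed_epochs not in self._records:
            return False
        prior = self._records[completed_epochs]
        prune = len(prior) >= self.min_records and loss > float(np.median(prior))
        prior.append(loss)
        return prune


# ---------------------------------------------------------------------------
# study
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    index: int
    config: dict
    objective: float | None  # final-epoch training MSE (scaled space)
    validation_rmse: float | None  # ng/mL
    pruned: bool
    seed: int
    duration: float
    partial_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        return cls(**d)


@dataclass
class StudyResult:
    trials: list[TrialRecord]
    sampler: str
    n_trials: int
    models: dict = field(default_factory=dict)  # index -> TrainedRegressor

    def completed(self) -> list[TrialRecord]:
        return [t for t in self.trials if not t.pruned and t.objective is not None]

    @property
    def best_by_objective(self) -> TrialRecord:
        done = self.completed()
        if not done:
            raise FitError("no completed trials")
        return min(done, key=lambda t: (t.objective, t.index))

    @property
    def best_by_validation_rmse(self) -> TrialRecord:
        done = [t for t in self.completed() if t.validation_rmse is not None]
        if not done:
            raise FitError("no completed trials with a validation RMSE")
        return min(
            done,
            key=lambda t: (
                t.validation_rmse,
                config_parameter_count(t.config),
                t.index,
            ),
        )


def _journal_append(path, record: TrialRecord) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(record.to_dict()) + "\n")


def load_study(journal_path, sampler: str = "tpe", n_trials: int | None = None):
    """Reconstruct a StudyResult from its append-only JSON-lines journal."""
    trials = []
    with open(journal_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trials.append(TrialRecord.from_dict(json.loads(line)))
    return StudyResult(trials=trials, sampler=sampler, n_trials=n_trials or len(trials))


def _training_evaluator(split, keep_model=True):
    """Default trial evaluator: really train the LSTM-ANN."""

    def evaluate(config, trial_seed, pruner):
        arch, cfg = config_to_specs(config, seed=trial_seed,
                                    time_steps=split.time_steps)
        model = build_model(arch, seed=trial_seed)
        pruned_flag = {"pruned": False}

        def callback(epoch, loss):
            if pruner is not None and pruner.report(epoch, loss):
                pruned_flag["pruned"] = True
                return False
            return True

        fitted = train(model, split, cfg, epoch_callback=callback)
        if pruned_flag["pruned"]:
            return None, None, True, fitted.history, None
        objective = fitted.history[-1]
        return objective, fitted.validation_rmse, False, fitted.history, (
            fitted if keep_model else None
        )

    return evaluate


def run_study(
    space: HyperparamSpace,
    split=None,
    sampler: str = "tpe",
    n_trials: int = 50,
    pruning: bool = True,
    seed: int = 0,
    journal_path=None,
    evaluator=None,
) -> StudyResult:
    """Run a hyperparameter study.

    Each trial samples a configuration (asserted to lie inside ``space``),
    evaluates it — by default by training the LSTM-ANN on ``split`` with
    per-epoch losses reported to the pruner — and records the final-epoch
    training MSE (the search objective) together with the validation RMSE.
    Reproducible given (seed, budget, data); resumable from the journal.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    space.validate()
    if evaluator is None:
        if split is None:
            raise InputError("run_study needs a SplitDataset or an evaluator")
        evaluator = _training_evaluator(split)
    sampler_cls = {"tpe": TPESampler, "random": RandomSampler}.get(sampler)
    if sampler_cls is None:
        raise ConfigurationError(f"sampler must be 'tpe' or 'random', got {sampler!r}")
    smp = sampler_cls(space, seed=seed)
    pruner = HalvingPruner() if pruning else None

    trials: list[TrialRecord] = []
    if journal_path is not None and Path(journal_path).exists():
        trials = load_study(journal_path, sampler, n_trials).trials
    models: dict[int, object] = {}
    history: list[tuple[dict, float | None]] = [
        (t.config, t.objective) for t in trials
    ]
    seed_rng = np.random.default_rng(seed + 1)
    trial_seeds = [int(seed_rng.integers(2**31)) for _ in range(n_trials)]

    for index in range(len(trials), n_trials):
        config = smp.suggest(history)
        assert space.contains(config), f"sampled config out of bounds: {config}"
        start = time.perf_counter()
        objective, val_rmse, pruned, partial, model = evaluator(
            config, trial_seeds[index], pruner
        )
        record = TrialRecord(
            index=index,
            config=config,
            objective=objective,
            validation_rmse=val_rmse,
            pruned=pruned,
            seed=trial_seeds[index],
            duration=time.perf_counter() - start,
            partial_history=list(partial or []),
        )
        trials.append(record)
        history.append((config, objective))
        if model is not None:
            models[index] = model
        if journal_path is not None:
            _journal_append(journal_path, record)

    study = StudyResult(trials=trials, sampler=sampler, n_trials=n_trials,
                        models=models)
    if not study.completed():
        raise FitError(
            "all trials were pruned or failed"
            + (f"; journal retained at {journal_path}" if journal_path else "")
        )
    return study


def select_final(study: StudyResult, split=None):
    """Final model = completed trial with the lowest validation RMSE.

    Ties break toward the smaller parameter count, then the earlier trial.
    If the winning trial's model is not held in memory (e.g. the study was
    reloaded from a journal), it is retrained deterministically from its
    recorded seed, which requires ``split``.
    """
    best = study.best_by_validation_rmse
    model = study.models.get(best.index)
    if model is None:
        if split is None:
            raise InputError(
                "winning trial's model not in memory; pass the SplitDataset "
                "to retrain it"
            )
        arch, cfg = config_to_specs(best.config, seed=best.seed,
                                    time_steps=split.time_steps)
        model = train(build_model(arch, seed=best.seed), split, cfg)
    return model, best


# ---------------------------------------------------------------------------
# deterministic surrogate objective (for sampler benchmarking)
# ---------------------------------------------------------------------------


def toy_objective(config: dict) -> float:
    """Smooth deterministic stand-in for the training loss.

    Separable quadratic bowl with its optimum strictly inside the search
    space; used to compare samplers without paying for real training runs.
    """
    lr_term = ((np.log10(config["learning_rate"]) + 3.6) / 0.5) ** 2
    node_term = ((config["lstm_nodes"] - 72) / 248.0) ** 2
    epoch_term = ((config["epochs"] - 80) / 80.0) ** 2
    depth_term = ((config["n_lstm_blocks"] - 2) / 2.0) ** 2
    dense_term = ((config["n_dense_blocks"] - 2) / 2.0) ** 2
    ann_term = sum(
        ((config[f"ann_nodes_{k}"] - 120) / 248.0) ** 2 for k in range(_MAX_DENSE)
    )
    return float(lr_term + node_term + epoch_term + depth_term + dense_term + ann_term)


def toy_evaluator(config, trial_seed, pruner):
    """Evaluator plugging :func:`toy_objective` into :func:`run_study`."""
    value = toy_objective(config)
    return value, value, False, [value], None
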