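"""Permutation importance of the static covariates for a trained regressor.

For covariate C, its column in the evaluation samples is randomly shuffled
(breaking its association with the outcome while preserving its marginal
distribution), predictions are recomputed, and the importance is the rise in
RMSE over the unpermuted baseline:

    PIMP_C = RMSE_Cp - RMSE        (ng/mL)

The shuffle is repeated ``n_reps`` times (default 10) with independent
derived seeds per (covariate, repetition); the report carries the mean and
standard deviation per covariate, ranked by descending mean importance.
One-hot race columns are permuted independently, like any other covariate,
so a permuted sample may transiently hold an invalid race combination — the
model only ever sees the columns as numbers.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .domain import COVARIATE_COLUMNS
from .exceptions import InputError
from .lstm_ann import TrainedRegressor, rmse
from .preprocessing import SequenceSample, invert_scaler, samples_to_arrays


@dataclass
class PIMPResult:
    """Per-covariate importance over repeated shuffles."""

    covariate: str
    importances: list[float]  # RMSE_Cp - RMSE per repetition, ng/mL
    baseline_rmse: float
    seed: int

    @property
    def n_reps(self) -> int:
        return len(self.importances)

    @property
    def mean(self) -> float:
        return float(np.mean(self.importances))

    @property
    def sd(self) -> float:
        if self.n_reps < 2:
            return 0.0  # single repetition: no spread to report
        return float(np.std(self.importances, ddof=1))


@dataclass
class PIMPReport:
    """All covariates, sorted by descending mean importance (ties by name)."""

    results: list[PIMPResult]
    partition: str
    baseline_rmse: float

    def sorted_results(self) -> list[PIMPResult]:
        return sorted(self.results, key=lambda r: (-r.mean, r.covariate))

    def to_json(self, path) -> None:
        payload = {
            "partition": self.partition,
            "baseline_rmse": self.baseline_rmse,
            "results": [
                {
                    "covariate": r.covariate,
                    "mean": r.mean,
                    "sd": r.sd,
                    "n_reps": r.n_reps,
                    "importances": r.importances,
                    "seed": r.seed,
                }
                for r in self.sorted_results()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["covariate", "mean", "sd", "n_reps"])
            for r in self.sorted_results():
                writer.writerow([r.covariate, r.mean, r.sd, r.n_reps])


def _covariate_index(name: str) -> int:
    if name not in COVARIATE_COLUMNS:
        raise InputError(
            f"unknown covariate {name!r}; valid names: {list(COVARIATE_COLUMNS)}"
        )
    return COVARIATE_COLUMNS.index(name)


def permute_covariate(samples, covariate_name: str, seed: int = 0):
    """Return new samples with one covariate column randomly permuted.

    All other columns, the dosing windows and the targets are untouched; the
    input list is not modified.
    """
    idx = _covariate_index(covariate_name)
    if len(samples) < 2:
        raise InputError("need at least 2 samples to permute")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    column = np.asarray([s.covariates[idx] for s in samples])
    out = []
    for i, s in enumerate(samples):
        cov = s.covariates.copy()
        cov[idx] = column[perm[i]]
        out.append(
            SequenceSample(
                dosing_window=s.dosing_window.copy(),
                covariates=cov,
                target=s.target,
                subject_id=s.subject_id,
            )
        )
    return out


def pimp(
    model: TrainedRegressor,
    samples,
    covariates=COVARIATE_COLUMNS,
    n_reps: int = 10,
    seed: int = 0,
    partition: str = "validation",
) -> PIMPReport:
    """Permutation-importance report for a trained regressor.

    The baseline RMSE is computed once on the ng/mL scale; each
    (covariate, repetition) pair uses an independent seed derived from
    ``seed`` so the full analysis is reproducible.
    """
    covariates = list(covariates)
    if not covariates:
        raise InputError("covariate list is empty")
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    for name in covariates:
        _covariate_index(name)

    _, _, y_scaled = samples_to_arrays(samples)
    observed = np.asarray(invert_scaler(y_scaled, model.scaler, "CONC"))
    baseline = rmse(observed, model.predict(samples))

    results = []
    for name in covariates:
        ci = _covariate_index(name)
        importances = []
        for r in range(n_reps):
            child_seed = np.random.SeedSequence([seed, ci, r])
            rep_seed = int(child_seed.generate_state(1)[0] % (2**31))
            permuted = permute_covariate(samples, name, seed=rep_seed)
            importances.append(
                rmse(observed, model.predict(permuted)) - baseline
            )
        results.append(
            PIMPResult(
                covariate=name,
                importances=importances,
                baseline_rmse=baseline,
                seed=seed,
            )
        )
    report = PIMPReport(
        results=sorted(results, key=lambda r: (-r.mean, r.covariate)),
        partition=partition,
        baseline_rmse=baseline,
    )
    return report
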