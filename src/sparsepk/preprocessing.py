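"""Data pipeline: pooling, chronological 70/30 split, min-max scaling, and
construction of the two model inputs (dosing sequence + static covariates).

The regressor downstream takes, per plasma sample, a short chronological
window of that subject's (time-since-first-dose, dose) records plus the
subject's 11 static covariates, and predicts the scaled concentration.
Scaling is plain min-max, ``x_scaled = (x - xmin) / (xmax - xmin)``, fitted
on the training partition only by default so validation rows may legitimately
fall outside [0, 1] and are never clipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .domain import COVARIATE_COLUMNS
from .exceptions import ConfigurationError, InputError
from .synthetic import read_dataset, write_dataset

logger = logging.getLogger(__name__)

#: Features transformed by the scaler, in canonical order (target last).
SCALED_COLUMNS = ("TSFD", "DOSE") + COVARIATE_COLUMNS + ("CONC",)


# ---------------------------------------------------------------------------
# scaler
# ---------------------------------------------------------------------------


@dataclass
class ScalerParams:
    """Per-feature (xmin, xmax) pairs, including the concentration target."""

    features: list[str]
    xmin: dict[str, float]
    xmax: dict[str, float]

    def constant_features(self) -> list[str]:
        return [f for f in self.features if self.xmax[f] == self.xmin[f]]

    def fingerprint(self) -> str:
        payload = json.dumps(
            [self.features, self.xmin, self.xmax], sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {"features": self.features, "xmin": self.xmin, "xmax": self.xmax}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            features=list(d["features"]),
            xmin={k: float(v) for k, v in d["xmin"].items()},
            xmax={k: float(v) for k, v in d["xmax"].items()},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ScalerParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_scaler(train_rows: pd.DataFrame, features=SCALED_COLUMNS) -> ScalerParams:
    """Record per-feature min/max from the given rows."""
    if len(train_rows) == 0:
        raise InputError("cannot fit a scaler on zero rows")
    xmin, xmax = {}, {}
    for f in features:
        col = train_rows[f].to_numpy(float)
        xmin[f] = float(col.min())
        xmax[f] = float(col.max())
        if xmin[f] == xmax[f]:
            logger.warning("feature %s is constant (=%s); will scale to 0", f, xmin[f])
    return ScalerParams(features=list(features), xmin=xmin, xmax=xmax)


def apply_scaler(rows: pd.DataFrame, scaler: ScalerParams) -> pd.DataFrame:
    """Min-max transform the scaler's features; other columns pass through.

    Values outside the training range map outside [0, 1] and are not
    clipped.  Constant features map to 0.
    """
    out = rows.copy()
    for f in scaler.features:
        span = scaler.xmax[f] - scaler.xmin[f]
        if span == 0:
            out[f] = 0.0
        else:
            out[f] = (rows[f].to_numpy(float) - scaler.xmin[f]) / span
    return out


def invert_scaler(scaled, scaler: ScalerParams, feature: str = "CONC"):
    """Map a scaled value back to its original units (identity for
    constant features)."""
    if feature not in scaler.features:
        raise InputError(f"feature {feature!r} not in scaler; valid: {scaler.features}")
    span = scaler.xmax[feature] - scaler.xmin[feature]
    if span == 0:
        return np.asarray(scaled) * 0.0 + scaler.xmin[feature]
    return np.asarray(scaled) * span + scaler.xmin[feature]


# ---------------------------------------------------------------------------
# chronological split
# ---------------------------------------------------------------------------


def sort_chronologically(dataset: pd.DataFrame) -> pd.DataFrame:
    """Ascending calendar order; ties broken by subject then sample time."""
    return dataset.sort_values(
        ["CALENDAR", "ID", "TSFD"], kind="mergesort"
    ).reset_index(drop=True)


def date_ordered_split(
    dataset: pd.DataFrame, train_frac: float = 0.70
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First ``floor(train_frac * N)`` rows (by calendar order) train, rest
    validation."""
    if not 0.0 < train_frac < 1.0:
        raise ConfigurationError(f"train_frac must be in (0, 1), got {train_frac}")
    ordered = sort_chronologically(dataset)
    n_train = int(np.floor(train_frac * len(ordered)))
    return ordered.iloc[:n_train].copy(), ordered.iloc[n_train:].copy()


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------


@dataclass
class SequenceSample:
    """One regression sample: a dosing window, static covariates, a target."""

    dosing_window: np.ndarray  # (time_steps, 2): scaled (tsfd, dose)
    covariates: np.ndarray  # (11,) scaled covariate vector
    target: float  # scaled concentration
    subject_id: int = -1

    def __eq__(self, other):
        return (
            isinstance(other, SequenceSample)
            and np.array_equal(self.dosing_window, other.dosing_window)
            and np.array_equal(self.covariates, other.covariates)
            and self.target == other.target
        )


def build_sequences(
    rows: pd.DataFrame, time_steps: int = 2, scaler: ScalerParams | None = None
) -> list[SequenceSample]:
    """One sample per observation row.

    The dosing window holds the subject's current and previous
    ``time_steps - 1`` scaled (TSFD, DOSE) records within ``rows``, in
    chronological order, front-padded with zeros before the subject's first
    observation.  ``rows`` must already be scaled (``scaler`` is only carried
    along for bookkeeping; pass the one used to scale the rows).
    """
    if time_steps < 1:
        raise ConfigurationError(f"time_steps must be >= 1, got {time_steps}")
    ordered = sort_chronologically(rows)
    seq = ordered[["TSFD", "DOSE"]].to_numpy(float)
    cov = ordered[list(COVARIATE_COLUMNS)].to_numpy(float)
    target = ordered["CONC"].to_numpy(float)
    ids = ordered["ID"].to_numpy()

    history: dict = {}
    samples = []
    for i in range(len(ordered)):
        past = history.setdefault(ids[i], [])
        window = np.zeros((time_steps, 2))
        take = past[-(time_steps - 1):] if time_steps > 1 else []
        for j, rec in enumerate(take):
            window[time_steps - 1 - len(take) + j] = rec
        window[time_steps - 1] = seq[i]
        past.append(seq[i])
        samples.append(
            SequenceSample(
                dosing_window=window,
                covariates=cov[i].copy(),
                target=float(target[i]),
                subject_id=int(ids[i]),
            )
        )
    return samples


def samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a list of samples into (X_seq, X_cov, y) arrays."""
    X_seq = np.stack([s.dosing_window for s in samples])
    X_cov = np.stack([s.covariates for s in samples])
    y = np.asarray([s.target for s in samples])
    return X_seq, X_cov, y


# ---------------------------------------------------------------------------
# split container
# ---------------------------------------------------------------------------


@dataclass
class SplitDataset:
    """Train/validation sequence samples plus the scaler that produced them."""

    train: list[SequenceSample]
    validation: list[SequenceSample]
    scaler: ScalerParams
    time_steps: int
    n_train_rows: int
    n_validation_rows: int
    train_rows: pd.DataFrame | None = None  # unscaled partitions, for saving
    validation_rows: pd.DataFrame | None = None

    def save(self, directory) -> dict:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.train_rows is None or self.validation_rows is None:
            raise InputError("cannot save a SplitDataset without its raw rows")
        write_dataset(self.train_rows, directory / "train.csv")
        write_dataset(self.validation_rows, directory / "validation.csv")
        self.scaler.save(directory / "scaler.json")
        manifest = {
            "time_steps": self.time_steps,
            "n_train_rows": self.n_train_rows,
            "n_validation_rows": self.n_validation_rows,
            "scaler_fingerprint": self.scaler.fingerprint(),
            "train_csv": "train.csv",
            "validation_csv": "validation.csv",
            "scaler_json": "scaler.json",
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest

    @classmethod
    def load(cls, directory) -> "SplitDataset":
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        train_rows = read_dataset(directory / manifest["train_csv"])
        validation_rows = read_dataset(directory / manifest["validation_csv"])
        scaler = ScalerParams.load(directory / manifest["scaler_json"])
        time_steps = int(manifest["time_steps"])
        return cls(
            train=build_sequences(apply_scaler(train_rows, scaler), time_steps, scaler),
            validation=build_sequences(
                apply_scaler(validation_rows, scaler), time_steps, scaler
            ),
            scaler=scaler,
            time_steps=time_steps,
            n_train_rows=len(train_rows),
            n_validation_rows=len(validation_rows),
            train_rows=train_rows,
            validation_rows=validation_rows,
        )


def prepare(
    dataset: pd.DataFrame,
    train_frac: float = 0.70,
    time_steps: int = 2,
    scaler_scope: str = "train",
) -> SplitDataset:
    """Full pipeline: chronological split, scaler fit, sequence building.

    ``scaler_scope`` is ``"train"`` (default; no leakage) or ``"pooled"``
    (min/max taken over the full dataset before splitting).
    """
    if scaler_scope not in ("train", "pooled"):
        raise ConfigurationError(
            f"scaler_scope must be 'train' or 'pooled', got {scaler_scope!r}"
        )
    train_rows, validation_rows = date_ordered_split(dataset, train_frac)
    scaler = fit_scaler(dataset if scaler_scope == "pooled" else train_rows)
    return SplitDataset(
        train=build_sequences(apply_scaler(train_rows, scaler), time_steps, scaler),
        validation=build_sequences(
            apply_scaler(validation_rows, scaler), time_steps, scaler
        ),
        scaler=scaler,
        time_steps=time_steps,
        n_train_rows=len(train_rows),
        n_validation_rows=len(validation_rows),
        train_rows=train_rows,
        validation_rows=validation_rows,
    )
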