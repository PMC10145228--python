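"""Multi-input LSTM-ANN concentration regressor, implemented in numpy.

Architecture: the dosing input (``time_steps`` x 2 scaled (TSFD, dose)
records) passes through 1-3 stacked blocks of [LSTM + dropout(0.1)]; every
block emits its hidden state at every time step, so the final flatten layer
exposes all hidden states, not just the last.  The flattened vector is
concatenated with the 11 static covariates and fed through 1-3 blocks of
[dense(ReLU) + dropout(0.1)] to a single linear output that predicts the
scaled concentration.  Training is per-sample (batch size 1) with Adam on a
mean-squared-error loss.

The LSTM cell follows the standard gate recurrence

    i_t = sigmoid(x_t U_i + h_{t-1} W_i + b_i)        input gate
    f_t = sigmoid(x_t U_f + h_{t-1} W_f + b_f)        forget gate
    o_t = sigmoid(x_t U_o + h_{t-1} W_o + b_o)        output gate
    g_t = tanh   (x_t U_g + h_{t-1} W_g + b_g)        candidate
    C_t = f_t * C_{t-1} + i_t * g_t
    h_t = o_t * act(C_t)

where ``act`` is ReLU by default (the cell-output activation is the
configurable "LSTM activation"; gates stay sigmoid) with standard tanh
available.  :func:`reference_lstm_step` is an independently coded one-step
version of the same equations used as a verification oracle for the
vectorized layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit

from .exceptions import (
    ConfigurationError,
    DimensionError,
    FitError,
    InputError,
)
from .preprocessing import ScalerParams, invert_scaler, samples_to_arrays

_GATES = ("i", "f", "o", "g")


def _sigmoid(x):
    return expit(x)  # overflow-safe logistic


def _cell_act(C, mode):
    return np.maximum(C, 0.0) if mode == "relu" else np.tanh(C)


def _cell_act_grad(C, mode):
    return (C > 0).astype(float) if mode == "relu" else 1.0 - np.tanh(C) ** 2


# ---------------------------------------------------------------------------
# reference single-step oracle
# ---------------------------------------------------------------------------


@dataclass
class LSTMCellParams:
    """Explicit per-gate weights of one LSTM cell."""

    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_g: np.ndarray
    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_g: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_g: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.U_i.shape[1]

    @property
    def input_size(self) -> int:
        return self.U_i.shape[0]

    def validate(self) -> None:
        I, H = self.input_size, self.hidden_size
        for g in _GATES:
            U = getattr(self, f"U_{g}")
            W = getattr(self, f"W_{g}")
            b = getattr(self, f"b_{g}")
            if U.shape != (I, H):
                raise DimensionError(f"U_{g} has shape {U.shape}, expected {(I, H)}")
            if W.shape != (H, H):
                raise DimensionError(f"W_{g} has shape {W.shape}, expected {(H, H)}")
            if b.shape != (H,):
                raise DimensionError(f"b_{g} has shape {b.shape}, expected {(H,)}")


def reference_lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    params: LSTMCellParams,
    cell_activation: str = "relu",
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM recurrence step, written directly from the gate equations.

    Deliberately independent of the vectorized layer implementation; used to
    cross-check it.  ``x_t`` has shape (input_size,), ``h_prev`` and
    ``C_prev`` shape (hidden,).
    """
    params.validate()
    x_t, h_prev, C_prev = map(np.asarray, (x_t, h_prev, C_prev))
    if x_t.shape != (params.input_size,):
        raise DimensionError(
            f"x_t has shape {x_t.shape}, expected {(params.input_size,)}"
        )
    if h_prev.shape != (params.hidden_size,) or C_prev.shape != (params.hidden_size,):
        raise DimensionError("h_prev/C_prev shape does not match hidden size")
    i_t = _sigmoid(x_t @ params.U_i + h_prev @ params.W_i + params.b_i)
    f_t = _sigmoid(x_t @ params.U_f + h_prev @ params.W_f + params.b_f)
    o_t = _sigmoid(x_t @ params.U_o + h_prev @ params.W_o + params.b_o)
    g_t = np.tanh(x_t @ params.U_g + h_prev @ params.W_g + params.b_g)
    C_t = f_t * C_prev + i_t * g_t
    h_t = o_t * _cell_act(C_t, cell_activation)
    return h_t, C_t


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureSpec:
    """Structure of the LSTM-ANN regressor (searchable fields only vary)."""

    n_lstm_blocks: int = 1
    lstm_nodes: int = 8
    n_dense_blocks: int = 2
    dense_nodes: tuple[int, ...] = (88, 184)
    dropout_rate: float = 0.1
    time_steps: int = 2
    n_covariates: int = 11
    cell_activation: str = "relu"  # activation applied to the cell state
    dense_activation: str = "relu"
    output_activation: str = "linear"

    def validate(self) -> None:
        if not 1 <= self.n_lstm_blocks <= 3:
            raise ConfigurationError("n_lstm_blocks must be in [1, 3]")
        if not 1 <= self.n_dense_blocks <= 3:
            raise ConfigurationError("n_dense_blocks must be in [1, 3]")
        if not 8 <= self.lstm_nodes <= 256:
            raise ConfigurationError("lstm_nodes must be in [8, 256]")
        if len(self.dense_nodes) != self.n_dense_blocks:
            raise ConfigurationError(
                "dense_nodes must list one width per dense block"
            )
        if any(not 8 <= n <= 256 for n in self.dense_nodes):
            raise ConfigurationError("dense node counts must be in [8, 256]")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.time_steps < 1:
            raise ConfigurationError("time_steps must be >= 1")
        if self.cell_activation not in ("relu", "tanh"):
            raise ConfigurationError("cell_activation must be 'relu' or 'tanh'")
        if self.output_activation not in ("linear", "relu"):
            raise ConfigurationError("output_activation must be 'linear' or 'relu'")

    def parameter_count(self) -> int:
        """Closed-form trainable-parameter total."""
        total = 0
        inp = 2
        for _ in range(self.n_lstm_blocks):
            H = self.lstm_nodes
            total += 4 * (inp * H + H * H + H)
            inp = H
        width = self.time_steps * self.lstm_nodes + self.n_covariates
        for n in self.dense_nodes:
            total += (width + 1) * n
            width = n
        total += width + 1  # linear output unit
        return total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dense_nodes"] = list(self.dense_nodes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["dense_nodes"] = tuple(d["dense_nodes"])
        return cls(**d)


@dataclass
class TrainConfig:
    """Training settings: Adam on per-sample MSE updates (batch size 1)."""

    learning_rate: float = 0.000125
    epochs: int = 69
    batch_size: int = 1
    seed: int = 0
    shuffle: bool = True
    clip_grad_norm: float | None = None

    def validate(self) -> None:
        if not 0.0001 <= self.learning_rate <= 0.001:
            raise ConfigurationError("learning_rate must be in [0.0001, 0.001]")
        if not 40 <= self.epochs <= 120:
            raise ConfigurationError("epochs must be in [40, 120]")
        if self.batch_size != 1:
            raise ConfigurationError("batch_size is fixed at 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class LSTMANNRegressor:
    """The multi-input network; weights live in plain numpy arrays.

    ``params`` maps names like ``lstm0_U_i``, ``dense1_W``, ``out_W`` to
    arrays.  Forward supports batches; backward implements full BPTT and is
    exercised by a finite-difference gradient check in the test suite.
    """

    def __init__(self, arch: ArchitectureSpec, seed: int = 0):
        arch.validate()
        self.arch = arch
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        inp = 2
        for l in range(arch.n_lstm_blocks):
            H = arch.lstm_nodes
            for g in _GATES:
                self.params[f"lstm{l}_U_{g}"] = self._glorot(rng, inp, H)
                self.params[f"lstm{l}_W_{g}"] = self._glorot(rng, H, H)
                self.params[f"lstm{l}_b_{g}"] = np.zeros(H)
            inp = H
        width = arch.time_steps * arch.lstm_nodes + arch.n_covariates
        for a, n in enumerate(arch.dense_nodes):
            self.params[f"dense{a}_W"] = self._glorot(rng, width, n)
            self.params[f"dense{a}_b"] = np.zeros(n)
            width = n
        self.params["out_W"] = self._glorot(rng, width, 1)
        self.params["out_b"] = np.zeros(1)

    @staticmethod
    def _glorot(rng, fan_in, fan_out):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_in, fan_out))

    # -- introspection ------------------------------------------------------

    def num_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def lstm_cell_params(self, block: int = 0) -> LSTMCellParams:
        kw = {}
        for g in _GATES:
            kw[f"U_{g}"] = self.params[f"lstm{block}_U_{g}"]
            kw[f"W_{g}"] = self.params[f"lstm{block}_W_{g}"]
            kw[f"b_{g}"] = self.params[f"lstm{block}_b_{g}"]
        return LSTMCellParams(**kw)

    # -- forward ------------------------------------------------------------

    def _lstm_block_forward(self, block, X, cache=None):
        """X: (N, T, I) -> outputs (N, T, H); caches per-step activations."""
        N, T, _ = X.shape
        H = self.arch.lstm_nodes
        p = self.params
        h = np.zeros((N, H))
        C = np.zeros((N, H))
        out = np.empty((N, T, H))
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            pre = {
                g: x_t @ p[f"lstm{block}_U_{g}"]
                + h @ p[f"lstm{block}_W_{g}"]
                + p[f"lstm{block}_b_{g}"]
                for g in _GATES
            }
            i_t = _sigmoid(pre["i"])
            f_t = _sigmoid(pre["f"])
            o_t = _sigmoid(pre["o"])
            g_t = np.tanh(pre["g"])
            C_prev = C
            C = f_t * C_prev + i_t * g_t
            hc = _cell_act(C, self.arch.cell_activation)
            h_prev = h
            h = o_t * hc
            out[:, t, :] = h
            if cache is not None:
                steps.append(
                    dict(x=x_t, h_prev=h_prev, C_prev=C_prev, i=i_t, f=f_t,
                         o=o_t, g=g_t, C=C, hc=hc)
                )
        if cache is not None:
            cache.append(steps)
        return out

    def forward(self, X_seq, X_cov, training=False, dropout_rng=None):
        """Predict scaled concentrations for a batch.

        Returns predictions of shape (N,).  When ``training`` is true,
        inverted dropout is applied with masks drawn from ``dropout_rng`` and
        a cache for backprop is retained on the instance.
        """
        X_seq = np.asarray(X_seq, float)
        X_cov = np.asarray(X_cov, float)
        if X_seq.ndim != 3 or X_seq.shape[1] != self.arch.time_steps:
            raise DimensionError(
                f"X_seq must be (N, {self.arch.time_steps}, 2), got {X_seq.shape}"
            )
        if X_cov.shape != (X_seq.shape[0], self.arch.n_covariates):
            raise DimensionError(
                f"X_cov must be (N, {self.arch.n_covariates}), got {X_cov.shape}"
            )
        rate = self.arch.dropout_rate if training else 0.0
        cache = {"lstm": [], "masks": {}, "dense": []} if training else None

        x = X_seq
        for l in range(self.arch.n_lstm_blocks):
            x = self._lstm_block_forward(
                l, x, cache["lstm"] if training else None
            )
            if rate > 0:
                mask = (dropout_rng.random(x.shape) >= rate) / (1.0 - rate)
                cache["masks"][f"lstm{l}"] = mask
                x = x * mask
        flat = x.reshape(x.shape[0], -1)
        a = np.concatenate([flat, X_cov], axis=1)
        if training:
            cache["concat_in"] = a
        for d in range(self.arch.n_dense_blocks):
            z = a @ self.params[f"dense{d}_W"] + self.params[f"dense{d}_b"]
            act = np.maximum(z, 0.0)
            if training:
                cache["dense"].append(dict(a_in=a, z=z))
            a = act
            if rate > 0:
                mask = (dropout_rng.random(a.shape) >= rate) / (1.0 - rate)
                cache["masks"][f"dense{d}"] = mask
                a = a * mask
        if training:
            cache["head_in"] = a
        y = (a @ self.params["out_W"] + self.params["out_b"])[:, 0]
        if self.arch.output_activation == "relu":
            if training:
                cache["head_pre"] = y.copy()
            y = np.maximum(y, 0.0)
        if training:
            self._cache = cache
        return y

    # -- backward -----------------------------------------------------------

    def backward(self, d_y):
        """Gradient of the loss wrt every parameter, given dL/dy (N,).

        Must be called right after a ``forward(..., training=True)`` pass.
        """
        cache = self._cache
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_y = np.asarray(d_y, float)
        if self.arch.output_activation == "relu":
            d_y = d_y * (cache["head_pre"] > 0)
        a = cache["head_in"]
        grads["out_W"] = a.T @ d_y[:, None]
        grads["out_b"] = np.array([d_y.sum()])
        d_a = d_y[:, None] @ self.params["out_W"].T

        for d in range(self.arch.n_dense_blocks - 1, -1, -1):
            mask = cache["masks"].get(f"dense{d}")
            if mask is not None:
                d_a = d_a * mask
            step = cache["dense"][d]
            d_z = d_a * (step["z"] > 0)
            grads[f"dense{d}_W"] = step["a_in"].T @ d_z
            grads[f"dense{d}_b"] = d_z.sum(axis=0)
            d_a = d_z @ self.params[f"dense{d}_W"].T

        T, H = self.arch.time_steps, self.arch.lstm_nodes
        N = d_a.shape[0]
        d_flat = d_a[:, : T * H]
        d_out_seq = d_flat.reshape(N, T, H)
        for l in range(self.arch.n_lstm_blocks - 1, -1, -1):
            mask = cache["masks"].get(f"lstm{l}")
            if mask is not None:
                d_out_seq = d_out_seq * mask
            d_out_seq = self._lstm_block_backward(l, cache["lstm"][l], d_out_seq, grads)
        return grads

    def _lstm_block_backward(self, block, steps, d_out, grads):
        p = self.params
        N, T, H = d_out.shape
        mode = self.arch.cell_activation
        dh_next = np.zeros((N, H))
        dC_next = np.zeros((N, H))
        I = steps[0]["x"].shape[1]
        d_x = np.zeros((N, T, I))
        for t in range(T - 1, -1, -1):
            s = steps[t]
            dh = d_out[:, t, :] + dh_next
            do = dh * s["hc"]
            dC = dC_next + dh * s["o"] * _cell_act_grad(s["C"], mode)
            df = dC * s["C_prev"]
            di = dC * s["g"]
            dg = dC * s["i"]
            dC_next = dC * s["f"]
            d_pre = {
                "i": di * s["i"] * (1 - s["i"]),
                "f": df * s["f"] * (1 - s["f"]),
                "o": do * s["o"] * (1 - s["o"]),
                "g": dg * (1 - s["g"] ** 2),
            }
            dh_next = np.zeros((N, H))
            for g in _GATES:
                grads[f"lstm{block}_U_{g}"] += s["x"].T @ d_pre[g]
                grads[f"lstm{block}_W_{g}"] += s["h_prev"].T @ d_pre[g]
                grads[f"lstm{block}_b_{g}"] += d_pre[g].sum(axis=0)
                dh_next += d_pre[g] @ p[f"lstm{block}_W_{g}"].T
                d_x[:, t, :] += d_pre[g] @ p[f"lstm{block}_U_{g}"].T
        return d_x


def build_model(arch: ArchitectureSpec, seed: int = 0) -> LSTMANNRegressor:
    """Construct an untrained regressor with seeded variance-scaling init."""
    return LSTMANNRegressor(arch, seed=seed)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedRegressor:
    """A fitted LSTM-ANN plus everything needed to reuse it."""

    model: LSTMANNRegressor
    arch: ArchitectureSpec
    config: TrainConfig
    scaler: ScalerParams
    history: list[float]  # per-epoch mean training loss (scaled space)
    train_rmse: float  # ng/mL
    validation_rmse: float  # ng/mL

    def predict(self, samples, scaler: ScalerParams | None = None) -> np.ndarray:
        """Predict concentrations (ng/mL) for sequence samples."""
        if scaler is not None and scaler.fingerprint() != self.scaler.fingerprint():
            raise InputError(
                "samples were scaled with a different scaler than the model"
            )
        X_seq, X_cov, _ = samples_to_arrays(samples)
        y_scaled = self.model.forward(X_seq, X_cov, training=False)
        return np.asarray(invert_scaler(y_scaled, self.scaler, "CONC"))

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.model.params)
        sidecar = {
            "arch": self.arch.to_dict(),
            "config": self.config.to_dict(),
            "scaler": self.scaler.to_dict(),
            "history": self.history,
            "train_rmse": self.train_rmse,
            "validation_rmse": self.validation_rmse,
        }
        with open(directory / "model.json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "TrainedRegressor":
        directory = Path(directory)
        with open(directory / "model.json") as fh:
            sidecar = json.load(fh)
        arch = ArchitectureSpec.from_dict(sidecar["arch"])
        model = LSTMANNRegressor(arch, seed=0)
        with np.load(directory / "weights.npz") as npz:
            for k in model.params:
                model.params[k] = npz[k]
        return cls(
            model=model,
            arch=arch,
            config=TrainConfig.from_dict(sidecar["config"]),
            scaler=ScalerParams.from_dict(sidecar["scaler"]),
            history=list(sidecar["history"]),
            train_rmse=float(sidecar["train_rmse"]),
            validation_rmse=float(sidecar["validation_rmse"]),
        )


def rmse(observed, predicted) -> float:
    """Root-mean-square error, in the units of its inputs."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise DimensionError("observed and predicted must have the same shape")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def train(
    model: LSTMANNRegressor,
    split,
    cfg: TrainConfig,
    epoch_callback=None,
) -> TrainedRegressor:
    """Train with per-sample Adam updates and seeded shuffling.

    ``epoch_callback(epoch_index, mean_loss)`` may return False to stop
    early (used by the pruning hyperparameter search).  Final train and
    validation RMSEs are computed on the ng/mL scale after inverse scaling.
    """
    cfg.validate()
    X_seq, X_cov, y = samples_to_arrays(split.train)
    rng = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    adam = _Adam(model.params, cfg.learning_rate)
    history: list[float] = []
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = np.empty(n)
        for j, idx in enumerate(order):
            pred = model.forward(
                X_seq[idx : idx + 1], X_cov[idx : idx + 1],
                training=True, dropout_rng=dropout_rng,
            )
            err = pred[0] - y[idx]
            losses[j] = err * err
            grads = model.backward(np.array([2.0 * err]))
            if cfg.clip_grad_norm is not None:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if norm > cfg.clip_grad_norm:
                    scale = cfg.clip_grad_norm / norm
                    grads = {k: g * scale for k, g in grads.items()}
            adam.step(model.params, grads)
        mean_loss = float(losses.mean())
        if not np.isfinite(mean_loss):
            raise FitError(
                f"training loss became non-finite at epoch {epoch} "
                f"(learning_rate={cfg.learning_rate})"
            )
        history.append(mean_loss)
        if epoch_callback is not None and epoch_callback(epoch, mean_loss) is False:
            break

    def _rmse_on(samples):
        Xs, Xc, yt = samples_to_arrays(samples)
        pred = model.forward(Xs, Xc, training=False)
        return rmse(
            invert_scaler(yt, split.scaler, "CONC"),
            invert_scaler(pred, split.scaler, "CONC"),
        )

    return TrainedRegressor(
        model=model,
        arch=model.arch,
        config=cfg,
        scaler=split.scaler,
        history=history,
        train_rmse=_rmse_on(split.train),
        validation_rmse=_rmse_on(split.validation) if split.validation else float("nan"),
    )


def mean_baseline_rmse(split) -> float:
    """Validation RMSE (ng/mL) of always predicting the training-set mean."""
    _, _, y_train = samples_to_arrays(split.train)
    _, _, y_val = samples_to_arrays(split.validation)
    obs = np.asarray(invert_scaler(y_val, split.scaler, "CONC"))
    mean_pred = float(np.mean(invert_scaler(y_train, split.scaler, "CONC")))
    return rmse(obs, np.full_like(obs, mean_pred))
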