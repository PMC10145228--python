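"""Population-pharmacokinetic baseline for sparse oral-dosing data.

Implements the benchmark that nonlinear mixed-effects software normally
provides: a one-compartment structural model with first-order absorption and
elimination, multiplicative covariate submodels on clearance, a first-order
(FO) approximation to the marginal likelihood with additive residual error,
and stepwise forward covariate selection driven by likelihood-ratio drops in
the objective function value (OFV = -2 log L).

Model summary
-------------
Structural: repeated oral doses ``D`` every ``tau`` hours; concentration is
the superposition of Bateman terms

    C(t) = sum_d  D*ka / (V*(ka - ke)) * (exp(-ke*(t - t_d)) - exp(-ka*(t - t_d)))

with ``ke = CL/V``, reported in ng/mL (doses in mg, volume in L).

Statistical: ``CL_i = TVCL(covariates_i) * exp(eta_i)`` with
``eta_i ~ N(0, omega^2)`` and observed ``y = C + eps``, ``eps ~ N(0, sigma^2)``.

Covariates: continuous covariates enter as power terms
``(x / median_x)^theta``; binary covariates as level ratios
``theta_level / theta_level0`` so that with a single categorical effect and
``tvcl`` equal to the level-0 clearance the two levels reproduce the two
estimated clearances directly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .domain import CovariateProfile, DosingRegimen
from .exceptions import ConfigurationError, FitError, ParameterError

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ContinuousEffect:
    """Power-law covariate effect on clearance: (x / reference)^exponent."""

    covariate: str
    exponent: float
    reference: float  # population median of the covariate

    def validate(self) -> None:
        if not np.isfinite(self.exponent):
            raise ParameterError(f"exponent for {self.covariate} must be finite")
        if self.reference <= 0:
            raise ParameterError(f"reference for {self.covariate} must be positive")


@dataclass
class CategoricalEffect:
    """Binary covariate effect: clearance multiplied by theta1/theta0 at level 1."""

    covariate: str
    theta0: float
    theta1: float

    @property
    def ratio(self) -> float:
        return self.theta1 / self.theta0

    def validate(self) -> None:
        if self.theta0 <= 0 or self.theta1 <= 0:
            raise ParameterError(
                f"level clearances for {self.covariate} must be positive"
            )


@dataclass
class PopPKParams:
    """Typical values, covariate effects and variance components."""

    tvcl: float  # typical clearance, L/h
    v: float  # apparent volume, L
    ka: float = 0.5  # absorption rate constant, 1/h (fixed by default)
    omega_cl: float = 0.3  # SD of eta on log clearance
    sigma_add: float = 10.0  # additive residual SD, ng/mL
    continuous_effects: list[ContinuousEffect] = field(default_factory=list)
    categorical_effects: list[CategoricalEffect] = field(default_factory=list)

    def validate(self) -> None:
        if self.tvcl <= 0:
            raise ParameterError(f"tvcl must be positive, got {self.tvcl}")
        if self.v <= 0:
            raise ParameterError(f"v must be positive, got {self.v}")
        if self.ka <= 0:
            raise ParameterError(f"ka must be positive, got {self.ka}")
        if self.omega_cl < 0:
            raise ParameterError(f"omega_cl must be >= 0, got {self.omega_cl}")
        if self.sigma_add < 0:
            raise ParameterError(f"sigma_add must be >= 0, got {self.sigma_add}")
        for eff in self.continuous_effects:
            eff.validate()
        for eff in self.categorical_effects:
            eff.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopPKParams":
        d = dict(d)
        d["continuous_effects"] = [
            ContinuousEffect(**e) for e in d.get("continuous_effects", [])
        ]
        d["categorical_effects"] = [
            CategoricalEffect(**e) for e in d.get("categorical_effects", [])
        ]
        return cls(**d)


@dataclass
class FitResult:
    """Outcome of an FO marginal-likelihood fit or a forward selection run."""

    estimates: PopPKParams
    ofv: float
    selected_covariates: list[str] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "ofv": self.ofv,
            "selected_covariates": self.selected_covariates,
            "trace": self.trace,
            "converged": self.converged,
            "message": self.message,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            estimates=PopPKParams.from_dict(d["estimates"]),
            ofv=d["ofv"],
            selected_covariates=list(d.get("selected_covariates", [])),
            trace=list(d.get("trace", [])),
            converged=d.get("converged", True),
            message=d.get("message", ""),
        )

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# structural model
# ---------------------------------------------------------------------------


def _geometric_exp_sum(k, tad, interval, n):
    """sum_{j=0}^{n-1} exp(-k * (tad + j*interval)), elementwise and stable."""
    q = np.exp(-k * interval)
    denom = 1.0 - q
    # q -> 1 only for vanishing elimination over the interval; fall back to n
    safe = denom > 1e-12
    series = np.where(safe, (1.0 - q**n) / np.where(safe, denom, 1.0), n)
    return np.exp(-k * tad) * series


def superposition_concentration(tsfd, dose, interval, n_doses, cl, v, ka):
    """Concentration (ng/mL) under repeated equal-interval dosing.

    Vectorized over observations: every argument may be scalar or array and
    is broadcast.  ``n_doses`` caps the number of administrations; doses are
    given at ``0, tau, 2*tau, ...`` and only those at or before ``tsfd``
    contribute (a dose at exactly ``tsfd`` contributes zero).
    """
    tsfd = np.asarray(tsfd, dtype=float)
    dose = np.asarray(dose, dtype=float)
    interval = np.asarray(interval, dtype=float)
    n_doses = np.asarray(n_doses)
    cl = np.asarray(cl, dtype=float)
    v = np.asarray(v, dtype=float)
    ka = np.asarray(ka, dtype=float)
    if np.any(cl <= 0) or np.any(v <= 0) or np.any(ka <= 0):
        raise ParameterError("cl, v and ka must all be positive")

    ke = cl / v
    shape = np.broadcast_shapes(
        tsfd.shape, dose.shape, interval.shape, np.shape(n_doses), ke.shape, ka.shape
    )
    tsfd, dose, interval, n_doses, ke, ka_b, v_b = np.broadcast_arrays(
        tsfd, dose, interval, n_doses, ke, ka, v
    )

    # number of administrations that have occurred strictly before tsfd
    n_given = np.floor(np.maximum(tsfd, 0.0) / interval + 1e-12).astype(int) + 1
    n = np.minimum(np.asarray(n_doses, dtype=int), n_given)
    n = np.where(tsfd > 0, np.maximum(n, 0), 0)
    tad = tsfd - (n - 1) * interval  # time since most recent contributing dose
    tad = np.where(n > 0, tad, 0.0)

    out = np.zeros(shape, dtype=float)
    active = n > 0
    if np.any(active):
        kaA, keA, tadA, intA, nA = (
            ka_b[active],
            ke[active],
            tad[active],
            interval[active],
            n[active],
        )
        degenerate = np.abs(kaA - keA) <= 1e-9 * kaA
        amp = np.empty(kaA.shape)
        reg = ~degenerate
        if np.any(reg):
            s_ke = _geometric_exp_sum(keA[reg], tadA[reg], intA[reg], nA[reg])
            s_ka = _geometric_exp_sum(kaA[reg], tadA[reg], intA[reg], nA[reg])
            amp[reg] = kaA[reg] / (kaA[reg] - keA[reg]) * (s_ke - s_ka)
        if np.any(degenerate):
            # Bateman limit ka -> ke = k: per-dose term k * dt * exp(-k*dt)
            k = kaA[degenerate]
            t0 = tadA[degenerate]
            tau = intA[degenerate]
            m = nA[degenerate]
            q = np.exp(-k * tau)
            s0 = np.where(1 - q > 1e-12, (1 - q**m) / (1 - q), m)
            j_series = np.where(
                1 - q > 1e-12,
                q * (1 - m * q ** (m - 1) + (m - 1) * q**m) / (1 - q) ** 2,
                m * (m - 1) / 2.0,
            )
            # sum_j (t0 + j*tau) q^j = t0*s0 + tau*j_series, all times exp(-k*t0)
            amp[degenerate] = k * np.exp(-k * t0) * (t0 * s0 + tau * j_series)
        out[active] = dose[active] / v_b[active] * amp * 1000.0  # mg/L -> ng/mL
    return out if out.shape else float(out)


def predict_concentration(
    tsfd: float, regimen: DosingRegimen, cl: float, v: float, ka: float
):
    """Concentration (ng/mL) at ``tsfd`` hours after the first dose.

    ``tsfd`` may be a scalar or array of times; the regimen supplies the dose
    amount, interval and the number of administrations before sampling.
    """
    return superposition_concentration(
        tsfd, regimen.dose_amount, regimen.interval, regimen.n_doses_before_sample,
        cl, v, ka,
    )


def typical_clearance(profile: CovariateProfile, params: PopPKParams) -> float:
    """Covariate-adjusted typical clearance for one subject (L/h)."""
    row = profile.as_row()
    cl = params.tvcl
    for eff in params.continuous_effects:
        if eff.covariate not in row:
            raise ConfigurationError(
                f"unknown covariate {eff.covariate!r}; valid: {sorted(row)}"
            )
        cl *= (row[eff.covariate] / eff.reference) ** eff.exponent
    for eff in params.categorical_effects:
        if eff.covariate not in row:
            raise ConfigurationError(
                f"unknown covariate {eff.covariate!r}; valid: {sorted(row)}"
            )
        level = row[eff.covariate]
        cl *= (eff.theta0 * (1 - level) + eff.theta1 * level) / eff.theta0
    return float(cl)


# ---------------------------------------------------------------------------
# FO marginal likelihood
# ---------------------------------------------------------------------------


def _dataset_arrays(dataset: pd.DataFrame):
    codes, _ = pd.factorize(dataset["ID"])
    tsfd = dataset["TSFD"].to_numpy(float)
    dose = dataset["DOSE"].to_numpy(float)
    if "INTERVAL" in dataset.columns:
        interval = dataset["INTERVAL"].to_numpy(float)
    else:
        interval = np.full(len(dataset), 24.0)
    n_doses = np.floor(tsfd / interval + 1e-12).astype(int) + 1
    y = dataset["CONC"].to_numpy(float)
    return codes, tsfd, dose, interval, n_doses, y


def _row_tvcl(dataset, tvcl, cont_effects, cat_effects):
    """Typical clearance per observation row (vectorized covariate submodel)."""
    cl = np.full(len(dataset), tvcl, dtype=float)
    for name, exponent, reference in cont_effects:
        cl *= (dataset[name].to_numpy(float) / reference) ** exponent
    for name, ratio in cat_effects:
        x = dataset[name].to_numpy(float)
        cl *= ratio**x
    return cl


def _fo_ofv(y, pred0, grad, codes, n_subjects, omega, sigma):
    """-2 log marginal likelihood under the FO linearization.

    Per subject the marginal covariance is the rank-one matrix
    ``omega^2 g g' + sigma^2 I``; determinant-lemma / Sherman-Morrison
    identities reduce everything to per-subject sums.
    """
    r = y - pred0
    s2 = sigma * sigma
    w2 = omega * omega
    gg = np.bincount(codes, weights=grad * grad, minlength=n_subjects)
    gr = np.bincount(codes, weights=grad * r, minlength=n_subjects)
    rr = np.bincount(codes, weights=r * r, minlength=n_subjects)
    n_i = np.bincount(codes, minlength=n_subjects).astype(float)
    denom = s2 + w2 * gg
    logdet = n_i * np.log(s2) + np.log1p(w2 * gg / s2)
    quad = (rr - w2 * gr * gr / denom) / s2
    return float(np.sum(n_i * _LOG2PI + logdet + quad))


_ETA_STEP = 1e-4


def _objective_factory(dataset, init: PopPKParams, free_effects, estimate_ka):
    codes, tsfd, dose, interval, n_doses, y = _dataset_arrays(dataset)
    n_subjects = int(codes.max()) + 1 if len(codes) else 0

    fixed_cont = [
        (e.covariate, e.exponent, e.reference) for e in init.continuous_effects
    ]
    fixed_cat = [(e.covariate, e.ratio) for e in init.categorical_effects]
    free_cont = [name for name, kind in free_effects if kind == "continuous"]
    free_cat = [name for name, kind in free_effects if kind == "categorical"]
    def _reference(name):
        # power terms need a positive reference; count covariates can have
        # median 0, in which case fall back to the mean (floored at 1)
        col = dataset[name].to_numpy(float)
        med = float(np.median(col))
        return med if med > 0 else max(float(col.mean()), 1.0)

    references = {name: _reference(name) for name in free_cont}

    def unpack(x):
        tvcl, v = np.exp(x[0]), np.exp(x[1])
        idx = 2
        if estimate_ka:
            ka = np.exp(x[idx])
            idx += 1
        else:
            ka = init.ka
        omega, sigma = np.exp(x[idx]), np.exp(x[idx + 1])
        idx += 2
        cont = list(fixed_cont) + [
            (name, x[idx + i], references[name]) for i, name in enumerate(free_cont)
        ]
        idx += len(free_cont)
        cat = list(fixed_cat) + [
            (name, np.exp(x[idx + i])) for i, name in enumerate(free_cat)
        ]
        return tvcl, v, ka, omega, sigma, cont, cat

    def objective(x):
        tvcl, v, ka, omega, sigma, cont, cat = unpack(x)
        tv = _row_tvcl(dataset, tvcl, cont, cat)
        try:
            pred0 = superposition_concentration(tsfd, dose, interval, n_doses, tv, v, ka)
            pred_p = superposition_concentration(
                tsfd, dose, interval, n_doses, tv * np.exp(_ETA_STEP), v, ka
            )
            pred_m = superposition_concentration(
                tsfd, dose, interval, n_doses, tv * np.exp(-_ETA_STEP), v, ka
            )
        except (ParameterError, FloatingPointError):
            return 1e12
        grad = (pred_p - pred_m) / (2.0 * _ETA_STEP)
        ofv = _fo_ofv(y, pred0, grad, codes, n_subjects, omega, sigma)
        return ofv if np.isfinite(ofv) else 1e12

    def x0():
        x = [np.log(init.tvcl), np.log(init.v)]
        if estimate_ka:
            x.append(np.log(init.ka))
        x += [np.log(max(init.omega_cl, 1e-3)), np.log(max(init.sigma_add, 1e-3))]
        x += [0.0] * len(free_cont)
        x += [0.0] * len(free_cat)
        return np.asarray(x)

    def bounds():
        b = [(-5.0, 12.0), (-5.0, 15.0)]
        if estimate_ka:
            b.append((-7.0, 5.0))
        b += [(np.log(1e-6), np.log(5.0)), (np.log(1e-6), np.log(1e4))]
        b += [(-10.0, 10.0)] * len(free_cont)
        b += [(-5.0, 5.0)] * len(free_cat)
        return b

    return objective, unpack, x0, bounds, references


def fit(
    dataset: pd.DataFrame,
    init: PopPKParams,
    effects_to_estimate: Sequence[tuple[str, str]] = (),
    estimate_ka: bool = False,
    n_starts: int = 3,
    jitter_seed: int = 0,
) -> FitResult:
    """Estimate population parameters by FO-approximate maximum likelihood.

    ``effects_to_estimate`` lists ``(covariate, kind)`` pairs with kind
    ``"continuous"`` (power exponent, reference = dataset median) or
    ``"categorical"`` (log level-ratio).  Effects already present in ``init``
    are applied with fixed values.  Three jittered starts guard against local
    minima; the best objective wins and the whole procedure is deterministic
    given (``init``, ``jitter_seed``).
    """
    if len(dataset) == 0:
        raise FitError("dataset is empty")
    init.validate()
    free = list(effects_to_estimate)
    objective, unpack, x0_fn, bounds_fn, references = _objective_factory(
        dataset, init, free, estimate_ka
    )
    x0 = x0_fn()
    bounds = bounds_fn()
    rng = np.random.default_rng(jitter_seed)
    best = None
    any_success = False
    messages = []
    for start in range(max(1, n_starts)):
        xs = x0.copy()
        if start > 0:
            xs = xs + rng.normal(0.0, 0.2, size=xs.shape)
            xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            res = optimize.minimize(
                objective, xs, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 500},
            )
        messages.append(str(res.message))
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    tvcl, v, ka, omega, sigma, cont, cat = unpack(best.x)
    estimates = PopPKParams(
        tvcl=float(tvcl),
        v=float(v),
        ka=float(ka),
        omega_cl=float(omega),
        sigma_add=float(sigma),
        continuous_effects=[
            ContinuousEffect(name, float(expo), float(ref)) for name, expo, ref in cont
        ],
        categorical_effects=[
            CategoricalEffect(name, 1.0, float(ratio)) for name, ratio in cat
        ],
    )
    if not any_success:
        logger.warning("FO fit did not converge: %s", messages)
    return FitResult(
        estimates=estimates,
        ofv=float(best.fun),
        converged=any_success,
        message="; ".join(messages),
    )


# ---------------------------------------------------------------------------
# forward covariate selection
# ---------------------------------------------------------------------------


def lrt_threshold(alpha: float = 0.01, df: int = 1) -> float:
    """Chi-square quantile used as the OFV-drop acceptance threshold."""
    return float(stats.chi2.ppf(1.0 - alpha, df))


def forward_select(
    dataset: pd.DataFrame,
    base: PopPKParams,
    candidate_covariates: Sequence[tuple[str, str]],
    alpha: float = 0.01,
    estimate_ka: bool = False,
    jitter_seed: int = 0,
) -> FitResult:
    """Stepwise forward covariate search on clearance.

    Each round refits the current model plus every remaining candidate and
    accepts the one with the largest OFV drop, provided the drop clears the
    chi-square quantile for its degrees of freedom at ``alpha`` (6.635 for one
    parameter at p < 0.01).  Stops when no candidate qualifies.
    """
    base_fit = fit(dataset, base, (), estimate_ka=estimate_ka, jitter_seed=jitter_seed)
    trace = [
        {"step": 0, "covariate": None, "ofv": base_fit.ofv, "drop": None,
         "accepted": True}
    ]
    selected: list[tuple[str, str]] = []
    current_ofv = base_fit.ofv
    current_fit = base_fit
    remaining = list(candidate_covariates)
    step = 0
    while remaining:
        step += 1
        results = []
        for cand in remaining:
            try:
                f = fit(
                    dataset, base, selected + [cand],
                    estimate_ka=estimate_ka, jitter_seed=jitter_seed,
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"candidate {cand[0]} fit failed: {exc}")
                continue
            results.append((current_ofv - f.ofv, cand, f))
        if not results:
            break
        results.sort(key=lambda t: (-t[0], t[1][0]))
        drop, cand, f = results[0]
        threshold = lrt_threshold(alpha, df=1)
        if drop >= threshold:
            selected.append(cand)
            remaining.remove(cand)
            current_ofv = f.ofv
            current_fit = f
            trace.append(
                {"step": step, "covariate": cand[0], "ofv": f.ofv,
                 "drop": float(drop), "accepted": True}
            )
        else:
            trace.append(
                {"step": step, "covariate": cand[0], "ofv": f.ofv,
                 "drop": float(drop), "accepted": False}
            )
            break
    return FitResult(
        estimates=current_fit.estimates,
        ofv=current_ofv,
        selected_covariates=[name for name, _ in selected],
        trace=trace,
        converged=current_fit.converged,
        message=current_fit.message,
    )


# ---------------------------------------------------------------------------
# individual (post-hoc) predictions
# ---------------------------------------------------------------------------


def individual_predictions(dataset: pd.DataFrame, params: PopPKParams) -> np.ndarray:
    """Empirical-Bayes individual predictions (ng/mL) for every row.

    For each subject the posterior mode of ``eta`` is found by a bounded
    scalar search; with ``omega_cl = 0`` the population prediction is
    returned.
    """
    params.validate()
    codes, tsfd, dose, interval, n_doses, y = _dataset_arrays(dataset)
    cont = [(e.covariate, e.exponent, e.reference) for e in params.continuous_effects]
    cat = [(e.covariate, e.ratio) for e in params.categorical_effects]
    tv = _row_tvcl(dataset, params.tvcl, cont, cat)
    preds = np.zeros(len(dataset))
    s2 = params.sigma_add**2
    w = params.omega_cl
    for i in np.unique(codes):
        mask = codes == i
        if w == 0:
            preds[mask] = superposition_concentration(
                tsfd[mask], dose[mask], interval[mask], n_doses[mask],
                tv[mask], params.v, params.ka,
            )
            continue

        def neg_post(eta):
            p = superposition_concentration(
                tsfd[mask], dose[mask], interval[mask], n_doses[mask],
                tv[mask] * np.exp(eta), params.v, params.ka,
            )
            return np.sum((y[mask] - p) ** 2) / s2 + (eta / w) ** 2

        res = optimize.minimize_scalar(
            neg_post, bounds=(-6.0 * w, 6.0 * w), method="bounded",
            options={"xatol": 1e-6},
        )
        preds[mask] = superposition_concentration(
            tsfd[mask], dose[mask], interval[mask], n_doses[mask],
            tv[mask] * np.exp(res.x), params.v, params.ka,
        )
    return preds


def evaluate_rmse(
    dataset: pd.DataFrame, params: PopPKParams, individual: bool = True
) -> float:
    """RMSE (ng/mL) of individual (default) or population predictions."""
    if individual:
        pred = individual_predictions(dataset, params)
    else:
        codes, tsfd, dose, interval, n_doses, y = _dataset_arrays(dataset)
        cont = [
            (e.covariate, e.exponent, e.reference) for e in params.continuous_effects
        ]
        cat = [(e.covariate, e.ratio) for e in params.categorical_effects]
        tv = _row_tvcl(dataset, params.tvcl, cont, cat)
        pred = superposition_concentration(
            tsfd, dose, interval, n_doses, tv, params.v, params.ka
        )
    y = dataset["CONC"].to_numpy(float)
    return float(np.sqrt(np.mean((y - pred) ** 2)))
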