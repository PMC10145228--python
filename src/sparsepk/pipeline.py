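"""End-to-end experiment orchestration from a single YAML config.

Stage order mirrors the two modeling arms: simulate (or load) the dataset,
preprocess it, fit the population-PK benchmark with forward covariate
selection, tune the LSTM-ANN hyperparameters (optional), train the final
network, evaluate both arms side by side, and run the permutation-importance
analysis.  Every stage receives an explicit seed derived from the root seed
and the stage name, and the run manifest records per-stage outputs and
metrics.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigurationError, SparsePKError
from .hyperopt import HyperparamSpace, run_study, select_final
from .importance import pimp
from .lstm_ann import (
    ArchitectureSpec,
    TrainConfig,
    TrainedRegressor,
    build_model,
    mean_baseline_rmse,
    train,
)
from .poppk import (
    CategoricalEffect,
    ContinuousEffect,
    PopPKParams,
    evaluate_rmse,
    forward_select,
)
from .preprocessing import prepare
from .synthetic import (
    default_pop_params,
    read_dataset,
    simulate_dataset,
    write_dataset,
)

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = [
    ["SMOK", "categorical"],
    ["SEX", "categorical"],
    ["RACE_B", "categorical"],
    ["AGE", "continuous"],
    ["WT", "continuous"],
]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    tag = zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([root_seed, tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "seeds": self.seeds,
            "outputs": self.outputs,
            "metrics": self.metrics,
            "completed_stages": self.completed_stages,
            "version": self.version,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def load_config(config_path) -> dict:
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return config


def _pop_params_from_config(sim_cfg: dict) -> PopPKParams:
    params = default_pop_params()
    for key in ("tvcl", "v", "ka", "omega_cl", "sigma_add"):
        if key in sim_cfg:
            setattr(params, key, float(sim_cfg[key]))
    for name, ratio in (sim_cfg.get("cl_covariate_ratios") or {}).items():
        params.categorical_effects.append(
            CategoricalEffect(covariate=name, theta0=1.0, theta1=float(ratio))
        )
    for name, (exponent, reference) in (
        sim_cfg.get("cl_covariate_exponents") or {}
    ).items():
        params.continuous_effects.append(
            ContinuousEffect(
                covariate=name, exponent=float(exponent), reference=float(reference)
            )
        )
    params.validate()
    return params


def run_experiment(config_path) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written to the
    output directory).  On stage failure the manifest records the stages that
    completed, then the error propagates with the stage name attached."""
    config = load_config(config_path) if not isinstance(config_path, dict) else dict(
        config_path
    )
    root_seed = int(config.get("seed", 0))
    outdir = Path(config.get("outdir", "sparsepk_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config)
    skip = set(config.get("skip") or [])
    current_stage = "init"

    try:
        # ------------------------------------------------------------ data
        current_stage = "simulate"
        sim_cfg = dict(config.get("simulate") or {})
        seed = stage_seed(root_seed, "simulate")
        manifest.seeds["simulate"] = seed
        if "dataset" in config:
            dataset = read_dataset(config["dataset"])
            truth = None
        else:
            params = _pop_params_from_config(sim_cfg)
            dataset, truth = simulate_dataset(
                n_subjects=int(sim_cfg.get("n_subjects", 523)),
                pop_params=params,
                seed=seed,
            )
        data_path = outdir / "dataset.csv"
        write_dataset(dataset, data_path)
        if truth is not None:
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth.to_dict(), fh)
            manifest.outputs["truth"] = str(outdir / "truth.json")
        manifest.outputs["dataset"] = str(data_path)
        manifest.metrics["simulate"] = {
            "n_subjects": int(dataset["ID"].nunique()),
            "n_observations": int(len(dataset)),
        }
        manifest.completed_stages.append("simulate")

        # ----------------------------------------------------- preprocess
        current_stage = "preprocess"
        split_cfg = dict(config.get("split") or {})
        split = prepare(
            dataset,
            train_frac=float(split_cfg.get("train_frac", 0.70)),
            time_steps=int((config.get("sequence") or {}).get("time_steps", 2)),
            scaler_scope=(config.get("scaler") or {}).get("scope", "train"),
        )
        split_dir = outdir / "split"
        split.save(split_dir)
        manifest.outputs["split"] = str(split_dir)
        manifest.metrics["preprocess"] = {
            "n_train_rows": split.n_train_rows,
            "n_validation_rows": split.n_validation_rows,
        }
        manifest.completed_stages.append("preprocess")

        # ------------------------------------------------------ PK baseline
        current_stage = "fit_poppk"
        baseline_rmse = None
        if "fit_poppk" not in skip:
            pk_cfg = dict(config.get("poppk") or {})
            init = default_pop_params()
            for key in ("tvcl", "v", "ka", "omega_cl", "sigma_add"):
                if key in pk_cfg:
                    setattr(init, key, float(pk_cfg[key]))
            candidates = [
                tuple(c) for c in pk_cfg.get("candidates", DEFAULT_CANDIDATES)
            ]
            pk_seed = stage_seed(root_seed, "fit_poppk")
            manifest.seeds["fit_poppk"] = pk_seed
            pk_fit = forward_select(dataset, init, candidates, jitter_seed=pk_seed)
            pk_fit.save(outdir / "poppk_fit.json")
            baseline_rmse = evaluate_rmse(dataset, pk_fit.estimates)
            manifest.outputs["poppk_fit"] = str(outdir / "poppk_fit.json")
            manifest.metrics["fit_poppk"] = {
                "ofv": pk_fit.ofv,
                "selected_covariates": pk_fit.selected_covariates,
                "rmse_individual": baseline_rmse,
                "trace": pk_fit.trace,
            }
            manifest.completed_stages.append("fit_poppk")

        # --------------------------------------------------------- tuning
        current_stage = "hyperopt"
        final_model: TrainedRegressor | None = None
        if "hyperopt" not in skip:
            hp_cfg = dict(config.get("hyperopt") or {})
            hp_seed = stage_seed(root_seed, "hyperopt")
            manifest.seeds["hyperopt"] = hp_seed
            space = HyperparamSpace(
                **{k: tuple(v) for k, v in (hp_cfg.get("space") or {}).items()}
            )
            study = run_study(
                space,
                split,
                sampler=hp_cfg.get("sampler", "tpe"),
                n_trials=int(hp_cfg.get("n_trials", 50)),
                pruning=bool(hp_cfg.get("pruning", True)),
                seed=hp_seed,
                journal_path=outdir / "study.jsonl",
            )
            final_model, best_trial = select_final(study, split)
            manifest.outputs["study_journal"] = str(outdir / "study.jsonl")
            manifest.metrics["hyperopt"] = {
                "n_trials": len(study.trials),
                "n_pruned": sum(t.pruned for t in study.trials),
                "best_config": best_trial.config,
                "best_validation_rmse": best_trial.validation_rmse,
            }
            manifest.completed_stages.append("hyperopt")

        # ---------------------------------------------------------- train
        current_stage = "train"
        train_seed = stage_seed(root_seed, "train")
        manifest.seeds["train"] = train_seed
        if final_model is None:
            arch_cfg = config.get("architecture") or {}
            arch = (
                ArchitectureSpec.from_dict(arch_cfg)
                if arch_cfg
                else ArchitectureSpec()
            )
            train_cfg = TrainConfig(seed=train_seed, **(config.get("train") or {}))
            final_model = train(build_model(arch, seed=train_seed), split, train_cfg)
        model_dir = outdir / "model"
        final_model.save(model_dir)
        loss_csv = outdir / "training_loss.csv"
        with open(loss_csv, "w") as fh:
            fh.write("epoch,train_mse_scaled\n")
            for e, loss in enumerate(final_model.history):
                fh.write(f"{e},{loss}\n")
        manifest.outputs["model"] = str(model_dir)
        manifest.outputs["training_loss"] = str(loss_csv)
        manifest.metrics["train"] = {
            "train_rmse": final_model.train_rmse,
            "validation_rmse": final_model.validation_rmse,
            "epochs_run": len(final_model.history),
            "parameter_count": final_model.model.num_params(),
        }
        manifest.completed_stages.append("train")

        # ------------------------------------------------------- evaluate
        current_stage = "evaluate"
        comparison = {
            "lstm_ann_validation_rmse": final_model.validation_rmse,
            "lstm_ann_train_rmse": final_model.train_rmse,
            "mean_predictor_validation_rmse": mean_baseline_rmse(split),
        }
        if baseline_rmse is not None:
            comparison["poppk_rmse_individual"] = baseline_rmse
        manifest.metrics["evaluate"] = comparison
        _scatter_plot(final_model, split, outdir / "observed_vs_predicted.png")
        manifest.outputs["scatter"] = str(outdir / "observed_vs_predicted.png")
        manifest.completed_stages.append("evaluate")

        # ----------------------------------------------------------- pimp
        current_stage = "pimp"
        if "pimp" not in skip:
            pimp_cfg = dict(config.get("pimp") or {})
            pimp_seed = stage_seed(root_seed, "pimp")
            manifest.seeds["pimp"] = pimp_seed
            report = pimp(
                final_model,
                split.validation if split.validation else split.train,
                n_reps=int(pimp_cfg.get("n_reps", 10)),
                seed=pimp_seed,
            )
            report.to_csv(outdir / "pimp.csv")
            report.to_json(outdir / "pimp.json")
            manifest.outputs["pimp"] = str(outdir / "pimp.csv")
            manifest.metrics["pimp"] = {
                "ranking": [
                    {"covariate": r.covariate, "mean": r.mean, "sd": r.sd}
                    for r in report.sorted_results()
                ]
            }
            manifest.completed_stages.append("pimp")
    except Exception as exc:
        manifest.metrics["error"] = {"stage": current_stage, "message": str(exc)}
        manifest.save(outdir / "manifest.json")
        raise SparsePKError(f"stage {current_stage!r} failed: {exc}") from exc

    manifest.save(outdir / "manifest.json")
    return manifest


def _scatter_plot(model: TrainedRegressor, split, path) -> None:
    """Observed vs. predicted concentrations for both partitions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .preprocessing import invert_scaler, samples_to_arrays

    fig, ax = plt.subplots(figsize=(5, 5))
    for samples, color, label in (
        (split.train, "tab:blue", "training"),
        (split.validation, "tab:green", "validation"),
    ):
        if not samples:
            continue
        _, _, y = samples_to_arrays(samples)
        obs = np.asarray(invert_scaler(y, split.scaler, "CONC"))
        pred = model.predict(samples)
        ax.scatter(obs, pred, s=8, alpha=0.5, color=color, label=label)
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("Observed concentration (ng/mL)")
    ax.set_ylabel("Predicted concentration (ng/mL)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
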