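import numpy as np
import pytest

from sparsepk.exceptions import ConfigurationError, FitError
from sparsepk.hyperopt import (
    HalvingPruner,
    HyperparamSpace,
    RandomSampler,
    StudyResult,
    TPESampler,
    TrialRecord,
    config_parameter_count,
    load_study,
    run_study,
    select_final,
    toy_evaluator,
    toy_objective,
)


class TestSamplers:
    def test_random_sampler_reproducible(self):
        space = HyperparamSpace()
        a = RandomSampler(space, seed=5)
        b = RandomSampler(space, seed=5)
        for _ in range(5):
            assert a.suggest([]) == b.suggest([])

    def test_all_samples_respect_bounds(self):
        space = HyperparamSpace()
        smp = TPESampler(space, seed=1, n_startup=3)
        history = []
        for _ in range(30):
            config = smp.suggest(history)
            assert space.contains(config)
            history.append((config, toy_objective(config)))

    def test_collapsed_space_returns_the_single_point(self):
        space = HyperparamSpace(
            n_lstm_blocks=(2, 2), lstm_nodes=(16, 16), n_dense_blocks=(1, 1),
            ann_nodes=(32, 32), learning_rate=(0.0005, 0.0005), epochs=(50, 50),
        )
        study = run_study(space, sampler="random", n_trials=1, pruning=False,
                          seed=0, evaluator=toy_evaluator)
        best = study.best_by_objective
        assert best.config["n_lstm_blocks"] == 2
        assert best.config["lstm_nodes"] == 16
        assert best.config["learning_rate"] == pytest.approx(0.0005)
        assert best.config["epochs"] == 50

    def test_tpe_converges_toward_toy_optimum(self):
        # after 40 trials the TPE best should be close to the bowl's bottom
        study = run_study(HyperparamSpace(), sampler="tpe", n_trials=40,
                          pruning=False, seed=3, evaluator=toy_evaluator)
        assert study.best_by_objective.objective < 1.0


class TestStudy:
    def test_seeded_study_reproducible(self):
        kwargs = dict(sampler="random", n_trials=5, pruning=False, seed=11,
                      evaluator=toy_evaluator)
        a = run_study(HyperparamSpace(), **kwargs)
        b = run_study(HyperparamSpace(), **kwargs)
        assert [t.config for t in a.trials] == [t.config for t in b.trials]

    def test_no_pruning_completes_all_trials(self):
        study = run_study(HyperparamSpace(), sampler="random", n_trials=7,
                          pruning=False, seed=2, evaluator=toy_evaluator)
        assert len(study.completed()) == 7

    def test_journal_round_trip(self, tmp_path):
        journal = tmp_path / "study.jsonl"
        study = run_study(HyperparamSpace(), sampler="random", n_trials=6,
                          pruning=False, seed=4, evaluator=toy_evaluator,
                          journal_path=journal)
        reloaded = load_study(journal, sampler="random", n_trials=6)
        assert (
            reloaded.best_by_validation_rmse.index
            == study.best_by_validation_rmse.index
        )
        assert reloaded.best_by_validation_rmse.validation_rmse == pytest.approx(
            study.best_by_validation_rmse.validation_rmse
        )

    def test_resume_from_journal_keeps_existing_trials(self, tmp_path):
        journal = tmp_path / "study.jsonl"
        first = run_study(HyperparamSpace(), sampler="random", n_trials=3,
                          pruning=False, seed=4, evaluator=toy_evaluator,
                          journal_path=journal)
        resumed = run_study(HyperparamSpace(), sampler="random", n_trials=6,
                            pruning=False, seed=4, evaluator=toy_evaluator,
                            journal_path=journal)
        assert [t.config for t in resumed.trials[:3]] == [
            t.config for t in first.trials
        ]
        assert len(resumed.trials) == 6

    def test_invalid_budget_rejected(self):
        with pytest.raises(ConfigurationError):
            run_study(HyperparamSpace(), n_trials=0, evaluator=toy_evaluator)


class TestPruner:
    def test_never_prunes_before_first_rung(self):
        pruner = HalvingPruner(rungs=(10, 20), min_records=2)
        assert not pruner.report(5, 1e9)

    def test_prunes_worse_than_median_at_rung(self):
        pruner = HalvingPruner(rungs=(10,), min_records=2)
        assert not pruner.report(9, 1.0)  # fewer than min_records: recorded
        assert not pruner.report(9, 2.0)
        assert pruner.report(9, 10.0)  # above median of {1, 2}
        assert not pruner.report(9, 0.5)  # below the running median

    def test_pruned_trials_carry_partial_history(self):
        # an evaluator that reports a terrible loss at the rung is pruned
        calls = {"n": 0}

        def evaluator(config, trial_seed, pruner):
            calls["n"] += 1
            loss = 1.0 if calls["n"] <= 5 else 100.0
            pruned = False
            history = []
            for epoch in range(15):
                history.append(loss)
                if pruner is not None and pruner.report(epoch, loss):
                    pruned = True
                    break
            if pruned:
                return None, None, True, history, None
            return loss, loss, False, history, None

        study = run_study(HyperparamSpace(), sampler="random", n_trials=8,
                          pruning=True, seed=0, evaluator=evaluator)
        pruned = [t for t in study.trials if t.pruned]
        assert pruned, "late bad trials should have been pruned"
        for t in pruned:
            assert t.validation_rmse is None
            assert t.partial_history  # intermediate losses retained


class TestSelectFinal:
    def _trial(self, index, val_rmse, lstm_nodes=8, objective=0.5):
        config = {
            "n_lstm_blocks": 1, "lstm_nodes": lstm_nodes, "n_dense_blocks": 1,
            "ann_nodes_0": 8, "ann_nodes_1": 8, "ann_nodes_2": 8,
            "learning_rate": 0.0005, "epochs": 40,
        }
        return TrialRecord(index=index, config=config, objective=objective,
                           validation_rmse=val_rmse, pruned=False, seed=0,
                           duration=0.0)

    def test_single_completed_trial_selected(self):
        study = StudyResult([self._trial(0, 5.0)], "random", 1)
        assert study.best_by_validation_rmse.index == 0

    def test_tie_broken_by_parameter_count(self):
        big = self._trial(0, 5.0, lstm_nodes=64)
        small = self._trial(1, 5.0, lstm_nodes=8)
        study = StudyResult([big, small], "random", 2)
        assert study.best_by_validation_rmse.index == 1
        assert config_parameter_count(small.config) < config_parameter_count(
            big.config
        )

    def test_lowest_validation_rmse_wins_regardless_of_objective(self):
        # a trial may have the best training MSE yet lose on validation RMSE
        a = self._trial(0, 9.0, objective=0.01)
        b = self._trial(1, 4.0, objective=0.9)
        study = StudyResult([a, b], "tpe", 2)
        assert study.best_by_objective.index == 0
        assert study.best_by_validation_rmse.index == 1

    def test_no_completed_trials_is_an_error(self):
        study = StudyResult([], "tpe", 0)
        with pytest.raises(FitError):
            study.best_by_validation_rmse
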