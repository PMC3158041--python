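"""Train/test harness: plan construction, disjointness, self-consistency."""

import numpy as np
import pytest

from cbmfit.generalization import (
    ObjectiveEvaluator,
    TrainTestPlan,
    build_training_sets,
    evaluate,
    train,
)
from cbmfit.optimizer import AcceptanceCriterion, GAConfig
from cbmfit.stimuli import default_battery
from cbmfit.surrogate import NoiseModel, generate


class TestPlans:
    def test_five_canonical_plans_total_8s(self):
        lib = default_battery()
        plans = build_training_sets(lib)
        assert set(plans) == {"step", "ramp", "step+ramp", "noise1", "noise2"}
        for name, plan in plans.items():
            total = sum(
                lib[s].params.get("step_duration_s",
                                  lib[s].params.get("rise_s", lib[s].duration))
                if lib[s].kind != "ou_noise" else 8.0
                for s in plan.train)
            assert total == pytest.approx(8.0)
        assert len(plans["step"].train) == 4
        assert len(plans["step+ramp"].train) == 4
        assert sum(s.startswith("step") for s in plans["step+ramp"].train) == 2

    def test_test_sets_exclude_training_intensities(self):
        plans = build_training_sets(default_battery())
        p = plans["step"]
        assert set(p.train).isdisjoint(p.test_sets["steps"])
        assert len(p.test_sets["steps"]) == 2  # 6 steps - 4 trained

    def test_full_design_covers_all_test_conditions(self):
        """Each plan tests on every condition except its own training
        stimuli; noise plans consume their whole noise realization in
        training, so their within-kind cell comes from training accuracy."""
        plans = build_training_sets(default_battery())
        for name, p in plans.items():
            expected = 3 if name in ("noise1", "noise2") else 4
            assert len(p.test_sets) == expected
        assert set(plans["noise1"].test_sets) == {"steps", "ramps", "noise2"}

    def test_incomplete_library_reports_missing(self):
        lib = default_battery()
        lib.pop("noise2")
        with pytest.raises(ValueError, match="noise2"):
            build_training_sets(lib)

    def test_overlap_guard_raises_before_computation(self):
        with pytest.raises(ValueError, match="excluded"):
            TrainTestPlan(name="bad", train=("step1",),
                          test_sets={"steps": ("step1", "step2")})

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="no training stimuli"):
            TrainTestPlan(name="empty", train=())


class TestEvaluator:
    def test_objective_layout(self, desk_battery, desk_targets, ground_truth,
                              morphology, desk_config, free_params):
        stims = {n: desk_battery[n] for n in ("stepA", "rampA")}
        ev = ObjectiveEvaluator(stims, desk_targets, ground_truth, free_params,
                                morphology, desk_config)
        # 6 step features + 8 ramp features
        assert len(ev.labels) == 14
        assert ev.kinds == ("feature",) * 14

    def test_ground_truth_scores_near_zero(self, desk_battery, desk_targets,
                                           ground_truth, morphology,
                                           desk_config, free_params):
        stims = {"stepA": desk_battery["stepA"]}
        ev = ObjectiveEvaluator(stims, desk_targets, ground_truth, free_params,
                                morphology, desk_config)
        x = np.array([ground_truth[n] for n in free_params])
        assert ev(x).max() < 2.0

    def test_missing_targets_rejected(self, desk_battery, ground_truth,
                                      morphology, desk_config, free_params):
        with pytest.raises(ValueError, match="no targets"):
            ObjectiveEvaluator({"stepA": desk_battery["stepA"]}, {},
                               ground_truth, free_params, morphology,
                               desk_config)

    def test_noise_objective_is_one_minus_gcf(self, ground_truth, morphology,
                                              desk_config, free_params):
        from cbmfit.stimuli import make_ou_noise

        noise = {"nz": make_ou_noise(50.0, 100.0, 2.0, 2.0, 0.1, seed=2,
                                     name="nz")}
        ds = generate(battery=noise, n_reps=3, seed=8, morphology=morphology,
                      config=desk_config)
        targets = {"nz": ds.spike_trains("nz")}
        ev = ObjectiveEvaluator(noise, targets, ground_truth, free_params,
                                morphology, desk_config)
        assert ev.kinds == ("gcf",)
        x = np.array([ground_truth[n] for n in free_params])
        val = ev(x)[0]
        # the true model is nearly as reliable as its own repetitions
        assert 0.0 <= val < 0.5


class TestEvaluateReport:
    def test_ground_truth_self_consistency(self, desk_battery, desk_dataset,
                                           desk_targets, ground_truth,
                                           morphology, desk_config,
                                           free_params):
        """The true model's generalization error on its own data is small."""
        plan = TrainTestPlan(name="self", train=("stepA",),
                             test_sets={"steps": ("stepB",),
                                        "ramps": ("rampA",)})
        ev = ObjectiveEvaluator({"stepA": desk_battery["stepA"]}, desk_targets,
                                ground_truth, free_params, morphology,
                                desk_config)
        from cbmfit.generalization import FitResult
        from cbmfit.optimizer import EvolutionResult

        x = np.array([[ground_truth[n] for n in free_params]])
        fit = FitResult(
            plan=plan,
            evolution=EvolutionResult(
                params=x, objectives=ev(x[0])[None, :],
                ranks=np.zeros(1, dtype=np.int64), convergence=[],
                config=GAConfig(population=4, generations=1, repeats=1)),
            evaluator=ev, accepted=np.array([0]),
            criterion=AcceptanceCriterion())
        report = evaluate(fit, desk_battery, desk_targets)
        for (_, tname), row in report.rows.items():
            assert row["metric"] == "feature_error"
            assert row["mean"] < 1.0
            assert row["n_models"] == 1

    def test_empty_accepted_raises_with_diagnostics(self, desk_battery,
                                                    desk_targets, ground_truth,
                                                    morphology, desk_config,
                                                    free_params):
        plan = TrainTestPlan(name="p", train=("stepA",),
                             test_sets={"steps": ("stepB",)})
        ev = ObjectiveEvaluator({"stepA": desk_battery["stepA"]}, desk_targets,
                                ground_truth, free_params, morphology,
                                desk_config)
        from cbmfit.generalization import FitResult
        from cbmfit.optimizer import EvolutionResult

        x = np.array([[ground_truth[n] for n in free_params]])
        fit = FitResult(
            plan=plan,
            evolution=EvolutionResult(
                params=x, objectives=np.full((1, 6), 99.0),
                ranks=np.zeros(1, dtype=np.int64), convergence=[],
                config=GAConfig(population=4, generations=1, repeats=1)),
            evaluator=ev, accepted=np.empty(0, dtype=np.int64),
            criterion=AcceptanceCriterion())
        with pytest.raises(ValueError, match="no accepted models"):
            evaluate(fit, desk_battery, desk_targets)
        params, worst = fit.nearest_miss()
        assert worst == 99.0


class TestNoiseTraining:
    def test_gcf_objective_training_approaches_one(self, ground_truth,
                                                   morphology, desk_config,
                                                   free_params):
        """Training on a noise stimulus maximizes spike-time coincidence;
        the best model's training GCF approaches the intrinsic ceiling."""
        from cbmfit.stimuli import make_ou_noise

        noise = {"nz": make_ou_noise(50.0, 100.0, 2.0, 2.0, 0.1, seed=4,
                                     name="nz")}
        ds = generate(battery=noise, n_reps=4, seed=11, morphology=morphology,
                      config=desk_config)
        targets = {"nz": ds.spike_trains("nz")}
        plan = TrainTestPlan(name="nz", train=("nz",))
        fit = train(plan, noise, targets, ground_truth, free_params,
                    morphology, desk_config,
                    GAConfig(population=16, generations=15, repeats=1, seed=0))
        best_one_minus_gcf = fit.evolution.objectives.min()
        assert best_one_minus_gcf < 0.35  # best training GCF > 0.65


class TestTrainSmoke:
    def test_desk_fit_accepts_models(self, desk_battery, desk_targets,
                                     ground_truth, morphology, desk_config,
                                     free_params):
        """A tiny GA run on one step target finds acceptable models."""
        plan = TrainTestPlan(name="mini", train=("stepA",))
        fit = train(plan, desk_battery, desk_targets, ground_truth,
                    free_params, morphology, desk_config,
                    GAConfig(population=24, generations=30, repeats=1, seed=0))
        assert fit.evolution.params.shape[0] == 24
        assert fit.accepted.size >= 1
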