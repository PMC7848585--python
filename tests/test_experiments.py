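import numpy as np
import pandas as pd
import pytest

from scenegate.experiments import (
    DEFAULT_PHASES,
    ExperimentSpec,
    learning_curve,
    run_experiment,
    run_session,
    switch_aligned_accuracy,
)
from scenegate.model import make_mirrored_population
from scenegate.readout import ChoicePolicy
from scenegate.task import make_task_config


def small_spec(**kw):
    kw.setdefault("n_seeds", 3)
    return ExperimentSpec(**kw)


def test_spec_validation():
    with pytest.raises(ValueError):
        ExperimentSpec(condition="bogus")
    with pytest.raises(ValueError):
        ExperimentSpec(condition="normal", preset="no_scene_eight_object")
    with pytest.raises(ValueError):
        ExperimentSpec(condition="no_scene", preset="two_object_two_scene")
    with pytest.raises(ValueError):
        ExperimentSpec(update_policy="oracle")


def test_spec_round_trip():
    spec = small_spec(condition="fsi_removed_after_learning", seed=7)
    again = ExperimentSpec.from_dict(spec.to_dict())
    assert again.to_dict() == spec.to_dict()


def test_run_session_fills_choices_and_rewards():
    config = make_task_config("two_object_two_scene", n_trials=40)
    pop = make_mirrored_population(("A", "B"))
    trials, new_pop = run_session(
        config, pop, ChoicePolicy(), np.random.default_rng(0)
    )
    assert len(trials) == 40
    for t in trials:
        assert t.chosen in t.offered
        assert t.reward_volume in (0.1, 0.3)
        assert t.reward_signal in (1.0, -0.5)
    # learning happened: weights moved off their initial value
    assert any(
        s.object_weights != pop[i][1].object_weights for i, (_, s) in enumerate(new_pop)
    )
    # the input population objects were not mutated
    assert all(s.object_weights == {"A": 1.0, "B": 1.0} for _, s in pop)


def test_experiment_is_deterministic_per_seed():
    a = run_experiment(small_spec(seed=11, n_seeds=2))
    b = run_experiment(small_spec(seed=11, n_seeds=2))
    for la, lb in zip(a.logs, b.logs):
        pd.testing.assert_frame_equal(la, lb)
    c = run_experiment(small_spec(seed=12, n_seeds=2))
    assert not a.logs[0].equals(c.logs[0])


def test_normal_phase_structure():
    result = run_experiment(small_spec(seed=0, n_seeds=1))
    log = result.logs[0]
    assert len(log) == sum(n for _, n in DEFAULT_PHASES["normal"])
    assert list(log["phase"].unique()) == [0, 1, 2]
    assert (log["index"].to_numpy() == np.arange(len(log))).all()


def test_fsi_removed_condition_produces_eval_and_ablation_logs():
    result = run_experiment(
        small_spec(condition="fsi_removed_after_learning", n_seeds=2, eval_trials=60)
    )
    assert len(result.eval_logs) == 2
    assert len(result.ablation_logs) == 2
    assert all(len(log) == 60 for log in result.eval_logs)


def test_no_scene_condition_runs_without_scenes():
    result = run_experiment(small_spec(condition="no_scene", n_seeds=1))
    log = result.logs[0]
    assert (log["scene"] == "").all()


def test_weight_trajectories_recorded_on_request():
    result = run_experiment(small_spec(n_seeds=1, record_weights=True))
    traj = result.weight_trajectories[0]
    assert set(traj.columns) == {"trial", "unit", "element", "weight"}
    n_trials = sum(n for _, n in DEFAULT_PHASES["normal"])
    # 2 units x (2 object + 2 scene weights) per trial
    assert len(traj) == n_trials * 2 * 4


def test_chosen_only_policy_supported():
    result = run_experiment(small_spec(n_seeds=1, update_policy="chosen_only"))
    assert len(result.logs[0]) == 480


def test_accuracies_last_n():
    result = run_experiment(small_spec(n_seeds=2))
    full = result.accuracies()
    tail = result.accuracies(last_n=40)
    assert full.shape == tail.shape == (2,)
    assert np.all((0 <= full) & (full <= 1))


def test_learning_curve_bins():
    log = pd.DataFrame({"correct": [True] * 10 + [False] * 10})
    curve = learning_curve(log, bin_size=5)
    assert curve.tolist() == [1.0, 1.0, 0.0, 0.0]
    assert learning_curve(log, bin_size=7).shape == (3,)
    with pytest.raises(ValueError):
        learning_curve(log, bin_size=0)
    with pytest.raises(ValueError):
        learning_curve(pd.DataFrame({"correct": []}), bin_size=5)


def test_switch_aligned_accuracy_positions():
    log = pd.DataFrame(
        {
            "scene": ["X", "X", "Y", "Y", "X", "X"],
            "correct": [True, True, False, True, False, True],
        }
    )
    series = switch_aligned_accuracy(log)
    # switches at trials 2 and 4; position 0 holds trials 2 (False) and
    # 4 (False), position 1 holds trials 3 (True) and 5 (True)
    assert series[0] == pytest.approx(0.0)
    assert series[1] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        switch_aligned_accuracy(
            pd.DataFrame({"scene": ["X", "X"], "correct": [True, True]})
        )
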