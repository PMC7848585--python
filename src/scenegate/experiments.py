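"""End-to-end virtual experiments on the scene-gated circuit.

Four conditions mirror the behavioral/pharmacological manipulations:

``normal``
    Mirrored FSI scene inputs (0.6/1 and 1/0.6). The default protocol is
    two 160-trial block-sequenced learning sessions followed by one
    160-trial random-sequenced session - block learning first, random
    sequencing once switching is acquired.
``low_fsi_during_learning``
    Scene-blind FSI input (0.5/0.5) from the start, random sequencing,
    300 trials: the in-silico analogue of blocking FSI excitation before
    new-object learning.
``fsi_removed_after_learning``
    Train under the normal condition, then set every FSI input to zero
    and evaluate (learning frozen by default). A second evaluation
    additionally zeroes the learned scene weights, the ablation that
    collapses the retained behavior.
``no_scene``
    Eight objects with fixed values and no background scene; FSI input
    is irrelevant because no scene is presented.

Learning updates apply to both offered objects under their scheduled
outcomes by default (``update_policy="both_offered"``); restricting the
update to the chosen object is available as ``"chosen_only"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    DEFAULT_FSI_LOW,
    DEFAULT_FSI_NORMAL,
    DEFAULT_LEARNING_RATE,
    MSNUnit,
    ModelState,
    RewardSignal,
    StimulusPresentation,
    apply_update,
    make_mirrored_population,
)
from .io import derive_seed
from .readout import ChoicePolicy, choose, sc_drive
from .task import TaskConfig, Trial, generate_trials, make_task_config, trials_to_frame

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "run_session",
    "run_experiment",
    "learning_curve",
    "switch_aligned_accuracy",
    "DEFAULT_PHASES",
]

CONDITIONS = (
    "normal",
    "low_fsi_during_learning",
    "fsi_removed_after_learning",
    "no_scene",
)

#: Default phase structure (sequencing, n_trials) per condition.
DEFAULT_PHASES = {
    "normal": (("block", 160), ("block", 160), ("random", 160)),
    "low_fsi_during_learning": (("random", 300),),
    "fsi_removed_after_learning": (("block", 160), ("block", 160), ("random", 160)),
    "no_scene": (("none", 160),),
}


@dataclass(frozen=True)
class ExperimentSpec:
    condition: str = "normal"
    preset: Optional[str] = None
    phases: Optional[tuple[tuple[str, int], ...]] = None
    fsi: Optional[dict[str, float]] = None
    policy: ChoicePolicy = field(default_factory=ChoicePolicy)
    rectify: bool = True
    update_policy: str = "both_offered"  # | "chosen_only"
    learning_rate: float = DEFAULT_LEARNING_RATE
    n_seeds: int = 100
    seed: int = 0
    #: for fsi_removed_after_learning: length of the post-removal session
    eval_trials: int = 160
    #: keep plasticity on during the post-removal session
    continue_learning: bool = False
    record_weights: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.update_policy not in ("both_offered", "chosen_only"):
            raise ValueError(f"unknown update_policy {self.update_policy!r}")
        preset = self.resolved_preset()
        if self.condition == "no_scene" and preset != "no_scene_eight_object":
            raise ValueError("no_scene condition requires the no-scene preset")
        if self.condition != "no_scene" and preset == "no_scene_eight_object":
            raise ValueError("scene-based conditions require a scene-based preset")

    def resolved_preset(self) -> str:
        if self.preset is not None:
            return self.preset
        return (
            "no_scene_eight_object"
            if self.condition == "no_scene"
            else "two_object_two_scene"
        )

    def resolved_phases(self) -> tuple[tuple[str, int], ...]:
        return self.phases or DEFAULT_PHASES[self.condition]

    def resolved_fsi(self) -> dict[str, float]:
        if self.fsi is not None:
            return dict(self.fsi)
        if self.condition == "low_fsi_during_learning":
            return dict(DEFAULT_FSI_LOW)
        return dict(DEFAULT_FSI_NORMAL)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "preset": self.resolved_preset(),
            "phases": [list(p) for p in self.resolved_phases()],
            "fsi": self.resolved_fsi(),
            "policy": {
                "kind": self.policy.kind,
                "temperature": self.policy.temperature,
                "epsilon": self.policy.epsilon,
            },
            "rectify": self.rectify,
            "update_policy": self.update_policy,
            "learning_rate": self.learning_rate,
            "n_seeds": self.n_seeds,
            "seed": self.seed,
            "eval_trials": self.eval_trials,
            "continue_learning": self.continue_learning,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentSpec":
        policy = d.get("policy", {})
        return cls(
            condition=d.get("condition", "normal"),
            preset=d.get("preset"),
            phases=tuple(tuple(p) for p in d["phases"]) if d.get("phases") else None,
            fsi=d.get("fsi"),
            policy=ChoicePolicy(
                kind=policy.get("kind", "softmax"),
                temperature=policy.get("temperature", 5.0),
                epsilon=policy.get("epsilon", 0.0),
            ),
            rectify=d.get("rectify", True),
            update_policy=d.get("update_policy", "both_offered"),
            learning_rate=d.get("learning_rate", DEFAULT_LEARNING_RATE),
            n_seeds=d.get("n_seeds", 100),
            seed=d.get("seed", 0),
            eval_trials=d.get("eval_trials", 160),
            continue_learning=d.get("continue_learning", False),
        )


# ----------------------------------------------------------------------
# Session loop
# ----------------------------------------------------------------------

def run_session(
    config: TaskConfig,
    population: list[tuple[MSNUnit, ModelState]],
    policy: ChoicePolicy,
    rng: np.random.Generator,
    *,
    rectify: bool = True,
    learn: bool = True,
    update_policy: str = "both_offered",
    weight_rows: Optional[list] = None,
    trial_offset: int = 0,
) -> tuple[list[Trial], list[tuple[MSNUnit, ModelState]]]:
    """Run one session: choose -> reward -> update, trial by trial.

    Returns the completed trials and the updated population. The input
    population list is not mutated.
    """
    trials = generate_trials(config, rng)
    population = list(population)
    for trial in trials:
        drives = sc_drive(population, trial.offered, trial.scene, rectify=rectify)
        chosen = choose(drives, policy, rng)
        trial.chosen = chosen
        trial.reward_volume = config.reward_volume(trial.scene, chosen)
        trial.reward_signal = config.reward_signal(trial.scene, chosen)
        if learn:
            if update_policy == "both_offered":
                updates = [
                    (obj, config.reward_signal(trial.scene, obj))
                    for obj in trial.offered
                ]
            else:
                updates = [(chosen, trial.reward_signal)]
            for obj, signal in updates:
                stim = StimulusPresentation(object=obj, scene=trial.scene)
                reward = RewardSignal(signal)
                population = [
                    (u, apply_update(s, u, stim, reward, rectify=rectify))
                    for u, s in population
                ]
        if weight_rows is not None:
            t = trial.index + trial_offset
            for u, s in population:
                for o, w in s.object_weights.items():
                    weight_rows.append((t, u.unit_id, f"object:{o}", w))
                for sc, w in s.scene_weights.items():
                    weight_rows.append((t, u.unit_id, f"scene:{sc}", w))
    return trials, population


def _behavior_frame(config: TaskConfig, trials: Sequence[Trial]) -> pd.DataFrame:
    frame = trials_to_frame(trials)
    frame["correct"] = [
        t.chosen in config.good_objects(t.scene) for t in trials
    ]
    return frame


# ----------------------------------------------------------------------
# Experiment driver
# ----------------------------------------------------------------------

@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    #: one training log per seed (phases concatenated; `phase` column)
    logs: list[pd.DataFrame]
    #: final population per seed (after training)
    populations: list[list[tuple[MSNUnit, ModelState]]]
    config: TaskConfig = None
    #: fsi_removed_after_learning only: post-removal evaluation logs
    eval_logs: Optional[list[pd.DataFrame]] = None
    #: fsi_removed_after_learning only: scene weights additionally zeroed
    ablation_logs: Optional[list[pd.DataFrame]] = None
    weight_trajectories: Optional[list[pd.DataFrame]] = None

    def accuracies(self, last_n: Optional[int] = None, logs=None) -> np.ndarray:
        """Per-seed fraction correct over the last ``last_n`` trials."""
        logs = self.logs if logs is None else logs
        out = []
        for log in logs:
            col = log["correct"].to_numpy()
            out.append(col[-last_n:].mean() if last_n else col.mean())
        return np.asarray(out)


def _child_seed(base: int, i: int) -> int:
    return derive_seed(base, i)


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    config = make_task_config(spec.resolved_preset())
    fsi = spec.resolved_fsi()
    logs: list[pd.DataFrame] = []
    populations = []
    eval_logs: list[pd.DataFrame] = []
    ablation_logs: list[pd.DataFrame] = []
    weight_frames: list[pd.DataFrame] = []

    for i in range(spec.n_seeds):
        rng = np.random.default_rng(_child_seed(spec.seed, i))
        if config.scene_ids:
            population = make_mirrored_population(
                config.object_ids, config.scene_ids, fsi=fsi,
                learning_rate=spec.learning_rate,
            )
        else:
            # no scene labels: two identical units without scene input
            units = [
                MSNUnit(unit_id=f"msn_{k}", fsi_input={}) for k in range(2)
            ]
            population = [
                (u, ModelState.initial(config.object_ids, (),
                                       learning_rate=spec.learning_rate))
                for u in units
            ]

        weight_rows: Optional[list] = [] if spec.record_weights else None
        frames = []
        offset = 0
        for phase_idx, (sequencing, n_trials) in enumerate(spec.resolved_phases()):
            phase_config = replace(config, sequencing=sequencing, n_trials=n_trials)
            trials, population = run_session(
                phase_config, population, spec.policy, rng,
                rectify=spec.rectify, learn=True,
                update_policy=spec.update_policy,
                weight_rows=weight_rows, trial_offset=offset,
            )
            frame = _behavior_frame(phase_config, trials)
            frame["phase"] = phase_idx
            frame["index"] += offset
            offset += n_trials
            frames.append(frame)
        logs.append(pd.concat(frames, ignore_index=True))
        populations.append(population)

        if spec.condition == "fsi_removed_after_learning":
            removed = [
                (u.with_fsi({s: 0.0 for s in u.fsi_input}), st)
                for u, st in population
            ]
            eval_config = replace(
                config, sequencing="random", n_trials=spec.eval_trials
            )
            trials, _ = run_session(
                eval_config, removed, spec.policy, rng,
                rectify=spec.rectify, learn=spec.continue_learning,
                update_policy=spec.update_policy,
            )
            eval_logs.append(_behavior_frame(eval_config, trials))

            ablated = [
                (u, st.with_scene_weights({s: 0.0 for s in st.scene_weights}))
                for u, st in removed
            ]
            trials, _ = run_session(
                eval_config, ablated, spec.policy, rng,
                rectify=spec.rectify, learn=False,
                update_policy=spec.update_policy,
            )
            ablation_logs.append(_behavior_frame(eval_config, trials))

        if weight_rows is not None:
            weight_frames.append(
                pd.DataFrame(
                    weight_rows, columns=["trial", "unit", "element", "weight"]
                )
            )

    return ExperimentResult(
        spec=spec,
        logs=logs,
        populations=populations,
        config=config,
        eval_logs=eval_logs or None,
        ablation_logs=ablation_logs or None,
        weight_trajectories=weight_frames or None,
    )


# ----------------------------------------------------------------------
# Behavior metrics
# ----------------------------------------------------------------------

def learning_curve(log: pd.DataFrame, bin_size: int) -> np.ndarray:
    """Fraction of good-object choices per bin of trials, in session order."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    correct = log["correct"].to_numpy()
    if correct.size == 0:
        raise ValueError("empty behavior log")
    n_bins = -(-correct.size // bin_size)
    return np.array(
        [correct[b * bin_size: (b + 1) * bin_size].mean() for b in range(n_bins)]
    )


def switch_aligned_accuracy(
    log: pd.DataFrame, switch_points: Optional[Sequence[int]] = None
) -> pd.Series:
    """Mean correctness as a function of trials since the last scene switch.

    Position 0 is the first trial after a scene change. Trials before the
    first switch are excluded; positions with no data are simply absent.
    """
    scenes = log["scene"].to_numpy()
    correct = log["correct"].to_numpy()
    if switch_points is None:
        switch_points = [
            i for i in range(1, len(scenes)) if scenes[i] != scenes[i - 1]
        ]
    if not len(switch_points):
        raise ValueError("no scene switches in the log")
    switch_set = set(switch_points)
    position = np.full(len(scenes), -1, dtype=int)
    k = -1
    for i in range(len(scenes)):
        if i in switch_set:
            k = 0
        elif k >= 0:
            k += 1
        position[i] = k
    mask = position >= 0
    frame = pd.DataFrame({"position": position[mask], "correct": correct[mask]})
    return frame.groupby("position")["correct"].mean()
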