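"""Task configurations and trial-sequence generation.

Implements the behavioral procedures the circuit model is exercised on:

* the scene-based object-value task, in which each object's reward size
  (large vs. small) reverses between two background scenes,
* the no-scene object-value task, with fixed object values, and
* the passive-viewing schedule used to probe learned responses.

Scenes and objects are symbolic labels; trial timing is recorded as
metadata only, because the learning model operates at trial resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TaskConfig",
    "Trial",
    "PassiveSchedule",
    "make_task_config",
    "generate_trials",
    "generate_passive_schedule",
    "trials_to_frame",
    "PRESETS",
]

#: Reward volumes used throughout (mL): large for "good", small for "bad".
REWARD_LARGE = 0.3
REWARD_SMALL = 0.1

#: Model-scale reward signal: large reward -> +1, small reward -> -0.5.
#: A "bad" outcome is a small positive reward, but the learning signal
#: treats it as a negative teaching signal.
DEFAULT_REWARD_SIGNALS = {"large": 1.0, "small": -0.5}

#: Trial timing metadata (ms). Not used by the trial-resolution model.
TRIAL_TIMING_MS = {
    "scene_duration": 800,
    "fixation_min": 600,
    "fixation_max": 1000,
    "hold": 200,
}


class TaskConfigError(ValueError):
    """Raised when a task configuration violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Declarative description of one task variant.

    ``contingency`` maps ``(scene, object) -> reward volume`` for
    scene-based tasks, with ``scene=None`` for the no-scene task.
    """

    scene_ids: tuple[str, ...]
    object_ids: tuple[str, ...]
    contingency: Mapping[tuple[Optional[str], str], float]
    reward_large: float = REWARD_LARGE
    reward_small: float = REWARD_SMALL
    sequencing: str = "block"  # one of {"block", "random", "none"}
    block_length: int = 20
    n_trials: int = 160
    reward_signals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REWARD_SIGNALS)
    )

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.reward_large <= self.reward_small or self.reward_small <= 0:
            raise TaskConfigError(
                "reward volumes must satisfy reward_large > reward_small > 0"
            )
        if self.sequencing not in ("block", "random", "none"):
            raise TaskConfigError(f"unknown sequencing {self.sequencing!r}")
        if self.sequencing == "none" and self.scene_ids:
            raise TaskConfigError(
                "sequencing='none' is only valid for a task without scenes"
            )
        if self.scene_ids and self.sequencing == "none":
            raise TaskConfigError("scene-based contingency requires scene sequencing")
        if self.n_trials < 0:
            raise TaskConfigError("n_trials must be >= 0")
        if self.block_length < 1:
            raise TaskConfigError("block_length must be >= 1")
        scenes: Sequence[Optional[str]] = self.scene_ids or (None,)
        volumes = {self.reward_large, self.reward_small}
        for s in scenes:
            for o in self.object_ids:
                if (s, o) not in self.contingency:
                    raise TaskConfigError(f"contingency missing entry for {(s, o)}")
                if self.contingency[(s, o)] not in volumes:
                    raise TaskConfigError(
                        f"contingency[{(s, o)}] must be one of {sorted(volumes)}"
                    )
        # scene-based tasks: each object's value label reverses between the
        # two scenes of a pair
        if len(self.scene_ids) == 2:
            s1, s2 = self.scene_ids
            for o in self.object_ids:
                if self.contingency[(s1, o)] == self.contingency[(s2, o)]:
                    raise TaskConfigError(
                        f"object {o!r} must reverse value between scenes "
                        f"{s1!r} and {s2!r}"
                    )

    # ------------------------------------------------------------------
    def good_objects(self, scene: Optional[str]) -> tuple[str, ...]:
        return tuple(
            o
            for o in self.object_ids
            if self.contingency[(scene, o)] == self.reward_large
        )

    def bad_objects(self, scene: Optional[str]) -> tuple[str, ...]:
        return tuple(
            o
            for o in self.object_ids
            if self.contingency[(scene, o)] == self.reward_small
        )

    def reward_volume(self, scene: Optional[str], obj: str) -> float:
        return self.contingency[(scene, obj)]

    def reward_signal(self, scene: Optional[str], obj: str) -> float:
        vol = self.reward_volume(scene, obj)
        key = "large" if vol == self.reward_large else "small"
        return self.reward_signals[key]

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scene_ids": list(self.scene_ids),
            "object_ids": list(self.object_ids),
            "contingency": [
                {"scene": s, "object": o, "reward_volume": v}
                for (s, o), v in sorted(
                    self.contingency.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])
                )
            ],
            "reward_large": self.reward_large,
            "reward_small": self.reward_small,
            "sequencing": self.sequencing,
            "block_length": self.block_length,
            "n_trials": self.n_trials,
            "reward_signals": dict(self.reward_signals),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        contingency = {
            (row["scene"], row["object"]): row["reward_volume"]
            for row in d["contingency"]
        }
        return cls(
            scene_ids=tuple(d["scene_ids"]),
            object_ids=tuple(d["object_ids"]),
            contingency=contingency,
            reward_large=d.get("reward_large", REWARD_LARGE),
            reward_small=d.get("reward_small", REWARD_SMALL),
            sequencing=d.get("sequencing", "block"),
            block_length=d.get("block_length", 20),
            n_trials=d.get("n_trials", 160),
            reward_signals=d.get("reward_signals", dict(DEFAULT_REWARD_SIGNALS)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class Trial:
    """One simulated trial. ``chosen``/rewards are filled by the agent."""

    index: int
    scene: Optional[str]
    offered: tuple[str, str]
    block_id: int
    chosen: Optional[str] = None
    reward_volume: Optional[float] = None
    reward_signal: Optional[float] = None


@dataclass(frozen=True)
class PassiveSchedule:
    """Ordered (scene, object) presentations for a passive-viewing probe."""

    presentations: tuple[tuple[Optional[str], str], ...]
    reps: int
    presentation_ms: int = 400
    interstimulus_ms: int = 400

    def counts(self) -> dict[tuple[Optional[str], str], int]:
        out: dict[tuple[Optional[str], str], int] = {}
        for p in self.presentations:
            out[p] = out.get(p, 0) + 1
        return out


# ----------------------------------------------------------------------
# Presets
# ----------------------------------------------------------------------

def _scene_based_contingency(
    scenes: Sequence[str], group_a: Sequence[str], group_b: Sequence[str]
) -> dict[tuple[Optional[str], str], float]:
    """Group A good in the first scene, group B good in the second."""
    s1, s2 = scenes
    cont: dict[tuple[Optional[str], str], float] = {}
    for o in group_a:
        cont[(s1, o)] = REWARD_LARGE
        cont[(s2, o)] = REWARD_SMALL
    for o in group_b:
        cont[(s1, o)] = REWARD_SMALL
        cont[(s2, o)] = REWARD_LARGE
    return cont


def _preset_two_object_two_scene() -> TaskConfig:
    return TaskConfig(
        scene_ids=("X", "Y"),
        object_ids=("A", "B"),
        contingency=_scene_based_contingency(("X", "Y"), ("A",), ("B",)),
        sequencing="block",
    )


def _preset_eight_object_two_scene() -> TaskConfig:
    group_a = tuple(f"A{i}" for i in range(1, 5))
    group_b = tuple(f"B{i}" for i in range(1, 5))
    return TaskConfig(
        scene_ids=("X", "Y"),
        object_ids=group_a + group_b,
        contingency=_scene_based_contingency(("X", "Y"), group_a, group_b),
        sequencing="block",
    )


def _preset_no_scene_eight_object() -> TaskConfig:
    goods = tuple(f"G{i}" for i in range(1, 5))
    bads = tuple(f"D{i}" for i in range(1, 5))
    cont: dict[tuple[Optional[str], str], float] = {}
    for o in goods:
        cont[(None, o)] = REWARD_LARGE
    for o in bads:
        cont[(None, o)] = REWARD_SMALL
    return TaskConfig(
        scene_ids=(),
        object_ids=goods + bads,
        contingency=cont,
        sequencing="none",
    )


PRESETS = {
    "two_object_two_scene": _preset_two_object_two_scene,
    "eight_object_two_scene": _preset_eight_object_two_scene,
    "no_scene_eight_object": _preset_no_scene_eight_object,
}


def make_task_config(preset: str, **overrides) -> TaskConfig:
    """Build a validated :class:`TaskConfig` from a named preset.

    ``overrides`` may touch any declared field; the result is re-validated,
    so an override that breaks the scene-reversal invariant raises
    :class:`TaskConfigError`.
    """
    if preset not in PRESETS:
        raise TaskConfigError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = PRESETS[preset]()
    if overrides:
        unknown = set(overrides) - set(config.__dataclass_fields__)
        if unknown:
            raise TaskConfigError(f"unknown override fields: {sorted(unknown)}")
        config = replace(config, **overrides)
    return config


# ----------------------------------------------------------------------
# Trial generation
# ----------------------------------------------------------------------

def _scene_sequence(config: TaskConfig, rng: np.random.Generator) -> list[Optional[str]]:
    n = config.n_trials
    if not config.scene_ids:
        return [None] * n
    scenes = list(config.scene_ids)
    if config.sequencing == "random":
        idx = rng.integers(0, len(scenes), size=n)
        return [scenes[i] for i in idx]
    # block mode: the scene is switched at every block boundary, so a
    # 160-trial session with block_length 20 contains exactly 8 maximal
    # runs of constant scene. The first block's scene is drawn from the rng.
    start = int(rng.integers(0, len(scenes)))
    seq: list[Optional[str]] = []
    n_blocks = -(-n // config.block_length)
    for b in range(n_blocks):
        seq.extend([scenes[(start + b) % len(scenes)]] * config.block_length)
    return seq[:n]


def generate_trials(config: TaskConfig, seed) -> list[Trial]:
    """Generate trial skeletons (scene and offered pair; choice unfilled).

    ``seed`` may be an int or a ``numpy.random.Generator``. Every trial
    offers exactly one currently-good and one currently-bad object, drawn
    uniformly and presented in random left/right order. Fully reproducible
    from the seed.
    """
    if config.scene_ids and config.sequencing == "none":
        raise TaskConfigError("scene-based contingency requires scene sequencing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scene_seq = _scene_sequence(config, rng)
    trials: list[Trial] = []
    for t, scene in enumerate(scene_seq):
        goods = config.good_objects(scene)
        bads = config.bad_objects(scene)
        g = goods[int(rng.integers(len(goods)))]
        b = bads[int(rng.integers(len(bads)))]
        offered = (g, b) if rng.random() < 0.5 else (b, g)
        block_id = t // config.block_length if config.scene_ids else 0
        trials.append(Trial(index=t, scene=scene, offered=offered, block_id=block_id))
    return trials


def generate_passive_schedule(
    config: TaskConfig, reps: int, seed, *, force: bool = False
) -> PassiveSchedule:
    """Shuffled schedule with every (scene, object) cell appearing ``reps`` times.

    Probe sessions present each object at least seven times per scene;
    ``reps < 7`` is rejected unless ``force=True``.
    """
    if reps < 7 and not force:
        raise TaskConfigError(
            "reps must be >= 7 (each object is presented at least seven times "
            "per scene); pass force=True to override"
        )
    if reps < 1:
        raise TaskConfigError("reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scenes: Sequence[Optional[str]] = config.scene_ids or (None,)
    cells = [(s, o) for s in scenes for o in config.object_ids for _ in range(reps)]
    order = rng.permutation(len(cells))
    return PassiveSchedule(
        presentations=tuple(cells[i] for i in order), reps=reps
    )


# ----------------------------------------------------------------------
# Serialization of behavior logs
# ----------------------------------------------------------------------

def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Long-format behavior log (one row per trial)."""
    rows = [
        {
            "index": t.index,
            "scene": t.scene if t.scene is not None else "",
            "offered_1": t.offered[0],
            "offered_2": t.offered[1],
            "chosen": t.chosen if t.chosen is not None else "",
            "reward_volume": t.reward_volume,
            "reward_signal": t.reward_signal,
            "block_id": t.block_id,
        }
        for t in trials
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "index",
            "scene",
            "offered_1",
            "offered_2",
            "chosen",
            "reward_volume",
            "reward_signal",
            "block_id",
        ],
    )
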