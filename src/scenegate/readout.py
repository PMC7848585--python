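"""Basal-ganglia readout and unit-level coding metrics.

MSN output reaches the superior colliculus through a double-inhibitory
(disinhibitory) pathway (MSN -| SNr -| SC); because that pathway is
monotone-increasing end to end, the saccade drive for an object is
modelled as the sum of MSN activations to that object under the current
scene. Choices are drawn from a logistic (softmax) policy on the drive
difference. The policy layer is a modelling convenience: the recorded
circuit specifies no behavioral choice rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .model import MSNUnit, ModelState, ResponseMatrix, StimulusPresentation, msn_response
from .task import TaskConfig

__all__ = [
    "ChoicePolicy",
    "sc_drive",
    "choose",
    "scene_preference",
    "value_coding_index",
    "DEFAULT_SOFTMAX_BETA",
]

#: Default inverse temperature; with it the normal-condition agent reaches
#: high late-session accuracy on the scene task.
DEFAULT_SOFTMAX_BETA = 5.0


@dataclass(frozen=True)
class ChoicePolicy:
    """Softmax or epsilon-greedy mapping from drives to a choice."""

    kind: str = "softmax"  # "softmax" | "argmax_with_epsilon"
    temperature: float = DEFAULT_SOFTMAX_BETA  # inverse temperature (beta)
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("softmax", "argmax_with_epsilon"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "softmax" and self.temperature <= 0:
            raise ValueError("softmax temperature (beta) must be > 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")


def sc_drive(
    population: Sequence[tuple[MSNUnit, ModelState]],
    offered: Sequence[str],
    scene: Optional[str],
    rectify: bool = False,
) -> dict[str, float]:
    """Summed MSN activation per offered object under the current scene.

    Monotone in every unit's activation, so it preserves the ordering the
    disinhibitory pathway establishes.
    """
    if not population:
        raise ValueError("population must be non-empty")
    return {
        obj: sum(
            msn_response(
                state, unit, StimulusPresentation(object=obj, scene=scene),
                rectify=rectify,
            )
            for unit, state in population
        )
        for obj in offered
    }


def choice_probability(d1: float, d2: float, beta: float) -> float:
    """P(choose object 1) under the logistic policy: 1/(1+exp(-beta*(d1-d2)))."""
    return float(expit(beta * (d1 - d2)))


def choose(
    drives: Mapping[str, float],
    policy: ChoicePolicy,
    rng: np.random.Generator,
) -> str:
    """Draw a choice between two offered objects from the policy."""
    items = list(drives.items())
    if len(items) != 2:
        raise ValueError("choose expects exactly two offered objects")
    (o1, d1), (o2, d2) = items
    if not (np.isfinite(d1) and np.isfinite(d2)):
        raise ValueError("drives must be finite")
    if policy.kind == "softmax":
        p1 = choice_probability(d1, d2, policy.temperature)
    else:
        if d1 == d2:
            p1 = 0.5
        else:
            greedy = 1.0 if d1 > d2 else 0.0
            p1 = (1 - policy.epsilon) * greedy + policy.epsilon * 0.5
    return o1 if rng.random() < p1 else o2


def scene_preference(matrix: ResponseMatrix, unit_id: str) -> tuple[str, bool]:
    """Preferred scene of a unit: argmax of mean activation over objects.

    Returns ``(scene, tied)``; ties resolve to the first-declared scene
    with the tie flag set.
    """
    if unit_id not in matrix.unit_ids:
        raise KeyError(f"unit {unit_id!r} not in matrix")
    means = [matrix.unit_scene_mean(unit_id, s) for s in matrix.scene_ids]
    best = int(np.argmax(means))
    tied = bool(np.sum(np.isclose(means, means[best])) > 1)
    return matrix.scene_ids[best], tied


def value_coding_index(
    matrix: ResponseMatrix,
    unit_id: str,
    config: TaskConfig,
    scene: str,
) -> float:
    """mean(activations to good objects) - mean(to bad objects) in a scene.

    Positive means the unit fires more to the objects that are currently
    good under that scene's contingency.
    """
    if scene not in config.scene_ids:
        raise KeyError(f"scene {scene!r} not in the task contingency")
    goods = config.good_objects(scene)
    bads = config.bad_objects(scene)
    good_mean = np.mean([matrix.activation(unit_id, o, scene) for o in goods])
    bad_mean = np.mean([matrix.activation(unit_id, o, scene) for o in bads])
    return float(good_mean - bad_mean)
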