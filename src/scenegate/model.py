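"""The MSN-FSI scene-gated value-learning model.

Each medium spiny neuron (MSN) receives plastic excitatory cortical input
for every object and every scene, and fixed scene-selective inhibition
from fast-spiking interneurons (FSIs). Its response to a presentation is

    MSN = (sum_o I_o * S_o  +  sum_s I_s * S_s) / (sum_s I_s * FSI_s)

where the indicators I are 1 for presented labels and 0 otherwise, S are
synaptic weights, and FSI_s is the inhibitory input magnitude for scene s.
The FSI term acts as divisive (shunting) gain: strong scene inhibition
(FSI = 1) leaves the drive unscaled, weak inhibition (FSI = 0.6) amplifies
it, so each MSN is more responsive - and more plastic - in the scene whose
FSI inhibits it least. When no scene is presented, or the presented
scene's FSI magnitude is zero (inhibition removed), the divisor is 1.

Dopamine-gated plasticity is a three-factor rule: every presented
element's weight moves by

    S_e <- S_e + I_e * MSN * Reward * LS

with the response evaluated on the pre-update state, Reward = +1 for a
large reward and -0.5 for a small one, and learning rate LS = 0.01.

Responses may optionally be rectified at zero (firing rates cannot be
negative); the bare equations are linear, so rectification defaults off
here and is switched on by the virtual experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MSNUnit",
    "ModelState",
    "StimulusPresentation",
    "RewardSignal",
    "ResponseMatrix",
    "msn_response",
    "apply_update",
    "simulate_passive_probe",
    "make_mirrored_population",
    "DEFAULT_FSI_NORMAL",
    "DEFAULT_FSI_LOW",
    "DEFAULT_LEARNING_RATE",
    "DEFAULT_INITIAL_WEIGHT",
]

#: FSI inhibitory magnitudes for the scene X-preferring unit under the
#: normal condition; the scene Y-preferring unit mirrors them.
DEFAULT_FSI_NORMAL = {"X": 0.6, "Y": 1.0}
#: Under the low-FSI (blockade-during-learning) condition both scenes
#: provide the same weak inhibition, so no scene information reaches MSNs.
DEFAULT_FSI_LOW = {"X": 0.5, "Y": 0.5}
DEFAULT_LEARNING_RATE = 0.01
DEFAULT_INITIAL_WEIGHT = 1.0


@dataclass(frozen=True)
class MSNUnit:
    """Immutable identity of one model MSN: its FSI scene-input vector."""

    unit_id: str
    fsi_input: Mapping[str, float]
    group: Optional[str] = None  # e.g. "scene_X_preferring"

    def __post_init__(self) -> None:
        for s, v in self.fsi_input.items():
            if v < 0:
                raise ValueError(f"fsi_input[{s!r}] must be >= 0")

    def with_fsi(self, fsi_input: Mapping[str, float]) -> "MSNUnit":
        return replace(self, fsi_input=dict(fsi_input))


@dataclass(frozen=True)
class ModelState:
    """One MSN's mutable synaptic weights (returned anew by updates)."""

    object_weights: Mapping[str, float]
    scene_weights: Mapping[str, float]
    learning_rate: float = DEFAULT_LEARNING_RATE

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        for d in (self.object_weights, self.scene_weights):
            for k, v in d.items():
                if not np.isfinite(v):
                    raise ValueError(f"weight for {k!r} is not finite")

    @classmethod
    def initial(
        cls,
        objects: Iterable[str],
        scenes: Iterable[str],
        learning_rate: float = DEFAULT_LEARNING_RATE,
        weight: float = DEFAULT_INITIAL_WEIGHT,
    ) -> "ModelState":
        return cls(
            object_weights={o: weight for o in objects},
            scene_weights={s: weight for s in scenes},
            learning_rate=learning_rate,
        )

    def with_scene_weights(self, scene_weights: Mapping[str, float]) -> "ModelState":
        return replace(self, scene_weights=dict(scene_weights))


@dataclass(frozen=True)
class StimulusPresentation:
    """At most one object and one scene, as in passive viewing."""

    object: Optional[str] = None
    scene: Optional[str] = None


@dataclass(frozen=True)
class RewardSignal:
    """Model-scale reward: +1 (large reward) or -0.5 (small/none)."""

    value: float

    LARGE = 1.0
    SMALL = -0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("reward value must be finite")


def msn_response(
    state: ModelState,
    unit: MSNUnit,
    stim: StimulusPresentation,
    rectify: bool = False,
) -> float:
    """Response of one MSN to a presentation. Pure function.

    Excitatory drive is the sum of the presented object's and scene's
    weights; the presented scene's FSI magnitude divides it. A zero FSI
    magnitude means the inhibition is absent (divisor 1), as does a
    presentation with no scene.
    """
    drive = 0.0
    if stim.object is not None:
        if stim.object not in state.object_weights:
            raise KeyError(f"unknown object {stim.object!r}")
        drive += state.object_weights[stim.object]
    divisor = 1.0
    if stim.scene is not None:
        if stim.scene not in state.scene_weights:
            raise KeyError(f"unknown scene {stim.scene!r}")
        drive += state.scene_weights[stim.scene]
        fsi = unit.fsi_input.get(stim.scene, 0.0)
        if fsi > 0:
            divisor = fsi
    activation = drive / divisor
    if rectify and activation < 0:
        return 0.0
    return activation


def apply_update(
    state: ModelState,
    unit: MSNUnit,
    stim: StimulusPresentation,
    reward: RewardSignal,
    rectify: bool = False,
) -> ModelState:
    """Three-factor weight update; returns a new state.

    Only the presented object's and scene's weights change, each by
    ``response * reward * learning_rate`` with the response computed on
    the pre-update state. Weights of absent elements are untouched.
    """
    response = msn_response(state, unit, stim, rectify=rectify)
    delta = response * reward.value * state.learning_rate
    object_weights = dict(state.object_weights)
    scene_weights = dict(state.scene_weights)
    if stim.object is not None:
        object_weights[stim.object] += delta
    if stim.scene is not None:
        scene_weights[stim.scene] += delta
    return ModelState(
        object_weights=object_weights,
        scene_weights=scene_weights,
        learning_rate=state.learning_rate,
    )


# ----------------------------------------------------------------------
# Population helpers and passive probes
# ----------------------------------------------------------------------

def make_mirrored_population(
    objects: Sequence[str],
    scenes: Sequence[str] = ("X", "Y"),
    fsi: Optional[Mapping[str, float]] = None,
    learning_rate: float = DEFAULT_LEARNING_RATE,
) -> list[tuple[MSNUnit, ModelState]]:
    """Two MSNs with mirrored FSI scene inputs.

    The first unit receives ``fsi`` as given (default: weak inhibition in
    scene X, hence scene X-preferring); the second receives the values
    with the two scenes swapped (scene Y-preferring). With equal FSI
    across scenes (the low-FSI condition) the two units are identical.
    """
    if fsi is None:
        fsi = DEFAULT_FSI_NORMAL
    if len(scenes) != 2:
        raise ValueError("the mirrored population is defined for two scenes")
    s1, s2 = scenes
    fsi1 = {s1: fsi[s1], s2: fsi[s2]}
    fsi2 = {s1: fsi[s2], s2: fsi[s1]}
    units = [
        MSNUnit(unit_id="msn_pref_" + s1, fsi_input=fsi1,
                group=f"scene_{s1}_preferring"),
        MSNUnit(unit_id="msn_pref_" + s2, fsi_input=fsi2,
                group=f"scene_{s2}_preferring"),
    ]
    return [
        (u, ModelState.initial(objects, scenes, learning_rate=learning_rate))
        for u in units
    ]


@dataclass
class ResponseMatrix:
    """Unit x object x scene activations from a passive-viewing probe."""

    activations: Mapping[tuple[str, str, str], float]
    unit_ids: tuple[str, ...]
    object_ids: tuple[str, ...]
    scene_ids: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def activation(self, unit_id: str, obj: str, scene: str) -> float:
        return self.activations[(unit_id, obj, scene)]

    def unit_scene_mean(self, unit_id: str, scene: str) -> float:
        """Mean activation across all objects in one scene."""
        return float(
            np.mean([self.activations[(unit_id, o, scene)] for o in self.object_ids])
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"unit": u, "object": o, "scene": s, "activation": a}
            for (u, o, s), a in sorted(self.activations.items())
        ]
        return pd.DataFrame(rows, columns=["unit", "object", "scene", "activation"])


def simulate_passive_probe(
    population: Sequence[tuple[MSNUnit, ModelState]],
    objects: Sequence[str],
    scenes: Sequence[str],
    rectify: bool = False,
    metadata: Optional[dict] = None,
) -> ResponseMatrix:
    """Probe every (unit, object, scene) combination without learning."""
    if not population:
        raise ValueError("population must be non-empty")
    activations = {
        (unit.unit_id, o, s): msn_response(
            state, unit, StimulusPresentation(object=o, scene=s), rectify=rectify
        )
        for unit, state in population
        for o in objects
        for s in scenes
    }
    return ResponseMatrix(
        activations=activations,
        unit_ids=tuple(u.unit_id for u, _ in population),
        object_ids=tuple(objects),
        scene_ids=tuple(scenes),
        metadata=dict(metadata or {}),
    )
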