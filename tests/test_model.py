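import numpy as np
import pytest
from hypothesis import given, strategies as st

from scenegate.model import (
    DEFAULT_FSI_LOW,
    DEFAULT_FSI_NORMAL,
    ModelState,
    MSNUnit,
    RewardSignal,
    StimulusPresentation,
    apply_update,
    make_mirrored_population,
    msn_response,
    simulate_passive_probe,
)

UNIT_X = MSNUnit(unit_id="u", fsi_input=DEFAULT_FSI_NORMAL)


def fresh_state(lr=0.01):
    return ModelState.initial(("A", "B"), ("X", "Y"), learning_rate=lr)


def test_response_is_divisively_gained_by_fsi():
    state = fresh_state()
    # weak inhibition (0.6) amplifies, strong (1.0) leaves unscaled
    rx = msn_response(state, UNIT_X, StimulusPresentation("A", "X"))
    ry = msn_response(state, UNIT_X, StimulusPresentation("A", "Y"))
    assert rx == pytest.approx((1 + 1) / 0.6)
    assert ry == pytest.approx(2.0)


def test_no_scene_and_zero_fsi_use_unit_divisor():
    state = fresh_state()
    assert msn_response(state, UNIT_X, StimulusPresentation("A", None)) == 1.0
    removed = UNIT_X.with_fsi({"X": 0.0, "Y": 0.0})
    assert msn_response(state, removed, StimulusPresentation("A", "X")) == 2.0


def test_unknown_labels_raise():
    state = fresh_state()
    with pytest.raises(KeyError):
        msn_response(state, UNIT_X, StimulusPresentation("Z", "X"))
    with pytest.raises(KeyError):
        msn_response(state, UNIT_X, StimulusPresentation("A", "Q"))


def test_rectification_clips_negative_responses():
    state = fresh_state().with_scene_weights({"X": -5.0, "Y": 1.0})
    stim = StimulusPresentation("A", "X")
    assert msn_response(state, UNIT_X, stim) < 0
    assert msn_response(state, UNIT_X, stim, rectify=True) == 0.0


def test_update_touches_only_presented_elements():
    state = fresh_state()
    stim = StimulusPresentation("A", "X")
    new = apply_update(state, UNIT_X, stim, RewardSignal(RewardSignal.LARGE))
    resp = msn_response(state, UNIT_X, stim)
    delta = resp * 1.0 * 0.01
    assert new.object_weights["A"] == pytest.approx(1 + delta)
    assert new.scene_weights["X"] == pytest.approx(1 + delta)
    assert new.object_weights["B"] == 1.0
    assert new.scene_weights["Y"] == 1.0
    # input state is unchanged (pure function)
    assert state.object_weights["A"] == 1.0


def test_update_uses_pre_update_response():
    state = fresh_state()
    stim = StimulusPresentation("A", "X")
    new = apply_update(state, UNIT_X, stim, RewardSignal(RewardSignal.SMALL))
    # delta computed from the response of the *old* state
    expected = msn_response(state, UNIT_X, stim) * (-0.5) * 0.01
    assert new.object_weights["A"] - 1.0 == pytest.approx(expected)


def test_zero_learning_rate_freezes_weights():
    state = fresh_state(lr=0.0)
    new = apply_update(
        state, UNIT_X, StimulusPresentation("A", "X"), RewardSignal(1.0)
    )
    assert new == state


@given(
    rewards=st.lists(st.sampled_from([1.0, -0.5]), min_size=1, max_size=60),
    seed=st.integers(0, 10_000),
)
def test_weights_stay_finite_and_deltas_bounded(rewards, seed):
    rng = np.random.default_rng(seed)
    state = fresh_state()
    for r in rewards:
        stim = StimulusPresentation(
            object=("A", "B")[rng.integers(2)], scene=("X", "Y")[rng.integers(2)]
        )
        resp = msn_response(state, UNIT_X, stim)
        new = apply_update(state, UNIT_X, stim, RewardSignal(r))
        d = new.object_weights[stim.object] - state.object_weights[stim.object]
        assert abs(d) <= abs(resp) * 0.01 * 1.0 + 1e-12
        assert all(np.isfinite(list(new.object_weights.values())))
        state = new


def test_mirrored_population_swaps_fsi():
    pop = make_mirrored_population(("A", "B"))
    (u1, _), (u2, _) = pop
    assert u1.fsi_input == {"X": 0.6, "Y": 1.0}
    assert u2.fsi_input == {"X": 1.0, "Y": 0.6}
    low = make_mirrored_population(("A", "B"), fsi=DEFAULT_FSI_LOW)
    assert low[0][0].fsi_input == low[1][0].fsi_input


def test_negative_fsi_rejected():
    with pytest.raises(ValueError):
        MSNUnit(unit_id="u", fsi_input={"X": -0.1})


def test_passive_probe_covers_all_cells_without_learning():
    pop = make_mirrored_population(("A", "B"))
    matrix = simulate_passive_probe(pop, ("A", "B"), ("X", "Y"))
    assert len(matrix.activations) == 2 * 2 * 2
    # naive weights: response depends only on the unit's FSI in that scene
    assert matrix.activation("msn_pref_X", "A", "X") == pytest.approx(2 / 0.6)
    assert matrix.activation("msn_pref_X", "A", "Y") == pytest.approx(2.0)
    frame = matrix.to_frame()
    assert set(frame.columns) == {"unit", "object", "scene", "activation"}
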