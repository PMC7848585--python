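import numpy as np
import pytest
from hypothesis import given, strategies as st

from scenegate.ephys import (
    ClassifierThresholds,
    baseline_rate,
    classify_record,
    classify_unit,
    median_waveform,
    paired_response_test,
    peak_trough_duration,
    response_significance,
    spike_density,
    window_counts,
)
from scenegate.units import (
    UnitRecord,
    generate_synthetic_unit,
    load_unit_record,
    save_unit_record,
    waveform_template,
)

T800 = ClassifierThresholds(duration_cutoff_us=800.0)


# ----------------------------------------------------------------------
# synthetic units
# ----------------------------------------------------------------------

def test_spike_times_strictly_increasing_enforced():
    with pytest.raises(ValueError):
        UnitRecord(
            waveform=np.zeros(8), sampling_interval_us=25.0,
            spike_times_s=np.array([0.1, 0.1, 0.2]),
        )


def test_generate_synthetic_unit_layout():
    u = generate_synthetic_unit(600, 5.0, n_events=10, seed=0)
    assert u.scene_onsets_s.shape == (10,)
    assert np.allclose(u.object_onsets_s - u.scene_onsets_s, 0.8)
    assert np.all(np.diff(u.spike_times_s) > 0)


def test_evoked_rate_raises_counts_in_window():
    u = generate_synthetic_unit(600, 2.0, evoked_hz=40.0, n_events=60, seed=3)
    evoked = window_counts(u.spike_times_s, u.object_onsets_s, (0.05, 0.40))
    pre = window_counts(u.spike_times_s, u.object_onsets_s, (-0.25, 0.0))
    assert evoked.mean() / 0.35 > 4 * (pre.mean() / 0.25 + 0.5)


def test_unit_record_h5_round_trip(tmp_path):
    u = generate_synthetic_unit(
        600, 5.0, n_events=5, seed=0, ground_truth_class="MSN",
        scene_object_pairs=[("X", "A"), ("Y", "B")],
    )
    path = tmp_path / "u.h5"
    save_unit_record(u, path)
    v = load_unit_record(path)
    assert np.allclose(u.waveform, v.waveform)
    assert np.allclose(u.spike_times_s, v.spike_times_s)
    assert v.object_labels == u.object_labels
    assert v.ground_truth_class == "MSN"


# ----------------------------------------------------------------------
# waveform measurements
# ----------------------------------------------------------------------

@given(duration=st.sampled_from([300, 400, 480, 600, 800, 1000, 1200]))
def test_duration_recovered_within_one_sample(duration):
    est = peak_trough_duration(waveform_template(duration), 25.0)
    assert abs(est - duration) <= 25.0


def test_peak_trough_rejects_flat_and_monotone():
    with pytest.raises(ValueError):
        peak_trough_duration(np.ones(20), 25.0)
    with pytest.raises(ValueError):
        peak_trough_duration(np.arange(20.0), 25.0)


def test_median_waveform_identical_traces():
    w = waveform_template(600)
    assert np.allclose(median_waveform([w, w, w]), w)


def test_median_waveform_constant_offsets():
    base = np.zeros(32)
    base[10] = 1.0  # give every trace the same peak position
    traces = [base + c for c in (0.0, 1.0, 2.0)]
    assert np.allclose(median_waveform(traces), base + 1.0)


def test_median_waveform_robust_to_outlier_and_jitter():
    w = waveform_template(600)
    traces = [np.roll(w, k) for k in (-1, 0, 0, 1, 0)]
    traces.append(traces[-1] + 5.0)  # one wild outlier
    est = peak_trough_duration(median_waveform(traces), 25.0)
    assert abs(est - 600) <= 25.0


# ----------------------------------------------------------------------
# rates and classification
# ----------------------------------------------------------------------

def test_baseline_rate_counts_pre_scene_spikes():
    onsets = np.array([1.0, 3.0])
    spikes = np.array([0.8, 0.9, 2.8, 2.9, 1.5])  # 4 in-window, 1 outside
    assert baseline_rate(spikes, onsets) == pytest.approx(4 / (2 * 0.25))


def test_baseline_rate_rejects_overlapping_windows():
    with pytest.raises(ValueError):
        baseline_rate(np.array([0.1]), np.array([1.0, 1.1]))


def test_classification_rules_and_strict_boundaries():
    assert classify_unit(400, 8.0, T800).label == "FSI"
    assert classify_unit(1200, 1.0, T800).label == "MSN"
    # boundary values are unclassified and flagged
    for dur, rate in [(800.0, 8.0), (400.0, 2.0), (1200.0, 10.0)]:
        uc = classify_unit(dur, rate, T800)
        assert uc.label == "unclassified"
        assert uc.boundary
    # inconsistent combinations are unclassified without the flag
    uc = classify_unit(400, 1.0, T800)  # narrow but quiet
    assert uc.label == "unclassified" and not uc.boundary
    assert classify_unit(1200, 20.0, T800).label == "unclassified"


def test_tan_flag_excludes():
    assert classify_unit(900, 5.0, T800, tan_flag=True).label == "TAN_excluded"


def test_cutoff_must_match_an_amplifier_profile():
    ClassifierThresholds(duration_cutoff_us=480.0)
    with pytest.raises(ValueError):
        ClassifierThresholds(duration_cutoff_us=600.0)


def test_classify_record_end_to_end():
    fsi = generate_synthetic_unit(400, 10.0, n_events=60, seed=1)
    msn = generate_synthetic_unit(1200, 0.8, n_events=60, seed=2)
    assert classify_record(fsi, T800).label == "FSI"
    assert classify_record(msn, T800).label == "MSN"


# ----------------------------------------------------------------------
# response statistics and density
# ----------------------------------------------------------------------

def test_response_significance_bonferroni():
    rng = np.random.default_rng(0)
    responsive = (rng.poisson(12, 40), rng.poisson(1, 40))
    silent = (rng.poisson(1, 40), rng.poisson(1, 40))
    table = response_significance(
        {"resp": responsive, "null": silent}, n_comparisons=16
    )
    by = table.set_index("stimulus")
    assert bool(by.loc["resp", "significant"])
    assert not bool(by.loc["null", "significant"])
    assert by["threshold"].iloc[0] == pytest.approx(0.05 / 16)


def test_permutation_test_agrees_with_t_on_clear_effect():
    rng = np.random.default_rng(1)
    post, pre = rng.poisson(15, 10), rng.poisson(1, 10)
    assert paired_response_test(post, pre, method="t") < 0.01
    assert paired_response_test(post, pre, method="permutation") < 0.01
    # identical samples: no effect
    same = rng.poisson(5, 10)
    assert paired_response_test(same, same * 0.25 / 0.35,
                                post_window_s=0.35, pre_window_s=0.25,
                                method="permutation") > 0.9


def test_single_spike_density_peak_and_mass():
    grid = np.arange(-0.2, 0.2, 0.004)
    dens = spike_density(np.array([0.0]), grid, sigma_s=0.015)
    peak = dens.max()
    assert peak == pytest.approx(1 / (0.015 * np.sqrt(2 * np.pi)), rel=1e-3)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, rel=0.01)


def test_density_grid_resolution_guard():
    with pytest.raises(ValueError):
        spike_density(np.array([0.0]), np.arange(0, 1, 0.01), sigma_s=0.015)
    with pytest.raises(ValueError):
        spike_density(np.array([0.0]), np.array([]))


def test_density_trial_normalization():
    grid = np.arange(-0.2, 0.2, 0.004)
    one = spike_density(np.array([0.0]), grid, n_trials=1)
    four = spike_density(np.array([0.0]), grid, n_trials=4)
    assert np.allclose(one, 4 * four)
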