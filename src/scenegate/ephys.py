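"""Unit classification and response statistics for striatal recordings.

Putative fast-spiking interneurons (FSIs) are narrow-spiking and
tonically active; putative medium spiny neurons (MSNs) are broad-spiking
and nearly silent at rest. Classification uses the peak-to-trough time of
the median spike waveform (cutoff 800 or 480 μs depending on the
amplifier's filter settings) together with the baseline firing rate
measured in the 250 ms before scene onset: FSI if duration < cutoff and
rate > 2 Hz, MSN if duration > cutoff and rate < 10 Hz. Tonically active
(cholinergic) neurons are excluded by an external annotation, and units
meeting neither rule set are left unclassified. Both inequalities are
strict, so measurements exactly at a threshold are unclassified and
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline

from .units import UnitRecord

__all__ = [
    "ClassifierThresholds",
    "UnitClass",
    "median_waveform",
    "peak_trough_duration",
    "baseline_rate",
    "classify_unit",
    "classify_record",
    "response_significance",
    "paired_response_test",
    "spike_density",
    "DURATION_CUTOFFS_US",
]

#: Amplifier-dependent peak-trough cutoffs (μs); spike shape depends on the
#: recording filter settings, so the cutoff is a required config choice.
DURATION_CUTOFFS_US = (800.0, 480.0)

BASELINE_WINDOW_S = 0.250
EVOKED_WINDOW_S = (0.050, 0.400)
DEFAULT_SIGMA_S = 0.015


@dataclass(frozen=True)
class ClassifierThresholds:
    duration_cutoff_us: float
    fsi_min_rate_hz: float = 2.0
    msn_max_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.duration_cutoff_us not in DURATION_CUTOFFS_US:
            raise ValueError(
                f"duration_cutoff_us must be one of {DURATION_CUTOFFS_US} "
                "(amplifier profile)"
            )
        if min(self.fsi_min_rate_hz, self.msn_max_rate_hz) <= 0:
            raise ValueError("rate thresholds must be positive")


@dataclass(frozen=True)
class UnitClass:
    label: str  # "FSI" | "MSN" | "TAN_excluded" | "unclassified"
    duration_us: Optional[float]
    baseline_hz: Optional[float]
    boundary: bool = False


# ----------------------------------------------------------------------
# Waveform measurements
# ----------------------------------------------------------------------

def median_waveform(traces: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise median of peak-aligned spike traces.

    Traces are shifted so their global peaks coincide, cropped to the
    common support, and the median is taken per sample. Robust to
    occasional outlier traces.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if not traces:
        raise ValueError("need at least one trace")
    n = traces[0].size
    if any(t.size != n for t in traces):
        raise ValueError("all traces must have equal length")
    peaks = [int(np.argmax(t)) for t in traces]
    ref = peaks[0]
    left = min(p for p in peaks)
    right = min(n - p for p in peaks)
    aligned = [t[p - left: p + right] for t, p in zip(traces, peaks)]
    return np.median(np.vstack(aligned), axis=0)


def peak_trough_duration(
    trace: np.ndarray,
    sampling_interval_us: float,
    upsample: int = 10,
) -> float:
    """Time (μs) from the waveform's global peak to the following trough.

    The trace is cubic-spline interpolated onto a grid ``upsample`` times
    finer before the extrema are located. Raises on flat or monotone
    traces that have no peak followed by a trough.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 4:
        raise ValueError("trace too short")
    if np.ptp(trace) == 0:
        raise ValueError("flat trace has no peak/trough pair")
    x = np.arange(trace.size)
    if upsample > 1:
        spline = CubicSpline(x, trace)
        fine = np.linspace(0, trace.size - 1, (trace.size - 1) * upsample + 1)
        values = spline(fine)
    else:
        fine, values = x.astype(float), trace
    peak = int(np.argmax(values))
    after = values[peak:]
    if after.size < 2 or np.all(np.diff(after) >= 0):
        raise ValueError("no trough after the waveform peak")
    trough = peak + int(np.argmin(after))
    return float((fine[trough] - fine[peak]) * sampling_interval_us)


# ----------------------------------------------------------------------
# Firing-rate measurements
# ----------------------------------------------------------------------

def baseline_rate(
    spike_times: np.ndarray,
    scene_onsets: np.ndarray,
    window_s: float = BASELINE_WINDOW_S,
) -> float:
    """Mean firing rate (Hz) in the ``window_s`` before each scene onset.

    Windows must be disjoint; overlapping windows (onsets closer than the
    window length) raise.
    """
    onsets = np.sort(np.asarray(scene_onsets, dtype=float))
    if onsets.size == 0:
        raise ValueError("need at least one scene onset")
    if onsets.size > 1 and np.any(np.diff(onsets) < window_s):
        raise ValueError("baseline windows overlap; onsets closer than the window")
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    total = 0
    for onset in onsets:
        total += int(
            np.searchsorted(spikes, onset) - np.searchsorted(spikes, onset - window_s)
        )
    return total / (onsets.size * window_s)


def window_counts(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float],
) -> np.ndarray:
    """Spike count per onset in [onset+window[0], onset+window[1])."""
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    lo = np.searchsorted(spikes, np.asarray(onsets) + window[0])
    hi = np.searchsorted(spikes, np.asarray(onsets) + window[1])
    return (hi - lo).astype(int)


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------

def classify_unit(
    duration_us: float,
    baseline_hz: float,
    thresholds: ClassifierThresholds,
    tan_flag: bool = False,
) -> UnitClass:
    """Apply the waveform/rate criteria. Strict inequalities on both sides."""
    if not (np.isfinite(duration_us) and np.isfinite(baseline_hz)):
        raise ValueError("measurements must be finite")
    if tan_flag:
        return UnitClass("TAN_excluded", duration_us, baseline_hz)
    cutoff = thresholds.duration_cutoff_us
    boundary = (
        duration_us == cutoff
        or baseline_hz == thresholds.fsi_min_rate_hz
        or baseline_hz == thresholds.msn_max_rate_hz
    )
    if duration_us < cutoff and baseline_hz > thresholds.fsi_min_rate_hz:
        label = "FSI"
    elif duration_us > cutoff and baseline_hz < thresholds.msn_max_rate_hz:
        label = "MSN"
    else:
        label = "unclassified"
    return UnitClass(label, duration_us, baseline_hz, boundary=boundary)


def classify_record(
    record: UnitRecord,
    thresholds: ClassifierThresholds,
    tan_flag: bool = False,
    upsample: int = 10,
) -> UnitClass:
    """Measure a :class:`UnitRecord` and classify it."""
    duration = peak_trough_duration(
        record.waveform, record.sampling_interval_us, upsample=upsample
    )
    rate = baseline_rate(record.spike_times_s, record.scene_onsets_s)
    return classify_unit(duration, rate, thresholds, tan_flag=tan_flag)


def classification_table(
    records: Sequence[UnitRecord],
    thresholds: ClassifierThresholds,
    tan_flags: Optional[Sequence[bool]] = None,
) -> pd.DataFrame:
    """Classification CSV table: unit_id, duration_us, baseline_hz, label."""
    tan_flags = tan_flags or [False] * len(records)
    rows = []
    for record, tan in zip(records, tan_flags):
        uc = classify_record(record, thresholds, tan_flag=tan)
        rows.append(
            {
                "unit_id": record.unit_id,
                "duration_us": uc.duration_us,
                "baseline_hz": uc.baseline_hz,
                "label": uc.label,
                "boundary": uc.boundary,
                "ground_truth": record.ground_truth_class or "",
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Responsiveness statistics
# ----------------------------------------------------------------------

def paired_response_test(
    post_counts: np.ndarray,
    pre_counts: np.ndarray,
    post_window_s: float = EVOKED_WINDOW_S[1] - EVOKED_WINDOW_S[0],
    pre_window_s: float = BASELINE_WINDOW_S,
    method: str = "t",
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Two-sided paired comparison of per-trial rates (Hz); returns p.

    Counts are normalized to rates because the windows differ in length.
    ``method='permutation'`` runs a sign-flip test on the paired rate
    differences (exact for <= 12 trials), for very small samples.
    """
    post = np.asarray(post_counts, dtype=float) / post_window_s
    pre = np.asarray(pre_counts, dtype=float) / pre_window_s
    if post.size != pre.size or post.size < 2:
        raise ValueError("need >= 2 paired trials")
    diffs = post - pre
    if method == "t":
        if np.allclose(diffs, diffs[0]) and np.allclose(diffs[0], 0.0):
            return 1.0
        res = stats.ttest_rel(post, pre)
        p = float(res.pvalue)
        return 1.0 if np.isnan(p) else p
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    observed = abs(diffs.mean())
    n = diffs.size
    if n <= 12:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
        null = np.abs(signs @ diffs) / n
        return float(np.mean(null >= observed - 1e-12))
    rng = rng or np.random.default_rng(0)
    flips = rng.choice((-1.0, 1.0), size=(n_permutations, n))
    null = np.abs(flips @ diffs) / n
    return float((1 + np.sum(null >= observed - 1e-12)) / (1 + n_permutations))


def response_significance(
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    n_comparisons: Optional[int] = None,
    alpha: float = 0.05,
    method: str = "t",
) -> pd.DataFrame:
    """Bonferroni-corrected responsiveness per stimulus.

    ``counts`` maps stimulus -> (post_counts, pre_counts). A stimulus is
    flagged significant iff its paired p-value is below
    ``alpha / n_comparisons`` (default: number of stimuli tested).
    """
    if n_comparisons is None:
        n_comparisons = len(counts)
    threshold = alpha / n_comparisons
    rows = []
    for stim, (post, pre) in counts.items():
        p = paired_response_test(post, pre, method=method)
        rows.append(
            {"stimulus": stim, "p": p, "threshold": threshold,
             "significant": p < threshold}
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Spike density
# ----------------------------------------------------------------------

def spike_density(
    spike_times: np.ndarray,
    grid: np.ndarray,
    sigma_s: float = DEFAULT_SIGMA_S,
    n_trials: int = 1,
) -> np.ndarray:
    """Gaussian-kernel spike density (Hz) on a time grid.

    Each spike contributes a unit-mass Gaussian (σ = 15 ms by default);
    the sum is divided by the trial count. The grid step must be at most
    σ/3 so the kernel is resolved.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if grid.size > 1:
        step = np.diff(grid).max()
        if step > sigma_s / 3 + 1e-12:
            raise ValueError("grid resolution must be <= sigma/3")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - spikes[None, :]) / sigma_s
    density = np.exp(-0.5 * z**2).sum(axis=1) / (sigma_s * np.sqrt(2 * np.pi))
    return density / n_trials
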