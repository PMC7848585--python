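"""Synthetic single-unit recordings.

Produces the two ingredients the spike-train analyses consume: an action
potential waveform with a controlled peak-to-trough duration, and an
inhomogeneous-Poisson spike train with controlled baseline and evoked
rates locked to scene/object onsets. Real recordings can be represented
with the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import h5py
import numpy as np

__all__ = [
    "UnitRecord",
    "waveform_template",
    "generate_synthetic_unit",
    "save_unit_record",
    "load_unit_record",
]

#: Default waveform sampling interval (μs).
DEFAULT_DT_US = 25.0

#: Default session layout (s): one scene presentation per trial period,
#: object onset 800 ms after the scene (the scene-task timing).
SCENE_OFFSET_S = 0.5
OBJECT_DELAY_S = 0.8
TRIAL_PERIOD_S = 2.0

#: Evoked-response window relative to a stimulus onset (s).
EVOKED_WINDOW_S = (0.050, 0.400)


@dataclass
class UnitRecord:
    """One isolated unit: waveform, spike times, and event markers."""

    waveform: np.ndarray
    sampling_interval_us: float
    spike_times_s: np.ndarray
    scene_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    object_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: per object onset: (scene label or "", object label)
    object_labels: tuple[tuple[str, str], ...] = ()
    ground_truth_class: Optional[str] = None
    unit_id: str = "unit"

    def __post_init__(self) -> None:
        st = np.asarray(self.spike_times_s, dtype=float)
        if st.size and np.any(np.diff(st) <= 0):
            raise ValueError("spike_times must be strictly increasing")
        self.spike_times_s = st
        self.waveform = np.asarray(self.waveform, dtype=float)


def waveform_template(
    duration_us: float,
    dt_us: float = DEFAULT_DT_US,
    total_us: Optional[float] = None,
    trough_amplitude: float = 0.7,
) -> np.ndarray:
    """Smooth biphasic spike template with a given peak-to-trough time.

    A positive Gaussian lobe followed by a negative one, separated by
    ``duration_us``. Lobe widths are duration/4, so the lobes barely
    overlap and the sampled extrema sit within one sampling interval of
    the construction times.
    """
    if duration_us <= 0:
        raise ValueError("duration_us must be > 0")
    if total_us is None:
        total_us = max(4.0 * duration_us, 1600.0)
    t = np.arange(0.0, total_us, dt_us)
    sigma = duration_us / 4.0
    t_peak = total_us / 3.0
    t_trough = t_peak + duration_us
    w = np.exp(-((t - t_peak) ** 2) / (2 * sigma**2)) - trough_amplitude * np.exp(
        -((t - t_trough) ** 2) / (2 * sigma**2)
    )
    return w


def _piecewise_poisson(
    segments: Sequence[tuple[float, float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Sample a piecewise-homogeneous Poisson process.

    ``segments`` is a list of (t0, t1, rate_hz) with disjoint intervals.
    """
    times: list[np.ndarray] = []
    for t0, t1, rate in segments:
        if t1 <= t0 or rate <= 0:
            continue
        n = rng.poisson(rate * (t1 - t0))
        if n:
            times.append(t0 + (t1 - t0) * rng.random(n))
    if not times:
        return np.empty(0)
    st = np.sort(np.concatenate(times))
    # enforce strict monotonicity (coincident samples are measure-zero but
    # possible in floating point)
    keep = np.concatenate(([True], np.diff(st) > 0))
    return st[keep]


def generate_synthetic_unit(
    duration_us: float,
    baseline_hz: float,
    evoked_hz: Union[float, Mapping[tuple[str, str], float], None] = None,
    n_events: int = 50,
    seed: Union[int, np.random.Generator] = 0,
    *,
    scene_object_pairs: Optional[Sequence[tuple[str, str]]] = None,
    scene_evoked_hz: Optional[float] = None,
    dt_us: float = DEFAULT_DT_US,
    trial_period_s: float = TRIAL_PERIOD_S,
    ground_truth_class: Optional[str] = None,
    unit_id: str = "synthetic",
) -> UnitRecord:
    """Generate one synthetic unit.

    The session consists of ``n_events`` trial periods. Each has a scene
    onset and an object onset 800 ms later. Firing is Poisson at
    ``baseline_hz`` except in the 50-400 ms window after each onset, where
    the rate steps to the evoked rate (``evoked_hz`` may be a scalar or a
    per-(scene, object) map; ``None`` keeps the baseline).
    """
    if duration_us <= 0:
        raise ValueError("duration_us must be > 0")
    if baseline_hz < 0:
        raise ValueError("baseline_hz must be >= 0")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if scene_object_pairs is None:
        scene_object_pairs = [("X", "A")]

    scene_onsets = SCENE_OFFSET_S + trial_period_s * np.arange(n_events)
    object_onsets = scene_onsets + OBJECT_DELAY_S
    labels = tuple(
        scene_object_pairs[i % len(scene_object_pairs)] for i in range(n_events)
    )

    w0, w1 = EVOKED_WINDOW_S
    total = SCENE_OFFSET_S + trial_period_s * n_events

    def evoked_rate_for(label: tuple[str, str]) -> float:
        if evoked_hz is None:
            return baseline_hz
        if isinstance(evoked_hz, Mapping):
            return float(evoked_hz.get(label, baseline_hz))
        return float(evoked_hz)

    # build disjoint segments: evoked windows override the baseline
    windows: list[tuple[float, float, float]] = []
    for i in range(n_events):
        if scene_evoked_hz is not None:
            windows.append((scene_onsets[i] + w0, scene_onsets[i] + w1, scene_evoked_hz))
        r = evoked_rate_for(labels[i])
        windows.append((object_onsets[i] + w0, object_onsets[i] + w1, r))
    for _, _, r in windows:
        if r < 0:
            raise ValueError("evoked rates must be >= 0")
    windows.sort()
    segments: list[tuple[float, float, float]] = []
    cursor = 0.0
    for t0, t1, r in windows:
        if t0 > cursor:
            segments.append((cursor, t0, baseline_hz))
        segments.append((t0, t1, r))
        cursor = t1
    if cursor < total:
        segments.append((cursor, total, baseline_hz))

    spikes = _piecewise_poisson(segments, rng)
    return UnitRecord(
        waveform=waveform_template(duration_us, dt_us=dt_us),
        sampling_interval_us=dt_us,
        spike_times_s=spikes,
        scene_onsets_s=scene_onsets,
        object_onsets_s=object_onsets,
        object_labels=labels,
        ground_truth_class=ground_truth_class,
        unit_id=unit_id,
    )


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def save_unit_record(record: UnitRecord, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveform", data=record.waveform)
        f.attrs["sampling_interval_us"] = record.sampling_interval_us
        f.attrs["unit_id"] = record.unit_id
        if record.ground_truth_class is not None:
            f.attrs["ground_truth_class"] = record.ground_truth_class
        f.create_dataset("spike_times_s", data=record.spike_times_s)
        f.create_dataset("scene_onsets_s", data=record.scene_onsets_s)
        f.create_dataset("object_onsets_s", data=record.object_onsets_s)
        if record.object_labels:
            labels = np.array(
                [[s, o] for s, o in record.object_labels], dtype=h5py.string_dtype()
            )
            f.create_dataset("object_labels", data=labels)


def load_unit_record(path) -> UnitRecord:
    with h5py.File(path, "r") as f:
        labels: tuple[tuple[str, str], ...] = ()
        if "object_labels" in f:
            raw = f["object_labels"][()]
            labels = tuple(
                (s.decode() if isinstance(s, bytes) else s,
                 o.decode() if isinstance(o, bytes) else o)
                for s, o in raw
            )
        gt = f.attrs.get("ground_truth_class")
        return UnitRecord(
            waveform=f["waveform"][()],
            sampling_interval_us=float(f.attrs["sampling_interval_us"]),
            spike_times_s=f["spike_times_s"][()],
            scene_onsets_s=f["scene_onsets_s"][()],
            object_onsets_s=f["object_onsets_s"][()],
            object_labels=labels,
            ground_truth_class=str(gt) if gt is not None else None,
            unit_id=str(f.attrs.get("unit_id", "unit")),
        )
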