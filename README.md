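# scenegate

Simulation and analysis of scene-gated object-value learning in a model
striatal circuit, plus the electrophysiology toolchain used to classify
the circuit's cell types in (synthetic) recordings.

The model asks how a small network can learn object values that *reverse*
with the background scene. Each medium spiny neuron (MSN) carries plastic
synapses for every object and scene and receives fixed, scene-selective
inhibition from fast-spiking interneurons (FSIs). The FSI input acts as a
divisive gain, so each MSN is most responsive — and, through a
three-factor reward rule, most plastic — in the scene whose FSI inhibits
it least. Two mirror-image MSNs therefore partition the task: each learns
the object values of its preferred scene, and their summed output drives
scene-appropriate choices. Removing the FSI input *after* learning leaves
behavior intact (the learned scene weights silence each unit outside its
scene), while equalizing FSI input *during* learning prevents acquisition
entirely.

## Worked example

```python
import numpy as np
from scenegate import (
    ExperimentSpec, run_experiment, learning_curve,
    simulate_passive_probe, value_coding_index,
)

# 1. Learn the scene task: 2 objects whose values reverse between scenes
#    X and Y; two block-sequenced sessions then one random session.
spec = ExperimentSpec(condition="normal", n_seeds=20, seed=0)
result = run_experiment(spec)

acc = result.accuracies(last_n=40)           # per-seed late accuracy
print(f"late accuracy: {acc.mean():.3f}")    # ~0.95+
print(learning_curve(result.logs[0], 20))    # one seed's curve, 20-trial bins

# 2. Probe the trained units passively (one object on one scene, no task)
config = result.config
matrix = simulate_passive_probe(
    result.populations[0], config.object_ids, config.scene_ids, rectify=True
)
# the scene-X-preferring unit codes value in scene X, much less in scene Y
print(value_coding_index(matrix, "msn_pref_X", config, "X"))  # > 0
print(value_coding_index(matrix, "msn_pref_X", config, "Y"))  # smaller |.|

# 3. Remove FSI input after learning: behavior is retained; zeroing the
#    learned scene weights instead collapses it to chance.
ret = run_experiment(ExperimentSpec(
    condition="fsi_removed_after_learning", n_seeds=20, seed=0))
print(ret.accuracies(logs=ret.eval_logs).mean())      # > 0.65
print(ret.accuracies(logs=ret.ablation_logs).mean())  # ~0.5
```

The same stages are available from the command line; every run writes a
`manifest.json` with config hashes, derived seeds, and file checksums:

```bash
scenegate simulate  --preset two_object_two_scene --seed 0 --out out/sim
scenegate experiment --condition normal --n-seeds 20 --seed 0 --out out/exp
scenegate report    --run out/exp --out out/report
scenegate probe     --condition normal --seed 0 --out out/probe
scenegate classify  --n-units 20 --cutoff 800 --out out/cls
```

## Repository layout

- `src/scenegate/` — the package:
  `task` (task configs, trial schedules), `model` (MSN response and
  plasticity equations), `readout` (collicular drive, softmax choice,
  coding metrics), `experiments` (multi-seed virtual experiments),
  `units`/`ephys` (synthetic recordings; waveform, rate, classification,
  and spike-density analyses), `io`/`cli` (manifests, configs, CLI).
- `analysis/` — numbered, standalone analysis drivers writing tables to
  `results/`: learning curves (01), FSI blockade (02), passive probe
  (03), FSI removal after learning (04), unit classification (05).
- `scripts/acceptance.py` — computes the headline quantities as JSON:
  `python scripts/acceptance.py --seed 1 --out results/acceptance.json`.
- `tests/` — unit, property-based, and acceptance tests (`pytest`).
- `docs/methods.md` — model equations, protocols, and analysis methods.

## Reproducibility

All randomness flows from a single integer seed through
`scenegate.io.derive_seed`; identical configs and seeds give
byte-identical outputs and equal manifest `run_hash` values.
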