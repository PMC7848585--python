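# Methods

## Task

**Scene-based object-value task.** Two (or eight) visual objects are
paired with two background scenes, X and Y. On each trial one scene is
shown and two objects are offered, one currently "good" (large reward,
0.3 mL) and one currently "bad" (small reward, 0.1 mL); every object's
value label reverses between the scenes, and this reversal is enforced
as a config invariant. Scene sequencing is either *block* (the scene
alternates strictly every 20 trials, so a 160-trial session contains
exactly eight 20-trial runs) or *random* (i.i.d. per trial). The model
reward signal maps the large reward to +1 and the small reward to −0.5:
on this task a small reward acts as a negative teaching signal.

**No-scene control.** Eight objects with fixed values and no background
scene.

**Passive viewing.** Single objects on single scenes, at least seven
repetitions per (scene, object) cell, with no choice or learning; used
to read out the learned responses.

## Circuit model

Each model MSN has plastic weights `S_o` for every object and `S_s` for
every scene, and a fixed FSI input magnitude `FSI_s` per scene. Its
response to a presentation (at most one object, one scene) is

```
MSN = (Σ_o I_o·S_o + Σ_s I_s·S_s) / (Σ_s I_s·FSI_s)
```

with indicators `I` equal to 1 for presented labels. The FSI term is a
divisive (shunting) gain: with `FSI = 1` the drive is unscaled, with
`FSI = 0.6` it is amplified, so the unit is most responsive in the scene
whose FSI inhibits it least. When no scene is shown, or the presented
scene's FSI magnitude is 0 (inhibition removed), the divisor is 1.

Plasticity is a three-factor delta rule applied to every presented
element:

```
S_e ← S_e + I_e · MSN · Reward · LS
```

with the response taken on the pre-update state, `Reward ∈ {+1, −0.5}`,
learning rate `LS = 0.01`, and all weights initialized to 1. Because the
update is proportional to the response, plasticity concentrates in each
unit's preferred scene — the mechanism by which mirrored FSI inputs make
the two MSNs divide the task between the scenes. With constant reward
magnitudes this rule has no fixed point, so weights keep growing during
training; choice behavior depends only on drive differences and is
unaffected.

The population comprises two mirror-image MSNs (FSI inputs 0.6/1 and
1/0.6). The drive for an offered object is the sum of the two MSN
responses (the downstream disinhibitory pathway is monotone), and
choices between the two offered objects follow a logistic (softmax)
policy on the drive difference with inverse temperature β = 5. Responses
are rectified at zero in the experiments (firing rates are nonnegative);
the bare response equation is linear and unrectified by default.

## Virtual experiments

All experiments derive per-replicate seeds deterministically from one
top-level seed. By default the learning update is applied to **both
offered objects** under their scheduled outcomes on every trial
(`update_policy="both_offered"`); restricting updates to the chosen
object (`"chosen_only"`) is available but, combined with the asymmetric
±(1, 0.5) reward signal, makes choice-contingent sampling self-reinforce
onto a single object and prevents learning.

- **normal** — mirrored FSI (0.6/1, 1/0.6); two 160-trial block sessions
  then one 160-trial random session. A single 160-trial session leaves
  learning partial; accuracy criteria are evaluated on the *late* (second
  block) session, and switch-aligned accuracy on the random session.
- **low_fsi_during_learning** — uniform FSI (0.5/0.5), random
  sequencing, 300 trials. With scene-blind gain the two units are
  identical and the population drive carries no scene information, so
  accuracy stays at chance.
- **fsi_removed_after_learning** — train the full normal protocol, then
  set every FSI input to 0 and evaluate with plasticity frozen. Retention
  requires the matured conjunctive representation: through rectification,
  each unit's strongly negative nonpreferred-scene weight silences it
  outside its scene, so scene selectivity survives without FSI input. A
  second evaluation additionally zeroes the learned scene weights, which
  removes that gating and collapses accuracy to chance. Training must run
  to completion — after only one block session the scene weights have not
  yet differentiated and retention is absent.
- **no_scene** — fixed object values; learning proceeds identically
  under any FSI setting because no scene input is presented.

## Electrophysiology analyses

- **Median waveform**: traces are aligned on their global peak, cropped
  to common support, and the pointwise median taken.
- **Peak–trough duration**: the waveform is cubic-spline interpolated
  (10× grid) and the time from the global peak to the following trough
  measured; flat or monotone traces are rejected.
- **Baseline rate**: spikes in the 250 ms before each scene onset,
  divided by total window time; overlapping windows are rejected.
- **Classification**: FSI if duration < cutoff *and* baseline rate
  > 2 Hz; MSN if duration > cutoff *and* rate < 10 Hz; otherwise
  unclassified (boundary equalities flagged). The duration cutoff is an
  amplifier profile, 800 or 480 μs. Tonically active neurons are
  excluded by an external annotation (no quantitative criterion is
  defined for them here).
- **Responsiveness**: per-trial spike counts in the 50–400 ms
  post-stimulus window vs. the 250 ms pre-stimulus window, normalized to
  rates, compared with a two-sided paired t test (or sign-flip
  permutation test for very small samples), Bonferroni-corrected at
  α = 0.05 across the stimuli tested.
- **Spike density**: Gaussian kernel, σ = 15 ms, one unit of mass per
  spike, divided by trial count; the evaluation grid must resolve the
  kernel (step ≤ σ/3).
- **Synthetic units**: biphasic double-Gaussian waveform templates with
  controlled peak–trough separation, and piecewise-homogeneous Poisson
  spike trains whose rate steps from the baseline to an evoked value in
  the 50–400 ms window after each scene/object onset.

## Headline quantities

`python scripts/acceptance.py --seed <int> --out <path>` recomputes, in a
few seconds: the exact-oracle error of the response/update equations;
chance-level accuracy under uniform FSI (200 seeds); late-session
accuracy, the fraction of seeds above 0.75, and the switch-aligned
position-0 gap under the normal condition (100 seeds); the passive-probe
value-coding asymmetry fractions; no-scene accuracy under both FSI
settings; retention and scene-weight-ablation accuracy after FSI
removal; and the ephys-suite metrics (classifier accuracy, duration
recovery error, density mass conservation, baseline-rate z-scores).
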