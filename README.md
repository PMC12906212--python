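# shallowbrain

A computational model of parallel cortico-subcortical ("shallow brain")
processing in a cue-dependent pro/antisaccade task.

## The scientific problem

Saccadic eye movements can be driven by two anatomically distinct routes:
a fast, shallow subcortical loop (retina → superior colliculus → brainstem
oculomotor nuclei) and a slower, deep cortical hierarchy (V1 → PPC → FEF →
dlPFC). In a pro/antisaccade task the two routes are placed in conflict: a
*prosaccade* cue instructs a reflexive movement toward the brighter of two
stimuli, while an *antisaccade* cue demands suppressing that reflex and
looking at the darker one. Monkeys are reliably slower on antisaccade
trials, and cortical lesions impair antisaccades but spare prosaccades —
suggesting the two pathways share the work according to task demands.

This package implements a firing-rate network in which both pathways run
in parallel and converge on a pair of motor units:

- a **deep cortical pathway**, in two interchangeable variants — a small
  convolutional network trained by backpropagation, or a three-layer
  Rao–Ballard predictive-coding hierarchy trained by local prediction-error
  minimisation — that classifies the cue (P/A) and the brighter side (L/R)
  and combines them through a hard-wired XOR gate into a rule-correct
  choice drive;
- a **shallow subcortical pathway** — a 2→16→2 perceptron (feedforward
  variant) or a frozen random excitatory/inhibitory recurrent network of
  two 128-unit populations and a 32-unit inhibitory pool (predictive-coding
  variant) — that sees only the two 4×4 stimulus patches and reflexively
  drives the choice toward the brighter square;
- a **cortico-subcortical projection** from the antisaccade rule neuron
  that silences the subcortex whenever the rule is "anti".

Every unit obeys the rate equation

    τ dr_i/dt = −r_i + f_i(b_i + Σ_j w_ij r_j),   τ = 100 ms,

integrated with the Euler method (Δt = 10 ms). Competing decision and
motor pairs use a normalized (softmax) activation so their rates lie in
(0, 1); a trial's **choice** and **reaction time** are read from the first
motor rate to cross the fixed threshold of 0.55 after stimulus onset, and
the **winning module** is the pathway whose decision pair crossed that
threshold first.

## Worked example

```python
import numpy as np
import shallowbrain as sb

model = sb.ModelBundle.build_ff(seed=0)          # ~80 s on one CPU

trial = sb.TrialSpec.make(sb.CueType.PRO, sb.BrightnessPair(0.9, 0.1))
result, traces = sb.run_trial(model, trial)
print(result.choice.value, result.rt_ms, result.winner.value)
# left 120.0 subcortex

trial = sb.TrialSpec.make(sb.CueType.ANTI, sb.BrightnessPair(0.9, 0.1))
result, _ = sb.run_trial(model, trial)
print(result.choice.value, result.rt_ms, result.winner.value)
# right 240.0 cortex

test = sb.make_test_set(500, seed=101)
pro, _ = sb.run_trials(model, [sb.TrialSpec.make(sb.CueType.PRO, p) for p in test.pairs], 0.0)
anti, _ = sb.run_trials(model, [sb.TrialSpec.make(sb.CueType.ANTI, p) for p in test.pairs], 0.0)
print(sb.rt_summary(pro + anti))
#  cue  mean_rt_ms  sd_rt_ms    n
#  pro       185.3      28.4  500
# anti       240.0       0.0  500
```

The easy prosaccade trial is resolved by the subcortex in 120 ms; the same
stimulus under the antisaccade cue is resolved by the cortex, in the
opposite direction, 120 ms later — the speed cost of inhibitory control.
Over a balanced 500-pair test set the mean prosaccade RT (~185 ms) is
about 55 ms faster than the antisaccade mean (~240 ms), matching the
monkey-experiment pattern the model is built to explain.

The predictive-coding variant (`ModelBundle.build_pc`) behaves the same
way and additionally exposes hierarchical reconstructions
(`cortex_pc.reconstruct_from_layer`) and the difficulty analysis
(`run_difficulty_experiment`), in which the subcortex wins most trials
with small brightness differences while the cortex takes over as the
difference grows.

## Command line

```
shallowbrain train --variant ff --seed 0 --out results/
shallowbrain eval-noise --variant ff --seed 0 --out results/
shallowbrain eval-rt --weights results/model_ff.npz --out results/
shallowbrain eval-difficulty --variant pc --seed 0 --out results/
shallowbrain reconstruct --weights results/model_pc.npz --out results/
shallowbrain demo --variant ff --seed 0 --out results/
```

All experiments write tidy CSV tables plus a JSON manifest (config, seeds,
weight hashes) for reproducibility.

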