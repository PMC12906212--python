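# Methods

This note documents the model, its parameters, the synthetic task, the
numerical choices, and the design decisions taken where the architecture
left the design open.

## Task

Screens are 16×32 nonnegative intensity grids. A trial presents a cue
screen (500 ms) followed by a stimulus screen (up to 1000 ms). The cue is
a unit-intensity two-pixel bar centered between the stimulus windows —
horizontal (2×1) for prosaccade, vertical (1×2) for antisaccade. The
stimulus is two 4×4 squares of brightness `x_left`, `x_right` ∈ [0, 1],
placed symmetrically about the vertical midline (rows 6–9, columns 6–9 and
22–25). The exact pixel coordinates are a package convention: the cortical
networks see the whole screen, so only consistency matters, and the cue
must lie outside the subcortical receptive-field windows so that the
subcortex is structurally blind to it.

Training pairs enumerate the 0.1-interval brightness grid (121 ordered
pairs; the 11 equal-brightness diagonal pairs carry undefined side labels
and are excluded from side-classification losses). Test pairs are drawn
without replacement from the 0.01-interval grid, balanced to exactly n/2
left-brighter and n/2 right-brighter. Grid values are generated as exact
rationals i/10 and i/100 before float conversion. Pixel noise is additive
i.i.d. Gaussian N(0, σ), drawn once per screen presentation and *not*
clipped to [0, 1] (clipping would bias extreme intensities).

## Rate dynamics

Every unit follows τ dr/dt = −r + f(b + Σ w·r) with τ = 100 ms, integrated
by the Euler method with Δt = 10 ms; all populations update synchronously
(step k+1 reads only step-k rates), and rates start at 0 at trial onset.
Competing pairs — cortical choice (C_L, C_R), subcortical decision
(S_L, S_R), motor (M_L, M_R) — use the exponentiated log-softmax (i.e.
softmax) over the pair as their activation, so their steady rates lie in
(0, 1) and sum to 1. This is the only reading under which the fixed 0.55
decision threshold is attainable: raw log-softmax outputs are ≤ 0 and
could never cross it. All other units are rectified linear.

A useful closed form for testing: a decision unit relaxing from 0 toward
a constant normalized output p crosses threshold θ at t = −τ ln(1 − θ/p);
for p = 1 and θ = 0.55 this is 79.9 ms. The Euler scheme is first-order
accurate (the test suite verifies error halving under dt halving).

## Cortical pathway, feedforward variant

A small CNN classifies every screen into (L, R, P, A): two 4×4 valid
convolutions (8 then 16 channels, stride 1) each followed by 3×3 max
pooling (stride 3, ceil mode — floor-mode pooling would collapse the
second feature map to zero height), then a 16-unit dense layer and 4
outputs. It is trained full-batch with Adam (lr 3·10⁻³) on class-weighted
cross-entropy over the 112 labelled screens (110 non-diagonal stimulus
screens + 2 cue screens) to ≥99% noiseless accuracy. A small L2 weight
decay (10⁻³) and a fixed 1500-epoch budget push the P/A boundary toward
the max-margin separator of the two cue patterns; without it the boundary
hugs one cue point and noisy antisaccade cues are misread. Channel counts,
pooling mode, and the optimizer are package choices — any small
configuration that reaches criterion behaves equivalently.

During the cue phase the classification result is written to an explicit
working-memory latch; during the stimulus phase a hard-wired two-layer
gate (four AND units feeding C_L/C_R) implements the XOR rule — prosaccade
keeps the brighter-side class, antisaccade flips it. The selected class
drives its C unit with a fixed gain through the pair softmax.

## Cortical pathway, predictive-coding variant

A three-layer linear Rao–Ballard hierarchy (512 input = flattened screen,
144 and 16 latents). Inference minimises
E = ‖x − U₁r₁‖² + ‖r₁ − U₂r₂‖² + λ(‖r₁‖² + ‖r₂‖²) by gradient descent on
the latents (rate 0.05, 60 iterations — a fixed count keeps trial timing
deterministic; λ = 0.05). Learning alternates inference with the local
update ΔU ∝ (error)·(latent)ᵀ (rate 0.05, 150 epochs); no gradients flow
through the hierarchy. Layer sizes denote representation units; error
terms are computed implicitly.

The hierarchy is trained on the screen statistics of the task: every
trial shows one cue screen and one stimulus screen, so the two cue
screens are presented as often (60 repetitions each) as the 121 stimulus
screens. Without this weighting the 512→144→16 compression discards the
two-pixel cue direction and the cue identity becomes unrecoverable from
the top latents under noise (the best linear readout drops to ~75% at
σ = 0.2; with the weighting it is ~98% at σ = 0.1).

A linear 16→4 classifier is fit post hoc on frozen top-layer latents
(softmax regression, class-weighted), using latents inferred from clean
and pixel-noised presentations (σ = 0.15, 8 replicas) so the readout
aligns with the signal direction rather than an arbitrary separator of
the tiny noiseless set. The classifier stores the median side-score gap
over the noiseless training pairs (`ref_gap`) as its internal evidence
scale.

Instead of a memory latch, two cue neurons (P, A) with excitatory
self-connections hold the rule. Their activation is a saturating
rectifier min(max(u, 0), 1): a plain ReLU self-loop either decays
(w_self < 1) or diverges, while saturation makes the latch bistable —
above the w_self = 1 bifurcation a transient drive flips the neuron to a
sustained high state. Default w_self = 1.5; the test suite locates the
bifurcation empirically.

## Subcortical pathway

Both variants read the screen only through the two 4×4 stimulus windows
(mean intensity per window; cue screens therefore produce zero input).

*Feedforward variant*: a 2→16→2 perceptron trained to ≥99% side accuracy.
Its logits, scaled by a small gain, drive the (S_L, S_R) pair through
relu(g_s·logits − g_inh·a), where `a` is the antisaccade neuron's rate and
g_inh = 5. The rectification before the pair softmax is essential: a
purely subtractive term inside a softmax is shift-invariant and could
never silence the pair, whereas clamping both pre-activations to zero
pins the pair at its symmetric 0.5 point, below the 0.55 threshold, for
the whole trial.

*Predictive-coding variant*: a frozen random E/I network — S_L, S_R
(128 excitatory units each) with self-recurrence (connection density
0.4), a shared inhibitory pool S_I (32 units; E→I density 0.3, I→E
density 0.8), input density 0.4, output density 0.8, all nonzero
magnitudes uniform(0, 1). Raw weights at these densities give expected
in-degrees of 25–100, which diverges under ReLU dynamics, so each
projection's drive is normalised by its expected in-degree (p·N_pre);
the stored weights keep the stated uniform(0, 1) scale. Per-unit Gaussian
background drive (σ_bg = 0.01) stands in for unmodelled recurrent input
from other subcortical populations and supplies trial-to-trial
variability. The antisaccade neuron excites S_I (gain 5), whose feedback
(gain 2 after normalisation) clamps both excitatory populations — the
indirect route to the same suppression the feedforward variant achieves
directly.

## Decision, reaction times, winner attribution

The motor pair is driven by g_m·(C + S) through its own softmax. RT is
the first time after stimulus onset at which either motor rate ≥ 0.55;
the crossing unit is the choice; simultaneous crossings are broken by the
higher rate and exact ties yield no choice. The winning module is the
decision pair (C or S) that crossed 0.55 first, with the same
tie-breaking. Trials whose motor pair never crosses within the 1000 ms
stimulus window are scored as unresolved (and as incorrect in accuracy
summaries). Phase durations (cue 500 ms, delay 0, stimulus window
1000 ms) are package defaults exposed in `TrialProtocol`.

## Drive gains and calibration

The mapping from classifier outputs to rate-equation drives has a small
number of free gains; they were calibrated once, by bisection
(`scripts/calibrate_gains.py`), and frozen as package defaults:

| gain | FF | PC | role |
|---|---|---|---|
| cortical | 0.3 | 1.6 | XOR output → C pair |
| subcortical | 0.0093 | 1.0 | subcortex output → S pair |
| motor | 1.95 | 6.0 | shared motor integration |
| inhibition | 5.0 | 5.0 | antisaccade → subcortex |
| confidence κ | — | 0.21 | side-evidence scaling (PC) |

For the feedforward variant the two behavioral anchors are the mean
antisaccade RT (cortex-only pathway; sets the motor gain at fixed
cortical gain) and the mean prosaccade RT (sets the subcortical gain).
The cortical gain (0.3) sets the cortical decision pair's own crossing
latency so that the subcortex, not the cortex, resolves easy prosaccade
trials. The subcortical logit gain must also satisfy
g_s·max|logit| < g_inh so antisaccade suppression clamps completely.

In the predictive-coding variant the cortical drive is scaled by the
latent classifier's side confidence, tanh(κ·gap/ref_gap): cortical
latency then falls as the brightness difference grows, while the
subcortical crossing stays comparatively flat. This reproduces the
difficulty structure of the model's behavior — the subcortex wins most
trials with |x_left − x_right| below ~0.6, the cortex takes over above
it, and the cortex/subcortex choice ratio rises monotonically with the
brightness gap. The `ref_gap` normalisation makes κ transferable across
training seeds (raw score scales vary about two-fold).

## What the synthetic task does and does not capture

The generator reproduces the task protocol exactly — screen
geometry, grid-enumerated brightness values, balance, additive Gaussian
noise — so passing tests demonstrate the architecture's behavior under
those conditions. It does not model retinal/LGN preprocessing, eye
kinematics, luminance adaptation, temporally fluctuating noise, or
stimulus uncertainty beyond i.i.d. pixel noise; conclusions about real
psychophysical data are correspondingly limited to the qualitative
pattern (pro < anti RT, noise robustness, difficulty-dependent pathway
dominance), not to quantitative fits.

## Known limitations

- With the feedforward variant's argmax-driven cortical pathway, every
  antisaccade trial follows identical dynamics at σ = 0, so the
  antisaccade RT distribution is nearly a point mass (sd ≈ 0) and its
  mean is quantized to the 10 ms Euler step. The prosaccade distribution
  (sd ≈ 28 ms) is narrower than the experimental one.
- Subcortical suppression leaves the normalized pair at its symmetric
  0.5 point rather than at literally zero firing; all threshold-based
  contracts are unaffected.
- The predictive-coding variant's end-to-end accuracy falls to ~0.6–0.7
  at σ = 0.2 — above chance but below the feedforward variant, whose
  robustness claim (>75% at every σ ≤ 0.2) it is not required to meet.
- Problem sizes in the test suite and acceptance script (5 repeats × 200
  pairs per noise level; 500 trials per RT condition; 400-trial
  difficulty runs) are scaled-down versions of the full protocol
  (100 × 1000); the measured quantities are means whose sampling error
  at these sizes is well inside the stated tolerances.
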