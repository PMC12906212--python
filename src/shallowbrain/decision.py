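"""Motor integration, reaction times, winner attribution, trial orchestration.

A trial runs cue -> delay -> stimulus. The motor units (M_L, M_R) form one
competing pair driven by the sum of the cortical (C_L, C_R) and
subcortical (S_L, S_R) decision rates, scaled by a shared motor gain.
Reaction time is the first time after stimulus onset at which either motor
rate crosses the fixed 0.55 threshold; the crossing unit is the choice.
The winning module (cortex vs subcortex) is whichever decision pair
crossed the same threshold first.

At rest every competing pair sits at its symmetric (0.5, 0.5) point, below
threshold, so undriven trials time out with no choice. The pro/anti RT
difference is architectural: on prosaccade trials cortex and subcortex
drive the motor pair together, while on antisaccade trials the cortical
antisaccade signal silences the subcortex and the (weaker) cortical drive
alone must push the motor pair across threshold.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cortex_ff, cortex_pc, subcortex
from .dynamics import DEFAULT_DT, DEFAULT_TAU
from .subcortex import (InhibitionMode, InhibitoryProjection, RNNGains,
                        RNNState)
from .task import CueType, Side, TrialSpec, render_cue, render_stimulus


class Winner(enum.Enum):
    CORTEX = "cortex"
    SUBCORTEX = "subcortex"
    NONE = "none"


class Choice(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"


@dataclass
class TrialProtocol:
    cue_duration: float = 0.5   # s
    delay: float = 0.0          # s
    stim_duration: float = 1.0  # s, max window after stimulus onset
    threshold: float = 0.55
    dt: float = DEFAULT_DT
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if not (0.5 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0.5, 1) for a 2-way pair")


@dataclass
class Gains:
    """Drive gains mapping classifier outputs into the rate dynamics.

    Calibrated once (scripts in the repository) so that the feedforward
    variant reproduces the pro/antisaccade mean reaction times; frozen
    thereafter.
    """

    cortical: float = 1.0       # XOR output -> C pair drive
    subcortical: float = 1.0    # FF: perceptron logit gain into the S pair
    motor: float = 1.0          # shared motor integration gain
    inhibition: float = 5.0     # antisaccade -> subcortex suppression
    cue_drive: float = 1.0      # latch/cue-neuron drive
    confidence_temp: float = 0.1  # PC: softness of the side-confidence readout
    rnn: RNNGains = field(default_factory=RNNGains)


# calibrated defaults per variant (see scripts/calibrate_gains.py)
FF_GAINS = Gains(cortical=0.3, subcortical=0.0093, motor=1.95, inhibition=5.0)
PC_GAINS = Gains(cortical=1.6, subcortical=1.0, motor=6.0, inhibition=5.0,
                 confidence_temp=0.21, rnn=RNNGains())


@dataclass
class TrialResult:
    choice: Choice
    rt_ms: float | None
    winner: Winner
    correct: bool | None
    difficulty: float
    cue: CueType
    x_left: float
    x_right: float


@dataclass
class ModelBundle:
    """The complete wired network for one variant."""

    variant: str  # "ff" | "pc"
    gains: Gains
    ff_cortex: cortex_ff.FFCortexWeights | None = None
    ff_subcortex: subcortex.SubcortexFFWeights | None = None
    pc_weights: cortex_pc.PCWeights | None = None
    pc_classifier: cortex_pc.LatentClassifier | None = None
    pc_hyper: cortex_pc.PCHyper | None = None
    rnn: subcortex.SubcortexRNN | None = None
    cue_w_self: float = 1.5

    @classmethod
    def build_ff(cls, seed: int = 0, gains: Gains | None = None) -> "ModelBundle":
        return cls(
            variant="ff",
            gains=gains or replace(FF_GAINS),
            ff_cortex=cortex_ff.train_ff_classifier(seed=seed),
            ff_subcortex=subcortex.train_subcortex_ff(seed=seed + 1),
        )

    @classmethod
    def build_pc(cls, seed: int = 0, gains: Gains | None = None,
                 hyper: cortex_pc.PCHyper | None = None) -> "ModelBundle":
        hyper = hyper or cortex_pc.PCHyper()
        w = cortex_pc.pc_learn(hyper=hyper, seed=seed)
        clf = cortex_pc.train_latent_classifier(w, hyper=hyper, seed=seed + 1)
        return cls(
            variant="pc",
            gains=gains or replace(PC_GAINS),
            pc_weights=w, pc_classifier=clf, pc_hyper=hyper,
            rnn=subcortex.sample_subcortex_rnn(seed + 2),
        )

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {"variant": np.array(self.variant)}
        if self.variant == "ff":
            arrays.update({f"cx_{k}": v for k, v in self.ff_cortex.params.items()})
            arrays.update({f"sc_{k}": v for k, v in self.ff_subcortex.params.items()})
        else:
            arrays.update(U1=self.pc_weights.U1, U2=self.pc_weights.U2,
                          clf_w=self.pc_classifier.w, clf_b=self.pc_classifier.b,
                          clf_ref_gap=np.array(self.pc_classifier.ref_gap))
            arrays.update({f"rnn_{k}": v for k, (v, _) in self.rnn.projections().items()})
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, gains: Gains | None = None) -> "ModelBundle":
        with np.load(path) as z:
            variant = str(z["variant"])
            if variant == "ff":
                return cls(
                    variant="ff", gains=gains or replace(FF_GAINS),
                    ff_cortex=cortex_ff.FFCortexWeights(
                        {k[3:]: z[k] for k in z.files if k.startswith("cx_")}),
                    ff_subcortex=subcortex.SubcortexFFWeights(
                        {k[3:]: z[k] for k in z.files if k.startswith("sc_")}),
                )
            rnn_arrays = {k[4:]: z[k] for k in z.files if k.startswith("rnn_")}
            return cls(
                variant="pc", gains=gains or replace(PC_GAINS),
                pc_weights=cortex_pc.PCWeights(U1=z["U1"], U2=z["U2"]),
                pc_classifier=cortex_pc.LatentClassifier(
                    w=z["clf_w"], b=z["clf_b"],
                    ref_gap=float(z["clf_ref_gap"])),
                pc_hyper=cortex_pc.PCHyper(),
                rnn=subcortex.SubcortexRNN(**rnn_arrays),
            )


def _pair_softmax(u: np.ndarray) -> np.ndarray:
    z = u - u.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _noisy(grids: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return grids
    return grids + rng.normal(0.0, sigma, size=grids.shape)


@dataclass
class _Recorder:
    enabled: bool
    traces: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def push(self, **named: np.ndarray) -> None:
        if not self.enabled:
            return
        for k, v in named.items():
            self.traces.setdefault(k, []).append(np.array(v, copy=True))

    def stacked(self) -> dict[str, np.ndarray]:
        return {k: np.stack(v) for k, v in self.traces.items()}


def run_trials(model: ModelBundle, trials: list[TrialSpec], sigma: float,
               protocol: TrialProtocol | None = None,
               rng: np.random.Generator | None = None,
               record: bool = False):
    """Run a batch of trials; returns (list[TrialResult], trace dict).

    Traces (step, trial, unit) are recorded for the stimulus window only
    when ``record`` is set.
    """
    protocol = protocol or TrialProtocol()
    rng = rng or np.random.default_rng(0)
    if model.variant == "ff":
        return _run_trials_ff(model, trials, sigma, protocol, rng, record)
    return _run_trials_pc(model, trials, sigma, protocol, rng, record)


def run_trial(model: ModelBundle, trial: TrialSpec, sigma: float = 0.0,
              protocol: TrialProtocol | None = None,
              rng: np.random.Generator | None = None):
    """Single-trial convenience wrapper: (TrialResult, rate traces)."""
    results, traces = run_trials(model, [trial], sigma, protocol, rng, record=True)
    return results[0], {k: v[:, 0] for k, v in traces.items()}


def _finalize(trials, protocol, m_cross_step, m_choice_idx, c_cross, s_cross,
              c_peak, s_peak) -> list[TrialResult]:
    dt_ms = protocol.dt * 1000.0
    out = []
    for i, t in enumerate(trials):
        if m_cross_step[i] < 0:
            out.append(TrialResult(Choice.NONE, None, Winner.NONE, None,
                                   t.difficulty, t.cue, t.pair.x_left, t.pair.x_right))
            continue
        choice = Choice.LEFT if m_choice_idx[i] == 0 else Choice.RIGHT
        rt = (m_cross_step[i] + 1) * dt_ms
        cc, sc = c_cross[i], s_cross[i]
        if cc < 0 and sc < 0:
            winner = Winner.NONE
        elif sc < 0 or (cc >= 0 and cc < sc):
            winner = Winner.CORTEX
        elif cc < 0 or sc < cc:
            winner = Winner.SUBCORTEX
        else:  # same step: break by peak rate at the crossing step
            if c_peak[i] > s_peak[i]:
                winner = Winner.CORTEX
            elif s_peak[i] > c_peak[i]:
                winner = Winner.SUBCORTEX
            else:
                winner = Winner.NONE
        correct = None
        if t.correct_side is not Side.UNDEFINED:
            correct = (choice is Choice.LEFT) == (t.correct_side is Side.LEFT)
        out.append(TrialResult(choice, rt, winner, correct, t.difficulty,
                               t.cue, t.pair.x_left, t.pair.x_right))
    return out


def _run_trials_ff(model, trials, sigma, protocol, rng, record):
    n = len(trials)
    k = protocol.dt / protocol.tau
    g = model.gains
    inhib = InhibitoryProjection(InhibitionMode.DIRECT_INHIBITION, g.inhibition)

    cue_grids = _noisy(np.stack([render_cue(t.cue).grid for t in trials]), sigma, rng)
    cue_scores = cortex_ff.classify_batch(model.ff_cortex, cue_grids)
    latched_anti = (cue_scores[:, cortex_ff.IDX_A]
                    > cue_scores[:, cortex_ff.IDX_P]).astype(float)

    stim_grids = _noisy(np.stack([render_stimulus(t.pair).grid for t in trials]),
                        sigma, rng)
    stim_scores = cortex_ff.classify_batch(model.ff_cortex, stim_grids)
    side_right = (stim_scores[:, cortex_ff.IDX_R]
                  > stim_scores[:, cortex_ff.IDX_L]).astype(float)
    # XOR rule integration: ANTI flips the brighter-side class
    target_right = np.logical_xor(side_right > 0.5, latched_anti > 0.5)
    c_onehot = np.zeros((n, 2))
    c_onehot[np.arange(n), target_right.astype(int)] = 1.0

    C = np.zeros((n, 2))
    S = np.zeros((n, 2))
    M = np.zeros((n, 2))
    A = np.zeros(n)
    a_drive = g.cue_drive * latched_anti

    cue_readout = subcortex.readout_batch(cue_grids)
    stim_readout = subcortex.readout_batch(stim_grids)
    rec = _Recorder(record)

    def advance(c_pre, readouts, n_steps, track=None):
        nonlocal C, S, M, A
        for step in range(n_steps):
            s_pre = subcortex.subcortex_ff_preactivation(
                model.ff_subcortex, readouts, A, inhib, g.subcortical)
            m_pre = g.motor * (C + S)
            C_new = C + k * (-C + _pair_softmax(c_pre))
            S_new = S + k * (-S + _pair_softmax(s_pre))
            M_new = M + k * (-M + _pair_softmax(m_pre))
            A = A + k * (-A + np.maximum(a_drive, 0.0))
            C, S, M = C_new, S_new, M_new
            if track is not None:
                track(step)
                rec.push(C=C, S=S, M=M, A=A)
        return

    n_cue = int(round(protocol.cue_duration / protocol.dt))
    n_delay = int(round(protocol.delay / protocol.dt))
    n_stim = int(round(protocol.stim_duration / protocol.dt))
    advance(np.zeros((n, 2)), cue_readout, n_cue)
    if n_delay:
        advance(np.zeros((n, 2)), np.zeros((n, 2)), n_delay)

    th = protocol.threshold
    m_cross = np.full(n, -1)
    m_choice = np.zeros(n, dtype=int)
    c_cross = np.full(n, -1)
    s_cross = np.full(n, -1)
    c_peak = np.zeros(n)
    s_peak = np.zeros(n)

    def track(step):
        _track_crossings(step, th, C, S, M, m_cross, m_choice, c_cross,
                         s_cross, c_peak, s_peak)

    advance(g.cortical * c_onehot, stim_readout, n_stim, track=track)
    return (_finalize(trials, protocol, m_cross, m_choice, c_cross, s_cross,
                      c_peak, s_peak), rec.stacked())


def _track_crossings(step, th, C, S, M, m_cross, m_choice, c_cross, s_cross,
                     c_peak, s_peak):
    newly = (m_cross < 0) & (M.max(axis=1) >= th)
    if newly.any():
        both = newly & (M[:, 0] >= th) & (M[:, 1] >= th)
        m_choice[newly] = M[newly].argmax(axis=1)
        exact_tie = both & (M[:, 0] == M[:, 1])
        m_cross[newly & ~exact_tie] = step
        # exact tie at the crossing step: no decision, keep searching
    c_new = (c_cross < 0) & (C.max(axis=1) >= th)
    c_cross[c_new] = step
    c_peak[c_new] = C[c_new].max(axis=1)
    s_new = (s_cross < 0) & (S.max(axis=1) >= th)
    s_cross[s_new] = step
    s_peak[s_new] = S[s_new].max(axis=1)


def _run_trials_pc(model, trials, sigma, protocol, rng, record):
    n = len(trials)
    k = protocol.dt / protocol.tau
    g = model.gains
    inhib = InhibitoryProjection(InhibitionMode.VIA_INTERNEURONS, g.inhibition)

    cue_grids = _noisy(np.stack([render_cue(t.cue).grid for t in trials]), sigma, rng)
    cue_states = cortex_pc.pc_infer(model.pc_weights, cue_grids, model.pc_hyper)
    cue_scores = model.pc_classifier.scores(cue_states.r2)
    cue_is_anti = (cue_scores[:, cortex_pc.IDX_A]
                   > cue_scores[:, cortex_pc.IDX_P]).astype(float)

    stim_grids = _noisy(np.stack([render_stimulus(t.pair).grid for t in trials]),
                        sigma, rng)
    stim_states = cortex_pc.pc_infer(model.pc_weights, stim_grids, model.pc_hyper)
    stim_scores = model.pc_classifier.scores(stim_states.r2)
    side_right = (stim_scores[:, cortex_pc.IDX_R]
                  > stim_scores[:, cortex_pc.IDX_L]).astype(float)
    # graded evidence: the cortical drive scales with the classifier's side
    # confidence (score gap on the classifier's own training scale), so
    # cortical latency falls with stimulus discriminability
    confidence = np.tanh(g.confidence_temp
                         * model.pc_classifier.side_confidence(stim_scores))

    p_rate = np.zeros(n)
    a_rate = np.zeros(n)
    C = np.zeros((n, 2))
    S = np.zeros((n, 2))
    M = np.zeros((n, 2))
    rnn_state = RNNState.zeros(n)
    rec = _Recorder(record)

    cue_readout = subcortex.readout_batch(cue_grids)
    stim_readout = subcortex.readout_batch(stim_grids)

    def advance(c_pre, readouts, drive_p, drive_a, n_steps, track=None):
        nonlocal C, S, M, p_rate, a_rate, rnn_state
        for step in range(n_steps):
            rnn_state, rnn_out = subcortex.step_subcortex_rnn(
                model.rnn, rnn_state, readouts, a_rate, inhib, g.rnn, rng,
                tau=protocol.tau, dt=protocol.dt)
            s_pre = g.subcortical * np.maximum(rnn_out, 0.0)
            m_pre = g.motor * (C + S)
            C = C + k * (-C + _pair_softmax(c_pre))
            S = S + k * (-S + _pair_softmax(s_pre))
            M = M + k * (-M + _pair_softmax(m_pre))
            p_rate, a_rate = cortex_pc.sustain_cue_batch(
                p_rate, a_rate, drive_p, drive_a, model.cue_w_self,
                tau=protocol.tau, dt=protocol.dt)
            if track is not None:
                track(step)
                rec.push(C=C, S=S, M=M, P=p_rate, A=a_rate,
                         SI=rnn_state.r_si.mean(axis=1))
        return

    n_cue = int(round(protocol.cue_duration / protocol.dt))
    n_delay = int(round(protocol.delay / protocol.dt))
    n_stim = int(round(protocol.stim_duration / protocol.dt))
    drive_p = g.cue_drive * (1.0 - cue_is_anti)
    drive_a = g.cue_drive * cue_is_anti
    advance(np.zeros((n, 2)), cue_readout, drive_p, drive_a, n_cue)
    zeros = np.zeros(n)
    if n_delay:
        advance(np.zeros((n, 2)), np.zeros((n, 2)), zeros, zeros, n_delay)

    # the sustained cue neuron, not the transient classification, sets the rule
    rule_anti = a_rate > p_rate
    target_right = np.logical_xor(side_right > 0.5, rule_anti)
    c_onehot = np.zeros((n, 2))
    c_onehot[np.arange(n), target_right.astype(int)] = confidence

    th = protocol.threshold
    m_cross = np.full(n, -1)
    m_choice = np.zeros(n, dtype=int)
    c_cross = np.full(n, -1)
    s_cross = np.full(n, -1)
    c_peak = np.zeros(n)
    s_peak = np.zeros(n)

    def track(step):
        _track_crossings(step, th, C, S, M, m_cross, m_choice, c_cross,
                         s_cross, c_peak, s_peak)

    advance(g.cortical * c_onehot, stim_readout, zeros, zeros, n_stim, track=track)
    return (_finalize(trials, protocol, m_cross, m_choice, c_cross, s_cross,
                      c_peak, s_peak), rec.stacked())


# --- summaries -------------------------------------------------------------

def results_to_frame(results: list[TrialResult],
                     model_variant: str = "", sigma: float = 0.0) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        rows.append(dict(trial_id=i, model_variant=model_variant,
                         cue=r.cue.value, x_left=r.x_left, x_right=r.x_right,
                         sigma=sigma, choice=r.choice.value, rt_ms=r.rt_ms,
                         winner=r.winner.value, correct=r.correct,
                         difficulty=r.difficulty))
    return pd.DataFrame(rows)


def rt_summary(results: list[TrialResult]) -> pd.DataFrame:
    """Per-cue (mean, sd, n) of reaction time; unresolved trials excluded."""
    rows = []
    present = [cue for cue in CueType if any(r.cue is cue for r in results)]
    for cue in present:
        rts = [r.rt_ms for r in results if r.cue is cue and r.rt_ms is not None]
        if not rts:
            raise ValueError(f"no resolved trials for cue {cue.value}")
        rows.append(dict(cue=cue.value, mean_rt_ms=float(np.mean(rts)),
                         sd_rt_ms=float(np.std(rts, ddof=1)) if len(rts) > 1 else 0.0,
                         n=len(rts)))
    return pd.DataFrame(rows)


def choice_accuracy(results: list[TrialResult]) -> float:
    """Fraction of correct choices; side-undefined trials excluded,
    unresolved (NONE) trials count as incorrect."""
    scored = [r for r in results if r.difficulty > 0]
    if not scored:
        raise ValueError("no scorable trials")
    return float(np.mean([r.correct is True for r in scored]))


def difficulty_analysis(results: list[TrialResult],
                        bins: np.ndarray | None = None) -> pd.DataFrame:
    """Winner counts, RT statistics, and the cortex/subcortex choice ratio
    per difficulty bin; prosaccade trials only."""
    if any(r.cue is not CueType.PRO for r in results):
        raise ValueError("difficulty analysis is defined for PRO trials only")
    bins = np.asarray(bins) if bins is not None else np.arange(0.0, 1.0001, 0.1)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        in_bin = [r for r in results
                  if lo <= r.difficulty < hi or (hi == bins[-1] and r.difficulty == hi)]
        ctx = [r for r in in_bin if r.winner is Winner.CORTEX]
        sub = [r for r in in_bin if r.winner is Winner.SUBCORTEX]
        ratio = len(ctx) / len(sub) if sub else np.nan
        def _stats(group):
            rts = [r.rt_ms for r in group if r.rt_ms is not None]
            return (float(np.mean(rts)) if rts else np.nan,
                    float(np.std(rts)) if rts else np.nan)
        ctx_mean, ctx_sd = _stats(ctx)
        sub_mean, sub_sd = _stats(sub)
        rows.append(dict(bin_lo=lo, bin_hi=hi, n=len(in_bin),
                         cortex_wins=len(ctx), subcortex_wins=len(sub),
                         choice_ratio=ratio,
                         cortex_rt_mean=ctx_mean, cortex_rt_sd=ctx_sd,
                         subcortex_rt_mean=sub_mean, subcortex_rt_sd=sub_sd))
    return pd.DataFrame(rows)
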