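"""Shallow subcortical pathway (superior-colliculus-like) in two variants.

Both variants see the screen only through two fixed 4x4 receptive-field
windows — the regions where the brightness squares appear — so the
subcortex responds to comparison stimuli but is structurally blind to the
cue bar.

* FF variant: a 2 -> 16 -> 2 perceptron trained by backpropagation on the
  brighter-side task; its output logits drive a competing (S_L, S_R)
  decision pair. The cortical antisaccade neuron projects *direct
  inhibition* onto both decision units: the inhibition is subtracted
  before a rectification, so a strong antisaccade signal clamps both
  pre-activations to zero and the normalized pair sits at its symmetric
  0.5 point, below the 0.55 decision threshold, for the whole trial.

* PC variant: a non-plastic random recurrent network — two excitatory
  populations of 128 units (S_L, S_R) with self-recurrence, a shared
  32-unit inhibitory population (S_I), sparse random connectivity
  (densities 0.3 excitatory-to-inhibitory, 0.8 inhibitory, 0.4
  self-recurrent and input, 0.8 output) with uniform(0,1) magnitudes.
  The antisaccade neuron suppresses it *indirectly* by exciting S_I.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .dynamics import DEFAULT_DT, DEFAULT_TAU
from .task import (LEFT_WINDOW, RIGHT_WINDOW, Side, StimulusFrame, TrialSet,
                   make_training_set, render_stimulus)

N_EXC = 128
N_INH = 32
P_EXC = 0.3      # S_L/S_R -> S_I
P_INH = 0.8      # S_I -> S_L/S_R
P_SELF = 0.4     # S_L -> S_L, S_R -> S_R
P_INPUT = 0.4    # receptive-field input -> S_L/S_R
P_OUTPUT = 0.8   # S_L/S_R -> motor readout


@dataclass(frozen=True)
class ReceptiveFieldReadout:
    left_value: float
    right_value: float


def readout_receptive_fields(frame: StimulusFrame) -> ReceptiveFieldReadout:
    """Mean intensity over each square's 4x4 window (linear in the pixels)."""
    return ReceptiveFieldReadout(
        left_value=float(frame.grid[LEFT_WINDOW].mean()),
        right_value=float(frame.grid[RIGHT_WINDOW].mean()),
    )


def readout_batch(grids: np.ndarray) -> np.ndarray:
    """(n, 2) window means for an (n, 16, 32) batch of screens."""
    grids = np.asarray(grids, dtype=float)
    return np.stack([
        grids[:, LEFT_WINDOW[0], LEFT_WINDOW[1]].mean(axis=(1, 2)),
        grids[:, RIGHT_WINDOW[0], RIGHT_WINDOW[1]].mean(axis=(1, 2)),
    ], axis=1)


# --- FF variant: trained perceptron ---------------------------------------

@dataclass
class SubcortexFFWeights:
    params: dict[str, np.ndarray]

    def logits(self, readouts: np.ndarray) -> np.ndarray:
        """(S_L, S_R) logits for (n, 2) receptive-field readouts."""
        h = np.maximum(readouts @ self.params["w1"] + self.params["b1"], 0.0)
        return h @ self.params["w2"] + self.params["b2"]

    def save(self, path) -> None:
        np.savez(path, **self.params)


class TrainingDidNotConvergeError(RuntimeError):
    pass


def train_subcortex_ff(train: TrialSet | None = None, seed: int = 0,
                       lr: float = 0.02, epochs: int = 1500) -> SubcortexFFWeights:
    """Train the 2->16->2 perceptron to >=99% side accuracy on the
    non-diagonal training pairs; deterministic under ``seed``."""
    train = train or make_training_set()
    xs, ys = [], []
    for p in train.pairs:
        if p.brighter is Side.UNDEFINED:
            continue
        r = readout_receptive_fields(render_stimulus(p))
        xs.append([r.left_value, r.right_value])
        ys.append(0 if p.brighter is Side.LEFT else 1)
    x = np.array(xs)
    y = np.array(ys)
    rng = np.random.default_rng(seed)
    params = {
        "w1": rng.normal(0, 1.0, size=(2, 16)), "b1": np.zeros(16),
        "w2": rng.normal(0, 0.35, size=(16, 2)), "b2": np.zeros(2),
    }
    opt = _nn.Adam(params, lr=lr)
    weights_cls = np.ones(2)
    acc = 0.0
    for _ in range(epochs):
        h = np.maximum(x @ params["w1"] + params["b1"], 0.0)
        logits = h @ params["w2"] + params["b2"]
        acc = float((logits.argmax(axis=1) == y).mean())
        _, dlogits = _nn.weighted_cross_entropy(logits, y, weights_cls)
        dh = dlogits @ params["w2"].T
        dh *= h > 0
        opt.step({
            "w2": h.T @ dlogits, "b2": dlogits.sum(axis=0),
            "w1": x.T @ dh, "b1": dh.sum(axis=0),
        })
    if acc < 0.99:
        raise TrainingDidNotConvergeError(f"side accuracy {acc:.3f} < 0.99")
    return SubcortexFFWeights(params=params)


# --- PC variant: non-plastic random E/I recurrent network -----------------

@dataclass
class SubcortexRNN:
    """Frozen random connectivity. Stored magnitudes are uniform(0, 1) at
    the stated densities; inhibitory signs and in-degree normalisation are
    applied at drive time."""

    W_si_sl: np.ndarray   # (32, 128) excitatory, p=0.3
    W_si_sr: np.ndarray   # (32, 128) excitatory, p=0.3
    W_sl_si: np.ndarray   # (128, 32) inhibitory magnitude, p=0.8
    W_sr_si: np.ndarray   # (128, 32) inhibitory magnitude, p=0.8
    W_sl_sl: np.ndarray   # (128, 128) self-recurrent, p=0.4
    W_sr_sr: np.ndarray   # (128, 128) self-recurrent, p=0.4
    w_sl_x: np.ndarray    # (128,) input, p=0.4
    w_sr_x: np.ndarray    # (128,) input, p=0.4
    w_ml_sl: np.ndarray   # (128,) output, p=0.8
    w_mr_sr: np.ndarray   # (128,) output, p=0.8

    def projections(self) -> dict[str, tuple[np.ndarray, float]]:
        return {
            "W_si_sl": (self.W_si_sl, P_EXC), "W_si_sr": (self.W_si_sr, P_EXC),
            "W_sl_si": (self.W_sl_si, P_INH), "W_sr_si": (self.W_sr_si, P_INH),
            "W_sl_sl": (self.W_sl_sl, P_SELF), "W_sr_sr": (self.W_sr_sr, P_SELF),
            "w_sl_x": (self.w_sl_x, P_INPUT), "w_sr_x": (self.w_sr_x, P_INPUT),
            "w_ml_sl": (self.w_ml_sl, P_OUTPUT), "w_mr_sr": (self.w_mr_sr, P_OUTPUT),
        }

    def to_triplets(self) -> pd.DataFrame:
        """Sparse (pre, post, weight, projection_name) triplet table."""
        rows = []
        for name, (w, _) in self.projections().items():
            w2 = np.atleast_2d(w)  # (n_post, n_pre); vectors become 1 x n_pre
            post, pre = np.nonzero(w2)
            for i, j in zip(post, pre):
                rows.append((int(j), int(i), float(w2[i, j]), name))
        return pd.DataFrame(rows, columns=["pre", "post", "weight", "projection_name"])

    def save(self, path) -> None:
        np.savez(path, **{k: v for k, (v, _) in self.projections().items()})


def _sample(rng: np.random.Generator, shape, p: float) -> np.ndarray:
    mask = rng.random(shape) < p
    return mask * rng.random(shape)


def sample_subcortex_rnn(seed: int) -> SubcortexRNN:
    """Sample the frozen connectivity: Bernoulli masks at the stated
    densities, uniform(0, 1) magnitudes; reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    return SubcortexRNN(
        W_si_sl=_sample(rng, (N_INH, N_EXC), P_EXC),
        W_si_sr=_sample(rng, (N_INH, N_EXC), P_EXC),
        W_sl_si=_sample(rng, (N_EXC, N_INH), P_INH),
        W_sr_si=_sample(rng, (N_EXC, N_INH), P_INH),
        W_sl_sl=_sample(rng, (N_EXC, N_EXC), P_SELF),
        W_sr_sr=_sample(rng, (N_EXC, N_EXC), P_SELF),
        w_sl_x=_sample(rng, N_EXC, P_INPUT),
        w_sr_x=_sample(rng, N_EXC, P_INPUT),
        w_ml_sl=_sample(rng, N_EXC, P_OUTPUT),
        w_mr_sr=_sample(rng, N_EXC, P_OUTPUT),
    )


class InhibitionMode(enum.Enum):
    DIRECT_INHIBITION = "direct"      # FF: A -> S_L, S_R with negative sign
    VIA_INTERNEURONS = "interneurons"  # PC: A -> S_I, excitatory


@dataclass
class InhibitoryProjection:
    mode: InhibitionMode
    gain: float = 5.0


@dataclass
class RNNGains:
    """Drive scaling for the random network (each projection's drive is
    normalised by its expected in-degree p * N_pre, so stored weights stay
    on the stated uniform(0, 1) scale)."""

    input_gain: float = 1.5
    recurrent_gain: float = 0.5
    inhibitory_gain: float = 2.0
    exc_to_inh_gain: float = 1.0
    background_sigma: float = 0.01
    output_gain: float = 16.0


@dataclass
class RNNState:
    r_sl: np.ndarray  # (B, 128)
    r_sr: np.ndarray  # (B, 128)
    r_si: np.ndarray  # (B, 32)

    @classmethod
    def zeros(cls, batch: int) -> "RNNState":
        return cls(np.zeros((batch, N_EXC)), np.zeros((batch, N_EXC)),
                   np.zeros((batch, N_INH)))


def subcortex_ff_preactivation(weights: SubcortexFFWeights, readouts: np.ndarray,
                               a_activity: np.ndarray, inhib: InhibitoryProjection,
                               logit_gain: float = 1.0) -> np.ndarray:
    """Rectified, inhibition-modulated drive to the (S_L, S_R) decision
    pair: relu(gain * logits - g_inh * a). The rectification makes the
    subtraction effective under the pair normalization."""
    if inhib.mode is not InhibitionMode.DIRECT_INHIBITION:
        raise ValueError("FF subcortex uses direct inhibition")
    logits = weights.logits(np.atleast_2d(readouts))
    a = np.atleast_1d(np.asarray(a_activity, dtype=float))
    return np.maximum(logit_gain * logits - inhib.gain * a[:, None], 0.0)


def step_subcortex_rnn(rnn: SubcortexRNN, state: RNNState, readouts: np.ndarray,
                       a_activity: np.ndarray, inhib: InhibitoryProjection,
                       gains: RNNGains, rng: np.random.Generator,
                       tau: float = DEFAULT_TAU, dt: float = DEFAULT_DT
                       ) -> tuple[RNNState, np.ndarray]:
    """One synchronous Euler step of all three populations.

    Returns the new state and the (B, 2) normalised population output
    (per-unit output weights, in-degree-normalised, before the decision
    pair's own dynamics)."""
    if inhib.mode is not InhibitionMode.VIA_INTERNEURONS:
        raise ValueError("the random-network subcortex is suppressed via S_I")
    x_l = readouts[:, 0:1]
    x_r = readouts[:, 1:2]
    a = np.atleast_1d(np.asarray(a_activity, dtype=float))[:, None]

    u_sl = (gains.input_gain * x_l * rnn.w_sl_x[None, :]
            + gains.recurrent_gain * state.r_sl @ rnn.W_sl_sl.T / (P_SELF * N_EXC)
            - gains.inhibitory_gain * state.r_si @ rnn.W_sl_si.T / (P_INH * N_INH)
            + rng.normal(0, gains.background_sigma, size=state.r_sl.shape))
    u_sr = (gains.input_gain * x_r * rnn.w_sr_x[None, :]
            + gains.recurrent_gain * state.r_sr @ rnn.W_sr_sr.T / (P_SELF * N_EXC)
            - gains.inhibitory_gain * state.r_si @ rnn.W_sr_si.T / (P_INH * N_INH)
            + rng.normal(0, gains.background_sigma, size=state.r_sr.shape))
    u_si = (gains.exc_to_inh_gain
            * (state.r_sl @ rnn.W_si_sl.T + state.r_sr @ rnn.W_si_sr.T)
            / (P_EXC * 2 * N_EXC)
            + inhib.gain * a)

    k = dt / tau
    new = RNNState(
        r_sl=state.r_sl + k * (-state.r_sl + np.maximum(u_sl, 0.0)),
        r_sr=state.r_sr + k * (-state.r_sr + np.maximum(u_sr, 0.0)),
        r_si=state.r_si + k * (-state.r_si + np.maximum(u_si, 0.0)),
    )
    out = np.stack([
        new.r_sl @ rnn.w_ml_sl / (P_OUTPUT * N_EXC),
        new.r_sr @ rnn.w_mr_sr / (P_OUTPUT * N_EXC),
    ], axis=1)
    return new, gains.output_gain * out
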