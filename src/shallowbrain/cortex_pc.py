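"""Predictive-coding cortical pathway (Rao-Ballard hierarchy).

A three-layer linear generative hierarchy over the flattened 16x32 screen:
layer 0 is the 512-pixel input, layers 1 and 2 hold 144 and 16 latent
units. Generative weights U1 (512x144) and U2 (144x16) predict each layer
from the one above; inference minimises the total squared prediction error

    E = ||x - U1 r1||^2 + ||r1 - U2 r2||^2 + lambda (||r1||^2 + ||r2||^2)

by gradient descent on the latents, and learning updates the weights with
the local Hebbian-style rule dU ~ (prediction error) x (latent)^T — no
backpropagation through the hierarchy. A separate linear classifier reads
the 16-unit top latents out into the four task classes (L, R, P, A).

Instead of an external memory latch, the rule is held across the delay by
two self-excitatory cue neurons (P and A) whose saturating rectified
dynamics are bistable: once driven past threshold they sustain activity
after the cue disappears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .dynamics import DEFAULT_DT, DEFAULT_TAU, RateUnitParams
from .task import (CueType, Side, StimulusFrame, TrialSet, make_training_set,
                   render_cue, render_stimulus)

LAYER_SIZES = (512, 144, 16)
CLASSES = ("L", "R", "P", "A")
IDX_L, IDX_R, IDX_P, IDX_A = range(4)


@dataclass
class PCHyper:
    inference_rate: float = 0.05
    inference_iters: int = 60
    learning_rate: float = 0.05
    prior_decay: float = 0.05
    epochs: int = 150
    divergence_patience: int = 5


@dataclass
class PCWeights:
    U1: np.ndarray  # (512, 144)
    U2: np.ndarray  # (144, 16)
    history: pd.DataFrame | None = None

    def save(self, path) -> None:
        np.savez(path, U1=self.U1, U2=self.U2)

    @classmethod
    def load(cls, path) -> "PCWeights":
        with np.load(path) as z:
            return cls(U1=z["U1"], U2=z["U2"])


@dataclass
class PCLayerStates:
    r0: np.ndarray  # the flattened input, (B, 512)
    r1: np.ndarray  # (B, 144)
    r2: np.ndarray  # (B, 16)
    energy: np.ndarray | None = None  # per-iteration total energy, (iters+1,)


class InferenceDivergedError(RuntimeError):
    pass


def init_pc_weights(seed: int = 0) -> PCWeights:
    rng = np.random.default_rng(seed)
    U1 = rng.normal(0.0, 1.0 / np.sqrt(LAYER_SIZES[1]), size=LAYER_SIZES[:2][::-1]).T
    U2 = rng.normal(0.0, 1.0 / np.sqrt(LAYER_SIZES[2]), size=(LAYER_SIZES[1], LAYER_SIZES[2]))
    return PCWeights(U1=U1, U2=U2)


def _energy(x, r1, r2, w: PCWeights, lam: float) -> float:
    e0 = x - r1 @ w.U1.T
    e1 = r1 - r2 @ w.U2.T
    return float((e0 ** 2).sum() + (e1 ** 2).sum()
                 + lam * ((r1 ** 2).sum() + (r2 ** 2).sum()))


def pc_infer(weights: PCWeights, frames: StimulusFrame | np.ndarray,
             hyper: PCHyper | None = None) -> PCLayerStates:
    """Latent inference: gradient descent on the prediction-error energy.

    Accepts one StimulusFrame or an (n, 16, 32) batch. The per-iteration
    energy is recorded; a sustained energy increase (divergence) raises.
    """
    hyper = hyper or PCHyper()
    n0, n1 = weights.U1.shape
    n2 = weights.U2.shape[1]
    if isinstance(frames, StimulusFrame):
        x = frames.grid.reshape(1, -1)
    else:
        x = np.asarray(frames, dtype=float).reshape(-1, n0)
    B = x.shape[0]
    r1 = np.zeros((B, n1))
    r2 = np.zeros((B, n2))
    lam, alpha = hyper.prior_decay, hyper.inference_rate
    energy = [_energy(x, r1, r2, weights, lam)]
    bad = 0
    for _ in range(hyper.inference_iters):
        e0 = x - r1 @ weights.U1.T
        e1 = r1 - r2 @ weights.U2.T
        r1 = r1 + alpha * (e0 @ weights.U1 - e1 - lam * r1)
        e1 = r1 - r2 @ weights.U2.T
        r2 = r2 + alpha * (e1 @ weights.U2 - lam * r2)
        energy.append(_energy(x, r1, r2, weights, lam))
        bad = bad + 1 if energy[-1] > energy[-2] else 0
        if bad > hyper.divergence_patience:
            raise InferenceDivergedError(
                f"inference energy increased for {bad} consecutive iterations")
    return PCLayerStates(r0=x, r1=r1, r2=r2, energy=np.array(energy))


def training_frames(train: TrialSet | None = None,
                    cue_repeats: int = 60) -> np.ndarray:
    """All screens seen during learning.

    Every trial of the task presents a cue screen followed by a stimulus
    screen, so the screen statistics the hierarchy is exposed to contain
    as many cue presentations as stimulus presentations. Each of the two
    cue screens is therefore repeated ``cue_repeats`` times alongside the
    121 stimulus screens of the training grid; without this weighting the
    generative model allocates almost no variance to the 2-pixel cue bars
    and their identity becomes unrecoverable from the top latents under
    pixel noise.
    """
    train = train or make_training_set()
    frames = ([render_cue(CueType.PRO).grid] * cue_repeats
              + [render_cue(CueType.ANTI).grid] * cue_repeats)
    frames += [render_stimulus(p).grid for p in train.pairs]
    return np.stack(frames)


def pc_learn(train: TrialSet | None = None, hyper: PCHyper | None = None,
             seed: int = 0) -> PCWeights:
    """Alternate latent inference and local weight updates until the mean
    reconstruction error stops improving; deterministic under ``seed``."""
    hyper = hyper or PCHyper()
    x = training_frames(train)
    w = init_pc_weights(seed)
    B = x.shape[0]
    log = []
    for epoch in range(hyper.epochs):
        st = pc_infer(w, x, hyper)
        e0 = st.r0 - st.r1 @ w.U1.T
        e1 = st.r1 - st.r2 @ w.U2.T
        w.U1 += hyper.learning_rate * e0.T @ st.r1 / B
        w.U2 += hyper.learning_rate * e1.T @ st.r2 / B
        if not (np.all(np.isfinite(w.U1)) and np.all(np.isfinite(w.U2))):
            raise FloatingPointError(
                f"non-finite weights at epoch {epoch}; "
                f"|U1|max={np.abs(w.U1).max():.3g}")
        log.append((epoch, float((e0 ** 2).sum(axis=1).mean()),
                    float((e1 ** 2).sum(axis=1).mean())))
    w.history = pd.DataFrame(log, columns=["epoch", "recon_error_l1", "recon_error_l2"])
    return w


def reconstruct_from_layer(weights: PCWeights, states: PCLayerStates,
                           layer: int) -> np.ndarray:
    """Top-down reconstruction of the input screen(s) from layer 1 or 2."""
    if layer == 1:
        flat = states.r1 @ weights.U1.T
    elif layer == 2:
        flat = (states.r2 @ weights.U2.T) @ weights.U1.T
    else:
        raise ValueError(f"layer must be 1 or 2, got {layer}")
    return flat.reshape(-1, 16, 32)


# --- linear readout of the top latents ------------------------------------

@dataclass
class LatentClassifier:
    w: np.ndarray  # (16, 4)
    b: np.ndarray  # (4,)
    # median |score_L - score_R| over the noiseless training pairs; used to
    # express side evidence on a scale independent of the fitted weight norm
    ref_gap: float = 1.0

    def side_confidence(self, scores: np.ndarray) -> np.ndarray:
        gap = np.abs(scores[..., IDX_L] - scores[..., IDX_R])
        return gap / self.ref_gap

    def scores(self, r2: np.ndarray) -> np.ndarray:
        r2 = np.asarray(r2, dtype=float)
        if r2.shape[-1] != LAYER_SIZES[2]:
            raise ValueError(f"expected {LAYER_SIZES[2]}-d latents, got {r2.shape}")
        return r2 @ self.w + self.b


def classify_latent(classifier: LatentClassifier, r2: np.ndarray) -> np.ndarray:
    """Class scores over (L, R, P, A) for one or a batch of top latents."""
    return classifier.scores(r2)


def train_latent_classifier(weights: PCWeights, train: TrialSet | None = None,
                            hyper: PCHyper | None = None, seed: int = 0,
                            lr: float = 0.05, epochs: int = 2000,
                            noise_sigma: float = 0.15,
                            noise_reps: int = 8) -> LatentClassifier:
    """Post-hoc linear fit (softmax regression on frozen latents).

    The readout is fit on latents inferred from both clean and
    pixel-noised screen presentations, so the learned directions are
    aligned with the signal rather than with arbitrary separating
    directions of the (tiny) noiseless training set — this is what makes
    cue classification robust at test-time noise levels.
    """
    train = train or make_training_set()
    frames = [render_cue(CueType.PRO).grid, render_cue(CueType.ANTI).grid]
    labels = [IDX_P, IDX_A]
    for p in train.pairs:
        if p.brighter is Side.UNDEFINED:
            continue
        frames.append(render_stimulus(p).grid)
        labels.append(IDX_L if p.brighter is Side.LEFT else IDX_R)
    x = np.stack(frames)
    y = np.array(labels)
    if noise_reps > 0 and noise_sigma > 0:
        noise_rng = np.random.default_rng(seed + 1)
        reps = [x]
        for _ in range(noise_reps):
            reps.append(x + noise_rng.normal(0, noise_sigma, size=x.shape))
        x = np.concatenate(reps)
        y = np.tile(y, noise_reps + 1)
    st = pc_infer(weights, x, hyper)
    counts = np.bincount(y, minlength=4).astype(float)
    class_w = len(y) / (4.0 * counts)
    rng = np.random.default_rng(seed)
    params = {"w": rng.normal(0, 0.1, size=(LAYER_SIZES[2], 4)), "b": np.zeros(4)}
    opt = _nn.Adam(params, lr=lr)
    for _ in range(epochs):
        logits = st.r2 @ params["w"] + params["b"]
        _, dlogits = _nn.weighted_cross_entropy(logits, y, class_w)
        opt.step({"w": st.r2.T @ dlogits, "b": dlogits.sum(axis=0)})
    clean = pc_infer(weights, np.stack(frames)[2:], hyper)  # stimulus screens only
    gaps = np.abs((clean.r2 @ params["w"] + params["b"])[:, IDX_L]
                  - (clean.r2 @ params["w"] + params["b"])[:, IDX_R])
    return LatentClassifier(w=params["w"], b=params["b"],
                            ref_gap=float(np.median(gaps)))


# --- self-recurrent cue neurons -------------------------------------------

@dataclass
class CueNeurons:
    """Bistable rule memory: two saturating rectified units with excitatory
    self-weight w_self. Above the w_self = 1 bifurcation a transient drive
    flips the driven unit to a sustained high state (rate pinned at the
    saturation level 1); below it the activity decays back to zero."""

    w_self: float = 1.5
    p_rate: float = 0.0
    a_rate: float = 0.0

    def reset(self) -> None:
        self.p_rate = 0.0
        self.a_rate = 0.0


def _saturating_relu(u: np.ndarray) -> np.ndarray:
    return np.clip(u, 0.0, 1.0)


def sustain_cue(neurons: CueNeurons, drive_p: float, drive_a: float,
                params: RateUnitParams | None = None) -> CueNeurons:
    """One Euler step of both cue neurons under external drives."""
    tau = params.tau if params else DEFAULT_TAU
    dt = params.dt if params else DEFAULT_DT
    fp = _saturating_relu(neurons.w_self * neurons.p_rate + drive_p)
    fa = _saturating_relu(neurons.w_self * neurons.a_rate + drive_a)
    neurons.p_rate += (dt / tau) * (-neurons.p_rate + float(fp))
    neurons.a_rate += (dt / tau) * (-neurons.a_rate + float(fa))
    return neurons


def sustain_cue_batch(p: np.ndarray, a: np.ndarray, drive_p: np.ndarray,
                      drive_a: np.ndarray, w_self: float,
                      tau: float = DEFAULT_TAU, dt: float = DEFAULT_DT):
    p = p + (dt / tau) * (-p + _saturating_relu(w_self * p + drive_p))
    a = a + (dt / tau) * (-a + _saturating_relu(w_self * a + drive_a))
    return p, a
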