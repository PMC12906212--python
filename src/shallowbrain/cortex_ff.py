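"""Convolutional feedforward cortical pathway.

A small CNN — two 4x4 convolutions each followed by 3x3 max pooling, a
16-unit dense layer, and 4 output units over the classes (L, R, P, A) —
classifies every screen: cue screens as pro (P) or anti (A), stimulus
screens by the brighter side (L or R). The cue classification is latched
in an explicit working-memory slot during the cue phase; during the
stimulus phase a hard-wired XOR gate combines the remembered rule with the
brighter-side class to produce the context-correct cortical choice drive
(C_L or C_R): PRO keeps the brighter side, ANTI flips it.

Trained by full-batch backpropagation (Adam) with class-weighted
cross-entropy on the 121-pair training grid (the 110 side-labelled
stimulus screens plus the two cue screens).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from .task import (CueType, Side, StimulusFrame, TrialSet, make_training_set,
                   render_cue, render_stimulus)

CLASSES = ("L", "R", "P", "A")  # fixed class order
IDX_L, IDX_R, IDX_P, IDX_A = range(4)

_CONV1_CHANNELS = 8
_CONV2_CHANNELS = 16
_POOL = 3  # 3x3, stride 3, ceil mode
_HIDDEN = 16


@dataclass
class TrainSettings:
    lr: float = 3e-3
    max_epochs: int = 2000
    min_epochs: int = 1500  # the margin keeps widening well past criterion
    target_accuracy: float = 0.99
    # small L2 penalty drives the rule (P/A) boundary toward the max-margin
    # separator of the two cue screens, which is what makes cue
    # classification survive pixel noise at test time
    weight_decay: float = 1e-3


@dataclass
class FFCortexWeights:
    params: dict[str, np.ndarray]
    history: pd.DataFrame | None = None

    def save(self, path) -> None:
        np.savez(path, **self.params,
                 _manifest=np.array([f"{k}:{v.shape}" for k, v in self.params.items()]),
                 _classes=np.array(CLASSES))

    @classmethod
    def load(cls, path) -> "FFCortexWeights":
        with np.load(path, allow_pickle=False) as z:
            params = {k: z[k] for k in z.files if not k.startswith("_")}
        return cls(params=params)


class EmptyCueMemoryError(RuntimeError):
    pass


@dataclass
class CueMemory:
    """Explicit working-memory latch for the cue classification."""

    stored_cue: CueType | None = None

    def write(self, cue: CueType) -> None:
        self.stored_cue = cue

    def read(self) -> CueType:
        if self.stored_cue is None:
            raise EmptyCueMemoryError("cue memory read before any cue was stored")
        return self.stored_cue

    def clear(self) -> None:
        self.stored_cue = None


def _init_params(rng: np.random.Generator) -> dict[str, np.ndarray]:
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    p = {
        "w1": he((4, 4, 1, _CONV1_CHANNELS), 16),
        "b1": np.zeros(_CONV1_CHANNELS),
        "w2": he((4, 4, _CONV1_CHANNELS, _CONV2_CHANNELS), 16 * _CONV1_CHANNELS),
        "b2": np.zeros(_CONV2_CHANNELS),
    }
    # trace shapes: 16x32 -> conv 13x29 -> pool 5x10 -> conv 2x7 -> pool 1x3
    flat = 1 * 3 * _CONV2_CHANNELS
    p["w3"] = he((flat, _HIDDEN), flat)
    p["b3"] = np.zeros(_HIDDEN)
    p["w4"] = he((_HIDDEN, 4), _HIDDEN)
    p["b4"] = np.zeros(4)
    return p


def _forward(params: dict[str, np.ndarray], x: np.ndarray, cache: bool = False):
    c1 = _nn.conv2d_forward(x, params["w1"], params["b1"])
    a1 = np.maximum(c1, 0.0)
    p1, idx1 = _nn.maxpool_forward(a1, _POOL, _POOL)
    c2 = _nn.conv2d_forward(p1, params["w2"], params["b2"])
    a2 = np.maximum(c2, 0.0)
    p2, idx2 = _nn.maxpool_forward(a2, _POOL, _POOL)
    flat = p2.reshape(x.shape[0], -1)
    h = np.maximum(flat @ params["w3"] + params["b3"], 0.0)
    logits = h @ params["w4"] + params["b4"]
    if not cache:
        return logits
    return logits, (x, c1, a1, p1, idx1, c2, a2, p2, idx2, flat, h)


def _backward(params, grad_logits, cache):
    x, c1, a1, p1, idx1, c2, a2, p2, idx2, flat, h = cache
    g = {}
    g["w4"] = h.T @ grad_logits
    g["b4"] = grad_logits.sum(axis=0)
    dh = grad_logits @ params["w4"].T
    dh *= h > 0
    g["w3"] = flat.T @ dh
    g["b3"] = dh.sum(axis=0)
    dflat = dh @ params["w3"].T
    dp2 = dflat.reshape(p2.shape)
    da2 = _nn.maxpool_backward(a2, p2, idx2, dp2)
    dc2 = da2 * (c2 > 0)
    dp1, g["w2"], g["b2"] = _nn.conv2d_backward(p1, params["w2"], dc2)
    da1 = _nn.maxpool_backward(a1, p1, idx1, dp1)
    dc1 = da1 * (c1 > 0)
    _, g["w1"], g["b1"] = _nn.conv2d_backward(x, params["w1"], dc1)
    return g


def training_frames(train: TrialSet | None = None):
    """Labelled screens for classifier training: the two cue screens plus
    every side-labelled (non-diagonal) stimulus screen."""
    train = train or make_training_set()
    frames = [render_cue(CueType.PRO).grid, render_cue(CueType.ANTI).grid]
    labels = [IDX_P, IDX_A]
    for p in train.pairs:
        if p.brighter is Side.UNDEFINED:
            continue
        frames.append(render_stimulus(p).grid)
        labels.append(IDX_L if p.brighter is Side.LEFT else IDX_R)
    x = np.stack(frames)[..., None]
    y = np.array(labels)
    return x, y


class TrainingDidNotConvergeError(RuntimeError):
    pass


def train_ff_classifier(train: TrialSet | None = None,
                        hyper: TrainSettings | None = None,
                        seed: int = 0) -> FFCortexWeights:
    """Train the four-way screen classifier to criterion (>=99% noiseless
    training accuracy for every class); deterministic under ``seed``."""
    hyper = hyper or TrainSettings()
    x, y = training_frames(train)
    counts = np.bincount(y, minlength=4).astype(float)
    class_w = len(y) / (4.0 * counts)
    params = _init_params(np.random.default_rng(seed))
    opt = _nn.Adam(params, lr=hyper.lr)
    log = []
    for epoch in range(hyper.max_epochs):
        logits, cache = _forward(params, x, cache=True)
        loss, dlogits = _nn.weighted_cross_entropy(logits, y, class_w)
        acc = float((logits.argmax(axis=1) == y).mean())
        log.append((epoch, loss, acc))
        if acc >= hyper.target_accuracy and epoch >= hyper.min_epochs:
            break
        grads = _backward(params, dlogits, cache)
        if hyper.weight_decay:
            for key in grads:
                grads[key] = grads[key] + hyper.weight_decay * params[key]
        opt.step(grads)
    history = pd.DataFrame(log, columns=["epoch", "loss", "accuracy"])
    if history["accuracy"].iloc[-1] < hyper.target_accuracy:
        raise TrainingDidNotConvergeError(
            f"training accuracy {history['accuracy'].iloc[-1]:.3f} below "
            f"criterion {hyper.target_accuracy} after {hyper.max_epochs} epochs")
    return FFCortexWeights(params=params, history=history)


def classify_frame(weights: FFCortexWeights, frame: StimulusFrame) -> np.ndarray:
    """Class scores over (L, R, P, A) for one screen; argmax is the class."""
    return classify_batch(weights, frame.grid[None, ...])[0]


def classify_batch(weights: FFCortexWeights, grids: np.ndarray) -> np.ndarray:
    grids = np.asarray(grids, dtype=float)
    if grids.shape[1:] != (16, 32):
        raise ValueError(f"expected (n, 16, 32) grids, got {grids.shape}")
    return _forward(weights.params, grids[..., None])


# --- hard-wired XOR rule integration -------------------------------------
# Inputs are the binary pair activations (P, A, L, R); four hidden AND
# units detect each (rule, side) conjunction; the output layer routes
# (P,L) and (A,R) to C_L, (P,R) and (A,L) to C_R.
_XOR_W_HIDDEN = np.array([
    # P  A  L  R
    [1, 0, 1, 0],   # P & L
    [1, 0, 0, 1],   # P & R
    [0, 1, 1, 0],   # A & L
    [0, 1, 0, 1],   # A & R
], dtype=float)
_XOR_HIDDEN_BIAS = -1.5
_XOR_W_OUT = np.array([
    # PL PR AL AR
    [2, 0, 0, 2],   # C_L
    [0, 2, 2, 0],   # C_R
], dtype=float)


def xor_combine(cue_class: CueType, stim_class: Side, gain: float = 1.0) -> np.ndarray:
    """Hard-wired rule integration: returns the (C_L, C_R) drive.

    PRO keeps the brighter side, ANTI flips it; exactly one output is
    driven (at ``gain``), for any positive gain.
    """
    if stim_class not in (Side.LEFT, Side.RIGHT):
        raise ValueError("stimulus class must be LEFT or RIGHT")
    inp = np.array([cue_class is CueType.PRO, cue_class is CueType.ANTI,
                    stim_class is Side.LEFT, stim_class is Side.RIGHT], dtype=float)
    hidden = np.maximum(_XOR_W_HIDDEN @ inp + _XOR_HIDDEN_BIAS, 0.0)
    return gain * (_XOR_W_OUT @ hidden)


def ff_cortical_drive(weights: FFCortexWeights, memory: CueMemory,
                      frame: StimulusFrame, gain: float = 1.0) -> np.ndarray:
    """Cortical (C_L, C_R) drive for one screen presentation.

    Cue screens write the memory latch and contribute no choice drive;
    stimulus screens are classified by side and combined with the
    remembered rule through the XOR gate.
    """
    scores = classify_frame(weights, frame)
    from .task import Phase

    if frame.phase is Phase.CUE:
        memory.write(CueType.PRO if scores[IDX_P] >= scores[IDX_A] else CueType.ANTI)
        return np.zeros(2)
    side = Side.LEFT if scores[IDX_L] >= scores[IDX_R] else Side.RIGHT
    return xor_combine(memory.read(), side, gain=gain)
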