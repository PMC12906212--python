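"""Behavioral task: cue/stimulus screens, trial sets, and pixel noise.

The task is a cue-dependent brightness comparison. Each trial starts with a
cue bar on a 16x32 screen — a horizontal 2x1 bar instructs a prosaccade
(look at the brighter square), a vertical 1x2 bar an antisaccade (look at
the darker square). The cue screen is followed by a stimulus screen with
two 4x4 squares of brightness ``x_left`` and ``x_right`` in [0, 1], placed
symmetrically about the vertical midline. Trial difficulty is
``|x_left - x_right|``.

Training pairs live on the 0.1-interval brightness grid (11 x 11 = 121
ordered pairs, equal-brightness diagonal included but side-undefined); test
pairs are drawn from the ten-fold finer 0.01 grid, balanced so that exactly
half are brighter on the left.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCREEN_SHAPE = (16, 32)

# Fixed pixel geometry (rows, cols are half-open slices).  The squares sit
# symmetrically about the vertical midline; the cue bar sits between them so
# the subcortical receptive-field windows never see it.
LEFT_WINDOW = (slice(6, 10), slice(6, 10))
RIGHT_WINDOW = (slice(6, 10), slice(22, 26))
CUE_PRO_PIXELS = (slice(7, 8), slice(15, 17))   # horizontal 2x1
CUE_ANTI_PIXELS = (slice(7, 9), slice(15, 16))  # vertical 1x2


class CueType(enum.Enum):
    """Trial rule: saccade toward (PRO) or away from (ANTI) the brighter square."""

    PRO = "pro"
    ANTI = "anti"


class Side(enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    UNDEFINED = "undefined"


class Phase(enum.Enum):
    CUE = "cue"
    STIM = "stim"


@dataclass(frozen=True)
class BrightnessPair:
    x_left: float
    x_right: float

    def __post_init__(self) -> None:
        for v in (self.x_left, self.x_right):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"brightness {v!r} outside [0, 1]")

    @property
    def difficulty(self) -> float:
        return abs(self.x_left - self.x_right)

    @property
    def brighter(self) -> Side:
        if self.x_left > self.x_right:
            return Side.LEFT
        if self.x_right > self.x_left:
            return Side.RIGHT
        return Side.UNDEFINED


def correct_side(cue: CueType, pair: BrightnessPair) -> Side:
    """Context-correct saccade side: toward the brighter square under PRO,
    away from it under ANTI; undefined for equal brightness."""
    b = pair.brighter
    if b is Side.UNDEFINED:
        return Side.UNDEFINED
    if cue is CueType.PRO:
        return b
    return Side.RIGHT if b is Side.LEFT else Side.LEFT


@dataclass(frozen=True)
class TrialSpec:
    cue: CueType
    pair: BrightnessPair
    correct_side: Side
    difficulty: float

    @classmethod
    def make(cls, cue: CueType, pair: BrightnessPair) -> "TrialSpec":
        return cls(cue=cue, pair=pair, correct_side=correct_side(cue, pair),
                   difficulty=pair.difficulty)


@dataclass
class StimulusFrame:
    grid: np.ndarray
    phase: Phase

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != SCREEN_SHAPE:
            raise ValueError(f"frame shape {self.grid.shape} != {SCREEN_SHAPE}")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.grid, delimiter=",", fmt="%.6g")


@dataclass
class TrialSet:
    """An ordered collection of brightness pairs plus per-cue trial expansion."""

    pairs: list[BrightnessPair]
    grid_interval: float
    balanced: bool = False

    def __len__(self) -> int:
        return len(self.pairs)

    def trials(self, cue: CueType) -> list[TrialSpec]:
        return [TrialSpec.make(cue, p) for p in self.pairs]

    def all_trials(self) -> list[TrialSpec]:
        """Both cue conditions over every pair (PRO block then ANTI block)."""
        return self.trials(CueType.PRO) + self.trials(CueType.ANTI)

    def side_counts(self) -> tuple[int, int, int]:
        """(left-brighter, right-brighter, equal) pair counts."""
        left = sum(p.brighter is Side.LEFT for p in self.pairs)
        right = sum(p.brighter is Side.RIGHT for p in self.pairs)
        return left, right, len(self.pairs) - left - right

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.all_trials()):
            rows.append(dict(trial_id=i, cue=t.cue.value,
                             x_left=t.pair.x_left, x_right=t.pair.x_right,
                             correct_side=t.correct_side.value,
                             difficulty=t.difficulty))
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def render_cue(cue: CueType) -> StimulusFrame:
    """Noiseless cue screen: a unit-intensity 2-pixel bar, horizontal for
    PRO, vertical for ANTI, centered between the stimulus windows."""
    grid = np.zeros(SCREEN_SHAPE)
    sl = CUE_PRO_PIXELS if cue is CueType.PRO else CUE_ANTI_PIXELS
    grid[sl] = 1.0
    return StimulusFrame(grid, Phase.CUE)


def render_stimulus(pair: BrightnessPair) -> StimulusFrame:
    """Noiseless stimulus screen: two 4x4 squares at the fixed left/right
    windows filled with the pair's brightness values."""
    grid = np.zeros(SCREEN_SHAPE)
    grid[LEFT_WINDOW] = pair.x_left
    grid[RIGHT_WINDOW] = pair.x_right
    return StimulusFrame(grid, Phase.STIM)


def _grid_values(denom: int) -> list[float]:
    # exact rationals i/denom, converted once, to avoid accumulation drift
    return [float(Fraction(i, denom)) for i in range(denom + 1)]


def make_training_set() -> TrialSet:
    """All 121 ordered brightness pairs on the 0.1-interval grid.

    Equal-brightness diagonal pairs are present (the enumeration is
    exhaustive) but carry UNDEFINED side labels and are excluded from
    side-classification losses and accuracies.
    """
    vals = _grid_values(10)
    pairs = [BrightnessPair(a, b) for a in vals for b in vals]
    return TrialSet(pairs=pairs, grid_interval=0.1, balanced=True)


def make_test_set(n: int, seed: int) -> TrialSet:
    """``n`` pairs sampled without replacement from the 0.01-interval grid,
    excluding equal-brightness pairs, exactly n/2 brighter on each side."""
    if n % 2 != 0:
        raise ValueError("n must be even for a balanced test set")
    vals = np.array(_grid_values(100))
    idx_l, idx_r = np.meshgrid(np.arange(101), np.arange(101), indexing="ij")
    mask = idx_l != idx_r
    cand = np.stack([vals[idx_l[mask]], vals[idx_r[mask]]], axis=1)
    left_cand = cand[cand[:, 0] > cand[:, 1]]
    right_cand = cand[cand[:, 0] < cand[:, 1]]
    if n // 2 > len(left_cand):
        raise ValueError(f"n={n} exceeds the {2 * len(left_cand)} available pairs")
    rng = np.random.default_rng(seed)
    chosen = np.concatenate([
        left_cand[rng.choice(len(left_cand), size=n // 2, replace=False)],
        right_cand[rng.choice(len(right_cand), size=n // 2, replace=False)],
    ])
    rng.shuffle(chosen, axis=0)
    pairs = [BrightnessPair(a, b) for a, b in chosen]
    return TrialSet(pairs=pairs, grid_interval=0.01, balanced=True)


def add_noise(frame: StimulusFrame, sigma: float,
              rng: np.random.Generator) -> StimulusFrame:
    """Additive i.i.d. Gaussian pixel noise, N(0, sigma); sigma=0 is a no-op.

    Noised intensities are intentionally not clipped back to [0, 1].
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return StimulusFrame(frame.grid.copy(), frame.phase)
    return StimulusFrame(frame.grid + rng.normal(0.0, sigma, size=frame.grid.shape),
                         frame.phase)
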