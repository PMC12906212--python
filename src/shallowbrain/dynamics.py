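"""Firing-rate dynamics: leaky rate units integrated with the Euler method.

Every unit in the network obeys the same first-order rate equation

    tau * dr_i/dt = -r_i + f_i(b_i + sum_j w_ij r_j)

integrated with a fixed Euler step (default dt = 10 ms, tau = 100 ms).
Decision and motor units compete in pairs: their activation is the
exponentiated log-softmax (i.e. a softmax) over the pair, so their steady
rates lie in (0, 1) and sum to 1, which makes the fixed 0.55 decision
threshold attainable. All other units are rectified-linear.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

DEFAULT_TAU = 0.1   # s, membrane time constant
DEFAULT_DT = 0.01   # s, Euler step


class Activation(enum.Enum):
    RELU = "relu"
    NORMALIZED_DECISION = "normalized_decision"  # softmax within the group
    IDENTITY = "identity"


def apply_activation(kind: Activation, preactivation: np.ndarray) -> np.ndarray:
    """Apply a unit activation along the last axis of ``preactivation``."""
    u = np.asarray(preactivation, dtype=float)
    if u.size == 0:
        raise ValueError("empty preactivation vector")
    if kind is Activation.RELU:
        return np.maximum(u, 0.0)
    if kind is Activation.IDENTITY:
        return u
    if kind is Activation.NORMALIZED_DECISION:
        # exp(log_softmax(u)) == softmax(u), computed stably
        shifted = u - u.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class RateUnitParams:
    tau: float = DEFAULT_TAU
    dt: float = DEFAULT_DT
    activation: Activation = Activation.RELU

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.dt > self.tau:
            raise ValueError("dt must not exceed tau (Euler stability)")


@dataclass
class RateState:
    rates: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)

    def copy(self) -> "RateState":
        return RateState(self.rates.copy(), self.time)


@dataclass
class DriveSpec:
    """Synaptic drive b + W @ r_pre for one population."""

    bias: np.ndarray
    weights: np.ndarray | None = None
    presynaptic: np.ndarray | None = None

    def preactivation(self) -> np.ndarray:
        u = np.asarray(self.bias, dtype=float)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            r = np.asarray(self.presynaptic, dtype=float)
            if w.shape[-1] != r.shape[-1]:
                raise ValueError(
                    f"weight shape {w.shape} incompatible with presynaptic "
                    f"rates of length {r.shape[-1]}")
            u = u + r @ w.T
        return u


def euler_step(state: RateState, drive: DriveSpec | np.ndarray,
               params: RateUnitParams) -> RateState:
    """One Euler update r <- r + (dt/tau) * (-r + f(b + W r_pre)).

    The input state is left unmodified; ``drive`` may be a DriveSpec or a
    precomputed preactivation vector.
    """
    u = drive.preactivation() if isinstance(drive, DriveSpec) else np.asarray(drive, dtype=float)
    if u.shape != state.rates.shape:
        raise ValueError(f"drive shape {u.shape} != state shape {state.rates.shape}")
    if not np.all(np.isfinite(u)):
        raise FloatingPointError("non-finite drive")
    f = apply_activation(params.activation, u)
    rates = state.rates + (params.dt / params.tau) * (-state.rates + f)
    return RateState(rates, state.time + params.dt)


def simulate(populations: Sequence[tuple[str, RateState, Callable[[dict], np.ndarray], RateUnitParams]],
             duration: float) -> dict[str, np.ndarray]:
    """Synchronously advance a set of named populations.

    ``populations`` entries are (name, initial state, drive function,
    params); each drive function receives a dict of the *previous* step's
    rates keyed by population name, so all updates at step k read rates
    from step k. Returns the recorded trajectory per population with shape
    (n_steps, n_units).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    states = {name: st.copy() for name, st, _, _ in populations}
    dt = populations[0][3].dt
    n_steps = int(round(duration / dt))
    traj: dict[str, list[np.ndarray]] = {name: [] for name, *_ in populations}
    for _ in range(n_steps):
        snapshot = {name: st.rates for name, st in states.items()}
        for name, _, drive_fn, params in populations:
            u = drive_fn(snapshot)
            states[name] = euler_step(states[name], u, params)
        for name, st in states.items():
            traj[name].append(st.rates.copy())
    return {name: np.array(rs) for name, rs in traj.items()}


def trajectories_to_frame(traj: dict[str, np.ndarray], dt: float = DEFAULT_DT):
    """Tidy (time, population, unit, rate) table for small runs."""
    import pandas as pd

    rows = []
    for name, arr in traj.items():
        for k in range(arr.shape[0]):
            for u in range(arr.shape[1]):
                rows.append((round((k + 1) * dt, 10), name, u, arr[k, u]))
    return pd.DataFrame(rows, columns=["time", "population", "unit", "rate"])
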