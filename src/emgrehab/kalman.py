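"""Streaming scalar Kalman filter for sEMG envelope estimation.

The envelope is modeled as locally constant: the state-transition and
observation maps are both identity scalars, so per channel and per sample

    prediction:  X_p = X_prev,            P_p = P_prev + Q
    gain:        KG  = P_p / (P_p + R)
    update:      X   = X_p + KG (Y - X_p),  P = (1 - KG) P_p

with process-noise variance ``Q`` and measurement-noise variance ``R``
fixed for all subjects and channels (defaults Q = 1e-4, R = 0.59948).
Because the covariance recursion does not depend on the data, the gain
sequence converges to a closed-form steady state and the filter becomes
an exponential smoother with gain ``KG*`` — both exposed here for delay
and attenuation analysis.

The exoskeleton control signal is the per-sample mean of the eight
filtered extensor channels; see :func:`control_signal`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synth_emg import EmgTrace

__all__ = [
    "FilterParams",
    "FilterState",
    "StepOutput",
    "KalmanBank",
    "kalman_step",
    "kalman_run",
    "filter_trace",
    "control_signal",
    "steady_state_gain",
    "steady_state_prediction_variance",
]

DEFAULT_Q = 0.0001
DEFAULT_R = 0.59948


@dataclass(frozen=True)
class FilterParams:
    """Filter constants.

    ``X0``/``P0`` default to None, meaning "seed from the data": the first
    measurement and R respectively.  This avoids a start-up transient from
    zero and keeps initialization scale-free.
    """

    Q: float = DEFAULT_Q
    R: float = DEFAULT_R
    X0: float | None = None
    P0: float | None = None

    def __post_init__(self) -> None:
        if self.Q < 0 or self.R < 0:
            raise ValueError("Q and R must be nonnegative")
        if self.P0 is not None and self.P0 < 0:
            raise ValueError("P0 must be nonnegative")
        if self.Q == 0 and self.R == 0 and (self.P0 == 0):
            raise ValueError("Q and R cannot both be 0 when P0 is 0")


@dataclass(frozen=True)
class FilterState:
    """Recursive state carried between samples: (X_{k-1}, P_{k-1})."""

    X_prev: float
    P_prev: float

    def __post_init__(self) -> None:
        if self.P_prev < 0:
            raise ValueError("P_prev must be nonnegative")


@dataclass(frozen=True)
class StepOutput:
    """One filter step: estimate X_k, error P_k, gain KG in [0, 1]."""

    X: float
    P: float
    KG: float


def kalman_step(
    state: FilterState, y: float, params: FilterParams
) -> tuple[FilterState, StepOutput]:
    """Advance the filter by one measurement.

    The degenerate case P_p = R = 0 defines KG = 1 (pass-through), removing
    a 0/0 that is unreachable under validated parameters.
    """
    if not math.isfinite(y):
        raise ValueError(f"measurement must be finite, got {y}")
    X_p = state.X_prev
    P_p = state.P_prev + params.Q
    denom = P_p + params.R
    KG = 1.0 if denom == 0.0 else P_p / denom
    X = X_p + KG * (y - X_p)
    P = (1.0 - KG) * P_p
    return FilterState(X_prev=X, P_prev=P), StepOutput(X=X, P=P, KG=KG)


def _initial_state(first: float, params: FilterParams) -> FilterState:
    X0 = first if params.X0 is None else params.X0
    P0 = params.R if params.P0 is None else params.P0
    return FilterState(X_prev=float(X0), P_prev=float(P0))


def kalman_run(series, params: FilterParams = FilterParams()) -> np.ndarray:
    """Filter a whole 1-D series; element k is the estimate X_k."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(y)):
        raise ValueError("series contains non-finite values")
    state = _initial_state(y[0], params)
    out = np.empty_like(y)
    for k in range(y.size):
        state, step = kalman_step(state, y[k], params)
        out[k] = step.X
    return out


class KalmanBank:
    """One filter per channel, stepped together for streaming use.

    The covariance recursion is shared (it is data-independent), so a single
    scalar (P, KG) drives all channels while X is a vector.
    """

    def __init__(self, n_channels: int, params: FilterParams = FilterParams()):
        if n_channels < 1:
            raise ValueError("need at least one channel")
        self.params = params
        self.n_channels = n_channels
        self._X: np.ndarray | None = None
        self._P: float | None = None

    def step(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} channel values")
        if self._X is None:
            self._X = y.copy() if self.params.X0 is None else np.full(y.shape, self.params.X0)
            self._P = self.params.R if self.params.P0 is None else self.params.P0
        P_p = self._P + self.params.Q
        denom = P_p + self.params.R
        KG = 1.0 if denom == 0.0 else P_p / denom
        self._X = self._X + KG * (y - self._X)
        self._P = (1.0 - KG) * P_p
        return self._X.copy()


def filter_trace(trace: EmgTrace, params: FilterParams = FilterParams()) -> EmgTrace:
    """Filter every channel of a raw trace independently."""
    bank = KalmanBank(trace.n_channels, params)
    out = np.empty_like(trace.samples)
    for k in range(trace.n_samples):
        out[k] = bank.step(trace.samples[k])
    # The smoother can undershoot 0 only if fed negative values, which the
    # trace invariant forbids; clamp defensively for float round-off.
    return EmgTrace(fs=trace.fs, samples=np.maximum(out, 0.0), kind="filtered")


def control_signal(filtered: EmgTrace) -> np.ndarray:
    """Mean over the filtered extensor channels, one value per sample."""
    if filtered.kind != "filtered":
        raise ValueError("control signal requires a filtered trace; filter first")
    if filtered.n_channels < 1:
        raise ValueError("need at least one channel")
    return filtered.samples.mean(axis=1)


def steady_state_prediction_variance(Q: float, R: float) -> float:
    """Unique nonnegative fixed point P_p* of the covariance recursion.

    P_p* solves P_p^2 - Q P_p - Q R = 0, i.e. (Q + sqrt(Q^2 + 4QR)) / 2.
    """
    if Q < 0 or R < 0:
        raise ValueError("Q and R must be nonnegative")
    if Q == 0 and R == 0:
        raise ValueError("Q and R cannot both be zero")
    return (Q + math.sqrt(Q * Q + 4.0 * Q * R)) / 2.0

def steady_state_gain(Q: float, R: float) -> float:
    """Steady-state Kalman gain KG* = P_p* / (P_p* + R) in [0, 1]."""
    P_p = steady_state_prediction_variance(Q, R)
    denom = P_p + R
    return 1.0 if denom == 0.0 else P_p / denom


def smoother_frequency_response(f_hz: float, fs: float, Q: float = DEFAULT_Q,
                                R: float = DEFAULT_R) -> float:
    """|H(f)| of the steady-state filter (an exponential smoother).

    H(z) = KG* / (1 - (1 - KG*) z^-1) evaluated on the unit circle; used to
    reason about envelope lag and noise attenuation above ~1 Hz.
    """
    a = steady_state_gain(Q, R)
    w = 2.0 * math.pi * f_hz / fs
    return abs(a / (1.0 - (1.0 - a) * complex(math.cos(w), -math.sin(w))))
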