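"""Per-subject MVE/Bias calibration: the EMG -> effort normalization.

Before training, the subject relaxes for 5 s and then performs a maximal
isometric knee extension for 5 s with the exoskeleton locked.  From the
8-channel-mean filtered envelope we extract:

* ``bias`` — mean envelope while relaxed (resting level),
* ``mve``  — the highest envelope level *sustained* for at least 1 s during
  the contraction, operationalized as the max over sliding windows of the
  within-window minimum,
* ``effort_cap`` — fraction of the Bias..MVE range used in training
  (default 0.6, a fatigue-avoidance cap).

A calibration whose voluntary range is not clearly above the resting noise
floor (mve - bias <= 3 x rest SD) is rejected — the safety-relevant case
where no usable voluntary signal exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CalibrationProtocol",
    "CalibrationResult",
    "InsufficientSignalRangeError",
    "estimate_bias",
    "estimate_mve",
    "calibrate",
]

DEFAULT_EFFORT_CAP = 0.6


class InsufficientSignalRangeError(ValueError):
    """Voluntary EMG range is absent or indistinguishable from rest noise."""


@dataclass(frozen=True)
class CalibrationProtocol:
    relax_duration: float = 5.0
    contract_duration: float = 5.0
    hold_duration: float = 1.0

    def __post_init__(self) -> None:
        if min(self.relax_duration, self.contract_duration, self.hold_duration) <= 0:
            raise ValueError("all protocol durations must be positive")
        if self.hold_duration > self.contract_duration:
            raise ValueError("hold_duration cannot exceed contract_duration")


@dataclass(frozen=True)
class CalibrationResult:
    bias: float
    mve: float
    effort_cap: float = DEFAULT_EFFORT_CAP

    def __post_init__(self) -> None:
        if not self.mve > self.bias:
            raise ValueError("mve must exceed bias")
        if not (0 < self.effort_cap <= 1):
            raise ValueError("effort_cap must be in (0, 1]")

    @property
    def signal_range(self) -> float:
        return self.mve - self.bias

    def to_dict(self) -> dict:
        return {"bias": self.bias, "mve": self.mve, "effort_cap": self.effort_cap}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(bias=d["bias"], mve=d["mve"], effort_cap=d.get("effort_cap", DEFAULT_EFFORT_CAP))


def _window_slice(window: tuple[float, float], fs: float, n: int) -> slice:
    start, end = window
    i0, i1 = round(start * fs), round(end * fs)
    if not (0 <= i0 < i1 <= n):
        raise ValueError(f"window {window} outside signal of {n / fs:.3f} s")
    return slice(i0, i1)


def estimate_bias(envelope, relax_window: tuple[float, float], fs: float) -> float:
    """Resting level: mean of the envelope over the relax window (>= 1 s)."""
    x = np.asarray(envelope, dtype=float)
    if relax_window[1] - relax_window[0] < 1.0:
        raise ValueError("relax window must be at least 1 s long")
    return float(x[_window_slice(relax_window, fs, x.size)].mean())


def estimate_mve(
    envelope, contract_window: tuple[float, float], fs: float, hold: float = 1.0
) -> float:
    """Highest envelope level sustained for ``hold`` seconds.

    Computed as max over all length-``hold`` sub-windows of the within-window
    minimum.  Limits: hold -> window length gives the global window minimum;
    hold -> one sample gives the global maximum.
    """
    x = np.asarray(envelope, dtype=float)
    seg = x[_window_slice(contract_window, fs, x.size)]
    w = max(1, round(hold * fs))
    if w > seg.size:
        raise ValueError("contract window shorter than the hold duration")
    return float(sliding_window_view(seg, w).min(axis=1).max())


def calibrate(
    envelope,
    fs: float,
    protocol: CalibrationProtocol = CalibrationProtocol(),
    effort_cap: float = DEFAULT_EFFORT_CAP,
) -> CalibrationResult:
    """Run the relax-then-contract protocol on a filtered envelope."""
    x = np.asarray(envelope, dtype=float)
    needed = protocol.relax_duration + protocol.contract_duration
    if x.size < round(needed * fs):
        raise ValueError(f"envelope shorter than the {needed:.0f} s protocol")
    relax = (0.0, protocol.relax_duration)
    contract = (protocol.relax_duration, needed)
    bias = estimate_bias(x, relax, fs)
    rest_sd = float(x[_window_slice(relax, fs, x.size)].std())
    mve = estimate_mve(x, contract, fs, hold=protocol.hold_duration)
    if mve - bias <= 0 or (mve - bias) < 3.0 * rest_sd:
        raise InsufficientSignalRangeError(
            f"insufficient signal range: mve - bias = {mve - bias:.4g}, "
            f"rest sd = {rest_sd:.4g}"
        )
    return CalibrationResult(bias=bias, mve=mve, effort_cap=effort_cap)
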