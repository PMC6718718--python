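"""Evaluation metrics: muscle activation, therapy dose, tracking and delay.

* MAL/mMAL — muscle activation level, the envelope normalized to [0, 1]
  between the calibrated Bias and MVE, and its mean over a block's active
  time steps.
* Block activation time (BAT) — cumulative time actually spent flying in a
  block: the active-therapy dose.  Hover pauses and rests are excluded.
* Tracking — RMSE between desired and actual joint angle, and the
  cross-correlation time lag between any two signals (filter delay,
  exoskeleton lag).
* Spectral attenuation — band power ratio of filtered vs raw EMG above a
  cutoff, for verifying that the Kalman filter suppresses noise above ~1 Hz.
* One-way ANOVA — classical fixed-effects F test used on per-block metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .calibration import CalibrationResult
from .game import GameEvent

__all__ = [
    "BlockMetrics",
    "mal",
    "mmal",
    "block_activation_time",
    "rmse",
    "xcorr_lag",
    "spectral_attenuation",
    "one_way_anova",
]


@dataclass(frozen=True)
class BlockMetrics:
    """Per-block summary: game score, mMAL, BAT and the raw MAL trace."""

    score: int
    mmal: float
    bat: float
    mal_trace: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 <= self.mmal <= 1.0):
            raise ValueError("mmal must lie in [0, 1]")
        if self.bat < 0:
            raise ValueError("bat must be nonnegative")

    def to_dict(self) -> dict:
        return {"score": self.score, "mmal": self.mmal, "bat_s": self.bat}


def mal(emg_value, calib: CalibrationResult):
    """Muscle activation level: clamp((EMG - Bias) / (MVE - Bias), 0, 1)."""
    frac = (np.asarray(emg_value, dtype=float) - calib.bias) / calib.signal_range
    return np.clip(frac, 0.0, 1.0)


def mmal(mal_trace) -> float:
    """Mean MAL over a block's T active time steps."""
    x = np.asarray(mal_trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty MAL trace")
    return float(x.mean())


def block_activation_time(events: list[GameEvent]) -> float:
    """Active (flying) time from an event log.

    Each flight segment opens with a ``life_start`` and closes with the next
    ``collision`` or ``block_over``.  A log that opens a flight and never
    closes it, or closes one that never opened, is malformed.
    """
    total = 0.0
    start = None
    for ev in events:
        if ev.kind == "life_start":
            if start is not None:
                raise ValueError("malformed log: life_start inside an open flight")
            start = ev.time
        elif ev.kind in ("collision", "block_over"):
            if ev.kind == "collision":
                if start is None:
                    raise ValueError("malformed log: collision outside a flight")
                total += ev.time - start
                start = None
            elif start is not None:
                total += ev.time - start
                start = None
    if start is not None:
        raise ValueError("malformed log: flight never closed")
    return total


def rmse(desired, actual) -> float:
    """Root mean square error between desired and actual joint angles."""
    d = np.asarray(desired, dtype=float)
    a = np.asarray(actual, dtype=float)
    if d.shape != a.shape or d.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    return float(np.sqrt(np.mean((d - a) ** 2)))


def xcorr_lag(reference, delayed, fs: float) -> float:
    """Time lag (ms) of ``delayed`` behind ``reference``.

    Lag maximizing the normalized cross-correlation of the mean-removed
    series, searched within +/- half the window; positive means the second
    series lags the first.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(delayed, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("series must be equal-length 1-D with >= 2 samples")
    a = a - a.mean()
    b = b - b.mean()
    if not a.any() or not b.any():
        raise ValueError("cross-correlation undefined for constant input")
    c = sps.correlate(b, a, mode="full")
    lags = sps.correlation_lags(b.size, a.size, mode="full")
    keep = np.abs(lags) <= a.size // 2
    best = lags[keep][np.argmax(c[keep])]
    return float(best) / fs * 1000.0


def spectral_attenuation(raw, filtered, fs: float, f_cut: float = 1.0) -> float:
    """dB power ratio (filtered / raw) above ``f_cut`` via the periodogram.

    Negative values mean the filter attenuated that band.  A filtered signal
    with zero band power returns -inf as a sentinel.
    """
    x = np.asarray(raw, dtype=float)
    y = np.asarray(filtered, dtype=float)
    if x.shape != y.shape or x.size < 2 * fs:
        raise ValueError("need equal-length series of at least 2 s")
    if f_cut >= fs / 2:
        raise ValueError("f_cut must lie below the Nyquist frequency")
    f, p_raw = sps.periodogram(x, fs=fs)
    _, p_fil = sps.periodogram(y, fs=fs)
    band = f > f_cut
    num = p_fil[band].sum()
    den = p_raw[band].sum()
    if den == 0:
        raise ValueError("raw signal has no power above the cutoff")
    if num == 0:
        return float("-inf")
    return float(10.0 * np.log10(num / den))


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: (F, upper-tail p).

    F = MS_between / MS_within with (k - 1, N - k) degrees of freedom.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_between = len(gs) - 1
    df_within = n_total - len(gs)
    if ss_within == 0 and ss_between == 0:
        raise ValueError("degenerate data: no variance between or within groups")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        return float("inf"), 0.0
    f_stat = ms_between / ms_within
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p
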