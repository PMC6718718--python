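"""Synthetic surface-EMG generation with known ground-truth activation.

The consumer-grade thigh band emulated here streams 8 channels of "raw"
sEMG at 200 Hz that has already been rectified and low-pass filtered on
the device, yet is still visibly noisy.  This module produces such traces
from a deterministic activation profile ``a(t)`` in [0, 1]: per channel,

    sample(t) = max(0, bias + gain * a(t) + eps),   eps ~ N(0, noise_sd^2)

so noiseless synthesis is exactly affine in activation and every sample is
nonnegative (the rectification clamp).  Each channel draws from its own
seeded generator, which makes every downstream stage reproducible without
hardware or human recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "ActivationProfile",
    "ChannelModel",
    "EmgTrace",
    "EmgSynthesizer",
    "default_channels",
    "make_activation",
    "mve_test_pattern",
    "synthesize_raw_emg",
]

#: Default signal-model preset: resting level, amplitude at full activation
#: and additive noise, all in arbitrary device units.  Chosen so raw traces
#: look realistically noisy while calibration remains recoverable.
DEFAULT_BIAS = 1.0
DEFAULT_GAIN = 4.0
DEFAULT_NOISE_SD = 0.5
DEFAULT_FS = 200.0
DEFAULT_N_CHANNELS = 8


@dataclass(frozen=True)
class ActivationProfile:
    """Ground-truth muscle activation ``a(t)`` in [0, 1] at a fixed rate."""

    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("activation values must be one-dimensional")
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("activation values must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ChannelModel:
    """Affine-plus-noise model of one electrode channel."""

    bias: float = DEFAULT_BIAS
    gain: float = DEFAULT_GAIN
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias < 0 or self.gain < 0 or self.noise_sd < 0:
            raise ValueError("bias, gain and noise_sd must be nonnegative")


@dataclass(frozen=True)
class EmgTrace:
    """A rectangular multi-channel EMG time series.

    ``samples`` is time x channel; ``kind`` distinguishes the noisy device
    output ("raw") from Kalman-filtered envelopes ("filtered").
    """

    fs: float
    samples: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.kind not in ("raw", "filtered"):
            raise ValueError(f"kind must be 'raw' or 'filtered', got {self.kind!r}")
        samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if samples.size and samples.min() < 0:
            raise ValueError("EMG samples must be nonnegative")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def to_csv(self, path) -> None:
        """Write as ``time_s,ch1..chN`` CSV (UTF-8, '.' decimal)."""
        df = pd.DataFrame(
            self.samples,
            columns=[f"ch{i + 1}" for i in range(self.n_channels)],
        )
        df.insert(0, "time_s", self.time)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "raw") -> "EmgTrace":
        df = pd.read_csv(path)
        if "time_s" not in df.columns or df.shape[0] < 2:
            raise ValueError("EMG CSV needs a time_s column and >= 2 rows")
        t = df["time_s"].to_numpy()
        fs = 1.0 / float(np.median(np.diff(t)))
        chans = [c for c in df.columns if c != "time_s"]
        return cls(fs=fs, samples=df[chans].to_numpy(), kind=kind)


def make_activation(
    schedule: list[tuple[float, float, float]],
    duration: float,
    fs: float = DEFAULT_FS,
    ramp: float = 0.0,
) -> ActivationProfile:
    """Build a piecewise-constant activation profile with linear ramps.

    ``schedule`` is a list of (start_s, end_s, level) segments; activation is
    0 outside segments and ramps linearly over ``ramp`` seconds at each
    segment's onset and offset (within the segment).
    """
    if ramp < 0:
        raise ValueError("ramp must be nonnegative")
    n = round(duration * fs)
    t = np.arange(n) / fs
    values = np.zeros(n)
    prev_end = None
    for start, end, level in sorted(schedule, key=lambda s: s[0]):
        if not (0 <= start < end <= duration):
            raise ValueError(f"segment ({start}, {end}) outside [0, {duration}]")
        if not (0 <= level <= 1):
            raise ValueError(f"activation level {level} outside [0, 1]")
        if prev_end is not None and start < prev_end:
            raise ValueError("overlapping activation segments")
        prev_end = end
        seg = (t >= start) & (t < end)
        values[seg] = level
        if ramp > 0:
            rise = seg & (t < start + ramp)
            values[rise] = level * (t[rise] - start) / ramp
            fall = seg & (t >= end - ramp)
            values[fall] = np.minimum(values[fall], level * (end - t[fall]) / ramp)
    return ActivationProfile(fs=fs, values=values)


def mve_test_pattern(fs: float = DEFAULT_FS) -> ActivationProfile:
    """Calibration pattern: 5 s of rest then 5 s of maximal isometric effort."""
    return make_activation([(5.0, 10.0, 1.0)], duration=10.0, fs=fs, ramp=0.0)


def default_channels(
    n_channels: int = DEFAULT_N_CHANNELS,
    seed: int = 0,
    bias: float = DEFAULT_BIAS,
    gain: float = DEFAULT_GAIN,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[ChannelModel]:
    """The default band: identical channel models, independent seeded streams."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n_channels)
    return [
        ChannelModel(bias=bias, gain=gain, noise_sd=noise_sd, seed=int(s))
        for s in child_seeds
    ]


def synthesize_raw_emg(
    activation: ActivationProfile, channels: list[ChannelModel]
) -> EmgTrace:
    """Render an activation profile into a raw multi-channel EMG trace."""
    if activation.n_samples == 0:
        raise ValueError("activation profile is empty")
    if not channels:
        raise ValueError("need at least one channel model")
    cols = []
    for ch in channels:
        rng = np.random.default_rng(ch.seed)
        noise = rng.normal(0.0, ch.noise_sd, activation.n_samples) if ch.noise_sd else 0.0
        cols.append(np.maximum(0.0, ch.bias + ch.gain * activation.values + noise))
    return EmgTrace(fs=activation.fs, samples=np.column_stack(cols), kind="raw")


class EmgSynthesizer:
    """Streaming counterpart of :func:`synthesize_raw_emg` for closed loops.

    Keeps one generator per channel so a sample-by-sample simulation produces
    the same statistics as batch synthesis.
    """

    def __init__(self, channels: list[ChannelModel]):
        if not channels:
            raise ValueError("need at least one channel model")
        self.channels = list(channels)
        self._rngs = [np.random.default_rng(ch.seed) for ch in channels]
        self._bias = np.array([ch.bias for ch in channels])
        self._gain = np.array([ch.gain for ch in channels])
        self._sd = np.array([ch.noise_sd for ch in channels])

    def sample(self, activation: float) -> np.ndarray:
        """One 1-x-n_channels raw sample at the given activation level."""
        a = min(max(float(activation), 0.0), 1.0)
        eps = np.array([rng.normal(0.0, sd) for rng, sd in zip(self._rngs, self._sd)])
        return np.maximum(0.0, self._bias + self._gain * a + eps)


def rescale_channels(channels: list[ChannelModel], **kwargs) -> list[ChannelModel]:
    """Return copies of the channel models with fields overridden."""
    return [replace(ch, **kwargs) for ch in channels]
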