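"""Signal containers and the three per-sample transforms of the detector.

The detector front-end turns the two boot-mounted vertical-acceleration
channels into a single quantised series in three steps:

1. :func:`fuse_boots` — per-sample mean of the absolute left/right values;
2. :func:`smooth` — centred rolling mean over a fixed number of samples,
   truncated at the series boundaries;
3. :func:`round_to_increment` — quantisation to the nearest multiple of a
   fixed increment (ties away from zero).

All accelerations are in m/s²; at that scale rounding to increments of
5 or 10 separates the grounded regime (magnitude near 9.81, rounds to 5
or 10) from free fall (magnitude near 0, rounds to 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, ParameterError

#: Standard gravity, used for the optional g -> m/s² input conversion.
G_MS2 = 9.80665

_STAGES = ("fused", "smoothed", "rounded")


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise FormatError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class BootPairSignal:
    """Two synchronised uniform-rate vertical-acceleration channels.

    Parameters
    ----------
    sample_rate_hz
        Sampling rate in Hz; samples are implicitly spaced ``1/sample_rate_hz``
        seconds apart.
    t0_s
        Time of the first sample, in seconds.
    left_acc_y, right_acc_y
        Vertical (boot-up axis) acceleration of the left and right boot in
        m/s².  May be signed; only magnitudes matter downstream.
    """

    sample_rate_hz: float
    t0_s: float
    left_acc_y: np.ndarray
    right_acc_y: np.ndarray

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ParameterError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        left = _as_float_array(self.left_acc_y, "left_acc_y")
        right = _as_float_array(self.right_acc_y, "right_acc_y")
        if left.size != right.size:
            raise FormatError(
                f"channel length mismatch: left has {left.size} samples, right has {right.size}"
            )
        if left.size == 0:
            raise FormatError("empty signal: channels must contain at least one sample")
        object.__setattr__(self, "left_acc_y", left)
        object.__setattr__(self, "right_acc_y", right)

    @property
    def n_samples(self) -> int:
        return int(self.left_acc_y.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


@dataclass(frozen=True)
class ProcessedSignal:
    """A single-channel non-negative series with its processing provenance.

    ``stage`` records how far through the pipeline the values are; the
    parameters that produced them (``window_samples``, ``increment``) travel
    with the data so downstream artefacts can report provenance.
    """

    sample_rate_hz: float
    t0_s: float
    values: np.ndarray
    stage: str
    window_samples: Optional[int] = None
    increment: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ParameterError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.stage not in _STAGES:
            raise ParameterError(f"unknown stage {self.stage!r}, expected one of {_STAGES}")
        values = _as_float_array(self.values, "values")
        if values.size == 0:
            raise FormatError("empty signal")
        if values.size and values.min() < 0:
            raise FormatError("processed values must be non-negative")
        object.__setattr__(self, "values", values)
        if self.stage in ("smoothed", "rounded"):
            if self.window_samples is None:
                raise ParameterError(f"stage={self.stage!r} requires window_samples")
            if int(self.window_samples) < 1:
                raise ParameterError(f"window_samples must be >= 1, got {self.window_samples}")
            object.__setattr__(self, "window_samples", int(self.window_samples))
        if self.stage == "rounded":
            if self.increment is None:
                raise ParameterError("stage='rounded' requires increment")
            if self.increment <= 0:
                raise ParameterError(f"increment must be > 0, got {self.increment}")
            multiples = np.round(values / self.increment)
            if not np.allclose(values, multiples * self.increment, rtol=0.0, atol=1e-9):
                raise FormatError("rounded values must be exact multiples of the increment")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz


def fuse_boots(pair: BootPairSignal) -> ProcessedSignal:
    """Per-sample mean of the absolute left and right accelerations.

    ``out[i] = (|left[i]| + |right[i]|) / 2``; sample rate and start time are
    carried through unchanged.
    """
    values = (np.abs(pair.left_acc_y) + np.abs(pair.right_acc_y)) / 2.0
    return ProcessedSignal(
        sample_rate_hz=pair.sample_rate_hz,
        t0_s=pair.t0_s,
        values=values,
        stage="fused",
    )


def smooth(sig: ProcessedSignal, window_samples: int) -> ProcessedSignal:
    """Centred rolling mean of nominal width ``window_samples``.

    Each output sample is the arithmetic mean of the input samples in a
    centred window, truncated at the series boundaries (edge windows average
    only the samples that exist).  Even window lengths place the extra sample
    on the trailing side.

    Notes
    -----
    The summation is performed per window offset in increasing index order,
    which makes the result bit-identical to a straight-line loop that adds
    ``values[lo:hi]`` left to right — convenient for exact oracle checks.
    """
    window_samples = int(window_samples)
    if window_samples < 1:
        raise ParameterError(f"window_samples must be >= 1, got {window_samples}")
    n = sig.n_samples
    if window_samples > n:
        raise ParameterError(
            f"window_samples={window_samples} exceeds signal length {n}"
        )
    values = sig.values
    half_lead = (window_samples - 1) // 2
    half_trail = window_samples // 2
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for off in range(-half_lead, half_trail + 1):
        lo = max(0, -off)
        hi = min(n, n - off)
        acc[lo:hi] += values[lo + off : hi + off]
        cnt[lo:hi] += 1.0
    return ProcessedSignal(
        sample_rate_hz=sig.sample_rate_hz,
        t0_s=sig.t0_s,
        values=acc / cnt,
        stage="smoothed",
        window_samples=window_samples,
    )


def round_to_increment(sig: ProcessedSignal, increment: float) -> ProcessedSignal:
    """Quantise each value to the nearest multiple of ``increment``.

    Exact halves round away from zero, so an ambiguous gravity-ward value is
    never zeroed into a spurious flight region (e.g. 2.5 at increment 5 maps
    to 5, not 0).
    """
    increment = float(increment)
    if increment <= 0:
        raise ParameterError(f"increment must be > 0, got {increment}")
    # values are non-negative by construction, so floor(v/inc + 0.5) is
    # round-half-away-from-zero
    values = np.floor(sig.values / increment + 0.5) * increment
    return ProcessedSignal(
        sample_rate_hz=sig.sample_rate_hz,
        t0_s=sig.t0_s,
        values=values,
        stage="rounded",
        window_samples=sig.window_samples,
        increment=increment,
    )


def g_to_ms2(pair: BootPairSignal) -> BootPairSignal:
    """Convert a pair recorded in g units to m/s² (multiply by 9.80665)."""
    return replace(
        pair,
        left_acc_y=pair.left_acc_y * G_MS2,
        right_acc_y=pair.right_acc_y * G_MS2,
    )
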