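"""Event extraction: zero regions of the quantised signal become jumps.

A jump is any maximal run of consecutive exactly-zero samples in the rounded
signal.  :func:`detect_jumps` is the one-call detector that chains the signal
transforms and converts index runs into timed events.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np

from .errors import ParameterError
from .signal import BootPairSignal, ProcessedSignal, fuse_boots, round_to_increment, smooth

#: Flight-time threshold (ms) separating small from medium jumps.
SMALL_MEDIUM_THRESHOLD_MS = 500.0

LABELS = ("detected", "small", "medium", "big_air", "unknown")


@dataclass(frozen=True)
class JumpEvent:
    """A detected or ground-truth jump interval.

    The interval is half-open: ``start_s`` is the time of the first zero
    sample and ``end_s`` is one sample period after the last zero sample.
    ``flight_ms`` equals ``(end_s - start_s) * 1000``.
    """

    start_s: float
    end_s: float
    flight_ms: float
    label: str = "detected"

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ParameterError(
                f"event must have end_s > start_s, got [{self.start_s}, {self.end_s})"
            )
        span_ms = (self.end_s - self.start_s) * 1000.0
        if not np.isclose(self.flight_ms, span_ms, rtol=1e-9, atol=1e-6):
            raise ParameterError(
                f"flight_ms={self.flight_ms} inconsistent with interval span {span_ms} ms"
            )
        if self.label not in LABELS:
            raise ParameterError(f"unknown label {self.label!r}, expected one of {LABELS}")

    @classmethod
    def from_interval(cls, start_s: float, end_s: float, label: str = "detected") -> "JumpEvent":
        return cls(start_s=start_s, end_s=end_s, flight_ms=(end_s - start_s) * 1000.0, label=label)


def find_zero_regions(sig: ProcessedSignal) -> List[Tuple[int, int]]:
    """Maximal runs of exactly-zero samples, as half-open index intervals.

    Runs touching the series boundary are included.  Returns an empty list
    when no sample is zero.
    """
    if sig.stage != "rounded":
        raise ParameterError(f"expected a rounded signal, got stage={sig.stage!r}")
    is_zero = sig.values == 0.0
    if not is_zero.any():
        return []
    padded = np.concatenate(([False], is_zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_jumps(
    pair: BootPairSignal,
    window_samples: int,
    increment: float,
    min_flight_ms: float = 0.0,
) -> List[JumpEvent]:
    """Run the full pipeline and return the jumps found in a run.

    Chains fuse -> smooth -> round -> zero-region extraction, converts index
    intervals to seconds via ``t0_s`` and the sample rate, and drops events
    shorter than ``min_flight_ms``.  All returned events carry the label
    ``"detected"``.
    """
    if min_flight_ms < 0:
        raise ParameterError(f"min_flight_ms must be >= 0, got {min_flight_ms}")
    rounded = round_to_increment(smooth(fuse_boots(pair), window_samples), increment)
    events = []
    for i0, i1 in find_zero_regions(rounded):
        start_s = pair.t0_s + i0 / pair.sample_rate_hz
        end_s = pair.t0_s + i1 / pair.sample_rate_hz
        event = JumpEvent.from_interval(start_s, end_s, label="detected")
        if event.flight_ms >= min_flight_ms:
            events.append(event)
    return events


def classify_flight(event: JumpEvent, big_air: bool = False) -> JumpEvent:
    """Relabel an event by flight time: < 500 ms is small, otherwise medium.

    ``big_air`` overrides the time rule — that class is assigned by context
    (one kicker jump per run), not by duration.
    """
    if big_air:
        return replace(event, label="big_air")
    label = "small" if event.flight_ms < SMALL_MEDIUM_THRESHOLD_MS else "medium"
    return replace(event, label=label)
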