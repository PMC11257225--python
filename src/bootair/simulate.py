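"""Seeded simulator for dual-boot vertical-acceleration runs.

The study's recordings are not public, so tests and benchmarks run on
synthetic twins with the same gross structure: a grounded baseline
oscillating around gravity magnitude with vibration noise on two correlated
channels, near-zero flight phases of scheduled duration, and short
high-magnitude takeoff/landing transients at the flight boundaries.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .detect import SMALL_MEDIUM_THRESHOLD_MS, JumpEvent
from .errors import ParameterError
from .signal import BootPairSignal

#: (start_s, flight_ms, label)
JumpSpec = Tuple[float, float, str]

# Flight-time ranges (ms) per class for benchmark suites.
FLIGHT_RANGES_MS = {
    "small": (200.0, 499.0),
    "medium": (500.0, 1200.0),
    "big_air": (1200.0, 2500.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated run.

    Accelerations are m/s².  ``jumps`` schedules the flight phases as
    ``(start_s, flight_ms, label)``; labels must respect the 500 ms
    small/medium rule.  ``interboot_corr`` is the weight of the noise
    component shared between the two boots.
    """

    duration_s: float
    jumps: Tuple[JumpSpec, ...] = ()
    sample_rate_hz: float = 54.0
    t0_s: float = 0.0
    baseline_mean_ms2: float = 9.81
    turn_amp_ms2: float = 2.0
    turn_freq_hz: float = 1.0
    vib_sigma_ms2: float = 1.2
    flight_sigma_ms2: float = 0.2
    impact_peak_ms2: float = 40.0
    takeoff_peak_ms2: float = 2.0
    impact_dur_ms: float = 60.0
    unweight_rate_hz: float = 0.08
    unweight_dur_ms: float = 450.0
    unweight_depth_ms2: float = 9.6
    interboot_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "jumps", tuple(tuple(j) for j in self.jumps))
        if self.duration_s <= 0:
            raise ParameterError(f"duration_s must be > 0, got {self.duration_s}")
        if self.sample_rate_hz <= 0:
            raise ParameterError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if not 0.0 <= self.interboot_corr <= 1.0:
            raise ParameterError(f"interboot_corr must be in [0, 1], got {self.interboot_corr}")
        for sigma_name in (
            "vib_sigma_ms2",
            "flight_sigma_ms2",
            "impact_peak_ms2",
            "takeoff_peak_ms2",
            "turn_amp_ms2",
        ):
            if getattr(self, sigma_name) < 0:
                raise ParameterError(f"{sigma_name} must be >= 0")
        if self.impact_dur_ms <= 0:
            raise ParameterError(f"impact_dur_ms must be > 0, got {self.impact_dur_ms}")
        if self.unweight_rate_hz < 0 or self.unweight_depth_ms2 < 0:
            raise ParameterError("unweight rate and depth must be >= 0")
        if self.unweight_dur_ms <= 0:
            raise ParameterError(f"unweight_dur_ms must be > 0, got {self.unweight_dur_ms}")

        prev_end = -np.inf
        for start_s, flight_ms, label in sorted(self.jumps):
            if flight_ms <= 0:
                raise ParameterError(f"flight_ms must be > 0, got {flight_ms}")
            end_s = start_s + flight_ms / 1000.0
            if start_s < 0 or end_s > self.duration_s:
                raise ParameterError(
                    f"jump [{start_s}, {end_s}) s extends outside the run [0, {self.duration_s}) s"
                )
            if start_s < prev_end:
                raise ParameterError(f"overlapping jumps near t={start_s} s")
            prev_end = end_s
            if label == "small" and flight_ms >= SMALL_MEDIUM_THRESHOLD_MS:
                raise ParameterError(f"'small' jump with flight_ms={flight_ms} >= 500")
            if label == "medium" and flight_ms < SMALL_MEDIUM_THRESHOLD_MS:
                raise ParameterError(f"'medium' jump with flight_ms={flight_ms} < 500")


def _impact_pulse(n_samples: int, peak: float) -> np.ndarray:
    """Half-cosine (raised at the centre) transient of ``n_samples`` samples."""
    u = (np.arange(n_samples) + 0.5) / n_samples
    return peak * np.sin(np.pi * u)


def simulate_run(cfg: SimConfig) -> Tuple[BootPairSignal, List[JumpEvent]]:
    """Generate one run and its ground-truth events.

    Outside flight windows each boot reads baseline + carving oscillation +
    correlated vibration noise; inside flight the magnitude is near-zero
    residual noise.  Half-cosine transients are added at the flight
    boundaries: a modest push of amplitude ``takeoff_peak_ms2`` ending at the
    first flight sample and a hard landing impact of amplitude
    ``impact_peak_ms2`` starting at the first grounded sample.  Ground truth
    carries the scheduled start times and flight durations verbatim.
    """
    rate = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * rate))
    if n < 1:
        raise ParameterError("run too short for a single sample")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n) / rate

    phase = rng.uniform(0.0, 2.0 * np.pi)
    carve = cfg.turn_amp_ms2 * np.sin(2.0 * np.pi * cfg.turn_freq_hz * t + phase)

    shared = rng.standard_normal(n)
    w_shared = np.sqrt(cfg.interboot_corr)
    w_indep = np.sqrt(1.0 - cfg.interboot_corr)
    channels = []
    for _ in range(2):
        indep = rng.standard_normal(n)
        noise = cfg.vib_sigma_ms2 * (w_shared * shared + w_indep * indep)
        channels.append(cfg.baseline_mean_ms2 + carve + noise)

    truth: List[JumpEvent] = []
    n_pulse = max(1, int(round(cfg.impact_dur_ms / 1000.0 * rate)))
    takeoff = _impact_pulse(n_pulse, cfg.takeoff_peak_ms2)
    landing = _impact_pulse(n_pulse, cfg.impact_peak_ms2)
    for start_s, flight_ms, label in sorted(cfg.jumps):
        i0 = int(round(start_s * rate))
        i1 = max(i0 + 1, int(round((start_s + flight_ms / 1000.0) * rate)))
        i0, i1 = min(i0, n - 1), min(i1, n)
        for ch in channels:
            # flight magnitude: near-zero residual, generated non-negative
            ch[i0:i1] = np.abs(rng.normal(0.0, cfg.flight_sigma_ms2, i1 - i0))
            # takeoff transient ends at the first flight sample
            lo = max(0, i0 - n_pulse)
            ch[lo:i0] += takeoff[n_pulse - (i0 - lo) :]
            # landing transient starts at the first grounded sample
            hi = min(n, i1 + n_pulse)
            ch[i1:hi] += landing[: hi - i1]
        truth.append(
            JumpEvent(
                start_s=cfg.t0_s + start_s,
                end_s=cfg.t0_s + start_s + flight_ms / 1000.0,
                flight_ms=flight_ms,
                label=label,
            )
        )

    # Brief unweighting dips between turns: deep enough to fool a short
    # smoothing window, shallow enough that a long one averages them away.
    # Kept >= 1.25 s clear of every flight so a dip-triggered detection can
    # never fall inside the matching tolerance of a true jump.
    if cfg.unweight_rate_hz > 0 and cfg.unweight_depth_ms2 > 0:
        max_dip = max(1, int(round(1.6 * cfg.unweight_dur_ms / 1000.0 * rate)))
        margin = int(round(1.25 * rate))
        blocked = np.zeros(n, dtype=bool)
        for start_s, flight_ms, _ in cfg.jumps:
            i0 = int(round(start_s * rate))
            i1 = int(round((start_s + flight_ms / 1000.0) * rate))
            blocked[max(0, i0 - margin - max_dip) : min(n, i1 + margin)] = True
        n_dips = int(rng.poisson(cfg.unweight_rate_hz * cfg.duration_s))
        placed = 0
        for _ in range(20 * n_dips):
            if placed >= n_dips or n <= max_dip:
                break
            j0 = int(rng.integers(0, n - max_dip))
            dur_ms = cfg.unweight_dur_ms * rng.uniform(0.6, 1.6)
            n_dip = max(1, int(round(dur_ms / 1000.0 * rate)))
            if blocked[j0 : j0 + n_dip].any():
                continue
            shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(n_dip) + 0.5) / n_dip))
            amp = cfg.unweight_depth_ms2 * rng.uniform(0.5, 1.0)
            for ch in channels:
                ch[j0 : j0 + n_dip] -= amp * rng.uniform(0.9, 1.1) * shape
            blocked[max(0, j0 - margin) : min(n, j0 + n_dip + margin)] = True
            placed += 1

    pair = BootPairSignal(
        sample_rate_hz=rate,
        t0_s=cfg.t0_s,
        left_acc_y=channels[0],
        right_acc_y=channels[1],
    )
    return pair, truth


def make_benchmark_suite(
    seed: int,
    n_small: int = 18,
    n_medium: int = 34,
    n_big_air: int = 15,
    **config_overrides,
) -> List[Tuple[BootPairSignal, List[JumpEvent]]]:
    """Deterministic suite of runs mirroring the study's class counts.

    Small and medium jumps are interleaved into multi-jump skiing runs (up
    to six jumps per run, well separated); each big-air jump gets its own
    single-jump run.  Flight times are drawn uniformly per class: small
    200–499 ms, medium 500–1200 ms, big air 1200–2500 ms.  Extra keyword
    arguments override :class:`SimConfig` noise/transient defaults.
    """
    if min(n_small, n_medium, n_big_air) < 0:
        raise ParameterError("class counts must be >= 0")
    rng = np.random.default_rng(seed)

    def draw_flight(label: str) -> float:
        lo, hi = FLIGHT_RANGES_MS[label]
        return float(rng.uniform(lo, hi))

    skiing_labels = ["small"] * n_small + ["medium"] * n_medium
    rng.shuffle(skiing_labels)

    suite: List[Tuple[BootPairSignal, List[JumpEvent]]] = []
    jumps_per_run = 6
    gap_s = 5.0
    for chunk_start in range(0, len(skiing_labels), jumps_per_run):
        labels = skiing_labels[chunk_start : chunk_start + jumps_per_run]
        jumps = []
        start = 3.0 + float(rng.uniform(0.0, 1.0))
        for label in labels:
            flight_ms = draw_flight(label)
            jumps.append((start, flight_ms, label))
            start += flight_ms / 1000.0 + gap_s + float(rng.uniform(0.0, 1.0))
        cfg = SimConfig(
            duration_s=start + 3.0,
            jumps=tuple(jumps),
            seed=int(rng.integers(0, 2**31)),
            **config_overrides,
        )
        suite.append(simulate_run(cfg))

    for _ in range(n_big_air):
        flight_ms = draw_flight("big_air")
        start = 3.0 + float(rng.uniform(0.0, 1.0))
        cfg = SimConfig(
            duration_s=start + flight_ms / 1000.0 + 3.0,
            jumps=((start, flight_ms, "big_air"),),
            seed=int(rng.integers(0, 2**31)),
            **config_overrides,
        )
        suite.append(simulate_run(cfg))
    return suite
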