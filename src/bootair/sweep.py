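"""Exhaustive (rolling window × rounding increment) parameter sweep.

Runs the detector over every grid cell, matches detections per run against
that run's ground truth, pools the counts, and stores one score report per
cell — the data behind detection-rate / overdetection heat maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .detect import JumpEvent, detect_jumps
from .errors import ParameterError
from .evaluate import DEFAULT_TOLERANCE_MS, ScoreReport, match_events, pooled_scores
from .signal import BootPairSignal

DEFAULT_WINDOWS = tuple(range(10, 26))
DEFAULT_INCREMENTS = (5.0, 10.0)

#: metric name -> ScoreReport attribute
_METRICS = {
    "ratio": "relative_ratio",
    "overdetected": "n_overdetected",
    "penalty": "penalty",
    "penalty_adjusted": "penalty_adjusted",
}

Run = Tuple[BootPairSignal, Sequence[JumpEvent]]


def points_to_ms(n: int, sample_rate_hz: float) -> float:
    """Duration of ``n`` data points in milliseconds, rounded to 0.1 ms.

    At 54 Hz one data point is 18.5 ms; the 10–25 sample window range spans
    185.2–463.0 ms.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if sample_rate_hz <= 0:
        raise ParameterError(f"sample_rate_hz must be > 0, got {sample_rate_hz}")
    return round(n * 1000.0 / sample_rate_hz, 1)


@dataclass(frozen=True)
class SweepGrid:
    """Score reports indexed by (window length in samples, increment)."""

    window_samples_axis: Tuple[int, ...]
    increment_axis: Tuple[float, ...]
    cells: Dict[Tuple[int, float], ScoreReport]
    sample_rate_hz: float

    def __post_init__(self) -> None:
        expected = {
            (w, inc) for w in self.window_samples_axis for inc in self.increment_axis
        }
        if set(self.cells) != expected:
            raise ParameterError("sweep grid is incomplete: one cell per axis combination required")

    def window_ms(self, window_samples: int) -> float:
        return points_to_ms(window_samples, self.sample_rate_hz)


def run_sweep(
    runs: Sequence[Run],
    windows: Optional[Sequence[int]] = None,
    increments: Optional[Sequence[float]] = None,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    truth_labels: Optional[Sequence[str]] = None,
    min_flight_ms: float = 0.0,
) -> SweepGrid:
    """Detect and score every (window, increment) combination.

    For each cell the detector runs once per recording; detections are
    matched per run against that run's full ground truth and the counts are
    pooled before the scores are computed (the overdetected count is the sum
    of per-run overdetections).  ``truth_labels`` restricts the detection
    ratio to ground-truth jumps of the given classes, classified post hoc
    from one shared detection pass.
    """
    if not runs:
        raise ParameterError("run_sweep requires at least one run")
    windows = tuple(int(w) for w in (windows if windows is not None else DEFAULT_WINDOWS))
    increments = tuple(
        float(i) for i in (increments if increments is not None else DEFAULT_INCREMENTS)
    )
    if not windows or not increments:
        raise ParameterError("both parameter axes must be non-empty")
    rates = {pair.sample_rate_hz for pair, _ in runs}
    if len(rates) != 1:
        raise ParameterError(f"all runs must share one sample rate, got {sorted(rates)}")

    cells: Dict[Tuple[int, float], ScoreReport] = {}
    for w in windows:
        for inc in increments:
            matches = [
                match_events(
                    detect_jumps(pair, w, inc, min_flight_ms=min_flight_ms),
                    truth,
                    tolerance_ms,
                )
                for pair, truth in runs
            ]
            cells[(w, inc)] = pooled_scores(matches, truth_labels=truth_labels)
    return SweepGrid(
        window_samples_axis=windows,
        increment_axis=increments,
        cells=cells,
        sample_rate_hz=rates.pop(),
    )


def export_heatmap_table(grid: SweepGrid, metric: str) -> pd.DataFrame:
    """Long-format table ``window_samples, window_ms, increment, value``.

    Rows are ordered row-major by (window, increment), matching the grid
    axes.  ``metric`` is one of ``ratio``, ``overdetected``, ``penalty``,
    ``penalty_adjusted``.
    """
    if metric not in _METRICS:
        raise ParameterError(
            f"unknown metric {metric!r}, expected one of {sorted(_METRICS)}"
        )
    attr = _METRICS[metric]
    rows: List[dict] = []
    for w in grid.window_samples_axis:
        for inc in grid.increment_axis:
            rows.append(
                {
                    "window_samples": w,
                    "window_ms": grid.window_ms(w),
                    "increment": inc,
                    "value": getattr(grid.cells[(w, inc)], attr),
                }
            )
    return pd.DataFrame(rows, columns=["window_samples", "window_ms", "increment", "value"])


def plot_heatmap(grid: SweepGrid, metric: str, path: str) -> None:
    """Render the metric matrix as a PNG heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = export_heatmap_table(grid, metric)
    matrix = table.pivot(index="increment", columns="window_ms", values="value")
    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), [f"{c:g}" for c in matrix.columns], rotation=45)
    ax.set_yticks(range(len(matrix.index)), [f"{i:g}" for i in matrix.index])
    ax.set_xlabel("rolling window (ms)")
    ax.set_ylabel("rounding increment (m/s²)")
    ax.set_title(metric)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
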