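"""Readers and writers for the plain-text interchange formats.

IMU CSV: columns ``time_s, acc_y_left, acc_y_right`` with optional
``#``-prefixed metadata lines (``# sample_rate_hz=54``, ``# units=ms2|g``).
Events CSV: columns ``start_s, end_s, flight_ms, label``.
Run manifests are YAML; score reports are JSON.  Times are seconds in all
files; only flight durations and tolerances are milliseconds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detect import JumpEvent
from .errors import FormatError, ParameterError
from .signal import G_MS2, BootPairSignal

logger = logging.getLogger(__name__)

IMU_COLUMNS = ("time_s", "acc_y_left", "acc_y_right")
EVENT_COLUMNS = ("start_s", "end_s", "flight_ms", "label")

#: maximum deviation from uniform spacing (s) before resampling kicks in
UNIFORM_TOL_S = 1e-6


def _read_metadata(path: Path) -> Dict[str, str]:
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    meta: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        frame = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return frame


def _numeric(frame: pd.DataFrame, columns: Sequence[str], path: Path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(bad.idxmax()) + 2
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise FormatError(f"{path}: missing value in column {col!r} at line {line}")
        frame[col] = converted.astype(float)
    return frame


def resample_uniform(
    times: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    sample_rate_hz: float,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Linear interpolation of an irregular series onto the nominal grid.

    Returns ``(t0_s, left, right)`` on a uniform grid at ``sample_rate_hz``
    spanning the original time range.
    """
    order = np.argsort(times)
    times, left, right = times[order], left[order], right[order]
    n_out = max(1, int(round((times[-1] - times[0]) * sample_rate_hz)) + 1)
    grid = times[0] + np.arange(n_out) / sample_rate_hz
    return (
        float(times[0]),
        np.interp(grid, times, left),
        np.interp(grid, times, right),
    )


def read_imu_csv(path: str | Path) -> BootPairSignal:
    """Load a dual-boot run from CSV.

    Honors ``# sample_rate_hz=`` and ``# units=`` metadata; values recorded
    in g are converted to m/s².  Non-uniform timestamps (within more than
    1 µs of the nominal grid) are resampled by linear interpolation with a
    logged warning.
    """
    path = Path(path)
    meta = _read_metadata(path)
    frame = _numeric(_read_table(path, IMU_COLUMNS), IMU_COLUMNS, path)
    if len(frame) == 0:
        raise FormatError(f"{path}: no samples")

    times = frame["time_s"].to_numpy()
    left = frame["acc_y_left"].to_numpy()
    right = frame["acc_y_right"].to_numpy()

    units = meta.get("units", "ms2")
    if units not in ("ms2", "g"):
        raise FormatError(f"{path}: unknown units {units!r} (expected 'ms2' or 'g')")
    if units == "g":
        left = left * G_MS2
        right = right * G_MS2

    if "sample_rate_hz" in meta:
        try:
            rate = float(meta["sample_rate_hz"])
        except ValueError:
            raise FormatError(f"{path}: bad sample_rate_hz metadata {meta['sample_rate_hz']!r}") from None
    elif len(times) > 1:
        rate = 1.0 / float(np.median(np.diff(times)))
    else:
        raise FormatError(f"{path}: single-sample file without '# sample_rate_hz=' metadata")
    if rate <= 0:
        raise FormatError(f"{path}: nonpositive sample rate {rate}")

    t0 = float(times[0])
    if len(times) > 1:
        expected = t0 + np.arange(len(times)) / rate
        if np.max(np.abs(times - expected)) > UNIFORM_TOL_S:
            logger.warning("%s: non-uniform timestamps; resampling to %g Hz", path, rate)
            t0, left, right = resample_uniform(times, left, right, rate)
    return BootPairSignal(sample_rate_hz=rate, t0_s=t0, left_acc_y=left, right_acc_y=right)


def write_imu_csv(path: str | Path, pair: BootPairSignal) -> None:
    """Write a dual-boot run with metadata header (always m/s²)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz={pair.sample_rate_hz:.10g}\n")
        fh.write("# units=ms2\n")
        fh.write(",".join(IMU_COLUMNS) + "\n")
        for t, l, r in zip(pair.times(), pair.left_acc_y, pair.right_acc_y):
            fh.write(f"{t:.9f},{l:.9f},{r:.9f}\n")


def read_events_csv(path: str | Path) -> List[JumpEvent]:
    """Load a jump-event list; an empty file with a header yields []."""
    path = Path(path)
    frame = _read_table(path, EVENT_COLUMNS)
    frame = _numeric(frame, ("start_s", "end_s", "flight_ms"), path)
    events = []
    for idx, row in frame.iterrows():
        if row["end_s"] <= row["start_s"]:
            raise FormatError(
                f"{path}: event at line {int(idx) + 2} has end_s <= start_s"
            )
        try:
            events.append(
                JumpEvent(
                    start_s=float(row["start_s"]),
                    end_s=float(row["end_s"]),
                    flight_ms=float(row["flight_ms"]),
                    label=str(row["label"]),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"{path}: invalid event at line {int(idx) + 2}: {exc}") from None
    return events


def write_events_csv(path: str | Path, events: Sequence[JumpEvent]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(f"{e.start_s:.9f},{e.end_s:.9f},{e.flight_ms:.9f},{e.label}\n")


@dataclass(frozen=True)
class ManifestEntry:
    imu_csv: Path
    truth_csv: Path
    label: str
    class_hint: Optional[str] = None


@dataclass(frozen=True)
class RunManifest:
    """List of (IMU run, ground truth) file pairs for a sweep."""

    entries: Tuple[ManifestEntry, ...]
    base_dir: Path


def read_manifest(path: str | Path) -> RunManifest:
    """Load a YAML manifest; every referenced file must exist.

    Schema::

        runs:
          - imu: run1.csv
            truth: truth1.csv
            label: run1          # optional, defaults to imu stem
            class_hint: medium   # optional

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "runs" not in doc or not isinstance(doc["runs"], list):
        raise FormatError(f"{path}: manifest must contain a 'runs' list")
    base = path.parent
    entries = []
    labels = set()
    for i, item in enumerate(doc["runs"]):
        if not isinstance(item, dict) or "imu" not in item or "truth" not in item:
            raise FormatError(f"{path}: run #{i + 1} must have 'imu' and 'truth' keys")
        imu = base / str(item["imu"])
        truth = base / str(item["truth"])
        for p in (imu, truth):
            if not p.exists():
                raise FormatError(f"{path}: referenced file does not exist: {p}")
        label = str(item.get("label", Path(str(item["imu"])).stem))
        if label in labels:
            raise FormatError(f"{path}: duplicate run label {label!r}")
        labels.add(label)
        entries.append(
            ManifestEntry(
                imu_csv=imu,
                truth_csv=truth,
                label=label,
                class_hint=item.get("class_hint"),
            )
        )
    return RunManifest(entries=tuple(entries), base_dir=base)


def write_report_json(path: str | Path, report: dict) -> None:
    """Write a score report with tool-version provenance."""
    payload = {"tool": "bootair", "version": __version__}
    payload.update(report)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
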