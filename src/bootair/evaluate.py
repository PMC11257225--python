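"""Validation: tolerance-based event matching and the four summary scores.

Detected events are paired one-to-one with ground-truth events when their
start times agree within a tolerance (150 ms by default).  From a match the
four scores are derived:

1. relative ratio    — matched / n_truth
2. overdetected      — number of detected events left unmatched
3. penalty           — overdetected / n_truth
4. penalty-adjusted  — relative ratio minus penalty (may be negative)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .detect import JumpEvent
from .errors import ParameterError, UndefinedScoreError

DEFAULT_TOLERANCE_MS = 150.0

MatchedPair = Tuple[JumpEvent, JumpEvent, float]  # (truth, detected, |Δstart| ms)


@dataclass(frozen=True)
class MatchResult:
    """One-to-one pairing of detected and ground-truth events."""

    matched_pairs: Tuple[MatchedPair, ...]
    undetected_truth: Tuple[JumpEvent, ...]
    overdetected: Tuple[JumpEvent, ...]
    n_truth: int

    def __post_init__(self) -> None:
        if len(self.matched_pairs) + len(self.undetected_truth) != self.n_truth:
            raise ParameterError("matched + undetected must equal n_truth")

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    @property
    def n_detected(self) -> int:
        return len(self.matched_pairs) + len(self.overdetected)


@dataclass(frozen=True)
class ScoreReport:
    """The four validation scores plus the counts they derive from."""

    relative_ratio: float
    n_overdetected: int
    penalty: float
    penalty_adjusted: float
    n_truth: int = 0
    n_matched: int = 0
    n_detected: int = 0

    @property
    def relative_ratio_pct(self) -> int:
        """Detection ratio as a whole percent (figure-style display)."""
        return int(round(self.relative_ratio * 100))

    def to_dict(self) -> dict:
        return {
            "relative_ratio": self.relative_ratio,
            "relative_ratio_pct": self.relative_ratio_pct,
            "n_overdetected": self.n_overdetected,
            "penalty": self.penalty,
            "penalty_adjusted": self.penalty_adjusted,
            "n_truth": self.n_truth,
            "n_matched": self.n_matched,
            "n_detected": self.n_detected,
        }


def match_events(
    detected: Sequence[JumpEvent],
    truth: Sequence[JumpEvent],
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> MatchResult:
    """Greedy nearest-start one-to-one matching within ``tolerance_ms``.

    Candidate (truth, detected) pairs with start-time difference at most
    ``tolerance_ms`` (inclusive) are accepted in increasing |Δstart| order,
    skipping events already matched; ties break toward the earlier detected
    event, then the earlier truth event.  Unmatched truth events are reported
    as undetected, unmatched detected events as overdetected.
    """
    if tolerance_ms < 0:
        raise ParameterError(f"tolerance_ms must be >= 0, got {tolerance_ms}")
    detected = sorted(detected, key=lambda e: e.start_s)
    truth = sorted(truth, key=lambda e: e.start_s)

    candidates = []
    for ti, t in enumerate(truth):
        for di, d in enumerate(detected):
            delta_ms = abs(d.start_s - t.start_s) * 1000.0
            if delta_ms <= tolerance_ms:
                candidates.append((delta_ms, d.start_s, t.start_s, ti, di))
    candidates.sort()

    truth_used = [False] * len(truth)
    det_used = [False] * len(detected)
    pairs: List[MatchedPair] = []
    for delta_ms, _, _, ti, di in candidates:
        if truth_used[ti] or det_used[di]:
            continue
        truth_used[ti] = True
        det_used[di] = True
        pairs.append((truth[ti], detected[di], delta_ms))

    pairs.sort(key=lambda p: p[0].start_s)
    return MatchResult(
        matched_pairs=tuple(pairs),
        undetected_truth=tuple(t for t, used in zip(truth, truth_used) if not used),
        overdetected=tuple(d for d, used in zip(detected, det_used) if not used),
        n_truth=len(truth),
    )


def relative_ratio(m: MatchResult) -> float:
    """Properly detected jumps over the total number of ground-truth jumps."""
    if m.n_truth == 0:
        raise UndefinedScoreError("relative ratio is undefined for empty ground truth")
    return m.n_matched / m.n_truth


def overdetected_count(m: MatchResult) -> int:
    """Number of detected events not matched to any ground-truth jump."""
    return len(m.overdetected)


def penalty_score(m: MatchResult) -> float:
    """Overdetected jumps divided by the total number of ground-truth jumps."""
    if m.n_truth == 0:
        raise UndefinedScoreError("penalty score is undefined for empty ground truth")
    return len(m.overdetected) / m.n_truth


def penalty_adjusted_score(m: MatchResult) -> float:
    """Relative ratio minus penalty score; negative when overdetections dominate."""
    if m.n_truth == 0:
        raise UndefinedScoreError("penalty-adjusted score is undefined for empty ground truth")
    return relative_ratio(m) - penalty_score(m)


def scores_from_match(m: MatchResult) -> ScoreReport:
    """Bundle the four scores computed from one match."""
    return ScoreReport(
        relative_ratio=relative_ratio(m),
        n_overdetected=overdetected_count(m),
        penalty=penalty_score(m),
        penalty_adjusted=penalty_adjusted_score(m),
        n_truth=m.n_truth,
        n_matched=m.n_matched,
        n_detected=m.n_detected,
    )


def pooled_scores(
    matches: Iterable[MatchResult],
    truth_labels: Optional[Sequence[str]] = None,
) -> ScoreReport:
    """Scores from counts pooled across runs.

    Matched and undetected counts can be restricted to truth events whose
    label is in ``truth_labels`` (detections are matched against the full
    truth list first, so a jump of another class never counts as an
    overdetection).  Overdetections are always pooled over all runs.
    """
    labels = set(truth_labels) if truth_labels is not None else None

    def in_class(event: JumpEvent) -> bool:
        return labels is None or event.label in labels

    n_matched = n_truth = n_over = 0
    for m in matches:
        n_matched += sum(1 for t, _, _ in m.matched_pairs if in_class(t))
        n_truth += sum(1 for t, _, _ in m.matched_pairs if in_class(t)) + sum(
            1 for t in m.undetected_truth if in_class(t)
        )
        n_over += len(m.overdetected)
    if n_truth == 0:
        raise UndefinedScoreError("no ground-truth jumps in the requested class")
    ratio = n_matched / n_truth
    penalty = n_over / n_truth
    return ScoreReport(
        relative_ratio=ratio,
        n_overdetected=n_over,
        penalty=penalty,
        penalty_adjusted=ratio - penalty,
        n_truth=n_truth,
        n_matched=n_matched,
        n_detected=n_matched + n_over,
    )


def score_report(
    detected: Sequence[JumpEvent],
    truth: Sequence[JumpEvent],
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> ScoreReport:
    """Match one run and compute all four scores.

    Raises :class:`UndefinedScoreError` when the ground-truth list is empty.
    """
    return scores_from_match(match_events(detected, truth, tolerance_ms))
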