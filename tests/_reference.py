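"""Straight-line reference implementations used as independent oracles.

Everything here is deliberately unvectorised pure Python: element-wise
loops, explicit window sums, exhaustive assignment search.  These are the
ground truth the package implementations are checked against.
"""

import itertools
import math


def ref_fuse(left, right):
    return [(abs(l) + abs(r)) / 2.0 for l, r in zip(left, right)]


def ref_smooth(values, window):
    """Centred window of nominal width ``window``, truncated at the edges.

    Even windows put the extra sample on the trailing side.  Sums run left
    to right so the float result is bit-identical to an equally ordered
    vectorised accumulation.
    """
    n = len(values)
    half_lead = (window - 1) // 2
    half_trail = window // 2
    out = []
    for i in range(n):
        lo = max(0, i - half_lead)
        hi = min(n, i + half_trail + 1)
        s = 0.0
        for j in range(lo, hi):
            s += values[j]
        out.append(s / (hi - lo))
    return out


def ref_round(values, increment):
    # non-negative input: floor(v/inc + 0.5) is round-half-away-from-zero
    return [math.floor(v / increment + 0.5) * increment for v in values]


def ref_zero_regions(values):
    regions = []
    start = None
    for i, v in enumerate(values):
        if v == 0.0 and start is None:
            start = i
        elif v != 0.0 and start is not None:
            regions.append((start, i))
            start = None
    if start is not None:
        regions.append((start, len(values)))
    return regions


def ref_detect(left, right, sample_rate_hz, t0_s, window, increment, min_flight_ms=0.0):
    """Full pipeline as one unvectorised pass; returns (start_s, end_s) pairs."""
    rounded = ref_round(ref_smooth(ref_fuse(left, right), window), increment)
    events = []
    for i0, i1 in ref_zero_regions(rounded):
        start = t0_s + i0 / sample_rate_hz
        end = t0_s + i1 / sample_rate_hz
        if (end - start) * 1000.0 >= min_flight_ms:
            events.append((start, end))
    return events


def ref_best_matching(detected_starts, truth_starts, tolerance_ms):
    """Exhaustive one-to-one assignment: maximise matches, then minimise
    total |Δstart|.  Only feasible for short lists."""
    best = (0, 0.0, ())
    d_idx = range(len(detected_starts))
    for k in range(min(len(detected_starts), len(truth_starts)), -1, -1):
        found = None
        for t_subset in itertools.combinations(range(len(truth_starts)), k):
            for d_perm in itertools.permutations(d_idx, k):
                deltas = [
                    abs(detected_starts[d] - truth_starts[t]) * 1000.0
                    for t, d in zip(t_subset, d_perm)
                ]
                if all(x <= tolerance_ms for x in deltas):
                    total = sum(deltas)
                    if found is None or total < found[0]:
                        found = (total, tuple(zip(t_subset, d_perm)))
        if found is not None:
            return k, found[0], found[1]
    return 0, 0.0, ()
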