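"""Sorted-array interval arithmetic (0-based, half-open).

Small numpy sweeps used by the enrichment, profiling and peak-cluster
stages. Abutting intervals ([a,b) and [b,c)) do not overlap.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "overlaps_any",
    "covered_bp",
    "coverage_fraction",
    "count_features_overlapping",
]


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping (>= 1 bp) intervals into disjoint sorted intervals.

    Abutting intervals are kept separate (half-open convention).
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for i in range(1, len(s)):
        if s[i] < out_e[-1]:  # strict: abutting does not merge
            if e[i] > out_e[-1]:
                out_e[-1] = int(e[i])
        else:
            out_s.append(int(s[i]))
            out_e.append(int(e[i]))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def overlaps_any(
    q_start, q_end, m_starts: np.ndarray, m_ends: np.ndarray
) -> np.ndarray:
    """For each query interval, whether it overlaps any merged interval.

    ``m_starts``/``m_ends`` must be disjoint and sorted (output of merge).
    Accepts scalars or arrays for the queries; returns bool array/scalar.
    """
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    if m_starts.size == 0:
        return np.zeros(q_start.shape, dtype=bool) if q_start.shape else False
    lo = np.searchsorted(m_ends, q_start, side="right")
    hi = np.searchsorted(m_starts, q_end, side="left")
    return lo < hi


def covered_bp(q_start, q_end, m_starts: np.ndarray, m_ends: np.ndarray):
    """Base pairs of each query interval covered by the merged set."""
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    if m_starts.size == 0:
        return np.zeros(len(q_start), dtype=np.int64)
    # prefix sums of merged interval lengths
    lens = (m_ends - m_starts).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])
    lo = np.searchsorted(m_ends, q_start, side="right")
    hi = np.searchsorted(m_starts, q_end, side="left")
    out = np.zeros(len(q_start), dtype=np.int64)
    for i in range(len(q_start)):
        a, b = lo[i], hi[i]
        if a >= b:
            continue
        full = cum[b] - cum[a]
        # trim the flanking partial overlaps
        full -= max(0, q_start[i] - m_starts[a])
        full -= max(0, m_ends[b - 1] - q_end[i])
        out[i] = full
    return out


def coverage_fraction(q_start, q_end, m_starts, m_ends) -> np.ndarray:
    q_start = np.atleast_1d(np.asarray(q_start, dtype=np.int64))
    q_end = np.atleast_1d(np.asarray(q_end, dtype=np.int64))
    bp = covered_bp(q_start, q_end, m_starts, m_ends)
    return bp / np.maximum(q_end - q_start, 1)


def count_features_overlapping(
    f_starts: np.ndarray, f_ends: np.ndarray, m_starts: np.ndarray, m_ends: np.ndarray
) -> int:
    """Number of feature intervals overlapping >= 1 bp of the merged set."""
    if len(f_starts) == 0:
        return 0
    return int(np.count_nonzero(overlaps_any(f_starts, f_ends, m_starts, m_ends)))
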