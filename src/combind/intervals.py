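"""Low-level interval arithmetic on numpy arrays.

All coordinates are 0-based half-open. "Overlap" everywhere in this package
means at least one shared base: [a, b) and [c, d) overlap iff a < d and c < b;
book-ended intervals ([0,10) and [10,20)) do NOT overlap.
"""
from __future__ import annotations

import numpy as np


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge intervals into the connected components of the >=1-bp overlap graph.

    Returns (merged_starts, merged_ends, component_index) where
    ``component_index[i]`` gives the merged interval containing input ``i``.
    Inputs need not be sorted.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    n = starts.size
    if n == 0:
        return starts.copy(), ends.copy(), np.zeros(0, dtype=np.int64)
    order = np.lexsort((ends, starts))
    s, e = starts[order], ends[order]
    cummax_e = np.maximum.accumulate(e)
    # a new component starts where the interval clears everything before it;
    # strict inequality keeps book-ended intervals separate
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    boundary[1:] = s[1:] >= cummax_e[:-1]
    comp_sorted = np.cumsum(boundary) - 1
    first = np.flatnonzero(boundary)
    out_s = s[first]
    out_e = np.maximum.reduceat(e, first)
    comp = np.empty(n, dtype=np.int64)
    comp[order] = comp_sorted
    return out_s, out_e, comp


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts: np.ndarray,
    s_ends: np.ndarray,
) -> np.ndarray:
    """Boolean mask: does each query interval share >=1 base with any subject?

    Subjects must be disjoint and sorted (merge them first if not).
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if s_starts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    # rightmost subject starting before the query end
    idx = np.searchsorted(s_starts, q_ends, side="left")
    hit = idx > 0
    # disjoint + sorted => ends are sorted too; that subject has the largest end
    hit[hit] = s_ends[idx[hit] - 1] > q_starts[hit]
    return hit


def overlap_ranges(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts: np.ndarray,
    s_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """For disjoint sorted subjects, return [lo, hi) subject-index ranges of
    the subjects overlapping each query interval."""
    lo = np.searchsorted(s_ends, np.asarray(q_starts, dtype=np.int64), side="right")
    hi = np.searchsorted(s_starts, np.asarray(q_ends, dtype=np.int64), side="left")
    return lo, hi


def covered_bases(
    q_start: int, q_end: int, s_starts: np.ndarray, s_ends: np.ndarray
) -> int:
    """Number of bases of [q_start, q_end) covered by disjoint sorted subjects."""
    lo, hi = overlap_ranges(np.array([q_start]), np.array([q_end]), s_starts, s_ends)
    lo, hi = int(lo[0]), int(hi[0])
    if hi <= lo:
        return 0
    ov = np.minimum(s_ends[lo:hi], q_end) - np.maximum(s_starts[lo:hi], q_start)
    return int(ov.sum())
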