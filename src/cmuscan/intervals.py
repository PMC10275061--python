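"""Sorted-array interval calculus on 0-based half-open genomic intervals.

These primitives back the Tversky similarity score, tissue-independent
region calling (per-basepair coverage stacking) and the matched-background
enrichment test, all of which operate on large numbers of small interval
sets where per-call overhead matters.  Intervals are given per chromosome
as parallel ``starts``/``ends`` int arrays.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

Region = tuple[str, int, int]


def merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or touching intervals; output sorted and disjoint."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    # running maximum of ends; a new merged block begins where start > max end so far
    cummax = np.maximum.accumulate(e)
    new_block = np.empty(s.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = s[1:] > cummax[:-1]
    idx = np.flatnonzero(new_block)
    out_s = s[idx]
    out_e = np.empty(idx.size, dtype=np.int64)
    out_e[:-1] = np.maximum.reduceat(cummax, idx)[:-1]
    out_e[-1] = cummax[-1]
    return out_s, out_e


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Boolean vector: does each query interval share >=1 bp with any target?

    Targets need not be disjoint; they are merged internally.
    """
    q_starts = np.asarray(q_starts, dtype=np.int64)
    q_ends = np.asarray(q_ends, dtype=np.int64)
    if q_starts.size == 0:
        return np.zeros(0, dtype=bool)
    ts, te = merge(t_starts, t_ends)
    if ts.size == 0:
        return np.zeros(q_starts.size, dtype=bool)
    # merged targets are disjoint and sorted: query [s,e) overlaps target i iff
    # t_start[i] < e and t_end[i] > s; candidates form a contiguous slice
    hi = np.searchsorted(ts, q_ends, side="left")
    lo = np.searchsorted(te, q_starts, side="right")
    return hi > lo


def hit_indices(
    q_start: int,
    q_end: int,
    t_starts: np.ndarray,
    t_ends: np.ndarray,
) -> np.ndarray:
    """Indices of target intervals sharing >=1 bp with the query.

    Targets must be sorted by start but may overlap each other; identity of
    each interval is preserved (needed for "unique overlap" statistics).
    """
    t_starts = np.asarray(t_starts, dtype=np.int64)
    t_ends = np.asarray(t_ends, dtype=np.int64)
    if t_starts.size == 0:
        return np.zeros(0, dtype=np.int64)
    hi = np.searchsorted(t_starts, q_end, side="left")
    cummax_end = np.maximum.accumulate(t_ends)
    lo = np.searchsorted(cummax_end, q_start, side="right")
    cand = np.arange(lo, hi, dtype=np.int64)
    return cand[t_ends[cand] > q_start]


def subtract(
    starts: np.ndarray,
    ends: np.ndarray,
    sub_starts: np.ndarray,
    sub_ends: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the (merged) subtrahend from each interval, keeping remainders."""
    ss, se = merge(sub_starts, sub_ends)
    out_s: list[int] = []
    out_e: list[int] = []
    for s, e in zip(np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)):
        cur = int(s)
        for i in hit_indices(int(s), int(e), ss, se):
            if ss[i] > cur:
                out_s.append(cur)
                out_e.append(int(ss[i]))
            cur = max(cur, int(se[i]))
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def coverage_runs(
    starts: np.ndarray,
    ends: np.ndarray,
    min_depth: int,
) -> list[tuple[int, int, int]]:
    """Maximal runs where stacked interval depth >= min_depth.

    Returns (start, end, max_depth_within_run) tuples.  Input intervals come
    from multiple stacked sets and may overlap arbitrarily.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0 or min_depth <= 0:
        return []
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(starts.size, np.int64), -np.ones(ends.size, np.int64)])
    order = np.lexsort((-delta, pos))  # at equal position, starts (+1) before ends (-1)
    pos, delta = pos[order], delta[order]
    depth = np.cumsum(delta)
    runs: list[tuple[int, int, int]] = []
    run_start = None
    run_max = 0
    for i in range(pos.size - 1):
        d = int(depth[i])
        seg_s, seg_e = int(pos[i]), int(pos[i + 1])
        if d >= min_depth and seg_e > seg_s:
            if run_start is None:
                run_start, run_max = seg_s, d
            else:
                run_max = max(run_max, d)
            run_end = seg_e
        elif run_start is not None and (d < min_depth) and seg_e > seg_s:
            runs.append((run_start, run_end, run_max))
            run_start = None
    if run_start is not None:
        runs.append((run_start, run_end, run_max))
    return runs


def by_chrom(regions: Iterable[Region]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Group (chrom, start, end) triples into per-chromosome sorted arrays."""
    buckets: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        buckets.setdefault(chrom, []).append((int(start), int(end)))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in buckets.items():
        ivals.sort()
        arr = np.asarray(ivals, dtype=np.int64).reshape(-1, 2)
        out[chrom] = (arr[:, 0].copy(), arr[:, 1].copy())
    return out


def total_length(starts: np.ndarray, ends: np.ndarray) -> int:
    ms, me = merge(starts, ends)
    return int((me - ms).sum())
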