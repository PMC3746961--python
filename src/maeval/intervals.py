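"""Half-open interval arithmetic on a single sequence axis.

Every coordinate in this package is 0-based and every interval is half-open,
``[start, end)``.  Conversion to the 1-based closed conventions of GFF and
tabular BLAST output happens only at the I/O boundary (:mod:`maeval.formats_io`).

An *interval set* is a list of ``(start, end)`` tuples that is sorted and
disjoint; :func:`merge_intervals` produces one from arbitrary input.  Touching
intervals (``a.end == b.start``) are merged: a region contiguously covered by
reads is a single region.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def _validate(intervals: Iterable[Interval]) -> List[Interval]:
    out = []
    for s, e in intervals:
        if e < s:
            raise ValueError(f"interval end < start: ({s}, {e})")
        if e > s:  # drop empty intervals
            out.append((int(s), int(e)))
    return out


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted, disjoint list (touching merged)."""
    ivs = sorted(_validate(intervals))
    merged: List[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            ps, pe = merged[-1]
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    """Sum of interval lengths (call on a merged set to get covered length)."""
    return sum(e - s for s, e in intervals)


def new_coverage(covered: List[Interval], interval: Interval) -> int:
    """Length of ``interval`` not already in the merged set ``covered``."""
    s, e = interval
    if e < s:
        raise ValueError(f"interval end < start: ({s}, {e})")
    novel = e - s
    for cs, ce in covered:
        if cs >= e:
            break
        if ce > s:
            novel -= min(e, ce) - max(s, cs)
    return novel


def add_interval(covered: List[Interval], interval: Interval) -> List[Interval]:
    """Merged set after adding one interval."""
    return merge_intervals(list(covered) + [interval])


def subtract_intervals(
    minuend: Iterable[Interval], subtrahend: Iterable[Interval]
) -> List[Interval]:
    """Parts of ``minuend`` not covered by ``subtrahend`` (both arbitrary)."""
    a = merge_intervals(minuend)
    b = merge_intervals(subtrahend)
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_intervals(
    a: Iterable[Interval], b: Iterable[Interval]
) -> List[Interval]:
    """Intersection of two interval sets as a merged set."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if s < e:
            out.append((s, e))
        if am[i][1] <= bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def complement(covered: Iterable[Interval], start: int, end: int) -> List[Interval]:
    """Parts of ``[start, end)`` not covered."""
    return subtract_intervals([(start, end)], covered)
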