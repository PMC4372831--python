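"""Phenophase intervals on the study-day axis.

A phenophase is the set of days a plant displays ripe fruit or a bird is
present at the site.  It is represented as a list of half-open intervals
``[start, end)`` in study days (0-based floats), so temporal overlap between
two species can be computed exactly as the total length of the intersection
of their interval sets.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Tuple

Interval = Tuple[float, float]


def normalize(intervals: Iterable[Sequence[float]]) -> List[Interval]:
    """Sort, validate and merge overlapping/touching intervals.

    Raises ``ValueError`` for an interval with ``end < start``.
    Zero-length intervals are dropped.
    """
    items: List[Interval] = []
    for iv in intervals:
        start, end = float(iv[0]), float(iv[1])
        if end < start:
            raise ValueError(f"interval end {end} before start {start}")
        if end > start:
            items.append((start, end))
    items.sort()
    merged: List[Interval] = []
    for start, end in items:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def total_length(intervals: Iterable[Sequence[float]]) -> float:
    """Total number of days covered by the interval set."""
    return sum(end - start for start, end in normalize(intervals))


def intersect(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> List[Interval]:
    """Intersection of two interval sets, as a normalized interval list."""
    ia, ib = normalize(a), normalize(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(ia) and j < len(ib):
        lo = max(ia[i][0], ib[j][0])
        hi = min(ia[i][1], ib[j][1])
        if hi > lo:
            out.append((lo, hi))
        if ia[i][1] <= ib[j][1]:
            i += 1
        else:
            j += 1
    return out


def overlap_days(a: Iterable[Sequence[float]], b: Iterable[Sequence[float]]) -> float:
    """Number of days two phenophases coincide."""
    return sum(end - start for start, end in intersect(a, b))


def parse_intervals(text: str) -> List[Interval]:
    """Parse the on-disk encoding ``"start-end;start-end"`` (days)."""
    text = text.strip()
    if not text:
        return []
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split("-")
        if len(parts) != 2:
            raise ValueError(f"malformed phenophase interval {chunk!r}")
        out.append((float(parts[0]), float(parts[1])))
    return normalize(out)


def format_intervals(intervals: Iterable[Sequence[float]]) -> str:
    """Inverse of :func:`parse_intervals` (``"%g"`` day formatting)."""
    return ";".join(f"{s:g}-{e:g}" for s, e in normalize(intervals))
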