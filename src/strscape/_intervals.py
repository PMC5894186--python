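"""Half-open interval arithmetic on (start, end) tuples.

All functions operate on plain integer pairs within a single sequence;
callers are responsible for grouping by seq_id first.
"""

from __future__ import annotations

from typing import Iterable


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or touching half-open intervals."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in intervals)


def intersect(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Pairwise intersection of two merged interval lists (sweep)."""
    a = list(a)
    b = list(b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[tuple[int, int]], b: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Parts of merged intervals `a` not covered by merged intervals `b`."""
    b = list(b)
    out = []
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur:
                continue
            if bs >= e:
                break
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]
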