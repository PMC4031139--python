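"""Small vectorised interval utilities (overlap queries, coverage, Jaccard).

Intervals here are plain (chrom, start, end) triples in half-open
coordinates; queries work on possibly-overlapping interval sets via
sorted starts plus a running maximum of ends.
"""

from __future__ import annotations

from typing import Dict, Iterable, Sequence, Tuple

import numpy as np

from .types import GenomicInterval


class IntervalIndex:
    """Per-chromosome overlap index over a static set of intervals."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: Dict[str, list[Tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            starts = arr[:, 0]
            cummax_end = np.maximum.accumulate(arr[:, 1])
            self._index[chrom] = (starts, cummax_end)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any indexed interval by >= 1 bp."""
        if chrom not in self._index:
            return False
        starts, cummax_end = self._index[chrom]
        i = np.searchsorted(starts, end, side="left")
        return i > 0 and cummax_end[i - 1] > start

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos + 1)


def coverage_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by the union of the intervals."""
    total = 0
    by_chrom: Dict[str, list[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for pairs in by_chrom.values():
        pairs.sort()
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
    return total


def jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    """Base-level Jaccard index |A ∩ B| / |A ∪ B| between two interval sets."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    inter = 0
    b_by_chrom: Dict[str, list[Tuple[int, int]]] = {}
    for iv in b:
        b_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # merge each set first so intersections are not double counted
    a_merged = _merge([(iv.chrom, iv.start, iv.end) for iv in a])
    b_merged = _merge([(iv.chrom, iv.start, iv.end) for iv in b])
    for chrom, a_pairs in a_merged.items():
        b_pairs = b_merged.get(chrom, [])
        i = j = 0
        while i < len(a_pairs) and j < len(b_pairs):
            s = max(a_pairs[i][0], b_pairs[j][0])
            e = min(a_pairs[i][1], b_pairs[j][1])
            if e > s:
                inter += e - s
            if a_pairs[i][1] < b_pairs[j][1]:
                i += 1
            else:
                j += 1
    union = coverage_bp(list(a) + list(b))
    return inter / union if union else 1.0


def _merge(triples: Sequence[Tuple[str, int, int]]) -> Dict[str, list[Tuple[int, int]]]:
    by_chrom: Dict[str, list[Tuple[int, int]]] = {}
    for chrom, s, e in triples:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: Dict[str, list[Tuple[int, int]]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged = [list(pairs[0])]
        for s, e in pairs[1:]:
            if s > merged[-1][1]:
                merged.append([s, e])
            else:
                merged[-1][1] = max(merged[-1][1], e)
        out[chrom] = [(s, e) for s, e in merged]
    return out
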