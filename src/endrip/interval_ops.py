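"""Sorted-array interval algebra used by every stage.

All functions take plain :class:`~endrip.core.GenomicInterval` lists and use
half-open overlap semantics: intervals overlap iff they share at least one
base pair, so abutting intervals ([a,b) and [b,c)) do NOT overlap.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import GenomeSpec, GenomicInterval

__all__ = [
    "sort_intervals",
    "merge_overlapping",
    "overlap_groups",
    "any_overlap_flags",
    "nearest_distance",
]


def sort_intervals(
    intervals: Sequence[GenomicInterval], genome: Optional[GenomeSpec] = None
) -> list[GenomicInterval]:
    """Deterministic ordering: genome chromosome order (or lexicographic when no
    genome is bound), then start, then end."""
    if genome is not None:
        key = lambda iv: (genome.order_of(iv.chrom), iv.start, iv.end)
    else:
        key = lambda iv: (iv.chrom, iv.start, iv.end)
    return sorted(intervals, key=key)


def overlap_groups(
    intervals: Sequence[GenomicInterval],
) -> list[tuple[GenomicInterval, list[int]]]:
    """Partition intervals into transitive overlap groups.

    Returns one (merged span, member indices) pair per connected component of
    the >=1 bp overlap graph, ordered by (chrom, start).
    """
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end))
    out: list[tuple[GenomicInterval, list[int]]] = []
    cur_chrom = None
    cur_start = cur_end = 0
    members: list[int] = []
    for i in order:
        iv = intervals[i]
        if cur_chrom == iv.chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
            members.append(i)
        else:
            if members:
                out.append((GenomicInterval(cur_chrom, cur_start, cur_end), members))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            members = [i]
    if members:
        out.append((GenomicInterval(cur_chrom, cur_start, cur_end), members))
    return out


def merge_overlapping(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union-merge of all >=1 bp-overlapping intervals."""
    return [span for span, _ in overlap_groups(intervals)]


def _merged_arrays(
    features: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    per: dict[str, list[GenomicInterval]] = defaultdict(list)
    for f in features:
        per[f.chrom].append(f)
    for chrom, fs in per.items():
        merged = merge_overlapping(fs)
        by_chrom[chrom] = (
            np.fromiter((m.start for m in merged), dtype=np.int64, count=len(merged)),
            np.fromiter((m.end for m in merged), dtype=np.int64, count=len(merged)),
        )
    return by_chrom


def any_overlap_flags(
    queries: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean flag per query: does it overlap (>=1 bp) any feature?"""
    arrays = _merged_arrays(features)
    flags = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in arrays:
            continue
        starts, ends = arrays[q.chrom]
        # first merged feature whose end exceeds the query start
        j = int(np.searchsorted(ends, q.start, side="right"))
        flags[i] = j < len(starts) and starts[j] < q.end
    return flags


def nearest_distance(
    queries: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> np.ndarray:
    """Unsigned bp gap from each query to the nearest feature on its chromosome.

    0 when overlapping; ``nan`` when the chromosome carries no feature.
    """
    arrays = _merged_arrays(features)
    out = np.full(len(queries), np.nan)
    for i, q in enumerate(queries):
        if q.chrom not in arrays:
            continue
        starts, ends = arrays[q.chrom]
        j = int(np.searchsorted(ends, q.start, side="right"))
        if j < len(starts) and starts[j] < q.end:
            out[i] = 0.0
            continue
        best = np.inf
        if j < len(starts):  # nearest feature to the right
            best = starts[j] - q.end
        if j > 0:  # nearest feature to the left
            best = min(best, q.start - ends[j - 1])
        out[i] = float(best)
    return out
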