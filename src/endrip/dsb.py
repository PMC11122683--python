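"""Double-strand-break calling from strand-specific peaks.

A blunt double-ended break (deDSB) leaves reads stacking on its left on the
minus strand and on its right on the plus strand, so it appears as a reverse
peak closely followed by a forward peak.  Pairing those peaks (gap below
``max_pair_gap``), taking the replicate consensus, and classifying the pairs
by their response at two treatment timepoints yields DSB clusters in the
persistent / transient / late kinetic classes.  Solitary single-strand peaks
far from any opposite-strand peak are candidate single-ended breaks (seDSBs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    FORWARD,
    REVERSE,
    ConfigError,
    GenomeSpec,
    GenomicInterval,
    StrandedPeak,
    ValidationError,
)
from .interval_ops import any_overlap_flags, merge_overlapping, nearest_distance, overlap_groups
from .io import SignalTrack

__all__ = [
    "DSBCluster",
    "SoloPeak",
    "call_strand_peaks",
    "pair_distance",
    "pair_strand_peaks",
    "consensus_clusters",
    "classify_dsb_kinetics",
    "detect_sedsb",
]


@dataclass
class DSBCluster:
    """Paired-strand break call spanning reverse-peak start to forward-peak end."""

    interval: GenomicInterval
    reverse_peak: Optional[StrandedPeak] = None
    forward_peak: Optional[StrandedPeak] = None
    gap: Optional[int] = None
    replicate_support: frozenset = frozenset()
    kinetic_class: str = "unclassified"


@dataclass
class SoloPeak:
    """Solitary single-strand peak, candidate single-ended break."""

    peak: StrandedPeak
    nearest_opposite_distance: float  # inf when no opposite-strand peak on the chromosome
    count: Optional[float] = None
    enriched: dict = field(default_factory=dict)


def call_strand_peaks(
    track: SignalTrack,
    background: SignalTrack,
    genome: GenomeSpec,
    strand: str,
    min_fold: float = 5.0,
    min_width: int = 150,
    replicate: Optional[int] = None,
) -> list[StrandedPeak]:
    """Threshold-and-run peak caller over piecewise-constant coverage.

    A position is above threshold when signal >= min_fold * max(local
    background, genome-wide background mean).  Maximal above-threshold runs
    separated by less than ``min_width/2`` bp of sub-threshold signal are
    merged; runs shorter than ``min_width`` are dropped.

    This is deliberately a minimal caller for rectangular synthetic coverage;
    model-based calling is out of scope.
    """
    if min_fold <= 1:
        raise ConfigError("min_fold must exceed 1")
    total_len = genome.total_length
    bg_integral = sum(
        float(background.integral(chrom, 0, genome.length_of(chrom))[0])
        for chrom in genome.names
    )
    bg_mean = bg_integral / total_len if total_len else 0.0

    peaks: list[StrandedPeak] = []
    for chrom in genome.names:
        length = genome.length_of(chrom)
        cuts = {0, length}
        for trk in (track, background):
            blocks = trk._blocks.get(chrom)
            if blocks is not None:
                starts, ends, _, _ = blocks
                cuts.update(int(x) for x in starts)
                cuts.update(int(x) for x in ends)
        bounds = sorted(c for c in cuts if 0 <= c <= length)
        runs: list[list[int]] = []  # [start, end] of above-threshold runs
        for a, b in zip(bounds[:-1], bounds[1:]):
            sig = track.value(chrom, a)
            thr = min_fold * max(background.value(chrom, a), bg_mean)
            if sig >= thr and sig > 0:
                if runs and runs[-1][1] == a:
                    runs[-1][1] = b
                else:
                    runs.append([a, b])
        # merge runs separated by short sub-threshold gaps
        merged: list[list[int]] = []
        for run in runs:
            if merged and run[0] - merged[-1][1] < min_width / 2:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        for a, b in merged:
            if b - a >= min_width:
                peaks.append(
                    StrandedPeak(GenomicInterval(chrom, a, b), strand, replicate=replicate)
                )
    return peaks


def pair_distance(reverse: GenomicInterval, forward: GenomicInterval) -> Optional[int]:
    """Signed reverse-to-forward distance; None for different chromosomes.

    0 when the peaks overlap, positive when the forward peak starts at or
    after the reverse end, negative when the forward peak lies entirely to
    the left of the reverse peak.
    """
    if reverse.chrom != forward.chrom:
        return None
    if forward.start < reverse.end and reverse.start < forward.end:
        return 0
    if forward.start >= reverse.end:
        return forward.start - reverse.end
    return -(reverse.start - forward.end)


def pair_strand_peaks(
    reverse_peaks: Sequence[StrandedPeak],
    forward_peaks: Sequence[StrandedPeak],
    max_pair_gap: int = 150,
) -> list[DSBCluster]:
    """Pair each reverse peak with its closest admissible forward peak.

    Admissible pairs satisfy 0 <= d < max_pair_gap where d is the signed
    reverse-to-forward distance (overlap counts as 0).  Matching is
    one-to-one and greedy over ascending (d, forward start, reverse start):
    each peak supports at most one cluster, smaller gaps win conflicts.
    Negative distances (forward peak left of the reverse peak) are discarded,
    as are gaps at or beyond the cutoff.
    """
    by_chrom: dict[str, tuple[list[StrandedPeak], list[StrandedPeak]]] = {}
    for p in reverse_peaks:
        by_chrom.setdefault(p.chrom, ([], []))[0].append(p)
    for p in forward_peaks:
        by_chrom.setdefault(p.chrom, ([], []))[1].append(p)

    clusters: list[DSBCluster] = []
    for chrom in sorted(by_chrom):
        revs, fwds = by_chrom[chrom]
        if not revs or not fwds:
            continue
        fwds_sorted = sorted(fwds, key=lambda p: (p.start, p.end))
        f_starts = np.array([p.start for p in fwds_sorted], dtype=np.int64)
        f_ends = np.array([p.end for p in fwds_sorted], dtype=np.int64)
        candidates: list[tuple[int, int, int, int]] = []  # (d, f_start, r_start, indices)
        pairs: list[tuple[int, StrandedPeak, StrandedPeak]] = []
        for r in revs:
            # forward peaks overlapping r or starting within [r.end, r.end + gap)
            lo = int(np.searchsorted(f_ends, r.start, side="right"))
            hi = int(np.searchsorted(f_starts, r.end + max_pair_gap, side="left"))
            for j in range(lo, hi):
                d = pair_distance(r.interval, fwds_sorted[j].interval)
                if d is not None and 0 <= d < max_pair_gap:
                    pairs.append((d, r, fwds_sorted[j]))
        pairs.sort(key=lambda t: (t[0], t[2].start, t[2].end, t[1].start, t[1].end))
        used_r: set[int] = set()
        used_f: set[int] = set()
        for d, r, f in pairs:
            if id(r) in used_r or id(f) in used_f:
                continue
            used_r.add(id(r))
            used_f.add(id(f))
            support = frozenset(x for x in (r.replicate,) if x is not None)
            clusters.append(
                DSBCluster(
                    interval=GenomicInterval(chrom, r.start, f.end),
                    reverse_peak=r,
                    forward_peak=f,
                    gap=d,
                    replicate_support=support,
                )
            )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    return clusters


def consensus_clusters(
    clusters_rep1: Sequence[DSBCluster], clusters_rep2: Sequence[DSBCluster]
) -> list[DSBCluster]:
    """Union-merge of overlap groups containing clusters from both replicates."""
    all_ivs = [c.interval for c in clusters_rep1] + [c.interval for c in clusters_rep2]
    n1 = len(clusters_rep1)
    out = []
    for span, members in overlap_groups(all_ivs):
        has1 = any(i < n1 for i in members)
        has2 = any(i >= n1 for i in members)
        if has1 and has2:
            out.append(
                DSBCluster(interval=span, replicate_support=frozenset({1, 2}))
            )
    return out


def classify_dsb_kinetics(
    enriched_t10: Sequence[GenomicInterval],
    enriched_t20: Sequence[GenomicInterval],
    universe: Optional[Sequence[GenomicInterval]] = None,
) -> dict[str, list[GenomicInterval]]:
    """Assign persistent / transient / late classes to enriched clusters.

    persistent: enriched at both timepoints; transient: 10-min only; late:
    20-min only.  Any transient cluster overlapping a late cluster is
    promoted (with that late cluster) to persistent.  Overlapping clusters
    within each final class are merged.  Universe clusters enriched in
    neither contrast are returned under ``unclassified``.
    """
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    set10 = {key(iv) for iv in enriched_t10}
    set20 = {key(iv) for iv in enriched_t20}
    by_key = {key(iv): iv for iv in list(enriched_t10) + list(enriched_t20)}

    persistent = [by_key[k] for k in sorted(set10 & set20)]
    transient = [by_key[k] for k in sorted(set10 - set20)]
    late = [by_key[k] for k in sorted(set20 - set10)]

    # promotion: transient clusters overlapping late clusters become persistent
    if transient and late:
        t_flags = any_overlap_flags(transient, late)
        l_flags = any_overlap_flags(late, transient)
        persistent += [iv for iv, f in zip(transient, t_flags) if f]
        persistent += [iv for iv, f in zip(late, l_flags) if f]
        transient = [iv for iv, f in zip(transient, t_flags) if not f]
        late = [iv for iv, f in zip(late, l_flags) if not f]

    result = {
        "persistent": merge_overlapping(persistent),
        "transient": merge_overlapping(transient),
        "late": merge_overlapping(late),
    }
    if universe is not None:
        enriched_keys = set10 | set20
        result["unclassified"] = [iv for iv in universe if key(iv) not in enriched_keys]
    else:
        result["unclassified"] = []
    return result


def detect_sedsb(
    forward_peaks: Sequence[StrandedPeak],
    reverse_peaks: Sequence[StrandedPeak],
    forward_counts: Optional[Sequence[float]] = None,
    reverse_counts: Optional[Sequence[float]] = None,
    max_pair_gap: int = 150,
) -> list[SoloPeak]:
    """Solitary-peak detection for single-ended break candidates.

    A peak is solitary when its distance to the nearest opposite-strand peak
    strictly exceeds ``max_pair_gap`` (or no opposite-strand peak exists on
    the chromosome).  Per strand, an inter-quartile outlier filter on the
    supplied (normalized) counts then retains only peaks whose count lies in
    [Q1, Q3] inclusive (linear-interpolation quantiles); with fewer than 4
    solitary peaks on a strand the filter is skipped with a warning.
    """
    out: list[SoloPeak] = []
    for peaks, counts, opposite in (
        (forward_peaks, forward_counts, reverse_peaks),
        (reverse_peaks, reverse_counts, forward_peaks),
    ):
        if not peaks:
            continue
        dists = nearest_distance([p.interval for p in peaks], [o.interval for o in opposite])
        dists = np.where(np.isnan(dists), np.inf, dists)
        solo = [
            SoloPeak(
                peak=p,
                nearest_opposite_distance=float(d),
                count=None if counts is None else float(counts[i]),
            )
            for i, (p, d) in enumerate(zip(peaks, dists))
            if d > max_pair_gap
        ]
        if counts is not None and solo:
            values = np.array([s.count for s in solo])
            if len(solo) < 4:
                warnings.warn(
                    "fewer than 4 solitary peaks on a strand: inter-quartile "
                    "filter skipped, all peaks retained"
                )
            else:
                q1, q3 = np.percentile(values, [25, 75])
                solo = [s for s in solo if q1 <= s.count <= q3]
        out.extend(solo)
    out.sort(key=lambda s: (s.peak.chrom, s.peak.start, s.peak.end, s.peak.strand))
    return out
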