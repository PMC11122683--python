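"""Spike-in normalization, moderated differential testing, and kinetic classes.

Normalization follows the spike-in recipe: per library a raw spike factor
``f`` (on-target spike reads / total quality-filtered reads for END-seq, the
spike read fraction for DRIP) is rescaled by the experiment minimum to give
``s`` (min over libraries is exactly 1) and combined with a median-ratio
library-size factor ``l = median(total_reads) / total_reads``.  Counts are
corrected by dividing by ``s`` and multiplying by ``l``: a library with
higher spike recovery or deeper sequencing is deflated.  The product
``s * l`` is also reported per library as the combined factor.

Differential testing is a moderated two-sample t-test on log2 normalized
counts: the per-region pooled variance is shrunk toward the median variance
across regions with prior degrees of freedom d0 (default 4), a deliberately
lightweight stand-in for full empirical-Bayes variance moderation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CountMatrix,
    GenomicInterval,
    LibraryInfo,
    NormalizationError,
    ValidationError,
)
from .interval_ops import overlap_groups

__all__ = [
    "ScaleFactorSet",
    "RLoopPeak",
    "count_fragments",
    "count_reads",
    "endseq_scale_factors",
    "drip_scale_factors",
    "moderated_test",
    "dsb_enriched",
    "rnaseh_filter",
    "consensus_regions",
    "classify_rloop_kinetics",
    "RLOOP_CATEGORIES",
]

RLOOP_CATEGORIES = (
    "stable_gain",
    "stable_loss",
    "transient_gain",
    "transient_loss",
    "late_gain",
    "late_loss",
    "no_change",
)
#: reported separately, never counted among the seven kinetic categories
DISCORDANT = "discordant"


@dataclass
class ScaleFactorSet:
    """Per-library normalization factors.

    f      raw spike factor (RiP/RQC for END-seq, spike fraction for DRIP)
    s      f rescaled by the experiment minimum (min over libraries == 1)
    l      library-size factor median(total_reads)/total_reads
    final  combined factor s * l

    ``normalize`` applies counts * l / s.
    """

    library_ids: list[str]
    f: np.ndarray
    s: np.ndarray
    l: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.s * self.l

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_id": self.library_ids,
                "f": self.f,
                "s": self.s,
                "l": self.l,
                "final": self.final,
            }
        )

    def normalize(self, counts: np.ndarray) -> np.ndarray:
        """Depth- and spike-corrected counts: raw * l / s per library column."""
        counts = np.asarray(counts, dtype=float)
        return counts * (self.l / self.s)[np.newaxis, :]


@dataclass
class RLoopPeak:
    """Consensus hybrid peak with per-contrast differential results and category."""

    interval: GenomicInterval
    category: str
    log2fc_5: float
    p_5: float
    log2fc_60: float
    p_60: float
    rnaseh_pass: bool = True


def count_fragments(
    regions: Sequence[GenomicInterval], fragments: Sequence[GenomicInterval]
) -> np.ndarray:
    """Number of fragments overlapping each region by >= 1 bp.

    A fragment spanning two regions is counted in both.
    """
    per_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for f in fragments:
        tmp.setdefault(f.chrom, []).append((f.start, f.end))
    for chrom, spans in tmp.items():
        starts = np.sort(np.array([s for s, _ in spans], dtype=np.int64))
        ends = np.sort(np.array([e for _, e in spans], dtype=np.int64))
        per_chrom[chrom] = (starts, ends)
    out = np.zeros(len(regions), dtype=np.int64)
    for i, r in enumerate(regions):
        if r.chrom not in per_chrom:
            continue
        starts, ends = per_chrom[r.chrom]
        n = len(starts)
        n_right = n - int(np.searchsorted(starts, r.end, side="left"))  # start >= end
        n_left = int(np.searchsorted(ends, r.start, side="right"))  # end <= start
        out[i] = n - n_right - n_left
    return out


def count_reads(
    regions: Sequence[GenomicInterval],
    fragments_by_library: dict[str, Sequence[GenomicInterval]],
    libraries: Sequence[LibraryInfo],
) -> CountMatrix:
    """Build a CountMatrix by overlap-counting fragments per library."""
    counts = np.zeros((len(regions), len(libraries)), dtype=np.int64)
    for j, lib in enumerate(libraries):
        counts[:, j] = count_fragments(regions, fragments_by_library[lib.library_id])
    return CountMatrix(regions=list(regions), libraries=list(libraries), counts=counts)


def _scale_factors(library_ids, f, totals) -> ScaleFactorSet:
    f = np.asarray(f, dtype=float)
    totals = np.asarray(totals, dtype=float)
    s = f / f.min()
    l = np.median(totals) / totals
    return ScaleFactorSet(library_ids=list(library_ids), f=f, s=s, l=l)


def endseq_scale_factors(libraries: Sequence[LibraryInfo]) -> ScaleFactorSet:
    """Spike factors from on-target spike reads (RiP) over total reads (RQC)."""
    rip = np.array(
        [lib.spike_on_target_reads if lib.spike_on_target_reads is not None else 0 for lib in libraries],
        dtype=float,
    )
    rqc = np.array([lib.total_reads for lib in libraries], dtype=float)
    if np.all(rip == 0):
        raise NormalizationError("spike-in absent: all libraries have zero on-target spike reads")
    if np.any(rip == 0):
        raise NormalizationError(
            "a library has zero on-target spike reads; its spike factor is undefined"
        )
    return _scale_factors([lib.library_id for lib in libraries], rip / rqc, rqc)


def drip_scale_factors(libraries: Sequence[LibraryInfo]) -> ScaleFactorSet:
    """Spike factors from the per-library spike read fraction."""
    fracs = []
    for lib in libraries:
        if lib.spike_fraction is None:
            raise NormalizationError(f"library {lib.library_id!r} has no spike_fraction")
        fracs.append(lib.spike_fraction)
    totals = [lib.total_reads for lib in libraries]
    return _scale_factors([lib.library_id for lib in libraries], fracs, totals)


def moderated_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    d0: float = 4.0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-sample t-test on log2(normalized count + pseudocount).

    Per region: log2FC = mean(log2 A) - mean(log2 B); the pooled within-group
    variance s^2 (on d = nA + nB - 2 df) is shrunk toward the median pooled
    variance s0^2 across regions: s~^2 = (d0*s0^2 + d*s^2) / (d0 + d).  The
    statistic t = log2FC / (s~ * sqrt(1/nA + 1/nB)) is referred to a
    t-distribution with d0 + d degrees of freedom (two-sided).

    Arrays are (n_regions, n_replicates); at least 2 replicates per group.
    Returns a DataFrame with columns log2fc, t, p, s2, s2_moderated.
    """
    a = np.log2(np.asarray(group_a, dtype=float) + pseudocount)
    b = np.log2(np.asarray(group_b, dtype=float) + pseudocount)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("moderated_test requires >= 2 replicates per group")
    n_a, n_b = a.shape[1], b.shape[1]
    d = n_a + n_b - 2
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / d
    s0_2 = float(np.median(s2))
    if s0_2 <= 0:
        warnings.warn("all-region pooled variance is zero; applying 1e-8 floor")
        s0_2 = 1e-8
    s2_mod = (d0 * s0_2 + d * s2) / (d0 + d)
    se = np.sqrt(s2_mod * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=d0 + d)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "s2": s2, "s2_moderated": s2_mod}
    )


def dsb_enriched(
    result: pd.DataFrame, log2fc_threshold: float = 1.0, p_threshold: float = 0.05
) -> pd.DataFrame:
    """Apply the DSB differential gate: |log2FC| > threshold and p < threshold.

    Adds boolean ``enriched`` (positive direction), ``depleted`` and
    ``differential`` columns.
    """
    out = result.copy()
    sig = (out["log2fc"].abs() > log2fc_threshold) & (out["p"] < p_threshold)
    out["differential"] = sig
    out["enriched"] = sig & (out["log2fc"] > 0)
    out["depleted"] = sig & (out["log2fc"] < 0)
    return out


def rnaseh_filter(
    ip_counts: np.ndarray,
    rnaseh_counts: np.ndarray,
    d0: float = 4.0,
    pseudocount: float = 0.5,
    log2fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> np.ndarray:
    """True-positive hybrid-region flags: IP enrichment over the RNase H control.

    A region passes when the moderated test of IP vs RNase H-treated
    libraries shows log2FC above the threshold at p below the gate.
    """
    res = moderated_test(ip_counts, rnaseh_counts, d0=d0, pseudocount=pseudocount)
    return ((res["log2fc"] > log2fc_threshold) & (res["p"] < p_threshold)).to_numpy()


def consensus_regions(
    peaks_by_condition: dict[str, dict[int, Sequence[GenomicInterval]]],
) -> list[GenomicInterval]:
    """Replicate-consensus region universe.

    A region enters the universe iff, in at least one condition, a
    replicate-1 peak and a replicate-2 peak overlap by >= 1 bp; the emitted
    region is the union-merge of the whole transitive overlap group across
    all conditions and replicates.
    """
    all_peaks: list[GenomicInterval] = []
    labels: list[tuple[str, int]] = []
    for cond, reps in peaks_by_condition.items():
        for rep, peaks in reps.items():
            for p in peaks:
                all_peaks.append(p)
                labels.append((cond, rep))
    universe: list[GenomicInterval] = []
    for span, members in overlap_groups(all_peaks):
        if _group_has_replicated_condition(all_peaks, labels, members):
            universe.append(span)
    return universe


def _group_has_replicated_condition(peaks, labels, members) -> bool:
    by_cond: dict[str, dict[int, list[GenomicInterval]]] = {}
    for i in members:
        cond, rep = labels[i]
        by_cond.setdefault(cond, {}).setdefault(rep, []).append(peaks[i])
    for reps in by_cond.values():
        rep_ids = sorted(reps)
        for i, r1 in enumerate(rep_ids):
            for r2 in rep_ids[i + 1 :]:
                for p in reps[r1]:
                    for q in reps[r2]:
                        if p.overlaps(q):
                            return True
    return False


def classify_rloop_kinetics(
    diff5: pd.DataFrame, diff60: pd.DataFrame, rloop_p: float = 0.01
) -> np.ndarray:
    """Seven-category kinetic classification of hybrid peaks.

    Per contrast a region is up/down/ns at p < rloop_p with the sign of
    log2FC.  (up,up) stable_gain; (down,down) stable_loss; (up,ns)
    transient_gain; (down,ns) transient_loss; (ns,up) late_gain; (ns,down)
    late_loss; (ns,ns) no_change; opposite-sign calls are reported as
    ``discordant`` and never counted among the seven categories.
    """
    if len(diff5) != len(diff60):
        raise ValidationError("contrasts cover different region universes")

    def state(df: pd.DataFrame) -> np.ndarray:
        sig = df["p"].to_numpy() < rloop_p
        up = sig & (df["log2fc"].to_numpy() > 0)
        down = sig & (df["log2fc"].to_numpy() < 0)
        out = np.full(len(df), "ns", dtype=object)
        out[up] = "up"
        out[down] = "down"
        return out

    s5, s60 = state(diff5), state(diff60)
    mapping = {
        ("up", "up"): "stable_gain",
        ("down", "down"): "stable_loss",
        ("up", "ns"): "transient_gain",
        ("down", "ns"): "transient_loss",
        ("ns", "up"): "late_gain",
        ("ns", "down"): "late_loss",
        ("ns", "ns"): "no_change",
        ("up", "down"): DISCORDANT,
        ("down", "up"): DISCORDANT,
    }
    return np.array([mapping[(a, b)] for a, b in zip(s5, s60)], dtype=object)
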