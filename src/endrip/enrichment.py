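"""Randomization overlap enrichment, gene-feature annotation, metaprofiles.

Enrichment of a query interval set in a feature set is measured against a
length- and chromosome-preserving randomization null: each query interval is
re-placed uniformly on its own chromosome, the overlap count is averaged
over shuffles, and the observed count is referred to a binomial tail with
per-interval success probability estimated from the randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeSpec, GenomicInterval, ValidationError
from .interval_ops import any_overlap_flags, nearest_distance
from .io import SignalTrack

__all__ = [
    "EnrichmentResult",
    "FeatureAnnotation",
    "GeneModel",
    "shuffle_intervals",
    "overlap_enrichment",
    "annotate_gene_feature",
    "annotate_gene_features",
    "nearest_feature_distance",
    "metaprofile",
]


@dataclass
class EnrichmentResult:
    """Observed vs shuffle-expected overlap of a query class with a feature set."""

    query_name: str
    feature_name: str
    n_query: int
    observed: int
    expected: float
    log2fc: float
    p: float
    direction: str  # "enriched" | "depleted"

    def as_row(self) -> dict:
        return {
            "query": self.query_name,
            "features": self.feature_name,
            "n_query": self.n_query,
            "observed": self.observed,
            "expected": self.expected,
            "log2fc": self.log2fc,
            "p": self.p,
            "neg_log10_p": float(-np.log10(self.p)),
            "direction": self.direction,
        }


@dataclass
class FeatureAnnotation:
    peak_id: Optional[str]
    category: str  # promoter | gene_body | terminator | intergenic
    gene_id: Optional[str]


@dataclass(frozen=True)
class GeneModel:
    """Minimal strand-aware gene model with UTR and exon spans.

    ``start``/``end`` bound the transcribed unit; the TSS is ``start`` for +
    genes and ``end`` for - genes (as a half-open boundary), the TES the
    opposite end.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


def shuffle_intervals(
    query: Sequence[GenomicInterval],
    genome: GenomeSpec,
    rng: Union[int, np.random.Generator],
) -> list[GenomicInterval]:
    """Uniform re-placement of each interval on its own chromosome.

    Lengths and per-chromosome counts are preserved exactly; shuffled
    intervals may overlap each other.
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = []
    for iv in query:
        chrom_len = genome.length_of(iv.chrom)
        if iv.width > chrom_len:
            raise ValidationError(
                f"interval of length {iv.width} exceeds chromosome {iv.chrom} ({chrom_len} bp)"
            )
        start = int(gen.integers(0, chrom_len - iv.width + 1))
        out.append(GenomicInterval(iv.chrom, start, start + iv.width, name=iv.name))
    return out


def overlap_enrichment(
    query: Sequence[GenomicInterval],
    features: Sequence[GenomicInterval],
    genome: GenomeSpec,
    n_shuffles: int = 100,
    rng: Union[int, np.random.Generator] = 0,
    query_name: str = "query",
    feature_name: str = "features",
) -> EnrichmentResult:
    """Randomization-based overlap enrichment with a binomial tail test.

    observed k = number of query intervals overlapping >= 1 feature by >= 1
    bp; expected = mean of the same count over ``n_shuffles`` uniform
    re-placements.  The per-interval success probability is estimated as
    expected/n (clamped away from 0 and 1 by half a shuffle resolution) and
    k is referred to the upper binomial tail when k >= expected, the lower
    tail otherwise.  log2FC = log2((k + 0.5) / (expected + 0.5)).
    """
    n = len(query)
    if n < 1:
        raise ValidationError("overlap_enrichment requires at least one query interval")
    if n_shuffles < 1:
        raise ValidationError("n_shuffles must be >= 1")
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    observed = int(any_overlap_flags(query, features).sum())
    shuffle_counts = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        placed = shuffle_intervals(query, genome, gen)
        shuffle_counts[i] = int(any_overlap_flags(placed, features).sum())
    expected = float(shuffle_counts.mean())

    # the moment estimate expected/n is clamped away from the degenerate
    # boundary of the tail being tested, so a finite number of shuffles can
    # never claim infinite significance
    floor = 1.0 / (2.0 * n * n_shuffles)
    if observed >= expected:
        p_hat = float(min(max(expected / n, floor), 1.0))
        p = float(stats.binom.sf(observed - 1, n, p_hat))
        direction = "enriched"
    else:
        p_hat = float(max(min(expected / n, 1.0 - floor), 0.0))
        p = float(stats.binom.cdf(observed, n, p_hat))
        direction = "depleted"
    log2fc = float(np.log2((observed + 0.5) / (expected + 0.5)))
    return EnrichmentResult(
        query_name=query_name,
        feature_name=feature_name,
        n_query=n,
        observed=observed,
        expected=expected,
        log2fc=log2fc,
        p=p,
        direction=direction,
    )


def _gene_windows(
    genes: Sequence[GeneModel], promoter_upstream: int, downstream: int
) -> dict[str, list[tuple[GenomicInterval, str]]]:
    windows: dict[str, list[tuple[GenomicInterval, str]]] = {
        "promoter": [],
        "terminator": [],
        "gene_body": [],
    }
    for g in genes:
        if g.strand == "+":
            prom = (max(0, g.tss - promoter_upstream), g.tss)
            term = (g.tes, g.tes + downstream)
        else:
            prom = (g.tss, g.tss + promoter_upstream)
            term = (max(0, g.tes - downstream), g.tes)
        spans = {"promoter": [prom], "terminator": [term], "gene_body": [(g.start, g.end)]}
        if g.utr5 is not None:
            spans["promoter"].append(g.utr5)
        if g.utr3 is not None:
            spans["terminator"].append(g.utr3)
        for cat, ss in spans.items():
            for s, e in ss:
                if e > s:
                    windows[cat].append((GenomicInterval(g.chrom, s, e), g.gene_id))
    return windows


def annotate_gene_features(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 10000,
    downstream: int = 10000,
) -> list[FeatureAnnotation]:
    """Assign each peak exactly one gene-feature category by its midpoint.

    promoter: up to ``promoter_upstream`` bp upstream of the TSS plus the
    5'UTR; terminator: 3'UTR plus ``downstream`` bp past the TES; gene_body:
    the remaining transcribed unit (exons and introns).  Priority promoter >
    terminator > gene_body > intergenic.
    """
    windows = _gene_windows(genes, promoter_upstream, downstream)
    lookup: dict[str, dict[str, list[tuple[int, int, str]]]] = {}
    for cat, items in windows.items():
        for iv, gid in items:
            lookup.setdefault(iv.chrom, {}).setdefault(cat, []).append((iv.start, iv.end, gid))
    out = []
    for peak in peaks:
        mid = peak.midpoint
        category, gene_id = "intergenic", None
        per_chrom = lookup.get(peak.chrom, {})
        for cat in ("promoter", "terminator", "gene_body"):
            hit = next(
                (gid for s, e, gid in per_chrom.get(cat, []) if s <= mid < e), None
            )
            if hit is not None:
                category, gene_id = cat, hit
                break
        out.append(FeatureAnnotation(peak_id=peak.name, category=category, gene_id=gene_id))
    return out


def annotate_gene_feature(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_upstream: int = 10000,
    downstream: int = 10000,
) -> FeatureAnnotation:
    return annotate_gene_features([peak], genes, promoter_upstream, downstream)[0]


def nearest_feature_distance(
    peaks: Sequence[GenomicInterval], features: Sequence[GenomicInterval]
) -> np.ndarray:
    """Unsigned bp gap to the nearest same-chromosome feature (0 on overlap,
    NaN when the peak's chromosome carries no feature)."""
    if not features:
        raise ValidationError("nearest_feature_distance requires a non-empty feature set")
    return nearest_distance(peaks, features)


def metaprofile(
    track: SignalTrack,
    regions: Sequence[GenomicInterval],
    half_window: int = 3000,
    n_bins: int = 100,
    genome: Optional[GenomeSpec] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference-point profile around region centers.

    For each region the window [c - half_window, c + half_window) around the
    center c = floor((start+end)/2) is cut into ``n_bins`` equal-width bins
    and the mean track value per bin is computed.  Bins extending past a
    chromosome edge (when a genome is bound) are masked as NaN.  Returns
    (per-bin column means over regions, the full regions x bins matrix).
    """
    if not regions:
        raise ValidationError("metaprofile requires at least one region")
    width = 2.0 * half_window / n_bins
    matrix = np.full((len(regions), n_bins), np.nan)
    any_on = False
    for i, r in enumerate(regions):
        c = r.midpoint
        edges = c - half_window + width * np.arange(n_bins + 1)
        lo, hi = edges[:-1], edges[1:]
        vals = track.integral(r.chrom, lo, hi) / width
        if genome is not None:
            if r.chrom not in genome:
                continue
            length = genome.length_of(r.chrom)
            mask = (lo >= 0) & (hi <= length)
            vals = np.where(mask, vals, np.nan)
        matrix[i] = vals
        any_on = True
    if genome is not None and not any_on:
        raise ValidationError("all regions lie on chromosomes absent from the genome")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", category=RuntimeWarning)
        profile = np.nanmean(matrix, axis=0)
    return profile, matrix
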