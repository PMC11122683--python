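"""End-to-end stage drivers over an on-disk dataset.

These functions wire the stages together exactly as the CLI subcommands and
the numbered analysis scripts run them: peak pairing -> replicate consensus
-> spike-in normalization -> moderated differential tests -> kinetic
classes, and the DRIP branch with the RNase H true-positive filter and the
seven-category classifier.  Every stage logs input -> output counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    MissingDataError,
    GenomeSpec,
    GenomicInterval,
    LibraryInfo,
    ThresholdConfig,
    ValidationError,
)
from .differential import (
    classify_rloop_kinetics,
    consensus_regions,
    drip_scale_factors,
    dsb_enriched,
    endseq_scale_factors,
    moderated_test,
    rnaseh_filter,
)
from .dsb import (
    DSBCluster,
    SoloPeak,
    classify_dsb_kinetics,
    consensus_clusters,
    detect_sedsb,
    pair_strand_peaks,
)
from .interval_ops import merge_overlapping, overlap_groups
from .io import read_count_matrix, read_genome, read_intervals, read_library_table

logger = logging.getLogger("endrip")

__all__ = [
    "DSBAnalysis",
    "RLoopAnalysis",
    "aggregate_counts",
    "run_dsb_analysis",
    "run_rloop_analysis",
]

ENDSEQ_TREATED = ("T10", "T20")
DRIP_TREATED = ("T5", "T60")


def aggregate_counts(
    matrix: CountMatrix, regions: Sequence[GenomicInterval]
) -> CountMatrix:
    """Re-key a count matrix onto a new region universe by overlap.

    Each output region receives the summed counts of all matrix regions it
    overlaps by >= 1 bp (a matrix region overlapping two output regions
    contributes to both).
    """
    out = np.zeros((len(regions), len(matrix.libraries)), dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(matrix.regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    for c in by_chrom.values():
        c.sort()
    for j, region in enumerate(regions):
        for s, e, i in by_chrom.get(region.chrom, []):
            if s >= region.end:
                break
            if e > region.start:
                out[j] += matrix.counts[i]
    return CountMatrix(regions=list(regions), libraries=matrix.libraries, counts=out)


@dataclass
class DSBAnalysis:
    universe: list[GenomicInterval]
    classes: dict[str, list[GenomicInterval]]
    diff_t10: pd.DataFrame
    diff_t20: pd.DataFrame
    scale_factors: pd.DataFrame
    sedsb: list[SoloPeak]
    sedsb_persistent: list[SoloPeak]
    per_condition_clusters: dict[str, list[DSBCluster]]
    discarded_pairs: pd.DataFrame


def _read_strand_peaks(dataset: Path, cond: str, rep: int):
    rev = read_intervals(dataset / "peaks" / f"endseq_{cond}_rep{rep}_rev.bed", expect_strand=True, replicate=rep)
    fwd = read_intervals(dataset / "peaks" / f"endseq_{cond}_rep{rep}_fwd.bed", expect_strand=True, replicate=rep)
    return rev, fwd


def run_dsb_analysis(
    dataset_dir,
    thresholds: Optional[ThresholdConfig] = None,
    replicates: int = 2,
) -> DSBAnalysis:
    """Strand-paired DSB cluster calling with kinetic classification.

    Per treated condition and replicate, reverse/forward peaks are paired
    (gap < max_pair_gap), replicate-consensus clusters are merged into a
    cluster universe, counts are normalized by spike-in and library size,
    each treated condition is tested against the untreated control, and
    enriched clusters are classified persistent / transient / late.
    Solitary peaks are screened as single-ended break candidates.
    """
    cfg = thresholds or ThresholdConfig()
    dataset = Path(dataset_dir)
    if replicates < 2:
        raise ValidationError("replicate consensus requires at least 2 replicates")

    libs = read_library_table(dataset / "libraries_endseq.tsv")
    matrix = read_count_matrix(dataset / "counts_endseq.tsv", libs)

    per_condition: dict[str, list[DSBCluster]] = {}
    discarded_rows = []
    strand_peaks: dict[tuple[str, int, str], list] = {}
    for cond in ENDSEQ_TREATED:
        per_rep = []
        for rep in range(1, replicates + 1):
            rev, fwd = _read_strand_peaks(dataset, cond, rep)
            strand_peaks[(cond, rep, "rev")] = rev
            strand_peaks[(cond, rep, "fwd")] = fwd
            clusters = pair_strand_peaks(rev, fwd, cfg.max_pair_gap)
            paired_rev = {id(c.reverse_peak) for c in clusters}
            for r in rev:
                if id(r) not in paired_rev:
                    discarded_rows.append(
                        {
                            "condition": cond,
                            "replicate": rep,
                            "chrom": r.chrom,
                            "start": r.start,
                            "end": r.end,
                            "reason": "no admissible forward peak within gap",
                        }
                    )
            logger.info(
                "pairing %s rep%d: %d reverse + %d forward peaks -> %d clusters",
                cond, rep, len(rev), len(fwd), len(clusters),
            )
            per_rep.append(clusters)
        cons = consensus_clusters(per_rep[0], per_rep[1])
        logger.info("consensus %s: %d clusters", cond, len(cons))
        per_condition[cond] = cons

    universe = merge_overlapping(
        [c.interval for cond in ENDSEQ_TREATED for c in per_condition[cond]]
    )
    logger.info("cluster universe: %d regions", len(universe))

    factors = endseq_scale_factors(libs)
    agg = aggregate_counts(matrix, universe)
    normalized = factors.normalize(agg.counts)

    def _cols(cond):
        return agg.columns_for(condition=cond, role="IP")

    diffs = {}
    enriched = {}
    for cond in ENDSEQ_TREATED:
        res = moderated_test(
            normalized[:, _cols(cond)],
            normalized[:, _cols("NT")],
            d0=cfg.moderation_df,
            pseudocount=cfg.pseudocount,
        )
        res = dsb_enriched(res, cfg.dsb_log2fc, cfg.dsb_p)
        diffs[cond] = res
        enriched[cond] = [universe[i] for i in np.flatnonzero(res["enriched"].to_numpy())]
        logger.info(
            "differential %s vs NT: %d/%d enriched", cond, len(enriched[cond]), len(universe)
        )

    classes = classify_dsb_kinetics(enriched["T10"], enriched["T20"], universe=universe)
    logger.info(
        "kinetic classes: %s",
        {k: len(v) for k, v in classes.items()},
    )

    # ---- single-ended DSB branch ----
    strand_universe = {}
    for strand in ("fwd", "rev"):
        per_cond_merged = []
        for cond in ENDSEQ_TREATED:
            reps = [
                [p.interval for p in strand_peaks[(cond, rep, strand)]]
                for rep in range(1, replicates + 1)
            ]
            groups = overlap_groups(reps[0] + reps[1])
            n1 = len(reps[0])
            for span, members in groups:
                if any(i < n1 for i in members) and any(i >= n1 for i in members):
                    per_cond_merged.append(span)
        strand_universe[strand] = merge_overlapping(per_cond_merged)

    from .core import FORWARD, REVERSE, StrandedPeak

    fwd_cons = [StrandedPeak(iv, FORWARD) for iv in strand_universe["fwd"]]
    rev_cons = [StrandedPeak(iv, REVERSE) for iv in strand_universe["rev"]]
    f_counts = aggregate_counts(matrix, strand_universe["fwd"])
    r_counts = aggregate_counts(matrix, strand_universe["rev"])
    f_norm = factors.normalize(f_counts.counts).mean(axis=1)
    r_norm = factors.normalize(r_counts.counts).mean(axis=1)
    solo = detect_sedsb(
        fwd_cons, rev_cons, f_norm, r_norm, max_pair_gap=cfg.max_pair_gap
    )
    logger.info("solitary peaks after distance + quartile filters: %d", len(solo))

    sedsb_persistent = []
    if solo:
        solo_regions = [s.peak.interval for s in solo]
        solo_counts = aggregate_counts(matrix, solo_regions)
        solo_norm = factors.normalize(solo_counts.counts)
        flags = {}
        for cond in ENDSEQ_TREATED:
            res = moderated_test(
                solo_norm[:, solo_counts.columns_for(condition=cond, role="IP")],
                solo_norm[:, solo_counts.columns_for(condition="NT", role="IP")],
                d0=cfg.moderation_df,
                pseudocount=cfg.pseudocount,
            )
            res = dsb_enriched(res, cfg.dsb_log2fc, cfg.dsb_p)
            flags[cond] = res["enriched"].to_numpy()
            for s, e in zip(solo, flags[cond]):
                s.enriched[cond] = bool(e)
        persistent_mask = flags["T10"] & flags["T20"]
        sedsb_persistent = [s for s, m in zip(solo, persistent_mask) if m]
    logger.info("persistent seDSB candidates: %d", len(sedsb_persistent))

    return DSBAnalysis(
        universe=universe,
        classes=classes,
        diff_t10=diffs["T10"],
        diff_t20=diffs["T20"],
        scale_factors=factors.as_frame(),
        sedsb=solo,
        sedsb_persistent=sedsb_persistent,
        per_condition_clusters=per_condition,
        discarded_pairs=pd.DataFrame(
            discarded_rows,
            columns=["condition", "replicate", "chrom", "start", "end", "reason"],
        ),
    )


@dataclass
class RLoopAnalysis:
    universe: list[GenomicInterval]
    rnaseh_pass: np.ndarray
    kept: list[GenomicInterval]
    diff5: pd.DataFrame
    diff60: pd.DataFrame
    categories: np.ndarray
    scale_factors: pd.DataFrame
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_rloop_analysis(
    dataset_dir,
    thresholds: Optional[ThresholdConfig] = None,
    replicates: int = 2,
) -> RLoopAnalysis:
    """DRIP branch: consensus universe, RNase H filter, seven kinetic classes."""
    cfg = thresholds or ThresholdConfig()
    dataset = Path(dataset_dir)
    libs = read_library_table(dataset / "libraries_drip.tsv")
    matrix = read_count_matrix(dataset / "counts_drip.tsv", libs)

    conditions = sorted({lib.condition for lib in libs if lib.role == "IP"})
    if "NT" not in conditions:
        raise MissingDataError("DRIP analysis requires an untreated (NT) condition")
    peaks_by_condition = {}
    for cond in conditions:
        peaks_by_condition[cond] = {
            rep: read_intervals(dataset / "peaks" / f"drip_{cond}_rep{rep}.bed")
            for rep in range(1, replicates + 1)
        }
    universe = consensus_regions(peaks_by_condition)
    logger.info("DRIP consensus universe: %d regions", len(universe))

    factors = drip_scale_factors(libs)
    agg = aggregate_counts(matrix, universe)
    normalized = factors.normalize(agg.counts)

    nt_cols = agg.columns_for(condition="NT", role="IP")
    rh_cols = agg.columns_for(role="RNaseH")
    if rh_cols:
        passed = rnaseh_filter(
            normalized[:, nt_cols],
            normalized[:, rh_cols],
            d0=cfg.moderation_df,
            pseudocount=cfg.pseudocount,
        )
    else:
        warnings.warn(
            "no RNase H libraries found: true-positive filter SKIPPED, "
            "all consensus regions retained"
        )
        passed = np.ones(len(universe), dtype=bool)
    kept_idx = np.flatnonzero(passed)
    kept = [universe[i] for i in kept_idx]
    logger.info("RNase H filter: %d/%d regions pass", len(kept), len(universe))

    diffs = {}
    for cond in DRIP_TREATED:
        cols = agg.columns_for(condition=cond, role="IP")
        res = moderated_test(
            normalized[kept_idx][:, cols],
            normalized[kept_idx][:, nt_cols],
            d0=cfg.moderation_df,
            pseudocount=cfg.pseudocount,
        )
        diffs[cond] = res
    categories = classify_rloop_kinetics(diffs["T5"], diffs["T60"], rloop_p=cfg.rloop_p)
    counts = pd.Series(categories).value_counts().to_dict()
    logger.info("kinetic categories: %s", counts)

    table = pd.DataFrame(
        {
            "chrom": [r.chrom for r in kept],
            "start": [r.start for r in kept],
            "end": [r.end for r in kept],
            "log2fc_5": diffs["T5"]["log2fc"].to_numpy(),
            "p_5": diffs["T5"]["p"].to_numpy(),
            "log2fc_60": diffs["T60"]["log2fc"].to_numpy(),
            "p_60": diffs["T60"]["p"].to_numpy(),
            "category": categories,
        }
    )
    return RLoopAnalysis(
        universe=universe,
        rnaseh_pass=passed,
        kept=kept,
        diff5=diffs["T5"],
        diff60=diffs["T60"],
        categories=categories,
        scale_factors=factors.as_frame(),
        table=table,
    )
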