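"""Synthetic END-seq / DRIP-seq study generator with planted ground truth.

The generator emulates the data structure of a two-timepoint topoisomerase-I
poison study on a small genome: double-ended breaks appear as a reverse-
strand peak closely followed by a forward-strand peak (gap below the pairing
cutoff), single-ended breaks as solitary one-strand peaks, and hybrid (R-loop)
peaks carry one of seven planted kinetic categories across untreated / early /
late treatment conditions.  Read counts are negative-binomial around planted
per-condition means, libraries differ in depth (+-30% jitter) and spike-in
recovery, and RNase H control libraries sit at background for true hybrid
peaks but at IP level for planted decoy (false-positive) peaks.

Everything is drawn from one seeded generator; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    FORWARD,
    REVERSE,
    CountMatrix,
    GenerationError,
    GenomeSpec,
    GenomicInterval,
    LibraryInfo,
    StrandedPeak,
    ValidationError,
)
from .differential import RLOOP_CATEGORIES
from .enrichment import GeneModel
from .io import (
    SignalTrack,
    write_count_matrix,
    write_genome,
    write_intervals,
    write_library_table,
    write_signal_track,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "plant_kinetics",
    "simulate_dataset",
    "DSB_CLASSES",
    "ENDSEQ_CONDITIONS",
    "DRIP_CONDITIONS",
]

DSB_CLASSES = ("persistent", "transient", "late")
ENDSEQ_CONDITIONS = ("NT", "T10", "T20")
DRIP_CONDITIONS = ("NT", "T5", "T60")


def _default_genome() -> GenomeSpec:
    return GenomeSpec.from_lengths({f"chr{i}": 5_000_000 for i in (1, 2, 3)})


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults define the standard desk-scale study: a 3 x 5 Mbp genome, 300
    double-ended breaks split over the three kinetic classes, 30 single-ended
    breaks, 40 hybrid peaks per kinetic category plus ~10% decoys, planted
    effect size |log2FC| = 2, negative-binomial dispersion 0.05, two
    replicates, and a 1:1000 spike-in genome ratio.
    """

    genome: GenomeSpec = field(default_factory=_default_genome)
    n_genes: int = 60
    n_dedsb_per_class: dict = field(
        default_factory=lambda: {"persistent": 100, "transient": 100, "late": 100}
    )
    n_sedsb: int = 30
    n_rloop_per_category: dict = field(
        default_factory=lambda: {cat: 40 for cat in RLOOP_CATEGORIES}
    )
    decoy_fraction: float = 0.10  # fraction of the DRIP peak universe that is decoys
    # fraction of persistent breaks planted inside stable-gain hybrid peaks,
    # emulating the association between persistent DSB clusters and stable gains
    dsb_in_stable_gain_fraction: float = 0.6
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    baseline_mean: float = 100.0
    peak_width_range: tuple = (800, 2000)
    dsb_flank_peak_width: int = 300
    dsb_gap_range: tuple = (0, 140)  # inclusive bounds, must stay below max_pair_gap
    spike_ratio: float = 0.001
    replicates: int = 2
    total_reads_base: int = 20_000_000
    library_jitter: float = 0.30
    rnaseh_background_ratio: float = 0.1  # RNase H mean / IP mean at true hybrid peaks
    track_peak_fold: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (
            ("n_genes", self.n_genes),
            ("n_sedsb", self.n_sedsb),
        ):
            if v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(v < 0 for v in self.n_dedsb_per_class.values()):
            raise ValidationError("deDSB class counts must be >= 0")
        if any(v < 0 for v in self.n_rloop_per_category.values()):
            raise ValidationError("R-loop category counts must be >= 0")
        if set(self.n_dedsb_per_class) - set(DSB_CLASSES):
            raise ValidationError(f"unknown deDSB classes: {set(self.n_dedsb_per_class) - set(DSB_CLASSES)}")
        if set(self.n_rloop_per_category) - set(RLOOP_CATEGORIES):
            raise ValidationError(
                f"unknown R-loop categories: {set(self.n_rloop_per_category) - set(RLOOP_CATEGORIES)}"
            )
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        if not (0 <= self.dsb_gap_range[0] <= self.dsb_gap_range[1] < 150):
            raise ValidationError("dsb_gap_range must lie within [0, 150)")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not (0 <= self.decoy_fraction < 1):
            raise ValidationError("decoy_fraction must lie in [0, 1)")
        if not (0 <= self.dsb_in_stable_gain_fraction <= 1):
            raise ValidationError("dsb_in_stable_gain_fraction must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown simulation config keys: {sorted(bad)}")
        if "genome" in d and not isinstance(d["genome"], GenomeSpec):
            d["genome"] = GenomeSpec.from_lengths(d["genome"])
        for key in ("peak_width_range", "dsb_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted features: one row per feature with class label and planted
    log2 fold-changes for the early and late contrasts."""

    frame: pd.DataFrame

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.frame[self.frame["kind"] == kind].reset_index(drop=True)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t"))


def plant_kinetics(
    class_label: str, baseline: float, delta: float = 2.0, assay: str = "DRIP"
) -> tuple[float, float, float]:
    """Per-condition expected means implementing a kinetic class.

    Conditions are (untreated, early, late): (NT, T5, T60) for DRIP hybrids,
    (NT, T10, T20) for END-seq breaks.  Gains multiply the baseline by
    2**delta at the conditions where the class is active, losses by
    2**-delta; DSB classes are gains only.
    """
    m = float(baseline)
    up, down = m * 2.0**delta, m * 2.0**-delta
    table = {
        "DRIP": {
            "stable_gain": (m, up, up),
            "stable_loss": (m, down, down),
            "transient_gain": (m, up, m),
            "transient_loss": (m, down, m),
            "late_gain": (m, m, up),
            "late_loss": (m, m, down),
            "no_change": (m, m, m),
            "decoy": (m, m, m),
        },
        "ENDseq": {
            "persistent": (m, up, up),
            "transient": (m, up, m),
            "late": (m, m, up),
            "sedsb": (m, up, up),
        },
    }
    try:
        return table[assay][class_label]
    except KeyError:
        raise ValidationError(f"unknown kinetic class {class_label!r} for assay {assay!r}") from None


class _Placer:
    """Rejection-samples feature midpoints keeping a minimum gap to everything
    already placed (per chromosome)."""

    def __init__(self, rng: np.random.Generator, genome: GenomeSpec, margin: int):
        self.rng = rng
        self.genome = genome
        self.margin = margin
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
        names = genome.names
        lengths = np.array([genome.length_of(c) for c in names], dtype=float)
        self._names = names
        self._probs = lengths / lengths.sum()

    def place(self, width: int, max_tries: int = 2000) -> GenomicInterval:
        for _ in range(max_tries):
            chrom = self._names[int(self.rng.choice(len(self._names), p=self._probs))]
            length = self.genome.length_of(chrom)
            if length <= width + 2 * self.margin:
                continue
            start = int(self.rng.integers(self.margin, length - width - self.margin))
            end = start + width
            occ = self.occupied[chrom]
            i = bisect.bisect_left(occ, (start, end))
            ok = True
            if i > 0 and occ[i - 1][1] + self.margin > start:
                ok = False
            if ok and i < len(occ) and end + self.margin > occ[i][0]:
                ok = False
            if ok:
                occ.insert(i, (start, end))
                return GenomicInterval(chrom, start, end)
        raise GenerationError(
            "infeasible packing: could not place a feature of width "
            f"{width} with margin {self.margin}; reduce feature counts or enlarge the genome"
        )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with var = mean + dispersion * mean^2."""
    if mean <= 0:
        return 0
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _make_libraries(
    rng: np.random.Generator, cfg: SimulationConfig, assay: str
) -> tuple[list[LibraryInfo], np.ndarray]:
    """Library metadata plus the per-library mean multiplier (depth x realized
    spike recovery) that the normalization stage must undo."""
    conds = ENDSEQ_CONDITIONS if assay == "ENDseq" else DRIP_CONDITIONS
    roles = [("IP", c) for c in conds]
    if assay == "DRIP":
        roles += [("RNaseH", "NT")]
    libs: list[LibraryInfo] = []
    totals: list[int] = []
    spike_reads: list[int] = []
    for role, cond in roles:
        for rep in range(1, cfg.replicates + 1):
            j = cfg.library_jitter
            total = int(round(cfg.total_reads_base * float(rng.uniform(1 - j, 1 + j))))
            efficiency = float(rng.uniform(0.6, 1.0))
            n_spike = int(rng.binomial(int(round(total * cfg.spike_ratio)), efficiency))
            prefix = "END" if assay == "ENDseq" else "DRIP"
            tag = "RH" if role == "RNaseH" else cond
            libs.append(
                LibraryInfo(
                    library_id=f"{prefix}_{tag}_r{rep}",
                    assay=assay,
                    condition=cond,
                    replicate=rep,
                    role=role,
                    total_reads=total,
                    spike_on_target_reads=n_spike if assay == "ENDseq" else None,
                    spike_fraction=(n_spike / total) if assay == "DRIP" else None,
                )
            )
            totals.append(total)
            spike_reads.append(n_spike)
    totals_a = np.array(totals, dtype=float)
    depth = totals_a / np.median(totals_a)
    realized_eff = np.array(spike_reads, dtype=float) / (totals_a * cfg.spike_ratio)
    return libs, depth * realized_eff


def _sample_counts(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    means_by_condition: Sequence[dict[str, float]],
    libs: Sequence[LibraryInfo],
    multipliers: np.ndarray,
) -> np.ndarray:
    counts = np.zeros((len(means_by_condition), len(libs)), dtype=np.int64)
    for i, means in enumerate(means_by_condition):
        for j, lib in enumerate(libs):
            key = "RNaseH" if lib.role == "RNaseH" else lib.condition
            counts[i, j] = _nb_draw(rng, means[key] * multipliers[j], cfg.nb_dispersion)
    return counts


def _jitter_peak(
    rng: np.random.Generator, chrom: str, start: int, end: int, inner: str, amount: int = 20
) -> GenomicInterval:
    """Jitter the outer edge of a break-flank peak only, so the planted
    reverse-to-forward gap is identical in every replicate."""
    u = int(rng.integers(-amount, amount + 1))
    if inner == "right":  # reverse peak: inner edge is its end
        return GenomicInterval(chrom, max(0, start + u), end)
    return GenomicInterval(chrom, start, end + u)


def _coverage_track(
    genome: GenomeSpec,
    peaks: Sequence[GenomicInterval],
    background: float,
    peak_value: float,
) -> SignalTrack:
    rows = []
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in genome.names}
    for p in peaks:
        by_chrom[p.chrom].append(p)
    for chrom in genome.names:
        length = genome.length_of(chrom)
        pos = 0
        for p in sorted(by_chrom[chrom], key=lambda x: x.start):
            if p.start > pos:
                rows.append((chrom, pos, p.start, background))
            rows.append((chrom, p.start, p.end, peak_value))
            pos = p.end
        if pos < length:
            rows.append((chrom, pos, length, background))
    return SignalTrack.from_intervals(rows)


def simulate_dataset(config: SimulationConfig, out_dir) -> TruthTable:
    """Generate the full synthetic study under ``out_dir``.

    Emits strand-specific END-seq peak BEDs and coverage bedGraphs per
    replicate and condition, DRIP peak BEDs, count matrices over the planted
    region universes, library metadata with spike-in fields, gene models, the
    genome sizes file, ``truth.tsv`` and ``manifest.yaml``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    (out / "tracks").mkdir(parents=True, exist_ok=True)

    genome = cfg.genome
    delta = cfg.planted_log2fc

    # ---- gene models (annotation only; may be overlapped by peaks) ----
    gene_placer = _Placer(rng, genome, margin=1000)
    genes: list[GeneModel] = []
    for k in range(cfg.n_genes):
        width = int(rng.integers(5000, 30001))
        span = gene_placer.place(width)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        utr = 500
        if strand == "+":
            utr5, utr3 = (span.start, span.start + utr), (span.end - utr, span.end)
        else:
            utr5, utr3 = (span.end - utr, span.end), (span.start, span.start + utr)
        genes.append(
            GeneModel(
                gene_id=f"gene{k:04d}",
                chrom=span.chrom,
                start=span.start,
                end=span.end,
                strand=strand,
                utr5=utr5,
                utr3=utr3,
            )
        )

    # ---- planted features ----
    # Hybrid peaks go down first so that a configurable fraction of the
    # persistent breaks can be nested inside stable-gain peaks, reproducing
    # the co-localization of persistent DSB clusters with stable hybrid gains.
    placer = _Placer(rng, genome, margin=2000)
    truth_rows = []

    rloops = []  # (feature_id, category, span)
    n_true = sum(cfg.n_rloop_per_category.values())
    for cat in RLOOP_CATEGORIES:
        for k in range(cfg.n_rloop_per_category.get(cat, 0)):
            width = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
            span = placer.place(width)
            fid = f"rloop_{cat}_{k:04d}"
            rloops.append((fid, cat, span))
            means = plant_kinetics(cat, cfg.baseline_mean, delta, assay="DRIP")
            truth_rows.append(
                {
                    "feature_id": fid,
                    "kind": "rloop",
                    "chrom": span.chrom,
                    "start": span.start,
                    "end": span.end,
                    "class_label": cat,
                    "log2fc_early": float(np.log2(means[1] / means[0])),
                    "log2fc_late": float(np.log2(means[2] / means[0])),
                }
            )

    free_hosts = [span for fid, cat, span in rloops if cat == "stable_gain"]
    dedsb = []  # (feature_id, class, chrom, break, gap, rev_span, fwd_span)
    for cls in DSB_CLASSES:
        for k in range(cfg.n_dedsb_per_class.get(cls, 0)):
            gap = int(rng.integers(cfg.dsb_gap_range[0], cfg.dsb_gap_range[1] + 1))
            w = cfg.dsb_flank_peak_width
            footprint = 2 * w + gap
            host = None
            if cls == "persistent" and free_hosts:
                if rng.uniform() < cfg.dsb_in_stable_gain_fraction:
                    fits = [h for h in free_hosts if h.width >= footprint]
                    if fits:
                        host = fits[int(rng.integers(len(fits)))]
                        free_hosts.remove(host)
            if host is not None:
                start = host.start + (host.width - footprint) // 2
                span = GenomicInterval(host.chrom, start, start + footprint)
            else:
                span = placer.place(footprint)
            b = span.start + w + gap // 2
            rev = (span.start, span.start + w)
            fwd = (span.start + w + gap, span.end)
            fid = f"dedsb_{cls}_{k:04d}"
            dedsb.append((fid, cls, span.chrom, b, gap, rev, fwd))
            means = plant_kinetics(cls, cfg.baseline_mean, delta, assay="ENDseq")
            truth_rows.append(
                {
                    "feature_id": fid,
                    "kind": "deDSB",
                    "chrom": span.chrom,
                    "start": rev[0],
                    "end": fwd[1],
                    "class_label": cls,
                    "log2fc_early": float(np.log2(means[1] / means[0])),
                    "log2fc_late": float(np.log2(means[2] / means[0])),
                }
            )

    sedsb = []  # (feature_id, chrom, span, strand)
    for k in range(cfg.n_sedsb):
        span = placer.place(cfg.dsb_flank_peak_width)
        strand = FORWARD if rng.integers(0, 2) == 0 else REVERSE
        fid = f"sedsb_{k:04d}"
        sedsb.append((fid, span, strand))
        means = plant_kinetics("sedsb", cfg.baseline_mean, delta, assay="ENDseq")
        truth_rows.append(
            {
                "feature_id": fid,
                "kind": "seDSB",
                "chrom": span.chrom,
                "start": span.start,
                "end": span.end,
                "class_label": "sedsb",
                "log2fc_early": float(np.log2(means[1] / means[0])),
                "log2fc_late": float(np.log2(means[2] / means[0])),
            }
        )
    n_decoys = int(round(n_true * cfg.decoy_fraction / (1 - cfg.decoy_fraction))) if n_true else 0
    for k in range(n_decoys):
        width = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
        span = placer.place(width)
        fid = f"decoy_{k:04d}"
        rloops.append((fid, "decoy", span))
        truth_rows.append(
            {
                "feature_id": fid,
                "kind": "decoy",
                "chrom": span.chrom,
                "start": span.start,
                "end": span.end,
                "class_label": "decoy",
                "log2fc_early": 0.0,
                "log2fc_late": 0.0,
            }
        )

    # ---- libraries ----
    end_libs, end_mult = _make_libraries(rng, cfg, "ENDseq")
    drip_libs, drip_mult = _make_libraries(rng, cfg, "DRIP")

    # ---- END-seq counts over cluster spans + solitary peaks ----
    end_regions = []
    end_means = []
    for fid, cls, chrom, b, gap, rev, fwd in dedsb:
        end_regions.append(GenomicInterval(chrom, rev[0], fwd[1], name=fid))
        m = plant_kinetics(cls, cfg.baseline_mean, delta, assay="ENDseq")
        end_means.append(dict(zip(ENDSEQ_CONDITIONS, m)))
    for fid, span, strand in sedsb:
        end_regions.append(GenomicInterval(span.chrom, span.start, span.end, name=fid))
        m = plant_kinetics("sedsb", cfg.baseline_mean, delta, assay="ENDseq")
        end_means.append(dict(zip(ENDSEQ_CONDITIONS, m)))
    end_counts = _sample_counts(rng, cfg, end_means, end_libs, end_mult)
    end_matrix = CountMatrix(regions=end_regions, libraries=end_libs, counts=end_counts)

    # ---- DRIP counts over hybrid peaks (IP per condition + RNase H) ----
    drip_regions = []
    drip_means = []
    for fid, cat, span in rloops:
        drip_regions.append(GenomicInterval(span.chrom, span.start, span.end, name=fid))
        m = plant_kinetics(cat, cfg.baseline_mean, delta, assay="DRIP")
        means = dict(zip(DRIP_CONDITIONS, m))
        if cat == "decoy":
            # false positives: RNase H-insensitive, IP-level control signal
            means["RNaseH"] = cfg.baseline_mean
        else:
            means["RNaseH"] = cfg.baseline_mean * cfg.rnaseh_background_ratio
        drip_means.append(means)
    drip_counts = _sample_counts(rng, cfg, drip_means, drip_libs, drip_mult)
    drip_matrix = CountMatrix(regions=drip_regions, libraries=drip_libs, counts=drip_counts)

    # ---- peak BEDs and coverage tracks ----
    files: list[str] = []

    def _emit_bed(records, name, extra=None):
        path = out / name
        write_intervals(records, path, genome=genome, extra_columns=extra)
        files.append(name)

    active = {
        "T10": {"persistent", "transient"},
        "T20": {"persistent", "late"},
    }
    for cond in ENDSEQ_CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            rev_peaks, fwd_peaks = [], []
            if cond in active:
                for fid, cls, chrom, b, gap, rev, fwd in dedsb:
                    if cls in active[cond]:
                        rev_iv = _jitter_peak(rng, chrom, rev[0], rev[1], inner="right")
                        fwd_iv = _jitter_peak(rng, chrom, fwd[0], fwd[1], inner="left")
                        rev_peaks.append(
                            StrandedPeak(rev_iv.with_name(f"{fid}_rev"), REVERSE, replicate=rep)
                        )
                        fwd_peaks.append(
                            StrandedPeak(fwd_iv.with_name(f"{fid}_fwd"), FORWARD, replicate=rep)
                        )
                for fid, span, strand in sedsb:
                    peak = StrandedPeak(span.with_name(fid), strand, replicate=rep)
                    (fwd_peaks if strand == FORWARD else rev_peaks).append(peak)
            _emit_bed(rev_peaks, f"peaks/endseq_{cond}_rep{rep}_rev.bed")
            _emit_bed(fwd_peaks, f"peaks/endseq_{cond}_rep{rep}_fwd.bed")
            for strand_name, peaks in (("rev", rev_peaks), ("fwd", fwd_peaks)):
                track = _coverage_track(
                    genome,
                    [p.interval for p in peaks],
                    background=1.0,
                    peak_value=cfg.track_peak_fold,
                )
                tname = f"tracks/endseq_{cond}_rep{rep}_{strand_name}.bedgraph"
                write_signal_track(track, out / tname, genome=genome)
                files.append(tname)
    input_track = _coverage_track(genome, [], background=1.0, peak_value=1.0)
    write_signal_track(input_track, out / "tracks/endseq_input.bedgraph", genome=genome)
    files.append("tracks/endseq_input.bedgraph")

    for cond in DRIP_CONDITIONS:
        for rep in range(1, cfg.replicates + 1):
            peaks = []
            for fid, cat, span in rloops:
                u = int(rng.integers(-20, 21))
                v = int(rng.integers(-20, 21))
                peaks.append(
                    GenomicInterval(
                        span.chrom, max(0, span.start + u), span.end + v, name=fid
                    )
                )
            _emit_bed(peaks, f"peaks/drip_{cond}_rep{rep}.bed")
        cond_idx = DRIP_CONDITIONS.index(cond)
        cond_track = _coverage_track(
            genome,
            [span for _, cat, span in rloops if cat != "decoy"],
            background=0.05,
            peak_value=1.0,
        )
        # scale peaks by the mean kinetic response of true peaks in this condition
        write_signal_track(cond_track, out / f"tracks/drip_{cond}.bedgraph", genome=genome)
        files.append(f"tracks/drip_{cond}.bedgraph")

    # ---- tables ----
    write_genome(genome, out / "genome.chrom.sizes")
    write_library_table(end_libs, out / "libraries_endseq.tsv")
    write_library_table(drip_libs, out / "libraries_drip.tsv")
    write_count_matrix(end_matrix, out / "counts_endseq.tsv")
    write_count_matrix(drip_matrix, out / "counts_drip.tsv")
    genes_df = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "utr5_start": g.utr5[0],
                "utr5_end": g.utr5[1],
                "utr3_start": g.utr3[0],
                "utr3_end": g.utr3[1],
            }
            for g in genes
        ]
    )
    genes_df.to_csv(out / "genes.tsv", sep="\t", index=False)
    truth = TruthTable(pd.DataFrame(truth_rows))
    truth.write(out / "truth.tsv")
    files += [
        "genome.chrom.sizes",
        "libraries_endseq.tsv",
        "libraries_drip.tsv",
        "counts_endseq.tsv",
        "counts_drip.tsv",
        "genes.tsv",
        "truth.tsv",
    ]

    manifest = {
        "seed": cfg.seed,
        "genome": {name: length for name, length in genome.chromosomes},
        "replicates": cfg.replicates,
        "conditions": {"ENDseq": list(ENDSEQ_CONDITIONS), "DRIP": list(DRIP_CONDITIONS)},
        "n_dedsb": sum(cfg.n_dedsb_per_class.values()),
        "n_sedsb": cfg.n_sedsb,
        "n_rloop": n_true,
        "n_decoys": n_decoys,
        "files": sorted(files),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return truth


def read_gene_models(path) -> list[GeneModel]:
    """Load the gene models table written by :func:`simulate_dataset`."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            utr5=(int(r.utr5_start), int(r.utr5_end)),
            utr3=(int(r.utr3_start), int(r.utr3_end)),
        )
        for r in df.itertuples(index=False)
    ]
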