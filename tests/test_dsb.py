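"""Strand-peak pairing, consensus, kinetic classes, solitary-peak detection."""

import numpy as np
import pytest

from endrip.core import ConfigError, GenomeSpec, GenomicInterval, StrandedPeak
from endrip.dsb import (
    call_strand_peaks,
    classify_dsb_kinetics,
    consensus_clusters,
    detect_sedsb,
    pair_distance,
    pair_strand_peaks,
)
from endrip.io import SignalTrack


def rev(chrom, s, e, rep=None):
    return StrandedPeak(GenomicInterval(chrom, s, e), "-", replicate=rep)


def fwd(chrom, s, e, rep=None):
    return StrandedPeak(GenomicInterval(chrom, s, e), "+", replicate=rep)


def brute_force_pairs(reverse_peaks, forward_peaks, max_pair_gap):
    """Independent all-pairs oracle: enumerate every (reverse, forward) pair,
    apply the signed-distance rule, greedily accept admissible minima."""
    candidates = []
    for r in reverse_peaks:
        for f in forward_peaks:
            if r.chrom != f.chrom:
                continue
            if f.start >= r.end:
                d = f.start - r.end
            elif f.end <= r.start:
                continue  # forward entirely left of the break: never admissible
            else:
                d = 0
            if 0 <= d < max_pair_gap:
                candidates.append((d, f.start, f.end, r.start, r.end, r, f))
    candidates.sort(key=lambda t: t[:5])
    used_r, used_f, out = set(), set(), []
    for d, *_rest, r, f in candidates:
        if id(r) in used_r or id(f) in used_f:
            continue
        used_r.add(id(r))
        used_f.add(id(f))
        out.append((r.chrom, r.start, f.end, d))
    return sorted(out)


def random_instance(rng, n_max=50):
    """Random per-strand non-overlapping peaks on two chromosomes."""
    revs, fwds = [], []
    for chrom in ("chr1", "chr2"):
        for strand_list, maker in ((revs, rev), (fwds, fwd)):
            pos = 0
            for _ in range(int(rng.integers(0, n_max + 1))):
                pos += int(rng.integers(1, 400))
                width = int(rng.integers(1, 300))
                strand_list.append(maker(chrom, pos, pos + width))
                pos += width
    return revs, fwds


class TestPairing:
    def test_gap_of_50_forms_cluster(self):
        (c,) = pair_strand_peaks([rev("chr1", 800, 950)], [fwd("chr1", 1000, 1200)], 150)
        assert (c.interval.start, c.interval.end, c.gap) == (800, 1200, 50)

    def test_gap_at_cutoff_is_discarded(self):
        assert pair_strand_peaks([rev("chr1", 800, 950)], [fwd("chr1", 1100, 1300)], 150) == []

    def test_overlapping_peaks_pair_at_distance_zero(self):
        (c,) = pair_strand_peaks([rev("chr1", 800, 1000)], [fwd("chr1", 950, 1200)], 150)
        assert (c.interval.start, c.interval.end, c.gap) == (800, 1200, 0)

    def test_forward_left_of_reverse_is_discarded(self):
        assert pair_strand_peaks([rev("chr1", 800, 950)], [fwd("chr1", 100, 300)], 150) == []

    def test_peaks_on_different_chromosomes_never_pair(self):
        assert pair_strand_peaks([rev("chr1", 800, 950)], [fwd("chr2", 1000, 1200)], 150) == []

    def test_forward_peak_supports_at_most_one_cluster(self):
        clusters = pair_strand_peaks(
            [rev("chr1", 100, 200), rev("chr1", 300, 400)],
            [fwd("chr1", 420, 500)],
            150,
        )
        assert len(clusters) == 1
        assert clusters[0].interval.start == 300  # smaller gap wins

    def test_signed_distance_convention(self):
        r = GenomicInterval("chr1", 800, 950)
        assert pair_distance(r, GenomicInterval("chr1", 1000, 1200)) == 50
        assert pair_distance(r, GenomicInterval("chr1", 900, 1200)) == 0
        assert pair_distance(r, GenomicInterval("chr1", 100, 300)) == -500
        assert pair_distance(r, GenomicInterval("chr2", 1000, 1200)) is None

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            revs, fwds = random_instance(rng)
            got = sorted(
                (c.interval.chrom, c.interval.start, c.interval.end, c.gap)
                for c in pair_strand_peaks(revs, fwds, 150)
            )
            assert got == brute_force_pairs(revs, fwds, 150)

    def test_every_cluster_satisfies_gap_invariant(self):
        rng = np.random.default_rng(7)
        revs, fwds = random_instance(rng)
        for c in pair_strand_peaks(revs, fwds, 150):
            assert 0 <= c.gap < 150
            assert c.interval.start == c.reverse_peak.start
            assert c.interval.end == c.forward_peak.end


def _cluster(chrom, s, e):
    from endrip.dsb import DSBCluster

    return DSBCluster(interval=GenomicInterval(chrom, s, e))


class TestConsensus:
    def test_overlapping_replicate_clusters_union_merge(self):
        out = consensus_clusters([_cluster("chr1", 100, 400)], [_cluster("chr1", 350, 600)])
        assert [(c.interval.start, c.interval.end) for c in out] == [(100, 600)]
        assert out[0].replicate_support == frozenset({1, 2})

    def test_disjoint_replicate_clusters_give_no_consensus(self):
        assert consensus_clusters([_cluster("chr1", 100, 400)], [_cluster("chr1", 500, 600)]) == []

    def test_transitive_merge_across_one_replicate(self):
        out = consensus_clusters(
            [_cluster("chr1", 100, 400), _cluster("chr1", 420, 700)],
            [_cluster("chr1", 300, 500)],
        )
        assert [(c.interval.start, c.interval.end) for c in out] == [(100, 700)]


class TestKineticClasses:
    def test_enriched_at_both_timepoints_is_persistent(self):
        iv = GenomicInterval("chr1", 0, 100)
        out = classify_dsb_kinetics([iv], [iv])
        assert out["persistent"] == [iv]
        assert out["transient"] == [] and out["late"] == []

    def test_early_only_without_late_overlap_is_transient(self):
        iv = GenomicInterval("chr1", 0, 100)
        out = classify_dsb_kinetics([iv], [])
        assert out["transient"] == [iv]

    def test_transient_overlapping_late_promotes_both_to_merged_persistent(self):
        t = GenomicInterval("chr1", 100, 300)
        l = GenomicInterval("chr1", 250, 500)
        out = classify_dsb_kinetics([t], [l])
        assert [(c.start, c.end) for c in out["persistent"]] == [(100, 500)]
        assert out["transient"] == [] and out["late"] == []

    def test_classes_partition_after_promotion(self):
        rng = np.random.default_rng(5)
        ivs = []
        pos = 0
        for _ in range(200):
            pos += int(rng.integers(1, 500))
            ivs.append(GenomicInterval("chr1", pos, pos + int(rng.integers(50, 400))))
            pos = ivs[-1].end
        flags10 = rng.uniform(size=200) < 0.5
        flags20 = rng.uniform(size=200) < 0.5
        out = classify_dsb_kinetics(
            [iv for iv, f in zip(ivs, flags10) if f],
            [iv for iv, f in zip(ivs, flags20) if f],
            universe=ivs,
        )
        from endrip.interval_ops import any_overlap_flags

        for a in ("persistent", "transient", "late"):
            for b in ("persistent", "transient", "late"):
                if a < b and out[a] and out[b]:
                    assert not any_overlap_flags(out[a], out[b]).any()

    def test_unenriched_universe_clusters_are_unclassified(self):
        u = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 500, 600)]
        out = classify_dsb_kinetics([u[0]], [], universe=u)
        assert out["unclassified"] == [u[1]]


class TestSolitaryPeaks:
    def test_distant_peak_is_solitary_candidate(self):
        out = detect_sedsb([fwd("chr1", 5000, 5300)], [rev("chr1", 1000, 1300)])
        assert len(out) == 2  # both are far from any opposite-strand peak
        assert out[0].nearest_opposite_distance == 3700

    def test_nearby_peak_is_not_solitary(self):
        out = detect_sedsb([fwd("chr1", 1400, 1700)], [rev("chr1", 1000, 1300)])
        assert out == []

    def test_no_opposite_strand_means_infinite_distance(self):
        out = detect_sedsb([fwd("chr1", 5000, 5300)], [])
        assert len(out) == 1
        assert np.isinf(out[0].nearest_opposite_distance)

    def test_interquartile_filter_retains_inner_half_inclusive(self):
        peaks = [fwd("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 100) for i in range(8)]
        counts = [10, 20, 30, 40, 50, 60, 70, 80]
        out = detect_sedsb(peaks, [], forward_counts=counts)
        assert sorted(s.count for s in out) == [30, 40, 50, 60]

    def test_fewer_than_four_peaks_skips_filter_with_warning(self):
        peaks = [fwd("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 100) for i in range(3)]
        with pytest.warns(UserWarning, match="quartile"):
            out = detect_sedsb(peaks, [], forward_counts=[1, 100, 10_000])
        assert len(out) == 3


class TestPeakCaller:
    genome = GenomeSpec.from_lengths({"chr1": 100_000})

    def flat(self, value=1.0):
        return SignalTrack.from_intervals([("chr1", 0, 100_000, value)])

    def test_flat_track_equal_to_background_gives_no_peaks(self):
        assert call_strand_peaks(self.flat(), self.flat(), self.genome, "+") == []

    def test_single_rectangular_block_gives_one_peak(self):
        sig = SignalTrack.from_intervals(
            [("chr1", 0, 5000, 1.0), ("chr1", 5000, 5400, 10.0), ("chr1", 5400, 100_000, 1.0)]
        )
        peaks = call_strand_peaks(sig, self.flat(), self.genome, "+", min_fold=5, min_width=150)
        assert [(p.start, p.end) for p in peaks] == [(5000, 5400)]

    def test_two_blocks_separated_by_background_give_two_peaks(self):
        sig = SignalTrack.from_intervals(
            [
                ("chr1", 0, 5000, 1.0),
                ("chr1", 5000, 5400, 10.0),
                ("chr1", 5400, 6400, 1.0),
                ("chr1", 6400, 6800, 10.0),
                ("chr1", 6800, 100_000, 1.0),
            ]
        )
        peaks = call_strand_peaks(sig, self.flat(), self.genome, "+", min_fold=5, min_width=150)
        assert [(p.start, p.end) for p in peaks] == [(5000, 5400), (6400, 6800)]

    def test_min_fold_at_or_below_one_is_a_config_error(self):
        with pytest.raises(ConfigError):
            call_strand_peaks(self.flat(), self.flat(), self.genome, "+", min_fold=1.0)

    def test_runs_split_by_short_gap_are_merged(self):
        sig = SignalTrack.from_intervals(
            [
                ("chr1", 0, 5000, 1.0),
                ("chr1", 5000, 5200, 10.0),
                ("chr1", 5200, 5250, 1.0),  # 50 bp gap < min_width/2
                ("chr1", 5250, 5450, 10.0),
                ("chr1", 5450, 100_000, 1.0),
            ]
        )
        peaks = call_strand_peaks(sig, self.flat(), self.genome, "+", min_fold=5, min_width=150)
        assert [(p.start, p.end) for p in peaks] == [(5000, 5450)]
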