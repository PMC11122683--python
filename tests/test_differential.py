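"""Normalization factors, moderated testing, RNase H filter, kinetic classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endrip.core import GenomicInterval, LibraryInfo, NormalizationError
from endrip.differential import (
    classify_rloop_kinetics,
    consensus_regions,
    count_fragments,
    drip_scale_factors,
    dsb_enriched,
    endseq_scale_factors,
    moderated_test,
    rnaseh_filter,
)


def lib(i, total, rip=None, frac=None, assay="ENDseq", cond="NT", rep=1, role="IP"):
    return LibraryInfo(
        library_id=f"L{i}",
        assay=assay,
        condition=cond,
        replicate=rep,
        role=role,
        total_reads=total,
        spike_on_target_reads=rip,
        spike_fraction=frac,
    )


class TestCounting:
    region = [GenomicInterval("chr1", 200, 400)]

    def test_partial_overlap_counts_once(self):
        assert count_fragments(self.region, [GenomicInterval("chr1", 100, 250)])[0] == 1

    def test_disjoint_fragment_not_counted(self):
        assert count_fragments(self.region, [GenomicInterval("chr1", 100, 150)])[0] == 0

    def test_abutting_fragment_not_counted(self):
        assert count_fragments(self.region, [GenomicInterval("chr1", 100, 200)])[0] == 0

    def test_fragment_spanning_two_regions_counted_in_both(self):
        regions = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 100, 200)]
        counts = count_fragments(regions, [GenomicInterval("chr1", 50, 150)])
        assert counts.tolist() == [1, 1]


class TestScaleFactors:
    def test_identical_libraries_all_factors_one(self):
        sf = endseq_scale_factors([lib(1, 10**6, rip=1000), lib(2, 10**6, rip=1000)])
        np.testing.assert_array_equal(sf.s, [1.0, 1.0])
        np.testing.assert_array_equal(sf.l, [1.0, 1.0])
        np.testing.assert_array_equal(sf.final, [1.0, 1.0])

    def test_doubled_spike_recovery_doubles_factor(self):
        sf = endseq_scale_factors([lib(1, 10**6, rip=1000), lib(2, 10**6, rip=2000)])
        np.testing.assert_allclose(sf.f, [0.001, 0.002], rtol=0, atol=0)
        np.testing.assert_array_equal(sf.s, [1.0, 2.0])
        np.testing.assert_array_equal(sf.l, [1.0, 1.0])
        np.testing.assert_array_equal(sf.final, [1.0, 2.0])

    def test_depth_enters_both_spike_and_library_factors(self):
        sf = endseq_scale_factors([lib(1, 10**6, rip=1000), lib(2, 2 * 10**6, rip=1000)])
        np.testing.assert_array_equal(sf.f, [0.001, 0.0005])
        np.testing.assert_array_equal(sf.s, [2.0, 1.0])
        np.testing.assert_array_equal(sf.l, [1.5, 0.75])
        np.testing.assert_array_equal(sf.final, [3.0, 0.75])

    def test_min_rescaled_factor_is_exactly_one(self):
        rng = np.random.default_rng(0)
        libs = [
            lib(i, int(rng.integers(10**6, 10**7)), rip=int(rng.integers(100, 10_000)))
            for i in range(6)
        ]
        assert endseq_scale_factors(libs).s.min() == 1.0

    def test_all_zero_spike_reads_is_an_error(self):
        with pytest.raises(NormalizationError):
            endseq_scale_factors([lib(1, 10**6, rip=0), lib(2, 10**6, rip=0)])

    def test_drip_identical_libraries_all_one(self):
        sf = drip_scale_factors(
            [lib(1, 10**6, frac=0.001, assay="DRIP"), lib(2, 10**6, frac=0.001, assay="DRIP")]
        )
        np.testing.assert_array_equal(sf.final, [1.0, 1.0])

    def test_drip_fractions_set_spike_factor(self):
        sf = drip_scale_factors(
            [lib(1, 10**6, frac=0.001, assay="DRIP"), lib(2, 10**6, frac=0.002, assay="DRIP")]
        )
        np.testing.assert_array_equal(sf.final, [1.0, 2.0])

    def test_doubling_total_reads_halves_library_size_factor(self):
        sf1 = drip_scale_factors(
            [lib(1, 10**6, frac=0.001, assay="DRIP"), lib(2, 10**6, frac=0.001, assay="DRIP")]
        )
        sf2 = drip_scale_factors(
            [lib(1, 10**6, frac=0.001, assay="DRIP"), lib(2, 2 * 10**6, frac=0.001, assay="DRIP")]
        )
        assert sf2.l[1] / sf1.l[1] == pytest.approx(0.5 * np.median([1, 2]) / 1)

    def test_missing_spike_fraction_is_an_error(self):
        with pytest.raises(NormalizationError):
            drip_scale_factors([lib(1, 10**6, assay="DRIP")])

    def test_between_library_ratios_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            totals = rng.integers(10**6, 10**7, size=4)
            rips = rng.integers(100, 10_000, size=4)
            raw = rng.integers(0, 500, size=(10, 4))
            c = int(rng.integers(2, 10))
            sf = endseq_scale_factors([lib(i, int(t), rip=int(r)) for i, (t, r) in enumerate(zip(totals, rips))])
            sf_scaled = endseq_scale_factors(
                [lib(i, int(t * c), rip=int(r * c)) for i, (t, r) in enumerate(zip(totals, rips))]
            )
            n1 = sf.normalize(raw)
            n2 = sf_scaled.normalize(raw * c)
            ratio = n2 / np.where(n1 == 0, np.nan, n1)
            finite = np.isfinite(ratio)
            assert np.allclose(ratio[finite], ratio[finite].flat[0])


def _counts_from_log2(y, pseudocount=0.5):
    return 2.0 ** np.asarray(y, dtype=float) - pseudocount


class TestModeratedTest:
    def test_identical_groups_give_null_result(self):
        a = np.tile([[10.0, 12.0]], (5, 1))
        res = moderated_test(a, a.copy())
        assert np.allclose(res.log2fc, 0) and np.allclose(res.t, 0)
        assert np.allclose(res.p, 1.0)

    def test_hand_worked_moderation_example(self):
        # target region: log2 values A=(8,8), B=(6,6) -> s2=0, log2FC=2.
        # fillers fix the median pooled variance at exactly 0.5, so
        # s~2 = (4*0.5 + 2*0)/6 = 1/3 and t = 2/sqrt(1/3) = 2*sqrt(3).
        ya = [[8, 8]] + [[v, v + 1] for v in (5, 6, 7, 8, 9)]
        yb = [[6, 6]] + [[v, v + 1] for v in (5, 6, 7, 8, 9)]
        res = moderated_test(_counts_from_log2(ya), _counts_from_log2(yb), d0=4)
        assert res.s2[0] == pytest.approx(0.0, abs=1e-12)
        assert res.s2_moderated[0] == pytest.approx(1 / 3)
        assert res.t[0] == pytest.approx(2 * np.sqrt(3), rel=1e-9)
        assert res.p[0] == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=6), rel=1e-9)

    def test_reduces_to_classical_t_test_as_prior_df_vanishes(self):
        rng = np.random.default_rng(2)
        a = rng.poisson(100, size=(50, 3)).astype(float)
        b = rng.poisson(120, size=(50, 3)).astype(float)
        res = moderated_test(a, b, d0=1e-9, pseudocount=0.5)
        t_ref, p_ref = stats.ttest_ind(
            np.log2(a + 0.5), np.log2(b + 0.5), axis=1, equal_var=True
        )
        np.testing.assert_allclose(res.t, t_ref, rtol=1e-5)
        np.testing.assert_allclose(res.p, p_ref, rtol=1e-4)

    def test_infinite_prior_df_pins_variance_at_the_median(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(100, size=(50, 3)).astype(float)
        b = rng.poisson(100, size=(50, 3)).astype(float)
        res = moderated_test(a, b, d0=1e12)
        s0 = np.median(
            (np.log2(a + 0.5).var(axis=1, ddof=1) * 2 + np.log2(b + 0.5).var(axis=1, ddof=1) * 2) / 4
        )
        np.testing.assert_allclose(res.s2_moderated, s0, rtol=1e-6)

    def test_zero_variance_everywhere_warns_and_floors(self):
        a = np.full((5, 2), 100.0)
        b = np.full((5, 2), 400.0)
        with pytest.warns(UserWarning, match="floor"):
            res = moderated_test(a, b)
        assert np.all(np.isfinite(res.t))

    def test_dsb_gate_requires_both_fold_and_p(self):
        res = pd.DataFrame({"log2fc": [2.0, 0.5, -2.0, 2.0], "p": [0.01, 0.01, 0.01, 0.5]})
        out = dsb_enriched(res)
        assert out["enriched"].tolist() == [True, False, False, False]
        assert out["depleted"].tolist() == [False, False, True, False]


class TestRNaseHFilter:
    def test_no_enrichment_over_control_fails(self):
        rng = np.random.default_rng(4)
        ip = rng.poisson(100, size=(50, 2)).astype(float)
        rh = rng.poisson(100, size=(50, 2)).astype(float)
        assert rnaseh_filter(ip, rh).mean() < 0.2

    def test_fourfold_enrichment_with_low_noise_passes(self):
        rng = np.random.default_rng(5)
        ip = rng.poisson(400, size=(50, 2)).astype(float)
        rh = rng.poisson(100, size=(50, 2)).astype(float)
        assert rnaseh_filter(ip, rh).mean() > 0.9


class TestConsensusRegions:
    def test_present_in_both_replicates_of_one_condition_included(self):
        peaks = {"NT": {1: [GenomicInterval("chr1", 0, 300)], 2: [GenomicInterval("chr1", 100, 400)]},
                 "T5": {1: [], 2: []}}
        assert [(r.start, r.end) for r in consensus_regions(peaks)] == [(0, 400)]

    def test_single_replicate_peak_everywhere_excluded(self):
        peaks = {
            "NT": {1: [GenomicInterval("chr1", 0, 300)], 2: []},
            "T5": {1: [GenomicInterval("chr1", 100, 400)], 2: []},
        }
        assert consensus_regions(peaks) == []

    def test_universe_region_is_union_merge_of_group(self):
        peaks = {
            "T5": {1: [GenomicInterval("chr1", 0, 300)], 2: [GenomicInterval("chr1", 200, 500)]}
        }
        assert [(r.start, r.end) for r in consensus_regions(peaks)] == [(0, 500)]


class TestRloopCategories:
    def make(self, p5, fc5, p60, fc60):
        d5 = pd.DataFrame({"log2fc": [fc5], "p": [p5]})
        d60 = pd.DataFrame({"log2fc": [fc60], "p": [p60]})
        return classify_rloop_kinetics(d5, d60, rloop_p=0.01)[0]

    @pytest.mark.parametrize(
        "p5,fc5,p60,fc60,expected",
        [
            (0.001, 1.2, 0.002, 1.1, "stable_gain"),
            (0.001, -1.2, 0.002, -1.1, "stable_loss"),
            (0.001, 1.2, 0.4, 0.1, "transient_gain"),
            (0.001, -1.2, 0.4, 0.1, "transient_loss"),
            (0.5, 0.2, 0.001, 1.2, "late_gain"),
            (0.5, 0.2, 0.001, -1.2, "late_loss"),
            (0.5, 0.2, 0.5, 0.1, "no_change"),
            (0.001, 1.2, 0.001, -1.2, "discordant"),
            (0.001, -1.2, 0.001, 1.2, "discordant"),
        ],
    )
    def test_state_pair_maps_to_category(self, p5, fc5, p60, fc60, expected):
        assert self.make(p5, fc5, p60, fc60) == expected

    def test_mismatched_universes_rejected(self):
        from endrip.core import ValidationError

        d5 = pd.DataFrame({"log2fc": [1.0], "p": [0.5]})
        d60 = pd.DataFrame({"log2fc": [1.0, 2.0], "p": [0.5, 0.5]})
        with pytest.raises(ValidationError):
            classify_rloop_kinetics(d5, d60)
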