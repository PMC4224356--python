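"""Methylation tracks, sequence descriptors and the window feature table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epirecomb.errors import DegenerateInputError, PairingError
from epirecomb.intervals import GenomeLayout, GenomicInterval, IntervalSet
from epirecomb.tracks import (
    MethylationTrack,
    build_window_table,
    cpg_count,
    cpg_oe,
    gc_content,
    methylation_difference,
    regional_methylation,
    repeat_fraction,
    site_fraction,
    window_rates,
)

from conftest import iset


def track_from(rows, min_depth=1):
    chroms, pos, c, t = zip(*rows)
    return MethylationTrack.from_arrays(chroms, pos, c, t, min_depth=min_depth)


class TestSiteFraction:
    @pytest.mark.parametrize("c,t,expected", [(3, 1, 0.75), (0, 5, 0.0), (7, 0, 1.0)])
    def test_direct_formula(self, c, t, expected):
        assert site_fraction(c, t) == expected

    def test_zero_depth_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            site_fraction(0, 0)


class TestRegionalMethylation:
    def test_mean_of_site_fractions(self):
        tr = track_from([("chr1", 10, 1, 4), ("chr1", 20, 4, 1)])  # 0.2 and 0.8
        assert regional_methylation(tr, GenomicInterval("chr1", 0, 100)) == pytest.approx(0.5)

    def test_no_sites_is_undefined(self):
        tr = track_from([("chr1", 500, 1, 1)])
        assert np.isnan(regional_methylation(tr, GenomicInterval("chr1", 0, 100)))

    def test_unweighted_across_depths(self):
        # 0.75 at depth 4 and 0.25 at depth 100: unweighted mean is 0.5
        tr = track_from([("chr1", 10, 3, 1), ("chr1", 20, 25, 75)])
        assert regional_methylation(tr, GenomicInterval("chr1", 0, 100)) == pytest.approx(0.5)

    def test_read_weighted_option(self):
        tr = track_from([("chr1", 10, 3, 1), ("chr1", 20, 25, 75)])
        got = regional_methylation(tr, GenomicInterval("chr1", 0, 100), weighted=True)
        assert got == pytest.approx(28 / 104)

    def test_constant_sites_give_that_constant(self):
        tr = track_from([("chr1", p, 3, 7) for p in range(0, 1000, 100)])
        assert regional_methylation(tr, GenomicInterval("chr1", 0, 1000)) == pytest.approx(0.3)

    def test_min_depth_filter_drops_sites(self):
        tr = track_from([("chr1", 10, 1, 0), ("chr1", 20, 5, 5)], min_depth=5)
        assert tr.n_sites == 1 and tr.dropped_low_depth == 1

    def test_converges_to_truth_at_high_depth(self, rng):
        # binomial reads at depth 1000 around m=0.63: the regional mean must
        # sit within 3 SE of the truth
        m, depth, k = 0.63, 1000, 200
        c = rng.binomial(depth, m, size=k)
        tr = track_from([("chr1", 10 * i, int(c[i]), depth - int(c[i])) for i in range(k)])
        est = regional_methylation(tr, GenomicInterval("chr1", 0, 10_000))
        se = np.sqrt(m * (1 - m) / depth / k)
        assert abs(est - m) < 3 * se


class TestMethylationDifference:
    def test_identical_tracks_zero(self):
        tr = track_from([("chr1", 10, 3, 1), ("chr1", 500, 1, 3)])
        d = methylation_difference(tr, tr, iset([("chr1", 0, 1000)]))
        assert d.tolist() == [0.0]

    def test_full_versus_none(self):
        a = track_from([("chr1", 10, 5, 0)])
        b = track_from([("chr1", 10, 0, 5)])
        d = methylation_difference(a, b, iset([("chr1", 0, 100)]))
        assert d.tolist() == [1.0]

    def test_uncovered_side_is_undefined(self):
        a = track_from([("chr1", 10, 5, 0)])
        b = track_from([("chr2", 10, 5, 0)])
        d = methylation_difference(a, b, iset([("chr1", 0, 100)]))
        assert np.isnan(d[0])

    def test_unpaired_lengths_raise(self):
        tr = track_from([("chr1", 10, 1, 1)])
        with pytest.raises(PairingError):
            methylation_difference(
                tr, tr, iset([("chr1", 0, 100)]), iset([("chr1", 0, 100), ("chr1", 200, 300)])
            )


class TestSequenceDescriptors:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ATGN", 1 / 3)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq,expected", [("CGCG", 2), ("GCGC", 1), ("AAAA", 0)])
    def test_cpg_count(self, seq, expected):
        assert cpg_count(seq) == expected

    @pytest.mark.parametrize("seq,expected", [("CGCG", 2.0), ("CCGG", 1.0)])
    def test_cpg_oe(self, seq, expected):
        assert cpg_oe(seq) == pytest.approx(expected)

    def test_cpg_oe_undefined_without_c_or_g(self):
        assert np.isnan(cpg_oe("AATT"))

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_descriptor_properties_hold_for_arbitrary_sequences(self, seq):
        unambiguous = sum(seq.count(b) for b in "ACGT")
        if unambiguous:
            assert 0.0 <= gc_content(seq) <= 1.0
        else:
            assert np.isnan(gc_content(seq))
        assert 0 <= cpg_count(seq) <= max(len(seq) - 1, 0)
        oe = cpg_oe(seq)
        if seq.count("C") and seq.count("G"):
            assert oe >= 0.0
        else:
            assert np.isnan(oe)

    def test_agrees_with_exhaustive_counting_on_random_sequence(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=1000, p=[0.24, 0.26, 0.26, 0.22, 0.02]))
            nA = sum(b == "A" for b in seq)
            nC = sum(b == "C" for b in seq)
            nG = sum(b == "G" for b in seq)
            nT = sum(b == "T" for b in seq)
            ncpg = sum(seq[i : i + 2] == "CG" for i in range(len(seq) - 1))
            L = nA + nC + nG + nT
            assert gc_content(seq) == pytest.approx((nG + nC) / L)
            assert cpg_count(seq) == ncpg
            assert cpg_oe(seq) == pytest.approx(ncpg * L / (nC * nG))


class TestRepeatFraction:
    def test_simple_half(self):
        assert repeat_fraction(GenomicInterval("chr1", 0, 100), iset([("chr1", 0, 50)])) == 0.5

    def test_union_not_sum(self):
        reps = iset([("chr1", 0, 60), ("chr1", 40, 80)])
        assert repeat_fraction(GenomicInterval("chr1", 0, 100), reps) == pytest.approx(0.8)

    def test_no_repeats(self):
        from epirecomb.intervals import IntervalSet

        assert repeat_fraction(GenomicInterval("chr1", 0, 100), IntervalSet()) == 0.0


class TestWindowTable:
    def test_row_count_and_uniform_rate(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        rate = iset([("chr1", 0, 1_000_000, 1.0)], layout)
        tr = track_from([("chr1", p, 1, 1) for p in range(0, 1_000_000, 10_000)])
        tab = build_window_table(layout, 500_000, rate, tr, min_sites=1)
        assert len(tab) == 2
        assert np.allclose(tab["recombination_rate"], 1.0)

    def test_rate_invariant_to_segment_split(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        tr = track_from([("chr1", 100, 1, 1)])
        one = iset([("chr1", 0, 1_000_000, 2.5)], layout)
        split = iset([("chr1", 0, 321_321, 2.5), ("chr1", 321_321, 1_000_000, 2.5)], layout)
        t1 = build_window_table(layout, 250_000, one, tr, min_sites=1)
        t2 = build_window_table(layout, 250_000, split, tr, min_sites=1)
        assert np.allclose(t1["recombination_rate"], t2["recombination_rate"])

    def test_bp_weighted_rate(self):
        layout = GenomeLayout([("chr1", 1_000)])
        segs = iset([("chr1", 0, 250, 4.0), ("chr1", 250, 1_000, 0.0)], layout)
        w = IntervalSet([GenomicInterval("chr1", 0, 1_000)], layout)
        assert window_rates(w, segs)[0] == pytest.approx(1.0)

    def test_low_coverage_window_methylation_undefined(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        rate = iset([("chr1", 0, 1_000_000, 1.0)], layout)
        tr = track_from([("chr1", 100, 1, 1)])
        tab = build_window_table(layout, 500_000, rate, tr, min_sites=5)
        assert np.isnan(tab["methylation"]).all()

    def test_planted_generator_means_within_2_se(self):
        # the generator's analytic expectations: window methylation centered
        # at m_mean, rate centered at rate_mean (no hotspot spikes)
        from epirecomb import simulate as sim

        b = sim.simulate_window_study(
            n_chrom=2, chrom_length=50_000_000, window_size=500_000, rho=0.2,
            depth=30, site_spacing=10_000, seed=3,
        )
        tab = build_window_table(b["layout"], 500_000, b["rec_map"], b["meth_track"], min_sites=1)
        n = len(tab)
        se_m = 0.08 / np.sqrt(n)
        se_r = 0.35 / np.sqrt(n)
        assert abs(tab["methylation"].mean() - 0.7) < 2 * se_m + 0.005
        assert abs(tab["recombination_rate"].mean() - 1.0) < 2 * se_r + 0.01
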