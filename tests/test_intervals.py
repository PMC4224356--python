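"""Interval algebra: tilings, overlap, distance, complement, synteny
projection, and control-region sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epirecomb.errors import InvalidParameterError, PlacementError
from epirecomb.intervals import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SyntenyMap,
    complement,
    count_overlapping,
    covered_bp,
    distance_to_nearest,
    intersect,
    map_via_synteny,
    sample_control_regions,
    tile_windows,
)

from conftest import iset, random_intervals


class TestTiling:
    def test_partial_terminal_window(self):
        layout = GenomeLayout([("chr1", 1_200_000)])
        w = tile_windows(layout, 500_000)
        assert [(x.start, x.end) for x in w] == [
            (0, 500_000), (500_000, 1_000_000), (1_000_000, 1_200_000)
        ]
        assert list(w.lengths == 500_000) == [True, True, False]

    def test_exact_multiple_has_no_partial(self):
        layout = GenomeLayout([("chr1", 500_000)])
        w = tile_windows(layout, 500_000)
        assert len(w) == 1 and w[0].length == 500_000

    def test_two_chromosomes(self, layout):
        w = tile_windows(layout, 250_000)
        assert len(w) == 8
        assert np.all(w.lengths == 250_000)

    def test_invalid_size(self, layout):
        with pytest.raises(InvalidParameterError):
            tile_windows(layout, 0)


class TestOverlap:
    def test_one_shared_base_counts(self):
        assert count_overlapping(iset([("chr1", 0, 10)]), iset([("chr1", 5, 15)])) == 1

    def test_half_open_abutment_is_not_overlap(self):
        assert count_overlapping(iset([("chr1", 0, 10)]), iset([("chr1", 10, 20)])) == 0

    def test_self_overlap_counts_every_interval(self, rng):
        s = random_intervals(rng, 100)
        assert count_overlapping(s, s) == 100

    def test_min_bp_threshold(self):
        q = iset([("chr1", 0, 10)])
        s = iset([("chr1", 5, 15)])
        assert count_overlapping(q, s, min_bp=5) == 1
        assert count_overlapping(q, s, min_bp=6) == 0

    def test_min_bp_not_conflated_across_adjacent_subjects(self):
        # two abutting 3 bp subjects each share 3 bp with the query; a merged
        # union would fake a 6 bp single-subject overlap
        q = iset([("chr1", 2, 8)])
        s = iset([("chr1", 0, 5), ("chr1", 5, 10)])
        assert count_overlapping(q, s, min_bp=3) == 1
        assert count_overlapping(q, s, min_bp=4) == 0

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(5):
            q = random_intervals(rng, 300)
            s = random_intervals(rng, 200)
            expected = 0
            for i in range(len(q)):
                qc, qs_, qe = q.chroms[i], q.starts[i], q.ends[i]
                for j in range(len(s)):
                    if (
                        s.chroms[j] == qc
                        and min(qe, s.ends[j]) - max(qs_, s.starts[j]) >= 1
                    ):
                        expected += 1
                        break
            assert count_overlapping(q, s) == expected


class TestDistance:
    def test_gap_between_closest_ends(self):
        d = distance_to_nearest(iset([("chr1", 100, 101)]), iset([("chr1", 200, 300)]))
        assert d.tolist() == [99.0]

    def test_containment_is_zero(self):
        d = distance_to_nearest(iset([("chr1", 250, 260)]), iset([("chr1", 200, 300)]))
        assert d.tolist() == [0.0]

    def test_nearer_right_neighbor(self):
        d = distance_to_nearest(
            iset([("chr1", 400, 410)]), iset([("chr1", 200, 300), ("chr1", 415, 500)])
        )
        assert d.tolist() == [5.0]

    def test_chromosome_without_subject_is_undefined(self):
        d = distance_to_nearest(
            iset([("chr1", 0, 10), ("chr2", 0, 10)]), iset([("chr1", 50, 60)])
        )
        assert d[0] == 40.0 and np.isnan(d[1])

    def test_empty_subject_warns_all_undefined(self):
        with pytest.warns(UserWarning):
            d = distance_to_nearest(iset([("chr1", 0, 10)]), IntervalSet())
        assert np.isnan(d).all()


class TestComplement:
    def test_empty_set(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        c = complement(layout, IntervalSet())
        assert [(x.start, x.end) for x in c] == [(0, 1_000_000)]

    def test_full_cover(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        c = complement(layout, iset([("chr1", 0, 1_000_000)], layout))
        assert len(c) == 0

    def test_middle_interval(self):
        layout = GenomeLayout([("chr1", 1_000)])
        c = complement(layout, iset([("chr1", 100, 200)], layout))
        assert [(x.start, x.end) for x in c] == [(0, 100), (200, 1_000)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 9_990), st.integers(1, 500)),
            min_size=0,
            max_size=30,
        )
    )
    def test_complement_property_arbitrary_sets(self, spans):
        layout = GenomeLayout([("chr1", 10_000)])
        s = iset([("chr1", a, min(a + l, 10_000)) for a, l in spans], layout)
        c = complement(layout, s)
        assert s.merged().total_bp + c.total_bp == 10_000
        assert count_overlapping(c, s) == 0
        # complement of the complement is the merged set
        cc = complement(layout, c)
        m = s.merged()
        assert [(x.start, x.end) for x in cc] == [(x.start, x.end) for x in m]

    def test_union_tiles_genome_exactly_once(self, rng, layout):
        s = random_intervals(rng, 200)
        c = complement(layout, s)
        # base-count: merged set + complement == genome, and they are disjoint
        assert s.merged().total_bp + c.total_bp == layout.total_bp
        assert count_overlapping(c, s) == 0


class TestIntersectCover:
    def test_intersection_and_union_coverage(self):
        a = iset([("chr1", 0, 60), ("chr1", 100, 150)])
        b = iset([("chr1", 40, 120)])
        x = intersect(a, b)
        assert [(i.start, i.end) for i in x] == [(40, 60), (100, 120)]

    def test_covered_bp_union_not_sum(self):
        region = iset([("chr1", 0, 100)])
        reps = iset([("chr1", 0, 60), ("chr1", 40, 80)])
        assert covered_bp(region, reps).tolist() == [80]


def _identity_map(layout, **kw):
    blocks = [(n, 0, l, n, 0, l, "+") for n, l in layout.chromosomes]
    return SyntenyMap(blocks, src_layout=layout, dst_layout=layout, **kw)


class TestSynteny:
    def test_identity_map_is_identity(self, layout):
        smap = _identity_map(layout)
        src = iset([("chr1", 1_000, 3_000), ("chr2", 10, 20)], layout)
        mapped, unmapped = map_via_synteny(src, smap)
        assert unmapped == []
        assert [(x.chrom, x.start, x.end) for x in mapped] == [
            ("chr1", 1_000, 3_000), ("chr2", 10, 20)
        ]

    def test_destination_insertion_shifts_downstream(self):
        layout = GenomeLayout([("chr1", 1_000)])
        # 10 bp inserted in the destination after source base 100
        smap = SyntenyMap(
            [("chr1", 0, 100, "chr1", 0, 100, "+"), ("chr1", 100, 1_000, "chr1", 110, 1_010, "+")],
            src_layout=layout,
        )
        mapped, unmapped = map_via_synteny(iset([("chr1", 200, 300)], layout), smap)
        assert unmapped == []
        assert (mapped[0].start, mapped[0].end) == (210, 310)

    def test_below_min_fraction_is_unmapped(self):
        layout = GenomeLayout([("chr1", 1_000)])
        # only the first half of the interval is aligned
        smap = SyntenyMap([("chr1", 0, 250, "chr1", 0, 250, "+")], src_layout=layout)
        mapped, unmapped = map_via_synteny(iset([("chr1", 200, 300)], layout), smap)
        assert len(mapped) == 0 and unmapped == ["0"]

    def test_negative_strand_reverses_block_coordinates(self):
        layout = GenomeLayout([("chr1", 1_000)])
        smap = SyntenyMap([("chr1", 0, 1_000, "chr1", 0, 1_000, "-")], src_layout=layout)
        mapped, _ = map_via_synteny(iset([("chr1", 100, 200)], layout), smap)
        assert (mapped[0].start, mapped[0].end) == (800, 900)

    def test_roundtrip_on_fully_aligned_intervals(self):
        layout = GenomeLayout([("chr1", 10_000)])
        smap = SyntenyMap(
            [
                ("chr1", 0, 4_000, "chr1", 0, 4_000, "+"),
                ("chr1", 4_100, 10_000, "chr1", 4_050, 9_950, "+"),
            ],
            src_layout=layout,
        )
        inv = smap.invert()
        src = iset([("chr1", 1_000, 2_000), ("chr1", 5_000, 6_000)], layout)
        there, _ = map_via_synteny(src, smap)
        back, _ = map_via_synteny(there, inv)
        assert [(x.start, x.end) for x in back] == [(x.start, x.end) for x in src]

    def test_overlapping_source_blocks_rejected(self):
        from epirecomb.errors import InvalidMapError

        with pytest.raises(InvalidMapError):
            SyntenyMap(
                [("chr1", 0, 100, "chr1", 0, 100, "+"), ("chr1", 50, 150, "chr1", 200, 300, "+")]
            )


class TestControlSampling:
    def test_length_multiset_preserved_and_exclusion_respected(self, rng):
        layout = GenomeLayout([("chr1", 100_000)])
        template = iset([("chr1", 0, 1_000), ("chr1", 5_000, 7_000)], layout)
        excluded = iset([("chr1", 20_000, 40_000)], layout)
        controls = sample_control_regions(template, layout, excluded, n=2, rng=rng)
        assert sorted(controls.lengths.tolist()) == [1_000, 2_000]
        assert count_overlapping(controls, excluded) == 0

    def test_confined_to_only_eligible_gap(self, rng):
        layout = GenomeLayout([("chr1", 1_000_000)])
        excluded = iset([("chr1", 0, 600_000), ("chr1", 610_000, 1_000_000)], layout)
        template = iset([("chr1", 0, 1_000)], layout)
        controls = sample_control_regions(template, layout, excluded, n=5, rng=rng)
        assert np.all(controls.starts >= 600_000) and np.all(controls.ends <= 610_000)

    def test_histogram_matches_template_at_equal_n(self, rng):
        layout = GenomeLayout([("chr1", 10_000_000)])
        template = random_intervals(rng, 500, chroms=("chr1",), clen=10_000_000)
        template = IntervalSet(list(template), layout)
        controls = sample_control_regions(template, layout, template, n=500, rng=rng)
        assert np.array_equal(
            np.sort(controls.lengths), np.sort(template.lengths)
        )
        assert count_overlapping(controls, template) == 0

    def test_default_n_is_one_million(self):
        import inspect

        assert inspect.signature(sample_control_regions).parameters["n"].default == 10**6

    def test_impossible_length_raises(self, rng):
        layout = GenomeLayout([("chr1", 10_000)])
        excluded = iset([("chr1", 0, 9_990)], layout)
        template = iset([("chr1", 0, 5_000)], layout)
        with pytest.raises(PlacementError):
            sample_control_regions(template, layout, excluded, n=1, rng=rng)

    def test_reproducible_given_seed(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        template = iset([("chr1", 0, 1_000)], layout)
        excluded = iset([("chr1", 500_000, 600_000)], layout)
        a = sample_control_regions(template, layout, excluded, n=50, seed=7)
        b = sample_control_regions(template, layout, excluded, n=50, seed=7)
        assert np.array_equal(a.starts, b.starts)
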