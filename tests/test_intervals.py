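"""Interval algebra: resizing, clustering, overlap kernels, profiles, tag QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from darscan.intervals import (
    GenomicInterval,
    RepeatInstance,
    TagSet,
    aggregate_profile,
    cluster_regions,
    count_region_overlaps,
    overlapping_instance_sets,
    qc_tag_gc,
    resize_to_center,
)


def iv(start, end, chrom="chr1", strand="."):
    return GenomicInterval(chrom, start, end, strand)


def inst(start, end, subfamily="S", strand="+"):
    return RepeatInstance(iv(start, end, strand=strand), subfamily, "F", "SINE", 100)


class TestGenomicInterval:
    def test_invariants(self):
        with pytest.raises(ValueError):
            iv(-1, 5)
        with pytest.raises(ValueError):
            iv(5, 5)
        assert iv(0, 10).length == 10

    def test_midpoint_floor_rule(self):
        assert iv(100, 301).midpoint == 200
        assert iv(100, 300).midpoint == 200


class TestResize:
    @pytest.mark.parametrize(
        "start,end,width,expected",
        [
            (100, 300, 200, (100, 300)),  # already centered
            (100, 301, 200, (100, 300)),  # floor midpoint
            (10, 20, 200, (0, 200)),      # clipped at chromosome start
        ],
    )
    def test_examples(self, start, end, width, expected):
        out = resize_to_center(iv(start, end), width)
        assert (out.start, out.end) == expected
        assert out.length == width

    def test_clip_at_chromosome_end(self):
        out = resize_to_center(iv(980, 990), 200, chrom_length=1000)
        assert (out.start, out.end) == (800, 1000)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            resize_to_center(iv(0, 10), 0)


class TestClustering:
    def test_gap_arithmetic(self):
        # gap 50 < 100 -> one cluster; gap 150 -> two
        one = cluster_regions([iv(0, 100), iv(150, 250)], 100)
        assert len(one) == 1 and (one[0].interval.start, one[0].interval.end) == (0, 250)
        two = cluster_regions([iv(0, 100), iv(250, 350)], 100)
        assert len(two) == 2

    def test_single_interval(self):
        out = cluster_regions([iv(5, 10)], 100)
        assert len(out) == 1 and out[0].members == [iv(5, 10)]

    def test_chromosomes_never_merge(self):
        out = cluster_regions([iv(0, 100), iv(50, 150, chrom="chr2")], 1000)
        assert len(out) == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 3000), st.integers(1, 200)), min_size=1, max_size=40
        ),
        st.integers(0, 300),
    )
    def test_idempotent_and_monotone(self, pairs, max_gap):
        regions = [iv(s, s + ln) for s, ln in pairs]
        clusters = cluster_regions(regions, max_gap)
        again = cluster_regions([c.interval for c in clusters], max_gap)
        assert [c.interval for c in again] == [c.interval for c in clusters]
        # cluster count is monotone non-increasing in max_gap
        assert len(cluster_regions(regions, max_gap + 50)) <= len(clusters)
        assert sum(len(c.members) for c in clusters) == len(regions)


class TestOverlap:
    def test_half_open_semantics(self):
        hits, flags = overlapping_instance_sets([iv(100, 300)], [inst(250, 400)])
        assert hits == {"S": frozenset({0})} and flags[0]
        hits, _flags = overlapping_instance_sets([iv(100, 300)], [inst(300, 400)])
        assert hits == {}

    def test_instance_counted_once(self):
        hits, _ = overlapping_instance_sets(
            [iv(100, 300), iv(200, 500)], [inst(250, 400)]
        )
        assert hits == {"S": frozenset({0})}

    @given(
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 150)), max_size=60),
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 150)), max_size=60),
    )
    def test_pair_counts_match_brute_force(self, qs, ss):
        regions = [iv(s, s + ln) for s, ln in qs]
        subjects = [iv(s, s + ln) for s, ln in ss]
        got = count_region_overlaps(regions, subjects)
        for j, sub in enumerate(subjects):
            brute = sum(1 for r in regions if r.overlaps(sub))
            assert got[j] == brute

    @given(
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 150)), max_size=50),
        st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 150)), min_size=1, max_size=50),
    )
    def test_instance_sets_match_brute_force(self, qs, ss):
        regions = [iv(s, s + ln) for s, ln in qs]
        instances = [inst(s, s + ln, subfamily=f"S{j}") for j, (s, ln) in enumerate(ss)]
        hits, flags = overlapping_instance_sets(regions, instances)
        for j, it in enumerate(instances):
            brute = any(r.overlaps(it.interval) for r in regions)
            assert (j in hits.get(it.subfamily, frozenset())) == brute
        for i, r in enumerate(regions):
            assert flags[i] == any(r.overlaps(it.interval) for it in instances)


class TestTagQC:
    def _tagset(self, gc):
        n = len(gc)
        return TagSet(
            "d",
            np.array(["chr1"] * n, dtype=object),
            np.arange(n),
            np.array(["+"] * n, dtype=object),
            np.asarray(gc, dtype=float),
        )

    def test_thresholds(self):
        assert qc_tag_gc(self._tagset([0.0, 0.0])) == (0.0, False)
        assert qc_tag_gc(self._tagset([0.5, 0.5])) == (0.5, True)
        mean, ok = qc_tag_gc(self._tagset([0.56] * 10))
        assert mean == pytest.approx(0.56) and not ok

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            qc_tag_gc(self._tagset([]))


class TestAggregateProfile:
    def test_no_tags_gives_zeros(self):
        prof = aggregate_profile(
            np.array([], dtype=object), np.array([], dtype=int), [inst(100, 200)], 10
        )
        assert prof.shape == (120,) and not prof.any()

    def test_plus_strand_counting(self):
        instances = [inst(100, 200), inst(500, 600)]
        prof = aggregate_profile(
            np.array(["chr1"], dtype=object), np.array([110]), instances, 10
        )
        # one tag at offset 10 of one of two instances -> density 0.5 at flank+10
        assert prof[10 + 10] == pytest.approx(0.5)
        assert prof.sum() == pytest.approx(0.5)

    def test_minus_strand_mirrors_offsets(self):
        instances = [inst(100, 200, strand="-")]
        prof = aggregate_profile(
            np.array(["chr1"], dtype=object), np.array([110]), instances, 10
        )
        # tag 10 bases into the instance maps to oriented offset 89
        assert prof[10 + 89] == pytest.approx(1.0)

    def test_empty_instances_error(self):
        with pytest.raises(ValueError):
            aggregate_profile(np.array([], dtype=object), np.array([]), [], 5)
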