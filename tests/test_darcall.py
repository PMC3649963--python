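"""DAR calling: expected-count scaling, fold, open fractions, recovery."""

import math

import numpy as np
import pytest

import darscan as ds
from darscan.darcall import (
    DARCallConfig,
    dataset_seed,
    expected_count,
    fold_enrichment,
    open_fraction,
)
from darscan.intervals import GenomicInterval, RepeatInstance


def inst(start, end, subfamily="S", chrom="chr1"):
    return RepeatInstance(
        GenomicInterval(chrom, start, end), subfamily, "F", "LTR/ERV", 120
    )


class TestExpectedCount:
    def test_no_hits(self):
        regions = [GenomicInterval("chr1", 0, 200)]
        assert expected_count(regions, [inst(5000, 5400)], "S", 100, 1) == 0.0

    def test_scaling_arithmetic(self):
        # 500 background overlaps among 200,000 random regions and 40,000
        # true peaks scale to an expectation of 100
        regions = [GenomicInterval("chr1", i * 1000, i * 1000 + 200) for i in range(500)]
        instances = [inst(i * 1000 + 100, i * 1000 + 300) for i in range(500)]
        assert expected_count(regions, instances, "S", 40_000, 200_000) == pytest.approx(100.0)

    def test_zero_random_errors(self):
        with pytest.raises(ValueError):
            expected_count([], [], "S", 10, 0)


class TestFoldEnrichment:
    def test_flagship_arithmetic(self):
        assert fold_enrichment(1237, 60.5) == pytest.approx(20.45, abs=0.01)

    def test_trivial_cases(self):
        assert fold_enrichment(5, 5) == 1.0
        assert fold_enrichment(0, 3.2) == 0.0
        assert fold_enrichment(0, 0) == 1.0
        assert math.isinf(fold_enrichment(3, 0))
        with pytest.raises(ValueError):
            fold_enrichment(-1, 1)


class TestOpenFraction:
    @pytest.mark.parametrize(
        "n,union_size,expected",
        [(492, 379, 0.770), (332, 215, 0.648), (2337, 1432, 0.613)],
    )
    def test_printed_subfamily_fractions(self, n, union_size, expected):
        sets = [frozenset(range(union_size))]
        assert open_fraction(n, sets) == pytest.approx(expected, abs=5e-4)

    def test_union_semantics(self):
        sets = [frozenset({1, 2}), frozenset({2, 3})]
        assert open_fraction(10, sets) == pytest.approx(0.3)


def test_dataset_seed_is_stable_and_distinct():
    assert dataset_seed(5, "H7esc") == dataset_seed(5, "H7esc")
    assert dataset_seed(5, "H7esc") != dataset_seed(5, "K562")
    assert 0 <= dataset_seed(5, "H7esc") < 2**31


class TestCallDars:
    def test_planted_subfamilies_recovered(self, small_bundle, small_dar_output):
        frame = small_dar_output.to_frame()
        ct_of = {d.dataset_id: d.cell_type for d in small_bundle.datasets}
        planted = small_bundle.truth[small_bundle.truth["effect"] == "dar"]
        for _i, row in planted.iterrows():
            sel = frame[
                (frame["subfamily"] == row["subfamily"])
                & (frame["dataset_id"] == row["dataset_id"])
            ]
            assert len(sel) == 1
            assert bool(sel["is_dar"].iloc[0]), (
                f"planted {row['subfamily']} not called in {row['dataset_id']}"
            )
            assert sel["fold"].iloc[0] > 2

    def test_null_study_calibrated(self):
        # with no planted enrichment the matched background must reproduce
        # the true hit rate: mean observed/expected near 1, no DAR calls
        from conftest import small_config

        bundle = ds.generate_study(small_config(enrichment={}, chip_factors=[]))
        out = ds.call_dars(
            bundle.datasets,
            bundle.repeats,
            bundle.genes,
            bundle.chrom_sizes,
            DARCallConfig(n_random=50_000, seed=3),
        )
        frame = out.to_frame()
        ratio = (frame["observed"] / frame["expected"]).replace(
            [np.inf, -np.inf], np.nan
        ).dropna()
        assert 0.8 <= ratio.mean() <= 1.2
        assert frame["is_dar"].mean() <= 10 * out.config.alpha * 100

    def test_planted_study_null_pairs_stay_quiet(self, small_bundle, small_dar_output):
        frame = small_dar_output.to_frame()
        planted_keys = {
            (r["subfamily"], r["dataset_id"])
            for _i, r in small_bundle.truth[small_bundle.truth["effect"] == "dar"].iterrows()
        }
        null = frame[
            [
                (r.subfamily, r.dataset_id) not in planted_keys
                for r in frame.itertuples()
            ]
        ]
        assert null["is_dar"].mean() <= 10 * small_dar_output.config.alpha * 100

    def test_result_invariants(self, small_dar_output):
        log10_alpha = math.log10(small_dar_output.config.alpha)
        for r in small_dar_output.results:
            assert 0 <= r.observed <= r.n_instances
            assert r.expected >= 0
            assert 0 <= r.p0 <= 1
            assert r.is_dar == (r.log10_p < log10_alpha)
            assert 0 <= r.q_value <= 1

    def test_peakless_dataset_rejected(self, small_bundle):
        empty = ds.DHSDataset("empty", "hESC", "hESC", "UW", [])
        with pytest.raises(ValueError, match="no peaks"):
            ds.call_dars(
                [empty],
                small_bundle.repeats,
                small_bundle.genes,
                small_bundle.chrom_sizes,
                DARCallConfig(n_random=1000),
            )

    def test_peaks_avoiding_repeats_yield_no_dars(self, small_bundle):
        # peaks placed in a repeat-free corridor produce observed == 0
        occupied = sorted(
            (r.interval.start, r.interval.end)
            for r in small_bundle.repeats
            if r.interval.chrom == "chr1"
        )
        gap_start = None
        prev = 0
        for s, e in occupied:
            if s - prev > 2_000:
                gap_start = prev + 500
                break
            prev = max(prev, e)
        assert gap_start is not None
        peaks = [
            ds.Peak(GenomicInterval("chr1", gap_start + i, gap_start + i + 100))
            for i in range(0, 300, 150)
        ]
        dataset = ds.DHSDataset("avoid", "hESC", "hESC", "UW", peaks)
        out = ds.call_dars(
            [dataset],
            small_bundle.repeats,
            small_bundle.genes,
            small_bundle.chrom_sizes,
            DARCallConfig(n_random=2_000, seed=1),
        )
        frame = out.to_frame()
        assert (frame["observed"] == 0).all()
        assert not frame["is_dar"].any()
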