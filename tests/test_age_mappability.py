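"""Jukes-Cantor ages, lineage partition, and read-uniqueness simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from darscan.age import AgeModel, jukes_cantor_age, lineage_partition, subfamily_profiles
from darscan.intervals import Cluster, GenomicInterval, RepeatInstance
from darscan.mappability import simulate_mappability


def inst(start, end, subfamily="S", repclass="SINE", milli_div=100, chrom="chr1"):
    return RepeatInstance(
        GenomicInterval(chrom, start, end), subfamily, "F", repclass, milli_div
    )


class TestJukesCantor:
    def test_zero_divergence(self):
        assert jukes_cantor_age(0) == (0.0, 0.0)

    def test_closed_form_at_15_percent(self):
        d, age = jukes_cantor_age(150)
        assert d == pytest.approx(0.16735, abs=1e-5)
        assert age == pytest.approx(76.07, abs=0.05)

    def test_primate_cutoff(self):
        model = AgeModel()
        # ages straddling the 95 Myr boundary classify differently
        assert 94.0 < model.primate_cutoff_myrs < 96.0
        _d, age94 = jukes_cantor_age(181)
        _d, age96 = jukes_cantor_age(185)
        assert age94 < 95 < age96

    def test_undefined_beyond_saturation(self):
        with pytest.raises(ValueError):
            jukes_cantor_age(750)
        with pytest.raises(ValueError):
            jukes_cantor_age(1000)

    @given(st.integers(1, 740))
    def test_strictly_increasing_and_d_above_p(self, md):
        d_lo, _ = jukes_cantor_age(md - 1)
        d_hi, _ = jukes_cantor_age(md)
        assert d_hi > d_lo
        assert d_hi >= md / 1000.0


def test_subfamily_profiles_summarize_divergence():
    instances = [
        inst(0, 100, milli_div=100),
        inst(200, 300, milli_div=200),
        inst(400, 480, "T", milli_div=50),
    ]
    frame = subfamily_profiles(instances).set_index("subfamily")
    assert frame.loc["S", "n_instances"] == 2
    assert frame.loc["S", "mean_milli_div"] == pytest.approx(150.0)
    assert frame.loc["S", "age_myrs"] == pytest.approx(76.07, abs=0.05)
    assert bool(frame.loc["S", "primate_specific"])
    assert frame.loc["S", "mean_length"] == pytest.approx(100.0)


class TestLineagePartition:
    def _clusters(self, spans):
        return [Cluster(GenomicInterval("chr1", s, e), []) for s, e in spans]

    def test_no_repeats_gives_zero_proportions(self):
        clusters = self._clusters([(0, 100), (200, 300)])
        frame = lineage_partition(clusters, ["primate", "primate"], [])
        row = frame.set_index("lineage").loc["primate"]
        assert row["n_clusters"] == 2
        assert row["SINE"] == 0.0 and row["no_repeat"] == 1.0

    def test_proportions(self):
        clusters = self._clusters([(i * 1000, i * 1000 + 100) for i in range(10)])
        instances = [inst(i * 1000 + 10, i * 1000 + 60) for i in range(4)]
        frame = lineage_partition(clusters, ["human"] * 10, instances)
        row = frame.set_index("lineage").loc["human"]
        assert row["SINE"] == pytest.approx(0.4)
        assert row["no_repeat"] == pytest.approx(0.6)

    def test_unlabeled_cluster_rejected(self):
        clusters = self._clusters([(0, 100)])
        with pytest.raises(ValueError, match="unlabeled"):
            lineage_partition(clusters, [""], [])
        with pytest.raises(ValueError):
            lineage_partition(clusters, [], [])

    def test_matches_generator_truth(self, small_bundle):
        # label clusters by a deterministic rule and check totals round-trip
        from darscan.intervals import cluster_regions

        peaks = [p.interval for d in small_bundle.datasets[:2] for p in d.peaks]
        clusters = cluster_regions(peaks, 100)
        labels = ["primate" if c.interval.start % 2 else "mammalian" for c in clusters]
        frame = lineage_partition(clusters, labels, small_bundle.repeats)
        assert frame["n_clusters"].sum() == len(clusters)
        for _i, row in frame.iterrows():
            total = sum(row[c] for c in ("LTR/ERV", "DNA", "LINE", "SINE")) + row["no_repeat"]
            assert total == pytest.approx(1.0)


class TestMappability:
    def _random_seq(self, rng, n):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_unique_genome_gives_ratio_one(self, rng):
        genome = {"chr1": self._random_seq(rng, 5000)}
        reps = [inst(1000, 1500, "U")]
        frame = simulate_mappability(genome, reps, 20, n_reads=4000, seed=1)
        assert frame.set_index("subfamily").loc["U", "ratio"] == 1.0

    def test_exact_duplication_gives_ratio_zero(self, rng):
        # two copies of an 800 bp segment, each followed by an identical
        # 19 bp context so every 20-mer starting inside an instance recurs
        seg = self._random_seq(rng, 819)
        a, b, c = (self._random_seq(rng, n) for n in (1000, 1000, 1000))
        genome = {"chr1": a + seg + b + seg + c}
        starts = [1000, 1000 + 819 + 1000]
        reps = [inst(s, s + 800, "DUP") for s in starts] + [inst(100, 900, "U")]
        frame = simulate_mappability(genome, reps, 20, n_reads=8000, seed=2)
        table = frame.set_index("subfamily")
        assert table.loc["DUP", "ratio"] == 0.0
        assert table.loc["U", "ratio"] == 1.0

    def test_zero_mismatch_agrees_with_substring_count_oracle(self, rng):
        genome = {"chr1": self._random_seq(rng, 3000) + self._random_seq(rng, 500) * 2}
        text = genome["chr1"]
        comp = str.maketrans("ACGT", "TGCA")
        frame = simulate_mappability(
            genome, [inst(0, 4000, "ALL")], 15, n_reads=500, seed=4
        )
        # independent oracle: a read is unique iff its sequence plus its
        # reverse complement occur exactly once in the genome text
        row = frame.set_index("subfamily").loc["ALL"]
        # oracle over every possible origin, compared in aggregate
        uniq_positions = 0
        total_positions = len(text) - 15 + 1
        for s in range(0, total_positions, 7):  # stride keeps the oracle fast
            read = text[s: s + 15]
            rc = read.translate(comp)[::-1]
            occurrences = text.count(read) + text.count(rc)
            if occurrences == 1:
                uniq_positions += 1
        oracle_ratio = uniq_positions / len(range(0, total_positions, 7))
        assert row["ratio"] == pytest.approx(oracle_ratio, abs=0.05)

    def test_more_mismatches_never_increase_ratio(self, rng):
        seg = self._random_seq(rng, 300)
        genome = {"chr1": self._random_seq(rng, 2000) + seg + self._random_seq(rng, 500) + seg}
        reps = [inst(0, len(genome["chr1"]), "ALL")]
        r0 = simulate_mappability(genome, reps, 20, n_reads=2000, max_mismatches=0, seed=5)
        r1 = simulate_mappability(genome, reps, 20, n_reads=2000, max_mismatches=1, seed=5)
        g0 = r0.set_index("subfamily").loc["__genome__", "ratio"]
        g1 = r1.set_index("subfamily").loc["__genome__", "ratio"]
        assert g1 <= g0

    def test_parameter_validation(self, rng):
        genome = {"chr1": self._random_seq(rng, 100)}
        with pytest.raises(ValueError):
            simulate_mappability(genome, [], 5, n_reads=10)
        with pytest.raises(ValueError):
            simulate_mappability(genome, [], 200, n_reads=10)
        with pytest.raises(ValueError):
            simulate_mappability(genome, [], 20, n_reads=0)
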