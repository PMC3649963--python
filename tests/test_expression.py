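"""Up-regulation calls and permutation Z of DAR-proximal gene expression."""

import math

import numpy as np
import pandas as pd
import pytest

from darscan.annotation import GeneModel
from darscan.expression import (
    ExpressionMatrix,
    dar_gene_set,
    expression_permutation_z,
    rnaseq_window_z,
    upregulated_genes,
)
from darscan.intervals import GenomicInterval, RepeatInstance


def _matrix(values, cell_types, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = [f"d{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        pd.Series(cell_types, index=cols),
    )


def inst(start, end, chrom="chr1"):
    return RepeatInstance(GenomicInterval(chrom, start, end), "S", "F", "LTR/ERV", 100)


def gene(name, start, end, chrom="chr1"):
    return GeneModel(name, GenomicInterval(chrom, start, end, "+"), "+")


class TestUpregulatedGenes:
    def test_constant_gene_never_called(self):
        expr = _matrix([[5, 5, 5, 5]], ["A", "B", "B", "B"])
        assert upregulated_genes(expr, "A") == set()

    def test_clear_shift_called(self):
        expr = _matrix([[9, 5, 6, 4]], ["A", "B", "B", "C"])
        assert upregulated_genes(expr, "A") == {"g0"}

    def test_planted_shifts_recovered_exactly(self, rng):
        # noise-free: 50 planted genes shifted by 4 noise-SD units are
        # exactly the genes called at threshold 2
        n_genes, n_ds = 300, 8
        base = rng.normal(8, 2, size=n_genes)
        noise = rng.normal(0, 1, size=(n_genes, n_ds))
        values = base[:, None] + noise
        planted = rng.choice(n_genes, size=50, replace=False)
        sds = np.std(values[:, 1:], axis=1, ddof=1)
        values[planted, 0] += 8 * sds[planted]  # far beyond any noise z
        expr = _matrix(values, ["A"] + ["B"] * 4 + ["C"] * 3)
        called = upregulated_genes(expr, "A", z_threshold=2)
        assert {f"g{i}" for i in planted} <= called

    def test_shift_invariance_per_gene(self, rng):
        values = rng.normal(0, 1, size=(40, 6))
        expr = _matrix(values, ["A", "A", "B", "B", "C", "C"])
        shifted = _matrix(values + 17.3, ["A", "A", "B", "B", "C", "C"])
        assert upregulated_genes(expr, "A") == upregulated_genes(shifted, "A")

    def test_needs_two_outside_datasets(self):
        expr = _matrix([[1, 2]], ["A", "B"])
        with pytest.raises(ValueError):
            upregulated_genes(expr, "A")


class TestDarGeneSet:
    def test_empty_when_no_gene_in_window(self):
        genes = [gene("G1", 500_000, 510_000)]
        assert dar_gene_set([inst(1000, 1200)], genes, 50_000) == set()

    def test_gene_counted_once_for_flanking_instances(self):
        genes = [gene("G1", 100_000, 110_000)]
        instances = [inst(80_000, 80_200), inst(120_000, 120_200)]
        assert dar_gene_set(instances, genes, 50_000) == {"G1"}

    def test_window_is_centered_on_midpoint(self):
        genes = [gene("G1", 126_000, 130_000)]
        # instance midpoint 100,100; half-window 25,000 -> edge at 125,100
        assert dar_gene_set([inst(100_000, 100_200)], genes, 50_000) == set()
        assert dar_gene_set([inst(100_000, 100_200)], genes, 52_000) == {"G1"}


class TestPermutationZ:
    def test_printed_z_formula(self):
        # a permutation mean 19.6 and sd 4.3 with 85 observed give z ~ 15.2
        from darscan.stats import zscore

        assert zscore(85, 19.6, 4.3) == pytest.approx(15.21, abs=0.01)

    def test_moments_match_closed_form_hypergeometric(self):
        universe = [f"g{i}" for i in range(200)]
        up = set(universe[:50])
        assoc = expression_permutation_z(
            observed_up=20,
            n_assoc_genes=40,
            upregulated_set=up,
            gene_universe=universe,
            n_perm=10_000,
            seed=11,
        )
        N, K, n = 200, 50, 40
        mean = n * K / N
        var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1)
        se = math.sqrt(var / 10_000)
        assert abs(assoc.perm_mean - mean) < 3 * se
        assert assoc.perm_sd == pytest.approx(math.sqrt(var), rel=0.05)

    def test_tiny_universe_mean(self):
        universe = [f"g{i}" for i in range(10)]
        assoc = expression_permutation_z(1, 2, set(universe[:5]), universe, 10_000, 3)
        assert assoc.perm_mean == pytest.approx(1.0, abs=0.05)

    def test_reproducible_to_full_precision(self):
        universe = [f"g{i}" for i in range(100)]
        a = expression_permutation_z(9, 20, set(universe[:30]), universe, 1_000, 5)
        b = expression_permutation_z(9, 20, set(universe[:30]), universe, 1_000, 5)
        assert a.z_specificity == b.z_specificity
        assert a.perm_mean == b.perm_mean

    def test_observed_at_mean_gives_near_zero_z(self):
        universe = [f"g{i}" for i in range(100)]
        assoc = expression_permutation_z(6, 20, set(universe[:30]), universe, 10_000, 5)
        assert abs(assoc.z_specificity) < 0.5

    def test_validation(self):
        with pytest.raises(ValueError):
            expression_permutation_z(1, 20, set(), ["g1"], 1_000, 0)
        with pytest.raises(ValueError):
            expression_permutation_z(0, 0, set(), ["g1"], 50, 0)


class TestRnaseqWindowZ:
    def _tags(self, rng, chrom_sizes, density_per_bp, hotspots=()):
        pos = {}
        for chrom, size in chrom_sizes.items():
            n = int(size * density_per_bp)
            p = rng.integers(0, size, size=n)
            for lo, hi, mult in hotspots:
                extra = rng.integers(lo, hi, size=int((hi - lo) * density_per_bp * mult))
                p = np.concatenate([p, extra])
            pos[chrom] = np.sort(p)
        return pos

    def test_all_zero_densities_give_no_upregulation(self):
        chrom_sizes = {"chr1": 400_000}
        tags = {f"d{i}": {"chr1": np.array([], dtype=int)} for i in range(5)}
        cts = {"d0": "A", "d1": "B", "d2": "B", "d3": "C", "d4": "C"}
        assoc = rnaseq_window_z(
            [inst(100_000, 100_200)], tags, cts, chrom_sizes, "A",
            window_bp=50_000, n_perm=200, seed=1,
        )
        assert assoc.n_upregulated == 0

    def test_planted_neighborhoods_detected(self, rng):
        chrom_sizes = {"chr1": 2_000_000}
        centers = [300_000, 700_000, 1_100_000, 1_500_000, 1_900_000 - 100_000]
        instances = [inst(c - 100, c + 100) for c in centers]
        cts = {"d0": "A", "d1": "A"}
        cts.update({f"d{i}": "BCDE"[(i - 2) % 4] for i in range(2, 10)})
        tags = {}
        for d, ct in cts.items():
            hot = [(c - 25_000, c + 25_000, 6.0) for c in centers] if ct == "A" else []
            tags[d] = self._tags(rng, chrom_sizes, 0.002, hot)
        assoc = rnaseq_window_z(
            instances, tags, cts, chrom_sizes, "A",
            window_bp=50_000, n_perm=2_000, seed=2,
        )
        assert assoc.n_upregulated >= 4
        assert assoc.z_specificity > 3 or math.isinf(assoc.z_specificity)

    def test_short_chromosome_contributes_no_background(self, rng):
        chrom_sizes = {"chr1": 200_000, "tiny": 10_000}
        tags = {
            f"d{i}": self._tags(rng, chrom_sizes, 0.001) for i in range(4)
        }
        cts = {"d0": "A", "d1": "B", "d2": "B", "d3": "C"}
        assoc = rnaseq_window_z(
            [inst(50_000, 50_200)], tags, cts, chrom_sizes, "A",
            window_bp=50_000, n_perm=200, seed=3,
        )
        assert assoc.n_assoc == 1
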