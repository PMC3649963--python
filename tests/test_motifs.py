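"""PWM scanning, exact p-values, joint tests, classifier features, ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from darscan.motifs import (
    PWM,
    classifier_features,
    dinucleotide_shuffle,
    joint_association_test,
    motif_support_rule,
    pwm_scan,
    pwm_score_pvalue,
    weighted_rank_average,
)

COMP = str.maketrans("ACGT", "TGCA")


def _consensus_pwm(site: str, strength: float = 50.0, motif_id: str = "M") -> PWM:
    counts = np.full((len(site), 4), 2.0)
    for i, base in enumerate(site):
        counts[i, "ACGT".index(base)] = strength
    return PWM.from_counts(motif_id, counts)


def _enumerate_scores(pwm: PWM) -> np.ndarray:
    lo = pwm.log_odds()[:, :4]
    L = len(pwm)
    words = np.array(list(itertools.product(range(4), repeat=L)))
    return lo[np.arange(L)[None, :], words].sum(axis=1)


class TestExactPValues:
    @pytest.mark.parametrize("L", [4, 5, 8])
    def test_convolution_matches_enumeration(self, L, rng):
        counts = rng.integers(1, 40, size=(L, 4)).astype(float)
        pwm = PWM.from_counts("t", counts)
        scores = _enumerate_scores(pwm)
        for q in (0.05, 0.25, 0.5, 0.75, 0.95, 0.999):
            thresh = float(np.quantile(scores, q))
            exact = float((scores >= thresh - 1e-9).mean())
            assert pwm.score_pvalue(thresh) == pytest.approx(exact, abs=2e-3)

    def test_extremes(self):
        pwm = _consensus_pwm("ACGTA")
        scores = _enumerate_scores(pwm)
        assert pwm.score_pvalue(scores.min()) == pytest.approx(1.0)
        assert pwm.score_pvalue(scores.max() + 1.0) == 0.0

    def test_non_uniform_background(self):
        probs = np.tile([0.7, 0.1, 0.1, 0.1], (4, 1))
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        pwm = PWM("m", probs, background=bg)
        scores = _enumerate_scores(pwm)
        # null uses the background distribution, not uniform; query at
        # mid-gap thresholds so ties cannot straddle the discretization
        weights = bg[np.array(list(itertools.product(range(4), repeat=4)))].prod(axis=1)
        uniq = np.unique(np.round(scores, 9))
        for lo, hi in zip(uniq[:-1], uniq[1:]):
            thresh = (lo + hi) / 2
            exact = float(weights[scores >= thresh].sum())
            assert pwm_score_pvalue(pwm, thresh) == pytest.approx(exact, abs=1e-6)


class TestScan:
    def test_uniform_pwm_hit_probability(self):
        # a 4-long perfect-consensus PWM hits a specific 4-mer; its exact
        # p-value equals the fraction of 4-mers scoring at least as high
        pwm = _consensus_pwm("AAAA", strength=1e6)
        hits = pwm_scan({"s": "TTTAAAATTT"}, pwm, p_threshold=0.01)
        assert len(hits) >= 1
        top = max(hits, key=lambda h: h.score)
        assert top.offset == 3 and top.strand == "+"
        assert top.p_value == pytest.approx(1 / 256, abs=1e-4)

    def test_reverse_complement_invariance(self, rng):
        pwm = _consensus_pwm("ACGGT")
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        fwd = pwm_scan({"s": seq}, pwm, p_threshold=0.01)
        rc = pwm_scan({"s": seq.translate(COMP)[::-1]}, pwm, p_threshold=0.01)
        mapped = sorted(
            (len(seq) - (h.offset + len(pwm)), {"+": "-", "-": "+"}[h.strand], round(h.score, 6))
        for h in rc)
        assert mapped == sorted((h.offset, h.strand, round(h.score, 6)) for h in fwd)

    def test_pwm_longer_than_sequence(self):
        pwm = _consensus_pwm("ACGTACGT")
        assert pwm_scan({"s": "ACG"}, pwm, p_threshold=0.5) == []

    def test_n_positions_score_zero_logodds(self):
        pwm = _consensus_pwm("AAAA", strength=1e6)
        hits = pwm_scan({"s": "ANAA"}, pwm, p_threshold=0.999)
        plus = [h for h in hits if h.strand == "+"]
        # the N contributes 0; remaining three As carry the score
        assert plus and plus[0].score < _enumerate_scores(pwm).max()


class TestJointAssociation:
    def test_disjoint_flags_not_significant(self):
        dhs = np.array([True] * 5 + [False] * 15)
        chip = np.array([False] * 5 + [True] * 5 + [False] * 10)
        assoc = joint_association_test(dhs, chip, "S", "TF")
        assert assoc.n_both == 0
        assert assoc.hypergeom_log10_p == 0.0
        assert not assoc.significant

    def test_full_overlap_small_universe(self):
        flags = np.array([True] * 10 + [False] * 10)
        assoc = joint_association_test(flags, flags, "S", "TF")
        expected = 1 / math.comb(20, 10)
        assert 10 ** assoc.hypergeom_log10_p == pytest.approx(expected, rel=1e-9)
        assert assoc.significant

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            joint_association_test(np.ones(3, bool), np.ones(4, bool))

    def test_null_flags_rarely_significant(self, rng):
        n_sig = 0
        trials = 1000
        for _t in range(trials):
            dhs = rng.random(40) < 0.3
            chip = rng.random(40) < 0.3
            if joint_association_test(dhs, chip).significant:
                n_sig += 1
        # nominal level 1e-3; allow generous binomial slack
        assert n_sig <= 8


class TestDinucleotideShuffle:
    @given(st.text(alphabet="ACGT", min_size=5, max_size=60))
    def test_preserves_dinucleotide_counts(self, seq):
        rng = np.random.default_rng(1)
        shuffled = dinucleotide_shuffle(seq, rng)
        def counts(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert counts(shuffled) == counts(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


class TestClassifierFeatures:
    def test_absent_motif_zeroes_f1_f2(self, rng):
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 80)]) for _ in range(5)]
        pwm = _consensus_pwm("ACGTACGTACGT", strength=1e6)
        feats = classifier_features(
            seqs, None, pwm, genome_hits=100, genome_scannable_bp=10_000,
            n_sim=2, seed=0, subfamily="S",
        )
        assert feats.f1_frac_instances_with_motif == 0.0
        assert feats.f2_frac_genome_hits_in_subfamily == 0.0

    def test_planted_motif_everywhere_gives_f1_one(self, rng):
        site = "ACGGTTCA"
        seqs = []
        for _i in range(10):
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
            seqs.append(s[:20] + site + s[28:])
        pwm = _consensus_pwm(site)
        feats = classifier_features(
            seqs, None, pwm, genome_hits=10, genome_scannable_bp=100_000,
            n_sim=2, seed=0, subfamily="S", p_threshold=1e-4,
        )
        assert feats.f1_frac_instances_with_motif == 1.0
        assert feats.f4_enrichment_log10_p < -5

    def test_f5_near_one_under_the_null(self, rng):
        # unstructured sequences have no motif-generation potential beyond
        # their composition, so observed/simulated hit ratio stays near 1;
        # sequence volume is chosen so the expected hit count is large
        seqs = [
            "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            for _ in range(20)
        ]
        pwm = _consensus_pwm("ACGT", strength=8)  # permissive motif, many hits
        feats = classifier_features(
            seqs, None, pwm, genome_hits=1, genome_scannable_bp=1,
            n_sim=5, seed=1, subfamily="S", p_threshold=0.05,
        )
        assert 0.6 < feats.f5_generation_ratio < 1.6

    def test_empty_subfamily_rejected(self):
        with pytest.raises(ValueError):
            classifier_features([], None, _consensus_pwm("ACGT"), 0, 0)


class TestWeightedRankAverage:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "motif_id", "subfamily",
                "f1_frac_instances_with_motif", "f2_frac_genome_hits_in_subfamily",
                "f3_bound_unbound_score_ratio", "f4_enrichment_log10_p",
                "f5_generation_ratio",
            ],
        )

    def test_single_pair_scores_one(self):
        table = self._table([("m", "s", 0.1, 0.1, np.nan, -1.0, 1.0)])
        out = weighted_rank_average(table)
        assert out["rank_score"].iloc[0] == 1.0
        assert bool(out["top_decile"].iloc[0])

    def test_dominant_pair_ranks_first(self):
        table = self._table(
            [
                ("m", "a", 0.9, 0.8, 2.0, -20.0, 5.0),
                ("m", "b", 0.1, 0.1, 1.0, -1.0, 1.0),
            ]
        )
        out = weighted_rank_average(table).set_index("subfamily")
        assert out.loc["a", "rank_score"] == 1.0
        assert out.loc["b", "rank_score"] == 0.0

    def test_feature_permutation_symmetry(self, rng):
        rows = [
            (f"m{i}", "s", *rng.random(3), -rng.random() * 10, rng.random() * 3)
            for i in range(12)
        ]
        table = self._table(rows)
        weights = {
            "f1_frac_instances_with_motif": 2.0,
            "f2_frac_genome_hits_in_subfamily": 1.0,
            "f3_bound_unbound_score_ratio": 0.5,
            "f4_enrichment_log10_p": 1.5,
            "f5_generation_ratio": 1.0,
        }
        a = weighted_rank_average(table, weights)["rank_score"]
        # permute two feature columns together with their weights
        swapped = table.rename(
            columns={
                "f1_frac_instances_with_motif": "f2_frac_genome_hits_in_subfamily",
                "f2_frac_genome_hits_in_subfamily": "f1_frac_instances_with_motif",
            }
        )
        w2 = dict(weights)
        w2["f1_frac_instances_with_motif"], w2["f2_frac_genome_hits_in_subfamily"] = (
            w2["f2_frac_genome_hits_in_subfamily"],
            w2["f1_frac_instances_with_motif"],
        )
        b = weighted_rank_average(swapped, w2)["rank_score"]
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_all_zero_weights_rejected(self):
        table = self._table([("m", "s", 0.1, 0.1, 1.0, -1.0, 1.0)])
        with pytest.raises(ValueError):
            weighted_rank_average(table, {c: 0.0 for c in table.columns[2:]})


class TestMotifSupportRule:
    @pytest.mark.parametrize(
        "n_with,n_open,n_open_with,expected",
        [
            (26, 100, 30, True),    # both thresholds cleared
            (25, 100, 30, False),   # instance count not strictly above 25
            (100, 100, 10, False),  # fraction 10% below 20%
            (100, 0, 0, False),     # nothing open
            (26, 100, 21, True),    # 21% fraction just above
            (26, 100, 20, False),   # exactly 20% rejected (strict)
        ],
    )
    def test_boundaries(self, n_with, n_open, n_open_with, expected):
        assert motif_support_rule(n_with, n_open, n_open_with) is expected
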