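"""PWM scanning with exact p-values, TF/motif–repeat association tests.

The scanner is a log-odds position-weight-matrix scan of both strands with
an exact null: the distribution of the score of a random background
sequence of motif length is computed by position-wise convolution of the
discretized per-position score distributions (bin width 1e-3 bits), so a
score threshold can be placed at any p-value (default 1e-5) without
sampling.  Positions containing N contribute log-odds 0.

TF (ChIP) and motif associations with open chromatin use a hypergeometric
test over the subfamily's instances: population N = instances, successes
K = instances bound by the partner, draws n = instances contributing DHS,
observed k = instances with both; significance cutoff p < 0.001.

A five-feature ranking ("classifier") scores every (motif, subfamily)
pair: fraction of instances with the motif, fraction of genomic motif
hits inside the subfamily, bound/unbound score ratio, a binomial
enrichment test against the genomic hit rate, and a dinucleotide-shuffle
estimate of the subfamily sequence's intrinsic motif-generation
potential.  Features are combined by a weighted rank average (trained
weights are not public, so the default is equal weights) and the top
decile is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import binom_sf_log10, hypergeom_sf_log10

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_BIN_BITS = 1e-3  # score discretization (bits) for the exact null


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class PWM:
    """A position weight matrix over A/C/G/T (rows = positions)."""

    motif_id: str
    probs: np.ndarray  # (L, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM probabilities must be (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-position probabilities must sum to 1")
        self.background = np.asarray(self.background, dtype=float)
        self._null_cache: dict = {}

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: np.ndarray | None = None,
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        probs = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        return cls(motif_id, probs, counts=counts, **kwargs)

    def __len__(self) -> int:
        return self.probs.shape[0]

    def log_odds(self) -> np.ndarray:
        """(L, 5) log2 odds; column 4 (N) scores 0."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs) - np.log2(self.background)[None, :]
        return np.hstack([lo, np.zeros((len(self), 1))])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.probs[::-1, ::-1].copy(), self.background)

    # ------------------------------------------------------------------
    # exact null score distribution
    # ------------------------------------------------------------------
    def _null(self) -> tuple[np.ndarray, np.ndarray]:
        """(quantized score grid, survival probabilities) under background.

        Windows containing a probability-0 letter score -inf and sit below
        the finite grid; their mass is simply absent from the finite pmf,
        which leaves every finite-threshold survival value exact.
        """
        key = (tuple(np.round(self.background, 12)),)
        if key in self._null_cache:
            return self._null_cache[key]
        lo = self.log_odds()[:, :4]
        finite = np.isfinite(lo)
        q = np.where(finite, np.round(lo / _BIN_BITS), 0).astype(np.int64)
        mins = np.where(finite, q, np.iinfo(np.int64).max).min(axis=1)
        maxs = np.where(finite, q, np.iinfo(np.int64).min).max(axis=1)
        # pmf indexed relative to the running minimum score
        pmf = np.array([1.0])
        for i in range(len(self)):
            width = int(maxs[i] - mins[i])
            new = np.zeros(len(pmf) + width)
            for letter in range(4):
                p = float(self.background[letter])
                if p == 0 or not finite[i, letter]:
                    continue
                shift = int(q[i, letter] - mins[i])
                new[shift: shift + len(pmf)] += p * pmf
            pmf = new
        lo_sum = int(mins.sum())
        scores = (lo_sum + np.arange(len(pmf))).astype(float) * _BIN_BITS
        sf = np.cumsum(pmf[::-1])[::-1]
        result = (scores, sf)
        self._null_cache[key] = result
        return result

    def score_pvalue(self, score: float) -> float:
        """Exact P(null window score >= score); 1.0 at/below the minimum."""
        scores, sf = self._null()
        q = round(score / _BIN_BITS) * _BIN_BITS
        idx = np.searchsorted(scores, q - _BIN_BITS / 2, side="left")
        if idx >= len(scores):
            return 0.0
        return float(min(1.0, sf[idx]))

    def score_threshold(self, p_threshold: float) -> float:
        """Smallest achievable score whose exact p-value is <= p_threshold."""
        scores, sf = self._null()
        ok = sf <= p_threshold
        if not ok.any():
            return math.inf
        return float(scores[np.argmax(ok)])


def pwm_score_pvalue(pwm: PWM, score: float) -> float:
    return pwm.score_pvalue(score)


@dataclass(frozen=True, slots=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float
    p_value: float


def _scan_codes(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Score every window of len(table) against a (L, 5) lookup table."""
    L = table.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += table[j, codes[j: j + n]]
    return scores


def pwm_scan(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    pwm: PWM,
    p_threshold: float = 1e-5,
) -> list[MotifHit]:
    """Scan both strands of each sequence; emit hits with p <= p_threshold.

    Offsets are 0-based on the forward sequence for both strands.  A PWM
    longer than the sequence yields no hits.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must be in (0, 1)")
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    fwd = pwm.log_odds()
    rev = pwm.reverse_complement()
    rev_table = rev.log_odds()
    cutoff = pwm.score_threshold(p_threshold)
    hits: list[MotifHit] = []
    if math.isinf(cutoff):
        return hits
    for seq_id, seq in items:
        codes = _encode(seq)
        for strand, table in (("+", fwd), ("-", rev_table)):
            scores = _scan_codes(codes, table)
            for off in np.nonzero(scores >= cutoff - _BIN_BITS / 2)[0]:
                s = float(scores[off])
                hits.append(
                    MotifHit(
                        sequence_id=seq_id,
                        offset=int(off),
                        strand=strand,
                        score=s,
                        p_value=pwm.score_pvalue(s),
                    )
                )
    return hits


# ---------------------------------------------------------------------------
# joint TF / DHS association
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class JointAssociation:
    subfamily: str
    partner: str
    n_instances: int
    n_dhs: int
    n_partner: int
    n_both: int
    hypergeom_log10_p: float
    significant: bool


def joint_association_test(
    dhs_flags: np.ndarray,
    partner_flags: np.ndarray,
    subfamily: str = "",
    partner: str = "",
    alpha: float = 1e-3,
) -> JointAssociation:
    """Hypergeometric test of DHS/partner co-occurrence over one subfamily.

    Universe N = the subfamily's instances, successes K = partner-bound
    instances, draws n = DHS-contributing instances, observed k = both.
    """
    dhs_flags = np.asarray(dhs_flags, dtype=bool)
    partner_flags = np.asarray(partner_flags, dtype=bool)
    if dhs_flags.shape != partner_flags.shape:
        raise ValueError("flag vectors must cover the same instance universe")
    N = len(dhs_flags)
    K = int(partner_flags.sum())
    n = int(dhs_flags.sum())
    k = int((dhs_flags & partner_flags).sum())
    log10_p = hypergeom_sf_log10(k, N, K, n)
    return JointAssociation(
        subfamily=subfamily,
        partner=partner,
        n_instances=N,
        n_dhs=n,
        n_partner=K,
        n_both=k,
        hypergeom_log10_p=log10_p,
        significant=log10_p < math.log10(alpha),
    )


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul–Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """A random sequence with identical dinucleotide counts (Eulerian walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)
    # pick per-vertex last edges forming a tree into `last`
    for _ in range(100):
        last_edge = {}
        for v in vertices:
            if v == last:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in vertices:
            if v == last:
                continue
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # extremely unlikely; fall back to the original order
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v != last:
            rest.remove(last_edge[v])
        order = rng.permutation(len(rest))
        out = [rest[i] for i in order]
        if v != last:
            out.append(last_edge[v])
        shuffled[v] = out
    walk = [seq[0]]
    ptr = {v: 0 for v in vertices}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        walk.append(nxt)
        cur = nxt
    return "".join(walk)


# ---------------------------------------------------------------------------
# classifier features and weighted rank average
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class ClassifierFeatures:
    motif_id: str
    subfamily: str
    f1_frac_instances_with_motif: float
    f2_frac_genome_hits_in_subfamily: float
    f3_bound_unbound_score_ratio: float  # NaN when bound flags absent
    f4_enrichment_log10_p: float
    f5_generation_ratio: float


def classifier_features(
    subfamily_sequences: Sequence[str],
    bound_flags: Sequence[bool] | None,
    pwm: PWM,
    genome_hits: int,
    genome_scannable_bp: int,
    n_sim: int = 10,
    seed: int = 0,
    p_threshold: float = 1e-4,
    subfamily: str = "",
    shuffled_pool: Sequence[str] | None = None,
) -> ClassifierFeatures:
    """The five motif-association features for one (motif, subfamily) pair.

    ``genome_hits`` is the motif's genome-wide hit count at the same
    threshold and ``genome_scannable_bp`` the genome's scannable length.
    ``shuffled_pool`` may supply precomputed dinucleotide-shuffled copies
    of the instance sequences (one list of strings per simulation);
    otherwise they are generated here from ``seed``.  Simulated sequences
    are scanned instance-by-instance exactly like the observed ones.
    """
    if not subfamily_sequences:
        raise ValueError("subfamily has no sequences")
    seqs = {str(i): s for i, s in enumerate(subfamily_sequences)}
    hits = pwm_scan(seqs, pwm, p_threshold)
    hit_count: dict[str, int] = {}
    best_score: dict[str, float] = {}
    for h in hits:
        hit_count[h.sequence_id] = hit_count.get(h.sequence_id, 0) + 1
        best_score[h.sequence_id] = max(best_score.get(h.sequence_id, -math.inf), h.score)
    n_inst = len(subfamily_sequences)
    n_with = len(hit_count)
    total_hits = sum(hit_count.values())

    f1 = n_with / n_inst
    f2 = total_hits / genome_hits if genome_hits > 0 else 0.0

    f3 = math.nan
    if bound_flags is not None:
        bound_scores = [
            best_score[str(i)]
            for i, b in enumerate(bound_flags)
            if b and str(i) in best_score
        ]
        unbound_scores = [
            best_score[str(i)]
            for i, b in enumerate(bound_flags)
            if not b and str(i) in best_score
        ]
        if bound_scores and unbound_scores:
            denom = float(np.mean(unbound_scores))
            f3 = float(np.mean(bound_scores)) / denom if denom != 0 else math.nan

    # f4: binomial enrichment of the hit count against the genomic hit rate
    subfamily_bp = sum(max(0, len(s) - len(pwm) + 1) for s in subfamily_sequences)
    rate = genome_hits / genome_scannable_bp if genome_scannable_bp > 0 else 0.0
    # hits on both strands: per-position rate doubled positions already
    # folded into `rate` since genome_hits counts both strands
    f4 = binom_sf_log10(min(total_hits, subfamily_bp), subfamily_bp, min(1.0, rate))

    # f5: observed hits / mean hits over dinucleotide-shuffled sequence
    rng = np.random.default_rng(seed)
    sim_counts = []
    for i in range(n_sim):
        if shuffled_pool is not None:
            shuffled = shuffled_pool[i]
        else:
            shuffled = [dinucleotide_shuffle(s, rng) for s in subfamily_sequences]
        if isinstance(shuffled, str):
            shuffled = [shuffled]
        sim_counts.append(
            len(pwm_scan([(str(j), s) for j, s in enumerate(shuffled)], pwm, p_threshold))
        )
    mean_sim = float(np.mean(sim_counts)) if sim_counts else 0.0
    if mean_sim == 0:
        f5 = 1.0 if total_hits == 0 else math.inf
    else:
        f5 = total_hits / mean_sim

    return ClassifierFeatures(
        motif_id=pwm.motif_id,
        subfamily=subfamily,
        f1_frac_instances_with_motif=f1,
        f2_frac_genome_hits_in_subfamily=f2,
        f3_bound_unbound_score_ratio=f3,
        f4_enrichment_log10_p=f4,
        f5_generation_ratio=f5,
    )


FEATURE_COLUMNS = {
    "f1_frac_instances_with_motif": +1,
    "f2_frac_genome_hits_in_subfamily": +1,
    "f3_bound_unbound_score_ratio": +1,
    "f4_enrichment_log10_p": -1,  # smaller p (more negative log10) is favorable
    "f5_generation_ratio": +1,
}


def weighted_rank_average(
    feature_table: pd.DataFrame,
    weights: Mapping[str, float] | None = None,
    top_fraction: float = 0.10,
) -> pd.DataFrame:
    """Combine feature columns into a normalized weighted rank score.

    Per feature, pairs are ranked with ties sharing the mean rank and the
    rank normalized to [0, 1] (1 = most motif-favorable).  Missing feature
    values drop that feature's weight for the affected row.  Pairs whose
    score reaches the (1 - top_fraction) quantile are flagged top-decile.
    """
    from scipy.stats import rankdata

    if weights is None:
        weights = {c: 1.0 for c in FEATURE_COLUMNS}
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    table = feature_table.copy()
    n = len(table)
    norm_ranks = {}
    for col, direction in FEATURE_COLUMNS.items():
        if col not in table or weights.get(col, 0.0) == 0.0:
            continue
        vals = table[col].to_numpy(dtype=float) * direction
        finite = np.isfinite(vals)
        ranks = np.full(n, np.nan)
        if finite.sum() == 1:
            ranks[finite] = 1.0
        elif finite.sum() > 1:
            r = rankdata(vals[finite], method="average")
            ranks[finite] = (r - 1) / (finite.sum() - 1)
        # +/- inf: best or worst rank
        ranks[np.isposinf(table[col].to_numpy(dtype=float) * direction)] = 1.0
        ranks[np.isneginf(table[col].to_numpy(dtype=float) * direction)] = 0.0
        norm_ranks[col] = ranks
    score = np.zeros(n)
    wsum = np.zeros(n)
    for col, ranks in norm_ranks.items():
        w = weights.get(col, 0.0)
        ok = ~np.isnan(ranks)
        score[ok] += w * ranks[ok]
        wsum[ok] += w
    with np.errstate(invalid="ignore"):
        table["rank_score"] = np.where(wsum > 0, score / np.maximum(wsum, 1e-300), np.nan)
    if n == 1:
        table["rank_score"] = 1.0
    threshold = np.nanquantile(table["rank_score"], 1.0 - top_fraction) if n else math.nan
    table["top_decile"] = table["rank_score"] >= threshold
    return table


def motif_support_rule(
    n_instances_with_motif: int,
    n_open_instances: int,
    n_open_with_motif: int,
    min_instances: int = 25,
    min_fraction: float = 0.20,
) -> bool:
    """Tissue-specific motif support: > min_instances motif-bearing instances
    AND motif present in > min_fraction of the DHS-contributing instances."""
    if n_open_instances == 0:
        return False
    return (
        n_instances_with_motif > min_instances
        and (n_open_with_motif / n_open_instances) > min_fraction
    )
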