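"""Chromatin-state assignment, conservation and dsQTL enrichments.

* A region is assigned to the chromatin state covering more than half of
  its length (none otherwise); the 15 learned states are reported after
  grouping into 7 combined states (e.g. strong + weak enhancers ->
  enhancer).
* Conservation: the fraction of open repeat instances overlapping a
  conserved non-exonic element (CNEE) is tested against the genome-wide
  instance fraction with the one-sided binomial kernel shared with DAR
  calling.
* dsQTLs: each dsQTL is attributed to at most one DHS cluster (largest
  overlap, ties to the leftmost) and enrichment of DAR-contributed
  clusters among dsQTL-bearing ones is a hypergeometric upper tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Cluster, GenomicInterval, RegionIndex, RepeatInstance
from .stats import binom_sf_log10, hypergeom_sf_log10

logger = logging.getLogger(__name__)

#: default grouping of 15 chromatin states into 7 combined states
DEFAULT_STATE_GROUPING: dict[str, str] = {
    "1_Active_Promoter": "promoter",
    "2_Weak_Promoter": "promoter",
    "3_Poised_Promoter": "promoter",
    "4_Strong_Enhancer": "enhancer",
    "5_Strong_Enhancer": "enhancer",
    "6_Weak_Enhancer": "enhancer",
    "7_Weak_Enhancer": "enhancer",
    "8_Insulator": "insulator",
    "9_Txn_Transition": "transcribed",
    "10_Txn_Elongation": "transcribed",
    "11_Weak_Txn": "transcribed",
    "12_Repressed": "repressed",
    "13_Heterochrom": "heterochromatin",
    "14_Repetitive_CNV": "repetitive",
    "15_Repetitive_CNV": "repetitive",
}

COMBINED_STATES = (
    "promoter",
    "enhancer",
    "insulator",
    "transcribed",
    "repressed",
    "heterochromatin",
    "repetitive",
)


@dataclass(slots=True)
class OverlapEnrichment:
    label: str
    n_total: int
    n_hit: int
    fraction: float
    comparison_fraction: float
    log10_p: float


class StateSegmentation:
    """Non-overlapping labeled segments for one cell type."""

    def __init__(
        self,
        cell_type: str,
        segments: Sequence[tuple[GenomicInterval, str]],
        grouping: Mapping[str, str] | None = None,
    ):
        self.cell_type = cell_type
        self.grouping = dict(grouping or DEFAULT_STATE_GROUPING)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._labels: dict[str, np.ndarray] = {}
        per: dict[str, list[tuple[int, int, str]]] = {}
        for iv, label in segments:
            per.setdefault(iv.chrom, []).append((iv.start, iv.end, label))
        for chrom, rows in per.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"segments overlap on {chrom}")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._labels[chrom] = np.array([r[2] for r in rows], dtype=object)

    def assign(
        self, region: GenomicInterval, min_overlap_fraction: float = 0.5
    ) -> str | None:
        """State covering > min_overlap_fraction of the region, else None."""
        starts = self._starts.get(region.chrom)
        if starts is None:
            return None
        ends, labels = self._ends[region.chrom], self._labels[region.chrom]
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        cover: dict[str, int] = {}
        for i in range(lo, hi):
            bases = min(ends[i], region.end) - max(starts[i], region.start)
            if bases > 0:
                cover[labels[i]] = cover.get(labels[i], 0) + int(bases)
        need = min_overlap_fraction * region.length
        for label, bases in sorted(cover.items(), key=lambda kv: -kv[1]):
            if bases > need:
                return label
        return None

    def combined(self, label: str | None) -> str:
        if label is None:
            return "unassigned"
        return self.grouping.get(label, "unassigned")


def assign_state(
    region: GenomicInterval,
    segmentation: StateSegmentation,
    min_overlap_fraction: float = 0.5,
) -> str | None:
    return segmentation.assign(region, min_overlap_fraction)


def state_proportions(
    dhs_regions: Sequence[GenomicInterval],
    repeat_overlap_flags: Sequence[bool],
    segmentation: StateSegmentation,
    chrom_sizes: Mapping[str, int],
    n_random: int = 10_000,
    seed: int = 0,
    min_overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Combined-state proportions for in-repeat / out-of-repeat / random sets.

    The random set draws uniform positions with lengths resampled from the
    true regions; per set the proportions (including ``unassigned``) sum
    to 1.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    lengths = np.array([r.length for r in dhs_regions], dtype=np.int64)
    pick_len = rng.choice(lengths, size=n_random)
    pick_chrom = rng.choice(len(chroms), size=n_random, p=sizes / sizes.sum())
    rand_regions = []
    for ci, ln in zip(pick_chrom, pick_len):
        hi = max(1, sizes[ci] - ln)
        s = int(rng.integers(0, hi))
        rand_regions.append(GenomicInterval(chroms[ci], s, s + int(ln)))

    flags = np.asarray(repeat_overlap_flags, dtype=bool)
    sets = {
        "in_repeat": [r for r, f in zip(dhs_regions, flags) if f],
        "out_repeat": [r for r, f in zip(dhs_regions, flags) if not f],
        "random": rand_regions,
    }
    states = list(COMBINED_STATES) + ["unassigned"]
    table = {}
    for name, regions in sets.items():
        counts = dict.fromkeys(states, 0)
        for r in regions:
            counts[segmentation.combined(segmentation.assign(r, min_overlap_fraction))] += 1
        total = max(1, len(regions))
        table[name] = [counts[s] / total for s in states]
    return pd.DataFrame(table, index=states)


def conservation_enrichment(
    all_instances: Sequence[RepeatInstance],
    open_ids: Sequence[int],
    cnee_intervals: Sequence[GenomicInterval],
) -> OverlapEnrichment:
    """Are open instances more often conserved than instances at large?"""
    index = RegionIndex(cnee_intervals)
    conserved = index.any_overlap([r.interval for r in all_instances])
    n_all, k_all = len(all_instances), int(conserved.sum())
    open_ids = np.asarray(sorted(set(open_ids)), dtype=np.int64)
    n_open = len(open_ids)
    k_open = int(conserved[open_ids].sum()) if n_open else 0
    frac_all = k_all / n_all if n_all else 0.0
    frac_open = k_open / n_open if n_open else 0.0
    log10_p = binom_sf_log10(k_open, n_open, frac_all) if n_open else 0.0
    return OverlapEnrichment(
        label="conservation",
        n_total=n_open,
        n_hit=k_open,
        fraction=frac_open,
        comparison_fraction=frac_all,
        log10_p=log10_p,
    )


def dsqtl_enrichment(
    dsqtls: Sequence[GenomicInterval],
    all_clusters: Sequence[Cluster],
    dar_cluster_flags: Sequence[bool],
) -> OverlapEnrichment:
    """Hypergeometric enrichment of DAR clusters among dsQTL-bearing ones.

    N = clusters, K = DAR-contributed clusters, n = distinct clusters with
    >= 1 assigned dsQTL, k = DAR clusters among them; each dsQTL goes to
    the cluster it overlaps most (ties leftmost) or to none.  Counting
    distinct clusters keeps n and k inside the hypergeometric support when
    several dsQTLs share a cluster (with dsQTLs sparse relative to the
    cluster count the two conventions coincide).
    """
    flags = np.asarray(dar_cluster_flags, dtype=bool)
    if len(flags) != len(all_clusters):
        raise ValueError("one DAR flag per cluster required")
    per: dict[str, list[tuple[int, int, int]]] = {}
    for i, cl in enumerate(all_clusters):
        per.setdefault(cl.interval.chrom, []).append(
            (cl.interval.start, cl.interval.end, i)
        )
    sorted_chrom = {
        c: (
            np.array([r[0] for r in sorted(rows)], dtype=np.int64),
            np.array([r[1] for r in sorted(rows)], dtype=np.int64),
            np.array([r[2] for r in sorted(rows)], dtype=np.int64),
        )
        for c, rows in per.items()
    }
    assigned: set[int] = set()
    for q in dsqtls:
        table = sorted_chrom.get(q.chrom)
        if table is None:
            continue
        starts, ends, idx = table
        lo = np.searchsorted(ends, q.start, side="right")
        hi = np.searchsorted(starts, q.end, side="left")
        best, best_ov = None, 0
        for i in range(lo, hi):
            ov = min(ends[i], q.end) - max(starts[i], q.start)
            if ov > best_ov:
                best, best_ov = int(idx[i]), ov
        if best is not None:
            assigned.add(best)
    n = len(assigned)
    k = sum(1 for i in assigned if flags[i])
    N, K = len(all_clusters), int(flags.sum())
    log10_p = hypergeom_sf_log10(k, N, K, n) if n else 0.0
    return OverlapEnrichment(
        label="dsqtl",
        n_total=n,
        n_hit=k,
        fraction=k / n if n else math.nan,
        comparison_fraction=K / N if N else math.nan,
        log10_p=log10_p,
    )
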