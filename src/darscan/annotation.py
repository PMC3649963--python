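"""Gene-proximity annotation and annotation-matched random backgrounds.

Every region is placed in exactly one of six categories by its midpoint's
relation to the nearest gene models, resolved in the precedence order
TSS > promoter > intragenic > proximal > distal > desert:

* ``TSS``        — within 1 kb of a transcription start site (either side)
* ``promoter``   — up to 5 kb upstream of a TSS (strand-aware)
* ``intragenic`` — inside a gene body
* ``proximal``   — up to 10 kb from a gene boundary
* ``distal``     — up to 100 kb from a gene boundary
* ``desert``     — more than 100 kb from any gene

The matched background sampler draws random fixed-width regions whose
category composition equals a target distribution: the genome is tiled at
``region_width // 4`` steps, tile centers are annotated once (vectorized),
and candidate positions are rejection-sampled within eligible tiles until
each category's quota is filled.  The draw is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval

CATEGORIES = ("TSS", "promoter", "intragenic", "proximal", "distal", "desert")

TSS_BP = 1_000
PROMOTER_BP = 5_000
PROXIMAL_BP = 10_000
DISTAL_BP = 100_000


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene body with a strand-aware TSS (start if +, end-1 if -)."""

    name: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals given as parallel arrays."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def _member(starts: np.ndarray, ends: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Membership of positions in a merged, sorted union of intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    ok[ok] = pos[ok] < ends[idx[ok]]
    return ok


class GeneAnnotator:
    """Precomputed per-chromosome structures for fast midpoint annotation."""

    def __init__(self, genes: Sequence[GeneModel], chrom_sizes: Mapping[str, int] | None = None):
        if not genes:
            raise ValueError("gene list must be non-empty")
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        self._tss: dict[str, np.ndarray] = {}
        self._prom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._body: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._prox: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._dist: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        per: dict[str, list[GeneModel]] = {}
        for g in genes:
            per.setdefault(g.interval.chrom, []).append(g)
        for chrom, gs in per.items():
            tss = np.array(sorted(g.tss for g in gs), dtype=np.int64)
            self._tss[chrom] = tss
            prom_s, prom_e = [], []
            for g in gs:
                if g.strand == "+":
                    prom_s.append(max(0, g.tss - PROMOTER_BP))
                    prom_e.append(g.tss)
                else:
                    prom_s.append(g.tss + 1)
                    prom_e.append(g.tss + 1 + PROMOTER_BP)
            self._prom[chrom] = _merge(np.asarray(prom_s), np.asarray(prom_e))
            body_s = np.array([g.interval.start for g in gs], dtype=np.int64)
            body_e = np.array([g.interval.end for g in gs], dtype=np.int64)
            self._body[chrom] = _merge(body_s, body_e)
            self._prox[chrom] = _merge(
                np.maximum(body_s - PROXIMAL_BP, 0), body_e + PROXIMAL_BP
            )
            self._dist[chrom] = _merge(
                np.maximum(body_s - DISTAL_BP, 0), body_e + DISTAL_BP
            )

    def annotate_positions(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Category index (into CATEGORIES) for each position on a chromosome."""
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), CATEGORIES.index("desert"), dtype=np.int8)
        if chrom not in self._tss:
            return out
        tss = self._tss[chrom]
        idx = np.clip(np.searchsorted(tss, pos), 1, len(tss)) - 1
        near = np.minimum(
            np.abs(pos - tss[idx]),
            np.abs(pos - tss[np.minimum(idx + 1, len(tss) - 1)]),
        )
        remaining = near > TSS_BP
        out[~remaining] = CATEGORIES.index("TSS")
        for name, table in (
            ("promoter", self._prom),
            ("intragenic", self._body),
            ("proximal", self._prox),
            ("distal", self._dist),
        ):
            if not remaining.any():
                break
            member = _member(*table[chrom], pos[remaining])
            hit_idx = np.nonzero(remaining)[0][member]
            out[hit_idx] = CATEGORIES.index(name)
            remaining[hit_idx] = False
        return out

    def annotate_midpoint(self, interval: GenomicInterval) -> str:
        idx = self.annotate_positions(
            interval.chrom, np.array([interval.midpoint], dtype=np.int64)
        )[0]
        return CATEGORIES[idx]


def annotate_region(interval: GenomicInterval, genes: Sequence[GeneModel]) -> str:
    """Annotate one region by its midpoint; builds a throwaway annotator.

    For bulk work construct a :class:`GeneAnnotator` once and reuse it.
    """
    return GeneAnnotator(genes).annotate_midpoint(interval)


def annotation_distribution(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel] | GeneAnnotator,
) -> dict[str, float]:
    """Per-category fractions of a region set; fractions sum to 1."""
    if not regions:
        raise ValueError("region list must be non-empty")
    annotator = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(genes)
    counts = np.zeros(len(CATEGORIES), dtype=np.int64)
    per: dict[str, list[int]] = {}
    for r in regions:
        per.setdefault(r.chrom, []).append(r.midpoint)
    for chrom, mids in per.items():
        idx = annotator.annotate_positions(chrom, np.asarray(mids))
        counts += np.bincount(idx, minlength=len(CATEGORIES))
    fracs = counts / counts.sum()
    return dict(zip(CATEGORIES, fracs.tolist()))


def _quota(target: Mapping[str, float], n: int) -> dict[str, int]:
    """Integer per-category counts summing to n (largest-remainder rounding)."""
    raw = np.array([target.get(cat, 0.0) for cat in CATEGORIES], dtype=float)
    if raw.sum() <= 0:
        raise ValueError("target distribution is empty")
    raw = raw / raw.sum() * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return {cat: int(c) for cat, c in zip(CATEGORIES, base)}


class MatchedBackgroundSampler:
    """Annotation-matched random region sampler over a tiled genome.

    Tiling and tile annotation are computed once per (genes, chrom_sizes,
    region_width); individual draws are then cheap, which matters when one
    background of 200,000 regions is drawn per dataset.
    """

    def __init__(
        self,
        genes: Sequence[GeneModel] | GeneAnnotator,
        chrom_sizes: Mapping[str, int],
        region_width: int = 200,
    ):
        if region_width <= 0:
            raise ValueError("region_width must be > 0")
        self.annotator = genes if isinstance(genes, GeneAnnotator) else GeneAnnotator(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self.region_width = region_width
        self.step = max(1, region_width // 4)
        half = region_width // 2
        chroms, centers, cats = [], [], []
        for ci, (chrom, size) in enumerate(sorted(self.chrom_sizes.items())):
            lo, hi = half, size - (region_width - half)
            if hi < lo:
                continue
            c = np.arange(lo, hi + 1, self.step, dtype=np.int64)
            chroms.append(np.full(len(c), ci, dtype=np.int32))
            centers.append(c)
            cats.append(self.annotator.annotate_positions(chrom, c))
        self._chrom_names = [c for c, _ in sorted(self.chrom_sizes.items())]
        self._tile_chrom = np.concatenate(chroms)
        self._tile_center = np.concatenate(centers)
        self._tile_cat = np.concatenate(cats)
        self._tiles_by_cat = {
            cat: np.nonzero(self._tile_cat == i)[0] for i, cat in enumerate(CATEGORIES)
        }

    def sample(
        self, target: Mapping[str, float], n: int, seed: int
    ) -> list[GenomicInterval]:
        """Draw n regions whose re-annotated categories match the target.

        Per-category counts are ``round(n * fraction)`` with the remainder
        assigned by largest fractional part; every returned region's midpoint
        annotation equals its assigned category (verified by rejection).
        """
        if n <= 0:
            raise ValueError("n must be > 0")
        rng = np.random.default_rng(seed)
        quota = _quota(target, n)
        half = self.region_width // 2
        out: list[GenomicInterval] = []
        for ci, cat in enumerate(CATEGORIES):
            need = quota[cat]
            if need == 0:
                continue
            tiles = self._tiles_by_cat[cat]
            if len(tiles) == 0:
                raise ValueError(
                    f"no genomic space eligible for category {cat!r} "
                    f"(target fraction {target.get(cat, 0.0):.4f})"
                )
            got = 0
            while got < need:
                batch = max(256, int((need - got) * 1.5))
                pick = rng.choice(tiles, size=batch)
                offset = rng.integers(-(self.step // 2), self.step - self.step // 2, size=batch)
                centers = self._tile_center[pick] + offset
                chrom_idx = self._tile_chrom[pick]
                for cj in np.unique(chrom_idx):
                    chrom = self._chrom_names[cj]
                    size = self.chrom_sizes[chrom]
                    sel = chrom_idx == cj
                    c = np.clip(centers[sel], half, size - (self.region_width - half))
                    ok = self.annotator.annotate_positions(chrom, c) == ci
                    for center in c[ok]:
                        if got >= need:
                            break
                        start = int(center) - half
                        out.append(
                            GenomicInterval(chrom, start, start + self.region_width)
                        )
                        got += 1
        return out


def sample_matched_random(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    target: Mapping[str, float],
    n: int,
    region_width: int = 200,
    seed: int = 0,
) -> list[GenomicInterval]:
    """One-shot matched background draw (see :class:`MatchedBackgroundSampler`)."""
    sampler = MatchedBackgroundSampler(genes, chrom_sizes, region_width)
    return sampler.sample(target, n, seed)
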