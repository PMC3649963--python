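"""Core genomic coordinate types and interval algebra.

All coordinates are 0-based, half-open (``[start, end)``), the UCSC table
convention; strand is ``+``, ``-`` or ``.`` (unstranded).  DHS and ChIP
peaks are unstranded; repeats and genes are stranded, and strand is only
consumed by aggregate profiles and TSS computation.

The overlap kernels are vectorized numpy (sorted starts + prefix-max of
ends) because the matched-background step issues millions of fixed-width
queries; a brute-force all-pairs oracle in the test suite guards them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: the eight tissue groups used to organize the DNase datasets
TISSUE_GROUPS = (
    "Fibroblast",
    "Muscle",
    "Epithelial",
    "Lymphoblastoid",
    "Others",
    "hESC",
    "Solid_tumor",
    "Leukemia",
)

LAB_GROUPS = ("UW", "Duke")

#: repeat classes as carried through the pipeline
REPEAT_CLASSES = (
    "LTR/ERV",
    "DNA",
    "LINE",
    "SINE",
    "Low_complexity",
    "Simple_repeat",
    "Other",
)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """floor((start + end) / 2) — the convention used for resizing."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Peak:
    """A called peak (narrowPeak-style) around an unstranded interval."""

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    neglog10_p: float | None = None
    neglog10_q: float | None = None
    point_source: int | None = None

    def __post_init__(self):
        if self.point_source is not None and not (
            0 <= self.point_source < self.interval.length
        ):
            raise ValueError(
                f"point_source {self.point_source} outside [0, {self.interval.length})"
            )


@dataclass(frozen=True, slots=True)
class RepeatInstance:
    """One genomic copy of a repeat subfamily, with RepeatMasker divergence."""

    interval: GenomicInterval
    subfamily: str
    family: str
    repclass: str
    milli_div: int

    def __post_init__(self):
        if not (0 <= self.milli_div <= 1000):
            raise ValueError(f"milli_div must be in [0, 1000], got {self.milli_div}")
        if self.repclass not in REPEAT_CLASSES:
            raise ValueError(
                f"repclass must be one of {REPEAT_CLASSES}, got {self.repclass!r}"
            )


@dataclass(slots=True)
class DHSDataset:
    """One DNase I hypersensitivity dataset (one cell line / replicate)."""

    dataset_id: str
    cell_type: str
    tissue_group: str
    lab_group: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self):
        if self.tissue_group not in TISSUE_GROUPS:
            raise ValueError(
                f"tissue_group must be one of {TISSUE_GROUPS}, got {self.tissue_group!r}"
            )
        if self.lab_group not in LAB_GROUPS:
            raise ValueError(
                f"lab_group must be one of {LAB_GROUPS}, got {self.lab_group!r}"
            )

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


@dataclass(slots=True)
class TagSet:
    """Sequenced-tag positions for one dataset, with per-tag GC fraction."""

    dataset_id: str
    chroms: np.ndarray  # object array of chromosome names
    positions: np.ndarray  # int array
    strands: np.ndarray  # '+'/'-' array
    gc: np.ndarray  # float array, per-tag GC fraction

    def __post_init__(self):
        if len(self.positions) and int(np.min(self.positions)) < 0:
            raise ValueError("tag positions must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(slots=True)
class Cluster:
    """A maximal merged group of intervals (peak clustering output)."""

    interval: GenomicInterval
    members: list
    member_indices: list = field(default_factory=list)  # positions in the input


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------

def resize_to_center(
    interval: GenomicInterval, width: int, chrom_length: int | None = None
) -> GenomicInterval:
    """Resize an interval to ``width`` bp centered on its midpoint.

    The window is ``[mid - width//2, mid - width//2 + width)`` and is shifted
    (not truncated) to stay within ``[0, chrom_length)``.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    start = interval.midpoint - width // 2
    end = start + width
    if start < 0:
        start, end = 0, width
    if chrom_length is not None and end > chrom_length:
        end = chrom_length
        start = max(0, end - width)
    return GenomicInterval(interval.chrom, start, end, interval.strand)


def cluster_regions(
    intervals: Sequence[GenomicInterval], max_gap: int
) -> list[Cluster]:
    """Group intervals whose inter-interval gap is strictly below ``max_gap``.

    Overlapping intervals count as gap 0, so with ``max_gap > 0`` they always
    merge; with ``max_gap == 0`` nothing merges (the strict inequality is
    deliberate and matches "within less than N bp").  Clusters are maximal
    chains and each cluster carries the merged span plus its members.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom, intervals[i].start))
    clusters: list[Cluster] = []
    cur: list = []
    cur_idx: list[int] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for i in order:
        iv = intervals[i]
        gap = max(0, iv.start - cur_end)
        if cur and iv.chrom == cur_chrom and gap < max_gap:
            cur.append(intervals[i])
            cur_idx.append(i)
            cur_end = max(cur_end, iv.end)
        else:
            if cur:
                clusters.append(
                    Cluster(GenomicInterval(cur_chrom, cur_start, cur_end), cur, cur_idx)
                )
            cur = [intervals[i]]
            cur_idx = [i]
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur:
        clusters.append(Cluster(GenomicInterval(cur_chrom, cur_start, cur_end), cur, cur_idx))
    return clusters


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group intervals into per-chromosome (starts, ends, original-index) arrays."""
    buckets: dict[str, list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(intervals):
        buckets.setdefault(iv.chrom, []).append((iv.start, iv.end, idx))
    out = {}
    for chrom, rows in buckets.items():
        arr = np.asarray(rows, dtype=np.int64)
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        out[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
    return out


def overlaps_any(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    s_starts_sorted: np.ndarray,
    s_ends_by_start: np.ndarray,
) -> np.ndarray:
    """Boolean per query: does it share >= 1 base with any subject interval?

    Subjects must be sorted by start; ``s_ends_by_start`` are the matching
    ends.  Classic sweep: a query overlaps some subject iff among subjects
    starting before the query end, the running maximum end exceeds the query
    start.
    """
    if len(s_starts_sorted) == 0:
        return np.zeros(len(q_starts), dtype=bool)
    max_ends = np.maximum.accumulate(s_ends_by_start)
    idx = np.searchsorted(s_starts_sorted, q_ends, side="left")
    hit = idx > 0
    hit[hit] = max_ends[idx[hit] - 1] > q_starts[hit]
    return hit


class RegionIndex:
    """Sorted per-chromosome index of intervals for fast any-overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._chrom = _by_chrom(intervals)
        self.n = len(intervals)

    def any_overlap(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Boolean array over the query intervals."""
        flags = np.zeros(len(intervals), dtype=bool)
        per = _by_chrom(intervals)
        for chrom, (qs, qe, qidx) in per.items():
            if chrom not in self._chrom:
                continue
            ss, se, _ = self._chrom[chrom]
            flags[qidx] = overlaps_any(qs, qe, ss, se)
        return flags

    def hit_subject_indices(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        """Original indices of every subject overlapped by >= 1 query interval."""
        hit_ids: list[np.ndarray] = []
        per = _by_chrom(intervals)
        for chrom, (qs, qe, _) in per.items():
            if chrom not in self._chrom:
                continue
            ss, se, sidx = self._chrom[chrom]
            flags = overlaps_any(ss, se, qs, qe)
            hit_ids.append(sidx[flags])
        if not hit_ids:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hit_ids))


def count_region_overlaps(
    regions: Sequence[GenomicInterval],
    subjects: Sequence[GenomicInterval],
) -> np.ndarray:
    """Number of regions overlapping each subject interval (pair counts).

    Counting rule: a (region, subject) pair overlaps iff it shares >= 1
    base; the result is the per-subject count of such pairs, computed from
    sorted start/end arrays (``overlapping = N - starts_after - ends_before``).
    """
    out = np.zeros(len(subjects), dtype=np.int64)
    per_q = _by_chrom(regions)
    per_s = _by_chrom(subjects)
    for chrom, (ss, se, sidx) in per_s.items():
        if chrom not in per_q:
            continue
        qs, qe, _ = per_q[chrom]
        qe_sorted = np.sort(qe)
        n = len(qs)
        starts_after = n - np.searchsorted(qs, se, side="left")
        ends_before = np.searchsorted(qe_sorted, ss, side="right")
        out[sidx] = n - starts_after - ends_before
    return out


def overlapping_instance_sets(
    regions: Sequence[GenomicInterval],
    instances: Sequence[RepeatInstance],
) -> tuple[dict[str, frozenset[int]], np.ndarray]:
    """Per-subfamily sets of instance indices overlapped by >= 1 region.

    Overlap means >= 1 shared base; each instance is counted at most once.
    Also returns per-region boolean flags (region touches >= 1 instance).
    Instance indices refer to positions in ``instances``.
    """
    region_index = RegionIndex(regions)
    inst_hit = region_index.any_overlap([inst.interval for inst in instances])
    by_subfamily: dict[str, set[int]] = {}
    for i in np.nonzero(inst_hit)[0]:
        by_subfamily.setdefault(instances[i].subfamily, set()).add(int(i))
    inst_index = RegionIndex([inst.interval for inst in instances])
    region_flags = inst_index.any_overlap(regions)
    return (
        {sf: frozenset(ids) for sf, ids in by_subfamily.items()},
        region_flags,
    )


def qc_tag_gc(
    tagset: TagSet, low: float = 0.45, high: float = 0.55
) -> tuple[float, bool]:
    """Mean GC fraction of a tag set and whether it passes the GC-bias QC.

    Datasets whose mean tag GC falls outside [low, high] (defaults 45–55%)
    are flagged as failing.
    """
    if len(tagset) == 0:
        raise ValueError(f"tagset {tagset.dataset_id} is empty")
    mean_gc = float(np.mean(tagset.gc))
    return mean_gc, bool(low <= mean_gc <= high)


def aggregate_profile(
    tag_chroms: np.ndarray,
    tag_positions: np.ndarray,
    instances: Sequence[RepeatInstance],
    flank: int,
) -> np.ndarray:
    """Strand-oriented aggregate tag density anchored at instance starts.

    Output length is ``flank + max(instance length) + flank``; entry ``j`` is
    the total number of tags at oriented offset ``j - flank`` from the
    instance start, divided by the number of instances.  Minus-strand
    instances are coordinate-reversed so that profiles align on the repeat's
    own 5' end.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if not instances:
        raise ValueError("instance list is empty")
    max_len = max(inst.interval.length for inst in instances)
    out_len = 2 * flank + max_len
    profile = np.zeros(out_len, dtype=float)
    # sort tag positions per chromosome once
    per_chrom: dict[str, np.ndarray] = {}
    tag_chroms = np.asarray(tag_chroms)
    tag_positions = np.asarray(tag_positions)
    for chrom in np.unique(tag_chroms):
        per_chrom[str(chrom)] = np.sort(tag_positions[tag_chroms == chrom])
    for inst in instances:
        pos = per_chrom.get(inst.interval.chrom)
        if pos is None or len(pos) == 0:
            continue
        iv = inst.interval
        if iv.strand == "-":
            lo, hi = iv.end - 1 + flank - (out_len - 1), iv.end - 1 + flank + 1
            window = pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]
            offsets = (iv.end - 1 + flank) - window
        else:
            lo, hi = iv.start - flank, iv.start - flank + out_len
            window = pos[np.searchsorted(pos, lo): np.searchsorted(pos, hi)]
            offsets = window - (iv.start - flank)
        keep = (offsets >= 0) & (offsets < out_len)
        np.add.at(profile, offsets[keep], 1.0)
    return profile / len(instances)
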