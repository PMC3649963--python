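"""Repeat subfamily age from divergence, and lineage partition bookkeeping.

Subfamily age is an alignment-free Jukes–Cantor estimate: the mean per-mil
divergence of the instances from their consensus (RepeatMasker milliDiv)
is converted to a substitution distance d = -(3/4) ln(1 - 4p/3) and then
to years with a constant substitution rate (default 2.2e-9 per site per
year, divergence accruing on one lineage).  Subfamilies younger than the
primate cutoff (default 95 Myr) are classed as primate-specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import REPEAT_CLASSES, Cluster, RepeatInstance


@dataclass(frozen=True, slots=True)
class AgeModel:
    substitution_rate: float = 2.2e-9  # substitutions / site / year
    primate_cutoff_myrs: float = 95.0

    def __post_init__(self):
        if self.substitution_rate <= 0:
            raise ValueError("substitution_rate must be > 0")


def jukes_cantor_age(
    mean_milli_div: float, model: AgeModel = AgeModel()
) -> tuple[float, float]:
    """(JC distance, age in Myr) from a mean per-mil divergence.

    Undefined (raises) at p >= 0.75 where the JC correction diverges.
    """
    if not (0 <= mean_milli_div < 1000):
        raise ValueError("mean_milli_div must be in [0, 1000)")
    p = mean_milli_div / 1000.0
    if p >= 0.75:
        raise ValueError(f"Jukes-Cantor undefined at proportion {p} >= 0.75")
    d = -0.75 * math.log1p(-4.0 * p / 3.0)
    age_myrs = d / model.substitution_rate / 1e6
    return d, age_myrs


def subfamily_profiles(
    instances: Sequence[RepeatInstance],
    model: AgeModel = AgeModel(),
    genome: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-subfamily summary: mean divergence, JC age, primate flag, size, GC."""
    if not instances:
        raise ValueError("instance list must be non-empty")
    rows: dict[str, dict] = {}
    for inst in instances:
        row = rows.setdefault(
            inst.subfamily,
            {"repclass": inst.repclass, "milli": [], "lengths": [], "gc": []},
        )
        row["milli"].append(inst.milli_div)
        row["lengths"].append(inst.interval.length)
        if genome is not None:
            seq = genome[inst.interval.chrom][inst.interval.start: inst.interval.end]
            row["gc"].append((seq.count("G") + seq.count("C")) / max(1, len(seq)))
    records = []
    for subfamily, row in sorted(rows.items()):
        mean_div = sum(row["milli"]) / len(row["milli"])
        d, age = jukes_cantor_age(mean_div, model)
        records.append(
            {
                "subfamily": subfamily,
                "repclass": row["repclass"],
                "n_instances": len(row["milli"]),
                "mean_milli_div": mean_div,
                "jc_distance": d,
                "age_myrs": age,
                "primate_specific": age < model.primate_cutoff_myrs,
                "mean_length": sum(row["lengths"]) / len(row["lengths"]),
                "mean_gc": (sum(row["gc"]) / len(row["gc"])) if row["gc"] else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)


def lineage_partition(
    clusters: Sequence[Cluster],
    lineage_labels: Sequence[str],
    instances: Sequence[RepeatInstance],
) -> pd.DataFrame:
    """Per-lineage cluster counts and repeat-class overlap proportions.

    Every cluster must carry a lineage label (e.g. pre-mammalian / mammalian
    / primate / human, supplied by the caller).  Each cluster is attributed
    to at most one repeat class — the class covering the most bases of the
    merged span, ties broken by the canonical class order — so per-lineage
    proportions sum to <= 1, the remainder being clusters in no repeat.
    """
    if len(clusters) != len(lineage_labels):
        raise ValueError("one lineage label is required per cluster")
    for i, label in enumerate(lineage_labels):
        if label is None or label == "":
            raise ValueError(f"cluster {i} is unlabeled")

    # merged per-class interval tables for fast coverage lookups
    merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for c in REPEAT_CLASSES:
        per: dict[str, list[tuple[int, int]]] = {}
        for r in instances:
            if r.repclass == c:
                per.setdefault(r.interval.chrom, []).append(
                    (r.interval.start, r.interval.end)
                )
        merged[c] = {
            chrom: _merge_pairs(pairs) for chrom, pairs in per.items()
        }
    assigned: list[str | None] = []
    for cl in clusters:
        best, best_cov = None, 0
        for c in REPEAT_CLASSES:
            table = merged[c].get(cl.interval.chrom)
            cov = _coverage(cl.interval, table) if table else 0
            if cov > best_cov:
                best, best_cov = c, cov
        assigned.append(best if best_cov > 0 else None)

    labels = sorted(set(lineage_labels))
    records = []
    for label in labels:
        idx = [i for i, l in enumerate(lineage_labels) if l == label]
        n = len(idx)
        rec = {"lineage": label, "n_clusters": n}
        for c in REPEAT_CLASSES:
            rec[c] = sum(1 for i in idx if assigned[i] == c) / n if n else 0.0
        rec["no_repeat"] = sum(1 for i in idx if assigned[i] is None) / n if n else 0.0
        records.append(rec)
    return pd.DataFrame.from_records(records)


def _merge_pairs(pairs: list[tuple[int, int]]) -> tuple["np.ndarray", "np.ndarray"]:
    pairs = sorted(pairs)
    starts, ends = [pairs[0][0]], [pairs[0][1]]
    for s, e in pairs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _coverage(iv, table: tuple["np.ndarray", "np.ndarray"]) -> int:
    """Bases of ``iv`` covered by a merged, sorted interval table."""
    starts, ends = table
    lo = np.searchsorted(ends, iv.start, side="right")
    hi = np.searchsorted(starts, iv.end, side="left")
    if hi <= lo:
        return 0
    s = np.maximum(starts[lo:hi], iv.start)
    e = np.minimum(ends[lo:hi], iv.end)
    return int(np.sum(np.maximum(0, e - s)))
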