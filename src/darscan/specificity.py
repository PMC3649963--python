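"""Cell-type specificity of repeat subfamily open-chromatin contribution.

Per (subfamily, dataset) the observed number of open instances is first
normalized by the dataset's total peak count, then divided by the median
normalized count across datasets of the same lab group (UW and Duke
medians are computed separately because of their different read lengths
and hence mappability).  A fold above 3 in a dataset where the subfamily
is also a DAR marks it as cell-type specific.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import DHSDataset, RegionIndex, cluster_regions
from .darcall import DARCallOutput


@dataclass(slots=True)
class SpecificityRecord:
    subfamily: str
    dataset_id: str
    normalized_count: float
    group_median: float
    specificity_fold: float
    is_dar: bool
    is_specific: bool


def normalized_counts(output: DARCallOutput, datasets: Sequence[DHSDataset]) -> pd.DataFrame:
    """observed / n_peaks per (subfamily, dataset)."""
    n_peaks = {d.dataset_id: d.n_peaks for d in datasets}
    frame = output.to_frame()
    frame["normalized_count"] = frame["observed"] / frame["dataset_id"].map(n_peaks)
    return frame


def specificity_table(
    output: DARCallOutput,
    datasets: Sequence[DHSDataset],
    fold_cutoff: float = 3.0,
    min_group: int = 3,
) -> pd.DataFrame:
    """Full specificity table with lab-group medians and fold > cutoff flags.

    The focal dataset is included in its own group median.  A group median
    of zero with a positive value yields an infinite fold (flagged); a
    subfamily absent everywhere in the group gets fold 1.
    """
    lab_of = {d.dataset_id: d.lab_group for d in datasets}
    group_sizes = pd.Series(list(lab_of.values())).value_counts()
    for group, size in group_sizes.items():
        if size < min_group:
            raise ValueError(
                f"lab group {group!r} has only {size} datasets (need >= {min_group})"
            )
    frame = normalized_counts(output, datasets)
    frame["lab_group"] = frame["dataset_id"].map(lab_of)
    medians = (
        frame.groupby(["subfamily", "lab_group"])["normalized_count"]
        .median()
        .rename("group_median")
    )
    frame = frame.join(medians, on=["subfamily", "lab_group"])

    def _fold(row):
        value, median = row["normalized_count"], row["group_median"]
        if median == 0:
            return 1.0 if value == 0 else math.inf
        return value / median

    frame["specificity_fold"] = frame.apply(_fold, axis=1)
    frame["is_specific"] = (frame["specificity_fold"] > fold_cutoff) & frame["is_dar"]
    return frame[
        [
            "subfamily",
            "dataset_id",
            "lab_group",
            "repclass",
            "observed",
            "normalized_count",
            "group_median",
            "specificity_fold",
            "is_dar",
            "is_specific",
        ]
    ]


def cluster_breadth(
    datasets: Sequence[DHSDataset],
    repeats=None,
    max_gap: int = 100,
) -> pd.DataFrame:
    """Histogram of distinct cell types per cross-dataset DHS cluster.

    Clusters are built over the union of all datasets' peaks; per breadth
    bin the fraction of clusters overlapping >= 1 repeat instance is
    reported when repeats are supplied.
    """
    if len(datasets) < 2:
        raise ValueError("cluster breadth needs >= 2 datasets")
    intervals, cell_types = [], []
    for d in datasets:
        for p in d.peaks:
            intervals.append(p.interval)
            cell_types.append(d.cell_type)
    clusters = cluster_regions(intervals, max_gap)
    breadths = []
    for cl in clusters:
        breadths.append(len({cell_types[i] for i in cl.member_indices}))
    breadths = np.asarray(breadths)
    if repeats is not None:
        index = RegionIndex([r.interval for r in repeats])
        overlap = index.any_overlap([cl.interval for cl in clusters])
    else:
        overlap = np.zeros(len(clusters), dtype=bool)
    records = []
    for b in range(1, int(breadths.max()) + 1):
        sel = breadths == b
        n = int(sel.sum())
        records.append(
            {
                "n_cell_types": b,
                "n_clusters": n,
                "n_overlapping_repeat": int(overlap[sel].sum()),
                "fraction_overlapping_repeat": float(overlap[sel].mean()) if n else math.nan,
            }
        )
    return pd.DataFrame.from_records(records)
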