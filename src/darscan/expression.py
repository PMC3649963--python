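"""Cell-type-specific expression of genes near open repeat instances.

A gene is called up-regulated in a cell type when its Z-score — the
deviation of one of that cell type's datasets from the mean/SD of all
other cell types' datasets — exceeds 2.  For a DAR, the genes within a
window (default 50 kb) of its open instances are collected and the number
of up-regulated ones among them is compared to a permutation null that
repeatedly draws the same number of genes uniformly without replacement
from the array's gene universe (default 10,000 draws); the result is the
permutation Z-score of cell-type-specific expression.

The permutation statistic (count of up-regulated genes in a uniform
no-replacement draw) is hypergeometric-distributed, so the draws are
realized with a seeded hypergeometric sampler — distributionally
identical to drawing gene names, and the closed-form hypergeometric
moments serve as an independent oracle in the tests.

The RNA-seq variant applies the same logic to 50-kb windows: windows
centered on open instances are tested against a genome segmented into
non-overlapping background windows of the same width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, RegionIndex, RepeatInstance
from .stats import zscore

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class ExpressionMatrix:
    """Log-scale expression values: genes x datasets with cell-type labels."""

    values: pd.DataFrame  # index = gene names, columns = dataset ids
    cell_types: pd.Series  # dataset id -> cell type

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("gene names must be unique")
        missing = [c for c in self.values.columns if c not in self.cell_types.index]
        if missing:
            raise ValueError(f"datasets without cell-type labels: {missing}")

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.index)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(self.values.columns) + "\n")
            fh.write(
                "cell_type\t"
                + "\t".join(str(self.cell_types[c]) for c in self.values.columns)
                + "\n"
            )
            self.values.to_csv(fh, sep="\t", header=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ct_row = fh.readline().rstrip("\n").split("\t")
            if ct_row[0] != "cell_type":
                raise ValueError("second header row must start with 'cell_type'")
            frame = pd.read_csv(fh, sep="\t", header=None, index_col=0)
        frame.columns = header[1:]
        frame.index.name = "gene_id"
        return cls(frame, pd.Series(ct_row[1:], index=header[1:]))


@dataclass(slots=True)
class ExpressionAssociation:
    subfamily: str
    cell_type: str
    n_open_instances: int
    n_assoc: int
    n_upregulated: int
    perm_mean: float
    perm_sd: float
    z_specificity: float
    n_perm: int
    seed: int


def upregulated_genes(
    expr: ExpressionMatrix, cell_type: str, z_threshold: float = 2.0
) -> set[str]:
    """Genes with Z > threshold in >= 1 of the cell type's datasets.

    Z is computed per focal dataset against the mean and SD (ddof=1) of the
    datasets from all other cell types; genes with zero spread elsewhere
    are never called (logged once).
    """
    focal = [c for c in expr.values.columns if expr.cell_types[c] == cell_type]
    others = [c for c in expr.values.columns if expr.cell_types[c] != cell_type]
    if not focal:
        raise ValueError(f"no datasets for cell type {cell_type!r}")
    if len(others) < 2:
        raise ValueError("need >= 2 datasets outside the cell type")
    other_vals = expr.values[others].to_numpy(dtype=float)
    mu = other_vals.mean(axis=1)
    sd = other_vals.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d genes with zero spread outside %s; not callable", degenerate.sum(), cell_type
        )
    out: set[str] = set()
    genes = np.asarray(expr.values.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in focal:
            z = (expr.values[c].to_numpy(dtype=float) - mu) / sd
            called = (~degenerate) & (z > z_threshold)
            out.update(genes[called].tolist())
    return out


def dar_gene_set(
    open_instances: Sequence[RepeatInstance],
    genes: Sequence[GeneModel],
    window_bp: int = 50_000,
) -> set[str]:
    """Distinct genes whose body overlaps a window centered on any open instance."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp // 2
    windows = []
    for inst in open_instances:
        mid = inst.interval.midpoint
        windows.append(
            GenomicInterval(inst.interval.chrom, max(0, mid - half), mid + half)
        )
    if not windows:
        return set()
    index = RegionIndex(windows)
    flags = index.any_overlap([g.interval for g in genes])
    return {g.name for g, hit in zip(genes, flags) if hit}


def expression_permutation_z(
    observed_up: int,
    n_assoc_genes: int,
    upregulated_set: set[str],
    gene_universe: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    subfamily: str = "",
    cell_type: str = "",
    n_open_instances: int = 0,
) -> ExpressionAssociation:
    """Permutation Z of the up-regulated count among DAR-associated genes."""
    N = len(gene_universe)
    if n_assoc_genes > N:
        raise ValueError("more associated genes than the universe holds")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    K = len(upregulated_set & set(gene_universe))
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(K, N - K, n_assoc_genes, size=n_perm) if n_assoc_genes else np.zeros(n_perm)
    mean = float(draws.mean())
    sd = float(draws.std(ddof=0))
    if sd == 0:
        logger.warning("degenerate permutation distribution (sd = 0)")
    z = zscore(observed_up, mean, sd)
    return ExpressionAssociation(
        subfamily=subfamily,
        cell_type=cell_type,
        n_open_instances=n_open_instances,
        n_assoc=n_assoc_genes,
        n_upregulated=observed_up,
        perm_mean=mean,
        perm_sd=sd,
        z_specificity=z,
        n_perm=n_perm,
        seed=seed,
    )


def dar_expression_association(
    open_instances: Sequence[RepeatInstance],
    genes: Sequence[GeneModel],
    expr: ExpressionMatrix,
    cell_type: str,
    window_bp: int = 50_000,
    z_threshold: float = 2.0,
    n_perm: int = 10_000,
    seed: int = 0,
    subfamily: str = "",
    upregulated: set[str] | None = None,
) -> ExpressionAssociation:
    """End-to-end association for one DAR: gene set, up-calls, permutation Z."""
    if upregulated is None:
        upregulated = upregulated_genes(expr, cell_type, z_threshold)
    assoc = dar_gene_set(open_instances, genes, window_bp)
    assoc &= set(expr.gene_names)
    observed = len(assoc & upregulated)
    return expression_permutation_z(
        observed_up=observed,
        n_assoc_genes=len(assoc),
        upregulated_set=upregulated,
        gene_universe=expr.gene_names,
        n_perm=n_perm,
        seed=seed,
        subfamily=subfamily,
        cell_type=cell_type,
        n_open_instances=len(open_instances),
    )


# ---------------------------------------------------------------------------
# RNA-seq window variant
# ---------------------------------------------------------------------------

def _window_density(
    tag_positions: Mapping[str, np.ndarray],
    windows: Sequence[GenomicInterval],
) -> np.ndarray:
    out = np.zeros(len(windows))
    for i, w in enumerate(windows):
        pos = tag_positions.get(w.chrom)
        if pos is None:
            continue
        out[i] = (
            np.searchsorted(pos, w.end) - np.searchsorted(pos, w.start)
        ) / w.length
    return out


def rnaseq_window_z(
    open_instances: Sequence[RepeatInstance],
    tags_by_dataset: Mapping[str, Mapping[str, np.ndarray]],
    dataset_cell_types: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    cell_type: str,
    window_bp: int = 50_000,
    n_perm: int = 10_000,
    seed: int = 0,
    z_threshold: float = 2.0,
    subfamily: str = "",
) -> ExpressionAssociation:
    """Window-based cell-type-specific expression Z for one DAR.

    Tag positions per dataset must be sorted per chromosome.  Chromosomes
    shorter than ``window_bp`` contribute no background windows (logged).
    """
    half = window_bp // 2
    inst_windows = [
        GenomicInterval(
            inst.interval.chrom,
            max(0, inst.interval.midpoint - half),
            inst.interval.midpoint - half + window_bp,
        )
        for inst in open_instances
    ]
    bg_windows: list[GenomicInterval] = []
    for chrom, size in sorted(chrom_sizes.items()):
        if size < window_bp:
            logger.warning("chromosome %s shorter than window; skipped", chrom)
            continue
        for s in range(0, size - window_bp + 1, window_bp):
            bg_windows.append(GenomicInterval(chrom, s, s + window_bp))
    datasets = list(tags_by_dataset)
    focal = [d for d in datasets if dataset_cell_types[d] == cell_type]
    others = [d for d in datasets if dataset_cell_types[d] != cell_type]
    if len(others) < 2:
        raise ValueError("need >= 2 datasets outside the cell type")

    def up_flags(windows: Sequence[GenomicInterval]) -> np.ndarray:
        dens = {d: _window_density(tags_by_dataset[d], windows) for d in datasets}
        other_mat = np.stack([dens[d] for d in others], axis=1)
        mu = other_mat.mean(axis=1)
        sd = other_mat.std(axis=1, ddof=1)
        flags = np.zeros(len(windows), dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            for d in focal:
                z = (dens[d] - mu) / sd
                flags |= (sd > 0) & (z > z_threshold)
        return flags

    observed = int(up_flags(inst_windows).sum())
    bg_flags = up_flags(bg_windows)
    N, K, n = len(bg_windows), int(bg_flags.sum()), len(inst_windows)
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(K, N - K, min(n, N), size=n_perm) if n else np.zeros(n_perm)
    mean, sd = float(draws.mean()), float(draws.std(ddof=0))
    return ExpressionAssociation(
        subfamily=subfamily,
        cell_type=cell_type,
        n_open_instances=len(open_instances),
        n_assoc=len(inst_windows),
        n_upregulated=observed,
        perm_mean=mean,
        perm_sd=sd,
        z_specificity=zscore(observed, mean, sd),
        n_perm=n_perm,
        seed=seed,
    )
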