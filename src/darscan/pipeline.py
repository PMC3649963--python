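"""Stage orchestration: run the analysis end-to-end over a study bundle.

Stages run in dependency order (qc -> dars -> age -> mappability ->
specificity -> tf_assoc -> motifs -> expression -> aux); each writes TSV
artifacts into the output directory and a run manifest records the seed,
parameters and per-stage status.  All randomness derives from the single
run seed combined with stable per-stage hashes, so a rerun with the same
config and inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import os
import time
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .age import AgeModel, subfamily_profiles
from .aux_enrich import StateSegmentation, conservation_enrichment, dsqtl_enrichment, state_proportions
from .darcall import DARCallConfig, call_dars, open_fraction, write_results_tsv
from .expression import dar_expression_association, upregulated_genes
from .intervals import cluster_regions, qc_tag_gc, RegionIndex, resize_to_center
from .mappability import simulate_mappability
from .motifs import (
    classifier_features,
    dinucleotide_shuffle,
    joint_association_test,
    motif_support_rule,
    pwm_scan,
    weighted_rank_average,
)
from .specificity import cluster_breadth, specificity_table
from .synthetic import StudyBundle

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "qc",
    "dars",
    "age",
    "mappability",
    "specificity",
    "tf_assoc",
    "motifs",
    "expression",
    "aux",
)


@dataclass(slots=True)
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    alpha: float = 1e-5
    n_random: int = 200_000
    region_width: int = 200
    cluster_gap: int = 100
    mappability_reads: int = 100_000
    mappability_read_lengths: tuple[int, ...] = (20, 36)
    mappability_mismatches: tuple[int, ...] = (1, 2)
    specificity_cutoff: float = 3.0
    joint_alpha: float = 1e-3
    motif_scan_p: float = 1e-5
    classifier_scan_p: float = 1e-4
    classifier_n_sim: int = 5
    expression_window: int = 50_000
    n_perm: int = 10_000

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _stage_seed(seed: int, stage: str) -> int:
    return (seed ^ zlib.crc32(stage.encode())) % (2**31)


def run_pipeline(bundle: StudyBundle, config: RunConfig, out_dir) -> dict:
    """Execute the enabled stages and return the manifest dictionary."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    enabled = [s for s in ALL_STAGES if s in config.stages]
    skipped = [s for s in ALL_STAGES if s not in config.stages]
    for s in skipped:
        logger.info("stage %s disabled; its outputs are omitted", s)
    dar_output = None
    spec_frame = None
    for stage in enabled:
        t0 = time.time()
        if stage == "dars":
            dar_output = _stage_dars(bundle, config, out_dir)
        elif stage in ("specificity", "tf_assoc", "expression", "aux") and dar_output is None:
            logger.warning("stage %s needs DAR calls; running dars implicitly", stage)
            dar_output = _stage_dars(bundle, config, out_dir)
        if stage == "qc":
            _stage_qc(bundle, out_dir)
        elif stage == "age":
            _stage_age(bundle, out_dir)
        elif stage == "mappability":
            _stage_mappability(bundle, config, out_dir)
        elif stage == "specificity":
            spec_frame = _stage_specificity(bundle, config, dar_output, out_dir)
        elif stage == "tf_assoc":
            _stage_tf_assoc(bundle, config, dar_output, out_dir)
        elif stage == "motifs":
            _stage_motifs(bundle, config, out_dir)
        elif stage == "expression":
            _stage_expression(bundle, config, dar_output, out_dir)
        elif stage == "aux":
            _stage_aux(bundle, config, dar_output, out_dir)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _stage_qc(bundle: StudyBundle, out_dir) -> None:
    rows = []
    for ds_id, tagset in sorted(bundle.tagsets.items()):
        mean_gc, ok = qc_tag_gc(tagset)
        rows.append({"dataset_id": ds_id, "mean_gc": mean_gc, "pass": ok})
    if rows:
        pd.DataFrame(rows).to_csv(os.path.join(out_dir, "qc.tsv"), sep="\t", index=False)
    else:
        logger.warning("no tag sets in bundle; qc stage produced no output")


def _stage_dars(bundle: StudyBundle, config: RunConfig, out_dir):
    dar_config = DARCallConfig(
        alpha=config.alpha,
        n_random=config.n_random,
        region_width=config.region_width,
        seed=_stage_seed(config.seed, "dars"),
    )
    output = call_dars(
        bundle.datasets, bundle.repeats, bundle.genes, bundle.chrom_sizes, dar_config
    )
    write_results_tsv(
        output,
        os.path.join(out_dir, "dars.tsv"),
        comments=[
            f"seed={dar_config.seed} alpha={dar_config.alpha} "
            f"n_random={dar_config.n_random} region_width={dar_config.region_width}"
        ],
    )
    # open fractions over the union of datasets
    subfams = sorted({r.subfamily for r in bundle.repeats})
    n_by_subfam = {sf: 0 for sf in subfams}
    for r in bundle.repeats:
        n_by_subfam[r.subfamily] += 1
    rows = []
    for sf in subfams:
        sets = [
            output.open_instances[d.dataset_id].get(sf, frozenset())
            for d in bundle.datasets
        ]
        rows.append(
            {
                "subfamily": sf,
                "n_instances": n_by_subfam[sf],
                "n_open_any": len(set().union(*sets)),
                "open_fraction": open_fraction(n_by_subfam[sf], sets),
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "open_fractions.tsv"), sep="\t", index=False
    )
    return output


def _stage_age(bundle: StudyBundle, out_dir) -> None:
    frame = subfamily_profiles(bundle.repeats, AgeModel(), genome=bundle.genome)
    frame.to_csv(os.path.join(out_dir, "subfamily_age.tsv"), sep="\t", index=False)


def _stage_mappability(bundle: StudyBundle, config: RunConfig, out_dir) -> None:
    frames = []
    for rl, mm in zip(config.mappability_read_lengths, config.mappability_mismatches):
        frames.append(
            simulate_mappability(
                bundle.genome,
                bundle.repeats,
                read_length=rl,
                n_reads=config.mappability_reads,
                max_mismatches=mm,
                seed=_stage_seed(config.seed, f"mappability{rl}"),
            )
        )
    pd.concat(frames).to_csv(
        os.path.join(out_dir, "mappability.tsv"), sep="\t", index=False
    )


def _stage_specificity(bundle: StudyBundle, config: RunConfig, dar_output, out_dir):
    frame = specificity_table(
        dar_output, bundle.datasets, fold_cutoff=config.specificity_cutoff
    )
    frame.to_csv(os.path.join(out_dir, "specificity.tsv"), sep="\t", index=False)
    breadth = cluster_breadth(bundle.datasets, bundle.repeats, config.cluster_gap)
    breadth.to_csv(os.path.join(out_dir, "cluster_breadth.tsv"), sep="\t", index=False)
    return frame


def _stage_tf_assoc(bundle: StudyBundle, config: RunConfig, dar_output, out_dir) -> None:
    rows = []
    subfam_ids: dict[str, np.ndarray] = {}
    for sf in sorted({r.subfamily for r in bundle.repeats}):
        subfam_ids[sf] = bundle.subfamily_ids(sf)
    for (tf, cell_type), peaks in sorted(bundle.chip_peaks.items()):
        chip_windows = [
            resize_to_center(p.interval, config.region_width, bundle.chrom_sizes.get(p.interval.chrom))
            for p in peaks
        ]
        chip_index = RegionIndex(chip_windows)
        chip_flags_all = chip_index.any_overlap([r.interval for r in bundle.repeats])
        for dataset in bundle.datasets:
            if dataset.cell_type != cell_type:
                continue
            open_sets = dar_output.open_instances[dataset.dataset_id]
            for sf, ids in subfam_ids.items():
                open_ids = open_sets.get(sf, frozenset())
                dhs_flags = np.isin(ids, np.fromiter(open_ids, dtype=np.int64, count=len(open_ids)))
                partner_flags = chip_flags_all[ids]
                assoc = joint_association_test(
                    dhs_flags, partner_flags, sf, tf, alpha=config.joint_alpha
                )
                if assoc.n_both == 0 and not assoc.significant:
                    continue
                rows.append(
                    {
                        "subfamily": sf,
                        "tf": tf,
                        "cell_type": cell_type,
                        "dataset_id": dataset.dataset_id,
                        "n_instances": assoc.n_instances,
                        "n_dhs": assoc.n_dhs,
                        "n_chip": assoc.n_partner,
                        "n_both": assoc.n_both,
                        "log10_p": assoc.hypergeom_log10_p,
                        "significant": assoc.significant,
                    }
                )
    pd.DataFrame(
        rows,
        columns=[
            "subfamily", "tf", "cell_type", "dataset_id", "n_instances",
            "n_dhs", "n_chip", "n_both", "log10_p", "significant",
        ],
    ).to_csv(os.path.join(out_dir, "tf_associations.tsv"), sep="\t", index=False)


def _stage_motifs(bundle: StudyBundle, config: RunConfig, out_dir) -> pd.DataFrame:
    seed = _stage_seed(config.seed, "motifs")
    subfams = sorted({r.subfamily for r in bundle.repeats})
    seqs = {sf: bundle.instance_sequences(sf) for sf in subfams}
    # shared dinucleotide-shuffled pool per subfamily, reused across motifs
    rng = np.random.default_rng(seed)
    shuffled = {
        sf: [
            [dinucleotide_shuffle(s, rng) for s in seqs[sf]]
            for _i in range(config.classifier_n_sim)
        ]
        for sf in subfams
    }
    genome_seqs = {c: bundle.genome[c] for c in sorted(bundle.genome)}
    scannable = sum(len(s) for s in genome_seqs.values())
    rows = []
    for pwm in bundle.pwms:
        genome_hits = len(pwm_scan(genome_seqs, pwm, config.classifier_scan_p))
        for sf in subfams:
            feats = classifier_features(
                seqs[sf],
                bound_flags=None,
                pwm=pwm,
                genome_hits=genome_hits,
                genome_scannable_bp=scannable,
                n_sim=config.classifier_n_sim,
                seed=seed,
                p_threshold=config.classifier_scan_p,
                subfamily=sf,
                shuffled_pool=shuffled[sf],
            )
            rows.append(
                {
                    "motif_id": feats.motif_id,
                    "subfamily": feats.subfamily,
                    "f1_frac_instances_with_motif": feats.f1_frac_instances_with_motif,
                    "f2_frac_genome_hits_in_subfamily": feats.f2_frac_genome_hits_in_subfamily,
                    "f3_bound_unbound_score_ratio": feats.f3_bound_unbound_score_ratio,
                    "f4_enrichment_log10_p": feats.f4_enrichment_log10_p,
                    "f5_generation_ratio": feats.f5_generation_ratio,
                }
            )
    frame = weighted_rank_average(pd.DataFrame(rows))
    frame.to_csv(os.path.join(out_dir, "motif_rank.tsv"), sep="\t", index=False)
    return frame


def _stage_expression(bundle: StudyBundle, config: RunConfig, dar_output, out_dir) -> None:
    ct_of = {d.dataset_id: d.cell_type for d in bundle.datasets}
    up_cache: dict[str, set[str]] = {}
    rows = []
    for r in dar_output.dars():
        cell_type = ct_of[r.dataset_id]
        if cell_type not in up_cache:
            try:
                up_cache[cell_type] = upregulated_genes(bundle.expression, cell_type)
            except ValueError as exc:
                logger.warning("expression skipped for %s: %s", cell_type, exc)
                up_cache[cell_type] = set()
        open_ids = dar_output.open_instances[r.dataset_id].get(r.subfamily, frozenset())
        open_insts = [bundle.repeats[i] for i in sorted(open_ids)]
        assoc = dar_expression_association(
            open_insts,
            bundle.genes,
            bundle.expression,
            cell_type,
            window_bp=config.expression_window,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, f"expr|{r.subfamily}|{r.dataset_id}"),
            subfamily=r.subfamily,
            upregulated=up_cache[cell_type],
        )
        rows.append(
            {
                "subfamily": r.subfamily,
                "dataset_id": r.dataset_id,
                "cell_type": cell_type,
                "n_open": assoc.n_open_instances,
                "n_genes": assoc.n_assoc,
                "n_upregulated": assoc.n_upregulated,
                "perm_mean": assoc.perm_mean,
                "perm_sd": assoc.perm_sd,
                "z": assoc.z_specificity,
                "n_perm": assoc.n_perm,
                "seed": assoc.seed,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "subfamily", "dataset_id", "cell_type", "n_open", "n_genes",
            "n_upregulated", "perm_mean", "perm_sd", "z", "n_perm", "seed",
        ],
    ).to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t", index=False)


def _stage_aux(bundle: StudyBundle, config: RunConfig, dar_output, out_dir) -> None:
    # chromatin states per cell type (first dataset of each)
    state_rows = []
    for ct, segments in sorted(bundle.segmentations.items()):
        datasets = [d for d in bundle.datasets if d.cell_type == ct]
        if not datasets:
            continue
        seg = StateSegmentation(ct, segments)
        regions = [p.interval for p in datasets[0].peaks]
        rep_index = RegionIndex([r.interval for r in bundle.repeats])
        flags = rep_index.any_overlap(regions)
        props = state_proportions(
            regions,
            flags,
            seg,
            bundle.chrom_sizes,
            n_random=5_000,
            seed=_stage_seed(config.seed, f"states|{ct}"),
        )
        props["cell_type"] = ct
        state_rows.append(props.reset_index(names="state"))
    if state_rows:
        pd.concat(state_rows).to_csv(
            os.path.join(out_dir, "chromatin_states.tsv"), sep="\t", index=False
        )

    # conservation of open instances
    open_union: set[int] = set()
    for sets in dar_output.open_instances.values():
        for ids in sets.values():
            open_union |= ids
    cons = conservation_enrichment(bundle.repeats, sorted(open_union), bundle.cnees)

    # dsQTL enrichment over lymphoblastoid clusters
    lympho = [d for d in bundle.datasets if d.cell_type == "Lymphoblastoid"]
    rows = [
        {
            "label": cons.label,
            "n_total": cons.n_total,
            "n_hit": cons.n_hit,
            "fraction": cons.fraction,
            "comparison_fraction": cons.comparison_fraction,
            "log10_p": cons.log10_p,
        }
    ]
    if lympho and bundle.dsqtls:
        clusters = cluster_regions(
            [p.interval for d in lympho for p in d.peaks], config.cluster_gap
        )
        dar_subfams = {
            r.subfamily
            for r in dar_output.dars()
            if any(d.dataset_id == r.dataset_id for d in lympho)
        }
        dar_ids: set[int] = set()
        for d in lympho:
            for sf in dar_subfams:
                dar_ids |= dar_output.open_instances[d.dataset_id].get(sf, frozenset())
        dar_index = RegionIndex([bundle.repeats[i].interval for i in sorted(dar_ids)])
        flags = dar_index.any_overlap([cl.interval for cl in clusters])
        ds = dsqtl_enrichment(bundle.dsqtls, clusters, flags)
        rows.append(
            {
                "label": ds.label,
                "n_total": ds.n_total,
                "n_hit": ds.n_hit,
                "fraction": ds.fraction,
                "comparison_fraction": ds.comparison_fraction,
                "log10_p": ds.log10_p,
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "aux_enrichments.tsv"), sep="\t", index=False
    )
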