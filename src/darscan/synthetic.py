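"""Seeded generator of a complete synthetic open-chromatin study.

The generator emulates the structure of a multi-cell-type DNase I study
over a repeat-rich genome: a small genome with CpG-depleted composition,
non-overlapping repeat instances derived from per-subfamily consensus
sequences at controlled divergence, gene models, per-dataset DHS peak
sets with planted subfamily-by-cell-type enrichments, ChIP peaks and
planted motifs co-localized with the active instances, an expression
matrix with shifted genes near active instances, chromatin-state
segmentations, conserved elements planted preferentially on open
instances, and dsQTLs biased toward DAR-contributed clusters.  A truth
table records every planted effect for recovery scoring.

Peak backgrounds are uniform over the genome, which by construction makes
the annotation-matched background an unbiased estimate of the null hit
rate, so null subfamilies calibrate to observed/expected near 1.
Everything is reproducible bit-for-bit from ``master_seed``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dio
from .annotation import GeneModel
from .expression import ExpressionMatrix
from .intervals import (
    DHSDataset,
    GenomicInterval,
    Peak,
    RepeatInstance,
    TagSet,
    RegionIndex,
    resize_to_center,
)
from .motifs import PWM

_BASES = np.array(list("ACGT"))


@dataclass(slots=True)
class DatasetSpec:
    dataset_id: str
    cell_type: str
    tissue_group: str
    lab_group: str
    n_peaks: int


@dataclass(slots=True)
class ChipFactorSpec:
    tf: str
    cell_type: str
    target_subfamilies: tuple[str, ...]
    bind_probability: float
    n_background: int = 300


@dataclass(slots=True)
class MotifPlantSpec:
    motif_id: str
    subfamily: str
    fraction: float
    length: int = 10


@dataclass(slots=True)
class StudyConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_subfamilies: int = 40
    instances_per_subfamily: tuple[int, int] = (100, 500)
    instance_length: tuple[int, int] = (120, 300)
    milli_div_mean_range: tuple[float, float] = (30.0, 250.0)
    milli_div_spread: float = 20.0
    n_genes: int = 300
    gc_content: float = 0.41
    peak_width: int = 150
    datasets: list[DatasetSpec] = field(default_factory=lambda: _default_datasets())
    enrichment: dict[tuple[str, str], float] = field(
        default_factory=lambda: _default_enrichment()
    )
    chip_factors: list[ChipFactorSpec] = field(
        default_factory=lambda: _default_chip_factors()
    )
    motif_plants: list[MotifPlantSpec] = field(
        default_factory=lambda: _default_motif_plants()
    )
    n_decoy_motifs: int = 2
    expression_effect: float = 4.0  # shift in noise-SD units near active instances
    expression_noise_sd: float = 1.0
    cnee_rate: float = 0.05  # per closed instance; doubled on open instances
    n_dsqtls: int = 400
    dsqtl_dar_fraction: float = 0.30
    n_tags_per_peak: int = 4
    master_seed: int = 20130509

    def __post_init__(self):
        for (sf, ct), fold in self.enrichment.items():
            if fold < 1:
                raise ValueError(f"planted fold for ({sf}, {ct}) must be >= 1")
        for spec in self.chip_factors:
            if not (0 <= spec.bind_probability <= 1):
                raise ValueError("bind probability must be in [0, 1]")
        for spec in self.motif_plants:
            if not (0 <= spec.fraction <= 1):
                raise ValueError("motif plant fraction must be in [0, 1]")


def subfamily_name(i: int) -> str:
    return f"SYN{i:02d}"


def _default_datasets() -> list[DatasetSpec]:
    rows = [
        ("H7esc", "hESC", "hESC", "UW", 1200),
        ("H1esc", "hESC", "hESC", "UW", 1100),
        ("K562", "Leukemia", "Leukemia", "UW", 1400),
        ("GM12878", "Lymphoblastoid", "Lymphoblastoid", "UW", 1300),
        ("HepG2", "Solid_tumor", "Solid_tumor", "UW", 1000),
        ("NHLF", "Fibroblast", "Fibroblast", "UW", 900),
        ("HSMM", "Muscle", "Muscle", "UW", 1000),
        ("SAEC", "Epithelial", "Epithelial", "UW", 1100),
        ("GM12865", "Lymphoblastoid", "Lymphoblastoid", "Duke", 800),
        ("Myometrial", "Others", "Others", "Duke", 900),
        ("HeLa-S3", "Solid_tumor", "Solid_tumor", "Duke", 1000),
        ("HCM", "Muscle", "Muscle", "Duke", 850),
    ]
    return [DatasetSpec(*row[:2], row[2], row[3], row[4]) for row in rows]


def _default_enrichment() -> dict[tuple[str, str], float]:
    # planted DARs: (subfamily, cell type) -> fold over the background rate
    return {
        (subfamily_name(0), "hESC"): 10.0,
        (subfamily_name(1), "Leukemia"): 8.0,
        (subfamily_name(2), "Lymphoblastoid"): 6.0,
        (subfamily_name(3), "Solid_tumor"): 5.0,
        (subfamily_name(4), "Fibroblast"): 5.0,
        (subfamily_name(5), "Muscle"): 7.0,
    }


def _default_chip_factors() -> list[ChipFactorSpec]:
    return [
        ChipFactorSpec("OCT4", "hESC", (subfamily_name(0),), 0.8),
        ChipFactorSpec("CTCF", "Leukemia", (subfamily_name(1),), 0.8),
    ]


def _default_motif_plants() -> list[MotifPlantSpec]:
    return [
        MotifPlantSpec("MOTIF_A", subfamily_name(0), 0.6),
        MotifPlantSpec("MOTIF_B", subfamily_name(1), 0.6),
        MotifPlantSpec("MOTIF_C", subfamily_name(2), 0.5),
        MotifPlantSpec("MOTIF_D", subfamily_name(5), 0.5),
    ]


@dataclass(slots=True)
class StudyBundle:
    """The generated study: every pipeline input plus the planted truth."""

    config: StudyConfig
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    repeats: list[RepeatInstance]
    genes: list[GeneModel]
    datasets: list[DHSDataset]
    tagsets: dict[str, TagSet]
    chip_peaks: dict[tuple[str, str], list[Peak]]
    pwms: list[PWM]
    expression: ExpressionMatrix
    segmentations: dict[str, list[tuple[GenomicInterval, str]]]
    cnees: list[GenomicInterval]
    dsqtls: list[GenomicInterval]
    truth: pd.DataFrame
    active_instances: dict[tuple[str, str], np.ndarray]  # (subfamily, cell_type) -> ids

    def instance_sequences(self, subfamily: str) -> list[str]:
        out = []
        for r in self.repeats:
            if r.subfamily == subfamily:
                out.append(
                    self.genome[r.interval.chrom][r.interval.start: r.interval.end]
                )
        return out

    def subfamily_ids(self, subfamily: str) -> np.ndarray:
        return np.array(
            [i for i, r in enumerate(self.repeats) if r.subfamily == subfamily],
            dtype=np.int64,
        )

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        dio.write_fasta(self.genome, os.path.join(out_dir, "genome.fa"))
        dio.write_rmsk(self.repeats, os.path.join(out_dir, "repeats.rmsk.tsv"))
        dio.write_genes(self.genes, os.path.join(out_dir, "genes.bed"))
        peaks_dir = os.path.join(out_dir, "peaks")
        os.makedirs(peaks_dir, exist_ok=True)
        meta = []
        for d in self.datasets:
            dio.write_narrowpeak(
                d.peaks, os.path.join(peaks_dir, f"{d.dataset_id}.narrowPeak")
            )
            meta.append(
                {
                    "dataset_id": d.dataset_id,
                    "cell_type": d.cell_type,
                    "tissue_group": d.tissue_group,
                    "lab_group": d.lab_group,
                }
            )
        pd.DataFrame(meta).to_csv(
            os.path.join(out_dir, "datasets.tsv"), sep="\t", index=False
        )
        tags_dir = os.path.join(out_dir, "tags")
        os.makedirs(tags_dir, exist_ok=True)
        for ds_id, ts in self.tagsets.items():
            seqs = [
                self.genome[c][p: p + 20] for c, p in zip(ts.chroms, ts.positions)
            ]
            dio.write_tagalign(
                ts, seqs, 20, os.path.join(tags_dir, f"{ds_id}.tagAlign")
            )
        chip_dir = os.path.join(out_dir, "chip")
        os.makedirs(chip_dir, exist_ok=True)
        for (tf, ct), peaks in self.chip_peaks.items():
            dio.write_narrowpeak(
                peaks, os.path.join(chip_dir, f"{tf}__{ct}.narrowPeak")
            )
        dio.write_jaspar(self.pwms, os.path.join(out_dir, "motifs.jaspar"))
        self.expression.write_tsv(os.path.join(out_dir, "expression.tsv"))
        states_dir = os.path.join(out_dir, "states")
        os.makedirs(states_dir, exist_ok=True)
        for ct, segments in self.segmentations.items():
            dio.write_bed4_states(segments, os.path.join(states_dir, f"{ct}.bed"))
        dio.write_bed(self.cnees, os.path.join(out_dir, "cnee.bed"))
        dio.write_bed(self.dsqtls, os.path.join(out_dir, "dsqtl.bed"))
        self.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "active_instances.json"), "w") as fh:
            json.dump(
                {f"{sf}|{ct}": ids.tolist() for (sf, ct), ids in self.active_instances.items()},
                fh,
            )
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(_config_to_json(self.config), fh, indent=1)


def _config_to_json(config: StudyConfig) -> dict:
    d = asdict(config)
    d["enrichment"] = {f"{sf}|{ct}": v for (sf, ct), v in config.enrichment.items()}
    return d


def _markov_genome(size: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """CpG-depleted first-order composition as uint8 codes (A,C,G,T=0..3)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=size, p=p).astype(np.uint8)
    # deplete CpG dinucleotides: G following C mutated to A with prob 0.6
    cpg = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
    hit = cpg[rng.random(len(cpg)) < 0.6] + 1
    codes[hit] = 0
    return codes


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    hit = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hit):
        out[hit] = (out[hit] + rng.integers(1, 4, size=len(hit))) % 4
    return out


def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Generate the full synthetic study from ``config.master_seed``."""
    config = config or StudyConfig()
    root = np.random.SeedSequence(config.master_seed)
    rngs = {
        name: np.random.default_rng(ss)
        for name, ss in zip(
            [
                "genome", "repeats", "genes", "peaks", "chip",
                "motifs", "expression", "states", "cnee", "dsqtl", "tags",
            ],
            root.spawn(11),
        )
    }
    chroms = sorted(config.chrom_sizes)
    genome_codes = {
        c: _markov_genome(config.chrom_sizes[c], config.gc_content, rngs["genome"])
        for c in chroms
    }
    genome_len = sum(config.chrom_sizes.values())

    # ------------------------------------------------------------------ repeats
    rng = rngs["repeats"]
    lo_n, hi_n = config.instances_per_subfamily
    counts = rng.integers(lo_n, hi_n + 1, size=config.n_subfamilies)
    # planted subfamilies need enough instances to be detectable
    planted_subfams = {sf for (sf, _ct) in config.enrichment}
    for i in range(config.n_subfamilies):
        if subfamily_name(i) in planted_subfams:
            counts[i] = max(counts[i], 200)
    lo_l, hi_l = config.instance_length
    consensus_len = hi_l
    consensus = {
        subfamily_name(i): rng.integers(0, 4, size=consensus_len).astype(np.uint8)
        for i in range(config.n_subfamilies)
    }
    classes = ["LTR/ERV", "DNA", "LINE", "SINE"]
    repclass = {
        subfamily_name(i): classes[i % len(classes)] for i in range(config.n_subfamilies)
    }
    family = {
        subfamily_name(i): f"FAM{i % 7}" for i in range(config.n_subfamilies)
    }
    div_means = rng.uniform(*config.milli_div_mean_range, size=config.n_subfamilies)

    total_instances = int(counts.sum())
    lengths = rng.integers(lo_l, hi_l + 1, size=total_instances)
    need_bp = int(lengths.sum())
    if need_bp > 0.6 * genome_len:
        raise ValueError(
            f"genome too small: need >= {int(need_bp / 0.6)} bp to host "
            f"{total_instances} instances"
        )
    # greedy non-overlapping placement: oversample starts, sort, accept gaps
    slots: list[tuple[str, int]] = []
    max_len = int(lengths.max())
    for c in chroms:
        n_target = int(round(total_instances * config.chrom_sizes[c] / genome_len * 4))
        starts = np.sort(rng.integers(0, config.chrom_sizes[c] - max_len, size=n_target))
        prev_end = -1
        for s in starts:
            if s > prev_end:
                slots.append((c, int(s)))
                prev_end = s + max_len + 5
    if len(slots) < total_instances:
        raise ValueError("genome too small for requested instance count")
    pick = rng.choice(len(slots), size=total_instances, replace=False)
    slot_order = rng.permutation(total_instances)

    repeats: list[RepeatInstance] = []
    inst_meta: list[tuple[str, int]] = []  # (subfamily, index-within)
    k = 0
    for i in range(config.n_subfamilies):
        sf = subfamily_name(i)
        for _j in range(counts[i]):
            chrom, start = slots[pick[slot_order[k]]]
            L = int(lengths[k])
            md = float(np.clip(rng.normal(div_means[i], config.milli_div_spread), 0, 600))
            inst_codes = _mutate(consensus[sf][:L], md / 1000.0, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            write_codes = inst_codes if strand == "+" else _revcomp_codes(inst_codes)
            genome_codes[chrom][start: start + L] = write_codes
            repeats.append(
                RepeatInstance(
                    interval=GenomicInterval(chrom, start, start + L, strand),
                    subfamily=sf,
                    family=family[sf],
                    repclass=repclass[sf],
                    milli_div=int(round(md)),
                )
            )
            inst_meta.append((sf, k))
            k += 1

    # ------------------------------------------------------------------ genes
    rng = rngs["genes"]
    genes: list[GeneModel] = []
    for g in range(config.n_genes):
        chrom = chroms[int(rng.choice(len(chroms), p=[config.chrom_sizes[c] / genome_len for c in chroms]))]
        length = int(np.clip(rng.lognormal(math.log(8000), 0.6), 1000, 60_000))
        start = int(rng.integers(0, config.chrom_sizes[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                name=f"GENE{g:04d}",
                interval=GenomicInterval(chrom, start, start + length, strand),
                strand=strand,
            )
        )

    # ------------------------------------------------------------------ motifs
    rng = rngs["motifs"]
    pwms: list[PWM] = []
    plant_sites: dict[str, np.ndarray] = {}  # motif_id -> consensus codes
    for spec in config.motif_plants:
        site = rng.integers(0, 4, size=spec.length).astype(np.uint8)
        plant_sites[spec.motif_id] = site
        counts_m = np.full((spec.length, 4), 2.0)
        counts_m[np.arange(spec.length), site] = 50.0
        pwms.append(PWM.from_counts(spec.motif_id, counts_m))
    for d in range(config.n_decoy_motifs):
        L = 10
        site = rng.integers(0, 4, size=L)
        counts_m = np.full((L, 4), 2.0)
        counts_m[np.arange(L), site] = 50.0
        pwms.append(PWM.from_counts(f"DECOY_{d}", counts_m))
    # plant motif sites into instance sequences (forward genome coordinates)
    motif_planted_ids: dict[str, np.ndarray] = {}
    sub_ids = {
        subfamily_name(i): np.array(
            [j for j, (sf, _k) in enumerate(inst_meta) if sf == subfamily_name(i)]
        )
        for i in range(config.n_subfamilies)
    }
    for spec in config.motif_plants:
        ids = sub_ids[spec.subfamily]
        chosen = rng.choice(ids, size=int(round(spec.fraction * len(ids))), replace=False)
        site = plant_sites[spec.motif_id]
        for j in chosen:
            iv = repeats[j].interval
            if iv.length <= len(site) + 2:
                continue
            off = int(rng.integers(0, iv.length - len(site)))
            genome_codes[iv.chrom][iv.start + off: iv.start + off + len(site)] = site
        motif_planted_ids[spec.motif_id] = np.sort(chosen)

    genome = {c: _codes_to_str(genome_codes[c]) for c in chroms}

    # ------------------------------------------------------------------ peaks
    rng = rngs["peaks"]
    width = config.peak_width
    truth_rows: list[dict] = []
    active: dict[tuple[str, str], np.ndarray] = {}
    inst_len = np.array([r.interval.length for r in repeats], dtype=np.int64)
    datasets: list[DHSDataset] = []
    for spec in config.datasets:
        n_peaks = spec.n_peaks
        planted_positions: list[tuple[str, int]] = []
        for (sf, ct), fold in config.enrichment.items():
            if ct != spec.cell_type or fold <= 1:
                continue
            ids = sub_ids[sf]
            # per-instance background hit probability for this dataset
            q = np.minimum(
                1.0, n_peaks * (inst_len[ids] + 200.0) / genome_len
            ).mean()
            n_plant = int(round((fold - 1.0) * len(ids) * q / max(1e-9, 1.0 - q)))
            n_plant = min(n_plant, int(0.9 * len(ids)))
            key = (sf, spec.cell_type)
            if key in active:
                chosen = active[key]  # same instances active in every dataset
                chosen = chosen[: n_plant] if n_plant < len(chosen) else chosen
            else:
                chosen = np.sort(rng.choice(ids, size=n_plant, replace=False))
                active[key] = chosen
            for j in chosen:
                iv = repeats[j].interval
                planted_positions.append((iv.chrom, iv.midpoint))
            truth_rows.append(
                {
                    "effect": "dar",
                    "subfamily": sf,
                    "cell_type": ct,
                    "dataset_id": spec.dataset_id,
                    "value": fold,
                    "n": len(chosen),
                }
            )
        n_bg = n_peaks - len(planted_positions)
        if n_bg < 0:
            raise ValueError(
                f"dataset {spec.dataset_id}: planted peaks exceed n_peaks"
            )
        bg_chrom = rng.choice(
            len(chroms), size=n_bg, p=[config.chrom_sizes[c] / genome_len for c in chroms]
        )
        peaks: list[Peak] = []
        for ci in bg_chrom:
            c = chroms[ci]
            mid = int(rng.integers(width, config.chrom_sizes[c] - width))
            planted_positions.append((c, mid))
        for c, mid in planted_positions:
            half = width // 2
            start = max(0, mid - half)
            peaks.append(
                Peak(
                    interval=GenomicInterval(c, start, start + width),
                    name=f"{spec.dataset_id}_{len(peaks)}",
                    score=float(rng.integers(100, 1000)),
                    signal=float(rng.uniform(1, 20)),
                    neglog10_p=float(rng.uniform(2, 30)),
                    neglog10_q=None,
                    point_source=half,
                )
            )
        datasets.append(
            DHSDataset(
                dataset_id=spec.dataset_id,
                cell_type=spec.cell_type,
                tissue_group=spec.tissue_group,
                lab_group=spec.lab_group,
                peaks=peaks,
            )
        )

    # ------------------------------------------------------------------ tags
    rng = rngs["tags"]
    tagsets: dict[str, TagSet] = {}
    for d in datasets:
        n_tags = config.n_tags_per_peak * len(d.peaks)
        pick = rng.integers(0, len(d.peaks), size=n_tags)
        chrom_list, pos_list = [], []
        for pi in pick:
            iv = d.peaks[pi].interval
            pos = int(np.clip(rng.normal(iv.midpoint, width / 4), 0, config.chrom_sizes[iv.chrom] - 21))
            chrom_list.append(iv.chrom)
            pos_list.append(pos)
        gc = np.array(
            [
                (genome[c][p: p + 20].count("G") + genome[c][p: p + 20].count("C")) / 20.0
                for c, p in zip(chrom_list, pos_list)
            ]
        )
        tagsets[d.dataset_id] = TagSet(
            dataset_id=d.dataset_id,
            chroms=np.asarray(chrom_list, dtype=object),
            positions=np.asarray(pos_list, dtype=np.int64),
            strands=np.asarray(["+" if rng.random() < 0.5 else "-" for _ in pos_list], dtype=object),
            gc=gc,
        )

    # ------------------------------------------------------------------ ChIP
    rng = rngs["chip"]
    chip_peaks: dict[tuple[str, str], list[Peak]] = {}
    for spec in config.chip_factors:
        peaks = []
        bound_ids = []
        for sf in spec.target_subfamilies:
            ids = active.get((sf, spec.cell_type), np.empty(0, dtype=np.int64))
            for j in ids:
                if rng.random() < spec.bind_probability:
                    iv = repeats[j].interval
                    mid = iv.midpoint
                    start = max(0, mid - 100)
                    peaks.append(
                        Peak(
                            interval=GenomicInterval(iv.chrom, start, start + 200),
                            name=f"{spec.tf}_{len(peaks)}",
                            score=900.0,
                            signal=10.0,
                            point_source=100,
                        )
                    )
                    bound_ids.append(int(j))
        for _b in range(spec.n_background):
            c = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, config.chrom_sizes[c] - 200))
            peaks.append(
                Peak(
                    interval=GenomicInterval(c, start, start + 200),
                    name=f"{spec.tf}_bg{_b}",
                    score=300.0,
                    signal=3.0,
                    point_source=100,
                )
            )
        chip_peaks[(spec.tf, spec.cell_type)] = peaks
        truth_rows.append(
            {
                "effect": "chip",
                "subfamily": ",".join(spec.target_subfamilies),
                "cell_type": spec.cell_type,
                "dataset_id": spec.tf,
                "value": spec.bind_probability,
                "n": len(bound_ids),
            }
        )

    # ------------------------------------------------------------------ motif truth
    for spec in config.motif_plants:
        truth_rows.append(
            {
                "effect": "motif",
                "subfamily": spec.subfamily,
                "cell_type": "",
                "dataset_id": spec.motif_id,
                "value": spec.fraction,
                "n": len(motif_planted_ids[spec.motif_id]),
            }
        )

    # ------------------------------------------------------------------ expression
    rng = rngs["expression"]
    gene_names = [g.name for g in genes]
    ds_ids = [d.dataset_id for d in datasets]
    base = rng.normal(8.0, 2.0, size=len(genes))
    noise = rng.normal(0.0, config.expression_noise_sd, size=(len(genes), len(ds_ids)))
    values = base[:, None] + noise
    gene_index = {g.name: i for i, g in enumerate(genes)}
    ct_of = {d.dataset_id: d.cell_type for d in datasets}
    for (sf, ct), ids in active.items():
        open_insts = [repeats[j] for j in ids]
        from .expression import dar_gene_set

        nearby = dar_gene_set(open_insts, genes, 50_000)
        shift = config.expression_effect * config.expression_noise_sd
        cols = [ci for ci, d in enumerate(ds_ids) if ct_of[d] == ct]
        for name in nearby:
            values[gene_index[name], cols] += shift
        truth_rows.append(
            {
                "effect": "expression",
                "subfamily": sf,
                "cell_type": ct,
                "dataset_id": "",
                "value": shift,
                "n": len(nearby),
            }
        )
    expression = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_names, columns=ds_ids),
        cell_types=pd.Series([ct_of[d] for d in ds_ids], index=ds_ids),
    )

    # ------------------------------------------------------------------ states
    rng = rngs["states"]
    state_names = sorted(set(_state_pool()))
    segmentations: dict[str, list[tuple[GenomicInterval, str]]] = {}
    for ct in sorted({d.cell_type for d in datasets}):
        segs = []
        for c in chroms:
            pos = 0
            size = config.chrom_sizes[c]
            while pos < size:
                ln = int(np.clip(rng.exponential(2000), 200, 20000))
                end = min(size, pos + ln)
                segs.append(
                    (GenomicInterval(c, pos, end), _state_pool()[int(rng.integers(0, 15))])
                )
                pos = end
        segmentations[ct] = segs

    # ------------------------------------------------------------------ CNEEs
    rng = rngs["cnee"]
    all_peak_windows = [
        resize_to_center(p.interval, 200, config.chrom_sizes[p.interval.chrom])
        for d in datasets
        for p in d.peaks
    ]
    open_flags = RegionIndex(all_peak_windows).any_overlap(
        [r.interval for r in repeats]
    )
    cnees: list[GenomicInterval] = []
    for j, r in enumerate(repeats):
        rate = 2 * config.cnee_rate if open_flags[j] else config.cnee_rate
        if rng.random() < rate:
            iv = r.interval
            ln = min(50, iv.length)
            off = int(rng.integers(0, max(1, iv.length - ln)))
            cnees.append(GenomicInterval(iv.chrom, iv.start + off, iv.start + off + ln))
    for _x in range(500):  # background conserved elements outside repeats
        c = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, config.chrom_sizes[c] - 50))
        cnees.append(GenomicInterval(c, start, start + 50))
    truth_rows.append(
        {
            "effect": "cnee",
            "subfamily": "",
            "cell_type": "",
            "dataset_id": "",
            "value": config.cnee_rate,
            "n": len(cnees),
        }
    )

    # ------------------------------------------------------------------ dsQTLs
    rng = rngs["dsqtl"]
    from .intervals import cluster_regions

    lympho = [d for d in datasets if d.cell_type == "Lymphoblastoid"]
    dsqtls: list[GenomicInterval] = []
    if lympho:
        clusters = cluster_regions(
            [p.interval for d in lympho for p in d.peaks], max_gap=100
        )
        lympho_active = np.concatenate(
            [ids for (sf, ct), ids in active.items() if ct == "Lymphoblastoid"]
        ) if any(ct == "Lymphoblastoid" for (_sf, ct) in active) else np.empty(0, np.int64)
        active_index = RegionIndex([repeats[j].interval for j in lympho_active])
        dar_flags = active_index.any_overlap([cl.interval for cl in clusters])
        dar_clusters = [cl for cl, f in zip(clusters, dar_flags) if f]
        other_clusters = [cl for cl, f in zip(clusters, dar_flags) if not f]
        for _x in range(config.n_dsqtls):
            u = rng.random()
            if u < config.dsqtl_dar_fraction and dar_clusters:
                cl = dar_clusters[int(rng.integers(0, len(dar_clusters)))]
                iv = cl.interval
            elif u < 0.8 and other_clusters:
                cl = other_clusters[int(rng.integers(0, len(other_clusters)))]
                iv = cl.interval
            else:
                c = chroms[int(rng.integers(0, len(chroms)))]
                s = int(rng.integers(0, config.chrom_sizes[c] - 60))
                iv = GenomicInterval(c, s, s + 60)
            s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 40)))
            dsqtls.append(GenomicInterval(iv.chrom, s, s + 40))
        truth_rows.append(
            {
                "effect": "dsqtl",
                "subfamily": "",
                "cell_type": "Lymphoblastoid",
                "dataset_id": "",
                "value": config.dsqtl_dar_fraction,
                "n": len(dsqtls),
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["effect", "subfamily", "cell_type", "dataset_id", "value", "n"],
    )
    return StudyBundle(
        config=config,
        genome=genome,
        chrom_sizes=dict(config.chrom_sizes),
        repeats=repeats,
        genes=genes,
        datasets=datasets,
        tagsets=tagsets,
        chip_peaks=chip_peaks,
        pwms=pwms,
        expression=expression,
        segmentations=segmentations,
        cnees=cnees,
        dsqtls=dsqtls,
        truth=truth,
        active_instances=active,
    )


def _state_pool() -> list[str]:
    from .aux_enrich import DEFAULT_STATE_GROUPING

    return sorted(DEFAULT_STATE_GROUPING)


# ---------------------------------------------------------------------------
# truth scoring
# ---------------------------------------------------------------------------

def truth_report(
    bundle: StudyBundle,
    dar_output=None,
    specificity_frame: pd.DataFrame | None = None,
    motif_frame: pd.DataFrame | None = None,
    expression_results: Sequence | None = None,
) -> dict:
    """Recovery metrics for whichever pipeline outputs are supplied."""
    report: dict = {}
    planted = bundle.truth[bundle.truth["effect"] == "dar"]
    if dar_output is not None:
        frame = dar_output.to_frame()
        ct_of = {d.dataset_id: d.cell_type for d in bundle.datasets}
        frame["cell_type"] = frame["dataset_id"].map(ct_of)
        planted_keys = {
            (row["subfamily"], row["dataset_id"]) for _i, row in planted.iterrows()
        }
        is_planted = frame.apply(
            lambda r: (r["subfamily"], r["dataset_id"]) in planted_keys, axis=1
        )
        detected = frame["is_dar"]
        n_planted = int(is_planted.sum())
        report["dar_sensitivity"] = (
            float(detected[is_planted].mean()) if n_planted else math.nan
        )
        null = ~is_planted
        report["dar_false_positive_rate"] = (
            float(detected[null].mean()) if null.any() else math.nan
        )
        report["n_planted_pairs"] = n_planted
        report["n_null_pairs"] = int(null.sum())
        # calibration over null pairs
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = frame.loc[null, "observed"] / frame.loc[null, "expected"]
        report["null_mean_obs_over_exp"] = float(ratio.replace([np.inf, -np.inf], np.nan).dropna().mean())
    if specificity_frame is not None:
        hits = []
        for _i, row in planted.iterrows():
            sel = specificity_frame[
                (specificity_frame["subfamily"] == row["subfamily"])
                & (specificity_frame["dataset_id"] == row["dataset_id"])
            ]
            if len(sel):
                hits.append(bool((sel["specificity_fold"] > 3).any()))
        report["specificity_recovered"] = float(np.mean(hits)) if hits else math.nan
    if motif_frame is not None:
        planted_pairs = {
            (row["dataset_id"], row["subfamily"])
            for _i, row in bundle.truth[bundle.truth["effect"] == "motif"].iterrows()
        }
        sel = motif_frame.apply(
            lambda r: (r["motif_id"], r["subfamily"]) in planted_pairs, axis=1
        )
        report["motif_top_decile_sensitivity"] = (
            float(motif_frame.loc[sel, "top_decile"].mean()) if sel.any() else math.nan
        )
    if expression_results is not None:
        zs = [r.z_specificity for r in expression_results]
        report["expression_min_planted_z"] = float(min(zs)) if zs else math.nan
        report["expression_median_planted_z"] = float(np.median(zs)) if zs else math.nan
    return report


def load_bundle(bundle_dir) -> StudyBundle:
    """Read a written bundle back through the pipeline's own readers."""
    genome = dio.read_fasta(os.path.join(bundle_dir, "genome.fa"))
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    repeats = dio.read_regions(os.path.join(bundle_dir, "repeats.rmsk.tsv"), "rmsk")
    genes = dio.read_genes(os.path.join(bundle_dir, "genes.bed"))
    meta = pd.read_csv(os.path.join(bundle_dir, "datasets.tsv"), sep="\t")
    datasets = []
    for _i, row in meta.iterrows():
        peaks = dio.read_regions(
            os.path.join(bundle_dir, "peaks", f"{row['dataset_id']}.narrowPeak"),
            "narrowPeak",
        )
        datasets.append(
            DHSDataset(
                dataset_id=row["dataset_id"],
                cell_type=row["cell_type"],
                tissue_group=row["tissue_group"],
                lab_group=row["lab_group"],
                peaks=peaks,
            )
        )
    tagsets = {}
    tags_dir = os.path.join(bundle_dir, "tags")
    if os.path.isdir(tags_dir):
        for fn in sorted(os.listdir(tags_dir)):
            ds_id = fn.rsplit(".", 1)[0]
            tagsets[ds_id] = dio.read_tagalign(os.path.join(tags_dir, fn), ds_id)
    chip_peaks = {}
    chip_dir = os.path.join(bundle_dir, "chip")
    if os.path.isdir(chip_dir):
        for fn in sorted(os.listdir(chip_dir)):
            tf, ct = fn.rsplit(".", 1)[0].split("__")
            chip_peaks[(tf, ct)] = dio.read_regions(
                os.path.join(chip_dir, fn), "narrowPeak"
            )
    pwms = dio.read_jaspar(os.path.join(bundle_dir, "motifs.jaspar"))
    expression = ExpressionMatrix.read_tsv(os.path.join(bundle_dir, "expression.tsv"))
    segmentations = {}
    states_dir = os.path.join(bundle_dir, "states")
    if os.path.isdir(states_dir):
        for fn in sorted(os.listdir(states_dir)):
            segmentations[fn.rsplit(".", 1)[0]] = dio.read_bed4_states(
                os.path.join(states_dir, fn)
            )
    cnees = dio.read_regions(os.path.join(bundle_dir, "cnee.bed"), "bed")
    dsqtls = dio.read_regions(os.path.join(bundle_dir, "dsqtl.bed"), "bed")
    truth = pd.read_csv(os.path.join(bundle_dir, "truth.tsv"), sep="\t").fillna("")
    with open(os.path.join(bundle_dir, "config.json")) as fh:
        cfg = json.load(fh)
    config = _config_from_json(cfg)
    active = {}
    active_path = os.path.join(bundle_dir, "active_instances.json")
    if os.path.exists(active_path):
        with open(active_path) as fh:
            for key, ids in json.load(fh).items():
                sf, ct = key.split("|")
                active[(sf, ct)] = np.asarray(ids, dtype=np.int64)
    return StudyBundle(
        config=config,
        genome=genome,
        chrom_sizes=chrom_sizes,
        repeats=repeats,
        genes=genes,
        datasets=datasets,
        tagsets=tagsets,
        chip_peaks=chip_peaks,
        pwms=pwms,
        expression=expression,
        segmentations=segmentations,
        cnees=cnees,
        dsqtls=dsqtls,
        truth=truth,
        active_instances=active,
    )


def _config_from_json(d: dict) -> StudyConfig:
    d = dict(d)
    d["enrichment"] = {
        tuple(k.split("|")): v for k, v in d.get("enrichment", {}).items()
    }
    d["datasets"] = [DatasetSpec(**row) for row in d.get("datasets", [])]
    d["chip_factors"] = [
        ChipFactorSpec(**{**row, "target_subfamilies": tuple(row["target_subfamilies"])})
        for row in d.get("chip_factors", [])
    ]
    d["motif_plants"] = [MotifPlantSpec(**row) for row in d.get("motif_plants", [])]
    d["chrom_sizes"] = dict(d["chrom_sizes"])
    d["instances_per_subfamily"] = tuple(d["instances_per_subfamily"])
    d["instance_length"] = tuple(d["instance_length"])
    d["milli_div_mean_range"] = tuple(d["milli_div_mean_range"])
    return StudyConfig(**d)
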