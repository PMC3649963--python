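"""Readers and writers for the plain-text genomics formats the pipeline uses.

Supported: BED3/BED6, ENCODE narrowPeak (10 columns), a UCSC rmsk-style
repeat table (genoName, genoStart, genoEnd, strand, repName, repClass,
repFamily, milliDiv), tagAlign, FASTA (via Biopython) and JASPAR / minimal
MEME motif files.  All coordinates are read and written as 0-based
half-open; writers emit deterministic, coordinate-sorted output so that a
read→write round trip is bit-exact on the coordinate columns.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, Peak, RepeatInstance, TagSet

FORMATS = ("bed", "narrowPeak", "rmsk")

#: rmsk repClass strings mapped onto the pipeline's repeat classes
_RMSK_CLASS = {
    "LTR": "LTR/ERV",
    "LTR/ERV": "LTR/ERV",
    "DNA": "DNA",
    "LINE": "LINE",
    "SINE": "SINE",
    "Low_complexity": "Low_complexity",
    "Simple_repeat": "Simple_repeat",
}


class ParseError(ValueError):
    """Raised for malformed records; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _opt_float(token: str) -> float | None:
    value = float(token)
    return None if value == -1 else value


def read_regions(path, format: str):
    """Parse a region file into Peak / GenomicInterval / RepeatInstance lists.

    ``format`` must be one of ``bed`` (BED3/BED6), ``narrowPeak`` or
    ``rmsk``.  Malformed lines raise :class:`ParseError` naming the line.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[5] if len(fields) >= 6 else "."
                    records.append(GenomicInterval(chrom, start, end, strand))
                elif format == "narrowPeak":
                    if len(fields) < 10:
                        raise ValueError(f"expected 10 columns, got {len(fields)}")
                    interval = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                    point = int(fields[9])
                    records.append(
                        Peak(
                            interval=interval,
                            name=fields[3],
                            score=float(fields[4]),
                            signal=float(fields[6]),
                            neglog10_p=_opt_float(fields[7]),
                            neglog10_q=_opt_float(fields[8]),
                            point_source=None if point == -1 else point,
                        )
                    )
                else:  # rmsk
                    if len(fields) < 8:
                        raise ValueError(f"expected 8 columns, got {len(fields)}")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    strand = fields[3]
                    repclass = _RMSK_CLASS.get(fields[5], "Other")
                    records.append(
                        RepeatInstance(
                            interval=GenomicInterval(chrom, start, end, strand),
                            subfamily=fields[4],
                            repclass=repclass,
                            family=fields[6],
                            milli_div=int(fields[7]),
                        )
                    )
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return records


def _sorted_by_coord(items, key):
    return sorted(items, key=key)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path,
    header_comments: Sequence[str] = (),
    bed6: bool = False,
) -> None:
    """Write intervals as BED3 (or BED6 with a dot name/score), sorted."""
    rows = _sorted_by_coord(list(intervals), lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for iv in rows:
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_narrowpeak(peaks: Iterable[Peak], path, header_comments: Sequence[str] = ()) -> None:
    rows = _sorted_by_coord(
        list(peaks), lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )

    def fmt(x: float | None) -> str:
        return "-1" if x is None else f"{x:g}"

    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for p in rows:
            iv = p.interval
            point = -1 if p.point_source is None else p.point_source
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t.\t"
                f"{p.signal:g}\t{fmt(p.neglog10_p)}\t{fmt(p.neglog10_q)}\t{point}\n"
            )


def write_rmsk(instances: Iterable[RepeatInstance], path, header_comments: Sequence[str] = ()) -> None:
    rows = _sorted_by_coord(
        list(instances), lambda r: (r.interval.chrom, r.interval.start, r.interval.end)
    )
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for r in rows:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\t{r.subfamily}\t"
                f"{r.repclass}\t{r.family}\t{r.milli_div}\n"
            )


def read_genes(path) -> list:
    """Read gene models from BED6 (name in column 4, strand in column 6)."""
    from .annotation import GeneModel  # local import to avoid a cycle

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < 6:
                    raise ValueError(f"expected 6 columns, got {len(fields)}")
                interval = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
                genes.append(GeneModel(name=fields[3], interval=interval, strand=fields[5]))
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return genes


def write_genes(genes, path) -> None:
    rows = _sorted_by_coord(
        list(genes), lambda g: (g.interval.chrom, g.interval.start, g.interval.end)
    )
    with open(path, "w") as fh:
        for g in rows:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.name}\t0\t{g.strand}\n")


def read_bed4_states(path) -> list[tuple[GenomicInterval, str]]:
    """Chromatin-state segments: BED with the state label in column 4."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                segments.append(
                    (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), fields[3])
                )
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return segments


def write_bed4_states(segments: Iterable[tuple[GenomicInterval, str]], path) -> None:
    rows = sorted(segments, key=lambda s: (s[0].chrom, s[0].start))
    with open(path, "w") as fh:
        for iv, label in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


# ---------------------------------------------------------------------------
# tagAlign
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def read_tagalign(path, dataset_id: str | None = None) -> TagSet:
    """Read a tagAlign file (chrom, start, end, sequence, score, strand)."""
    chroms, positions, strands, gc = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chroms.append(fields[0])
                positions.append(int(fields[1]))
                strands.append(fields[5] if len(fields) >= 6 else "+")
                gc.append(_gc_fraction(fields[3]) if len(fields) >= 4 else float("nan"))
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(str(path)))[0]
    return TagSet(
        dataset_id=dataset_id,
        chroms=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        strands=np.asarray(strands, dtype=object),
        gc=np.asarray(gc, dtype=float),
    )


def write_tagalign(tagset: TagSet, sequences: Sequence[str], length: int, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, strand, seq in zip(
            tagset.chroms, tagset.positions, tagset.strands, sequences
        ):
            fh.write(f"{chrom}\t{pos}\t{pos + length}\t{seq}\t1000\t{strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def read_jaspar(path):
    """Read JASPAR-format count matrices (``>id name`` then A/C/G/T rows)."""
    from .motifs import PWM

    pwms = []
    with open(path) as fh:
        motif_id, rows = None, {}
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if motif_id is not None:
                    pwms.append(PWM.from_counts(motif_id, _jaspar_matrix(rows)))
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                inner = line[line.index("[") + 1: line.index("]")] if "[" in line else line[1:]
                rows[base] = [float(tok) for tok in inner.split()]
        if motif_id is not None:
            pwms.append(PWM.from_counts(motif_id, _jaspar_matrix(rows)))
    return pwms


def _jaspar_matrix(rows: dict[str, list[float]]) -> np.ndarray:
    if set(rows) != {"A", "C", "G", "T"}:
        raise ValueError(f"JASPAR matrix must have A/C/G/T rows, got {sorted(rows)}")
    return np.array([rows["A"], rows["C"], rows["G"], rows["T"]], dtype=float).T


def write_jaspar(pwms, path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            counts = pwm.counts if pwm.counts is not None else pwm.probs * 100
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in counts[:, i])
                fh.write(f"{base} [ {vals} ]\n")


def read_meme_minimal(path):
    """Read a minimal MEME motif file (letter-probability matrices)."""
    from .motifs import PWM

    pwms = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while i < len(lines) and "letter-probability" not in lines[i]:
                i += 1
            if i == len(lines):
                raise ValueError(f"MOTIF {motif_id} has no letter-probability matrix")
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            matrix = []
            for j in range(1, width + 1):
                matrix.append([float(tok) for tok in lines[i + j].split()])
            pwms.append(PWM(motif_id, np.asarray(matrix, dtype=float)))
            i += width
        i += 1
    return pwms
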