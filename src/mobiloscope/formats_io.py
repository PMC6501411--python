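"""Readers/writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open with strands '+', '-', '.'.
The converters in this module are the only place 1-based arithmetic occurs:
RepeatMasker .out and GFF3 are 1-based inclusive; BED is already 0-based
half-open; strand 'C' in .out files means minus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")
TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "other")


class FormatError(ValueError):
    """Malformed record in an input file (carries the line number)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TEAnnotation:
    """One repeat hit on a genome or transcript.

    ``divergence_pct`` is the percent mismatch to the subfamily consensus
    (the D of the age model).  ``overshadowed`` marks hits flagged '*' by
    RepeatMasker (a higher-scoring hit covers the same bases); they are
    kept on ingest and excluded downstream on request.
    """

    interval: GenomicInterval
    te_class: str
    family: str
    subfamily: str
    divergence_pct: float
    score: float = 0.0
    overshadowed: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence_pct <= 100.0):
            raise ValueError(f"divergence_pct {self.divergence_pct} not in [0,100]")
        if not self.subfamily:
            raise ValueError("subfamily must be non-empty")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene (protein-coding or lncRNA) with exons; introns are derived."""

    gene_id: str
    biotype: str  # protein_coding | lncRNA
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds: Optional[tuple[GenomicInterval, ...]] = None

    def __post_init__(self) -> None:
        if self.biotype not in ("protein_coding", "lncRNA"):
            raise ValueError(f"unknown biotype {self.biotype!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"{self.gene_id}: exon on wrong chrom")
            if not (self.interval.start <= ex.start and ex.end <= self.interval.end):
                raise ValueError(f"{self.gene_id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = ex.end

    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.interval.strand)
                )
        return tuple(out)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: exon blocks on the genome, optional sequence."""

    transcript_id: str
    kind: str  # mRNA | EST | lncRNA
    blocks: tuple[GenomicInterval, ...]
    sequence: Optional[str] = None
    parent_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("mRNA", "EST", "lncRNA"):
            raise ValueError(f"unknown transcript kind {self.kind!r}")
        prev_end = None
        for b in self.blocks:
            if prev_end is not None and b.start < prev_end:
                raise ValueError(f"{self.transcript_id}: blocks overlap or unsorted")
            prev_end = b.end
        if self.sequence is not None and len(self.sequence) != self.block_length():
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"total block length {self.block_length()}"
            )

    def block_length(self) -> int:
        return sum(len(b) for b in self.blocks)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

_RM_HEADER = """\
   SW  perc perc perc  query      position in query           matching       repeat              position in  repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

"""


def _split_class_family(text: str) -> tuple[str, str]:
    if "/" in text:
        cls, fam = text.split("/", 1)
    else:
        cls, fam = text, text
    if cls not in TE_CLASSES:
        cls = "other"
    return cls, fam


def read_repeatmasker_out(path: Union[str, Path]) -> list[TEAnnotation]:
    """Parse a RepeatMasker .out annotation file.

    Coordinates are converted from 1-based inclusive to 0-based half-open;
    strand 'C' becomes '-'; the class/family column is split on '/'; a
    trailing '*' marks an overshadowed hit (kept, flagged).
    """
    out: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(("SW", "score")):
                continue  # header lines
            fields = stripped.split()
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: expected >=11 columns, got {len(fields)}")
            try:
                score = float(fields[0])
                div = float(fields[1])
                chrom = fields[4]
                begin = int(fields[5])
                end = int(fields[6])
                strand = fields[8]
                name = fields[9]
                clsfam = fields[10]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if begin < 1 or end < begin:
                raise FormatError(f"{path}:{lineno}: bad coordinates {begin}-{end}")
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            cls, fam = _split_class_family(clsfam)
            out.append(
                TEAnnotation(
                    interval=GenomicInterval(chrom, begin - 1, end, strand),
                    te_class=cls,
                    family=fam,
                    subfamily=name,
                    divergence_pct=div,
                    score=score,
                    overshadowed=fields[-1] == "*",
                )
            )
    return out


def write_repeatmasker_out(annotations: Iterable[TEAnnotation], path: Union[str, Path]) -> None:
    """Write annotations in RepeatMasker .out layout (inverse of the reader)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, a in enumerate(annotations, 1):
            iv = a.interval
            strand = "C" if iv.strand == "-" else "+"
            clsfam = a.te_class if a.te_class == a.family else f"{a.te_class}/{a.family}"
            star = " *" if a.overshadowed else ""
            fh.write(
                f"{a.score:7.0f} {a.divergence_pct:5.2f}  0.0  0.0  {iv.chrom} "
                f"{iv.start + 1} {iv.end} (0) {strand} {a.subfamily} {clsfam} "
                f"1 {len(iv)} (0) {i}{star}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(
    path: Union[str, Path], dialect: str = "bed6"
) -> Union[list[GenomicInterval], list[TranscriptModel]]:
    """Read BED6 intervals or BED12 transcript models.

    BED is natively 0-based half-open, so no coordinate shift is applied.
    In BED12, blockSizes/blockStarts are expanded into exon intervals.
    """
    if dialect not in ("bed6", "bed12"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    rows: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if dialect == "bed6":
                if len(f) < 3:
                    raise FormatError(f"{path}:{lineno}: too few columns for BED6")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                strand = f[5] if len(f) >= 6 else "."
                if end <= start:
                    raise FormatError(f"{path}:{lineno}: end <= start")
                rows.append(GenomicInterval(chrom, start, end, strand))
            else:
                if len(f) < 12:
                    raise FormatError(f"{path}:{lineno}: too few columns for BED12")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5]
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
                starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise FormatError(
                        f"{path}:{lineno}: blockCount {n_blocks} does not match "
                        f"blockSizes/blockStarts lengths"
                    )
                if end <= start:
                    raise FormatError(f"{path}:{lineno}: end <= start")
                blocks = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(starts, sizes)
                )
                rows.append(TranscriptModel(transcript_id=name, kind="EST", blocks=blocks))
    return rows


def write_bed6(intervals: Iterable[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def write_bed12(transcripts: Iterable[TranscriptModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            chrom = t.blocks[0].chrom
            start = t.blocks[0].start
            end = t.blocks[-1].end
            strand = t.blocks[0].strand
            sizes = ",".join(str(len(b)) for b in t.blocks) + ","
            starts = ",".join(str(b.start - start) for b in t.blocks) + ","
            fh.write(
                f"{chrom}\t{start}\t{end}\t{t.transcript_id}\t0\t{strand}\t"
                f"{start}\t{end}\t0\t{len(t.blocks)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_descriptions(path: Union[str, Path]) -> dict[str, str]:
    """Read FASTA description lines keyed by record id."""
    return {rec.id: rec.description for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: Union[str, Path],
                descriptions: Optional[dict[str, str]] = None) -> None:
    seqrecs = []
    for name, seq in records.items():
        desc = (descriptions or {}).get(name, "")
        seqrecs.append(SeqRecord(Seq(seq), id=name, description=desc))
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _gff_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: Union[str, Path]) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive -> converted).

    gene/exon/CDS features are grouped by ID/Parent; biotype is taken from
    the ``biotype`` or ``gene_biotype`` attribute.  Exons with no resolvable
    parent gene are skipped with a logged count.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    orphans = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attr_text = f[:9]
            start, end = int(start1) - 1, int(end1)
            attrs = _gff_attrs(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene{lineno}")
                biotype = attrs.get("biotype", attrs.get("gene_biotype", "protein_coding"))
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end, strand),
                    "biotype": biotype,
                    "exons": [],
                    "cds": [],
                }
            elif ftype in ("mRNA", "transcript", "lnc_RNA"):
                tid = attrs.get("ID")
                parent = attrs.get("Parent")
                if tid and parent:
                    mrna_parent[tid] = parent
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent", "")
                gid = mrna_parent.get(parent, parent)
                if gid not in genes:
                    orphans += 1
                    continue
                iv = GenomicInterval(chrom, start, end, strand)
                genes[gid]["exons" if ftype == "exon" else "cds"].append(iv)
    if orphans:
        logger.warning("read_gff3: skipped %d features with no resolvable parent gene", orphans)
    out = []
    for gid, g in genes.items():
        exons = tuple(sorted(set(g["exons"]), key=lambda iv: iv.start)) or (g["interval"],)
        cds = tuple(sorted(set(g["cds"]), key=lambda iv: iv.start)) or None
        biotype = g["biotype"] if g["biotype"] in ("protein_coding", "lncRNA") else "protein_coding"
        out.append(GeneModel(gene_id=gid, biotype=biotype, interval=g["interval"],
                             exons=exons, cds=cds))
    return out


def write_gff3(genes: Iterable[GeneModel], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tmobiloscope\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id};biotype={g.biotype}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                fh.write(
                    f"{ex.chrom}\tmobiloscope\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, c in enumerate(g.cds or (), 1):
                fh.write(
                    f"{c.chrom}\tmobiloscope\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{c.strand}\t.\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )
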