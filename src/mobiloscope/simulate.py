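"""Synthetic mobilome generator: ground-truthed inputs for every stage.

Plants TE copies diverged from known consensus sequences at known ages
under a Jukes-Cantor substitution process (optionally 5'-truncated, with a
polyA tail), lays out protein-coding and lncRNA gene models, and emits
transcripts carrying TE cassettes of controlled length, fraction and
orientation.  Everything is driven by one integer seed; a fixed seed gives
byte-identical output files.

The emitted .out-style annotation records the *realized* per-copy mismatch
percentage against the source consensus (what an annotator would measure),
not the input substitution parameter, so dating tests measure estimator
error rather than simulator shortcuts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from mobiloscope.formats_io import (
    GeneModel,
    GenomicInterval,
    TEAnnotation,
    TranscriptModel,
    write_bed6,
    write_bed12,
    write_fasta,
    write_gff3,
    write_repeatmasker_out,
)
from mobiloscope.subfamily import ConsensusRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class FamilyPlan:
    """One planted subfamily: how many copies, how old, how decayed."""

    consensus: ConsensusRecord
    copy_count: int
    true_age_mya: float
    te_class: str = "LINE"
    truncation_prob: float = 0.0
    polya_len_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.true_age_mya < 0:
            raise ValueError("true_age_mya must be non-negative")


@dataclass
class GenePlan:
    n_pc: int = 20
    n_lnc: int = 10
    exons_per_gene: tuple[int, int] = (2, 5)   # inclusive range
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (500, 2000)
    # genomic TE insertions planted into gene introns (gene-hit ground truth)
    genic_te_fraction: float = 0.0       # fraction of genes receiving insertions
    genic_te_per_gene: int = 1
    genic_orientation_ratio: float = 0.5  # P(sense relative to the gene)


@dataclass
class CassettePlan:
    """TE cassettes planted into transcripts for the chimeric cascade."""

    lengths: tuple[int, ...] = (100, 200, 300)
    chimeric_fraction: float = 0.5       # fraction of mRNAs given a cassette
    orientation_ratio: float = 0.5       # P(sense)
    cassette_divergence_pct: float = 0.0
    n_ests_per_mrna: int = 2
    est_mutation_pct: float = 1.0
    n_decoy_ests: int = 5


@dataclass
class SimulationConfig:
    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 500_000),)
    families: tuple[FamilyPlan, ...] = ()
    r: float = 2.2e-9
    gc_content: float = 0.5
    gene_plan: GenePlan = field(default_factory=GenePlan)
    cassette_plan: CassettePlan = field(default_factory=CassettePlan)


# ---------------------------------------------------------------------------
# Core sequence operations
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def mutate_jc(seq: str, K_pct: float, rng: np.random.Generator) -> str:
    """Mutate under a Jukes-Cantor process with expected K substitutions.

    Each site is substituted independently with probability
    p = 3/4 (1 - exp(-4/3 K/100)), the replacement drawn uniformly from the
    three other bases; length is preserved.
    """
    if K_pct < 0:
        raise ValueError("K must be non-negative")
    if set(seq) - set("ACGTN"):
        raise ValueError("invalid bases in sequence")
    if K_pct == 0 or not seq:
        return seq
    p = 0.75 * (1.0 - math.exp(-(4.0 / 3.0) * K_pct / 100.0))
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < p
    n_hit = int(hit.sum())
    if n_hit:
        # uniform among the 3 other bases: shift by 1..3 in base order
        codes = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
        orig = np.array([codes.get(b, 0) for b in arr[hit]])
        shift = rng.integers(1, 4, size=n_hit)
        arr[hit] = _BASES[(orig + shift) % 4]
    return arr.tobytes().decode()


def mismatch_pct(a: str, b: str) -> float:
    """Percent mismatching positions between equal-length sequences."""
    if len(a) != len(b) or not a:
        raise ValueError("sequences must be equal nonzero length")
    diff = sum(1 for x, y in zip(a, b) if x != y)
    return diff / len(a) * 100.0


def age_to_k_pct(age_mya: float, r: float) -> float:
    """Expected percent substitutions for a copy of the given age: K = 2 r t * 100."""
    return 2.0 * r * age_mya * 1e6 * 100.0


# ---------------------------------------------------------------------------
# Copy planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedCopy:
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    family: str
    te_class: str
    true_age_mya: float
    realized_divergence_pct: float
    truncated: bool
    polya_len: int


def plant_copies(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[PlantedCopy], list[TEAnnotation]]:
    """Plant diverged TE copies uniformly, without overlap, into a background
    genome.  Returns (genome, truth records, .out-style annotations carrying
    the realized divergence)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genome = {chrom: list(random_sequence(length, rng, cfg.gc_content))
              for chrom, length in cfg.genome}
    chrom_names = [c for c, _ in cfg.genome]
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    total_planned = sum(len(f.consensus.sequence) * f.copy_count for f in cfg.families)
    total_bp = sum(l for _, l in cfg.genome)
    if total_planned >= total_bp:
        raise ValueError("total planted bp must be smaller than the genome")

    truth: list[PlantedCopy] = []
    annotations: list[TEAnnotation] = []
    for fam in cfg.families:
        K = age_to_k_pct(fam.true_age_mya, cfg.r)
        for _ in range(fam.copy_count):
            core = fam.consensus.sequence
            truncated = False
            if fam.truncation_prob > 0 and rng.random() < fam.truncation_prob:
                # 5' truncation at a uniform point, keeping >= 50 bp
                cut = int(rng.integers(0, max(1, len(core) - 50)))
                core = core[cut:]
                truncated = cut > 0
            mutated = mutate_jc(core, K, rng)
            realized_d = mismatch_pct(mutated, core) if core else 0.0
            lo, hi = fam.polya_len_range
            polya = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            strand = "+" if rng.random() < 0.5 else "-"
            insert = mutated + "A" * polya
            if strand == "-":
                insert = str(Seq(insert).reverse_complement())
            placed = _place(insert, chrom_names, cfg, occupied, rng)
            if placed is None:
                raise RuntimeError("could not place copy without overlap; genome too full")
            chrom, pos = placed
            genome[chrom][pos: pos + len(insert)] = list(insert)
            truth.append(PlantedCopy(
                chrom=chrom, start=pos, end=pos + len(insert), strand=strand,
                subfamily=fam.consensus.name, family=fam.consensus.family,
                te_class=fam.te_class, true_age_mya=fam.true_age_mya,
                realized_divergence_pct=realized_d,
                truncated=truncated, polya_len=polya,
            ))
            annotations.append(TEAnnotation(
                interval=GenomicInterval(chrom, pos, pos + len(insert), strand),
                te_class=fam.te_class, family=fam.consensus.family,
                subfamily=fam.consensus.name,
                divergence_pct=realized_d, score=1000.0,
            ))
    return {c: "".join(s) for c, s in genome.items()}, truth, annotations


def _place(
    insert: str,
    chrom_names: Sequence[str],
    cfg: SimulationConfig,
    occupied: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> Optional[tuple[str, int]]:
    lengths = dict(cfg.genome)
    for _ in range(max_tries):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        limit = lengths[chrom] - len(insert)
        if limit <= 0:
            continue
        pos = int(rng.integers(0, limit))
        span = (pos, pos + len(insert))
        if all(span[1] <= s or span[0] >= e for s, e in occupied[chrom]):
            occupied[chrom].append(span)
            return chrom, pos
    return None


# ---------------------------------------------------------------------------
# Genes, transcripts, cassettes
# ---------------------------------------------------------------------------

@dataclass
class CassetteTruth:
    transcript_id: str
    start: int
    end: int
    subfamily: str
    te_class: str
    orientation: str  # sense | antisense
    length: int
    te_fraction: float
    expected_chimeric: bool


def plant_genes_and_transcripts(
    cfg: SimulationConfig,
    genome: dict[str, str],
    occupied: Optional[list[PlantedCopy]] = None,
    rng: Optional[np.random.Generator] = None,
    library: Optional[Sequence[ConsensusRecord]] = None,
    min_te_bases: int = 50,
    max_te_fraction: float = 0.80,
) -> tuple[list[GeneModel], list[TranscriptModel], list[TranscriptModel], dict]:
    """Lay out gene models and emit mRNAs/ESTs with planted TE cassettes.

    Genes avoid one another (not the planted TE copies — TEs inside introns
    are the point).  A configurable fraction of mRNAs receives one TE
    cassette, orientation drawn at the plan's sense ratio; ESTs are mRNA
    fragments with light mutation plus off-gene decoys.  Returns (genes,
    mrnas, ests, truth) where truth holds per-gene hit labels and
    per-transcript cassette records consistent with the stated thresholds.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    gp, cp = cfg.gene_plan, cfg.cassette_plan
    lib = list(library) if library else [f.consensus for f in cfg.families]
    lib_class = {f.consensus.name: f.te_class for f in cfg.families}
    chrom_lengths = dict(cfg.genome)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    if occupied:
        for c in occupied:
            taken[c.chrom].append((c.start, c.end))

    genes: list[GeneModel] = []
    n_total = gp.n_pc + gp.n_lnc
    for gi in range(n_total):
        biotype = "protein_coding" if gi < gp.n_pc else "lncRNA"
        gene_id = (f"pcgene{gi + 1}" if biotype == "protein_coding"
                   else f"lncgene{gi - gp.n_pc + 1}")
        n_ex = int(rng.integers(gp.exons_per_gene[0], gp.exons_per_gene[1] + 1))
        ex_lens = [int(rng.integers(gp.exon_len[0], gp.exon_len[1] + 1))
                   for _ in range(n_ex)]
        in_lens = [int(rng.integers(gp.intron_len[0], gp.intron_len[1] + 1))
                   for _ in range(n_ex - 1)]
        span = sum(ex_lens) + sum(in_lens)
        placed = None
        for _ in range(300):
            chrom = list(genome)[int(rng.integers(0, len(genome)))]
            limit = chrom_lengths[chrom] - span - 1
            if limit <= 0:
                continue
            pos = int(rng.integers(0, limit))
            if all(pos + span <= s or pos >= e for s, e in taken[chrom]):
                placed = (chrom, pos)
                taken[chrom].append((pos, pos + span))
                break
        if placed is None:
            raise RuntimeError("infeasible gene plan: cannot place gene without overlap")
        chrom, pos = placed
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        cursor = pos
        for k, el in enumerate(ex_lens):
            exons.append(GenomicInterval(chrom, cursor, cursor + el, strand))
            cursor += el
            if k < len(in_lens):
                cursor += in_lens[k]
        genes.append(GeneModel(
            gene_id=gene_id, biotype=biotype,
            interval=GenomicInterval(chrom, pos, cursor, strand),
            exons=tuple(exons),
        ))

    # genomic TE insertions into introns: overwrite intronic background with
    # a diverged consensus fragment so the gene demonstrably "contains" a TE
    genic_annotations: list[TEAnnotation] = []
    genic_truth: list[dict] = []
    if gp.genic_te_fraction > 0 and cfg.families:
        mutable = {c: list(s) for c, s in genome.items()}
        fams = list(cfg.families)
        used: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
        for g in genes:
            introns = g.introns()
            if not introns or rng.random() >= gp.genic_te_fraction:
                continue
            for _ in range(gp.genic_te_per_gene):
                intron = introns[int(rng.integers(0, len(introns)))]
                fam = fams[int(rng.integers(0, len(fams)))]
                cons = fam.consensus.sequence
                L = min(len(cons), len(intron) - 20)
                if L < 50:
                    continue
                frag = cons[len(cons) - L:]  # 5'-truncated fragment
                K = age_to_k_pct(fam.true_age_mya, cfg.r)
                frag = mutate_jc(frag, K, rng)
                realized_d = mismatch_pct(frag, cons[len(cons) - L:])
                sense = rng.random() < gp.genic_orientation_ratio
                strand = g.interval.strand if sense else ("-" if g.interval.strand == "+" else "+")
                placed_seq = frag if strand == "+" else str(Seq(frag).reverse_complement())
                start = None
                for _try in range(50):  # avoid clobbering a sibling insertion
                    off = int(rng.integers(0, len(intron) - L + 1))
                    cand = intron.start + off
                    if all(cand + L <= s or cand >= e for s, e in used[intron.chrom]):
                        start = cand
                        break
                if start is None:
                    continue
                used[intron.chrom].append((start, start + L))
                mutable[intron.chrom][start: start + L] = list(placed_seq)
                genic_annotations.append(TEAnnotation(
                    interval=GenomicInterval(intron.chrom, start, start + L, strand),
                    te_class=fam.te_class, family=fam.consensus.family,
                    subfamily=fam.consensus.name,
                    divergence_pct=realized_d, score=1000.0))
                genic_truth.append({
                    "gene_id": g.gene_id, "biotype": g.biotype,
                    "chrom": intron.chrom, "start": start, "end": start + L,
                    "strand": strand,
                    "orientation": "sense" if sense else "antisense",
                    "subfamily": fam.consensus.name})
        genome = {c: "".join(s) for c, s in mutable.items()}

    # mRNAs: spliced exon sequence of each protein-coding gene, with an
    # optional TE cassette inserted at a uniform internal position
    mrnas: list[TranscriptModel] = []
    cassettes: list[CassetteTruth] = []
    transcript_gene: dict[str, str] = {}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        seq = "".join(genome[e.chrom][e.start: e.end] for e in g.exons)
        if g.interval.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        tid = f"{g.gene_id}.m1"
        if lib and rng.random() < cp.chimeric_fraction:
            cons = lib[int(rng.integers(0, len(lib)))]
            length = int(cp.lengths[int(rng.integers(0, len(cp.lengths)))])
            length = min(length, len(cons.sequence))
            cstart = int(rng.integers(0, len(cons.sequence) - length + 1))
            cassette = cons.sequence[cstart: cstart + length]
            if cp.cassette_divergence_pct > 0:
                cassette = mutate_jc(cassette, cp.cassette_divergence_pct, rng)
            sense = rng.random() < cp.orientation_ratio
            if not sense:
                cassette = str(Seq(cassette).reverse_complement())
            ins_at = int(rng.integers(1, max(2, len(seq))))
            seq = seq[:ins_at] + cassette + seq[ins_at:]
            frac = length / len(seq)
            cassettes.append(CassetteTruth(
                transcript_id=tid, start=ins_at, end=ins_at + length,
                subfamily=cons.name, te_class=lib_class.get(cons.name, "LINE"),
                orientation="sense" if sense else "antisense", length=length,
                te_fraction=frac,
                expected_chimeric=(length >= min_te_bases and frac <= max_te_fraction),
            ))
        # blocks must tile the sequence length; a cassette-bearing mRNA has
        # no genomic counterpart for its TE bases, so it gets one synthetic
        # block anchored at the gene start instead of the exon chain
        if len(seq) == sum(len(e) for e in g.exons):
            blocks = g.exons
        else:
            bstart = min(g.interval.start, chrom_lengths[g.interval.chrom] - len(seq))
            blocks = (GenomicInterval(g.interval.chrom, bstart, bstart + len(seq),
                                      g.interval.strand),)
        mrnas.append(TranscriptModel(
            transcript_id=tid, kind="mRNA", blocks=blocks,
            sequence=seq, parent_gene=g.gene_id,
        ))
        transcript_gene[tid] = g.gene_id

    # ESTs: fragments of mRNAs with light mutation, plus intergenic decoys
    gene_by_id = {g.gene_id: g for g in genes}
    ests: list[TranscriptModel] = []
    for m in mrnas:
        g = gene_by_id[m.parent_gene]
        span = len(g.interval)
        for k in range(cp.n_ests_per_mrna):
            L = len(m.sequence)
            flen = min(max(60, int(0.8 * L)), span)
            start = int(rng.integers(0, L - flen + 1)) if L > flen else 0
            frag = m.sequence[start: start + flen]
            frag = mutate_jc(frag, cp.est_mutation_pct, rng)
            tid = f"{m.transcript_id}.est{k + 1}"
            # one genomic block inside the gene body, same length as the
            # fragment (keeps the block/sequence contract and guarantees the
            # 90% coordinate-overlap stage sees a fully genic EST)
            ests.append(TranscriptModel(
                transcript_id=tid, kind="EST",
                blocks=(GenomicInterval(g.interval.chrom, g.interval.start,
                                        g.interval.start + flen, g.interval.strand),),
                sequence=frag, parent_gene=m.parent_gene,
            ))
            transcript_gene[tid] = m.parent_gene
    for k in range(cp.n_decoy_ests):
        chrom = list(genome)[int(rng.integers(0, len(genome)))]
        L = 300
        for _ in range(200):
            pos = int(rng.integers(0, chrom_lengths[chrom] - L))
            if all(pos + L <= s or pos >= e for s, e in taken[chrom]):
                break
        else:
            raise RuntimeError("could not place decoy EST outside genes/TEs")
        ests.append(TranscriptModel(
            transcript_id=f"decoy{k + 1}", kind="EST",
            blocks=(GenomicInterval(chrom, pos, pos + L, "+"),),
            sequence=genome[chrom][pos: pos + L],
        ))

    truth = {
        "transcript_gene": transcript_gene,
        "cassettes": [asdict(c) for c in cassettes],
        "chimeric_mrnas": sorted(c.transcript_id for c in cassettes
                                 if c.expected_chimeric),
        "chimeric_genes": sorted({transcript_gene[c.transcript_id]
                                  for c in cassettes if c.expected_chimeric}),
        "genic_insertions": genic_truth,
        "genes_hit": sorted({t["gene_id"] for t in genic_truth}),
    }
    return genes, mrnas, ests, truth, genome, genic_annotations


# ---------------------------------------------------------------------------
# Default library and top-level driver
# ---------------------------------------------------------------------------

def default_library(seed: int = 7_777_777) -> list[ConsensusRecord]:
    """A small deterministic consensus library (L1-, SINE- and ERV-like).

    Sequences are random but fixed by the seed; landmark spans follow the
    canonical element anatomies at reduced scale.
    """
    rng = np.random.default_rng(seed)
    l1 = random_sequence(3000, rng)
    sine = random_sequence(300, rng)
    erv = random_sequence(1500, rng)
    return [
        ConsensusRecord(
            name="L1_SYN1", family="L1", sequence=l1,
            landmarks={"5UTR": (0, 600), "ORF1": (600, 1500), "IGR": (1500, 1600),
                       "ORF2": (1600, 2800), "3UTR": (2800, 3000)},
        ),
        ConsensusRecord(
            name="SINE_SYN1", family="SINEA", sequence=sine,
            landmarks={"head": (0, 100), "TC-rich": (100, 180),
                       "GC-rich": (180, 260), "A-tail": (260, 300)},
        ),
        ConsensusRecord(
            name="ERV_SYN1", family="ERV6", sequence=erv,
            landmarks={"LTR5": (0, 200), "gag": (200, 700), "pol": (700, 1200),
                       "env": (1200, 1300), "LTR3": (1300, 1500)},
        ),
    ]


def simulate(cfg: SimulationConfig, outdir) -> dict:
    """Run the full generator and write genome.fa, te_truth.bed, te.out,
    genes.gff3, mrnas.fa, ests.bed12, ests.fa and truth.json into outdir.
    Returns the truth dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    genome, planted, annotations = plant_copies(cfg, rng)
    genes, mrnas, ests, tx_truth, genome, genic_annotations = plant_genes_and_transcripts(
        cfg, genome, occupied=planted, rng=rng)
    annotations = annotations + genic_annotations

    write_fasta(genome, outdir / "genome.fa")
    write_bed6([GenomicInterval(c.chrom, c.start, c.end, c.strand) for c in planted],
               outdir / "te_truth.bed")
    write_repeatmasker_out(annotations, outdir / "te.out")
    write_gff3(genes, outdir / "genes.gff3")
    write_fasta({m.transcript_id: m.sequence for m in mrnas}, outdir / "mrnas.fa")
    write_bed12(ests, outdir / "ests.bed12")
    write_fasta({e.transcript_id: e.sequence for e in ests}, outdir / "ests.fa")

    truth = {
        "seed": cfg.seed,
        "genome_bp": sum(l for _, l in cfg.genome),
        "rate": cfg.r,
        "planted_copies": [asdict(c) for c in planted],
        "per_family_true_age_mya": {f.consensus.name: f.true_age_mya
                                    for f in cfg.families},
        **tx_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
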