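"""TE-gene chimeric transcript calling: a staged filter cascade.

ESTs are kept only when >= 90% of their genomic bases fall inside a single
protein-coding gene body, then only when they align to an mRNA of those
genes at >= 95% identity covering > 70% of the EST.  Survivors (and the
mRNAs themselves) are annotated against the TE consensus library; reads
that are > 80% TE (likely transcripts of an active element itself) are
discarded, and transcripts carrying >= 50 TE bases are called chimeric.

The internal repeat annotator is a local-alignment scan against the
consensus library with iterative masking; a RepeatMasker-style .out file
of transcript-space hits can be supplied instead and is the faithful path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from mobiloscope.formats_io import GeneModel, TEAnnotation, TranscriptModel
from mobiloscope.genic import round_pct
from mobiloscope.subfamily import ConsensusRecord, _make_aligner

STAGES = ("coord_overlap", "aln_coverage", "annotated", "te_fraction", "min_te_bases")

RETRO_CLASSES = frozenset({"LINE", "SINE", "LTR"})


@dataclass(frozen=True)
class TESegment:
    """A repeat-derived segment of a transcript (transcript coordinates)."""

    start: int
    end: int
    subfamily: str
    te_class: str
    score: float
    strand: str = "+"


@dataclass
class ChimericCall:
    transcript_id: str
    stage_flags: dict[str, bool]
    te_bases: int = 0
    te_fraction: float = 0.0
    status: str = "rejected(coord_overlap)"

    @property
    def is_chimeric(self) -> bool:
        return self.status == "chimeric"


# ---------------------------------------------------------------------------
# Stage 1: genomic-coordinate overlap with protein-coding genes
# ---------------------------------------------------------------------------

def gene_overlap_fraction(est: TranscriptModel, genes: Sequence[GeneModel]) -> float:
    """Largest single-gene fraction of EST block bases inside a pc gene body."""
    total = est.block_length()
    if total == 0:
        raise ValueError(f"{est.transcript_id}: zero-length EST")
    best = 0
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        inside = sum(b.overlap_bp(g.interval) for b in est.blocks)
        best = max(best, inside)
    return best / total


def filter_by_gene_overlap(
    ests: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    threshold: float = 0.90,
) -> list[TranscriptModel]:
    """Keep ESTs with >= threshold of their bases inside one pc gene body."""
    return [e for e in ests if gene_overlap_fraction(e, genes) >= threshold]


# ---------------------------------------------------------------------------
# Stage 2: alignment coverage against mRNAs
# ---------------------------------------------------------------------------

def _best_mrna_alignment(est_seq: str, mrna_seq: str) -> tuple[float, float]:
    """(identity, est_coverage) of the best local alignment."""
    aligner = _make_aligner("local")
    alns = aligner.align(est_seq, mrna_seq)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    ra, rb = str(aln[0]), str(aln[1])
    cols = len(ra)
    if cols == 0:
        return 0.0, 0.0
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    est_bases = sum(1 for x in ra if x != "-")
    return matches / cols, est_bases / len(est_seq)


def filter_by_mrna_alignment(
    ests: Sequence[TranscriptModel],
    mrnas: Sequence[TranscriptModel],
    coverage_threshold: float = 0.70,
    min_identity: float = 0.95,
    psl: Optional[dict[str, tuple[float, float]]] = None,
) -> list[TranscriptModel]:
    """Keep ESTs whose best mRNA alignment has identity >= ``min_identity``
    and EST coverage strictly > ``coverage_threshold``.

    ``psl`` optionally supplies precomputed per-EST (identity, coverage)
    pairs (e.g. from a PSL import), bypassing internal alignment.
    """
    if psl is not None:
        return [e for e in ests
                if psl.get(e.transcript_id, (0.0, 0.0))[0] >= min_identity
                and psl.get(e.transcript_id, (0.0, 0.0))[1] > coverage_threshold]
    if any(m.sequence is None for m in mrnas):
        raise ValueError("mRNA sequences required for internal alignment mode")
    kept = []
    for est in ests:
        if est.sequence is None:
            raise ValueError(f"{est.transcript_id}: sequence required (or supply psl)")
        for m in mrnas:
            ident, cov = _best_mrna_alignment(est.sequence, m.sequence)
            if ident >= min_identity and cov > coverage_threshold:
                kept.append(est)
                break
    return kept


def read_psl_coverage(path) -> dict[str, tuple[float, float]]:
    """Best (identity, query coverage) per query from a PSL alignment file."""
    best: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 17 or not f[0].lstrip("-").isdigit():
                continue  # header / psLayout banner
            matches, mismatches = int(f[0]), int(f[1])
            qname, qsize = f[9], int(f[10])
            aligned = matches + mismatches
            if aligned == 0 or qsize == 0:
                continue
            ident = matches / aligned
            cov = aligned / qsize
            prev = best.get(qname)
            if prev is None or (ident, cov) > prev:
                best[qname] = (ident, cov)
    return best


# ---------------------------------------------------------------------------
# Stage 3: repeat annotation of transcript sequences
# ---------------------------------------------------------------------------

_LOW_COMPLEXITY_FAMILIES = frozenset({"Low_complexity", "Simple_repeat"})


def annotate_repeats_in_transcripts(
    transcripts: Sequence[TranscriptModel],
    library: Sequence[ConsensusRecord],
    min_score: int = 50,
    library_classes: Optional[dict[str, str]] = None,
    skip_low_complexity: bool = True,
    max_hits_per_transcript: int = 8,
) -> dict[str, list[TESegment]]:
    """Scan transcript sequences against a consensus library.

    Each consensus (both strands) is locally aligned to the transcript;
    hits scoring >= ``min_score`` are accepted best-first with the covered
    bases masked before rescanning, so overlapping raw hits resolve by
    score then length.  Returns non-overlapping segments per transcript.
    """
    if not library:
        raise ValueError("empty consensus library in internal annotation mode")
    classes = library_classes or {}
    lib = [c for c in library
           if not (skip_low_complexity and c.family in _LOW_COMPLEXITY_FAMILIES)]
    aligner = _make_aligner("local")
    out: dict[str, list[TESegment]] = {}
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.transcript_id}: sequence required for annotation")
        seq = list(t.sequence)
        segments: list[TESegment] = []
        for _ in range(max_hits_per_transcript):
            best: Optional[tuple[float, int, int, str, str, str]] = None
            target = "".join(seq)
            for cons in lib:
                for strand, cseq in (("+", cons.sequence),
                                     ("-", str(Seq(cons.sequence).reverse_complement()))):
                    alns = aligner.align(target, cseq)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    if aln.score < min_score:
                        continue
                    tstart = int(aln.aligned[0][0][0])
                    tend = int(aln.aligned[0][-1][1])
                    cand = (float(aln.score), tend - tstart, tstart, cons.name, strand)
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = (*cand[:3], cons.name, strand)
            if best is None:
                break
            score, length, tstart, name, strand = best
            tend = tstart + length
            segments.append(TESegment(
                start=tstart, end=tend, subfamily=name,
                te_class=classes.get(name, "other"), score=score, strand=strand,
            ))
            for i in range(tstart, tend):
                seq[i] = "X"  # mask so rescans find the next-best hit
        segments.sort(key=lambda s: s.start)
        out[t.transcript_id] = segments
    return out


def segments_from_repeatmasker(
    annotations: Sequence[TEAnnotation],
) -> dict[str, list[TESegment]]:
    """Convert transcript-space .out annotations (chrom = transcript id)."""
    out: dict[str, list[TESegment]] = {}
    for a in annotations:
        out.setdefault(a.interval.chrom, []).append(
            TESegment(start=a.interval.start, end=a.interval.end,
                      subfamily=a.subfamily, te_class=a.te_class,
                      score=a.score, strand=a.interval.strand)
        )
    for segs in out.values():
        segs.sort(key=lambda s: s.start)
    return out


def _union_bp(segments: Iterable[TESegment], classes: Optional[frozenset] = None) -> int:
    ivs = sorted((s.start, s.end) for s in segments
                 if classes is None or s.te_class in classes)
    total, cur_end = 0, -1
    for s, e in ivs:
        s = max(s, cur_end)
        if e > s:
            total += e - s
            cur_end = e
        cur_end = max(cur_end, e)
    return total


# ---------------------------------------------------------------------------
# Stages 4-5: fraction discard and minimum TE bases
# ---------------------------------------------------------------------------

def call_chimeric(
    transcripts: Sequence[TranscriptModel],
    segments: dict[str, list[TESegment]],
    max_te_fraction: float = 0.80,
    min_te_bases: int = 50,
    prior_flags: Optional[dict[str, dict[str, bool]]] = None,
    retro_only: bool = False,
) -> list[ChimericCall]:
    """Final chimeric decision for transcripts that reached annotation.

    te_fraction > ``max_te_fraction`` rejects (transcript likely is the TE);
    otherwise te_bases >= ``min_te_bases`` calls it chimeric.
    """
    calls = []
    classes = RETRO_CLASSES if retro_only else None
    for t in transcripts:
        length = len(t.sequence) if t.sequence is not None else t.block_length()
        segs = segments.get(t.transcript_id, [])
        te_bases = _union_bp(segs, classes)
        frac = te_bases / length if length else 0.0
        flags = dict((prior_flags or {}).get(
            t.transcript_id, {"coord_overlap": True, "aln_coverage": True}))
        flags["annotated"] = True
        flags["te_fraction"] = frac <= max_te_fraction
        flags["min_te_bases"] = flags["te_fraction"] and te_bases >= min_te_bases
        if not flags["te_fraction"]:
            status = "rejected(te_fraction)"
        elif not flags["min_te_bases"]:
            status = "rejected(min_te_bases)"
        else:
            status = "chimeric"
        calls.append(ChimericCall(t.transcript_id, flags, te_bases, frac, status))
    return calls


# ---------------------------------------------------------------------------
# Full cascade and summary
# ---------------------------------------------------------------------------

def run_cascade(
    ests: Sequence[TranscriptModel],
    mrnas: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    library: Sequence[ConsensusRecord],
    gene_overlap_threshold: float = 0.90,
    coverage_threshold: float = 0.70,
    min_identity: float = 0.95,
    max_te_fraction: float = 0.80,
    min_te_bases: int = 50,
    min_score: int = 50,
    library_classes: Optional[dict[str, str]] = None,
    est_filter_mode: str = "sequential",
    psl: Optional[dict[str, tuple[float, float]]] = None,
    rm_segments: Optional[dict[str, list[TESegment]]] = None,
) -> tuple[list[ChimericCall], dict[str, int]]:
    """Run the full cascade; returns calls plus per-stage survivor counts.

    ``est_filter_mode`` 'sequential' applies the alignment filter to the
    coordinate-filter survivors; 'union' keeps ESTs passing either filter.
    ESTs rejected at stage k carry no flags set beyond k.  mRNAs enter at
    the annotation stage directly.
    """
    if est_filter_mode not in ("sequential", "union"):
        raise ValueError("est_filter_mode must be 'sequential' or 'union'")
    counts = {"ests_in": len(ests), "mrnas_in": len(mrnas)}
    calls: list[ChimericCall] = []
    stage1 = set(e.transcript_id for e in filter_by_gene_overlap(
        ests, genes, gene_overlap_threshold))
    counts["ests_coord_overlap_pass"] = len(stage1)
    pool = [e for e in ests if e.transcript_id in stage1] if est_filter_mode == "sequential" else list(ests)
    stage2 = set(e.transcript_id for e in filter_by_mrna_alignment(
        pool, mrnas, coverage_threshold, min_identity, psl=psl))
    if est_filter_mode == "sequential":
        survivors_ids = stage2
    else:
        survivors_ids = stage1 | stage2
    counts["ests_aln_coverage_pass"] = len(stage2)
    counts["ests_surviving"] = len(survivors_ids)

    prior: dict[str, dict[str, bool]] = {}
    for e in ests:
        s1 = e.transcript_id in stage1
        s2 = e.transcript_id in survivors_ids
        prior[e.transcript_id] = {"coord_overlap": s1, "aln_coverage": s2}
        if e.transcript_id not in survivors_ids:
            status = "rejected(coord_overlap)" if not s1 else "rejected(aln_coverage)"
            calls.append(ChimericCall(
                e.transcript_id,
                {"coord_overlap": s1, "aln_coverage": False,
                 "annotated": False, "te_fraction": False, "min_te_bases": False},
                status=status))
    survivors = [e for e in ests if e.transcript_id in survivors_ids]
    to_annotate = survivors + list(mrnas)
    for m in mrnas:
        prior[m.transcript_id] = {"coord_overlap": True, "aln_coverage": True}
    if rm_segments is not None:
        segments = rm_segments
    else:
        segments = annotate_repeats_in_transcripts(
            to_annotate, library, min_score=min_score, library_classes=library_classes)
    calls.extend(call_chimeric(
        to_annotate, segments, max_te_fraction, min_te_bases, prior_flags=prior))
    counts["chimeric"] = sum(1 for c in calls if c.is_chimeric)
    return calls, counts


def summarize_chimeric(
    calls: Sequence[ChimericCall],
    transcript_gene: dict[str, str],
    genes: Sequence[GeneModel],
    kinds: Optional[dict[str, str]] = None,
) -> dict[str, float]:
    """Percent of transcripts chimeric (overall and per kind) and percent of
    protein-coding genes with >= 1 chimeric transcript.  Two decimals,
    round half up.
    """
    if not genes:
        raise ValueError("empty gene universe")
    n = len(calls)
    n_chim = sum(1 for c in calls if c.is_chimeric)
    out: dict[str, float] = {"pct_transcripts_chimeric": round_pct(n_chim, n) if n else 0.0}
    if kinds:
        for kind in sorted(set(kinds.values())):
            sub = [c for c in calls if kinds.get(c.transcript_id) == kind]
            if sub:
                out[f"pct_{kind}_chimeric"] = round_pct(
                    sum(1 for c in sub if c.is_chimeric), len(sub))
    pc_universe = [g.gene_id for g in genes if g.biotype == "protein_coding"]
    hit_genes = {transcript_gene[c.transcript_id] for c in calls
                 if c.is_chimeric and c.transcript_id in transcript_gene}
    hit_genes &= set(pc_universe)
    if pc_universe:
        out["pct_genes_chimeric"] = round_pct(len(hit_genes), len(pc_universe))
    return out
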