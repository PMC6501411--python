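"""Subfamily construction from candidate TE loci.

Candidate loci from de novo detectors are merged when redundant (same
strand, inter-locus gap <= 3000 bp), extended upstream/downstream to
capture UTRs (strand-aware, 2500 bp / 200 bp), clustered by promoter-region
(5'UTR) similarity with single linkage, and each surviving cluster (>= 10
members) is collapsed to a majority-rule consensus through a deterministic
center-star multiple alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from mobiloscope.formats_io import GenomicInterval, TEAnnotation

#: L1 landmark order used to validate ConsensusRecord spans.
L1_LANDMARK_ORDER = ("5UTR", "ORF1", "IGR", "ORF2", "3UTR")


@dataclass(frozen=True)
class TECopy:
    """A genome-extracted TE copy in element orientation.

    ``landmarks`` maps region names (e.g. ``5UTR``) to half-open spans in
    copy coordinates; copies lacking a requested region are excluded from
    region-based clustering with a logged count.
    """

    annotation: TEAnnotation
    sequence: str
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("sequence alphabet must be within {A,C,G,T,N}")

    def region_sequence(self, region: Optional[str]) -> Optional[str]:
        if region is None:
            return self.sequence
        span = self.landmarks.get(region)
        if span is None:
            return None
        return self.sequence[span[0]: span[1]]


@dataclass
class Cluster:
    cluster_id: str
    members: list[TECopy]
    seed_index: int  # center-star reference (medoid)


@dataclass
class ConsensusRecord:
    """Subfamily consensus with structural landmark spans."""

    name: str
    family: str
    sequence: str
    landmarks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for region, (s, e) in self.landmarks.items():
            if not (0 <= s <= e <= len(self.sequence)):
                raise ValueError(f"landmark {region} span ({s},{e}) outside consensus")


# ---------------------------------------------------------------------------
# Locus merging and flank extension
# ---------------------------------------------------------------------------

def merge_loci(
    loci: Sequence[GenomicInterval], max_distance: int = 3000
) -> list[GenomicInterval]:
    """Transitively merge same-chrom, same-strand loci with gap <= max_distance.

    Overlapping intervals count as gap 0.  The result is sorted and the
    operation is idempotent.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be non-negative")
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in loci:
        groups.setdefault((iv.chrom, iv.strand), []).append(iv)
    merged: list[GenomicInterval] = []
    for (chrom, strand), ivs in groups.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            gap = iv.start - cur_end  # negative when overlapping
            if gap <= max_distance:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, strand))
    merged.sort()
    return merged


def extend_flanks(
    locus: GenomicInterval,
    chrom_length: int,
    upstream: int = 2500,
    downstream: int = 200,
) -> GenomicInterval:
    """Strand-aware flank extension (bedtools slop -s semantics).

    On '+' the 5' side is the interval start; on '-' it is the end.
    Coordinates are clamped to [0, chrom_length].
    """
    if locus.strand not in ("+", "-"):
        raise ValueError("strand-aware extension undefined for unstranded locus")
    if chrom_length < locus.end:
        raise ValueError("chrom_length smaller than locus end")
    if locus.strand == "+":
        start = locus.start - upstream
        end = locus.end + downstream
    else:
        start = locus.start - downstream
        end = locus.end + upstream
    return GenomicInterval(locus.chrom, max(0, start), min(chrom_length, end), locus.strand)


# ---------------------------------------------------------------------------
# Pairwise alignment and identity
# ---------------------------------------------------------------------------

def _make_aligner(mode: str = "global") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matching columns / total aligned columns."""
    if a == b:
        return 1.0
    aln = _make_aligner().align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ra, rb) if x == y and x != "-")
    return matches / len(ra)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_by_similarity(
    copies: Sequence[TECopy],
    region: Optional[str] = "5UTR",
    min_identity: float = 0.80,
    min_cluster_size: int = 10,
) -> list[Cluster]:
    """Single-linkage clustering on pairwise alignment identity.

    A link joins two copies when their region sequences align at identity
    >= ``min_identity``; clusters smaller than ``min_cluster_size`` are
    dropped.  Every surviving copy belongs to exactly one cluster.
    """
    if not (0.0 < min_identity <= 1.0):
        raise ValueError("min_identity must be in (0, 1]")
    usable = [(i, c, c.region_sequence(region)) for i, c in enumerate(copies)]
    excluded = sum(1 for _, _, s in usable if s is None or not s)
    usable = [(i, c, s) for i, c, s in usable if s]
    if excluded:
        import logging
        logging.getLogger(__name__).info(
            "cluster_by_similarity: excluded %d copies lacking region %r", excluded, region
        )
    n = len(usable)
    uf = _UnionFind(n)
    # cache identities: identical strings shortcut avoids O(L^2) alignment
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if pairwise_identity(usable[i][2], usable[j][2]) >= min_identity:
                uf.union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(uf.find(i), []).append(i)
    clusters: list[Cluster] = []
    kept = [sorted(members) for root, members in sorted(comps.items())
            if len(members) >= min_cluster_size]
    for k, members in enumerate(kept):
        copies_k = [usable[i][1] for i in members]
        seed = _medoid_index([usable[i][2] for i in members])
        clusters.append(Cluster(cluster_id=f"cluster{k + 1}", members=copies_k, seed_index=seed))
    return clusters


def _medoid_index(seqs: Sequence[str]) -> int:
    """Member with maximal summed pairwise identity (ties: lowest index)."""
    if len(seqs) == 1:
        return 0
    best_i, best_sum = 0, -1.0
    for i in range(len(seqs)):
        total = sum(pairwise_identity(seqs[i], seqs[j]) for j in range(len(seqs)) if j != i)
        if total > best_sum + 1e-12:
            best_i, best_sum = i, total
    return best_i


# ---------------------------------------------------------------------------
# Center-star MSA and consensus
# ---------------------------------------------------------------------------

def build_msa(sequences: Sequence[str], center_index: Optional[int] = None) -> list[str]:
    """Center-star multiple alignment around the medoid.

    Pairwise global alignments of every member against the center are merged
    by the once-a-gap-always-a-gap rule.  Removing gaps from row i recovers
    member i exactly.  A single member is returned unchanged.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return [sequences[0]]
    if center_index is None:
        center_index = _medoid_index(sequences)
    center = sequences[center_index]
    aligner = _make_aligner()

    # per-pairwise-alignment gap counts inserted into the center before each
    # center position i (i = 0..len(center)); master = columnwise maximum
    pair_rows: list[tuple[int, Optional[list[int]], Optional[str], Optional[str]]] = []
    master = [0] * (len(center) + 1)
    for idx, seq in enumerate(sequences):
        if idx == center_index:
            pair_rows.append((idx, None, None, None))
            continue
        aln = aligner.align(center, seq)[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        gaps = [0] * (len(center) + 1)
        pos = 0
        for ch in c_aln:
            if ch == "-":
                gaps[pos] += 1
            else:
                pos += 1
        master = [max(m, g) for m, g in zip(master, gaps)]
        pair_rows.append((idx, gaps, c_aln, s_aln))

    rows: list[Optional[str]] = [None] * len(sequences)
    # center row under the master gap pattern
    out = []
    for i, base in enumerate(center):
        out.append("-" * master[i])
        out.append(base)
    out.append("-" * master[len(center)])
    rows[center_index] = "".join(out)

    for idx, gaps, c_aln, s_aln in pair_rows:
        if gaps is None:
            continue
        # walk the pairwise alignment, padding each center-gap run up to the
        # master count for that slot
        out = []
        pos = 0  # next center position
        run = []  # member chars emitted in the current center-gap run
        k = 0
        while k <= len(c_aln):
            if k < len(c_aln) and c_aln[k] == "-":
                run.append(s_aln[k])
                k += 1
                continue
            # close the run at center position `pos`
            out.append("".join(run) + "-" * (master[pos] - len(run)))
            run = []
            if k == len(c_aln):
                break
            out.append(s_aln[k])
            pos += 1
            k += 1
        rows[idx] = "".join(out)
    assert all(r is not None for r in rows)
    return [r for r in rows if r is not None]


def build_cluster_msa(cluster: Cluster, region: Optional[str] = None) -> list[str]:
    """Align the full sequences (or a landmark region) of a cluster."""
    seqs = [m.region_sequence(region) or "" for m in cluster.members]
    return build_msa(seqs, center_index=cluster.seed_index)


def derive_consensus(
    alignment: Sequence[str],
    name: str = "consensus",
    family: str = "unknown",
    seed_row: int = 0,
    seed_landmarks: Optional[dict[str, tuple[int, int]]] = None,
) -> ConsensusRecord:
    """Majority-rule consensus of a gapped alignment.

    Per column the plurality base is emitted (ties broken alphabetically,
    A<C<G<T); a column is omitted when its gap frequency exceeds 50%.
    Landmarks of the seed row are projected through the alignment into
    consensus coordinates.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(r) != width for r in alignment):
        raise ValueError("alignment rows must be equal length")
    n = len(alignment)
    consensus_chars: list[str] = []
    col_to_cons: list[Optional[int]] = []  # alignment column -> consensus index
    for col in range(width):
        column = [row[col] for row in alignment]
        gaps = column.count("-")
        if gaps * 2 > n:  # strict 50% threshold
            col_to_cons.append(None)
            continue
        counts: dict[str, int] = {}
        for ch in column:
            if ch in "ACGT":
                counts[ch] = counts.get(ch, 0) + 1
        if not counts:
            col_to_cons.append(None)
            continue
        best = max(sorted(counts), key=lambda b: counts[b])  # alphabetical tie-break
        col_to_cons.append(len(consensus_chars))
        consensus_chars.append(best)

    landmarks: dict[str, tuple[int, int]] = {}
    if seed_landmarks:
        # map seed residue index -> alignment column
        seed = alignment[seed_row]
        res_to_col = [c for c, ch in enumerate(seed) if ch != "-"]
        n_cons = len(consensus_chars)

        def project(res_idx: int) -> int:
            if res_idx >= len(res_to_col):
                return n_cons
            col = res_to_col[res_idx]
            # consensus position at or after this column
            for c in range(col, width):
                if col_to_cons[c] is not None:
                    return col_to_cons[c]
            return n_cons

        for region, (s, e) in seed_landmarks.items():
            ps, pe = project(s), project(e)
            if pe > ps:
                landmarks[region] = (ps, pe)
    return ConsensusRecord(name=name, family=family,
                           sequence="".join(consensus_chars), landmarks=landmarks)


def consensus_from_cluster(
    cluster: Cluster, name: Optional[str] = None, family: str = "unknown"
) -> ConsensusRecord:
    """Convenience: MSA + majority consensus for one cluster."""
    aln = build_cluster_msa(cluster)
    seed_landmarks = cluster.members[cluster.seed_index].landmarks or None
    return derive_consensus(
        aln,
        name=name or cluster.cluster_id,
        family=family,
        seed_row=cluster.seed_index,
        seed_landmarks=seed_landmarks,
    )
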