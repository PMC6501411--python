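"""TE intersection with genes, flanks, and orientation-bias statistics.

Each TE is assigned to exactly one location category by a fixed precedence
(pc/lncRNA overlap > exon > intron, genic > flank, 5' > 3', protein-coding
before lncRNA on ties), keeping only overlaps of at least ``min_overlap``
bp (default 25).  Coverage per region set is computed on interval unions so
no base is counted twice.  Sense/antisense insertion counts are tested
against a 50/50 expectation with a 1-dof chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2 as chi2_dist

from mobiloscope.formats_io import GeneModel, GenomicInterval, TEAnnotation

#: Location categories in precedence order.
CATEGORIES = (
    "pc_lnc_overlap",
    "pc_exon",
    "lnc_exon",
    "pc_intron",
    "lnc_intron",
    "pc_5flank",
    "pc_3flank",
    "lnc_5flank",
    "lnc_3flank",
    "intergenic",
)

GENIC_CATEGORIES = frozenset(
    {"pc_exon", "pc_intron", "lnc_exon", "lnc_intron", "pc_lnc_overlap"}
)


@dataclass(frozen=True)
class OverlapRecord:
    te: TEAnnotation
    feature_owner: tuple[str, ...]  # gene id(s); empty for intergenic
    location: str
    orientation: str  # sense | antisense | na
    overlap_bp: int


@dataclass(frozen=True)
class BiasResult:
    stratum: tuple[str, str]  # (te_class, location)
    sense_n: int
    antisense_n: int
    chi2: float
    p: float


def round_pct(numerator: int, denominator: int) -> float:
    """Percentage to two decimals, round half up (printed-style formatting)."""
    if denominator == 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Flanks
# ---------------------------------------------------------------------------

def build_flanks(
    genes: Sequence[GeneModel],
    chrom_lengths: dict[str, int],
    up: int = 5000,
    down: int = 3000,
) -> dict[str, dict[str, Optional[GenomicInterval]]]:
    """Strand-aware 5'/3' flanks adjacent to each gene body, clamped.

    Returns {gene_id: {"5flank": interval|None, "3flank": interval|None}};
    a flank fully clamped away is None.  Flanks never overlap their own
    gene body.
    """
    out: dict[str, dict[str, Optional[GenomicInterval]]] = {}
    for g in genes:
        iv = g.interval
        if iv.strand not in ("+", "-"):
            raise ValueError(f"{g.gene_id}: flanks undefined for unstranded gene")
        clen = chrom_lengths[iv.chrom]
        if iv.strand == "+":
            five = (max(0, iv.start - up), iv.start)
            three = (iv.end, min(clen, iv.end + down))
        else:
            five = (iv.end, min(clen, iv.end + up))
            three = (max(0, iv.start - down), iv.start)
        out[g.gene_id] = {
            "5flank": GenomicInterval(iv.chrom, *five, iv.strand) if five[1] > five[0] else None,
            "3flank": GenomicInterval(iv.chrom, *three, iv.strand) if three[1] > three[0] else None,
        }
    return out


# ---------------------------------------------------------------------------
# TE / feature intersection
# ---------------------------------------------------------------------------

def _interval_union(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _pc_lnc_overlap_regions(genes: Sequence[GeneModel]) -> list[tuple[GenomicInterval, tuple[str, str]]]:
    """Pairwise intersections of pc and lncRNA gene bodies (any strands)."""
    pcs = [g for g in genes if g.biotype == "protein_coding"]
    lncs = [g for g in genes if g.biotype == "lncRNA"]
    out = []
    for p in pcs:
        for l in lncs:
            if p.interval.chrom != l.interval.chrom:
                continue
            s = max(p.interval.start, l.interval.start)
            e = min(p.interval.end, l.interval.end)
            if e > s:
                out.append((GenomicInterval(p.interval.chrom, s, e, "."),
                            (p.gene_id, l.gene_id)))
    return out


def intersect_te_features(
    tes: Sequence[TEAnnotation],
    genes: Sequence[GeneModel],
    flanks: Optional[dict[str, dict[str, Optional[GenomicInterval]]]] = None,
    min_overlap: int = 25,
    exclude_overshadowed: bool = False,
) -> list[OverlapRecord]:
    """Assign each TE to one location category by precedence.

    A TE is genic only when some single feature overlaps it by at least
    ``min_overlap`` bp; within the winning category ``overlap_bp`` is the
    largest single-feature overlap, and all owning genes at that category
    are reported.  TEs overlapping nothing sufficiently are intergenic.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    # category -> chrom -> IntervalTree of (owner ids)
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in CATEGORIES[:-1]}

    def add(cat: str, iv: GenomicInterval, owner: tuple[str, ...]) -> None:
        trees[cat].setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, owner)

    for iv, owners in _pc_lnc_overlap_regions(genes):
        add("pc_lnc_overlap", iv, owners)
    for g in genes:
        pre = "pc" if g.biotype == "protein_coding" else "lnc"
        for ex in g.exons:
            add(f"{pre}_exon", ex, (g.gene_id,))
        for intron in g.introns():
            add(f"{pre}_intron", intron, (g.gene_id,))
        if flanks and g.gene_id in flanks:
            for side in ("5flank", "3flank"):
                fiv = flanks[g.gene_id][side]
                if fiv is not None:
                    add(f"{pre}_{side}", fiv, (g.gene_id,))

    records: list[OverlapRecord] = []
    for te in tes:
        if exclude_overshadowed and te.overshadowed:
            continue
        iv = te.interval
        assigned = False
        for cat in CATEGORIES[:-1]:
            tree = trees[cat].get(iv.chrom)
            if tree is None:
                continue
            best_bp, owners = 0, []
            for hit in tree.overlap(iv.start, iv.end):
                bp = min(iv.end, hit.end) - max(iv.start, hit.begin)
                if bp >= min_overlap:
                    owners.extend(hit.data)
                    best_bp = max(best_bp, bp)
            if best_bp == 0:
                continue
            owner_ids = tuple(sorted(set(owners)))
            orientation = "na"
            if cat != "pc_lnc_overlap":
                gene = gene_by_id[owner_ids[0]]
                if iv.strand in "+-" and gene.interval.strand in "+-":
                    orientation = "sense" if iv.strand == gene.interval.strand else "antisense"
            records.append(OverlapRecord(te, owner_ids, cat, orientation, best_bp))
            assigned = True
            break
        if not assigned:
            records.append(OverlapRecord(te, (), "intergenic", "na", 0))
    return records


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def region_te_coverage(
    tes: Sequence[TEAnnotation],
    regions: dict[str, Sequence[GenomicInterval]],
    exclude_overshadowed: bool = False,
) -> pd.DataFrame:
    """Percent of each region set covered by each TE class.

    TE intervals of a class are unioned before counting so overlapping hits
    are not double-counted; region sets are unioned likewise.
    """
    by_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for te in tes:
        if exclude_overshadowed and te.overshadowed:
            continue
        by_class.setdefault(te.te_class, {}).setdefault(
            te.interval.chrom, []
        ).append((te.interval.start, te.interval.end))
    union_by_class = {
        cls: {chrom: _interval_union(ivs) for chrom, ivs in chroms.items()}
        for cls, chroms in by_class.items()
    }
    rows = []
    for rname, rivs in regions.items():
        region_union: dict[str, list[tuple[int, int]]] = {}
        for iv in rivs:
            region_union.setdefault(iv.chrom, []).append((iv.start, iv.end))
        region_union = {c: _interval_union(v) for c, v in region_union.items()}
        total_bp = sum(e - s for ivs in region_union.values() for s, e in ivs)
        if total_bp == 0:
            raise ValueError(f"region set {rname!r} has zero length")
        for cls, chroms in sorted(union_by_class.items()):
            covered = 0
            for chrom, r_ivs in region_union.items():
                t_ivs = chroms.get(chrom, [])
                covered += _union_overlap_bp(r_ivs, t_ivs)
            rows.append({"region": rname, "te_class": cls,
                         "pct_covered": covered / total_bp * 100.0})
    return pd.DataFrame(rows, columns=["region", "te_class", "pct_covered"])


def _union_overlap_bp(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Overlap bp of two sorted disjoint interval lists (two-pointer sweep)."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            total += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


# ---------------------------------------------------------------------------
# Orientation bias
# ---------------------------------------------------------------------------

def orientation_bias(
    records: Sequence[OverlapRecord],
    stratum: tuple[str, str],
    continuity_correction: bool = False,
) -> BiasResult:
    """Chi-square test of sense/antisense counts against 50/50.

    chi2 = (s - n/2)^2/(n/2) + (a - n/2)^2/(n/2), 1 dof upper tail.
    """
    te_class, location = stratum
    s = sum(1 for r in records
            if r.te.te_class == te_class and r.location == location
            and r.orientation == "sense")
    a = sum(1 for r in records
            if r.te.te_class == te_class and r.location == location
            and r.orientation == "antisense")
    n = s + a
    if n == 0:
        raise ValueError(f"no oriented records in stratum {stratum}")
    exp = n / 2.0
    if continuity_correction:
        stat = 2 * (abs(s - exp) - 0.5) ** 2 / exp if abs(s - exp) > 0.5 else 0.0
    else:
        stat = (s - exp) ** 2 / exp + (a - exp) ** 2 / exp
    p = float(chi2_dist.sf(stat, df=1))
    return BiasResult(stratum=stratum, sense_n=s, antisense_n=a, chi2=stat, p=p)


# ---------------------------------------------------------------------------
# Gene-hit summary
# ---------------------------------------------------------------------------

def gene_hit_summary(
    records: Sequence[OverlapRecord],
    genes: Sequence[GeneModel],
    young_subfamilies: Iterable[str] = (),
) -> pd.DataFrame:
    """Per-biotype counts of genes with >= 1 genic TE insertion.

    A gene is "hit" when some OverlapRecord with a genic location (exon,
    intron or pc/lnc overlap) references it; the "young" columns restrict
    to TEs whose subfamily is in ``young_subfamilies``.  Percentages are
    formatted to two decimals, round half up.
    """
    if not genes:
        raise ValueError("empty gene universe")
    young = set(young_subfamilies)
    hit: dict[str, set[str]] = {"protein_coding": set(), "lncRNA": set()}
    hit_young: dict[str, set[str]] = {"protein_coding": set(), "lncRNA": set()}
    biotype = {g.gene_id: g.biotype for g in genes}
    for r in records:
        if r.location not in GENIC_CATEGORIES:
            continue
        for gid in r.feature_owner:
            bt = biotype.get(gid)
            if bt is None:
                continue
            hit[bt].add(gid)
            if r.te.subfamily in young:
                hit_young[bt].add(gid)
    rows = []
    for bt in ("protein_coding", "lncRNA"):
        universe = [g.gene_id for g in genes if g.biotype == bt]
        if not universe:
            continue
        n, ny = len(hit[bt]), len(hit_young[bt])
        rows.append({
            "biotype": bt,
            "n_genes": len(universe),
            "n_genes_hit": n,
            "pct_of_genes": round_pct(n, len(universe)),
            "n_genes_hit_young": ny,
            "pct_young": round_pct(ny, len(universe)),
        })
    return pd.DataFrame(rows)
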