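"""Brute-force oracles shared by the acceptance tests.

These deliberately mirror the documented precedence rules with O(n*m)
all-pairs scans and no interval index, so they stay independent of the
implementation they check.
"""

from mobiloscope.formats_io import GenomicInterval
from mobiloscope.genic import CATEGORIES


def _ov(a, b):
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def oracle_category(te, genes, flanks, min_overlap=25):
    """All-pairs location assignment for one TE annotation."""
    iv = te.interval
    hits = {c: 0 for c in CATEGORIES}
    for p in genes:
        if p.biotype != "protein_coding":
            continue
        for l in genes:
            if l.biotype != "lncRNA" or p.interval.chrom != l.interval.chrom:
                continue
            s = max(p.interval.start, l.interval.start)
            e = min(p.interval.end, l.interval.end)
            if e > s:
                region = GenomicInterval(p.interval.chrom, s, e, ".")
                hits["pc_lnc_overlap"] = max(hits["pc_lnc_overlap"], _ov(iv, region))
    for g in genes:
        pre = "pc" if g.biotype == "protein_coding" else "lnc"
        for ex in g.exons:
            hits[f"{pre}_exon"] = max(hits[f"{pre}_exon"], _ov(iv, ex))
        for intr in g.introns():
            hits[f"{pre}_intron"] = max(hits[f"{pre}_intron"], _ov(iv, intr))
        for side in ("5flank", "3flank"):
            fiv = flanks.get(g.gene_id, {}).get(side)
            if fiv is not None:
                hits[f"{pre}_{side}"] = max(hits[f"{pre}_{side}"], _ov(iv, fiv))
    for cat in CATEGORIES[:-1]:
        if hits[cat] >= min_overlap:
            return cat
    return "intergenic"
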