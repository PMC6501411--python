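"""Gene flanks, TE-feature intersection, coverage, orientation bias."""

import math

import numpy as np
import pytest

from mobiloscope.formats_io import GeneModel, GenomicInterval, TEAnnotation
from mobiloscope.genic import (
    CATEGORIES,
    GENIC_CATEGORIES,
    build_flanks,
    gene_hit_summary,
    intersect_te_features,
    orientation_bias,
    region_te_coverage,
    round_pct,
)

CHROMS = {"chr1": 10**6}


def _gene(gid, start, end, strand="+", biotype="protein_coding", exons=None):
    iv = GenomicInterval("chr1", start, end, strand)
    exons = exons or [iv]
    return GeneModel(gid, biotype, iv, tuple(exons))


def _te(start, end, strand="+", te_class="LINE", sub="L1D1"):
    return TEAnnotation(GenomicInterval("chr1", start, end, strand),
                        te_class, "L1", sub, 1.0)


class TestBuildFlanks:
    def test_plus_strand(self):
        f = build_flanks([_gene("g", 10000, 20000)], CHROMS)["g"]
        assert f["5flank"] == GenomicInterval("chr1", 5000, 10000, "+")
        assert f["3flank"] == GenomicInterval("chr1", 20000, 23000, "+")

    def test_minus_strand_mirrored(self):
        f = build_flanks([_gene("g", 10000, 20000, "-")], CHROMS)["g"]
        assert f["5flank"] == GenomicInterval("chr1", 20000, 25000, "-")
        assert f["3flank"] == GenomicInterval("chr1", 7000, 10000, "-")

    def test_clamped_at_chrom_start(self):
        f = build_flanks([_gene("g", 2000, 4000)], CHROMS)["g"]
        assert f["5flank"] == GenomicInterval("chr1", 0, 2000, "+")

    def test_unstranded_gene_rejected(self):
        with pytest.raises(ValueError):
            build_flanks([_gene("g", 10, 20, ".")], CHROMS)


class TestIntersect:
    def test_25bp_exon_overlap_retained_24_falls_through(self):
        gene = _gene("g", 1000, 2000)
        te_ok = _te(900, 1025)  # overlap exactly 25
        te_no = _te(900, 1024)  # overlap 24
        rec_ok, rec_no = intersect_te_features([te_ok, te_no], [gene])
        assert rec_ok.location == "pc_exon" and rec_ok.overlap_bp == 25
        assert rec_no.location == "intergenic"

    def test_pc_lnc_overlap_category(self):
        pc = _gene("p", 1000, 5000)
        lnc = _gene("l", 4000, 8000, biotype="lncRNA")
        te = _te(4100, 4300)
        (rec,) = intersect_te_features([te], [pc, lnc])
        assert rec.location == "pc_lnc_overlap"
        assert set(rec.feature_owner) == {"p", "l"}

    def test_exon_beats_intron_within_one_gene(self):
        g = _gene("g", 1000, 5000,
                  exons=[GenomicInterval("chr1", 1000, 2000, "+"),
                         GenomicInterval("chr1", 4000, 5000, "+")])
        te = _te(1900, 2200)  # spans exon (100 bp) and intron (200 bp)
        (rec,) = intersect_te_features([te], [g])
        assert rec.location == "pc_exon"

    def test_genic_beats_flank_and_5_beats_3(self):
        g1 = _gene("a", 10000, 20000)
        flanks = build_flanks([g1], CHROMS)
        te_flank = _te(8000, 9000)
        (rec,) = intersect_te_features([te_flank], [g1], flanks)
        assert rec.location == "pc_5flank"

    def test_orientation_relative_to_gene(self):
        g = _gene("g", 1000, 2000, "+")
        sense = _te(1100, 1300, "+")
        anti = _te(1400, 1600, "-")
        recs = intersect_te_features([sense, anti], [g])
        assert [r.orientation for r in recs] == ["sense", "antisense"]

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            genes = []
            for i in range(int(rng.integers(2, 15))):
                s = int(rng.integers(0, 80000))
                L = int(rng.integers(500, 6000))
                n_ex = int(rng.integers(1, 4))
                bounds = sorted(rng.integers(0, L, size=2 * n_ex).tolist())
                strand = "+" if rng.random() < 0.5 else "-"
                bt = "protein_coding" if rng.random() < 0.6 else "lncRNA"
                exons = [GenomicInterval("chr1", s + bounds[2 * k], s + bounds[2 * k + 1], strand)
                         for k in range(n_ex) if bounds[2 * k + 1] > bounds[2 * k]]
                if not exons:
                    continue
                iv = GenomicInterval("chr1", s, s + L, strand)
                exons = [e for e in exons if e.end <= iv.end]
                try:
                    genes.append(GeneModel(f"g{trial}_{i}", bt, iv, tuple(exons)))
                except ValueError:
                    continue
            tes = [_te(int(p), int(p) + int(rng.integers(10, 900)),
                       "+" if rng.random() < 0.5 else "-")
                   for p in rng.integers(0, 90000, size=int(rng.integers(5, 40)))]
            flanks = build_flanks(genes, CHROMS)
            recs = intersect_te_features(tes, genes, flanks, min_overlap=25)
            assert len(recs) == len(tes)
            for te, rec in zip(tes, recs):
                assert rec.location == _oracle_category(te, genes, flanks)

    def test_categories_partition_all_tes(self):
        g = _gene("g", 1000, 2000)
        tes = [_te(s, s + 100) for s in range(0, 5000, 500)]
        recs = intersect_te_features(tes, [g])
        assert len(recs) == len(tes)
        assert all(r.location in CATEGORIES for r in recs)


def _oracle_category(te, genes, flanks, min_overlap=25):
    """Brute-force all-pairs category assignment."""
    iv = te.interval

    def ov(a, b):
        if a.chrom != b.chrom:
            return 0
        return max(0, min(a.end, b.end) - max(a.start, b.start))

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
                hits["pc_lnc_overlap"] = max(hits["pc_lnc_overlap"], ov(iv, region))
    for g in genes:
        pre = "pc" if g.biotype == "protein_coding" else "lnc"
        for ex in g.exons:
            hits[f"{pre}_exon"] = max(hits[f"{pre}_exon"], ov(iv, ex))
        for intr in g.introns():
            hits[f"{pre}_intron"] = max(hits[f"{pre}_intron"], ov(iv, intr))
        for side in ("5flank", "3flank"):
            fiv = flanks.get(g.gene_id, {}).get(side)
            if fiv is not None:
                hits[f"{pre}_{side}"] = max(hits[f"{pre}_{side}"], ov(iv, fiv))
    for cat in CATEGORIES[:-1]:
        if hits[cat] >= min_overlap:
            return cat
    return "intergenic"


class TestCoverage:
    def test_half_covered(self):
        cov = region_te_coverage([_te(0, 50)], {"r": [GenomicInterval("chr1", 0, 100, "+")]})
        assert cov.iloc[0].pct_covered == pytest.approx(50.0)

    def test_union_prevents_double_counting(self):
        cov = region_te_coverage([_te(0, 60), _te(40, 80)],
                                 {"r": [GenomicInterval("chr1", 0, 100, "+")]})
        assert cov.iloc[0].pct_covered == pytest.approx(80.0)

    def test_zero_length_region_rejected(self):
        with pytest.raises(ValueError):
            region_te_coverage([_te(0, 50)], {"r": []})

    def test_coverage_never_exceeds_100(self):
        rng = np.random.default_rng(5)
        tes = [_te(int(s), int(s) + int(rng.integers(10, 500)),
                   te_class=str(rng.choice(["LINE", "SINE", "LTR"])))
               for s in rng.integers(0, 5000, size=60)]
        regions = {"r": [GenomicInterval("chr1", 0, 3000, "+"),
                         GenomicInterval("chr1", 2500, 6000, "+")]}
        cov = region_te_coverage(tes, regions)
        assert (cov.pct_covered <= 100.0 + 1e-9).all()
        # cross-check one class against per-bp counting
        cls = cov.iloc[0].te_class
        base = np.zeros(6000, bool)
        for t in tes:
            if t.te_class == cls:
                base[t.interval.start: min(6000, t.interval.end)] = True
        assert cov.iloc[0].pct_covered == pytest.approx(base.sum() / 6000 * 100)


class TestOrientationBias:
    def _records(self, s, a):
        g = _gene("g", 0, 10**5)
        tes = [_te(i * 300, i * 300 + 100, "+") for i in range(s)]
        tes += [_te((s + i) * 300, (s + i) * 300 + 100, "-") for i in range(a)]
        return intersect_te_features(tes, [g])

    def test_balanced_counts_give_zero_chi2(self):
        b = orientation_bias(self._records(50, 50), ("LINE", "pc_exon"))
        assert b.chi2 == 0.0 and b.p == pytest.approx(1.0)

    def test_30_70_gives_chi2_16(self):
        b = orientation_bias(self._records(30, 70), ("LINE", "pc_exon"))
        assert b.chi2 == pytest.approx(16.0)
        assert b.p == pytest.approx(math.erfc(math.sqrt(16.0 / 2.0)), rel=1e-10)

    def test_extreme_counts(self):
        b = orientation_bias(self._records(0, 10), ("LINE", "pc_exon"))
        assert b.chi2 == pytest.approx(10.0)

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            orientation_bias([], ("SINE", "lnc_intron"))


class TestGeneHitSummary:
    def test_printed_ratio_formatting(self):
        assert round_pct(17278, 21087) == 81.94
        assert round_pct(1, 800) == 0.13  # 0.125 rounds half-up

    def test_counts_against_constructed_truth(self):
        genes = [_gene(f"p{i}", i * 10000, i * 10000 + 3000) for i in range(4)]
        genes += [_gene("l0", 50000, 56000, biotype="lncRNA")]
        tes = [_te(100, 400, sub="L1D1"),            # hits p0 (young)
               _te(10100, 10400, sub="L1D5"),        # hits p1 (old)
               _te(51000, 51200, sub="SINEA1")]      # hits l0 (young)
        recs = intersect_te_features(tes, genes)
        out = gene_hit_summary(recs, genes, young_subfamilies={"L1D1", "SINEA1"})
        pc = out[out.biotype == "protein_coding"].iloc[0]
        lnc = out[out.biotype == "lncRNA"].iloc[0]
        assert (pc.n_genes_hit, pc.n_genes_hit_young) == (2, 1)
        assert pc.pct_of_genes == 50.0 and pc.pct_young == 25.0
        assert (lnc.n_genes_hit, lnc.pct_of_genes) == (1, 100.0)

    def test_no_hits_and_empty_universe(self):
        genes = [_gene("p0", 0, 1000)]
        out = gene_hit_summary([], genes)
        assert out.iloc[0].pct_of_genes == 0.0
        with pytest.raises(ValueError):
            gene_hit_summary([], [])
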