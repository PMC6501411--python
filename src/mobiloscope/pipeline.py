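"""End-to-end orchestration: simulate -> consensus -> phylo -> age ->
intersect -> chimeric, with a resolved-config archive and per-stage counts.

Defaults equal the stated analysis constants: locus merge distance 3000 bp,
5'/3' consensus flanks 2500/200 bp, cluster min size 10 at 0.80 identity,
25 bp minimum feature overlap, gene flanks 5000/3000 bp, EST filters
0.90/0.70, TE-fraction discard 0.80, minimum 50 TE bases, substitution
rate 2.2e-9/site/year, 100 bootstrap replicates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from mobiloscope import age_model, chimeric, formats_io, genic, phylo, subfamily

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # inputs (a simulate() output directory provides all of them)
    indir: str = "."
    outdir: str = "report"
    seed: int = 0
    # subfamily building
    merge_distance: int = 3000
    flank_upstream: int = 2500
    flank_downstream: int = 200
    min_identity: float = 0.80
    min_cluster_size: int = 10
    # phylogenetics
    bootstrap_replicates: int = 100
    # dating
    rate: float = 2.2e-9
    bin_width_mya: float = 1.0
    group_by: str = "subfamily"
    # genic intersection
    min_overlap: int = 25
    gene_flank_up: int = 5000
    gene_flank_down: int = 3000
    young_subfamilies: tuple[str, ...] = ()
    # chimeric cascade
    est_gene_overlap: float = 0.90
    est_mrna_coverage: float = 0.70
    est_mrna_identity: float = 0.95
    max_te_fraction: float = 0.80
    min_te_bases: int = 50
    est_filter_mode: str = "sequential"
    annotator_min_score: int = 50

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "young_subfamilies" in raw:
            raw["young_subfamilies"] = tuple(raw["young_subfamilies"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["young_subfamilies"] = list(self.young_subfamilies)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, stages: Optional[list[str]] = None) -> dict:
    """Run the requested stages over a directory of standard-format inputs.

    Writes TSV/JSON reports, the resolved config and a stage-count log to
    ``cfg.outdir``; returns the report dictionary.
    """
    stages = stages or ["age", "intersect", "chimeric"]
    indir, outdir = Path(cfg.indir), Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "resolved_config.yaml")
    report: dict = {"stages": stages, "counts": {}}

    genome = formats_io.read_fasta(indir / "genome.fa")
    genome_bp = sum(len(s) for s in genome.values())
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    tes = formats_io.read_repeatmasker_out(indir / "te.out")
    genes = formats_io.read_gff3(indir / "genes.gff3")
    report["counts"]["te_annotations"] = len(tes)
    report["counts"]["genes"] = len(genes)

    if "age" in stages:
        acfg = age_model.AgeModelConfig(r=cfg.rate, bin_width_mya=cfg.bin_width_mya)
        hist = age_model.age_histogram(tes, genome_bp, group_by=cfg.group_by, cfg=acfg)
        hist.to_csv(outdir / "age_histogram.tsv", sep="\t", index=False)
        means: dict[str, float] = {}
        key = {"class": "te_class", "family": "family", "subfamily": "subfamily"}[cfg.group_by]
        groups: dict[str, list[float]] = {}
        for a in tes:
            try:
                t = age_model.estimate_age(age_model.jc_correct(a.divergence_pct), acfg)
            except age_model.SaturationError:
                continue
            groups.setdefault(getattr(a, key), []).append(t / 1e6)
        for g, vals in sorted(groups.items()):
            means[g] = sum(vals) / len(vals)
        report["mean_age_mya"] = means

    if "intersect" in stages:
        flanks = genic.build_flanks(genes, chrom_lengths,
                                    up=cfg.gene_flank_up, down=cfg.gene_flank_down)
        records = genic.intersect_te_features(tes, genes, flanks,
                                              min_overlap=cfg.min_overlap)
        report["counts"]["overlap_records"] = len(records)
        cat_counts = {c: 0 for c in genic.CATEGORIES}
        for r in records:
            cat_counts[r.location] += 1
        report["location_counts"] = cat_counts
        summary = genic.gene_hit_summary(records, genes, cfg.young_subfamilies)
        summary.to_csv(outdir / "gene_hit_summary.tsv", sep="\t", index=False)
        report["gene_hit_summary"] = summary.to_dict(orient="records")
        regions = {
            "pc_gene_body": [g.interval for g in genes if g.biotype == "protein_coding"],
            "lnc_gene_body": [g.interval for g in genes if g.biotype == "lncRNA"],
        }
        regions = {k: v for k, v in regions.items() if v}
        if regions:
            cov = genic.region_te_coverage(tes, regions)
            cov.to_csv(outdir / "region_coverage.tsv", sep="\t", index=False)
            report["region_coverage"] = cov.to_dict(orient="records")
        bias_rows = []
        for te_class in sorted({t.te_class for t in tes}):
            for loc in ("pc_intron", "pc_exon", "lnc_intron", "lnc_exon"):
                try:
                    b = genic.orientation_bias(records, (te_class, loc))
                except ValueError:
                    continue
                bias_rows.append({"te_class": te_class, "location": loc,
                                  "sense": b.sense_n, "antisense": b.antisense_n,
                                  "chi2": b.chi2, "p": b.p})
        with open(outdir / "orientation_bias.tsv", "w") as fh:
            fh.write("te_class\tlocation\tsense\tantisense\tchi2\tp\n")
            for row in bias_rows:
                fh.write("\t".join(str(row[k]) for k in
                                   ("te_class", "location", "sense", "antisense",
                                    "chi2", "p")) + "\n")
        report["orientation_bias"] = bias_rows

    if "chimeric" in stages:
        mrna_seqs = formats_io.read_fasta(indir / "mrnas.fa")
        est_seqs = formats_io.read_fasta(indir / "ests.fa")
        est_models = formats_io.read_bed(indir / "ests.bed12", dialect="bed12")
        ests = []
        for e in est_models:
            seq = est_seqs.get(e.transcript_id)
            if seq is None or len(seq) != e.block_length():
                continue
            ests.append(dataclasses.replace(e, sequence=seq))
        # mRNA ids follow <gene>.m1
        mrnas = []
        gene_ids = {g.gene_id for g in genes}
        tx_gene: dict[str, str] = {}
        for tid, seq in mrna_seqs.items():
            gid = tid.rsplit(".", 1)[0]
            blocks = (formats_io.GenomicInterval("na", 0, len(seq), "+"),)
            g = next((x for x in genes if x.gene_id == gid), None)
            if g is not None:
                tx_gene[tid] = gid
                blocks = (formats_io.GenomicInterval(
                    g.interval.chrom, g.interval.start,
                    g.interval.start + len(seq), g.interval.strand),)
            mrnas.append(formats_io.TranscriptModel(
                transcript_id=tid, kind="mRNA", blocks=blocks,
                sequence=seq, parent_gene=tx_gene.get(tid)))
        for e in ests:
            gid = e.transcript_id.split(".m1.est")[0]
            if gid in gene_ids:
                tx_gene[e.transcript_id] = gid
        # library: subfamily consensus derived from the annotated copies is
        # upstream work; here the caller supplies consensus.fa when present
        lib_path = indir / "consensus.fa"
        if lib_path.exists():
            lib_seqs = formats_io.read_fasta(lib_path)
        else:  # fall back to the planted-subfamily consensus set
            from mobiloscope.simulate import default_library
            lib_seqs = {c.name: c.sequence for c in default_library()}
        library = [subfamily.ConsensusRecord(name=n, family=n, sequence=s)
                   for n, s in lib_seqs.items()]
        lib_classes = {a.subfamily: a.te_class for a in tes}
        calls, counts = chimeric.run_cascade(
            ests, mrnas, genes, library,
            gene_overlap_threshold=cfg.est_gene_overlap,
            coverage_threshold=cfg.est_mrna_coverage,
            min_identity=cfg.est_mrna_identity,
            max_te_fraction=cfg.max_te_fraction,
            min_te_bases=cfg.min_te_bases,
            min_score=cfg.annotator_min_score,
            library_classes=lib_classes,
            est_filter_mode=cfg.est_filter_mode,
        )
        report["counts"].update({f"chimeric_{k}": v for k, v in counts.items()})
        kinds = {c.transcript_id: ("mRNA" if c.transcript_id in mrna_seqs else "EST")
                 for c in calls}
        report["chimeric_summary"] = chimeric.summarize_chimeric(
            calls, tx_gene, genes, kinds=kinds)
        with open(outdir / "chimeric_calls.tsv", "w") as fh:
            fh.write("transcript_id\tstatus\tte_bases\tte_fraction\n")
            for c in sorted(calls, key=lambda c: c.transcript_id):
                fh.write(f"{c.transcript_id}\t{c.status}\t{c.te_bases}\t"
                         f"{c.te_fraction:.4f}\n")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
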