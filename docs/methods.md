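# Methods

This note documents the models implemented in mobiloscope, the parameters
that matter, the design choices made where the procedure was genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open with strands `+`/`-`/`.`.
The format readers are the only place 1-based arithmetic occurs:
RepeatMasker `.out` and GFF3 (1-based inclusive) are converted on ingest;
BED is passed through. `.out` hits flagged `*` (overshadowed by a
higher-scoring hit) are kept but marked, and downstream operations accept a
flag to exclude them — their handling in published pipelines is usually
unstated, so keeping them visible is the safer default.

## Subfamily construction

* **Locus merging.** "Distance" between two same-strand loci is read as the
  inter-interval gap (0 when overlapping), merged transitively at ≤ 3000 bp.
  Gap rather than start-to-start distance matches the intent of collapsing
  overlapping or adjacent duplicate calls from multiple detectors; the
  boundary is inclusive. The merge is idempotent and is tested against a
  union-find transitive-closure oracle.
* **Flank extension** is strand-aware (2500 bp 5′, 200 bp 3′ by default,
  the values used to recover L1 UTR boundaries) and clamps at chromosome
  ends, mirroring `bedtools slop -s`.
* **Clustering.** Single-linkage on pairwise global-alignment identity
  (match +1, mismatch −1, gap open −4, extend −1; identity = matching
  columns / alignment columns). The similarity threshold is not a published
  constant, so it is configurable with default 0.80 — conventional for
  subfamily-level grouping of young elements. Clusters under 10 members are
  discarded. Raising the threshold can only split clusters (monotonicity is
  tested).
* **MSA.** A center-star alignment around the medoid (maximum summed
  pairwise identity, ties to the lowest index) replaces a progressive
  aligner. For the ≥ 80%-identity clusters this stage consumes, center-star
  is within a constant factor of optimal and fully deterministic, which the
  downstream consensus and tests rely on. Gap-removal round trips are
  property-tested.
* **Consensus.** Per-column plurality base; columns with > 50% gaps are
  dropped; ties break alphabetically (A<C<G<T). Both rules exist purely for
  determinism — plurality behaviour differs across published consensus
  tools and versions. Structural landmarks (5′UTR/ORF1/IGR/ORF2/3′UTR for
  L1) are projected from the cluster seed through the alignment; this is an
  approximation, since true UTR boundaries would come from homology
  evidence the pipeline does not consume.

## Phylogenetics

* **K2P distance** with complete deletion (columns holding a gap or N in
  either sequence are removed first). Saturation (1−2P−Q ≤ 0 or 1−2Q ≤ 0)
  raises rather than returning a capped value.
* **Neighbor joining** (Saitou–Nei). Q-criterion ties break to the lowest
  label-sorted pair; negative branch estimates are clamped to zero with the
  deficit moved to the sibling edge (the convention of mainstream tree
  software). On additive matrices the reconstruction is exact, verified on
  random 4–12-leaf trees against a generate-from-tree oracle.
* **Bootstrap**: column resampling with a seeded generator; support = % of
  replicates containing each internal bipartition of the reference tree.
  Replicates whose resampled alignment saturates are skipped and count
  against support.
* **Family assignment.** No published cut criterion exists for reading
  families off such trees, so two explicit stand-ins are provided: a height
  cut (remove internal edges deeper than h from the root; connected leaf
  groups are families) and monophyletic seeds (each leaf joins the seed
  with which it shares the smallest enclosing clade containing no other
  seed; exact ties raise).
* **ERV ladder.** Flags are cumulative: RT presence, gag/pol/env presence,
  `full` (two LTRs + all three polyproteins), `putatively_active` (full and
  longest ORF ≥ 1500 aa). The ORF threshold is configurable; 1500 aa sits
  safely below the ~1750-aa polyproteins of replication-competent
  proviruses while excluding degraded copies.
* **RT reference panel.** The packaged panel
  (`data/synthetic_rt_panel.fasta`) is a *synthetic stand-in*: 15 sequences
  generated under a seeded two-level divergence model (class ancestors at
  high divergence from a common root, members at moderate divergence from
  their ancestor), labelled with the conventional reference names and
  classes (I/gamma, II/beta, III/spuma). Class assignment of a query is by
  nearest reference under K2P after global alignment — a nearest-neighbour
  approximation of nearest-clade placement. Results on the synthetic panel
  demonstrate the machinery, not real retroviral affinities.

## Insertion dating

K = −75 · ln(1 − 4D/300) converts percent divergence D to percent
substitutions per site; t = (K/100)/(2r). The division by 100 is required
for unit consistency (the formula yields percent, the rate r is per site)
and is the only reading that produces sensible timescales (D ≈ 2.17% →
≈ 5 Mya at r = 2.2 × 10⁻⁹/site/year, the assumed pig substitution rate).
D is used as reported by the annotator, with no CpG adjustment. Histogram
bins are half-open `[lo, hi)` of width 1 Mya by default; saturated copies
(D ≥ 75%) and ages beyond `max_age_mya` accumulate in an explicit overflow
bin rather than being dropped. Dating is per copy; per-group means are also
reported. Note that a true age lying exactly on a bin edge can place the
histogram mode in either adjacent bin.

## Genic intersection

A TE joins exactly one category by fixed precedence: pc/lncRNA gene-body
overlap regions, then exon before intron (a TE spanning both counts as
exon, the convention of feature-counting tools), protein-coding before
lncRNA on ties, genic before flank, 5′ flank before 3′. Only single-feature
overlaps of ≥ 25 bp count; anything less is intergenic. `overlap_bp` is the
largest single-feature overlap within the winning category, and all owning
genes at that category are recorded — so a TE hitting two genes counts once
in category proportions but once per gene in the gene-hit summary.
Coverage is computed on interval unions (no double counting), and the
orientation test is a plain 1-dof χ² against 50/50 without continuity
correction (a corrected variant is available by flag). Percentages print
at two decimals, round half up.

## Chimeric cascade

The five stages run strictly in order and each call records which stages
passed, so a transcript rejected at stage k carries no later flags:

1. ≥ 90% of EST bases inside a **single** protein-coding gene body (the
   per-gene maximum, not the union over genes — the union reading is noted
   as the alternative);
2. best local alignment to some mRNA at ≥ 95% identity covering **> 70%**
   of the EST (precomputed PSL coverage can replace internal alignment);
3. repeat annotation of the surviving ESTs and all mRNAs;
4. transcripts **> 80%** TE are discarded as probable transcripts of an
   active element — applied to ESTs and mRNAs alike, since the motive
   applies to both;
5. **≥ 50** TE bases (union of segments) calls a chimera.

Stage 2 applies to stage-1 survivors (`sequential`); a `union` mode keeps
ESTs passing either filter, since the published phrasing admits both
readings. The internal repeat annotator is a local-alignment scan of each
transcript against the consensus library (both strands) with iterative
masking, accepting hits above a score threshold best-first — it is a
simplified annotator sufficient for library-derived cassettes at modest
divergence (recall ≥ 0.95 at 5% divergence, ≥ 100 bp, in tests), not a
reimplementation of a full repeat annotation engine; importing
transcript-space `.out` files is the faithful path. Low-complexity library
entries are skipped in internal mode.

## Synthetic mobilome

The generator emulates exactly the statistical structure the estimators
assume: copies diverge from a known consensus by i.i.d. Jukes–Cantor
substitutions at per-site probability p = ¾(1 − e^(−4K/300)) with
K = 2rt, optional 5′ truncation (uniform cut) and polyA tails; background
sequence is i.i.d. with a GC knob; genes are laid out without mutual
overlap, with uniform exon/intron sizes; intronic TE insertions overwrite
background at a planted sense/antisense ratio; transcript cassettes are
consensus fragments of controlled length and orientation; ESTs are mRNA
fragments with light mutation plus intergenic decoys. The emitted `.out`
records the *realized* mismatch percentage of each copy, not the input K,
so dating tests measure estimator error only. One integer seed makes all
outputs byte-identical; all randomness flows through one integer-based
generator.

What the generator does **not** model: insertion-site preferences,
target-site duplications (off by default; flag available), indels and
recombination decay of old copies, isochore/GC structure, splice-aware EST
block structure (a cassette-bearing transcript gets a single synthetic
block, as its TE bases have no genomic counterpart), and subfamily
birth–death phylogenies. Passing tests therefore demonstrate correctness
of the estimators and filters under their own model assumptions, not
performance on real genomes.

## Problem sizes

The default test and acceptance runs use desk-scale instances chosen to
make sampling error negligible relative to the tolerances: 500 copies of a
3-kb consensus for age recovery (binomial SD of the mean divergence
≈ 0.012%, i.e. ≈ 0.03 Mya), 250 + 250 copies for the two-wave histogram,
~500 intronic insertions for the orientation test (χ² power ≫ 0.99 at
ρ = 0.7), 100 random instances for the interval-engine oracle and 100
random additive matrices for NJ exactness, and a 400-kb, 15-gene mobilome
for the end-to-end loop.
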