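"""Locus merging, flank extension, clustering, center-star MSA, consensus."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobiloscope.formats_io import GenomicInterval, TEAnnotation
from mobiloscope.simulate import mutate_jc, random_sequence
from mobiloscope.subfamily import (
    TECopy,
    build_msa,
    cluster_by_similarity,
    consensus_from_cluster,
    derive_consensus,
    extend_flanks,
    merge_loci,
    pairwise_identity,
)


def _brute_force_merge(loci, max_distance):
    """Transitive closure over all pairs (union-find oracle)."""
    n = len(loci)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = loci[i], loci[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= max_distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(loci[i])
    out = [
        GenomicInterval(g[0].chrom, min(x.start for x in g),
                        max(x.end for x in g), g[0].strand)
        for g in groups.values()
    ]
    return sorted(out)


class TestMergeLoci:
    def test_gap_2900_merges(self):
        got = merge_loci([GenomicInterval("c", 100, 500, "+"),
                          GenomicInterval("c", 3400, 3800, "+")])
        assert got == [GenomicInterval("c", 100, 3800, "+")]

    def test_opposite_strands_stay_separate(self):
        got = merge_loci([GenomicInterval("c", 100, 500, "+"),
                          GenomicInterval("c", 100, 500, "-")])
        assert len(got) == 2

    def test_gap_boundary_3000_inclusive_3002_separate(self):
        inside = merge_loci([GenomicInterval("c", 100, 500, "+"),
                             GenomicInterval("c", 3500, 3800, "+")])
        outside = merge_loci([GenomicInterval("c", 100, 500, "+"),
                              GenomicInterval("c", 3502, 3800, "+")])
        assert len(inside) == 1 and len(outside) == 2

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            merge_loci([], max_distance=-1)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["c1", "c2"]),
                  st.integers(0, 5000), st.integers(1, 800),
                  st.sampled_from(["+", "-"])),
        min_size=1, max_size=60))
    def test_matches_brute_force_oracle_and_is_idempotent(self, raw):
        loci = [GenomicInterval(c, s, s + l, d) for c, s, l, d in raw]
        got = merge_loci(loci, max_distance=300)
        assert got == _brute_force_merge(loci, 300)
        assert merge_loci(got, max_distance=300) == got


class TestExtendFlanks:
    def test_plus_strand(self):
        got = extend_flanks(GenomicInterval("c", 10000, 16000, "+"), 10**6)
        assert got == GenomicInterval("c", 7500, 16200, "+")

    def test_minus_strand_mirrored(self):
        got = extend_flanks(GenomicInterval("c", 10000, 16000, "-"), 10**6)
        assert got == GenomicInterval("c", 9800, 18500, "-")

    def test_clamped_at_chromosome_start(self):
        got = extend_flanks(GenomicInterval("c", 1000, 5000, "+"), 10**6)
        assert got == GenomicInterval("c", 0, 5200, "+")

    def test_unstranded_rejected(self):
        with pytest.raises(ValueError):
            extend_flanks(GenomicInterval("c", 10, 20, "."), 1000)


def _copy(seq, landmarks=None):
    ann = TEAnnotation(GenomicInterval("c", 0, len(seq), "+"),
                       "LINE", "L1", "cand", 0.0)
    return TECopy(annotation=ann, sequence=seq, landmarks=landmarks or {})


class TestClustering:
    def test_twelve_identical_form_one_cluster(self, rng):
        seq = random_sequence(200, rng)
        clusters = cluster_by_similarity([_copy(seq)] * 12, region=None)
        assert len(clusters) == 1 and len(clusters[0].members) == 12

    def test_nine_identical_filtered_out(self, rng):
        seq = random_sequence(200, rng)
        assert cluster_by_similarity([_copy(seq)] * 9, region=None) == []

    def test_two_divergent_blocks_give_two_clusters(self, rng):
        a = random_sequence(300, rng)
        b = random_sequence(300, rng)  # unrelated: ~25% identity to a
        copies = [_copy(mutate_jc(a, 1.0, rng)) for _ in range(15)]
        copies += [_copy(mutate_jc(b, 1.0, rng)) for _ in range(15)]
        clusters = cluster_by_similarity(copies, region=None)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [15, 15]

    def test_output_partitions_surviving_copies(self, rng):
        a = random_sequence(300, rng)
        copies = [_copy(mutate_jc(a, 2.0, rng)) for _ in range(12)]
        clusters = cluster_by_similarity(copies, region=None)
        seen = [id(m) for c in clusters for m in c.members]
        assert len(seen) == len(set(seen)) == 12

    def test_raising_min_identity_never_merges(self, rng):
        a, b = random_sequence(200, rng), random_sequence(200, rng)
        copies = [_copy(mutate_jc(a, 5.0, rng)) for _ in range(12)]
        copies += [_copy(mutate_jc(b, 5.0, rng)) for _ in range(12)]
        loose = cluster_by_similarity(copies, region=None, min_identity=0.6,
                                      min_cluster_size=1)
        tight = cluster_by_similarity(copies, region=None, min_identity=0.9,
                                      min_cluster_size=1)
        assert len(tight) >= len(loose)

    def test_region_absent_copies_excluded(self, rng):
        seq = random_sequence(300, rng)
        with_region = [_copy(seq, {"5UTR": (0, 100)}) for _ in range(10)]
        without = [_copy(seq) for _ in range(5)]
        clusters = cluster_by_similarity(with_region + without, region="5UTR")
        assert len(clusters) == 1 and len(clusters[0].members) == 10


def _brute_force_best_global(a, b):
    """Enumerate all alignments of two short sequences; return max score."""
    from functools import lru_cache

    # affine gaps, match +1 / mismatch -1 / open -4 / extend -1
    import itertools
    best = -1e9
    la, lb = len(a), len(b)

    def score(ra, rb):
        s, prev_gap = 0.0, None
        for x, y in zip(ra, rb):
            if x == "-" or y == "-":
                which = 0 if x == "-" else 1
                s += -1 if prev_gap == which else -4
                prev_gap = which
            else:
                s += 1 if x == y else -1
                prev_gap = None
        return s

    def gen(i, j, ra, rb):
        nonlocal best
        if i == la and j == lb:
            best = max(best, score(ra, rb))
            return
        if i < la:
            gen(i + 1, j, ra + a[i], rb + "-")
        if j < lb:
            gen(i, j + 1, ra + "-", rb + b[j])
        if i < la and j < lb:
            gen(i + 1, j + 1, ra + a[i], rb + b[j])

    gen(0, 0, "", "")
    return best


class TestMSA:
    def test_identical_sequences_align_trivially(self):
        assert build_msa(["ACGT", "ACGT", "ACGT"]) == ["ACGT"] * 3

    def test_single_gap_alignment_is_optimal(self):
        rows = build_msa(["ACGT", "ACGGT"])
        assert [r.replace("-", "") for r in rows] == ["ACGT", "ACGGT"]
        assert len(rows[0]) == len(rows[1]) == 5
        assert rows[0].count("-") == 1
        # score of the produced pairwise alignment equals the brute-force optimum
        s = 0
        prev = None
        for x, y in zip(*rows):
            if x == "-" or y == "-":
                w = 0 if x == "-" else 1
                s += -1 if prev == w else -4
                prev = w
            else:
                s += 1 if x == y else -1
                prev = None
        assert s == _brute_force_best_global("ACGT", "ACGGT")

    def test_single_member_returned_unchanged(self):
        assert build_msa(["ACGT"]) == ["ACGT"]

    def test_gap_removal_round_trip_random_clusters(self, rng):
        base = random_sequence(120, rng)
        seqs = [mutate_jc(base, 8.0, rng) for _ in range(6)]
        # introduce a small indel to exercise gap handling
        seqs[2] = seqs[2][:40] + seqs[2][45:]
        seqs[4] = seqs[4][:80] + "ACGT" + seqs[4][80:]
        rows = build_msa(seqs)
        assert len({len(r) for r in rows}) == 1
        assert [r.replace("-", "") for r in rows] == seqs


class TestConsensus:
    def test_majority_column(self):
        rec = derive_consensus(["A", "A", "G"])
        assert rec.sequence == "A"

    def test_majority_gap_column_omitted(self):
        rec = derive_consensus(["ATT", "-TT", "-TT"])
        assert rec.sequence == "TT"

    def test_tie_breaks_alphabetically(self):
        rec = derive_consensus(["A", "A", "G", "G"])
        assert rec.sequence == "A"
        rec = derive_consensus(["T", "T", "C", "C"])
        assert rec.sequence == "C"

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            derive_consensus([])

    def test_landmarks_projected_from_seed(self):
        rows = ["AACGT", "AACGT", "AA-GT"]
        rec = derive_consensus(rows, seed_row=0,
                               seed_landmarks={"5UTR": (0, 2), "ORF1": (2, 5)})
        assert rec.landmarks["5UTR"] == (0, 2)
        assert rec.landmarks["ORF1"] == (2, 5)

    def test_recovers_true_consensus_from_mutated_cluster(self, rng):
        truth = random_sequence(500, rng)
        copies = [_copy(mutate_jc(truth, 10.0, rng)) for _ in range(20)]
        (cluster,) = cluster_by_similarity(copies, region=None, min_identity=0.7)
        rec = consensus_from_cluster(cluster)
        assert pairwise_identity(rec.sequence, truth) >= 0.99
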