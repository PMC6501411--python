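"""Distance-based phylogenetics for TE family assignment.

Pairwise Kimura 2-parameter (K2P) distances with complete deletion feed a
Saitou-Nei neighbor-joining reconstruction; bootstrap support comes from
column resampling.  Families are read off the tree either by a height cut
or from user-supplied monophyletic seed members.  ERV candidates are placed
on a structural ladder (RT -> gag/pol/env -> full -> putatively active).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SaturationError",
    "k2p_distance",
    "k2p_matrix",
    "TreeNode",
    "PhyloTree",
    "nj_tree",
    "bootstrap_support",
    "assign_families",
    "ERVCandidate",
    "classify_erv_structure",
    "load_rt_panel",
    "classify_erv_class",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class SaturationError(ValueError):
    """Distance undefined: substitutions saturated the correction formula."""


# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or N are removed first
    (complete deletion).  With P the transition and Q the transversion
    fraction over the retained columns,

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n = transitions = transversions = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        same_type = (x in _PURINES) == (y in _PURINES)
        if same_type:
            transitions += 1
        else:
            transversions += 1
    if n == 0:
        raise ValueError("no retained columns after complete deletion")
    P, Q = transitions / n, transversions / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P saturated (P={P:.4g}, Q={Q:.4g})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """All-pairs K2P distances for a gapped alignment keyed by label."""
    labels = list(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(alignment[labels[i]], alignment[labels[j]])
    return labels, d


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root (NJ trifurcation)."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.leaves()]

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(f"{fmt(c)}:{bl:.6f}" for c, bl in node.children)
            label = ""
            if with_support and node.support is not None:
                label = f"{node.support:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path length between every leaf pair (for additivity checks)."""
        dists: dict[tuple[str, str], float] = {}

        def below(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.name or "", 0.0)]
            groups = []
            for child, bl in node.children:
                groups.append([(n, d + bl) for n, d in below(child)])
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for na, da in groups[gi]:
                        for nb, db in groups[gj]:
                            key = (na, nb) if na < nb else (nb, na)
                            dists[key] = da + db
            return [x for g in groups for x in g]

        below(self.root)
        return dists

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions as the child-side leaf set.

        Keys are canonicalized to the side NOT containing the overall
        smallest leaf label, so rooted placement does not matter.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root:
                side = below if anchor not in below else all_leaves - below
                if 1 < len(side) < len(all_leaves) - 1:
                    parts[side] = node
            return below

        walk(self.root)
        return parts

    def edge_sides(self) -> list[frozenset]:
        """Both sides of every edge (including leaf edges) as leaf sets."""
        all_leaves = frozenset(self.leaf_names())
        sides: list[frozenset] = []

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                below = frozenset([node.name])
            else:
                below = frozenset().union(*(walk(c) for c, _ in node.children))
            if node is not self.root:
                sides.append(below)
                sides.append(all_leaves - below)
            return below

        walk(self.root)
        return sides


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: Sequence[str], d: np.ndarray) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Joins the pair minimizing the Q-criterion at each step; ties are broken
    by the lowest label-sorted pair index.  Negative branch-length estimates
    are clamped to zero with the deficit moved to the sibling edge.  For an
    additive matrix the unique additive tree is recovered exactly.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if n == 2:
        half = d[0, 1] / 2.0
        root = TreeNode(children=[(TreeNode(name=labels[0]), half),
                                  (TreeNode(name=labels[1]), half)])
        return PhyloTree(root)

    # iterate over active nodes; order for tie-breaks follows sorted labels
    order = sorted(range(n), key=lambda i: labels[i])
    nodes: dict[int, TreeNode] = {i: TreeNode(name=labels[i]) for i in range(n)}
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    active = order[:]  # maintained in tie-break order
    next_id = n

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[next_id, k] = D[k, next_id] = dk
        D[next_id, next_id] = 0.0
        pos = min(active.index(i), active.index(j))
        active = [k for k in active if k not in (i, j)]
        active.insert(pos, next_id)
        next_id += 1

    # final trifurcation: solve the three terminal branch lengths exactly
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode(children=[(nodes[a], max(la, 0.0)),
                              (nodes[b], max(lb, 0.0)),
                              (nodes[c], max(lc, 0.0))])
    return PhyloTree(root)


def nj_from_alignment(alignment: dict[str, str]) -> PhyloTree:
    labels, d = k2p_matrix(alignment)
    return nj_tree(labels, d)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: dict[str, str], replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support of each internal bipartition of the reference (full-alignment)
    tree is the percentage of replicate trees containing it.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    width = len(next(iter(alignment.values())))
    if width < 1:
        raise ValueError("alignment must have at least one column")
    reference = nj_from_alignment(alignment)
    parts = reference.bipartitions()
    counts = {side: 0 for side in parts}
    rng = np.random.default_rng(seed)
    labels = list(alignment)
    cols = [[alignment[lab][c] for lab in labels] for c in range(width)]
    for _ in range(replicates):
        idx = rng.integers(0, width, size=width)
        rep_aln = {
            lab: "".join(cols[c][k] for c in idx) for k, lab in enumerate(labels)
        }
        try:
            rep_tree = nj_from_alignment(rep_aln)
        except (SaturationError, ValueError):
            continue  # uninformative resample; counts unchanged
        rep_parts = set(rep_tree.bipartitions())
        for side in counts:
            if side in rep_parts:
                counts[side] += 1
    for side, node in parts.items():
        node.support = 100.0 * counts[side] / replicates
    return reference


# ---------------------------------------------------------------------------
# Family assignment
# ---------------------------------------------------------------------------

def assign_families(
    tree: PhyloTree,
    method: str = "cut_height",
    h: Optional[float] = None,
    seeds: Optional[dict[str, str]] = None,
) -> dict[str, str]:
    """Partition the leaves of a tree into families.

    cut_height: internal edges whose child lies deeper than ``h`` from the
    root are removed; families are the connected leaf groups that remain.

    monophyletic_seeds: ``seeds`` maps family name -> one known member leaf.
    Each leaf joins the family of the seed with which it shares the smallest
    enclosing clade (edge-side, unrooted sense) that contains no other seed;
    a leaf whose smallest enclosing clade with every seed also holds a second
    seed stays "unassigned", and an exact tie between two seeds raises an
    error naming the conflict.
    """
    if method == "cut_height":
        if h is None:
            raise ValueError("cut_height requires h")
        families: dict[str, str] = {}
        counter = [0]

        def walk(node: TreeNode, depth: float, fam: Optional[str]) -> None:
            if fam is None:
                counter[0] += 1
                fam = f"family{counter[0]}"
            if node.is_leaf:
                families[node.name or ""] = fam
                return
            for child, bl in node.children:
                cd = depth + bl
                if not child.is_leaf and cd > h:
                    walk(child, cd, None)  # cut this edge: new family below
                else:
                    walk(child, cd, fam)

        walk(tree.root, 0.0, None)
        return families

    if method == "monophyletic_seeds":
        if not seeds:
            raise ValueError("monophyletic_seeds requires a non-empty seed map")
        leaf_set = set(tree.leaf_names())
        seed_leaves = set(seeds.values())
        missing = seed_leaves - leaf_set
        if missing:
            raise ValueError(f"seed leaves not in tree: {sorted(missing)}")
        if len(seed_leaves) < len(seeds):
            raise ValueError("two families share the same seed leaf")
        sides = tree.edge_sides()
        seed_fam = {leaf: fam for fam, leaf in seeds.items()}
        assignment: dict[str, str] = {}
        for leaf in sorted(leaf_set):
            if leaf in seed_fam:
                assignment[leaf] = seed_fam[leaf]
                continue
            best_size: Optional[int] = None
            best_fams: list[str] = []
            for fam, seed in sorted(seeds.items()):
                enclosing = [s for s in sides if leaf in s and seed in s
                             and not (seed_leaves - {seed}) & s]
                if not enclosing:
                    continue
                size = min(len(s) for s in enclosing)
                if best_size is None or size < best_size:
                    best_size, best_fams = size, [fam]
                elif size == best_size:
                    best_fams.append(fam)
            if best_size is None:
                assignment[leaf] = "unassigned"
            elif len(best_fams) > 1:
                raise ValueError(
                    f"leaf {leaf!r} sits in the same minimal clade as seeds of "
                    f"families {best_fams}"
                )
            else:
                assignment[leaf] = best_fams[0]
        return assignment

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# ERV structural ladder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ERVCandidate:
    """An ERV candidate with upstream-detected LTRs and domain spans."""

    id: str
    ltr_spans: tuple[tuple[int, int], ...] = ()
    domain_spans: dict = field(default_factory=dict)  # RT/gag/pol/env -> (s,e) or None
    longest_orf_aa: int = 0

    def __post_init__(self) -> None:
        if len(self.ltr_spans) > 2:
            raise ValueError(f"{self.id}: more than 2 LTR spans")
        for dom, span in self.domain_spans.items():
            if span is not None and span[1] <= span[0]:
                raise ValueError(f"{self.id}: empty {dom} span")


def classify_erv_structure(c: ERVCandidate, min_orf_aa: int = 1500) -> dict[str, bool]:
    """Cumulative structural flags for an ERV candidate.

    ``full`` requires two LTRs plus gag, pol and env; ``putatively_active``
    additionally requires a long intact ORF (default >= 1500 aa, matching
    the scale of replication-competent proviruses).
    """
    has = {dom: c.domain_spans.get(dom) is not None for dom in ("RT", "gag", "pol", "env")}
    full = len(c.ltr_spans) == 2 and has["gag"] and has["pol"] and has["env"]
    return {
        "has_RT": has["RT"],
        "has_gag": has["gag"],
        "has_pol": has["pol"],
        "has_env": has["env"],
        "full": full,
        "putatively_active": full and c.longest_orf_aa >= min_orf_aa,
    }


# ---------------------------------------------------------------------------
# Reference RT panel (synthetic stand-in, packaged)
# ---------------------------------------------------------------------------

def load_rt_panel() -> tuple[dict[str, str], dict[str, str]]:
    """Load the packaged retroviral RT reference panel.

    Returns (sequences, classes) where classes maps each reference name to
    its retroviral class (I/gamma, II/beta, III/spuma).  The packaged panel
    is a synthetic stand-in generated under a seeded divergence model (see
    the file header); names follow the conventional exogenous/endogenous
    reference set used for ERV classification.
    """
    from importlib.resources import files

    from mobiloscope.formats_io import read_fasta, read_fasta_descriptions

    path = files("mobiloscope.data").joinpath("synthetic_rt_panel.fasta")
    seqs = read_fasta(str(path))
    descs = read_fasta_descriptions(str(path))
    classes = {}
    for name, desc in descs.items():
        for token in desc.split():
            if token.startswith("class="):
                classes[name] = token.split("=", 1)[1]
    return seqs, classes


def classify_erv_class(
    query: str,
    panel: Optional[tuple[dict[str, str], dict[str, str]]] = None,
) -> str:
    """Assign a retroviral class to an RT-region query sequence.

    The query is globally aligned to every panel reference; the class of
    the nearest reference under the K2P distance wins (nearest-reference
    approximation of nearest-clade placement).
    """
    from mobiloscope.subfamily import _make_aligner

    seqs, classes = panel if panel is not None else load_rt_panel()
    aligner = _make_aligner()
    best: Optional[tuple[float, str]] = None
    for name in sorted(seqs):
        aln = aligner.align(query, seqs[name])[0]
        try:
            dist = k2p_distance(str(aln[0]), str(aln[1]))
        except SaturationError:
            continue
        if best is None or dist < best[0] - 1e-15:
            best = (dist, classes.get(name, "unknown"))
    if best is None:
        raise SaturationError("query saturated against every panel reference")
    return best[1]
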