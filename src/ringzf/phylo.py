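"""Redundancy clustering and neighbor-joining trees with bootstrap support.

``cluster_redundant`` is a greedy incremental identity clustering in the
style of CD-HIT: sequences are taken in decreasing length order and join
the first representative whose global pairwise identity (matched alignment
columns over the shorter sequence length) exceeds the cutoff.

``neighbor_joining`` implements the Saitou-Nei agglomeration with the
standard Q criterion and branch-length formulas; ties on the minimal Q are
broken by the smallest (i, j) index pair and negative branch-length
estimates are clamped to zero (recorded on the tree).  Bootstrap support
is the percentage of column-resampled replicate trees containing each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib
import numpy as np

from .io import ProteinRecord

GAP = "-"


# ---------------------------------------------------------------------------
# Greedy identity clustering

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matched columns / shorter length."""
    if not a or not b:
        raise ValueError("empty sequence")
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    matches = nice["matched_aligned"].count("|")
    return matches / min(len(a), len(b))


def cluster_redundant(
    seqs: Sequence[ProteinRecord], identity_cutoff: float = 0.95
):
    """Greedy representative selection at the given identity cutoff.

    Returns ``(representatives, cluster_map)`` where ``cluster_map`` sends
    every input id to its representative's id.  Deterministic: input is
    processed by decreasing length, ties by id.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    ordered = sorted(seqs, key=lambda r: (-len(r.sequence), r.id))
    reps: list = []
    cluster_map: dict = {}
    for rec in ordered:
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) > identity_cutoff:
                cluster_map[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            cluster_map[rec.id] = rec.id
    return reps, cluster_map


# ---------------------------------------------------------------------------
# Alignments and p-distances

@dataclass(frozen=True)
class DomainAlignment:
    """Equal-length aligned rows over the amino-acid alphabet plus '-'."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "DomainAlignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return DomainAlignment(self.ids, rows)


def p_distance_matrix(aln: DomainAlignment) -> np.ndarray:
    """Pairwise mismatch proportions over columns where neither row gaps."""
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            compared = mismatches = 0
            for x, y in zip(a, b):
                if x == GAP or y == GAP:
                    continue
                compared += 1
                if x != y:
                    mismatches += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            d[i, j] = d[j, i] = mismatches / compared
    return d


# ---------------------------------------------------------------------------
# Trees

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch length)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> frozenset:
        if self.is_leaf:
            return frozenset([self.name])
        out: set = set()
        for child, _ in self.children:
            out |= child.leaf_names()
        return frozenset(out)


@dataclass
class Tree:
    """An unrooted tree held at an arbitrary (trifurcating) root.

    ``supports`` maps canonical bipartitions to percentages in [0, 100];
    ``clamped`` records whether any negative NJ branch length was clipped.
    """

    root: TreeNode
    clamped: bool = False
    supports: dict = field(default_factory=dict)

    @property
    def leaf_names(self) -> frozenset:
        return self.root.leaf_names()

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.leaf_names)
        return side if ref not in side else self.leaf_names - side

    def bipartitions(self) -> frozenset:
        """Canonical nontrivial bipartitions (side not holding the
        lexicographically smallest leaf)."""
        n = len(self.leaf_names)
        out: set = set()

        def walk(node: TreeNode):
            names = node.leaf_names()
            if 2 <= len(names) <= n - 2:
                out.add(self._canonical(names))
            for child, _ in node.children:
                walk(child)

        for child, _ in self.root.children:
            walk(child)
        return frozenset(out)

    def to_newick(self, with_supports: bool = False, digits: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(c)}:{bl:.{digits}f}" for c, bl in node.children
            )
            label = ""
            if with_supports and self.supports:
                names = node.leaf_names()
                key = self._canonical(names)
                if key in self.supports:
                    label = f"{self.supports[key]:g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> dict:
        """Patristic distances between all leaf pairs."""
        dists: dict = {}

        def walk(node: TreeNode) -> dict:
            # returns leaf -> distance to this node
            if node.is_leaf:
                return {node.name: 0.0}
            sub = []
            for child, bl in node.children:
                cd = walk(child)
                sub.append({k: v + bl for k, v in cd.items()})
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for la, da in sub[i].items():
                        for lb, db in sub[j].items():
                            dists[frozenset((la, lb))] = da + db
            merged: dict = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return dists


def neighbor_joining(d: np.ndarray, ids: Sequence[str]) -> Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Requires n >= 3.  Ties on the minimal Q value are broken by the
    smallest (i, j) pair in the current node ordering, making the result
    deterministic; negative branch lengths are clamped to 0 and flagged.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(ids):
        raise ValueError("distance matrix and ids mismatch")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.abs(d - d.T).max() > 1e-9:
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix has a nonzero diagonal")

    nodes = [TreeNode(name=i) for i in ids]
    D = d.copy()
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(D[i, j] - (D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                newD[a, b] = D[ka, kb]
        for a, ka in enumerate(keep):
            du = (D[i, ka] + D[j, ka] - D[i, j]) / 2.0
            newD[a, m - 2] = newD[m - 2, a] = du
        nodes = [nodes[k] for k in keep] + [new]
        D = newD

    (a, b, c) = nodes
    la = clamp((D[0, 1] + D[0, 2] - D[1, 2]) / 2.0)
    lb = clamp((D[0, 1] + D[1, 2] - D[0, 2]) / 2.0)
    lc = clamp((D[0, 2] + D[1, 2] - D[0, 1]) / 2.0)
    root = TreeNode(children=[(a, la), (b, lb), (c, lc)])
    return Tree(root=root, clamped=clamped)


def nj_tree_from_alignment(aln: DomainAlignment) -> Tree:
    return neighbor_joining(p_distance_matrix(aln), aln.ids)


def bootstrap_support(
    aln: DomainAlignment, n_reps: int = 1000, seed: int = 0
) -> Tree:
    """NJ tree of the full alignment with bootstrap supports in [0, 100].

    Columns are resampled with replacement per replicate; support for each
    internal bipartition of the full-data tree is the percentage of
    replicate trees containing it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree_from_alignment(aln)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_bps = nj_tree_from_alignment(rep).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    tree.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# Random additive trees (simulation inputs)

def random_tree(n_leaves: int, seed: int = 0,
                min_bl: float = 0.05, max_bl: float = 1.0) -> Tree:
    """A random unrooted binary tree with uniform branch lengths.

    Built by inserting leaves on uniformly chosen edges; leaf names are
    ``t1 .. tN``.  Its patristic distance matrix is additive by
    construction, so NJ must recover it exactly.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.uniform(min_bl, max_bl))

    # start with a 3-leaf star
    root = TreeNode(children=[(TreeNode(name=f"t{i}"), bl()) for i in (1, 2, 3)])
    # edge list as (parent, child index)
    for leaf_no in range(4, n_leaves + 1):
        edges = []

        def collect(node: TreeNode):
            for idx, (child, _) in enumerate(node.children):
                edges.append((node, idx))
                collect(child)

        collect(root)
        parent, idx = edges[int(rng.integers(len(edges)))]
        child, old_bl = parent.children[idx]
        split = float(rng.uniform(0.25, 0.75)) * old_bl
        mid = TreeNode(children=[(child, old_bl - split),
                                 (TreeNode(name=f"t{leaf_no}"), bl())])
        parent.children[idx] = (mid, split)
    return Tree(root=root)


def tree_distance_matrix(tree: Tree):
    """(ids, matrix) of patristic distances for *tree*'s leaves."""
    ids = sorted(tree.leaf_names)
    dd = tree.leaf_distances()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dd[frozenset((ids[i], ids[j]))]
    return ids, d
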