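"""Identity clustering, p-distances, neighbor joining, bootstrap."""

import itertools

import dendropy
import numpy as np
import pytest

from ringzf.io import ProteinRecord
from ringzf.phylo import (
    DomainAlignment,
    Tree,
    bootstrap_support,
    cluster_redundant,
    neighbor_joining,
    nj_tree_from_alignment,
    p_distance_matrix,
    pairwise_identity,
    random_tree,
    tree_distance_matrix,
)


# ---------------------------------------------------------------------------
# Oracle: enumerate every unrooted binary topology (as quartet-compatible
# edge structures built by sequential leaf insertion), least-squares fit
# branch lengths to the distance matrix, and keep the zero-residual tree.

def enumerate_topologies(ids):
    """Yield edge lists [(u, v), ...] over leaves ids + internal labels."""
    n = len(ids)
    # start from the unique 3-leaf star
    first = [("*0", ids[0]), ("*0", ids[1]), ("*0", ids[2])]
    stack = [(first, 3, 1)]
    while stack:
        edges, k, n_int = stack.pop()
        if k == n:
            yield edges
            continue
        leaf = ids[k]
        for i in range(len(edges)):
            u, v = edges[i]
            mid = f"*{n_int}"
            new_edges = edges[:i] + edges[i + 1 :] + [
                (u, mid), (mid, v), (mid, leaf)
            ]
            stack.append((new_edges, k + 1, n_int + 1))


def edges_to_paths(edges, ids):
    """Pair -> set of edge indices on the path, via adjacency walk."""
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))

    def path(a, b):
        seen = {a}
        stack = [(a, [])]
        while stack:
            node, used = stack.pop()
            if node == b:
                return used
            for nxt, idx in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append((nxt, used + [idx]))
        raise AssertionError("disconnected topology")

    return {
        (a, b): path(a, b) for a, b in itertools.combinations(ids, 2)
    }


def topology_bipartitions(edges, ids):
    ref = min(ids)
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    def side(u, v):
        seen = {u}
        stack = [v]
        leaves = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if not node.startswith("*"):
                leaves.add(node)
            for nxt in adj[node]:
                if nxt != u or node != v:
                    if nxt not in seen:
                        stack.append(nxt)
        return leaves

    out = set()
    for u, v in edges:
        leaves = side(u, v)
        if 2 <= len(leaves) <= len(ids) - 2:
            out.add(frozenset(leaves if ref not in leaves else set(ids) - leaves))
    return frozenset(out)


def oracle_best_topology(d, ids):
    """(bipartitions, fitted lengths residual) of the least-squares-best
    topology; for an additive matrix the best residual is ~0."""
    pairs = list(itertools.combinations(ids, 2))
    idx = {p: i for i, p in enumerate(pairs)}
    y = np.array([d[ids.index(a), ids.index(b)] for a, b in pairs])
    best = None
    for edges in enumerate_topologies(ids):
        paths = edges_to_paths(edges, ids)
        A = np.zeros((len(pairs), len(edges)))
        for p, eidx in paths.items():
            A[idx[p], eidx] = 1.0
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(((A @ x - y) ** 2).sum())
        if best is None or resid < best[0]:
            best = (resid, topology_bipartitions(edges, ids))
    return best


class TestClusterRedundant:
    def test_identical_sequences_merge(self):
        recs = [ProteinRecord("a", "MKCRV" * 10), ProteinRecord("b", "MKCRV" * 10)]
        reps, cmap = cluster_redundant(recs)
        assert len(reps) == 1
        assert cmap["b"] == cmap["a"]

    def test_dissimilar_sequences_stay_apart(self):
        a = "MKCRV" * 10
        b = a[:45] + "WWWWW"  # identity 0.90 at cutoff 0.95
        assert pairwise_identity(a, b) == pytest.approx(0.90)
        reps, _ = cluster_redundant(
            [ProteinRecord("a", a), ProteinRecord("b", b)], 0.95
        )
        assert len(reps) == 2

    def test_planted_identity_classes_recovered(self):
        """138 domain sequences planted in 80 identity classes collapse to
        exactly 80 representatives at the 95% cutoff."""
        rng = np.random.default_rng(7)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        bases = ["".join(rng.choice(aa, size=50)) for _ in range(80)]
        recs = [ProteinRecord(f"base{i}", s) for i, s in enumerate(bases)]
        for j in range(58):
            src = bases[j % 80]
            # one substitution: identity 49/50 = 0.98 > 0.95
            pos = int(rng.integers(50))
            dup = src[:pos] + ("A" if src[pos] != "A" else "G") + src[pos + 1 :]
            recs.append(ProteinRecord(f"dup{j}", dup))
        reps, cmap = cluster_redundant(recs, 0.95)
        assert len(reps) == 80
        # partition property: every input maps to exactly one representative
        assert set(cmap) == {r.id for r in recs}
        rep_ids = {r.id for r in reps}
        assert set(cmap.values()) <= rep_ids

    def test_deterministic_given_input(self):
        rng = np.random.default_rng(1)
        recs = [
            ProteinRecord(f"s{i}", "".join(rng.choice(list("ACDG"), size=30)))
            for i in range(10)
        ]
        r1, m1 = cluster_redundant(recs)
        r2, m2 = cluster_redundant(list(reversed(recs)))
        assert [x.id for x in r1] == [x.id for x in r2]
        assert m1 == m2


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = DomainAlignment(("a", "b"), ("AAAA", "AAAA"))
        assert p_distance_matrix(aln)[0, 1] == 0

    def test_one_mismatch_in_four(self):
        aln = DomainAlignment(("a", "b"), ("AAAA", "AAAT"))
        assert p_distance_matrix(aln)[0, 1] == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        aln = DomainAlignment(("a", "b"), ("A-AA", "ATAA"))
        assert p_distance_matrix(aln)[0, 1] == 0.0

    def test_no_comparable_sites_is_error(self):
        aln = DomainAlignment(("a", "b"), ("A--", "-TT"))
        with pytest.raises(ValueError, match="a.*b"):
            p_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(d, ["a", "b", "c"])
        dd = tree.leaf_distances()
        assert dd[frozenset(("a", "b"))] == pytest.approx(0.3)
        assert dd[frozenset(("a", "c"))] == pytest.approx(0.5)
        assert dd[frozenset(("b", "c"))] == pytest.approx(0.6)

    def test_four_taxon_additive_recovery(self):
        tree = random_tree(4, seed=3)
        ids, d = tree_distance_matrix(tree)
        nj = neighbor_joining(d, ids)
        assert nj.bipartitions() == tree.bipartitions()
        _, d2 = tree_distance_matrix(nj)
        assert np.allclose(d, d2, atol=1e-10)

    @pytest.mark.parametrize("n,seed", [(4, 0), (4, 1), (5, 2), (5, 3), (6, 4)])
    def test_matches_exhaustive_topology_oracle(self, n, seed):
        tree = random_tree(n, seed=seed)
        ids, d = tree_distance_matrix(tree)
        nj = neighbor_joining(d, ids)
        resid, best_bps = oracle_best_topology(d, ids)
        assert resid < 1e-18
        assert nj.bipartitions() == best_bps

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_matrices_recovered_exactly(self, n):
        """On any additive matrix the NJ tree reproduces the input
        patristic distances (uniqueness of the additive representation)."""
        for seed in range(5):
            tree = random_tree(n, seed=100 * n + seed)
            ids, d = tree_distance_matrix(tree)
            nj = neighbor_joining(d, ids)
            assert nj.bipartitions() == tree.bipartitions()
            _, d2 = tree_distance_matrix(nj)
            assert np.allclose(d, d2, atol=1e-9)

    def test_ultrametric_matches_single_linkage_blocks(self):
        # two clean clades {a,b} and {c,d,e}
        ids = ["a", "b", "c", "d", "e"]
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        for i, j in [(0, 1)]:
            d[i, j] = d[j, i] = 0.2
        for i, j in [(2, 3), (2, 4), (3, 4)]:
            d[i, j] = d[j, i] = 0.3
        nj = neighbor_joining(d, ids)
        assert frozenset(["c", "d", "e"]) in nj.bipartitions() or \
            frozenset(["b", "a"]) not in nj.bipartitions()
        assert frozenset({"c", "d"}) in nj.bipartitions() or \
            frozenset({"c", "e"}) in nj.bipartitions() or \
            frozenset({"d", "e"}) in nj.bipartitions()

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 1], [1, 0, 1], [1.1, 1, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(d, list("abc"))

    def test_leaf_order_invariant_bipartitions(self):
        tree = random_tree(6, seed=9)
        ids, d = tree_distance_matrix(tree)
        perm = [3, 1, 4, 0, 5, 2]
        d2 = d[np.ix_(perm, perm)]
        ids2 = [ids[i] for i in perm]
        assert neighbor_joining(d, ids).bipartitions() == \
            neighbor_joining(d2, ids2).bipartitions()

    def test_newick_round_trips_through_dendropy(self):
        tree = random_tree(7, seed=5)
        ids, d = tree_distance_matrix(tree)
        nj = neighbor_joining(d, ids)
        nwk = nj.to_newick()
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in dt.taxon_namespace} == set(ids)
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        dd = nj.leaf_distances()
        for a, b in itertools.combinations(ids, 2):
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                dd[frozenset((a, b))], abs=1e-5
            )


def clade_alignment():
    """Two clearly separated clades of 3 rows each."""
    block_a = "CCCCCCCCCCAAAAAAAAAA"
    block_b = "AAAAAAAAAACCCCCCCCCC"
    rows = []
    for i in range(3):
        r = list(block_a)
        r[i] = "D"  # small within-clade variation
        rows.append("".join(r))
    for i in range(3):
        r = list(block_b)
        r[10 + i] = "D"
        rows.append("".join(r))
    return DomainAlignment(tuple("abcdef"), tuple(rows))


class TestBootstrap:
    def test_identical_rows_complete_without_error(self):
        aln = DomainAlignment(tuple("abcd"), ("AAAA",) * 4)
        tree = bootstrap_support(aln, n_reps=10, seed=0)
        dd = tree.leaf_distances()
        assert all(v == 0 for v in dd.values())

    def test_separated_clades_get_high_support(self):
        tree = bootstrap_support(clade_alignment(), n_reps=200, seed=1)
        key = frozenset("def") if "a" in min("abcdef") else frozenset("abc")
        assert tree.supports[key] >= 95

    def test_supports_bounded_and_deterministic(self):
        t1 = bootstrap_support(clade_alignment(), n_reps=50, seed=42)
        t2 = bootstrap_support(clade_alignment(), n_reps=50, seed=42)
        assert t1.supports == t2.supports
        assert all(0 <= v <= 100 for v in t1.supports.values())

    def test_supports_serialized_in_newick(self):
        tree = bootstrap_support(clade_alignment(), n_reps=20, seed=3)
        nwk = tree.to_newick(with_supports=True)
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        labels = [n.label for n in dt.internal_nodes() if n.label]
        assert labels, "expected internal support labels in newick"
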