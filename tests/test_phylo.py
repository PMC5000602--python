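import numpy as np
import pytest

from tcskit.errors import ValidationError
from tcskit.phylo import DistanceMatrix, Msa, bootstrap_support, nj_tree, p_distance_matrix

# ---------------------------------------------------------------------------
# oracle: random additive trees and their path-length matrices


def random_additive_tree(n_taxa, rng):
    """Random binary tree as (children adjacency, root) with uniform branch
    lengths; returns (ids, distance matrix) of its leaf path metric."""
    nodes = {i: None for i in range(n_taxa)}  # node -> (child, child) or None
    lengths = {}
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        nodes[nxt] = (a, b)
        lengths[a] = float(rng.uniform(0.1, 2.0))
        lengths[b] = float(rng.uniform(0.1, 2.0))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]

    # leaf-to-root paths -> pairwise distances
    def paths(node, acc, out):
        if nodes[node] is None:
            out[node] = acc
            return
        for c in nodes[node]:
            paths(c, acc + [(c, lengths[c])], out)

    out = {}
    paths(root, [], out)
    ids = tuple(f"t{i}" for i in range(n_taxa))
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            ei = {e for e, _ in out[i]}
            ej = {e for e, _ in out[j]}
            shared = ei & ej
            dist = sum(l for e, l in out[i] if e not in shared) + sum(
                l for e, l in out[j] if e not in shared
            )
            d[i, j] = d[j, i] = dist
    return ids, d


def tree_path_metric(tree):
    """Pairwise leaf distances of a TreeNode, by traversal."""
    dists = {}

    def walk(node, acc):
        if node.is_leaf:
            dists[node.label] = acc
            return
        for c in node.children:
            walk(c, acc + [(id(c), c.length or 0.0)])

    walk(tree, [])
    ids = sorted(dists)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ei = {e for e, _ in dists[ids[i]]}
            ej = {e for e, _ in dists[ids[j]]}
            shared = ei & ej
            d[i, j] = d[j, i] = sum(
                l for e, l in dists[ids[i]] if e not in shared
            ) + sum(l for e, l in dists[ids[j]] if e not in shared)
    return ids, d


# ---------------------------------------------------------------------------
# p-distance


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(Msa(("a", "b"), ("ACDE", "ACDE")))
        assert dm.d[0, 1] == 0.0

    def test_direct_count(self):
        dm = p_distance_matrix(Msa(("a", "b"), ("AAAA", "AATT")))
        assert dm.d[0, 1] == 0.5

    def test_pairwise_deletion_drops_gap_columns(self):
        dm = p_distance_matrix(Msa(("a", "b"), ("A-CD", "AACD")))
        assert dm.d[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValidationError, match="a .*and b|a and b"):
            p_distance_matrix(Msa(("a", "b"), ("A--", "-AA")))


# ---------------------------------------------------------------------------
# neighbor joining


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {l.label: l.length for l in tree.leaves()}
        # la = (dAB + dAC - dBC)/2 etc.
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})
        assert sum(lengths.values()) == pytest.approx((3 + 4 + 5) / 2)

    def test_four_taxon_worked_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        lengths = {l.label: l.length for l in tree.leaves()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        internal = [c for c in tree.children if not c.is_leaf][0]
        assert internal.length == pytest.approx(1.0)

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(12)
        ids, d = random_additive_tree(6, rng)
        base = nj_tree(DistanceMatrix(ids, d)).bipartitions()
        perm = rng.permutation(6)
        got = nj_tree(
            DistanceMatrix(tuple(ids[i] for i in perm), d[np.ix_(perm, perm)])
        ).bipartitions()
        assert got == base

    def test_additive_recovery_100_random_trees(self):
        """NJ must reproduce the generating tree metric to 1e-9 on additive
        inputs of 5-10 taxa."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(5, 11))
            ids, d = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(ids, d))
            got_ids, got_d = tree_path_metric(tree)
            assert tuple(got_ids) == tuple(sorted(ids))
            order = [got_ids.index(i) for i in sorted(ids)]
            src = [list(ids).index(i) for i in sorted(ids)]
            assert np.allclose(got_d, d[np.ix_(src, src)], atol=1e-9)

    def test_matches_scikit_bio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(31)
        ids, d = random_additive_tree(7, rng)
        ours = nj_tree(DistanceMatrix(ids, d)).bipartitions()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
        theirs = set()
        for node in sk_tree.non_tips():
            below = frozenset(t.name for t in node.tips())
            rest = frozenset(ids) - below
            if 1 < len(below) < len(ids) - 1:
                theirs.add(min(below, rest, key=lambda s: (len(s), sorted(s))))
        assert ours == theirs

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], float)))


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    CLEAN = Msa(("A", "B", "C", "D"), ("AAAAAAAA", "AAAAAAAA", "TTTTTTTT", "TTTTTTTT"))

    def test_clean_two_clade_alignment_all_supports_100(self):
        tree = bootstrap_support(self.CLEAN, reps=50, seed=1)
        supports = [
            n.support
            for n in tree.children
            if not n.is_leaf and n.support is not None
        ]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self):
        msa = Msa(
            ("A", "B", "C", "D"),
            ("ACGTACGTAA", "ACGTACGTTT", "TGCATGCAAA", "TGCATGCATT"),
        )
        tree = bootstrap_support(msa, reps=1, seed=5)

        def all_supports(node):
            out = []
            for c in node.children:
                if not c.is_leaf:
                    if c.support is not None:
                        out.append(c.support)
                    out += all_supports(c)
            return out

        assert set(all_supports(tree)) <= {0.0, 100.0}

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(self.CLEAN, reps=20, seed=7)
        t2 = bootstrap_support(self.CLEAN, reps=20, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_reps_below_one_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_support(self.CLEAN, reps=0, seed=1)
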