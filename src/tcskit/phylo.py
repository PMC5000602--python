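"""Distance phylogenetics: p-distances, neighbor-joining, bootstrap.

The tree builder is the Saitou-Nei neighbor-joining algorithm with the
standard Q-criterion and branch-length formulas; on additive distance
matrices it recovers the generating unrooted topology and branch lengths
exactly.  Ties in the Q-criterion break deterministically on the lowest
index pair, and negative branch lengths are clamped to zero with the
deficit moved to the sister edge, so near-degenerate matrices yield
reproducible trees.  Bootstrap support resamples alignment columns with
replacement and counts bipartition recovery over replicates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .seqio import read_fasta

_NEWICK_META = re.compile(r"[\s(),:;'\[\]]")


@dataclass
class TreeNode:
    """A node in a phylogeny; ``length`` is the edge above the node."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def _node_newick(self) -> str:
        if self.is_leaf:
            name = self.label or ""
            if _NEWICK_META.search(name):
                name = "'" + name.replace("'", "''") + "'"
            part = name
        else:
            part = "(" + ",".join(c._node_newick() for c in self.children) + ")"
            if self.support is not None:
                part += f"{self.support:g}"
        if self.length is not None:
            part += f":{self.length:g}"
        return part

    def to_newick(self) -> str:
        return self._node_newick() + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted tree, each as the smaller-or-
        canonical leaf set under an internal edge."""
        all_leaves = frozenset(self.leaf_names())
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                other = all_leaves - below
                splits.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self)
        return splits


@dataclass(frozen=True)
class Msa:
    """A multiple alignment: equal-length gapped rows keyed by unique IDs."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate IDs in alignment")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows differ in length")

    @property
    def ncol(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Msa":
        recs = read_fasta(path)
        return cls(tuple(r.id for r in recs), tuple(r.seq for r in recs))

    def resample_columns(self, rng: np.random.Generator) -> "Msa":
        cols = rng.integers(0, self.ncol, size=self.ncol)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Msa(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        object.__setattr__(self, "d", d)


def p_distance_matrix(msa: Msa, gap_mode: str = "pairwise_delete") -> DistanceMatrix:
    """Proportion-of-differences distances with pairwise gap deletion."""
    if gap_mode != "pairwise_delete":
        raise ValidationError(f"unsupported gap mode {gap_mode!r}")
    n = len(msa.ids)
    if n < 2:
        raise ValidationError("need at least two sequences")
    arr = np.array([list(r) for r in msa.rows])
    gap = (arr == "-") | (arr == ".")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gap[i] | gap[j])
            m = int(usable.sum())
            if m == 0:
                raise ValidationError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            d[i, j] = d[j, i] = float((arr[i, usable] != arr[j, usable]).sum()) / m
    return DistanceMatrix(msa.ids, d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Returns a tree rooted at the final three-way join (the conventional
    unrooted NJ topology).  Exact on additive matrices.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=i) for i in dm.ids]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = li, lj
        new = TreeNode(children=[ni, nj_])
        # distances from the new node (standard reduction)
        new_idx = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_idx]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for node, l in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = max(l, 0.0)
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def bootstrap_support(msa: Msa, reps: int = 1000, seed: int = 0) -> TreeNode:
    """NJ tree from the full alignment with column-bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    the NJ tree, and scores which original bipartitions it recovers;
    supports are percentages on the internal edges of the original tree.
    """
    if reps < 1:
        raise ValidationError("bootstrap requires at least 1 replicate")
    tree = nj_tree(p_distance_matrix(msa))
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        rep = msa.resample_columns(rng)
        rep_splits = nj_tree(p_distance_matrix(rep)).bipartitions()
        for split in target:
            if split in rep_splits:
                counts[split] += 1

    def annotate(node: TreeNode, root: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset().union(*(annotate(c, root) for c in node.children))
        if node is not root:
            all_leaves = frozenset(root.leaf_names())
            if 1 < len(below) < len(all_leaves) - 1:
                canon = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
                node.support = 100.0 * counts[canon] / reps
        return below

    annotate(tree, tree)
    return tree
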