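"""Neighbor-joining trees with column-resampling bootstrap.

Distance trees over haplotype sets: the classic Saitou-Nei
neighbor-joining agglomeration on a p-distance matrix, with
deterministic tie-breaking (lowest label-index pair), negative branch
lengths clamped to zero with the deficit moved to the sibling edge, and
non-parametric bootstrap supports obtained by resampling alignment
columns with replacement and counting how often each original internal
split recurs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .divstats import p_distance

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "pdistance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "attach_supports",
    "write_newick",
    "to_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError("matrix shape must match number of labels")
        if np.any(vals < 0):
            raise ValueError("distances must be non-negative")
        if np.any(np.diagonal(vals) != 0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TreeNode:
    """A node of an unrooted tree, stored with an arbitrary root."""

    label: str | None = None
    length: float = 0.0  # branch to parent, substitutions/site
    support: float | None = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]


@dataclass
class PhyloTree:
    """An unrooted tree over labelled taxa."""

    root: TreeNode
    labels: tuple[str, ...]

    def splits(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial bipartitions, keyed by the side not containing
        the first taxon (a label-order-independent normal form)."""
        all_taxa = set(self.labels)
        anchor = self.labels[0]
        result: dict[frozenset[str], TreeNode] = {}

        def visit(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for child in node.children:
                below |= visit(child)
            if node is not self.root and 1 < len(below) < len(all_taxa) - 1:
                side = below if anchor not in below else all_taxa - below
                result[frozenset(side)] = node
            return below

        visit(self.root)
        return result

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Patristic (path-length) distances between all leaf pairs."""
        dists: dict[tuple[str, str], float] = {}

        def visit(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, 0.0)]
            per_child = []
            for child in node.children:
                per_child.append(
                    [(lab, d + child.length) for lab, d in visit(child)]
                )
            for a_list, b_list in itertools.combinations(per_child, 2):
                for la, da in a_list:
                    for lb, db in b_list:
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
            return [pair for lst in per_child for pair in lst]

        visit(self.root)
        return dists


def pdistance_matrix(
    sequences: Mapping[str, str], aligned: bool = False
) -> DistanceMatrix:
    """All-pairs p-distance matrix for a set of sequences."""
    labels = tuple(sequences)
    n = len(labels)
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = p_distance(
            sequences[labels[i]], sequences[labels[j]], pairwise_aligned=aligned
        )
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals)


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei neighbor joining.

    Q-matrix minimization with ties broken on the lowest (i, j) index
    pair; final three nodes resolved by the closed-form three-point
    equations. Negative branch lengths are clamped to zero and the
    deficit is moved to the sibling edge.
    """
    n = len(d)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]
    dist = d.values.astype(float).copy()
    active = list(range(n))

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        # move any negative deficit to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dist[i][j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[i][j] - sums[i] - sums[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * dist[i][j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dist[i][j] - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # new node reuses slot i
        for k in active:
            if k in (i, j):
                continue
            dist[i][k] = dist[k][i] = 0.5 * (
                dist[i][k] + dist[j][k] - dist[i][j]
            )
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point closed form
    li = 0.5 * (dist[i][j] + dist[i][k] - dist[j][k])
    lj = 0.5 * (dist[i][j] + dist[j][k] - dist[i][k])
    lk = 0.5 * (dist[i][k] + dist[j][k] - dist[i][j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root, labels=d.labels)


def bootstrap_supports(
    sequences: Mapping[str, str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap supports for the NJ tree's splits.

    Sequences must be aligned (equal length). Returns, for every
    internal split of the tree built from the original alignment, the
    percentage of replicate NJ trees containing that split.
    """
    labels = tuple(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires aligned, equal-length sequences")
    (length,) = lengths
    matrix = np.array(
        [np.frombuffer(sequences[lab].encode(), dtype="S1") for lab in labels]
    )

    def replicate_tree(cols: np.ndarray):
        sub = matrix[:, cols]
        n = len(labels)
        vals = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = sub[i], sub[j]
            keep = (a != b"-") & (b != b"-")
            compared = int(keep.sum())
            vals[i, j] = vals[j, i] = (
                float((a[keep] != b[keep]).sum()) / compared if compared else 0.0
            )
        return nj_tree(DistanceMatrix(labels, vals))

    def tree_splits(cols: np.ndarray) -> set[frozenset[str]]:
        return set(replicate_tree(cols).splits())

    # splits sitting on zero-length internal edges are unresolved, not
    # supported structure; they get no support entry
    original = {
        split
        for split, node in replicate_tree(np.arange(length)).splits().items()
        if node.length > 1e-12
    }
    counts = {split: 0 for split in original}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        for split in tree_splits(cols):
            if split in counts:
                counts[split] += 1
    return {
        split: 100.0 * c / n_replicates for split, c in counts.items()
    }


def attach_supports(
    tree: PhyloTree, supports: Mapping[frozenset[str], float]
) -> PhyloTree:
    """Write bootstrap percentages onto the matching internal nodes."""
    for split, node in tree.splits().items():
        if split in supports:
            node.support = supports[split]
    return tree


_NEWICK_RESERVED = set("();,:[]' \t\n")


def _quote(label: str) -> str:
    if set(label) & _NEWICK_RESERVED:
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree) -> str:
    """Standard newick with branch lengths and integer supports as
    internal node labels."""

    def render(node: TreeNode, with_length: bool) -> str:
        if node.is_leaf:
            body = _quote(node.label or "")
        else:
            inner = ",".join(render(c, True) for c in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            body = f"({inner}){label}"
        return f"{body}:{node.length:.9g}" if with_length else body

    return render(tree.root, False) + ";"


def write_newick(tree: PhyloTree, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(to_newick(tree) + "\n")
    return path
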