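"""Divisive binary tree construction and reduced-error pruning.

The full sample set is recursively bisected by spectral splits until
every branch terminates, giving a binary tree whose leaves are the
finest clusters.  Pruning then repeatedly collapses the internal node
with the lowest *quality* — the sum of squared similarities between
samples lying in different leaves of its subtree — recomputing
qualities after every collapse.  Each collapse yields one partition, so
a single run produces the whole nested sequence from the unpruned tree
down to a single cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import bisect

__all__ = [
    "TreeNode",
    "Partition",
    "build_tree",
    "node_ss",
    "node_quality",
    "prune_sequence",
]


@dataclass
class TreeNode:
    """A node of the divisive tree: a set of sample indices plus children."""

    members: np.ndarray
    children: tuple["TreeNode", "TreeNode"] | None = None
    ss: float = 0.0  # within-node sum of squared similarities
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def size(self) -> int:
        return len(self.members)

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        left, right = self.children
        return left.leaves() + right.leaves()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        left, right = self.children
        return [self] + left.internal_nodes() + right.internal_nodes()


@dataclass
class Partition:
    """Assignment of every sample to exactly one cluster, labels 1..k."""

    labels: np.ndarray
    k: int = field(default=0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        k = len(uniq)
        if not np.array_equal(uniq, np.arange(1, k + 1)):
            raise ValueError("cluster labels must be contiguous 1..k")
        self.k = k

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def cluster_members(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.labels == c) for c in range(1, self.k + 1)]


def node_ss(members: np.ndarray, S: np.ndarray) -> float:
    """Sum of squared similarities over unordered distinct pairs of a node."""
    members = np.asarray(members)
    if len(members) < 2:
        return 0.0
    sub = S[np.ix_(members, members)]
    total = float(np.sum(sub * sub))
    diag = float(np.sum(np.diagonal(sub) ** 2))
    return 0.5 * (total - diag)


def node_quality(node: TreeNode, S: np.ndarray) -> float:
    """Quality of an internal node: its SS minus the SS of its current leaves.

    Algebraically identical to the sum of squared similarities over
    pairs whose members sit in different leaves of the node's subtree.
    """
    if node.is_leaf:
        raise ValueError("quality is defined for internal nodes only")
    return node.ss - sum(leaf.ss for leaf in node.leaves())


def build_tree(
    S: np.ndarray,
    rng: np.random.Generator,
    min_node_size: int = 3,
    *,
    gmm_restarts: int = 5,
    gmm_tol: float = 1e-6,
    gmm_max_iter: int = 200,
) -> TreeNode:
    """Recursively bisect all samples of a similarity matrix into a tree.

    The similarity matrix is computed once; every split works on the
    sliced submatrix of its node's members.  Member counts strictly
    decrease along any branch, so construction always terminates.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if n < 2:
        raise ValueError("tree building needs at least 2 samples")

    def grow(members: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(members=members, depth=depth, ss=node_ss(members, S))
        if len(members) >= 2:
            split = bisect(
                S[np.ix_(members, members)],
                rng,
                min_node_size,
                gmm_restarts=gmm_restarts,
                gmm_tol=gmm_tol,
                gmm_max_iter=gmm_max_iter,
            )
            if not split.terminal:
                left = members[split.labels == 0]
                right = members[split.labels == 1]
                node.children = (grow(left, depth + 1), grow(right, depth + 1))
        return node

    return grow(np.arange(n), depth=0)


def _partition_from_leaves(leaves: list[TreeNode], n: int) -> Partition:
    # label clusters 1..k in order of their smallest member index
    ordered = sorted(leaves, key=lambda leaf: int(leaf.members.min()))
    labels = np.empty(n, dtype=np.int64)
    for c, leaf in enumerate(ordered, start=1):
        labels[leaf.members] = c
    return Partition(labels)


def _clone(node: TreeNode) -> TreeNode:
    copy = TreeNode(members=node.members, ss=node.ss, depth=node.depth)
    if not node.is_leaf:
        left, right = node.children
        copy.children = (_clone(left), _clone(right))
    return copy


def prune_sequence(
    root: TreeNode, S: np.ndarray, *, fringe_only: bool = False
) -> list[Partition]:
    """Reduced-error pruning: the nested partition sequence of a tree.

    Returns partitions starting at the unpruned tree (k = number of
    leaves) and ending with the single-cluster partition.  At each step
    the internal node with the lowest quality is collapsed into a leaf;
    qualities are recomputed on the new topology before the next step.
    Ties go to the deepest node, then the smallest member index.  With
    ``fringe_only`` the candidates are restricted to parents of two
    leaves, which forces unit decrements of k.
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    work = _clone(root)
    partitions = [_partition_from_leaves(work.leaves(), n)]
    while not work.is_leaf:
        internal = work.internal_nodes()
        if fringe_only:
            candidates = [
                node
                for node in internal
                if node.children[0].is_leaf and node.children[1].is_leaf
            ]
        else:
            candidates = internal
        best = min(
            candidates,
            key=lambda node: (
                node_quality(node, S),
                -node.depth,
                int(node.members.min()),
            ),
        )
        best.children = None  # collapse the whole subtree into a leaf
        partitions.append(_partition_from_leaves(work.leaves(), n))
    return partitions
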