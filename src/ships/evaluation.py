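"""Clustering agreement: contingency tables and the adjusted Rand index."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tree import Partition

__all__ = ["ContingencyTable", "contingency", "adjusted_rand_index"]


@dataclass
class ContingencyTable:
    """Cross-tabulation n_ij of two clusterings of the same samples."""

    counts: np.ndarray  # (R, C) integer grid
    row_sums: np.ndarray  # a_i
    col_sums: np.ndarray  # b_j
    total: int  # N

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.row_sums = np.asarray(self.row_sums, dtype=np.int64)
        self.col_sums = np.asarray(self.col_sums, dtype=np.int64)
        if self.counts.sum() != self.total:
            raise ValueError("contingency counts do not sum to the total")


def _as_labels(partition: Partition | np.ndarray) -> np.ndarray:
    if isinstance(partition, Partition):
        return partition.labels
    return np.asarray(partition)


def contingency(U: Partition | np.ndarray, V: Partition | np.ndarray) -> ContingencyTable:
    """Contingency table of two clusterings over identical samples."""
    u = _as_labels(U)
    v = _as_labels(V)
    if u.shape != v.shape:
        raise ValueError(
            f"clusterings cover different sample sets ({u.shape[0]} vs {v.shape[0]})"
        )
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    R, C = ui.max() + 1, vi.max() + 1
    counts = np.zeros((R, C), dtype=np.int64)
    np.add.at(counts, (ui, vi), 1)
    return ContingencyTable(
        counts=counts,
        row_sums=counts.sum(axis=1),
        col_sums=counts.sum(axis=0),
        total=int(len(u)),
    )


def _pairs(x: np.ndarray) -> np.ndarray:
    """Binomial coefficient C(x, 2), elementwise."""
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(U: Partition | np.ndarray, V: Partition | np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index between two clusterings.

    Computed from the contingency table as
    ``(sum_ij C(n_ij,2) - E) / (M - E)`` with
    ``E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(N,2)`` and
    ``M = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2``.

    When both clusterings put every sample in one cluster the index is
    formally 0/0; that structure is perfectly recovered, so 1 is
    returned by convention.
    """
    table = contingency(U, V)
    if table.counts.shape == (1, 1):
        return 1.0
    index = float(_pairs(table.counts).sum())
    sum_a = float(_pairs(table.row_sums).sum())
    sum_b = float(_pairs(table.col_sums).sum())
    expected = sum_a * sum_b / _pairs(np.array(table.total)).item()
    max_index = 0.5 * (sum_a + sum_b)
    denom = max_index - expected
    if denom == 0.0:
        # e.g. both clusterings all-singletons: perfect agreement
        return 1.0
    return (index - expected) / denom
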