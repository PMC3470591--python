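"""Cluster-number selection with a no-logarithm gap statistic.

For every realized cluster count k of the nested partition sequence,
the pooled within-cluster dispersion

    W_k = sum_r D_r / (2 n_r),   D_r = sum over ordered pairs (i, j)
                                        within cluster r of d_ij^2

(squared allele-sharing dissimilarities) is compared against its mean
over B reference datasets with i.i.d. genotypes uniform on {0, 1, 2} —
data with no population structure.  The dispersion itself, not its
logarithm, is used.  Each reference dataset is pushed through the same
similarity → tree → pruning pipeline as the observed data.  K is then
chosen with the Dudoit–Fridlyand rule: the smallest k whose gap is
within one simulation-error band of the next larger k's gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix
from .similarity import asd_similarity_values
from .tree import Partition, TreeNode, build_tree, prune_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GapTable",
    "within_dispersion",
    "simulate_null_matrix",
    "nested_partitions",
    "gap_curve",
    "select_k",
]


@dataclass
class GapTable:
    """Per-k gap statistic summary over the realized cluster counts."""

    ks: np.ndarray  # realized cluster counts, ascending, includes 1
    W: np.ndarray  # observed dispersion per k
    W_null: np.ndarray  # (B, len(ks)) null dispersions
    gap: np.ndarray  # mean_b W_null - W
    sd: np.ndarray  # per-k null standard deviation
    s: np.ndarray  # sd * sqrt(1 + 1/B)
    k_hat: int | None = field(default=None)

    @property
    def n_null(self) -> int:
        return self.W_null.shape[0]


def within_dispersion(partition: Partition, D: np.ndarray) -> float:
    """Pooled within-cluster dispersion of squared dissimilarities."""
    D = np.asarray(D, dtype=np.float64)
    if D.shape[0] != partition.n_samples:
        raise ValueError(
            f"partition covers {partition.n_samples} samples but the "
            f"dissimilarity matrix has {D.shape[0]}"
        )
    W = 0.0
    for members in partition.cluster_members():
        n_r = len(members)
        if n_r < 2:
            continue
        sub = D[np.ix_(members, members)]
        W += float(np.sum(sub * sub)) / (2.0 * n_r)  # ordered pairs; diagonal is 0
    return W


def simulate_null_matrix(n: int, p: int, rng: np.random.Generator) -> GenotypeMatrix:
    """Structureless reference data: i.i.d. genotypes uniform on {0, 1, 2}."""
    if n < 2 or p < 1:
        raise ValueError(f"need n >= 2 and p >= 1, got ({n}, {p})")
    values = rng.integers(0, 3, size=(n, p), dtype=np.int16)
    return GenotypeMatrix(values)


def nested_partitions(
    values: np.ndarray,
    rng: np.random.Generator,
    min_node_size: int = 3,
    *,
    fringe_only: bool = False,
    gmm_restarts: int = 5,
    gmm_tol: float = 1e-6,
    gmm_max_iter: int = 200,
) -> tuple[list[Partition], np.ndarray, np.ndarray, "TreeNode"]:
    """Similarity → tree → pruning on a raw genotype array.

    This single code path serves both the observed data and every null
    replicate.  Returns the nested partitions, the similarity matrix,
    the dissimilarity matrix and the unpruned tree root.
    """
    S = asd_similarity_values(values)
    root = build_tree(
        S,
        rng,
        min_node_size,
        gmm_restarts=gmm_restarts,
        gmm_tol=gmm_tol,
        gmm_max_iter=gmm_max_iter,
    )
    partitions = prune_sequence(root, S, fringe_only=fringe_only)
    D = 2.0 - S
    np.fill_diagonal(D, 0.0)
    return partitions, S, D, root


def _dispersion_by_k(
    partitions: list[Partition], D: np.ndarray, k_cap: int
) -> dict[int, float]:
    out: dict[int, float] = {}
    for part in partitions:
        if part.k <= k_cap and part.k not in out:
            out[part.k] = within_dispersion(part, D)
    return out


def _lookup_coarser(w_by_k: dict[int, float], k: int) -> float:
    """Dispersion at k, imputed from the nearest realized coarser count."""
    if k in w_by_k:
        return w_by_k[k]
    coarser = [kk for kk in w_by_k if kk < k]
    k_near = max(coarser)  # k = 1 is always realized
    logger.info("null replicate missing k=%d; imputed from realized k=%d", k, k_near)
    return w_by_k[k_near]


def gap_curve(
    observed_partitions: list[Partition],
    D_obs: np.ndarray,
    n: int,
    p: int,
    B: int,
    k_max: int,
    rng: np.random.Generator,
    *,
    min_node_size: int = 3,
    fringe_only: bool = False,
    gmm_restarts: int = 5,
    gmm_tol: float = 1e-6,
    gmm_max_iter: int = 200,
) -> GapTable:
    """Gap statistic over the realized cluster counts up to ``k_max``."""
    if B < 2:
        raise ValueError("at least 2 null replicates are needed for a standard deviation")
    obs_by_k = _dispersion_by_k(observed_partitions, D_obs, k_max)
    ks = np.array(sorted(obs_by_k), dtype=np.int64)
    W = np.array([obs_by_k[k] for k in ks])

    W_null = np.empty((B, len(ks)), dtype=np.float64)
    for b in range(B):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        null = simulate_null_matrix(n, p, child)
        parts, _, D_null, _ = nested_partitions(
            null.values,
            child,
            min_node_size,
            fringe_only=fringe_only,
            gmm_restarts=gmm_restarts,
            gmm_tol=gmm_tol,
            gmm_max_iter=gmm_max_iter,
        )
        null_by_k = _dispersion_by_k(parts, D_null, k_max)
        W_null[b] = [_lookup_coarser(null_by_k, int(k)) for k in ks]

    gap = W_null.mean(axis=0) - W
    sd = W_null.std(axis=0)
    s = sd * np.sqrt(1.0 + 1.0 / B)
    table = GapTable(ks=ks, W=W, W_null=W_null, gap=gap, sd=sd, s=s)
    table.k_hat = select_k(table)
    return table


def select_k(table: GapTable) -> int:
    """Dudoit selection: smallest k with Gap(k) >= Gap(k') - s(k')

    where k' is the next larger realized count.  Falls back to the
    largest realized count (with a warning) if no k qualifies.
    """
    ks, gap, s = table.ks, table.gap, table.s
    if len(ks) == 0:
        raise ValueError("empty gap table")
    for i in range(len(ks) - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            return int(ks[i])
    if len(ks) > 1:
        logger.warning(
            "no cluster count satisfied the gap rule; falling back to k=%d", ks[-1]
        )
    return int(ks[-1])
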