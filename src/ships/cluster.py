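"""Divisive hierarchical spectral clustering as a scikit-learn estimator.

:class:`ShipsClustering` clusters individuals into genetically
homogeneous sub-populations from an (n samples x p SNPs) genotype
matrix coded 0/1/2 and estimates the number of sub-populations.  The
fit pipeline is: allele-sharing similarity matrix -> recursive spectral
bisection into a binary tree -> reduced-error pruning into nested
partitions -> gap-statistic selection of the cluster count against
structureless reference data.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .gap import GapTable, gap_curve, nested_partitions
from .genotypes import GenotypeMatrix
from .tree import Partition

logger = logging.getLogger(__name__)

__all__ = ["ShipsClustering"]


class ShipsClustering(ClusterMixin, BaseEstimator):
    """Divisive spectral clustering of SNP genotypes with gap-selected K.

    Parameters
    ----------
    k_max : int, default=20
        Largest cluster count investigated by the gap statistic.
    null_reps : int, default=20
        Number of structureless reference datasets (B) simulated for
        the gap statistic.
    n_clusters : int or None, default=None
        If set, skip gap selection and report the stored partition with
        this many clusters (the nearest realized coarser one if the
        exact count was never produced by pruning).
    min_node_size : int, default=3
        Groups smaller than this are never split further.
    fringe_only : bool, default=False
        Restrict pruning candidates to parents of two leaves, forcing
        the cluster count to decrease in unit steps.
    gmm_restarts, gmm_tol, gmm_max_iter
        Settings of the 2-component Gaussian mixture used to assign
        samples within each spectral bisection.
    random_state : int, Generator or None, default=None
        Master seed; fixes every spectral split, mixture restart and
        null simulation, making repeated fits bit-identical.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster label of each sample (0-based, scikit-learn style).
    n_clusters_ : int
        Selected number of sub-populations.
    partition_ : Partition
        The selected partition with field-style labels 1..k.
    partitions_ : list of Partition
        The full nested sequence from the unpruned tree down to one
        cluster.
    gap_table_ : GapTable or None
        Gap-statistic table (None when ``n_clusters`` was forced).
    similarity_ : ndarray of shape (n_samples, n_samples)
        Allele-sharing similarity matrix.
    tree_ : TreeNode
        Root of the unpruned divisive tree.

    Examples
    --------
    >>> from ships.popsim import simulate_scenario
    >>> import numpy as np
    >>> geno, truth = simulate_scenario("M3", np.random.default_rng(0))
    >>> model = ShipsClustering(k_max=10, null_reps=20, random_state=0)
    >>> model.fit_predict(geno.values).shape
    (150,)
    """

    def __init__(
        self,
        k_max: int = 20,
        null_reps: int = 20,
        n_clusters: int | None = None,
        min_node_size: int = 3,
        fringe_only: bool = False,
        gmm_restarts: int = 5,
        gmm_tol: float = 1e-6,
        gmm_max_iter: int = 200,
        random_state=None,
    ) -> None:
        self.k_max = k_max
        self.null_reps = null_reps
        self.n_clusters = n_clusters
        self.min_node_size = min_node_size
        self.fringe_only = fringe_only
        self.gmm_restarts = gmm_restarts
        self.gmm_tol = gmm_tol
        self.gmm_max_iter = gmm_max_iter
        self.random_state = random_state

    def _validate(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            geno = X
        else:
            geno = GenotypeMatrix(np.asarray(X))
        geno.require_clusterable()
        return geno

    def fit(self, X, y=None) -> "ShipsClustering":
        """Cluster the samples of a genotype matrix.

        Parameters
        ----------
        X : array-like or GenotypeMatrix of shape (n_samples, n_loci)
            Genotype codes 0/1/2; missing entries as NaN or -1.
        y : ignored
        """
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        if self.null_reps < 2 and self.n_clusters is None:
            raise ValueError("null_reps must be at least 2 for gap selection")
        geno = self._validate(X)
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        gmm_kwargs = dict(
            gmm_restarts=self.gmm_restarts,
            gmm_tol=self.gmm_tol,
            gmm_max_iter=self.gmm_max_iter,
        )
        partitions, S, D, root = nested_partitions(
            geno.values,
            rng,
            self.min_node_size,
            fringe_only=self.fringe_only,
            **gmm_kwargs,
        )
        self.similarity_ = S
        self.tree_ = root
        self.partitions_ = partitions
        self.sample_ids_ = list(geno.sample_ids)

        if self.n_clusters is not None:
            self.gap_table_: GapTable | None = None
            k_hat = self._nearest_realized(self.n_clusters)
        else:
            n, p = geno.shape
            self.gap_table_ = gap_curve(
                partitions,
                D,
                n,
                p,
                self.null_reps,
                self.k_max,
                rng,
                min_node_size=self.min_node_size,
                fringe_only=self.fringe_only,
                **gmm_kwargs,
            )
            k_hat = int(self.gap_table_.k_hat)

        self.partition_ = self._partition_at(k_hat)
        self.n_clusters_ = k_hat
        self.labels_ = self.partition_.labels - 1
        self.n_features_in_ = geno.n_loci
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Fit and return the 0-based cluster labels."""
        return self.fit(X).labels_

    # -- helpers -------------------------------------------------------

    def _realized_ks(self) -> list[int]:
        return sorted({p.k for p in self.partitions_})

    def _nearest_realized(self, k: int) -> int:
        ks = self._realized_ks()
        if k in ks:
            return k
        coarser = [kk for kk in ks if kk < k]
        near = max(coarser) if coarser else min(ks)
        logger.warning(
            "no partition with %d clusters was realized; using k=%d "
            "(realized counts: %s)",
            k,
            near,
            ks,
        )
        return near

    def _partition_at(self, k: int) -> Partition:
        for part in self.partitions_:
            if part.k == k:
                return part
        raise ValueError(f"no stored partition with {k} clusters")

    def partition_at(self, k: int) -> Partition:
        """The stored nested partition with exactly ``k`` clusters."""
        check_is_fitted(self, "partitions_")
        return self._partition_at(k)
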