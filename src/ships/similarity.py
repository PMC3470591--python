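"""Allele-sharing similarity and dissimilarity matrices.

The per-locus score between two diploid genotype codes ``g_i, g_j`` in
``{0, 1, 2}`` is ``2 - |g_i - g_j|``: 2 when the genotypes are identical,
0 when the samples share no allele (opposite homozygotes), 1 otherwise.
The pairwise similarity is the mean of this score over the loci at which
both samples are called, so it lives in ``[0, 2]`` regardless of the
number of loci.  The dissimilarity matrix is its exact 2-complement
(the allele sharing distance, ASD) — the two are linearly related and
never require a second pass over the genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "locus_similarity",
    "asd_similarity",
    "asd_similarity_values",
    "dissimilarity_from_similarity",
]


@dataclass
class SimilarityMatrix:
    """Symmetric n-by-n allele-sharing similarity with a diagonal of 2."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample id count must match matrix size")


@dataclass
class DissimilarityMatrix:
    """Symmetric n-by-n allele-sharing distance with a zero diagonal."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square")
        if len(self.sample_ids) != n:
            raise ValueError("sample id count must match matrix size")


def locus_similarity(g_i: int, g_j: int) -> int:
    """Similarity contribution of a single locus: ``2 - |g_i - g_j|``."""
    if g_i not in (0, 1, 2) or g_j not in (0, 1, 2):
        raise ValueError(f"genotype codes must be 0, 1 or 2; got ({g_i}, {g_j})")
    return 2 - abs(g_i - g_j)


def asd_similarity_values(values: np.ndarray) -> np.ndarray:
    """ASD similarity matrix from a raw genotype code array.

    ``values`` is an ``(n, p)`` integer array with entries in
    ``{0, 1, 2}`` or :data:`MISSING`.  Missing calls are excluded
    pairwise: each pair is averaged over its mutually called loci.
    """
    values = np.asarray(values)
    n, p = values.shape
    valid = values != MISSING
    G = np.where(valid, values, 0).astype(np.float64)
    V = valid.astype(np.float64)

    # sum over shared loci of |g_i - g_j| decomposes into
    # sum (g_i - g_j)^2 - 2 * (# opposite-homozygote loci),
    # since |d| = d^2 for d in {0,1} and |d| = d^2 - 2 for |d| = 2.
    sq = G * G
    gram = G @ G.T
    row_sq = sq @ V.T  # (i,j): sum over shared loci of g_i^2
    sum_sq_diff = row_sq + row_sq.T - 2.0 * gram
    hom0 = ((values == 0) & valid).astype(np.float64)
    hom2 = ((values == 2) & valid).astype(np.float64)
    n02 = hom0 @ hom2.T
    total_diff = sum_sq_diff - 2.0 * (n02 + n02.T)

    overlap = V @ V.T
    off_diag = ~np.eye(n, dtype=bool)
    no_overlap = (overlap < 0.5) & off_diag
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise ValueError(
            f"samples {i + 1} and {j + 1} share no called locus; "
            "cannot compute their allele-sharing distance"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        D = total_diff / overlap
    S = 2.0 - D
    # clip tiny negative rounding noise from the matmul decomposition
    np.clip(S, 0.0, 2.0, out=S)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 2.0)
    return S


def asd_similarity(genotypes: GenotypeMatrix) -> SimilarityMatrix:
    """Pairwise allele-sharing similarity over all sample pairs."""
    genotypes.require_clusterable()
    S = asd_similarity_values(genotypes.values)
    return SimilarityMatrix(S, list(genotypes.sample_ids))


def dissimilarity_from_similarity(similarity: SimilarityMatrix) -> DissimilarityMatrix:
    """ASD dissimilarity: ``D = 2 - S`` entrywise with a forced zero diagonal."""
    D = 2.0 - similarity.values
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(D, list(similarity.sample_ids))
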