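"""Normalized spectral bisection of a sample group.

One step of the divisive engine: embed the samples of a node with the
two lowest eigenvectors of the normalized Laplacian of their similarity
submatrix (normalized spectral clustering in the Ng–Jordan–Weiss form),
then assign each sample to one of two Gaussian-mixture components.  A
group is declared *terminal* — genetically homogeneous — when it is too
small to model or when one mixture component ends up empty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = ["SpectralSplit", "normalized_laplacian", "spectral_embedding", "bisect"]

#: Row norms below this are left as zero vectors in the embedding.
ZERO_ROW_TOL = 1e-12


@dataclass
class SpectralSplit:
    """Outcome of one bisection attempt.

    ``labels`` holds 0/1 group assignments (``None`` for a terminal
    split); ``terminal`` is True iff the node was declared homogeneous;
    ``embedding`` is the row-normalized 2-D spectral embedding when one
    was computed.
    """

    labels: np.ndarray | None
    terminal: bool
    embedding: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.terminal != (self.labels is None):
            raise ValueError("terminal splits carry no labels; non-terminal must")
        if self.labels is not None:
            counts = np.bincount(self.labels, minlength=2)
            if counts[0] == 0 or counts[1] == 0:
                raise ValueError("non-terminal split must have two non-empty groups")


def normalized_laplacian(S: np.ndarray) -> np.ndarray:
    """``L = I - D^{-1/2} S D^{-1/2}`` with D the diagonal degree matrix."""
    S = np.asarray(S, dtype=np.float64)
    deg = S.sum(axis=1)
    if np.any(deg <= 0):
        i = int(np.argmax(deg <= 0))
        raise ValueError(f"zero or negative degree for sample {i + 1}")
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = -(inv_sqrt[:, None] * S * inv_sqrt[None, :])
    L[np.diag_indices_from(L)] += 1.0
    return 0.5 * (L + L.T)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the first coordinate of non-negligible magnitude positive."""
    out = vectors.copy()
    for col in range(out.shape[1]):
        v = out[:, col]
        nz = np.flatnonzero(np.abs(v) > 1e-10)
        if nz.size and v[nz[0]] < 0:
            out[:, col] = -v
    return out


def spectral_embedding(L: np.ndarray, k: int = 2) -> np.ndarray:
    """Rows of the ``k`` lowest eigenvectors of L, rescaled to unit norm.

    Rows whose eigenvector coordinates are all below tolerance are left
    as zero vectors rather than divided by a vanishing norm.
    """
    n = L.shape[0]
    if n < k:
        raise ValueError(f"need at least {k} samples for a {k}-vector embedding, got {n}")
    _, vectors = scipy.linalg.eigh(L, subset_by_index=[0, k - 1])
    vectors = _fix_signs(vectors)
    norms = np.linalg.norm(vectors, axis=1)
    safe = norms > ZERO_ROW_TOL
    embedding = np.zeros_like(vectors)
    embedding[safe] = vectors[safe] / norms[safe, None]
    if not safe.all():
        logger.warning("%d embedding rows had vanishing norm; left at zero", (~safe).sum())
    return embedding


def bisect(
    S_sub: np.ndarray,
    rng: np.random.Generator,
    min_node_size: int = 3,
    *,
    gmm_restarts: int = 5,
    gmm_tol: float = 1e-6,
    gmm_max_iter: int = 200,
    gmm_init: str = "k-means++",
) -> SpectralSplit:
    """Split one group in two, or declare it terminal.

    Groups smaller than ``min_node_size`` are terminal by fiat (a
    two-component mixture on so few points is degenerate).  Otherwise a
    2-component full-covariance Gaussian mixture is fitted to the 2-D
    spectral embedding and samples take their maximum-posterior
    component; if a component receives no sample, the group is deemed
    homogeneous and the split is terminal.
    """
    S_sub = np.asarray(S_sub, dtype=np.float64)
    n = S_sub.shape[0]
    if n < max(2, min_node_size):
        return SpectralSplit(labels=None, terminal=True)

    embedding = spectral_embedding(normalized_laplacian(S_sub), k=2)
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gmm = GaussianMixture(
                n_components=2,
                covariance_type="full",
                n_init=gmm_restarts,
                init_params=gmm_init,
                tol=gmm_tol,
                max_iter=gmm_max_iter,
                reg_covar=1e-6,
                random_state=seed,
            )
            labels = gmm.fit_predict(embedding)
    except Exception as exc:  # degenerate geometry: treat as homogeneous
        logger.warning("GMM fit failed (%s); node of size %d treated as terminal", exc, n)
        return SpectralSplit(labels=None, terminal=True, embedding=embedding)

    counts = np.bincount(labels, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        return SpectralSplit(labels=None, terminal=True, embedding=embedding)
    # relabel so group 0 contains the lowest sample index (determinism)
    if labels[0] == 1:
        labels = 1 - labels
    return SpectralSplit(labels=labels.astype(np.int8), terminal=False, embedding=embedding)
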