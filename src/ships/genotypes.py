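"""Genotype matrix container.

Samples are rows, SNP loci are columns. Each entry counts the reference
alleles carried by a diploid individual at a locus, so valid codes are
0, 1 and 2; missing calls are stored as :data:`MISSING`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Sentinel for a missing genotype call (stored in the integer matrix).
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """An n-sample by p-locus matrix of diploid genotype codes.

    Parameters
    ----------
    values
        Integer array of shape ``(n, p)`` with entries in ``{0, 1, 2}``
        or :data:`MISSING`.
    sample_ids
        ``n`` unique sample identifiers.
    locus_ids
        ``p`` locus identifiers; autogenerated as ``snp_1 ... snp_p``
        when omitted.
    """

    values: np.ndarray
    sample_ids: list[str] = field(default=None)  # type: ignore[assignment]
    locus_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError(f"genotype matrix must be 2-D, got shape {values.shape}")
        if not np.issubdtype(values.dtype, np.integer):
            if np.issubdtype(values.dtype, np.floating):
                nan_mask = np.isnan(values)
                rounded = np.where(nan_mask, MISSING, values)
                values = rounded.astype(np.int16)
            else:
                raise TypeError("genotype matrix must be integer-valued")
        else:
            values = values.astype(np.int16, copy=False)
        bad = ~np.isin(values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {values[i, j]} at sample row {i + 1}, "
                f"locus column {j + 1}; expected 0, 1, 2 or missing"
            )
        self.values = values
        n, p = values.shape
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i + 1}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
        if self.locus_ids is None:
            self.locus_ids = [f"snp_{j + 1}" for j in range(p)]
        else:
            self.locus_ids = [str(s) for s in self.locus_ids]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.locus_ids) != p:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {p} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_clusterable(self) -> None:
        """Raise unless the matrix meets the clustering entry contract."""
        n, p = self.shape
        if n < 2:
            raise ValueError(f"clustering needs at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("clustering needs at least 1 locus")
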