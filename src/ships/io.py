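"""Reading genotype matrices and writing partitions, trees and gap tables.

Supported inputs: a plain 0/1/2 text matrix (whitespace- or
comma-separated, with optional locus-id header and optional sample-id
first column, both auto-detected), a PLINK ``.raw``-style additive
table, and a minimal VCF whose diploid GT fields are converted to
reference-allele counts.  Outputs are TSVs plus a Newick-style tree in
which branch lengths are deliberately omitted (they carry no meaning
for a divisive tree).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gap import GapTable
from .genotypes import MISSING, GenotypeMatrix
from .tree import Partition, TreeNode

__all__ = [
    "read_genotype_matrix",
    "write_partition",
    "read_partition",
    "write_gap_table",
    "read_gap_table",
    "gap_table_frame",
    "write_tree",
    "write_similarity",
]

_MISSING_TOKENS = {"NA", "-9", ".", "nan", "NaN"}
_VALID_TOKENS = {"0", "1", "2"} | _MISSING_TOKENS


def read_genotype_matrix(path: str | Path, format: str = "matrix012") -> GenotypeMatrix:
    """Read a genotype matrix from ``matrix012``, ``plink_raw`` or ``vcf``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {
        "matrix012": _read_matrix012,
        "plink_raw": _read_plink_raw,
        "vcf": _read_vcf,
    }
    if format not in readers:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(readers)}")
    geno = readers[format](path)
    if geno.n_samples < 2:
        raise ValueError(f"{path}: need at least 2 samples, found {geno.n_samples}")
    return geno


def _tokenize(path: Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rows.append(line.replace(",", " ").split())
    if not rows:
        raise ValueError(f"{path}: file is empty")
    return rows


def _parse_cell(token: str, row: int, col: int, path: Path) -> int:
    if token in _MISSING_TOKENS:
        return MISSING
    if token not in _VALID_TOKENS:
        raise ValueError(
            f"{path}: invalid genotype {token!r} at data row {row}, column {col}; "
            "expected 0, 1, 2 or a missing code (NA, -9, .)"
        )
    return int(token)


def _read_matrix012(path: Path) -> GenotypeMatrix:
    rows = _tokenize(path)
    # sample-id column present iff some first token of a data row is not a code
    body = rows[1:] if len(rows) > 1 else rows
    has_ids = any(r[0] not in _VALID_TOKENS for r in body)
    start = 1 if has_ids else 0
    # header present iff the first row has any non-code token past the id column
    has_header = any(t not in _VALID_TOKENS for t in rows[0][start:])
    data_rows = rows[1:] if has_header else rows

    if not data_rows:
        raise ValueError(f"{path}: no data rows")
    width = len(data_rows[0])
    locus_ids = None
    if has_header:
        header = rows[0]
        # the header may or may not carry a label above the sample-id column
        locus_ids = header[start:] if len(header) == width else header
        if len(locus_ids) != width - start:
            raise ValueError(
                f"{path}: header has {len(locus_ids)} locus ids for "
                f"{width - start} genotype columns"
            )
    values = []
    sample_ids = []
    for r, row in enumerate(data_rows, start=1):
        if len(row) != width:
            raise ValueError(
                f"{path}: data row {r} has {len(row)} fields, expected {width}"
            )
        sample_ids.append(row[0] if has_ids else f"sample_{r}")
        values.append(
            [
                _parse_cell(tok, r, c, path)
                for c, tok in enumerate(row[start:], start=start + 1)
            ]
        )
    return GenotypeMatrix(np.array(values, dtype=np.int16), sample_ids, locus_ids)


_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep=r"\s+")
    if table.empty:
        raise ValueError(f"{path}: file is empty")
    meta = [c for c in _PLINK_META_COLS if c in table.columns]
    sample_ids = (
        table["IID"].astype(str).tolist()
        if "IID" in table.columns
        else [f"sample_{i + 1}" for i in range(len(table))]
    )
    body = table.drop(columns=meta)
    values = body.to_numpy(dtype=np.float64)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int16)
    return GenotypeMatrix(values, sample_ids, list(body.columns))


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns = []
    locus_ids = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {variant.CHROM}:{variant.POS}; "
                "only biallelic SNPs are supported"
            )
        column = np.empty(len(sample_ids), dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                column[i] = MISSING
            else:
                column[i] = int(a == 0) + int(b == 0)  # reference-allele count
        columns.append(column)
        locus_ids.append(
            variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}"
        )
    if not columns:
        raise ValueError(f"{path}: no variant records")
    values = np.stack(columns, axis=1)
    return GenotypeMatrix(values, sample_ids, locus_ids)


# -- outputs -----------------------------------------------------------


def write_partition(
    partition: Partition, path: str | Path, sample_ids: list[str] | None = None
) -> None:
    """Partition as a two-column TSV (sample_id, cluster)."""
    ids = sample_ids or [f"sample_{i + 1}" for i in range(partition.n_samples)]
    if len(ids) != partition.n_samples:
        raise ValueError("sample id count must match the partition")
    frame = pd.DataFrame({"sample_id": ids, "cluster": partition.labels})
    frame.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> tuple[Partition, list[str]]:
    """Read a partition TSV back; returns the partition and the sample ids."""
    frame = pd.read_csv(path, sep="\t")
    labels = frame["cluster"].to_numpy(dtype=np.int64)
    # accept arbitrary positive labels, remap to contiguous 1..k by first use
    uniq = sorted(set(labels.tolist()))
    remap = {lab: i + 1 for i, lab in enumerate(uniq)}
    labels = np.array([remap[lab] for lab in labels])
    return Partition(labels), frame["sample_id"].astype(str).tolist()


def gap_table_frame(gap: GapTable) -> pd.DataFrame:
    """Gap table as a tidy frame, one row per realized cluster count."""
    return pd.DataFrame(
        {
            "k": gap.ks,
            "W": gap.W,
            "null_mean": gap.W_null.mean(axis=0),
            "null_sd": gap.sd,
            "gap": gap.gap,
            "s": gap.s,
            "selected": (gap.ks == gap.k_hat).astype(int),
        }
    )


def write_gap_table(gap: GapTable, path: str | Path) -> None:
    gap_table_frame(gap).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gap_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _newick(node: TreeNode, counter: list[int]) -> str:
    if node.is_leaf:
        counter[0] += 1
        return f"cluster_{counter[0]}(n={node.size})"
    left, right = node.children
    return f"({_newick(left, counter)},{_newick(right, counter)})"


def tree_newick(tree: TreeNode) -> str:
    """Newick-style serialization; leaves named cluster_<i>(n=<size>).

    Branch lengths are omitted: the divisive tree encodes split order,
    not evolutionary distance.
    """
    return _newick(tree, [0]) + ";"


def write_tree(tree: TreeNode, path: str | Path) -> None:
    Path(path).write_text(tree_newick(tree) + "\n")


def write_similarity(
    values: np.ndarray, sample_ids: list[str], path: str | Path
) -> None:
    """Square labeled TSV dump of a similarity or dissimilarity matrix."""
    frame = pd.DataFrame(values, index=sample_ids, columns=sample_ids)
    frame.to_csv(path, sep="\t", float_format="%.10g")
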