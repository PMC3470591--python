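"""End-to-end run: read genotypes, cluster, write every output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .cluster import ShipsClustering
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_ships"]


@dataclass
class RunConfig:
    """Resolved settings of one full clustering run."""

    input: str | Path
    format: str = "matrix012"
    k_max: int = 20
    null_reps: int = 20
    seed: int | None = None
    min_node_size: int = 3
    fringe_only: bool = False
    n_clusters: int | None = None  # skip gap selection when set
    out_dir: str | Path = "ships_out"

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")
        if self.null_reps < 2:
            raise ValueError("null_reps must be at least 2")


@dataclass
class RunResult:
    """Bundle returned by :func:`run_ships`."""

    model: ShipsClustering
    config: RunConfig
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.model.n_clusters_


def run_ships(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write partition, gap table and tree.

    Outputs land in ``config.out_dir``: ``partition.tsv`` (the selected
    clustering), ``partition_k<k>.tsv`` for every realized nested
    partition within ``k_max``, ``gap.tsv`` and ``tree.nwk``.
    """
    geno: GenotypeMatrix = io.read_genotype_matrix(config.input, config.format)
    logger.info(
        "read %d samples x %d loci from %s (seed=%s, k_max=%d, B=%d)",
        geno.n_samples,
        geno.n_loci,
        config.input,
        config.seed,
        config.k_max,
        config.null_reps,
    )
    model = ShipsClustering(
        k_max=config.k_max,
        null_reps=config.null_reps,
        n_clusters=config.n_clusters,
        min_node_size=config.min_node_size,
        fringe_only=config.fringe_only,
        random_state=config.seed,
    ).fit(geno)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["partition"] = out / "partition.tsv"
    io.write_partition(model.partition_, files["partition"], model.sample_ids_)
    for part in model.partitions_:
        if part.k <= config.k_max:
            key = f"partition_k{part.k}"
            if key in files:
                continue
            files[key] = out / f"{key}.tsv"
            io.write_partition(part, files[key], model.sample_ids_)
    if model.gap_table_ is not None:
        files["gap"] = out / "gap.tsv"
        io.write_gap_table(model.gap_table_, files["gap"])
    files["tree"] = out / "tree.nwk"
    io.write_tree(model.tree_, files["tree"])

    logger.info("selected %d clusters; outputs in %s", model.n_clusters_, out)
    return RunResult(model=model, config=config, files=files)
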