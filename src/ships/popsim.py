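"""Synthetic genotype data with known population structure.

Two generators:

* :func:`simulate_structured` — K discrete sub-populations whose allele
  frequencies drift apart along a population-split tree under the
  Balding–Nichols model: a branch with differentiation parameter F maps
  a parent frequency q to a Beta(q(1-F)/F, (1-q)(1-F)/F) draw, so F
  plays the role of the Fst accumulated along that branch.  Genotypes
  are binomial(2, q) per locus (Hardy–Weinberg within populations, loci
  independent).  A single-population model yields unstructured data.

* :func:`simulate_admixed` — a discretely admixed group created by one
  generation of random mating between two source populations followed
  by further generations of random mating within the admixed pool, so
  each admixed genome derives roughly half from each source.

Scenario presets (one population; 3, 5, 10 and 20 populations with
increasingly nested split trees; and the two-source admixture scenario)
mirror population histories of increasing complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .genotypes import GenotypeMatrix
from .tree import Partition

__all__ = [
    "PopulationModel",
    "AdmixtureSpec",
    "simulate_structured",
    "simulate_admixed",
    "scenario_model",
    "simulate_scenario",
    "SCENARIOS",
]

#: A population split tree: a leaf (population index) or a pair of subtrees.
SplitTree = Union[int, tuple]


def _balanced_tree(pop_indices: Sequence[int]) -> SplitTree:
    if len(pop_indices) == 1:
        return pop_indices[0]
    half = len(pop_indices) // 2
    return (_balanced_tree(pop_indices[:half]), _balanced_tree(pop_indices[half:]))


def _tree_leaves(tree: SplitTree) -> list[int]:
    if isinstance(tree, int):
        return [tree]
    left, right = tree
    return _tree_leaves(left) + _tree_leaves(right)


@dataclass
class PopulationModel:
    """Hierarchical drift model for K discrete sub-populations."""

    pop_sizes: Sequence[int]
    n_loci: int
    branch_f: float = 0.1
    split_tree: SplitTree | None = None
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        self.pop_sizes = [int(s) for s in self.pop_sizes]
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("every population needs at least 1 sample")
        if self.n_loci < 1:
            raise ValueError("need at least 1 locus")
        if not 0.0 <= self.branch_f < 1.0:
            raise ValueError(f"branch drift F must lie in [0, 1), got {self.branch_f}")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("ancestral frequency range must sit inside (0, 1)")
        if self.split_tree is None:
            self.split_tree = _balanced_tree(list(range(self.n_pops)))
        leaves = sorted(_tree_leaves(self.split_tree))
        if leaves != list(range(self.n_pops)):
            raise ValueError("split tree leaves must be populations 0..K-1, each once")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)


@dataclass
class AdmixtureSpec:
    """Discrete admixture by iterated random mating between two sources."""

    n_admixed: int
    generations: int = 5

    def __post_init__(self) -> None:
        if self.n_admixed < 1:
            raise ValueError("need at least 1 admixed sample")
        if self.generations < 1:
            raise ValueError("need at least 1 generation of mating")


def _drift(freq: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw of daughter frequencies around ``freq``."""
    if f <= 0.0:
        return freq.copy()
    scale = (1.0 - f) / f
    daughter = rng.beta(freq * scale, (1.0 - freq) * scale)
    # beta() can return exact 0/1 at extreme parameters; keep loci polymorphic-capable
    return np.clip(daughter, 1e-12, 1.0 - 1e-12)


def simulate_structured(
    model: PopulationModel, rng: np.random.Generator
) -> tuple[GenotypeMatrix, Partition]:
    """Genotypes for K drifted sub-populations plus their true labels."""
    lo, hi = model.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=model.n_loci)

    terminal_freqs: dict[int, np.ndarray] = {}

    def walk(tree: SplitTree, freq: np.ndarray) -> None:
        if isinstance(tree, int):
            terminal_freqs[tree] = freq
            return
        for subtree in tree:
            walk(subtree, _drift(freq, model.branch_f, rng))

    if model.n_pops == 1:
        terminal_freqs[0] = ancestral  # no drift branch: plain unstructured data
    else:
        walk(model.split_tree, ancestral)

    blocks = []
    labels = []
    for pop in range(model.n_pops):
        size = model.pop_sizes[pop]
        geno = rng.binomial(2, terminal_freqs[pop], size=(size, model.n_loci))
        blocks.append(geno.astype(np.int16))
        labels.extend([pop + 1] * size)
    values = np.vstack(blocks)
    sample_ids = [f"pop{lab}_{i + 1}" for i, lab in enumerate(labels)]
    return GenotypeMatrix(values, sample_ids=sample_ids), Partition(np.array(labels))


def _mate(
    pool_a: np.ndarray, pool_b: np.ndarray, n_off: int, rng: np.random.Generator
) -> np.ndarray:
    """One generation: each offspring draws one allele from a random parent
    in each pool (parents transmit a reference allele with probability g/2)."""
    pa = pool_a[rng.integers(0, pool_a.shape[0], size=n_off)]
    pb = pool_b[rng.integers(0, pool_b.shape[0], size=n_off)]
    allele_a = rng.binomial(1, pa / 2.0)
    allele_b = rng.binomial(1, pb / 2.0)
    return (allele_a + allele_b).astype(np.int16)


def simulate_admixed(
    G_A: GenotypeMatrix,
    G_B: GenotypeMatrix,
    spec: AdmixtureSpec,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, Partition]:
    """Two sources plus a discretely admixed pool, with 3 truth labels.

    Generation 1 crosses random parents from A with random parents from
    B; later generations mate randomly within the admixed pool, so the
    expected ancestry of every admixed genome stays 50/50.
    """
    if G_A.n_loci != G_B.n_loci:
        raise ValueError(
            f"source populations must share loci ({G_A.n_loci} vs {G_B.n_loci})"
        )
    pool = _mate(G_A.values, G_B.values, spec.n_admixed, rng)
    for _ in range(spec.generations - 1):
        pool = _mate(pool, pool, spec.n_admixed, rng)

    values = np.vstack([G_A.values, G_B.values, pool])
    labels = np.concatenate(
        [
            np.full(G_A.n_samples, 1),
            np.full(G_B.n_samples, 2),
            np.full(spec.n_admixed, 3),
        ]
    )
    sample_ids = (
        [f"A_{s}" for s in G_A.sample_ids]
        + [f"B_{s}" for s in G_B.sample_ids]
        + [f"adx_{i + 1}" for i in range(spec.n_admixed)]
    )
    return GenotypeMatrix(values, sample_ids=sample_ids), Partition(labels)


@dataclass(frozen=True)
class _Scenario:
    n_pops: int
    pop_size: int
    n_loci: int
    branch_f: float


#: Preset scenarios of increasing structural complexity.
SCENARIOS: dict[str, _Scenario] = {
    "M1": _Scenario(n_pops=1, pop_size=100, n_loci=1000, branch_f=0.0),
    "M3": _Scenario(n_pops=3, pop_size=50, n_loci=2000, branch_f=0.1),
    "M5": _Scenario(n_pops=5, pop_size=40, n_loci=2000, branch_f=0.1),
    "M10": _Scenario(n_pops=10, pop_size=30, n_loci=3000, branch_f=0.1),
    "M20": _Scenario(n_pops=20, pop_size=25, n_loci=3000, branch_f=0.1),
}

#: Defaults for the two-source admixture scenario.
MADX_DEFAULTS = {
    "source_size": 60,
    "n_admixed": 60,
    "n_loci": 2000,
    "branch_f": 0.15,
    "generations": 5,
}


def scenario_model(
    name: str, n_loci: int | None = None, pop_size: int | None = None
) -> PopulationModel:
    """The drift model behind a discrete preset (M1/M3/M5/M10/M20)."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)} or Madx")
    preset = SCENARIOS[name]
    return PopulationModel(
        pop_sizes=[pop_size or preset.pop_size] * preset.n_pops,
        n_loci=n_loci or preset.n_loci,
        branch_f=preset.branch_f,
    )


def simulate_scenario(
    name: str,
    rng: np.random.Generator,
    n_loci: int | None = None,
    pop_size: int | None = None,
) -> tuple[GenotypeMatrix, Partition]:
    """Simulate a preset scenario, including the admixture preset ``Madx``."""
    if name == "Madx":
        d = MADX_DEFAULTS
        sources = PopulationModel(
            pop_sizes=[pop_size or d["source_size"]] * 2,
            n_loci=n_loci or d["n_loci"],
            branch_f=d["branch_f"],
        )
        geno, _ = simulate_structured(sources, rng)
        n_a = sources.pop_sizes[0]
        G_A = GenotypeMatrix(geno.values[:n_a], sample_ids=geno.sample_ids[:n_a])
        G_B = GenotypeMatrix(geno.values[n_a:], sample_ids=geno.sample_ids[n_a:])
        spec = AdmixtureSpec(
            n_admixed=pop_size or d["n_admixed"], generations=d["generations"]
        )
        return simulate_admixed(G_A, G_B, spec, rng)
    model = scenario_model(name, n_loci=n_loci, pop_size=pop_size)
    return simulate_structured(model, rng)
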