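# Methods

## Model and procedure

`ships` treats population structure inference as divisive hierarchical
clustering on an allele-sharing similarity matrix, with the number of
sub-populations chosen by a gap statistic. The pipeline is strictly
sequential — similarity → binary tree → pruning → K selection — and
every stage after the first operates only on the n × n similarity
matrix, never on the genotypes again.

**Similarity.** The per-locus score between genotype codes is
2 − |g_i − g_j|; the pairwise similarity is its *mean* over the loci at
which both samples are called. Averaging (rather than summing) makes
the scale independent of the locus count and of per-pair missingness,
so the anchor values — 0 for a pair sharing no allele at any locus, 2
for identical genomes — hold at matrix level. Heterozygote vs
heterozygote scores 2: the genotypes are identical, even though the
phased allele pairing is unknown. Missing calls are excluded pairwise;
a pair with no mutually called locus is an error rather than a silent
guess. Any constant rescaling of the similarity would leave all
clustering decisions unchanged except the absolute gap scale, which is
consistent because null data pass through the same code path.

**Spectral bisection.** Each node's similarity submatrix is converted
to the normalized Laplacian L = I − D^(−1/2) S D^(−1/2) (symmetric;
eigenvalues in [0, 2]; smallest eigenvalue 0). Samples are embedded
with the eigenvectors of the two smallest eigenvalues — the standard
normalized-spectral-clustering construction — and each embedding row is
rescaled to unit norm; rows with vanishing norm are left at zero and
flagged. Eigenvector sign is fixed by making the first non-negligible
coordinate positive, removing one source of run-to-run arbitrariness. A
2-component Gaussian mixture (full covariance, 5 restarts with
k-means++ seeding, tolerance 1e-6, max 200 iterations, all seeded from
the pipeline generator) hard-assigns samples by maximum posterior. The
node is terminal when either component receives no sample (the group is
deemed homogeneous), when the node is smaller than `min_node_size`
(default 3; a 2-component mixture on ≤ 2 points is degenerate), or when
the mixture fit fails outright.

In practice the empty-component termination fires rarely on unstructured
data: the embedding of a homogeneous group is a noise arc on the unit
circle that a 2-component mixture happily halves, so trees usually grow
until nodes are small. This does not disturb K estimation — identifying
homogeneity is the gap statistic's job, and the tree's over-splits are
collapsed first during pruning — it only costs extra split attempts on
small nodes.

**Pruning.** A node's SS is the sum of squared similarities over its
unordered sample pairs (diagonal excluded; self-similarity is constant
and uninformative). An internal node's quality is
Q(G) = SS(G) − Σ SS(current leaves under G), algebraically equal to the
squared-similarity sum over pairs split across different leaves — both
forms are computed and compared in the test suite. Pruning repeatedly
collapses the internal node with minimal quality, recomputing qualities
on the new topology each step; candidates are all internal nodes by
default (a collapse of a deep node can skip several k values; the gap
selector works on the realized k grid), or only parents-of-leaves with
`fringe_only=True`, which forces unit decrements. Ties are broken by
depth (deepest first), then smallest member index, for determinism.

Because quality is an un-normalized sum, it scales with the number of
cross-leaf pairs: small fringe nodes created by noise splits have the
smallest quality and are collapsed first, which is what makes the
nested sequence informative on genotype data. The flip side is that on
adversarial inputs where a large node's leaves are *exactly* mutually
dissimilar its quality can be 0 and it is collapsed early; this does
not arise with allele-sharing similarities on real or simulated
genotypes, where cross-population similarity stays well above 0.

**Gap statistic.** For each realized k ≤ `k_max`, the pooled
within-cluster dispersion is W_k = Σ_r D_r/(2 n_r), with D_r the sum of
squared allele-sharing distances over ordered within-cluster pairs —
the classical pooled-dispersion shape applied to squared ASD, used
*without* the logarithm. Reference data are i.i.d. genotypes uniform on
{0, 1, 2}, the maximal-entropy choice on the code alphabet; no feature
matching (allele frequencies, HWE) is attempted. Uniform null genotypes
have a higher dissimilarity scale than any Hardy–Weinberg population
(mean per-locus distance 8/9 vs ≤ 3/4 at frequency one-half), so past
the true K the observed dispersion falls more slowly than the null's
and the gap declines — which is what makes the selection rule stop.
Each of the B replicates (default 20) runs the *identical* pipeline
code path; a replicate whose tree never realized some k contributes the
dispersion of its nearest realized coarser partition (logged). K̂ is
the smallest realized k with Gap(k) ≥ Gap(k′) − s(k′) for the next
larger realized k′, s(k) = sd(k)·√(1+1/B); if no k qualifies, the
largest realized k is reported with a warning.

W is provably non-decreasing under merges only for squared-Euclidean
dispersions; squared ASD is not squared-Euclidean, and arbitrary merges
can lower W by a few percent in corner cases. Along the nested
sequences pruning actually produces, monotonicity holds empirically
(checked by brute force in the tests), which is the property the
selection rule relies on.

**Evaluation.** The Hubert–Arabie adjusted Rand index is computed from
the contingency table. When *both* clusterings are the single
all-in-one cluster the index is formally 0/0 and is returned as 1 — the
structure was recovered perfectly; when only one side is all-in-one the
formula's value 0 is kept.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k_max` | 20 | largest cluster count investigated (no hard cap is imposed by the method) |
| `null_reps` (B) | 20 | reference datasets per gap curve; cost is linear in B |
| `min_node_size` | 3 | nodes smaller than this are terminal; configurable down to 1 |
| `fringe_only` | False | restrict prune candidates to parents of two leaves |
| `gmm_restarts` | 5 | mixture restarts per bisection |
| `random_state` | None | master seed; fixes splits, restarts and null data, making runs bit-identical |

## Synthetic data

The generator emulates discrete population structure by hierarchical
allele-frequency drift: ancestral frequencies are uniform on
(0.1, 0.9); each branch of a population-split tree applies a
Balding–Nichols draw, Beta(q(1−F)/F, (1−q)(1−F)/F), so F acts as the
Fst accumulated on that branch; genotypes are binomial(2, q) within
populations. Loci are independent (no linkage disequilibrium) — the
allele-sharing distance is locus-wise, so LD affects only the effective
number of independent loci, not the method's logic. Scenario presets of
increasing complexity: M1 (one population, 100 samples, p=1000), M3
(3 × 50, p=2000), M5 (5 × 40, p=2000), M10 (10 × 30, p=3000, nested
splits) and M20 (20 × 25, p=3000, nested splits), all with branch
F=0.1 — strong, continental-scale differentiation. The preset sizes are
desk-scale choices that keep a full gap-statistic run in seconds-to-
minutes; they are deliberately smaller than typical GWAS panels, and
the branch-F values and balanced topologies are this package's own
calibration, chosen so that difficulty rises with the number of
populations.

The admixture preset (Madx) drifts two sources apart (F=0.15,
2 × 60 samples, p=2000), then mates 60 offspring from random A×B parent
pairs and continues random mating within the admixed pool for 5
generations, so each admixed genome is ≈ 50/50 ancestry. The admixed
group is *discrete* — a genuine third cluster — which is exactly the
structure the clustering should report as K=3.

What passing these simulations does **not** show: robustness to LD,
to genotyping error or missingness patterns of real arrays, to
continuous admixture clines, or to relatedness within samples; real
data carry all of these and published allele-sharing-based analyses are
known to lose power under them.

## Numerical choices and degenerate inputs

Eigen-decomposition uses LAPACK's dense symmetric solver restricted to
the two lowest eigenpairs. Similarity assembly is exact integer
arithmetic reorganized into three matrix products (|a−b| decomposes as
(a−b)² minus twice the opposite-homozygote indicator), with tiny
negative rounding noise clipped at 0. The GMM's reg_covar is 1e-6; a
fit failure is treated as a terminal (homogeneous) node with a logged
warning rather than an abort. A zero-degree Laplacian row cannot occur
with ASD (the diagonal of S is 2) but is asserted anyway. Null-matrix
child generators are spawned from the master generator, so changing B
changes later replicates only.

## Known limitations

* The uniform-code null ignores the observed allele-frequency spectrum;
  it is conservative in the direction described above and worked across
  all presets, but datasets dominated by rare variants shrink the
  observed/null scale contrast and may need a larger B.
* Quality-based pruning is a greedy heuristic; it does not revisit
  collapses, and the nested sequence can skip k values when deep nodes
  are collapsed (`fringe_only` avoids this at the cost of literalness).
* Runtime is dominated by the B full null pipelines; it scales roughly
  as B · n³ for the eigen-decompositions plus B · n · (GMM fits).
* VCF input is minimal by design: biallelic SNPs, GT field only.
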