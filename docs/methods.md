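# Methods

## Problem

Given a binary association matrix `A` (`nm` miRNAs × `nd` diseases) of
experimentally confirmed miRNA–disease links, a precomputed miRNA
functional-similarity matrix, and a forest of disease DAGs, rank the
unknown (zero) entries of `A` by how likely they are to be true
associations. The working assumption is the standard one for this class
of methods: functionally similar miRNAs tend to associate with
phenotypically similar diseases.

## Similarity construction

**Gaussian interaction-profile (GIP) kernel.** Each entity's binary
association profile `BV(i)` (a row of `A` for miRNAs, a column for
diseases) is compared by a Gaussian of the squared Euclidean distance,

    K(i, j) = exp(-γ ‖BV(i) − BV(j)‖²),   γ = 1 / ( (1/n) Σ_i ‖BV(i)‖² ).

The bandwidth is the reciprocal of the mean squared profile norm, so a
denser association matrix produces a flatter kernel. An all-zero `A`
leaves γ undefined and is rejected. Note that γ is a *global* statistic:
editing a single entry of `A` perturbs every kernel value slightly, even
though only one row's and one column's profiles (and pairwise distances)
actually move. The tests assert the latter, correct locality.

**Disease semantic similarity.** Each disease `d` has a DAG `D(d)` of
ancestor terms plus itself. A term `t` contributes
`−log(n_t / N)` to the semantic value `DV(d)`, where `n_t` is the number
of disease-of-interest DAGs containing `t` and `N` the number of
diseases of interest — rare (specific) ancestors count more than common
(general) ones. Similarity is the shared-term contribution mass
normalized by the two semantic values:

    SD(i, j) = Σ_{t ∈ D(i)∩D(j)} (D_i(t) + D_j(t)) / (DV(i) + DV(j)).

The logarithm base cancels in this ratio; natural log is used so `DV`
itself is reproducible. A disease all of whose terms occur in every DAG
has `DV = 0`; the resulting 0/0 is resolved to 1 on the diagonal and 0
off it, preserving `SD(d, d) = 1`.

**Fusion.** The fused miRNA matrix `SM` keeps the functional score where
one exists and falls back to the GIP kernel where the base entry is zero
(precomputed functional-similarity tables are sparse), averaging the two
elsewhere. The disease matrix `SD` is fused identically from the
semantic matrix and the disease-side GIP kernel. Both fusion rules
condition on the non-GIP matrix's zeros.

## Features, hypergraph, learner

A pair `(i, j)` is represented by concatenating row `i` of `SM` with row
`j` of `SD` — an `(nm + nd)`-dimensional vector (878 at the 495 × 383
scale the method was designed for). Features are used unscaled: all
entries already live in [0, 1].

Training uses every known pair as a positive and an equal-sized seeded
uniform sample of unknown pairs as negatives (without replacement;
during cross-validation the held-out positives are excluded from the
negative pool so a test pair can never be drawn as a training negative).

A hypergraph is built over the training rows: one hyperedge per vertex,
containing the vertex and its `k` Euclidean nearest neighbours
(`δ(e) = k + 1`; self-inclusion guarantees every vertex degree is
positive). Distance ties break toward the lower vertex index, duplicate
hyperedges are retained, and all weights are `1/|E|`. With incidence
`H`, weights `W`, and degree matrices `Dv`, `De`, the smoothness
operator is

    Δ = I − Dv^{−1/2} H W De^{−1} H^T Dv^{−1/2},

a positive semi-definite normalized hypergraph Laplacian: `fᵀΔf` equals
the normalized sum of squared differences of `f` over vertices sharing a
hyperedge (the squared form — the unsquared variant that sometimes
appears in print does not produce a quadratic form).

The projection `P` minimizes

    tr(PᵀXᵀΔXP) + λ‖XP − Y‖² + μ‖P‖²,

with closed-form solution `P = λ (XᵀΔX + λXᵀX + μI)^{−1} XᵀY`. The
system matrix is symmetric positive definite for any `μ > 0` and is
solved directly (Cholesky via `scipy.linalg.solve(assume_a="pos")`)
rather than inverted. `Y` is a single {0,1} column (`l = 1`): a two-column
one-hot encoding would change scores only by an affine map and therefore
no ranking. Scoring a query pair is `x · P`; query pairs never join the
hypergraph.

Defaults `k = 15`, `λ = 10`, `μ = 1`. The learner requires `k < n`;
evaluation on small fixtures uses `k = 5` where the per-fold training
set would otherwise be too small for `k = 15` to be meaningful.

## Evaluation protocol

Both schemes hold out known associations, **zero them in `A`, and
recompute the GIP kernels and fused matrices from the modified `A`**
before retraining — otherwise the held-out pair's own entry leaks into
its features. The DAG semantic part does not depend on `A` and is
computed once. Candidates are all pairs unknown in the original `A`.

- **LOOCV** holds out one known pair at a time and records its
  normalized rank (ties at half) among the candidate scores of its own
  fold; the global AUC pools these ranks (the rank-threshold sweep). A
  seeded `max_test_pairs` subsample supports desk-scale runs and is
  flagged in the result as an approximation.
- **k-fold CV** partitions the positives per repeat, zeroes a whole fold
  at once, and reports mean ± SD of the per-repeat AUCs.
- `roc_auc` is the standard rank statistic
  `P(score⁺ > score⁻) + ½·P(tie)` (scikit-learn's implementation; the
  test suite checks it against exhaustive pairwise comparison).

Negative samples are redrawn per fold, seeded by `(seed, fold)`, from
the pairs unknown in the *original* matrix, so held-out positives are
never used as negatives.

## Synthetic benchmark

`SyntheticSpec` plants co-cluster structure: miRNAs and diseases are
split into `n_blocks` contiguous blocks; `A(i,j) = 1` with probability
`density_in` inside a co-cluster and `density_out` outside. The base
similarity is the block indicator plus symmetric Gaussian noise
(`sim_noise`), clipped to [0, 1], with a fraction `sim_sparsity` of
off-diagonal entries forced to exactly zero (emulating the sparsity of
real functional-similarity tables). The ontology is one chain of
`dag_depth` internal terms per block with that block's diseases attached
below, so semantic similarity is high within a block and zero across
blocks. Defaults: `nm = 30`, `nd = 20`, `n_blocks = 3`,
`density_in = 0.5`, `density_out = 0.02`, `sim_noise = 0.1`,
`sim_sparsity = 0.3`, `dag_depth = 3`, `seed = 7`. The noise and
sparsity levels are moderate values typical of curated similarity
resources; the DAG depth gives within-block diseases several shared
ancestors without making the chains degenerate.

`planted_truth` returns the within-block zero pairs — unknown but
structurally plausible associations used as ground truth for recovery
experiments.

### What the generator does and does not emulate — the additive ceiling

The score `x · P` with `x = [SM_i, SD_j]` decomposes as
`score(i, j) = f(i) + g(j)`: the model is **additive** in its two
endpoints and cannot represent an interaction such as "`i` and `j` are
in the *same* block". On a symmetric equal-block design,
ranking within-block zero pairs above cross-block zeros is exactly such
an interaction: an oracle additive scorer fitted directly to the
evaluation labels tops out near AUC 0.64 on the default instance, and
the honest pipeline sits near chance (the frozen regression value for
LOOCV on the default spec is 0.4906, seed 1). Independent linear
baselines (ridge, logistic regression) behave identically, and the same
pipeline reaches LOOCV AUC ≈ 0.75 on a degree-heterogeneous association
matrix — the signal the method *can* express is marginal (degree-like)
structure, which real association databases have in abundance
(heavy-tailed degree distributions) and the symmetric block generator
deliberately lacks. Passing tests on this generator therefore
demonstrate correctness of the machinery (similarities, hypergraph,
closed form, protocol, determinism), not real-data ranking power; the
end-to-end recovery assertion against the planted truth set is retained
in the acceptance suite and documented as failing for this structural
reason. Consistently, degrading the planted signal
(`density_in → density_out`) drives the recovery AUC toward 0.5 —
from below, since within-block zeros anti-correlate with realized
degree.

## Numerical choices and degenerate inputs

- Similarity tables with asymmetry ≤ 1e−8 are symmetrized by averaging
  (float-formatting noise in real files); larger asymmetry is an error.
- KNN distance ties break by lower vertex index; duplicate feature rows
  are allowed (zero-distance neighbours).
- Score-table ranks break ties by input order (stable sort).
- Δ is symmetrized (`(Δ + Δᵀ)/2`) to remove floating-point asymmetry
  before use; its minimum eigenvalue is asserted ≥ −1e−8 in tests.
- All randomness (negative sampling, fold assignment, subsampling)
  derives from a single integer seed through named `numpy` seed
  sequences, making every pipeline output byte-reproducible.

## Known limitations

- Additive scoring cannot capture endpoint interactions (see above);
  the method inherits this from its feature construction.
- Hyperedge weights are fixed at `1/|E|`; no weight learning or dynamic
  hypergraph updates.
- The hypergraph build is dense (`O(n²)` distances) and the closed form
  solves a `p × p` system; both are comfortable at the 878-feature,
  ~10⁴-sample scale the method targets but are not engineered beyond it.
- Exhaustive LOOCV refits one model per known association; at database
  scale use the seeded `max_test_pairs` subsample or k-fold CV.
- Identifier matching is exact and case-sensitive; no normalization
  across miRNA naming conventions is attempted.
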