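# Methods

## Model

Let `M ∈ {0,1}^{d×t}` be the validated drug–target interaction matrix,
`DS ∈ [0,1]^{d×d}` and `TS ∈ [0,1]^{t×t}` symmetric similarity matrices
with unit diagonals, and `A` the binary indicator of *training*
interactions (equal to `M` for a full fit; test entries, rows or
columns zeroed under cross-validation).  The completed score matrix `X`
minimizes

```
F(X) = ‖X‖_* + α‖X‖²_F + β‖A∘X − A‖²_F + λ[ tr(XᵀL_d X) + tr(X L_t Xᵀ) ]
```

- `‖X‖_*` — nuclear norm, the convex surrogate for low rank; the
  completed interaction landscape is assumed to be driven by a small
  number of latent drug/target factors.
- `α‖X‖²_F` — Tikhonov ridge keeping the problem strongly convex and
  the scores bounded.
- `β‖A∘X − A‖²_F` — fidelity: observed interactions are pulled toward 1
  (zero entries of `A` are *unobserved*, not trusted negatives, so they
  are not pulled toward 0 by this term).
- the λ-term — dual Laplacian smoothness with `L_d = D_d − DS`,
  `D_d(i,i) = Σ_j DS(i,j)` (same for `L_t`/`TS`).  The trace form is
  canonical here; it equals half the weighted pairwise sum
  `Σ_ij DS(i,j)‖x^i − x^j‖²` over rows (and analogously over columns),
  so a pairwise-sum formulation differs only by a factor 2 absorbed
  into λ.  Self-similarity diagonal entries are retained: they enter
  the degrees but cancel exactly in the quadratic form.

Laplacians are unnormalized and built on the dense similarity matrices
by default.  kNN sparsification (symmetric union of per-row top-k) and
a Gaussian re-weighting `W′ = exp(−(1−W)²/2σ²)` are available as
opt-in preprocessing (`knn_k`, `rbf_sigma`) for experimenting with
sparser graphs; they are not the default because the dense similarity
matrices are the canonical published inputs.

## Solver

The Hadamard product makes joint minimization awkward, so the problem
is split with two auxiliary variables, `X = J` (nuclear norm) and
`X = Z` (fidelity), and solved by inexact ALM on the augmented
Lagrangian with multipliers `Y₁, Y₂` and penalties `μ₁, μ₂`.  Per
iteration, in fixed order:

1. **J-block** — `J = SVT(X + Y₁/μ₁, 1/μ₁)`, the exact proximal map of
   the nuclear norm (soft-threshold the singular values).
2. **Z-block** — the stationarity system is diagonal,
   `(2β·diag(vec A) + μ₂I) vec Z = vec(2βA + μ₂X + Y₂)`, solved
   elementwise: `Z_ij = (2βA_ij + μ₂X_ij + Y₂_ij)/(2βA_ij + μ₂)`.
   The dense linear system is kept only as a test oracle.
3. **X-block** — the Sylvester equation
   `[(2α+μ₁+μ₂)I + 2λL_d]X + X[2λL_t] = μ₁J + μ₂Z − Y₁ − Y₂`.
   Both Laplacians are symmetric PSD and constant across iterations, so
   they are eigendecomposed once per fit and each solve is an
   elementwise division in the eigenbasis; the left coefficient
   `2α+μ₁+μ₂+2λ·eig` is strictly positive, so the solution is unique.
   The solver's contract is a stationarity residual ≤ 1e-8·(1+‖RHS‖_∞),
   checked on every call.  At λ = 0 the equation is diagonal and is
   solved by direct division — this keeps structurally zero rows and
   columns (fully blinded units) *exactly* zero instead of picking up
   ~1e-16 basis-rotation roundoff, which matters for honest λ = 0
   ablations: otherwise the ablation ranks test entries by roundoff
   noise instead of producing ties.
4. **Multipliers** — `Y ← Y + μ(X−·)`, then `μ ← min(ρμ, μ_max)`.

Each block minimizes the augmented Lagrangian exactly in its variables,
so the AL value is non-increasing across the three block updates of an
iteration (a tested invariant).

**Initialization and schedule** (conventions, exposed as config):
`X = J = Z = A`, `Y₁ = Y₂ = 0`; `μ₁ = μ₂ = 1e-2`, growth `ρ = 1.1`,
cap `μ_max = 1e6`.  Convergence: `max(‖X−J‖_∞, ‖X−Z‖_∞) ≤ tol = 1e-6`,
`max_iter = 500`; non-convergence returns the last iterate with a
warning flag.  On the default 54×26 synthetic dataset the solver
converges in ≈ 75–100 iterations (< 0.1 s).

**Hyperparameters.**  Defaults `α = 0.1, β = 1, λ = 1`; each of the
three weights is conventionally tuned over
`{0.001, 0.01, 0.1, 1, 10, 100, 1000}` by grid search.  The effective
Tikhonov gradient coefficient is `2α` (the stationarity condition is
taken literally).  On dense similarity graphs small λ values
(10⁻³–10⁻²) are typically selected: large λ over-smooths because every
node has many strong neighbors, flattening the column-specific signal.

**Baseline.**  `plain_matrix_completion` solves the equality-constrained
problem `min ‖X‖_* s.t. X_E = M_E` by the classic SVT iteration
(`τ = 5√(dt)`, dual step `δ = min(1.2·dt/|E|, 1.9)` — the ascent
converges for steps in (0, 2) and the uncapped heuristic exceeds 2 on
densely observed small matrices).  It exists only as a comparison point.

## Evaluation protocol

5 repetitions of 10-fold cross-validation under three blinding schemes:
cv1 partitions drug–target pairs, cv2 whole drug rows, cv3 whole target
columns.  By default cv1 partitions *all* d·t pairs; a `positives` mode
partitions only observed interactions and scores the full negative pool
each fold.  Within a repetition all folds' test predictions are pooled
into one AUPR (pooling rather than per-fold averaging, because per-fold
positive counts can be zero on small datasets); the mean ± sample
standard deviation over repetitions is reported.  Folds with no
positive test entries are skipped with a warning and recorded.

**AUPR.**  PR points are computed at every distinct score threshold
(ties collapse to a single threshold) with the conventional
(recall 0, precision 1) anchor.  The area is computed by the
**step-wise (average precision) rule** `Σ ΔR·P` by default; trapezoidal
interpolation is available via a flag.  Linear interpolation in PR
space is over-optimistic — most visibly for a degenerate all-tied score
set, where it reports `(1+prevalence)/2` instead of the prevalence.
That case actually occurs here: the λ = 0 ablation under cv3 scores
every blinded column exactly zero, and the step rule correctly collapses
it to the prevalence while the trapezoid would inflate it to ≈ 0.5.
Scores for blinded rows/columns come directly from the completed `X`;
no neighbor-profile imputation is applied, so the ablation isolates the
Laplacian term.

Under random ranking the expected step AUPR is the positive prevalence
up to a positive O(1/n_pos) finite-sample bias — the permutation
baseline in the tests uses n = 1000 with 200 positives, where the bias
is below 0.01.

## Similarity construction

- **Drugs** — Jaccard overlap `|c∩c′|/|c∪c′|` over caller-supplied
  substructure/fingerprint token sets.  Graph-alignment engines that
  produce such common-substructure sets are external; precomputed
  similarity files remain the canonical input path for benchmarks.
  Convention: two empty sets are identical (similarity 1); empty vs
  non-empty is 0.
- **Targets** — normalized Smith–Waterman
  `SW(g,g′)/√(SW(g,g)·SW(g′,g′))` over amino-acid sequences, exact
  affine-gap local alignment via Biopython.  Scoring defaults are the
  standard BLOSUM62 with gap open 10 / extend 1 (a length-L gap costs
  `10 + (L−1)·1`); the upstream convention is unstated, so externally
  supplied similarity files are preferred for benchmark reproduction.
  Self-similarity is exactly 1; if an exotic scoring scheme ever pushes
  the ratio above 1 it is clipped with a warning rather than silently.

## Synthetic data generator

Emulates the benchmark regime: latent factors `U ∈ R^{d×r}`,
`V ∈ R^{t×r}` with standard normal entries; true scores `X* = UVᵀ`;
similarities are RBF kernels on the factor rows with bandwidth set to
the median pairwise distance, blended with the identity by a
`graph_smoothness` weight (1 = fully informative graphs, 0 = graphs
carry no signal); `M` is 1 where `X* + ε` (ε Gaussian, sd `noise_sd`)
exceeds the `sparsity` quantile of its entries.  Defaults mirror the
smallest benchmark scale: d = 54, t = 26, r = 3, sparsity 0.9359
(→ exactly 90 interactions), noise sd 0.1, so experiments run in
seconds.  Graph smoothness of `X*` holds by construction, making the
λ-ablation falsifiable: if the solver's graph term worked incorrectly,
tuned λ > 0 would not beat λ = 0 under target blinding.

What the generator does **not** emulate: real chemical or sequence
structure, hub drugs/promiscuous targets, similarity noise that is
correlated with assay coverage.  Passing the synthetic ablation shows
the machinery propagates graph signal correctly; it does not certify
AUPR levels on real benchmark data.

The ablation experiment (`recovery_experiment`) shares one dataset and
one fold plan between the λ-on and λ-off runs; with `lam_grid` given, λ
is selected by grid search on the same plan and the best result
reported, mirroring the usual best-parameters reporting protocol.  The
experiment uses one repetition per seed and varies the generator seed
instead — across-seed variation dominates across-repetition variation
at this scale.

## Numerical and design notes

- Similarity files are symmetrized `(S+Sᵀ)/2` on load (files may carry
  rounding asymmetry), clipped to [0,1], diagonal forced to 1; loading
  is idempotent.  ID order is defined by first appearance in the
  interaction file; similarity files are reindexed to it.
- Summary statistics are rounded half-away-from-zero to 2 decimals,
  matching the precision of the published tables.
- Ranking ties (top-k prediction) break on the lexicographically
  smaller target ID, for determinism.
- The solver is deterministic; all stochastic components (generator,
  fold plans) are driven by explicit seeds, and repeated runs are
  bit-identical.
- Known limitations: full SVD per iteration limits matrix sizes to
  roughly a few thousand per side; the fidelity term treats zeros as
  unobserved, so the model cannot use trusted negatives; hyperparameter
  grid search is a plain loop (no warm starts).
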