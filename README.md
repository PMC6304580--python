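# dlgrmc — dual Laplacian graph regularized matrix completion for drug–target interaction prediction

Experimentally validated drug–target interactions (DTIs) are scarce:
standard benchmark datasets are 93–99.8 % zeros.  Predicting which of
the unobserved pairs are real interactions is a bipartite link
prediction problem, and a strong prior is that **similar drugs hit
similar targets and similar targets are hit by similar drugs**.

`dlgrmc` implements a matrix-completion model that encodes exactly that
prior.  Given a binary interaction matrix `M ∈ {0,1}^{d×t}`, a drug–drug
chemical similarity matrix `DS` and a target–target sequence similarity
matrix `TS`, it solves

```
min_X  ‖X‖_*  +  α‖X‖²_F  +  β‖A∘X − A‖²_F  +  λ[ tr(XᵀL_d X) + tr(X L_t Xᵀ) ]
```

where `‖X‖_*` is the nuclear norm (convex surrogate for low rank), `A`
is the binary indicator of observed interactions (`∘` = Hadamard
product), and `L_d = D_d − DS`, `L_t = D_t − TS` are the unnormalized
graph Laplacians of the two similarity networks.  The last term is the
*dual Laplacian* regularizer: it forces the completed score matrix `X`
to vary smoothly over both graphs, which is what lets the model score
drugs or targets with **no observed interactions at all** (cold start).
Predictions are read off by sorting the entries of `X` in descending
order.

The problem is solved by an inexact augmented-Lagrange-multiplier (ALM)
scheme with two variable splits: the nuclear-norm block is a singular
value thresholding (SVT) step, the fidelity block is an elementwise
closed form, and the primal block is a Sylvester equation solved in the
eigenbasis of the two Laplacians.  Every block solve is exact, so the
augmented Lagrangian is monotone within each iteration.

The package is a library first (`import dlgrmc`), with short narrative
scripts under `examples/` and a thin `dlgrmc` command-line wrapper
(`simulate | stats | fit | predict | cv | similarity`).

## What is included

- `dlgrmc.datasets` — typed containers and TSV dialects for interaction
  and similarity matrices; summary statistics (sparsity, interactions
  per drug/target).
- `dlgrmc.similarity` — Jaccard similarity over substructure sets and
  normalized Smith–Waterman similarity over protein sequences
  (`SW(g,g′)/√(SW(g,g)·SW(g′,g′))`, BLOSUM62, gap open 10 / extend 1).
- `dlgrmc.graph` — Laplacian construction, optional kNN sparsification
  and Gaussian re-weighting.
- `dlgrmc.solver` — the ALM solver, plus a plain equality-constrained
  SVT completion baseline.
- `dlgrmc.evaluation` — 5×10-fold cross-validation with pair (cv1),
  drug (cv2) or target (cv3) blinding; PR curves and AUPR.
- `dlgrmc.synthetic` — a generator of graph-smooth low-rank synthetic
  DTI datasets with known ground truth, and a paired λ-ablation
  experiment.

## Worked example

`examples/02_cross_validation.py` blinds whole target columns (10-fold,
new-target scenario) on a 54×26 synthetic dataset with 90 interactions
and compares the grid-tuned Laplacian weight with the λ = 0 ablation:

```
tuned Laplacian weight: lambda = 0.001
AUPR with dual Laplacian regularization: 0.0820
AUPR with lambda = 0 (ablation):        0.0740
difference: +0.0080
```

With λ = 0 a blinded target column receives no signal (its scores are
all zero), so its AUPR contribution is the positive prevalence
(≈ 0.064 here); the positive gap is the contribution of the similarity
graphs.  Averaged over five generator seeds the gap is larger (≈ 0.16
vs ≈ 0.07, see the reproduction script below) — a single seed is shown
here for speed.

`examples/04_dataset_statistics.py` reproduces the derivable summary
cells of the five standard benchmark datasets from their published
counts, e.g. for the nuclear-receptor set (54 drugs, 26 targets, 90
interactions): sparsity 93.59 %, 3.46 drugs per target, 1.67 targets
per drug.

## Notes

- On the real benchmark datasets, the canonical inputs are the
  published similarity files; computing them from raw SMILES/graphs
  (SIMCOMP) is out of scope, but the printed set-overlap formula is
  available for caller-supplied fingerprint sets.
- See `docs/methods.md` for the model, solver and design details.
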