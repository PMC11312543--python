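# Methods

## Model and fitting algorithm

Given condition-wise matrices `X_i ∈ ℝ^{J_i × K}` (cells × genes), Pf2
minimizes `Σ_i ‖X_i − P_i B diag(a_i) Cᵀ‖²_F` subject to `P_iᵀP_i = I`.
The fit uses the direct alternating scheme:

1. **Projection update.** For fixed factors, each `P_i` has a closed-form
   orthogonal-Procrustes solution: with `M_i = B diag(a_i) Cᵀ`, the thin
   SVD `X_i M_iᵀ = U Σ Vᵀ` gives `P_i = U Vᵀ`. This is the exact minimizer
   over column-orthonormal matrices.
2. **Factor update.** Because the `P_i` are orthonormal, the objective
   equals `Σ_i ‖P_iᵀX_i − B diag(a_i) Cᵀ‖²_F` plus a constant, i.e. a CP
   decomposition of the aligned I × R × K tensor with slices `P_iᵀX_i`.
   We run 20 CP-ALS sweeps per outer iteration, warm-started from the
   previous iteration's factors. Normal equations are solved by Cholesky;
   a rank-deficient Gram matrix falls back to the pseudoinverse.

Both steps decrease the objective, so the R2X sequence
(`1 − Σ‖X_i − X̂_i‖² / Σ‖X_i‖²`) is non-decreasing. The outer loop stops
when the absolute change in R2X between iterations falls below `1e-6` or
after 200 iterations (both configurable). The residual is evaluated in the
projected domain (`‖X‖² − 2⟨P_iᵀX_i, M_i⟩ + ‖M‖²`), so no cell-scale
reconstruction is ever materialized during fitting; the cost per iteration
is dominated by I thin SVDs of J_i × R matrices and the CP sweeps on the
small aligned tensor.

**Initialization.** The concatenated (Σ J_i) × K matrix is decomposed by
SVD (exact, or seeded randomized SVD with oversampling 10 and 2 power
iterations for large data); the first R right singular vectors initialize
the gene factors C. B starts as the identity and A as all ones, and the
projections are computed on the first iteration. The published description
of this initialization assigns the singular vectors to B and the identity
to C, which is not shape-consistent (right singular vectors of a
cells × genes matrix are K-dimensional while B is R × R); we use the only
shape-consistent reading.

**Acceleration.** An optional Nesterov-like extrapolation treats the three
factor matrices jointly: after each outer iteration, the extrapolated
point `F + β(F − F_prev)` is evaluated (with its own Procrustes update);
if it improves the objective it is accepted and β grows by γ = 1.1 (capped
by a running bound that itself grows by γ̄ = 1.03 from β̄₀ = 1), otherwise
it is rejected and β shrinks by η = 1.5, starting from β₀ = 0.05. The
reject rule preserves ALS monotonicity. Every correctness property is also
tested with acceleration off.

**Degenerate inputs.** An all-zero `M_i X_iᵀ` makes the Procrustes
subproblem arbitrary; we raise rather than return an arbitrary basis,
since silently arbitrary projections would poison downstream factors.
All-zero datasets are rejected (R2X undefined). Ranks above
`min(K, min_i J_i)` are rejected up front.

## Preprocessing

From raw counts, in order: (1) remove genes whose mean raw expression
pooled over all cells is below `min_gene_mean` (default 0.01; 0.1 suits
cohort-scale data where even rare genes clear the lower bar); (2) CPM
per cell (rows scaled to 1e6); (3) per-gene scaling — each gene column is
divided by its pooled total and multiplied by the total cell count, so a
uniformly expressed gene keeps unit scale (the scaling is a switchable
config flag, `do_gene_sum_scale`); (4) the variance-stabilizing transform
`g(y) = ln(y + 100)` — the large pseudocount keeps the transform nearly
linear at low counts while compressing high ones; (5) per-gene
mean-centering pooled across all cells. Centering is pooled rather than
per-condition deliberately: per-condition centering would remove exactly
the condition-level differences that the condition factors A exist to
capture. Zero-count cells are an error (CPM is undefined), not silently
dropped — upstream QC owns that decision. Natural log is used; centering
absorbs any constant factor a different base would introduce.

## Standardization conventions

A CP-type factorization is unique only up to component scale, paired sign
flips, and order. `standardize` fixes all three: every factor column is
divided by its Euclidean norm and the product of the three norms is stored
as the component's weight; signs are flipped so the condition and
eigen-state columns have nonnegative means, with compensating flips
applied to the gene column (two flips cancel there, one lands there); and
components are sorted by ascending Gini coefficient
(`Σ_jk |v_j − v_k| / (2 n Σ v_j)` on absolute values) of the condition
column, so components shared across conditions come first and
condition-specific ones last. Gini uses absolute loadings because
condition factors may be negative; ties keep the original index order for
determinism. Reconstruction is preserved to machine precision and the
operation is idempotent. The applied permutation is recorded in
`component_order` so planted or previously numbered components can be
traced through the reordering.

## Factor Match Score

Two factorizations are compared on their condition (A) and gene (C)
factors only — the eigen-state factors describe different cells in any
two datasets and are excluded. Components are matched one-to-one by
linear sum assignment maximizing the total score; a matched pair (r, s)
contributes

```
(1 − |w_r − w_s| / max(w_r, w_s)) · |cos(A_r, A_s)| · |cos(C_r, C_s)|
```

and the mean over the R matched pairs is reported, so self-similarity is
exactly 1. Two choices here deserve justification:

- **Relative weights.** The per-component weights (products of factor
  column norms) are normalized to proportions within each decomposition
  before comparison. The absolute scale of a factorization grows with the
  number of cells, so raw weights would cap the FMS between a full fit
  and a half-subsample fit near √½ ≈ 0.71 even when the factors are
  identical — a size artifact, not instability.
- **Absolute cosines.** With B excluded, a component's (A, C) pair is
  only defined up to sign: flipping an eigen-state column compensates a
  flip of either, and the shared frame carries a left-orthogonal
  indeterminacy (`P_i → P_iQ`, `B → QᵀB`) that no column-wise sign
  convention on B can pin down across independent fits. Signed cosines
  would therefore randomly contribute −1 for perfectly recovered
  components; absolute cosines are the frame-invariant choice. The null
  scale remains low (mean FMS ≈ 0.14 between independent fits of pure
  noise at rank 3).

## Stability protocols and abundance experiments

Two resampling protocols probe robustness. *Subsample*: the full dataset
is fitted once, then refitted on per-condition subsamples of
`⌈fraction · J_i⌉` cells (without replacement, preserving cell order) and
compared by FMS at a fixed rank. *Bootstrap*: per rank, the original fit
is compared against a fit of one same-size with-replacement resample.
Resampling is per-condition so no condition is ever emptied, and all
draws are seeded.

The ablation experiment removes (or thins to `keep_fraction`) a labeled
cell type within a single condition, refits, matches components between
the reference and ablated fits via the FMS assignment (requiring
gene-factor cosine ≥ 0.5 for a trustworthy match), and reports the
per-condition change in the matched component's condition weights. On
data where a labeled block drives a component, the ablated condition
shows the largest positive weight drop.

## Synthetic data generator

The generator draws condition factors from a chosen law (uniform(0.05, 1),
lognormal(0, 0.5), or block-structured where each component concentrates
on a subset of conditions), a near-identity eigen-state matrix
`B = I + 0.1·N(0,1)` (a random dense option exists as a stress mode),
orthonormalized Gaussian gene factors, and random column-orthonormal
projections, then forms `X_i = P_i B diag(a_i) Cᵀ + σ·ε` with i.i.d.
Gaussian noise. Labeled cell blocks elevate the block cells' projection
rows on a chosen component (and suppress everyone else's) before
re-orthonormalization by polar decomposition, which preserves the row
pattern; planted components get condition weights bounded away from zero
so abundance changes are detectable everywhere. Ground truth is returned
standardized. `calibrate_noise_sd` converts a desired noise variance
share into σ by measuring the signal's root-mean-square entry under the
same seed.

What the generator does *not* emulate: count statistics (negative
binomial dispersion, dropout), batch effects, or doublets. It targets the
Pf2 model class itself, so passing tests demonstrate correct and stable
recovery of planted low-rank structure — not robustness to sequencing
noise, which enters real analyses through the preprocessing pipeline.

Default problem sizes (8 conditions, 40–80 cells each, 50 genes, rank 3)
keep every fit under a second; the stability experiments use 150–250
cells per condition, about a three-fold scale-down of the per-condition
cell counts of a typical perturbation panel, because subsample-FMS at
very small cell counts is dominated by finite-sample weight fluctuation
rather than method stability.

## Association workflow

Condition factors are z-scored per column (penalized coefficients are
scale-sensitive) and fed to an L1-penalized logistic regression (SAGA
solver, tolerance 1e-4, iteration cap 10,000). Cross-validation is
leave-one-batch-out in the training direction: the model trains on the
conditions of one processing batch and predicts all remaining batches
pooled; folds whose training labels are single-class are skipped with a
warning. The inverse regularization strength is chosen from 10
log-spaced values on [1e-3, 1e2] by the same CV, maximizing pooled
ROC-AUC over concatenated held-out predictions. The pairwise component
scan fits unpenalized models on every component pair under the same CV,
and the rank-selection curve refits Pf2 at each candidate rank and
reports the pooled AUC, the basis for choosing R.

## Known limitations

- The CP step assumes the aligned tensor fits in memory (I × R × K — small
  by construction); the raw data may be sparse and is only densified
  per-condition where required.
- Pf2's per-condition rotations make its model class strictly larger than
  a plain CP on a conforming tensor; equality of converged fits holds
  exactly only for data generated with a shared frame (this limit is
  tested on noiseless shared-frame data).
- No non-negativity or coupling constraints; no batch correction; no
  doublet detection or highly-variable-gene selection — those belong
  upstream.
- Randomized SVD makes initialization (and hence the fit path) depend on
  the seed; exact SVD gives bit-reproducible fits.
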