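"""Fit Pf2 to a synthetic multi-condition dataset with known structure.

Generates a ragged dataset (8 conditions, 40-80 cells each, 50 genes)
from planted rank-3 factors, fits the model at the true rank, and checks
the recovery with R2X and the Factor Match Score against ground truth.
"""

import pf2sc as p

spec = p.SyntheticSpec(
    n_conditions=8, cells_per_condition=(40, 80), n_genes=50, rank=3, seed=0
)
ds, truth = p.make_synthetic(spec)
print(f"dataset: {ds.n_conditions} conditions, {ds.n_cells} cells, "
      f"{ds.n_genes} genes, cells/condition = {[int(j) for j in ds.cell_counts]}")

dec = p.fit(ds, p.FitConfig(rank=3, seed=0))
print(f"fit: R2X = {dec.r2x:.6f} after {dec.n_iterations} iterations "
      f"(converged = {dec.converged})")

std = p.standardize(dec)
print(f"component weights: {std.component_weights.round(3)}")
print(f"FMS(fit, truth) = {p.fms(std, truth):.4f}")
print("R2X near 1 means the model explains almost all variance; "
      "FMS near 1 means the planted condition and gene factors were recovered.")
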