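"""Normalization pipeline from raw counts to the matrices Pf2 consumes.

Steps, in order: (1) drop genes with low mean raw expression pooled over
all cells; (2) counts-per-million per cell; (3) per-gene scaling by the
gene's pooled total; (4) variance-stabilizing log transform
``g(y) = log(y + c)`` with a large pseudocount (a Delta-method choice that
keeps the transform approximately linear for low counts); (5) per-gene
mean-centering pooled across all cells.

Centering is pooled rather than per-condition on purpose: per-condition
centering would remove exactly the condition-level signal the condition
factors are meant to capture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data_model import RaggedDataset
from .errors import ValidationError

__all__ = ["PreprocessConfig", "filter_genes", "normalize", "preprocess"]


@dataclass
class PreprocessConfig:
    """Parameters of the normalization pipeline.

    min_gene_mean
        Genes with pooled mean raw expression below this are removed
        (0.01 suits droplet panels of ~10^4 cells; 0.1 for very large
        cohorts where even rare genes clear 0.01).
    cpm_scale
        Per-cell target sum (1e6 = counts per million).
    log_pseudocount
        The ``c`` in ``log(y + c)``.
    do_gene_sum_scale
        Apply the per-gene pooled-sum scaling step.
    do_center
        Apply pooled per-gene mean-centering.
    """

    min_gene_mean: float = 0.01
    cpm_scale: float = 1e6
    log_pseudocount: float = 100.0
    do_gene_sum_scale: bool = True
    do_center: bool = True

    def __post_init__(self):
        if self.cpm_scale <= 0:
            raise ValidationError("cpm_scale must be positive")
        if self.log_pseudocount <= 0:
            raise ValidationError("log_pseudocount must be positive")
        if self.min_gene_mean < 0:
            raise ValidationError("min_gene_mean must be nonnegative")


def _pooled_gene_sums(ds: RaggedDataset) -> np.ndarray:
    total = np.zeros(ds.n_genes)
    for X in ds.matrices:
        if sp.issparse(X):
            total += np.asarray(X.sum(axis=0)).ravel()
        else:
            total += np.asarray(X).sum(axis=0)
    return total


def filter_genes(ds: RaggedDataset, min_gene_mean: float) -> RaggedDataset:
    """Drop genes whose mean raw value across ALL cells is below threshold.

    The mean pools cells over every condition, so rare genes are not
    rescued by a single small condition. Idempotent at a fixed threshold.
    """
    means = _pooled_gene_sums(ds) / ds.n_cells
    keep = means >= min_gene_mean
    if not keep.any():
        raise ValidationError(
            f"gene filter at mean >= {min_gene_mean} would remove all genes "
            f"(max gene mean is {means.max():.4g})"
        )
    if keep.all():
        return ds.copy()
    kept_idx = np.flatnonzero(keep)
    return RaggedDataset(
        matrices=[X[:, kept_idx] for X in ds.matrices],
        condition_ids=list(ds.condition_ids),
        gene_ids=[ds.gene_ids[j] for j in kept_idx],
        cell_labels=None
        if ds.cell_labels is None
        else [np.asarray(l).copy() for l in ds.cell_labels],
        condition_meta=None if ds.condition_meta is None else ds.condition_meta.copy(),
    )


def normalize(ds: RaggedDataset, cfg: PreprocessConfig | None = None) -> RaggedDataset:
    """CPM -> gene-sum scaling -> log(y + c) -> pooled mean-centering.

    The gene-sum scaling divides each gene column by its pooled total and
    multiplies by the total cell count, so a gene expressed uniformly at
    one CPM unit per cell keeps unit scale. Genes with zero pooled total
    (possible only when no filter preceded) are left unscaled.

    Output matrices are dense float64: the log transform and centering
    destroy sparsity.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    dense = ds.dense_matrices()

    # per-cell CPM
    for i, X in enumerate(dense):
        rowsum = X.sum(axis=1)
        zero = np.flatnonzero(rowsum == 0)
        if zero.size:
            raise ValidationError(
                f"condition {ds.condition_ids[i]!r}: cell(s) at row(s) "
                f"{zero[:5].tolist()} have zero total count; remove them upstream"
            )
        dense[i] = X * (cfg.cpm_scale / rowsum)[:, None]

    if cfg.do_gene_sum_scale:
        gene_tot = np.sum([X.sum(axis=0) for X in dense], axis=0)
        scale = np.ones_like(gene_tot)
        nz = gene_tot > 0
        scale[nz] = ds.n_cells / gene_tot[nz]
        dense = [X * scale[None, :] for X in dense]

    dense = [np.log(X + cfg.log_pseudocount) for X in dense]

    if cfg.do_center:
        gene_mean = np.sum([X.sum(axis=0) for X in dense], axis=0) / ds.n_cells
        dense = [X - gene_mean[None, :] for X in dense]

    return RaggedDataset(
        matrices=dense,
        condition_ids=list(ds.condition_ids),
        gene_ids=list(ds.gene_ids),
        cell_labels=None
        if ds.cell_labels is None
        else [np.asarray(l).copy() for l in ds.cell_labels],
        condition_meta=None if ds.condition_meta is None else ds.condition_meta.copy(),
    )


def preprocess(ds: RaggedDataset, cfg: PreprocessConfig | None = None) -> RaggedDataset:
    """Full pipeline: :func:`filter_genes` then :func:`normalize`."""
    if cfg is None:
        cfg = PreprocessConfig()
    return normalize(filter_genes(ds, cfg.min_gene_mean), cfg)
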