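"""Containers for ragged multi-condition expression data and Pf2 factors.

A multi-condition single-cell experiment measures a different set of cells
for every condition, so the data cannot be arranged as a single tensor.
:class:`RaggedDataset` holds one cells x genes matrix per condition, all
sharing the gene axis; :class:`Pf2Decomposition` holds the factor matrices
and per-condition orthonormal projections produced by the PARAFAC2 fit.

I/O goes through the field's standard formats: AnnData/h5ad for datasets,
an HDF5 group layout for factor bundles, Matrix Market + TSV annotation
bundles for sparse inputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, FormatError, ValidationError

__all__ = [
    "RaggedDataset",
    "Pf2Decomposition",
    "read_dataset",
    "write_dataset",
    "read_decomposition",
    "write_decomposition",
    "concatenated_projections",
    "export_factors_csv",
]


def _is_sparse(x) -> bool:
    return sp.issparse(x)


@dataclass
class RaggedDataset:
    """Ordered collection of condition-wise cell x gene matrices.

    Parameters
    ----------
    matrices
        One matrix per condition, shape ``(J_i, K)``; dense ndarray or
        scipy sparse. All matrices share the gene axis (columns).
    condition_ids
        Unique condition identifiers, one per matrix, in dataset order.
    gene_ids
        Gene identifiers matching the shared column order.
    cell_labels
        Optional per-condition arrays of per-cell categorical labels
        (e.g. cell types), each of length ``J_i``, in matrix row order.
    condition_meta
        Optional table keyed by ``condition_id`` (disease status,
        processing batch, ...).
    """

    matrices: list
    condition_ids: list[str]
    gene_ids: list[str]
    cell_labels: list[np.ndarray] | None = None
    condition_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if len(self.matrices) != len(self.condition_ids):
            raise ValidationError("one condition_id per matrix is required")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValidationError("condition_ids must be unique")
        K = len(self.gene_ids)
        for cid, X in zip(self.condition_ids, self.matrices):
            if X.ndim != 2 or X.shape[1] != K:
                raise ValidationError(
                    f"condition {cid!r}: matrix has {X.shape[1]} columns, "
                    f"expected {K} genes"
                )
            if X.shape[0] < 1:
                raise ValidationError(f"condition {cid!r} has no cells")
        if self.cell_labels is not None:
            if len(self.cell_labels) != len(self.matrices):
                raise ValidationError("cell_labels must have one array per condition")
            for cid, X, lab in zip(self.condition_ids, self.matrices, self.cell_labels):
                if len(lab) != X.shape[0]:
                    raise ValidationError(
                        f"condition {cid!r}: {len(lab)} labels for {X.shape[0]} cells"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_conditions(self) -> int:
        return len(self.matrices)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def cell_counts(self) -> np.ndarray:
        return np.array([X.shape[0] for X in self.matrices])

    @property
    def n_cells(self) -> int:
        return int(self.cell_counts.sum())

    def condition_index(self, condition_id: str) -> int:
        try:
            return self.condition_ids.index(condition_id)
        except ValueError:
            raise ValidationError(f"unknown condition {condition_id!r}") from None

    def dense_matrices(self) -> list[np.ndarray]:
        """Matrices as dense float64 arrays (copies only when needed)."""
        return [
            np.asarray(X.todense()) if _is_sparse(X) else np.asarray(X, dtype=float)
            for X in self.matrices
        ]

    def all_cell_labels(self) -> np.ndarray | None:
        if self.cell_labels is None:
            return None
        return np.concatenate([np.asarray(l) for l in self.cell_labels])

    def copy(self) -> "RaggedDataset":
        return RaggedDataset(
            matrices=[X.copy() for X in self.matrices],
            condition_ids=list(self.condition_ids),
            gene_ids=list(self.gene_ids),
            cell_labels=None
            if self.cell_labels is None
            else [np.asarray(l).copy() for l in self.cell_labels],
            condition_meta=None
            if self.condition_meta is None
            else self.condition_meta.copy(),
        )


@dataclass
class Pf2Decomposition:
    """PARAFAC2 factor set for a ragged dataset.

    The model is ``X_i ~ P_i B diag(a_i) C^T`` where ``a_i`` is row *i* of
    the condition factors ``A`` (I x R), ``B`` (R x R) holds the cell
    eigen-state factors, ``C`` (K x R) the gene factors and ``P_i``
    (J_i x R) is a column-orthonormal projection aligning condition *i*'s
    cells to the shared eigen-state frame.

    ``component_weights`` carries the per-component scale extracted when
    the factors are standardized to unit column norm; it is all ones for a
    freshly fitted (unstandardized) decomposition.
    """

    rank: int
    condition_factors: np.ndarray
    eigenstate_factors: np.ndarray
    gene_factors: np.ndarray
    projections: list | None = None
    component_weights: np.ndarray | None = None
    r2x: float | None = None
    n_iterations: int = 0
    converged: bool = False
    standardized: bool = False
    condition_ids: list[str] | None = None
    gene_ids: list[str] | None = None
    r2x_history: list[float] = field(default_factory=list)
    # permutation applied by standardization: output component j was
    # component component_order[j] before reordering
    component_order: np.ndarray | None = None

    def __post_init__(self):
        if self.component_weights is None:
            self.component_weights = np.ones(self.rank)
        A, B, C = self.condition_factors, self.eigenstate_factors, self.gene_factors
        R = self.rank
        if A.shape[1] != R or B.shape != (R, R) or C.shape[1] != R:
            raise ValidationError("factor matrix shapes inconsistent with rank")

    @property
    def n_conditions(self) -> int:
        return self.condition_factors.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gene_factors.shape[0]

    def copy(self) -> "Pf2Decomposition":
        return Pf2Decomposition(
            rank=self.rank,
            condition_factors=self.condition_factors.copy(),
            eigenstate_factors=self.eigenstate_factors.copy(),
            gene_factors=self.gene_factors.copy(),
            projections=None
            if self.projections is None
            else [P.copy() for P in self.projections],
            component_weights=self.component_weights.copy(),
            r2x=self.r2x,
            n_iterations=self.n_iterations,
            converged=self.converged,
            standardized=self.standardized,
            condition_ids=None if self.condition_ids is None else list(self.condition_ids),
            gene_ids=None if self.gene_ids is None else list(self.gene_ids),
            r2x_history=list(self.r2x_history),
            component_order=None
            if self.component_order is None
            else np.asarray(self.component_order).copy(),
        )


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

LABEL_KEY = "cell_label"


def read_dataset(path, condition_key: str) -> RaggedDataset:
    """Read a multi-condition dataset from h5ad or an MTX bundle.

    ``path`` is either an h5ad file (cells x genes, with ``condition_key``
    in ``.obs``) or a directory holding ``matrix.mtx`` (cells x genes),
    ``genes.tsv`` (one gene id per line, first column) and ``cells.tsv``
    (TSV with a header containing ``condition_key``).

    Conditions are ordered by first appearance in the file; cells keep
    file order within each condition.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_bundle(path, condition_key)
    import anndata as ad

    adata = ad.read_h5ad(path)
    if condition_key not in adata.obs.columns:
        raise ConfigurationError(
            f"condition key {condition_key!r} not found in cell metadata "
            f"(available: {list(adata.obs.columns)})"
        )
    cond_series = adata.obs[condition_key].astype(str)
    condition_ids = list(pd.unique(cond_series))
    matrices, labels = [], []
    have_labels = LABEL_KEY in adata.obs.columns
    for cid in condition_ids:
        mask = (cond_series == cid).to_numpy()
        if mask.sum() == 0:
            raise ValidationError(f"condition {cid!r} has no cells")
        X = adata.X[mask]
        matrices.append(X.tocsr() if sp.issparse(X) else np.asarray(X))
        if have_labels:
            labels.append(adata.obs[LABEL_KEY].to_numpy()[mask].astype(str))
    meta = None
    cond_cols = [
        c
        for c in adata.obs.columns
        if c not in (condition_key, LABEL_KEY)
        and adata.obs.groupby(cond_series, observed=True)[c].nunique().max() <= 1
    ]
    if cond_cols:
        meta = (
            adata.obs.assign(**{condition_key: cond_series})
            .groupby(condition_key, observed=True, sort=False)[cond_cols]
            .first()
            .loc[condition_ids]
        )
    return RaggedDataset(
        matrices=matrices,
        condition_ids=condition_ids,
        gene_ids=list(map(str, adata.var_names)),
        cell_labels=labels if have_labels else None,
        condition_meta=meta,
    )


def _read_mtx_bundle(path: Path, condition_key: str) -> RaggedDataset:
    import scipy.io

    mtx_path = path / "matrix.mtx"
    genes_path = path / "genes.tsv"
    cells_path = path / "cells.tsv"
    for p in (mtx_path, genes_path, cells_path):
        if not p.exists():
            raise FormatError(f"MTX bundle is missing {p.name}")
    X = scipy.io.mmread(mtx_path).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(cells_path, sep="\t")
    if condition_key not in cells.columns:
        raise ConfigurationError(
            f"condition key {condition_key!r} not found in cells.tsv "
            f"(available: {list(cells.columns)})"
        )
    if X.shape[1] != len(genes):
        raise FormatError(
            f"matrix has {X.shape[1]} gene columns but genes.tsv lists {len(genes)}"
        )
    if X.shape[0] != len(cells):
        raise FormatError(
            f"matrix has {X.shape[0]} cell rows but cells.tsv lists {len(cells)}"
        )
    cond_series = cells[condition_key].astype(str)
    condition_ids = list(pd.unique(cond_series))
    matrices, labels = [], []
    have_labels = LABEL_KEY in cells.columns
    for cid in condition_ids:
        mask = (cond_series == cid).to_numpy()
        matrices.append(X[mask])
        if have_labels:
            labels.append(cells[LABEL_KEY].to_numpy()[mask].astype(str))
    return RaggedDataset(
        matrices=matrices,
        condition_ids=condition_ids,
        gene_ids=genes,
        cell_labels=labels if have_labels else None,
    )


def write_dataset(ds: RaggedDataset, path, condition_key: str = "condition") -> None:
    """Write a :class:`RaggedDataset` to an h5ad file."""
    import anndata as ad

    if any(_is_sparse(X) for X in ds.matrices):
        X = sp.vstack([sp.csr_matrix(M) for M in ds.matrices]).tocsr()
    else:
        X = np.vstack(ds.dense_matrices())
    obs = pd.DataFrame(
        {condition_key: np.repeat(ds.condition_ids, ds.cell_counts)},
        index=[f"cell{i}" for i in range(ds.n_cells)],
    )
    if ds.cell_labels is not None:
        obs[LABEL_KEY] = ds.all_cell_labels()
    if ds.condition_meta is not None:
        for col in ds.condition_meta.columns:
            obs[col] = (
                ds.condition_meta[col].reindex(obs[condition_key]).to_numpy()
            )
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=list(ds.gene_ids)))
    adata.write_h5ad(Path(path))


# ---------------------------------------------------------------------------
# Decomposition I/O
# ---------------------------------------------------------------------------


def write_decomposition(dec: Pf2Decomposition, path) -> None:
    """Persist a decomposition to an HDF5 factor bundle.

    Layout: datasets ``A``, ``B``, ``C``, ``weights`` and a ``projections``
    group with one dataset per condition, plus scalar diagnostics as root
    attributes. Read-back via :func:`read_decomposition` reproduces the
    object bit-for-bit for metadata and to float precision for values.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory {path.parent} does not exist")
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=dec.condition_factors)
        f.create_dataset("B", data=dec.eigenstate_factors)
        f.create_dataset("C", data=dec.gene_factors)
        f.create_dataset("weights", data=dec.component_weights)
        if dec.projections is not None:
            g = f.create_group("projections")
            for i, P in enumerate(dec.projections):
                g.create_dataset(str(i), data=np.asarray(P))
        f.attrs["rank"] = dec.rank
        f.attrs["n_iterations"] = dec.n_iterations
        f.attrs["converged"] = dec.converged
        f.attrs["standardized"] = dec.standardized
        if dec.r2x is not None:
            f.attrs["r2x"] = dec.r2x
        if dec.r2x_history:
            f.create_dataset("r2x_history", data=np.asarray(dec.r2x_history))
        if dec.condition_ids is not None:
            f.create_dataset(
                "condition_ids", data=np.array(dec.condition_ids, dtype="S")
            )
        if dec.gene_ids is not None:
            f.create_dataset("gene_ids", data=np.array(dec.gene_ids, dtype="S"))
        if dec.component_order is not None:
            f.create_dataset("component_order", data=np.asarray(dec.component_order))


def read_decomposition(path) -> Pf2Decomposition:
    """Read a factor bundle written by :func:`write_decomposition`."""
    with h5py.File(Path(path), "r") as f:
        projections = None
        if "projections" in f:
            g = f["projections"]
            projections = [g[str(i)][...] for i in range(len(g))]
        dec = Pf2Decomposition(
            rank=int(f.attrs["rank"]),
            condition_factors=f["A"][...],
            eigenstate_factors=f["B"][...],
            gene_factors=f["C"][...],
            projections=projections,
            component_weights=f["weights"][...],
            r2x=float(f.attrs["r2x"]) if "r2x" in f.attrs else None,
            n_iterations=int(f.attrs["n_iterations"]),
            converged=bool(f.attrs["converged"]),
            standardized=bool(f.attrs["standardized"]),
            condition_ids=[s.decode() for s in f["condition_ids"][...]]
            if "condition_ids" in f
            else None,
            gene_ids=[s.decode() for s in f["gene_ids"][...]]
            if "gene_ids" in f
            else None,
            r2x_history=list(f["r2x_history"][...]) if "r2x_history" in f else [],
            component_order=f["component_order"][...]
            if "component_order" in f
            else None,
        )
    return dec


def concatenated_projections(dec: Pf2Decomposition) -> np.ndarray:
    """Row-wise concatenation of the projections in condition order.

    This (sum J_i) x R matrix summarizes cell-to-cell variation independent
    of condition effects; it is the input handed to external embedding
    tools (e.g. PaCMAP) for visualization.
    """
    if dec.projections is None:
        raise ValidationError("decomposition has no projections")
    return np.vstack([np.asarray(P) for P in dec.projections])


def export_factors_csv(
    dec: Pf2Decomposition, prefix, min_abs_loading: float | None = None
) -> None:
    """Write condition factors (A) and gene factors (C) as CSV.

    ``min_abs_loading`` filters the gene-factor export to genes whose
    loading magnitude reaches the threshold in at least one component
    (a display filter only; stored factors are never thresholded).
    """
    prefix = str(prefix)
    comp_cols = [f"comp{r + 1}" for r in range(dec.rank)]
    idx_a = dec.condition_ids if dec.condition_ids is not None else None
    pd.DataFrame(dec.condition_factors, columns=comp_cols, index=idx_a).to_csv(
        prefix + "_A.csv", index_label="condition"
    )
    C = dec.gene_factors
    idx_c = dec.gene_ids if dec.gene_ids is not None else [str(i) for i in range(len(C))]
    dfC = pd.DataFrame(C, columns=comp_cols, index=idx_c)
    if min_abs_loading is not None:
        dfC = dfC[(dfC.abs() >= min_abs_loading).any(axis=1)]
    dfC.to_csv(prefix + "_C.csv", index_label="gene")
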