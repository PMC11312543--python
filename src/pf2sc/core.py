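"""PARAFAC2 (Pf2) fitting for ragged multi-condition data.

The model seeks

    argmin_{A,B,C,P}  sum_i || X_i - P_i B diag(a_i) C^T ||_F^2
    subject to        P_i^T P_i = I  for every i

where X_i is condition i's cells x genes matrix, A (I x R) holds the
condition factors, B (R x R) the cell eigen-state factors, C (K x R) the
gene factors and the P_i (J_i x R) are column-orthonormal projections.

Fitting alternates two exact subproblem solutions (Kiers' direct
algorithm): each P_i is the orthogonal-Procrustes minimizer given the
factors, obtained from the SVD of B diag(a_i) C^T X_i^T; the factors are
then updated by CP alternating least squares on the I x R x K tensor whose
slice i is P_i^T X_i. Both steps decrease the objective, so the fit is
monotone. An optional Nesterov-like extrapolation of the factor matrices
accelerates convergence; extrapolated steps that worsen the objective are
rejected, preserving monotonicity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .data_model import Pf2Decomposition, RaggedDataset
from .errors import NumericError, ValidationError

__all__ = [
    "FitConfig",
    "init_factors",
    "update_projections",
    "project_data",
    "cpd_als",
    "fit",
    "reconstruct",
    "r2x",
]

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Fit hyperparameters.

    ``r2x_tolerance`` stops the outer loop once successive explained
    variance changes by less than this; together with ``max_iterations``
    these are the stock termination settings for this algorithm. The
    acceleration step sizes (gamma, gamma_bar, eta, beta0, beta0_bar)
    control how aggressively the momentum coefficient grows, is capped,
    and shrinks after a rejected extrapolation.
    """

    rank: int
    max_iterations: int = 200
    r2x_tolerance: float = 1e-6
    cpd_iterations_per_step: int = 20
    accelerate: bool = True
    accel_gamma: float = 1.1
    accel_gamma_bar: float = 1.03
    accel_eta: float = 1.5
    accel_beta0: float = 0.05
    accel_beta0_bar: float = 1.0
    svd_method: str = "exact"  # or "randomized"
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValidationError("rank must be a positive integer")
        if self.svd_method not in ("exact", "randomized"):
            raise ValidationError("svd_method must be 'exact' or 'randomized'")


def _validate_rank(ds: RaggedDataset, rank: int) -> None:
    limit = min(ds.n_genes, int(ds.cell_counts.min()))
    if rank > limit:
        raise ValidationError(
            f"rank {rank} exceeds smallest condition's cell count or gene "
            f"count (limit {limit})"
        )


def init_factors(
    ds: RaggedDataset, rank: int, seed: int = 0, svd_method: str = "exact"
) -> Pf2Decomposition:
    """SVD-based initialization from the concatenated cell x gene matrix.

    All condition matrices are stacked along the cell axis; the first
    ``rank`` right singular vectors seed the gene factors C. B starts as
    the identity and A as all ones; the projections are left unset and
    computed on the first fit iteration.
    """
    _validate_rank(ds, rank)
    if any(sp.issparse(X) for X in ds.matrices):
        stacked = sp.vstack([sp.csr_matrix(X) for X in ds.matrices])
    else:
        stacked = np.vstack(ds.dense_matrices())
    if svd_method == "randomized":
        _, _, Vt = randomized_svd(
            stacked, n_components=rank, n_oversamples=10, n_iter=2, random_state=seed
        )
        C = Vt.T
    else:
        dense = stacked.toarray() if sp.issparse(stacked) else stacked
        _, _, Vt = np.linalg.svd(dense, full_matrices=False)
        C = Vt[:rank].T
    I = ds.n_conditions
    return Pf2Decomposition(
        rank=rank,
        condition_factors=np.ones((I, rank)),
        eigenstate_factors=np.eye(rank),
        gene_factors=C,
        projections=None,
        condition_ids=list(ds.condition_ids),
        gene_ids=list(ds.gene_ids),
    )


def update_projections(
    ds: RaggedDataset, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> list[np.ndarray]:
    """Orthogonal-Procrustes update of every projection matrix.

    For each condition, with M_i = B diag(a_i) C^T, the column-orthonormal
    minimizer of ||X_i - P_i M_i||_F is P_i = U V^T where U S V^T is the
    thin SVD of X_i M_i^T (equivalently V U^T from the SVD of M_i X_i^T).
    """
    R = B.shape[1]
    projections = []
    for i, X in enumerate(ds.matrices):
        if X.shape[0] < R:
            raise ValidationError(
                f"condition {ds.condition_ids[i]!r} has {X.shape[0]} cells, "
                f"fewer than rank {R}"
            )
        M = (B * A[i]) @ C.T  # R x K
        H = X @ M.T  # J_i x R; sparse @ dense gives dense
        H = np.asarray(H)
        if not np.isfinite(H).all():
            raise NumericError(f"non-finite values in projection update {i}")
        if np.linalg.norm(H) == 0.0:
            raise NumericError(
                f"degenerate Procrustes subproblem for condition "
                f"{ds.condition_ids[i]!r}: B diag(a_i) C^T X_i^T is zero"
            )
        U, _, Vt = np.linalg.svd(H, full_matrices=False)
        projections.append(U @ Vt)
    return projections


def project_data(ds: RaggedDataset, projections: list[np.ndarray]) -> np.ndarray:
    """Stack P_i^T X_i into the aligned I x R x K tensor."""
    if len(projections) != ds.n_conditions:
        raise ValidationError("one projection per condition is required")
    R = projections[0].shape[1]
    T = np.empty((ds.n_conditions, R, ds.n_genes))
    for i, (P, X) in enumerate(zip(projections, ds.matrices)):
        if P.shape[0] != X.shape[0] or P.shape[1] != R:
            raise ValidationError(f"projection {i} shape {P.shape} mismatches data")
        if sp.issparse(X):
            T[i] = np.asarray((X.T @ P).T)
        else:
            T[i] = P.T @ X
    return T


def _solve_gram(gram: np.ndarray, rhs: np.ndarray) -> tuple[np.ndarray, bool]:
    """Solve factors @ gram = rhs; fall back to pseudoinverse when singular."""
    try:
        np.linalg.cholesky(gram)  # detects rank deficiency reliably
        return np.linalg.solve(gram, rhs.T).T, False
    except np.linalg.LinAlgError:
        return rhs @ np.linalg.pinv(gram), True


def _cp_norm_sq(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> float:
    return float(np.sum((A.T @ A) * (B.T @ B) * (C.T @ C)))


def cpd_als(
    T: np.ndarray,
    rank: int,
    n_iter: int,
    init: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """CP alternating least squares on a dense third-order tensor.

    Runs ``n_iter`` sweeps from the warm start ``init`` and returns the
    updated factor matrices plus a flag set when any normal-equation
    system was rank deficient and solved by pseudoinverse. Each sweep
    solves three exact least-squares subproblems, so the fit never
    worsens.
    """
    A, B, C = (np.array(f, dtype=float) for f in init)
    if T.ndim != 3:
        raise ValidationError("tensor must be third order")
    deficient = False
    for _ in range(n_iter):
        # mode-0: A <- T_(0) (C ⊙ B) (C^T C * B^T B)^+
        mttkrp = np.einsum("irk,rj,kj->ij", T, B, C, optimize=True)
        A, flag = _solve_gram((B.T @ B) * (C.T @ C), mttkrp)
        deficient |= flag
        mttkrp = np.einsum("irk,ij,kj->rj", T, A, C, optimize=True)
        B, flag = _solve_gram((A.T @ A) * (C.T @ C), mttkrp)
        deficient |= flag
        mttkrp = np.einsum("irk,ij,rj->kj", T, A, B, optimize=True)
        C, flag = _solve_gram((A.T @ A) * (B.T @ B), mttkrp)
        deficient |= flag
    return A, B, C, deficient


def _objective_parts(
    ds: RaggedDataset,
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    total_norm_sq: float,
):
    """Projections, projected tensor and residual for the given factors.

    With orthonormal P_i the residual splits as
    ||X_i||^2 - ||P_i^T X_i||^2 + ||P_i^T X_i - M_i||^2, avoiding any
    reconstruction at cell scale.
    """
    projections = update_projections(ds, A, B, C)
    T = project_data(ds, projections)
    mttkrp = np.einsum("irk,rj,kj->ij", T, B, C, optimize=True)
    inner = float(np.sum(mttkrp * A))
    resid = total_norm_sq - 2.0 * inner + _cp_norm_sq(A, B, C)
    return projections, T, resid


def _total_norm_sq(ds: RaggedDataset) -> float:
    total = 0.0
    for X in ds.matrices:
        if sp.issparse(X):
            total += float((X.multiply(X)).sum())
        else:
            total += float(np.sum(np.asarray(X) ** 2))
    return total


def fit(ds: RaggedDataset, cfg: FitConfig) -> Pf2Decomposition:
    """Fit the Pf2 model.

    Alternates the Procrustes projection update with warm-started CP-ALS
    sweeps on the projected tensor until the explained-variance change
    drops below ``cfg.r2x_tolerance`` or ``cfg.max_iterations`` outer
    iterations elapse. Deterministic for a given (dataset, config, seed)
    when ``svd_method='exact'``.
    """
    _validate_rank(ds, cfg.rank)
    total = _total_norm_sq(ds)
    if total == 0.0:
        raise ValidationError("dataset is all-zero; the fit is undefined")

    dec0 = init_factors(ds, cfg.rank, seed=cfg.seed, svd_method=cfg.svd_method)
    A, B, C = dec0.condition_factors, dec0.eigenstate_factors, dec0.gene_factors

    beta = cfg.accel_beta0
    beta_bar = cfg.accel_beta0_bar
    prev_factors = None
    r2x_prev = -np.inf
    history: list[float] = []
    converged = False
    projections = None
    n_done = 0

    for it in range(1, cfg.max_iterations + 1):
        projections = update_projections(ds, A, B, C)
        T = project_data(ds, projections)
        A_new, B_new, C_new, _ = cpd_als(
            T, cfg.rank, cfg.cpd_iterations_per_step, init=(A, B, C)
        )
        mttkrp = np.einsum("irk,rj,kj->ij", T, B_new, C_new, optimize=True)
        resid = (
            total
            - 2.0 * float(np.sum(mttkrp * A_new))
            + _cp_norm_sq(A_new, B_new, C_new)
        )
        r2x_cur = 1.0 - resid / total

        if cfg.accelerate and prev_factors is not None:
            A_ext = A_new + beta * (A_new - prev_factors[0])
            B_ext = B_new + beta * (B_new - prev_factors[1])
            C_ext = C_new + beta * (C_new - prev_factors[2])
            try:
                proj_ext, T_ext, resid_ext = _objective_parts(
                    ds, A_ext, B_ext, C_ext, total
                )
            except NumericError:
                resid_ext = np.inf
                proj_ext = None
            if resid_ext < resid:
                A_new, B_new, C_new = A_ext, B_ext, C_ext
                projections = proj_ext
                r2x_cur = 1.0 - resid_ext / total
                beta = min(beta * cfg.accel_gamma, beta_bar)
                beta_bar *= cfg.accel_gamma_bar
            else:
                beta /= cfg.accel_eta

        if not np.isfinite(r2x_cur):
            raise NumericError(f"non-finite R2X at iteration {it}")

        prev_factors = (A, B, C)
        A, B, C = A_new, B_new, C_new
        history.append(r2x_cur)
        logger.info("iteration %d: R2X = %.8f", it, r2x_cur)
        n_done = it
        if abs(r2x_cur - r2x_prev) < cfg.r2x_tolerance:
            converged = True
            break
        r2x_prev = r2x_cur

    # final consistent state: projections for the final factors
    projections = update_projections(ds, A, B, C)
    T = project_data(ds, projections)
    mttkrp = np.einsum("irk,rj,kj->ij", T, B, C, optimize=True)
    resid = total - 2.0 * float(np.sum(mttkrp * A)) + _cp_norm_sq(A, B, C)
    return Pf2Decomposition(
        rank=cfg.rank,
        condition_factors=A,
        eigenstate_factors=B,
        gene_factors=C,
        projections=projections,
        r2x=1.0 - resid / total,
        n_iterations=n_done,
        converged=converged,
        standardized=False,
        condition_ids=list(ds.condition_ids),
        gene_ids=list(ds.gene_ids),
        r2x_history=history,
    )


def reconstruct(dec: Pf2Decomposition) -> list[np.ndarray]:
    """Per-condition model reconstruction X_hat_i = P_i B diag(a_i w) C^T.

    The component weights extracted during standardization are folded back
    in, so reconstruction is invariant to standardization.
    """
    if dec.projections is None:
        raise ValidationError("decomposition has no projections")
    A, B, C, w = (
        dec.condition_factors,
        dec.eigenstate_factors,
        dec.gene_factors,
        dec.component_weights,
    )
    return [P @ ((B * (A[i] * w)) @ C.T) for i, P in enumerate(dec.projections)]


def r2x(ds: RaggedDataset, dec: Pf2Decomposition) -> float:
    """Fraction of total squared Frobenius norm explained by the model.

    ``1 - sum_i ||X_i - X_hat_i||^2 / sum_i ||X_i||^2``; equals 1 exactly
    when the reconstruction is exact, and can be negative for a model
    worse than predicting zero.
    """
    total = _total_norm_sq(ds)
    if total == 0.0:
        raise ValidationError("R2X is undefined for all-zero data")
    recon = reconstruct(dec)
    dense = ds.dense_matrices()
    if any(X.shape != Xh.shape for X, Xh in zip(dense, recon)):
        raise ValidationError("dataset and decomposition shapes mismatch")
    resid = sum(float(np.sum((X - Xh) ** 2)) for X, Xh in zip(dense, recon))
    return 1.0 - resid / total
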