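"""Resolve CP indeterminacies into fixed reporting conventions.

A CP-type factorization is unique only up to per-component scaling, sign
flips that cancel across modes, and component order. :func:`standardize`
fixes all three: factor columns are scaled to unit norm (the scale moves
into ``component_weights``), signs are flipped so condition and
eigen-state columns average nonnegative (compensating flips go to the
gene factors), and components are ordered by ascending Gini coefficient
of the condition loadings, so broadly shared components come first and
condition-specific ones last.
"""

from __future__ import annotations

import numpy as np

from .data_model import Pf2Decomposition
from .errors import ValidationError

__all__ = ["standardize", "gini", "weighted_projections", "WeightedProjections"]


def gini(v: np.ndarray) -> float:
    """Mean-absolute-difference Gini coefficient of ``|v|``.

    ``(sum_jk |v_j - v_k|) / (2 n sum_j v_j)`` on absolute values; 0 for a
    constant vector, approaching 1 as mass concentrates in one entry.
    Scale invariant.
    """
    v = np.abs(np.asarray(v, dtype=float).ravel())
    if v.size < 1:
        raise ValidationError("gini of an empty vector is undefined")
    s = v.sum()
    if s == 0:
        raise ValidationError("gini of an all-zero vector is undefined")
    # sorted closed form of the double sum
    x = np.sort(v)
    n = x.size
    return float(np.sum((2 * np.arange(1, n + 1) - n - 1) * x) / (n * s))


def standardize(dec: Pf2Decomposition) -> Pf2Decomposition:
    """Scale, sign and order conventions; reconstruction is unchanged.

    Idempotent: a standardized decomposition passes through untouched.
    Raises on a zero-norm factor column (that component carries no
    information and cannot be scaled).
    """
    if dec.standardized:
        return dec.copy()
    out = dec.copy()
    A, B, C = out.condition_factors, out.eigenstate_factors, out.gene_factors
    w = out.component_weights.astype(float).copy()

    for r in range(out.rank):
        na = np.linalg.norm(A[:, r])
        nb = np.linalg.norm(B[:, r])
        nc = np.linalg.norm(C[:, r])
        if na == 0 or nb == 0 or nc == 0:
            raise ValidationError(f"component {r} has a zero-norm factor column")
        A[:, r] /= na
        B[:, r] /= nb
        C[:, r] /= nc
        w[r] *= na * nb * nc
        # sign: make means of the condition and eigen-state columns
        # nonnegative; both flips are compensated in the gene factors
        sa = -1.0 if A[:, r].mean() < 0 else 1.0
        sb = -1.0 if B[:, r].mean() < 0 else 1.0
        A[:, r] *= sa
        B[:, r] *= sb
        C[:, r] *= sa * sb

    ginis = np.array([gini(A[:, r]) for r in range(out.rank)])
    order = np.argsort(ginis, kind="stable")  # ties keep original index order

    out.condition_factors = A[:, order]
    out.eigenstate_factors = B[:, order]
    out.gene_factors = C[:, order]
    out.component_weights = w[order]
    out.component_order = np.asarray(order)
    out.standardized = True
    return out


class WeightedProjections:
    """Per-cell component association scores, W_i = P_i B.

    Row j of W_i scores cell j of condition i against each component;
    these are the values used to color cell embeddings by component.
    """

    def __init__(self, matrices: list[np.ndarray], condition_ids: list[str] | None):
        self.matrices = matrices
        self.condition_ids = condition_ids

    def concatenated(self) -> np.ndarray:
        return np.vstack(self.matrices)


def weighted_projections(dec: Pf2Decomposition) -> WeightedProjections:
    """Compute W_i = P_i B for every condition.

    Meaningful on a standardized decomposition, where component columns
    follow the fixed sign and order conventions.
    """
    if dec.projections is None:
        raise ValidationError("decomposition has no projections")
    B = dec.eigenstate_factors
    return WeightedProjections(
        [np.asarray(P) @ B for P in dec.projections], dec.condition_ids
    )
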