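"""Synthetic ragged datasets with planted Pf2 structure.

The generator draws ground-truth factors and per-condition orthonormal
projections, builds ``X_i = P_i B diag(a_i) C^T + noise`` with a varying
number of cells per condition, and returns both the dataset and the
ground truth in standardized form so recovered factors can be compared
by FMS without extra alignment.

Optional labeled cell blocks plant a cell-type-like structure: the
block's cells carry elevated projection rows on a chosen component, so
removing the block from a condition removes that condition's expression
of the component. This emulates cell-type abundance changes, not
sequencing noise — entries are Gaussian, not counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import Pf2Decomposition, RaggedDataset
from .errors import ValidationError
from .postprocess import standardize

__all__ = ["SyntheticSpec", "make_synthetic", "null_dataset", "calibrate_noise_sd"]


@dataclass
class SyntheticSpec:
    """Ground-truth generating conditions for one synthetic dataset.

    ``cells_per_condition`` is an inclusive ``(J_min, J_max)`` range;
    ``condition_factor_law`` is one of ``uniform`` (entries on (0, 1)),
    ``lognormal`` (heavier-tailed condition weights) or ``block`` (each
    component strongly expressed in its own subset of conditions).
    ``labeled_blocks`` lists ``(label, component_index, cell_fraction)``
    triples; ``hard_b`` swaps the near-identity eigen-state matrix for a
    random dense one as a stress mode.
    """

    n_conditions: int = 8
    cells_per_condition: tuple[int, int] = (40, 80)
    n_genes: int = 50
    rank: int = 3
    condition_factor_law: str = "uniform"
    noise_sd: float = 0.0
    labeled_blocks: list[tuple[str, int, float]] | None = None
    seed: int = 0
    hard_b: bool = False

    def __post_init__(self):
        j_min, j_max = self.cells_per_condition
        if self.rank > min(j_min, self.n_genes):
            raise ValidationError("rank must not exceed J_min or the gene count")
        if j_min < 1 or j_max < j_min:
            raise ValidationError("invalid cells_per_condition range")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.condition_factor_law not in ("uniform", "lognormal", "block"):
            raise ValidationError("unknown condition_factor_law")
        if self.labeled_blocks:
            for label, comp, frac in self.labeled_blocks:
                if not (0 <= comp < self.rank):
                    raise ValidationError(f"block {label!r}: component out of range")
                if not (0 < frac < 1):
                    raise ValidationError(f"block {label!r}: fraction must be in (0,1)")


def _orthonormal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.standard_normal((rows, cols)))
    return Q


def _polar(G: np.ndarray) -> np.ndarray:
    """Closest column-orthonormal matrix; preserves G's row structure."""
    U, _, Vt = np.linalg.svd(G, full_matrices=False)
    return U @ Vt


def _draw_condition_factors(rng, spec: SyntheticSpec) -> np.ndarray:
    I, R = spec.n_conditions, spec.rank
    if spec.condition_factor_law == "lognormal":
        A = rng.lognormal(mean=0.0, sigma=0.5, size=(I, R))
    elif spec.condition_factor_law == "block":
        A = 0.05 + 0.1 * rng.uniform(size=(I, R))
        for i in range(I):
            A[i, i % R] = 1.0 + 0.2 * rng.uniform()
    else:
        A = rng.uniform(0.05, 1.0, size=(I, R))
    if spec.labeled_blocks:
        # planted components must be expressed in every condition for
        # abundance-change experiments to have a detectable signal
        for _, comp, _ in spec.labeled_blocks:
            A[:, comp] = rng.uniform(0.6, 1.0, size=I)
    return A


def make_synthetic(spec: SyntheticSpec) -> tuple[RaggedDataset, Pf2Decomposition]:
    """Generate a dataset and its standardized ground-truth decomposition.

    Standardization reorders components by Gini coefficient; the truth's
    ``component_order`` records the permutation, so the standardized
    position of planted component ``c`` is
    ``np.flatnonzero(truth.component_order == c)[0]``.
    """
    rng = np.random.default_rng(spec.seed)
    I, K, R = spec.n_conditions, spec.n_genes, spec.rank
    j_min, j_max = spec.cells_per_condition
    J = rng.integers(j_min, j_max + 1, size=I)

    A = _draw_condition_factors(rng, spec)
    if spec.hard_b:
        B = rng.standard_normal((R, R)) + 2.0 * np.eye(R)  # keeps conditioning sane
    else:
        B = np.eye(R) + 0.1 * rng.standard_normal((R, R))
    C = _orthonormal(rng, K, R)

    projections, labels = [], []
    for i in range(I):
        G = rng.standard_normal((J[i], R))
        lab = np.array(["other"] * J[i], dtype=object)
        if spec.labeled_blocks:
            perm = rng.permutation(J[i])
            start = 0
            for label, comp, frac in spec.labeled_blocks:
                n_block = max(1, int(round(frac * J[i])))
                block = perm[start : start + n_block]
                start += n_block
                non_block = np.setdiff1d(np.arange(J[i]), block)
                G[block, comp] = 3.0 + np.abs(rng.standard_normal(block.size))
                G[non_block, comp] *= 0.05
                lab[block] = label
        projections.append(_polar(G))
        labels.append(lab.astype(str))

    matrices = []
    for i in range(I):
        X = projections[i] @ ((B * A[i]) @ C.T)
        if spec.noise_sd > 0:
            X = X + spec.noise_sd * rng.standard_normal(X.shape)
        matrices.append(X)

    condition_ids = [f"cond{i}" for i in range(I)]
    gene_ids = [f"gene{k}" for k in range(K)]
    ds = RaggedDataset(
        matrices=matrices,
        condition_ids=condition_ids,
        gene_ids=gene_ids,
        cell_labels=labels if spec.labeled_blocks else None,
    )
    truth = Pf2Decomposition(
        rank=R,
        condition_factors=A,
        eigenstate_factors=B,
        gene_factors=C,
        projections=projections,
        n_iterations=0,
        converged=True,
        condition_ids=condition_ids,
        gene_ids=gene_ids,
    )
    return ds, standardize(truth)


def calibrate_noise_sd(spec: SyntheticSpec, noise_share: float) -> float:
    """Noise level giving the requested share of total variance.

    Generates the noiseless signal under ``spec``'s own seed, measures its
    root-mean-square entry, and returns the i.i.d. noise standard
    deviation for which noise is expected to contribute ``noise_share``
    of the total sum of squares.
    """
    if not (0 <= noise_share < 1):
        raise ValidationError("noise_share must lie in [0, 1)")
    clean = SyntheticSpec(**{**spec.__dict__, "noise_sd": 0.0})
    ds, _ = make_synthetic(clean)
    total = sum(float(np.sum(np.asarray(X) ** 2)) for X in ds.matrices)
    rms = np.sqrt(total / ds.n_cells / ds.n_genes)
    return float(rms * np.sqrt(noise_share / (1.0 - noise_share)))


def null_dataset(I: int, J, K: int, seed: int = 0) -> RaggedDataset:
    """Pure i.i.d. standard-Gaussian data with no planted structure.

    ``J`` is either a fixed per-condition cell count or an inclusive
    ``(J_min, J_max)`` range. Used to calibrate the FMS null scale.
    """
    if I < 1 or K < 1:
        raise ValidationError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    if np.isscalar(J):
        counts = np.full(I, int(J))
    else:
        counts = rng.integers(J[0], J[1] + 1, size=I)
    if counts.min() < 1:
        raise ValidationError("cell counts must be positive")
    return RaggedDataset(
        matrices=[rng.standard_normal((int(j), K)) for j in counts],
        condition_ids=[f"cond{i}" for i in range(I)],
        gene_ids=[f"gene{k}" for k in range(K)],
    )
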