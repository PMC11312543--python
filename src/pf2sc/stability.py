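"""Factor Match Score and resampling-based stability protocols.

The FMS quantifies how similar two factorizations are. Components are
first matched one-to-one by a linear sum assignment that maximizes the
total matched similarity; each matched pair contributes

    (1 - |w_r - w_s| / max(w_r, w_s)) * |cos(A_r, A_s)| * |cos(C_r, C_s)|

where the w are per-component scale weights, normalized to proportions
within each decomposition (the total scale of a factorization grows with
the number of cells, so only relative component weights are comparable
across datasets of different size), and the cosines compare the
condition-factor and gene-factor columns. The eigen-state factors are
excluded: the cells they describe differ between any two datasets. With
them excluded, a component's (A, C) pair is only defined up to sign — a
flipped eigen-state column compensates either one, and the shared frame
itself carries a left-orthogonal indeterminacy (P_i -> P_i Q, B -> Q^T B)
that no column-wise sign convention on B can pin down — so the cosines
are compared in absolute value. The mean matched score over components
is reported; identical factorizations score 1.

Two stability protocols are provided: refitting on cell subsamples at a
fixed rank (how much data the factors need), and refitting one bootstrap
replicate per rank (how stable each rank is). The cell-type ablation
experiment removes or thins a labeled cell block in one condition and
asks whether the matched component's condition weight drops there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import FitConfig, fit
from .data_model import Pf2Decomposition, RaggedDataset
from .errors import MatchingError, ValidationError
from .postprocess import standardize

__all__ = [
    "fms",
    "fms_assignment",
    "subsample_cells",
    "bootstrap_cells",
    "stability_curve",
    "StabilityReport",
    "ablate_cell_type",
    "compare_condition_weights",
]


def _cos(a: np.ndarray, b: np.ndarray) -> float:
    num = float(np.dot(a, b))
    den = float(np.sqrt(np.dot(a, a) * np.dot(b, b)))
    if den == 0.0:
        raise ValidationError("zero-norm component column in FMS")
    return float(np.clip(num / den, -1.0, 1.0))


def _score_matrix(d1: Pf2Decomposition, d2: Pf2Decomposition) -> np.ndarray:
    """Pairwise component similarity between two standardized factor sets."""
    R = d1.rank
    # unit-norm columns after standardization, so the weights carry all
    # scale; compare them as within-decomposition proportions
    w1 = np.asarray(d1.component_weights, dtype=float)
    w2 = np.asarray(d2.component_weights, dtype=float)
    if w1.sum() > 0:
        w1 = w1 / w1.sum()
    if w2.sum() > 0:
        w2 = w2 / w2.sum()
    S = np.empty((R, R))
    for r in range(R):
        for s in range(R):
            wmax = max(w1[r], w2[s])
            wterm = 1.0 if wmax == 0 else 1.0 - abs(w1[r] - w2[s]) / wmax
            S[r, s] = (
                wterm
                * abs(_cos(d1.condition_factors[:, r], d2.condition_factors[:, s]))
                * abs(_cos(d1.gene_factors[:, r], d2.gene_factors[:, s]))
            )
    return S


def _as_standardized(dec: Pf2Decomposition) -> Pf2Decomposition:
    return dec if dec.standardized else standardize(dec)


def fms_assignment(
    dec1: Pf2Decomposition, dec2: Pf2Decomposition
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal component matching and per-pair scores.

    Returns ``(rows, cols, scores)`` from the linear sum assignment that
    maximizes total similarity.
    """
    if dec1.rank != dec2.rank:
        raise ValidationError(
            f"rank mismatch: {dec1.rank} vs {dec2.rank}; FMS requires equal ranks"
        )
    for ids1, ids2, what in (
        (dec1.condition_ids, dec2.condition_ids, "condition"),
        (dec1.gene_ids, dec2.gene_ids, "gene"),
    ):
        if ids1 is not None and ids2 is not None and list(ids1) != list(ids2):
            raise ValidationError(f"{what} sets differ between decompositions")
    d1, d2 = _as_standardized(dec1), _as_standardized(dec2)
    S = _score_matrix(d1, d2)
    rows, cols = linear_sum_assignment(-S)
    return rows, cols, S[rows, cols]


def fms(dec1: Pf2Decomposition, dec2: Pf2Decomposition) -> float:
    """Factor Match Score in (-inf, 1]; 1 means complete similarity."""
    _, _, scores = fms_assignment(dec1, dec2)
    return float(scores.mean())


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def _take_cells(ds: RaggedDataset, idx_per_cond: list[np.ndarray]) -> RaggedDataset:
    return RaggedDataset(
        matrices=[X[idx] for X, idx in zip(ds.matrices, idx_per_cond)],
        condition_ids=list(ds.condition_ids),
        gene_ids=list(ds.gene_ids),
        cell_labels=None
        if ds.cell_labels is None
        else [np.asarray(l)[idx] for l, idx in zip(ds.cell_labels, idx_per_cond)],
        condition_meta=None if ds.condition_meta is None else ds.condition_meta.copy(),
    )


def subsample_cells(ds: RaggedDataset, fraction: float, seed: int) -> RaggedDataset:
    """Per-condition subsample of ``ceil(fraction * J_i)`` cells.

    Sampling is without replacement and per condition, so no condition is
    ever emptied; drawn cells keep their original within-condition order.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    idx = []
    for X in ds.matrices:
        J = X.shape[0]
        n = int(np.ceil(fraction * J))
        idx.append(np.sort(rng.choice(J, size=n, replace=False)))
    return _take_cells(ds, idx)


def bootstrap_cells(ds: RaggedDataset, seed: int) -> RaggedDataset:
    """Per-condition resample with replacement to the same size."""
    rng = np.random.default_rng(seed)
    idx = [np.sort(rng.integers(0, X.shape[0], size=X.shape[0])) for X in ds.matrices]
    return _take_cells(ds, idx)


@dataclass
class StabilityReport:
    """FMS values across subsample fractions or bootstrap ranks."""

    protocol: str  # "subsample" or "bootstrap"
    levels: list  # fractions (subsample) or ranks (bootstrap)
    seeds: list[int]
    fms_values: list[float] = field(default_factory=list)
    records: list[tuple] = field(default_factory=list)  # (level, seed, fms)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.records, columns=["level", "seed", "fms"])
        df.insert(0, "protocol", self.protocol)
        return df


def stability_curve(
    ds: RaggedDataset,
    cfg: FitConfig,
    protocol: str,
    levels,
    seeds,
) -> StabilityReport:
    """Run one stability protocol over all (level, seed) pairs.

    subsample: fit the full dataset once at ``cfg.rank``, then for each
    fraction in ``levels`` and each seed fit the subsampled dataset and
    record FMS(full, subsample).

    bootstrap: for each rank in ``levels``, fit the original dataset and
    one bootstrap replicate per seed at that rank and record their FMS.
    """
    if protocol not in ("subsample", "bootstrap"):
        raise ValidationError("protocol must be 'subsample' or 'bootstrap'")
    report = StabilityReport(protocol=protocol, levels=list(levels), seeds=list(seeds))
    if protocol == "subsample":
        ref = standardize(fit(ds, cfg))
        for level in levels:
            for seed in seeds:
                try:
                    sub = subsample_cells(ds, level, seed)
                    val = fms(ref, standardize(fit(sub, cfg)))
                except Exception as exc:
                    raise type(exc)(
                        f"stability fit failed at level={level} seed={seed}: {exc}"
                    ) from exc
                report.records.append((level, seed, val))
                report.fms_values.append(val)
    else:
        for rank in levels:
            rank_cfg = FitConfig(**{**cfg.__dict__, "rank": int(rank)})
            ref = standardize(fit(ds, rank_cfg))
            for seed in seeds:
                try:
                    boot = bootstrap_cells(ds, seed)
                    val = fms(ref, standardize(fit(boot, rank_cfg)))
                except Exception as exc:
                    raise type(exc)(
                        f"stability fit failed at rank={rank} seed={seed}: {exc}"
                    ) from exc
                report.records.append((int(rank), seed, val))
                report.fms_values.append(val)
    return report


# ---------------------------------------------------------------------------
# Cell-type abundance experiments
# ---------------------------------------------------------------------------


def ablate_cell_type(
    ds: RaggedDataset,
    label: str,
    condition_id: str,
    keep_fraction: float,
    seed: int = 0,
) -> RaggedDataset:
    """Thin a labeled cell type within one condition to ``keep_fraction``.

    ``keep_fraction=0`` removes the cell type entirely from that
    condition; fractions in between keep ``ceil(keep_fraction * n)`` of
    its cells, sampled without replacement. All other cells and all other
    conditions are untouched.
    """
    if ds.cell_labels is None:
        raise ValidationError("dataset has no cell labels")
    if not (0 <= keep_fraction <= 1):
        raise ValidationError("keep_fraction must lie in [0, 1]")
    ci = ds.condition_index(condition_id)
    all_labels = {str(x) for labs in ds.cell_labels for x in labs}
    if label not in all_labels:
        raise ValidationError(f"unknown cell label {label!r}")
    rng = np.random.default_rng(seed)
    idx = []
    for i, X in enumerate(ds.matrices):
        J = X.shape[0]
        if i != ci:
            idx.append(np.arange(J))
            continue
        labs = np.asarray(ds.cell_labels[i]).astype(str)
        labeled = np.flatnonzero(labs == label)
        others = np.flatnonzero(labs != label)
        n_keep = int(np.ceil(keep_fraction * labeled.size))
        kept = (
            rng.choice(labeled, size=n_keep, replace=False)
            if n_keep < labeled.size
            else labeled
        )
        keep_idx = np.sort(np.concatenate([others, kept]))
        if keep_idx.size == 0:
            raise ValidationError(
                f"removing {label!r} would empty condition {condition_id!r}"
            )
        idx.append(keep_idx)
    return _take_cells(ds, idx)


def compare_condition_weights(
    dec_ref: Pf2Decomposition,
    dec_ablated: Pf2Decomposition,
    component: int,
    min_gene_cosine: float = 0.5,
) -> np.ndarray:
    """Per-condition weight change of one component after an ablation.

    Components of the two standardized decompositions are matched by the
    FMS assignment; the returned vector is
    ``A_ref[:, component] - A_ablated[:, matched]``, so a positive entry
    means the condition lost weight on that component. Raises
    :class:`MatchingError` when the matched gene factors are less similar
    than ``min_gene_cosine``.
    """
    if dec_ref.rank != dec_ablated.rank:
        raise ValidationError("decompositions must share the rank")
    d1, d2 = _as_standardized(dec_ref), _as_standardized(dec_ablated)
    rows, cols, _ = fms_assignment(d1, d2)
    matched = int(cols[list(rows).index(component)])
    gcos = _cos(d1.gene_factors[:, component], d2.gene_factors[:, matched])
    if gcos < min_gene_cosine:
        raise MatchingError(
            f"component {component} matches component {matched} with gene-factor "
            f"cosine {gcos:.3f} < {min_gene_cosine}; no reliable correspondence"
        )
    return d1.condition_factors[:, component] - d2.condition_factors[:, matched]
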