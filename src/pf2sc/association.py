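"""Condition-factor classification: disease association and rank selection.

The condition factors (one R-vector per condition) are the features; a
binary condition-level label (e.g. disease status) is the target. To
respect processing-batch structure, cross-validation is
leave-one-batch-out in the training direction: the model is trained on
the conditions of ONE batch and evaluated on all remaining batches
pooled. An L1 penalty keeps the coefficient vector sparse so the
informative components can be read off directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score

from .core import FitConfig, fit
from .errors import ValidationError
from .postprocess import standardize

__all__ = [
    "ClassificationResult",
    "classify_conditions",
    "pairwise_component_scan",
    "rank_selection_curve",
]

DEFAULT_PENALTY_GRID = tuple(np.logspace(-3, 2, 10))


@dataclass
class ClassificationResult:
    """Cross-validated association of condition factors with a label."""

    fold_batches: list
    fold_accuracies: list[float]
    fold_aucs: list[float]
    pooled_auc: float
    pooled_accuracy: float
    best_penalty: float
    coefficients: np.ndarray
    components_used: list[int] = field(default_factory=list)


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _lr(C: float | None, max_iter: int = 10_000, tol: float = 1e-4):
    if C is None:  # unpenalized
        return LogisticRegression(
            C=np.inf, solver="lbfgs", max_iter=max_iter, tol=tol
        )
    return LogisticRegression(
        l1_ratio=1.0, C=C, solver="saga", max_iter=max_iter, tol=tol
    )


def _folds(labels: np.ndarray, batches: np.ndarray):
    """Train-on-one-batch folds; skip folds whose training set is single-class."""
    folds = []
    for b in list(dict.fromkeys(batches)):  # first-appearance order
        train = batches == b
        test = ~train
        if len(np.unique(labels[train])) < 2 or test.sum() == 0:
            warnings.warn(f"skipping batch {b!r}: training fold is single-class")
            continue
        folds.append((b, train, test))
    return folds


def _run_cv(X: np.ndarray, y: np.ndarray, folds, C: float | None):
    """Per-fold metrics plus pooled metrics over concatenated predictions."""
    accs, aucs, all_scores, all_preds, all_true = [], [], [], [], []
    for _, train, test in folds:
        model = _lr(C).fit(X[train], y[train])
        scores = model.decision_function(X[test])
        preds = model.predict(X[test])
        accs.append(float(accuracy_score(y[test], preds)))
        if len(np.unique(y[test])) == 2:
            aucs.append(float(roc_auc_score(y[test], scores)))
        else:
            aucs.append(float("nan"))
        all_scores.append(scores)
        all_preds.append(preds)
        all_true.append(y[test])
    yt = np.concatenate(all_true)
    pooled_auc = float(roc_auc_score(yt, np.concatenate(all_scores)))
    pooled_acc = float(accuracy_score(yt, np.concatenate(all_preds)))
    return accs, aucs, pooled_auc, pooled_acc


def classify_conditions(
    A: np.ndarray,
    labels,
    batches,
    penalty_grid=None,
    standardize_features: bool = True,
    components=None,
) -> ClassificationResult:
    """L1 logistic regression of a binary label on condition factors.

    The inverse regularization strength is chosen by grid search under
    the same leave-one-batch-out scheme (train on one batch, test on the
    pooled rest), maximizing pooled ROC-AUC. The reported coefficients
    come from a final fit on all conditions at the selected strength.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(labels)
    b = np.asarray(batches)
    if A.shape[0] != y.size or y.size != b.size:
        raise ValidationError("factors, labels and batches must align per condition")
    if len(np.unique(y)) != 2:
        raise ValidationError("labels must be binary")
    if len(np.unique(b)) < 2:
        raise ValidationError("at least two batches are required")
    if components is not None:
        A = A[:, list(components)]
    X = _zscore(A) if standardize_features else A
    folds = _folds(y, b)
    if not folds:
        raise ValidationError("every fold was single-class; cannot cross-validate")
    grid = DEFAULT_PENALTY_GRID if penalty_grid is None else tuple(penalty_grid)

    best = None
    for C in grid:
        accs, aucs, pooled_auc, pooled_acc = _run_cv(X, y, folds, C)
        if best is None or pooled_auc > best[0]:
            best = (pooled_auc, pooled_acc, accs, aucs, C)
    pooled_auc, pooled_acc, accs, aucs, best_C = best
    final = _lr(best_C).fit(X, y)
    return ClassificationResult(
        fold_batches=[f[0] for f in folds],
        fold_accuracies=accs,
        fold_aucs=aucs,
        pooled_auc=pooled_auc,
        pooled_accuracy=pooled_acc,
        best_penalty=float(best_C),
        coefficients=final.coef_.ravel(),
        components_used=list(components) if components is not None else list(range(A.shape[1])),
    )


def pairwise_component_scan(A: np.ndarray, labels, batches) -> np.ndarray:
    """Pooled CV accuracy for every component pair (unpenalized model).

    Entry (r, s) uses components r and s as the only features; the
    diagonal uses the single component. Symmetric by construction.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(labels)
    b = np.asarray(batches)
    X = _zscore(A)
    folds = _folds(y, b)
    if not folds:
        raise ValidationError("every fold was single-class; cannot cross-validate")
    R = A.shape[1]
    out = np.empty((R, R))
    for r in range(R):
        for s in range(r, R):
            cols = [r] if r == s else [r, s]
            _, _, _, pooled_acc = _run_cv(X[:, cols], y, folds, None)
            out[r, s] = out[s, r] = pooled_acc
    return out


def rank_selection_curve(
    ds,
    labels,
    batches,
    ranks,
    fit_config: FitConfig | None = None,
    penalty_grid=None,
) -> dict[int, float]:
    """Pooled ROC-AUC of the condition-factor classifier at each rank.

    Fits a fresh Pf2 model per rank (all other fit settings shared),
    standardizes it, and runs :func:`classify_conditions` on the
    condition factors. The resulting AUC-vs-rank curve is the basis for
    choosing the number of components.
    """
    base = fit_config or FitConfig(rank=1)
    curve: dict[int, float] = {}
    for rank in ranks:
        cfg = FitConfig(**{**base.__dict__, "rank": int(rank)})
        dec = standardize(fit(ds, cfg))
        res = classify_conditions(
            dec.condition_factors, labels, batches, penalty_grid=penalty_grid
        )
        curve[int(rank)] = res.pooled_auc
    return curve
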