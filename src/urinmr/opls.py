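"""OPLS-DA group-separation modelling and ROC evaluation.

Orthogonal projections to latent structures split predictor variation
into one class-predictive component and components orthogonal to the
class labels.  Model quality is summarized by fitted R²Y, the
cross-validated Q² (1 - PRESS/TSS over held-out predictions with
subject-grouped folds), and a within-pair label-permutation p-value.
The selected biomarker panel is evaluated by a ROC curve over
cross-validated scores with a stratified bootstrap confidence
interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .viavc import auc_concordance, grouped_folds, paired_permutations

logger = logging.getLogger(__name__)


@dataclass
class OplsModel:
    x_mean: np.ndarray
    y_mean: float
    w_pred: np.ndarray  # predictive weights
    p_pred: np.ndarray  # predictive loadings
    q_pred: float
    t_pred: np.ndarray  # predictive scores (training)
    w_orth: list[np.ndarray] = field(default_factory=list)
    p_orth: list[np.ndarray] = field(default_factory=list)
    t_orth: list[np.ndarray] = field(default_factory=list)
    r2y: float = 0.0
    q2: float | None = None
    n_orth: int = 0
    perm_p_r2y: float | None = None
    perm_p_q2: float | None = None

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(predictive score, first orthogonal score) for new rows."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        t_o_first = Xc @ self.w_orth[0] if self.w_orth else np.zeros(len(Xc))
        for w_o, p_o in zip(self.w_orth, self.p_orth):
            t_o = Xc @ w_o
            Xc = Xc - np.outer(t_o, p_o)
        return Xc @ self.w_pred, t_o_first

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class value for new rows."""
        t, _ = self.transform(X)
        return t * self.q_pred + self.y_mean


def _fit_opls_core(X: np.ndarray, y: np.ndarray, n_orth: int) -> OplsModel:
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    w = Xc.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w < 1e-12:  # no covariance between X and y: degenerate flat model
        zeros = np.zeros(X.shape[1])
        return OplsModel(
            x_mean=x_mean, y_mean=y_mean, w_pred=zeros, p_pred=zeros,
            q_pred=0.0, t_pred=np.zeros(len(y)), r2y=0.0, n_orth=0,
        )
    w = w / norm_w
    w_orth_list, p_orth_list, t_orth_list = [], [], []
    for _ in range(n_orth):
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / norm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / (t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        w_orth_list.append(w_o)
        p_orth_list.append(p_o)
        t_orth_list.append(t_o)
    # predictive component on the deflated matrix
    w_pred = Xc.T @ yc
    w_pred = w_pred / max(np.linalg.norm(w_pred), 1e-300)
    t_pred = Xc @ w_pred
    p_pred = Xc.T @ t_pred / (t_pred @ t_pred)
    q_pred = float(yc @ t_pred / (t_pred @ t_pred))
    resid = yc - q_pred * t_pred
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    return OplsModel(
        x_mean=x_mean, y_mean=y_mean, w_pred=w_pred, p_pred=p_pred,
        q_pred=q_pred, t_pred=t_pred, w_orth=w_orth_list, p_orth=p_orth_list,
        t_orth=t_orth_list, r2y=r2y, n_orth=len(w_orth_list),
    )


def fit_opls_da(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int | str = "auto",
    cv_folds: int = 10,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> OplsModel:
    """Fit OPLS-DA with ``n_orth`` orthogonal components (or pick 0-3 by Q²).

    With ``n_orth=0`` the predictive scores equal one-component PLS1
    scores exactly.  Orthogonal score vectors are uncorrelated with y
    by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y > 0).all() or (y < 0).all():
        raise ValueError("need both classes present")
    if n_orth == "auto":
        best_q2, best_n = -np.inf, 0
        for n in range(0, 4):
            q2 = q2_cv(X, y, n_orth=n, folds=cv_folds, groups=groups, seed=seed)
            if q2 > best_q2 + 1e-12:
                best_q2, best_n = q2, n
        n_orth = best_n
    model = _fit_opls_core(X, y, int(n_orth))
    model.q2 = q2_cv(X, y, n_orth=model.n_orth, folds=cv_folds, groups=groups, seed=seed)
    return model


def q2_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_orth: int = 0,
    folds: int = 10,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> float:
    """Q² = 1 - PRESS/TSS over held-out predictions with grouped folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups) if groups is not None else np.arange(len(y))
    rng = np.random.default_rng(seed)
    fold_idx = grouped_folds(g, folds, rng)
    press = 0.0
    preds = np.empty(len(y))
    for test_idx in fold_idx:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        if (y[train] > 0).all() or (y[train] < 0).all():
            logger.warning("fold without both classes; refolding with fewer folds")
            return q2_cv(X, y, n_orth, max(2, folds - 1), groups, seed)
        model = _fit_opls_core(X[train], y[train], n_orth)
        preds[test_idx] = model.predict(X[test_idx])
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / tss


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    statistic: str = "Q2",
    n_orth: int = 0,
    n_perm: int = 1999,
    folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p for R2Y or Q²: within-subject phase swaps.

    Returns (observed statistic, p) with
    ``p = (#{permuted >= observed} + 1) / (n_perm + 1)``; the smallest
    attainable p at the default 1999 permutations is 5e-4.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups) if groups is not None else np.arange(len(y))
    rng = np.random.default_rng(seed)

    def stat(yv: np.ndarray) -> float:
        if statistic == "R2Y":
            return _fit_opls_core(X, yv, n_orth).r2y
        if statistic == "Q2":
            return q2_cv(X, yv, n_orth, folds, g, seed)
        raise ValueError(f"unknown statistic: {statistic}")

    observed = stat(y)
    flips = paired_permutations(g, n_perm, rng)
    count = 0
    for f in flips:
        if stat(y * f) >= observed - 1e-12:
            count += 1
    return observed, (count + 1.0) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# ROC

@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    accuracy: float
    degenerate: bool = False


def roc_from_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve, concordance AUC, stratified-bootstrap percentile CI, accuracy.

    Accuracy is the fraction correct at score threshold 0 (the natural
    boundary for ±1-coded balanced classes).  Constant scores yield a
    degenerate result with AUC 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    if pos.all() or not pos.any():
        raise ValueError("need both classes present")
    if np.ptp(scores) == 0:
        diag = np.array([0.0, 1.0])
        acc = float(np.mean((scores > 0) == pos))
        return RocResult(thresholds=np.array([np.inf, scores[0]]), fpr=diag, tpr=diag,
                         auc=0.5, ci95=(0.5, 0.5), accuracy=acc, degenerate=True)
    # threshold sweep over unique scores, descending
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    fpr = np.array([np.mean(scores[~pos] >= t) for t in thr])
    tpr = np.array([np.mean(scores[pos] >= t) for t in thr])
    auc = auc_concordance(scores, labels)
    rng = np.random.default_rng(seed)
    ipos, ineg = np.flatnonzero(pos), np.flatnonzero(~pos)
    boots = []
    for _ in range(n_boot):
        bp = rng.choice(ipos, size=len(ipos), replace=True)
        bn = rng.choice(ineg, size=len(ineg), replace=True)
        idx = np.concatenate([bp, bn])
        b_scores, b_labels = scores[idx], labels[idx]
        if np.ptp(b_scores) == 0:
            boots.append(0.5)
        else:
            boots.append(auc_concordance(b_scores, b_labels))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    accuracy = float(np.mean((scores > 0) == pos))
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                     ci95=(float(lo), float(hi)), accuracy=accuracy)


def cross_validated_scores(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    n_orth: int = 0,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Held-out OPLS-DA predictions per sample (never resubstitution scores)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    g = np.asarray(groups) if groups is not None else np.arange(len(y))
    rng = np.random.default_rng(seed)
    preds = np.empty(len(y))
    for test_idx in grouped_folds(g, folds, rng):
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        model = _fit_opls_core(X[train], y[train], n_orth)
        preds[test_idx] = model.predict(X[test_idx])
    return preds
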