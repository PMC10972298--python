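"""Variable Importance Analysis based on random Variable Combination (VIAVC).

Features are scored by how their inclusion changes cross-validated
PLS-LDA classification performance across random feature subsets
(binary matrix resampling).  Comparing the AUC distributions of top
subsets that contain vs lack a feature classifies it as strongly
informative, weakly informative, uninformative, or interfering;
iteratively removing the last two classes yields an F-ranked list of
survivors and a best subset chosen by double (nested) cross-validation.

The paired design is respected throughout: cross-validation folds
group both samples of a subject together, and permutation null
distributions swap phase labels within subject pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import holm_adjust

logger = logging.getLogger(__name__)

STRONG = "strongly_informative"
WEAK = "weakly_informative"
UNINFORMATIVE = "uninformative"
INTERFERING = "interfering"


@dataclass
class ViavcConfig:
    n_resamples: int = 500
    inclusion_prob: float = 0.5
    n_components: int = 2
    cv_folds: int = 10
    top_fraction: float = 1.0
    class_alpha: float = 0.05
    max_iterations: int = 20
    n_permutations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.inclusion_prob < 1:
            raise ValueError("inclusion_prob must lie in (0, 1)")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.n_resamples < 20:
            raise ValueError("n_resamples must be >= 20 (classification needs them)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class ViavcResult:
    classes: dict[str, str]
    f_ranked: list[str]
    best_subset: list[str]
    best_subset_cv_auc: float
    p_raw: dict[str, float]
    p_holm: dict[str, float]
    trace: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# building blocks

def bmr_subsets(
    p_vars: int,
    n_resamples: int = 500,
    inclusion_prob: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Binary inclusion grid (n_resamples x p_vars); rows with < 2 ones redrawn."""
    if p_vars < 2:
        raise ValueError("need at least 2 variables")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = (rng.random((n_resamples, p_vars)) < inclusion_prob).astype(np.int8)
    bad = np.flatnonzero(grid.sum(axis=1) < 2)
    while len(bad):
        grid[bad] = (rng.random((len(bad), p_vars)) < inclusion_prob).astype(np.int8)
        bad = bad[grid[bad].sum(axis=1) < 2]
    return grid


def auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pairwise concordance probability (ties count one half).

    Computed from mid-ranks: (sum of positive ranks - n1(n1+1)/2) /
    (n1 * n0), which equals the Mann-Whitney U statistic divided by
    n1 * n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels > 0
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def grouped_folds(
    groups: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample-index folds that never split a group (subject) across folds."""
    uniq = np.unique(groups)
    n_folds = min(n_folds, len(uniq))
    if n_folds < 2:
        raise ValueError("need at least 2 groups for grouped folds")
    order = rng.permutation(uniq)
    folds = []
    for chunk in np.array_split(order, n_folds):
        folds.append(np.flatnonzero(np.isin(groups, chunk)))
    return folds


def _pls1_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_components: int,
) -> np.ndarray:
    """PLS1 regression scores for the test rows (NIPALS; exact for one y)."""
    xm = X_train.mean(axis=0)
    ym = y_train.mean()
    X = X_train - xm
    y = y_train - ym
    W, P, q = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt < 1e-12:
            break
        P.append(X.T @ t / tt)
        q.append(y @ t / tt)
        W.append(w)
        X = X - np.outer(t, P[-1])
        y = y - q[-1] * t
    if not W:
        return np.zeros(len(X_test))
    Wm, Pm, qv = np.column_stack(W), np.column_stack(P), np.array(q)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return (X_test - xm) @ coef + ym


def pls_lda_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray | Sequence[int] | None = None,
    n_components: int = 2,
    folds: int | list[np.ndarray] = 10,
    groups: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Cross-validated AUC of a PLS-LDA model on the chosen variable subset.

    Per fold, a PLS1 model of the ±1 labels is fit on the training
    rows and its score (a one-dimensional discriminant axis) evaluated
    on the held-out rows; held-out scores are pooled across folds and
    AUC computed by pairwise concordance.  Folds may be passed
    explicitly (e.g. shared across many subsets) or built here,
    grouped by ``groups``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y[y != 0])) < 2 or (y > 0).all() or (y < 0).all():
        raise ValueError("need both classes present")
    cols = np.arange(X.shape[1]) if subset is None else np.asarray(list(subset), dtype=int)
    Xs = X[:, cols]
    if isinstance(folds, int):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        g = groups if groups is not None else np.arange(len(y))
        folds = grouped_folds(np.asarray(g), folds, rng)
    scores = np.empty(len(y))
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        ncomp = int(min(n_components, len(cols), len(train) - 1))
        scores[test_idx] = _pls1_predict(Xs[train], y[train], Xs[test_idx], ncomp)
    return auc_concordance(scores, y)


def classify_variables(
    inclusion: np.ndarray,
    aucs: np.ndarray,
    top_fraction: float = 1.0,
    class_alpha: float = 0.05,
) -> list[str]:
    """Four-way classification by contrast of subset-AUC distributions.

    Each variable's with-subsets vs without-subsets AUC distributions
    are compared by one-sided rank-sum tests in both directions:
    significantly higher with the variable -> strongly informative;
    higher (or tied) but not significant -> weakly informative;
    significantly lower -> interfering; otherwise uninformative.  The
    comparison uses all resampled subsets by default; ``top_fraction``
    < 1 restricts it to the best-performing fraction (a variable
    present in all or none of the restricted subsets falls back to the
    full resample set).
    """
    inclusion = np.asarray(inclusion)
    aucs = np.asarray(aucs, dtype=float)
    if len(aucs) < 20:
        raise ValueError("need at least 20 resamples to classify")
    k = max(2, int(round(top_fraction * len(aucs))))
    top = np.argsort(-aucs, kind="stable")[:k]
    classes = []
    for j in range(inclusion.shape[1]):
        mask = inclusion[top, j] == 1
        if mask.all() or not mask.any():
            logger.info("variable %d in all/none of top subsets; using full resample set", j)
            mask_full = inclusion[:, j] == 1
            if mask_full.all() or not mask_full.any():
                classes.append(UNINFORMATIVE)
                continue
            a_with, a_without = aucs[mask_full], aucs[~mask_full]
        else:
            a_with, a_without = aucs[top][mask], aucs[top][~mask]
        p_greater = stats.mannwhitneyu(a_with, a_without, alternative="greater").pvalue
        p_less = stats.mannwhitneyu(a_with, a_without, alternative="less").pvalue
        if p_greater < class_alpha:
            classes.append(STRONG)
        elif p_less < class_alpha:
            classes.append(INTERFERING)
        elif a_with.mean() >= a_without.mean():
            # ties (e.g. saturated AUC) get the benefit of the doubt
            classes.append(WEAK)
        else:
            classes.append(UNINFORMATIVE)
    return classes


# ---------------------------------------------------------------------------
# nested CV and permutation machinery

def double_cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    cols: np.ndarray,
    max_components: int,
    n_folds: int,
    rng: np.random.Generator,
) -> float:
    """Double (nested) CV AUC: outer folds estimate performance, inner folds
    pick the PLS component count."""
    outer = grouped_folds(groups, n_folds, rng)
    scores = np.empty(len(y))
    for test_idx in outer:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        inner = grouped_folds(groups[train], n_folds, rng)
        best_c, best_auc = 1, -np.inf
        for c in range(1, max_components + 1):
            inner_scores = np.empty(len(train))
            for in_test in inner:
                in_train = np.setdiff1d(np.arange(len(train)), in_test)
                ncomp = int(min(c, len(cols), len(in_train) - 1))
                inner_scores[in_test] = _pls1_predict(
                    X[train][in_train][:, cols], y[train][in_train],
                    X[train][in_test][:, cols], ncomp,
                )
            a = auc_concordance(inner_scores, y[train])
            if a > best_auc + 1e-12:
                best_c, best_auc = c, a
        ncomp = int(min(best_c, len(cols), len(train) - 1))
        scores[test_idx] = _pls1_predict(X[train][:, cols], y[train], X[test_idx][:, cols], ncomp)
    return auc_concordance(scores, y)


def _single_var_cv_scores(
    X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]
) -> np.ndarray:
    """Held-out one-component PLS scores for every variable at once.

    For a single variable PLS1 reduces to scaling the centered column
    by its training covariance with y, so the whole matrix is handled
    with vectorized operations.
    """
    out = np.empty_like(X)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        xm = X[train].mean(axis=0)
        yc = y[train] - y[train].mean()
        cov = (X[train] - xm).T @ yc
        out[test_idx] = (X[test_idx] - xm) * cov
    return out


def paired_permutations(
    groups: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Sign-flip matrix (n_perm x n_samples): each permutation swaps the phase
    labels of a random set of subjects (within-pair label permutation)."""
    uniq, inverse = np.unique(groups, return_inverse=True)
    flips = rng.integers(0, 2, size=(n_perm, len(uniq))) * 2 - 1
    return flips[:, inverse]


# ---------------------------------------------------------------------------
# the iterative procedure

def viavc_iterate(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: ViavcConfig | None = None,
) -> ViavcResult:
    """Full VIAVC: BMR -> CV AUC -> classify -> drop, iterated to a fixed point.

    Survivors are F-ranked by the mean AUC of top subsets containing
    them; the best subset is the F-ranked prefix maximizing double CV
    AUC.  Per-variable p-values come from a within-pair label
    permutation null of each survivor's single-variable CV AUC,
    Holm-corrected.
    """
    config = config or ViavcConfig()
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"v{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if Xv.shape[1] < 3:
        raise ValueError("need at least 3 variables")
    if set(np.sign(y[y != 0])) != {-1.0, 1.0}:
        raise ValueError("labels must contain both +1 and -1")

    ss = np.random.SeedSequence(config.seed)
    rng_folds, rng_bmr, rng_best, rng_perm = [np.random.default_rng(s) for s in ss.spawn(4)]
    folds = grouped_folds(groups, config.cv_folds, rng_folds)

    survivors = np.arange(Xv.shape[1])
    trace: list[dict] = []
    classes: list[str] = [WEAK] * len(survivors)
    inclusion = aucs = None
    for iteration in range(config.max_iterations):
        if len(survivors) < 3:
            break
        inclusion = bmr_subsets(len(survivors), config.n_resamples,
                                config.inclusion_prob, rng_bmr)
        aucs = np.array([
            pls_lda_cv_auc(Xv, y, subset=survivors[row == 1],
                           n_components=config.n_components, folds=folds)
            for row in inclusion
        ])
        classes = classify_variables(inclusion, aucs, config.top_fraction,
                                     config.class_alpha)
        keep = np.array([c in (STRONG, WEAK) for c in classes])
        trace.append({
            "iteration": iteration,
            "n_variables": int(len(survivors)),
            "mean_subset_auc": float(aucs.mean()),
            "best_subset_auc": float(aucs.max()),
            "n_dropped": int((~keep).sum()),
            "n_strong": int(sum(c == STRONG for c in classes)),
        })
        if keep.all():
            break
        if keep.sum() < 3:
            # keep the classification but stop dropping below the minimum
            break
        survivors = survivors[keep]
        classes = [c for c, k in zip(classes, keep) if k]

    # F-rank survivors by mean AUC of top subsets containing them
    k = max(2, int(round(config.top_fraction * len(aucs))))
    top = np.argsort(-aucs, kind="stable")[:k]
    mean_auc_with = np.full(len(survivors), -np.inf)
    for jj in range(len(survivors)):
        mask = inclusion[top, jj] == 1
        pool = aucs[top][mask] if mask.any() else aucs[inclusion[:, jj] == 1]
        if len(pool):
            mean_auc_with[jj] = float(pool.mean())
    order = np.argsort(-mean_auc_with, kind="stable")
    f_ranked_idx = survivors[order]

    # best subset: F-ranked prefix maximizing double CV AUC
    best_len, best_auc = 1, -np.inf
    for m in range(1, len(f_ranked_idx) + 1):
        a = double_cv_auc(Xv, y, groups, f_ranked_idx[:m],
                          config.n_components, config.cv_folds, rng_best)
        if a > best_auc + 1e-12:
            best_len, best_auc = m, a

    # permutation p per survivor: single-variable CV AUC under phase swaps
    sv_scores = _single_var_cv_scores(Xv[:, survivors], y, folds)
    obs = np.array([auc_concordance(sv_scores[:, j], y) for j in range(len(survivors))])
    obs = np.maximum(obs, 1 - obs)  # two-sided in direction
    flips = paired_permutations(groups, config.n_permutations, rng_perm)
    exceed = np.zeros(len(survivors))
    for f in flips:
        yp = y * f
        perm_scores = _single_var_cv_scores(Xv[:, survivors], yp, folds)
        pa = np.array([auc_concordance(perm_scores[:, j], yp) for j in range(len(survivors))])
        pa = np.maximum(pa, 1 - pa)
        exceed += pa >= obs - 1e-12
    p_raw = (exceed + 1.0) / (config.n_permutations + 1.0)
    p_holm = holm_adjust(p_raw)

    name = lambda j: names[j]  # noqa: E731
    return ViavcResult(
        classes={name(j): c for j, c in zip(survivors, classes)},
        f_ranked=[name(j) for j in f_ranked_idx],
        best_subset=[name(j) for j in f_ranked_idx[:best_len]],
        best_subset_cv_auc=float(best_auc),
        p_raw={name(j): float(p) for j, p in zip(survivors, p_raw)},
        p_holm={name(j): float(p) for j, p in zip(survivors, p_holm)},
        trace=trace,
    )
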