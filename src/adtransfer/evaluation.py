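"""Model evaluation: AUC, fixed-cutoff metrics, nested cross-validation and
maxT permutation family-wise error control.

The AUC is computed as the Mann-Whitney probability estimate
``(concordant pairs + 0.5 * tied pairs) / (n1 * n0)`` via the rank-sum
formula, so it is invariant to strictly increasing transforms of the
scores and to the class ratio.

Nested cross-validation estimates out-of-sample performance without
hyperparameter-selection optimism: an inner CV inside every outer training
set picks the grid point with the best inner AUC, the model is refit on the
outer training set and scored on the held-out outer fold; outer-fold scores
are pooled per repeat into one AUC and averaged over repeats.

Significance against chance uses a maxT permutation scheme: for every
permutation the labels of each comparison are reshuffled, all comparison
AUCs recomputed, and only the maximum is kept; each observed AUC is referred
to this null distribution of maxima, which controls the family-wise error
over all comparisons jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import (
    PenalizedLogisticModel,
    fit_elastic_net_logistic,
    fit_group_lasso_logistic,
    predict_scores,
)


# ----------------------------------------------------------------------
# AUC and cutoff metrics
# ----------------------------------------------------------------------

def _check_two_class(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    return labels, n1, n0


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted half (rank-sum form of the Mann-Whitney statistic)."""
    scores = np.asarray(scores, dtype=float)
    labels, n1, n0 = _check_two_class(labels)
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class CutoffMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float


def classification_metrics(scores: np.ndarray, labels: np.ndarray,
                           cutoff: float = 0.5) -> CutoffMetrics:
    """Confusion-matrix ratios at a fixed score cutoff; scores exactly at
    the cutoff are assigned to the more-severe (positive) class.  An empty
    predicted class leaves the corresponding predictive value undefined
    (NaN, with a warning)."""
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels, _, _ = _check_two_class(labels)
    pred = scores >= cutoff
    pos = labels == 1
    tp = int((pred & pos).sum())
    fn = int((~pred & pos).sum())
    fp = int((pred & ~pos).sum())
    tn = int((~pred & ~pos).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    if tp + fp == 0:
        warnings.warn("no positive predictions: PPV undefined")
        ppv = float("nan")
    else:
        ppv = tp / (tp + fp)
    if tn + fn == 0:
        warnings.warn("no negative predictions: NPV undefined")
        npv = float("nan")
    else:
        npv = tn / (tn + fn)
    return CutoffMetrics(sens, spec, ppv, npv)


# ----------------------------------------------------------------------
# model-spec plumbing shared by the CV routines
# ----------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Which penalty family to fit and, for the group lasso, the feature
    grouping (one group label per column of X)."""

    kind: str                       # "elastic_net" | "group_lasso"
    groups: Sequence | None = None
    feature_names: Sequence[str] | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, params: dict,
            warm_start: PenalizedLogisticModel | None = None
            ) -> PenalizedLogisticModel:
        if self.kind == "elastic_net":
            return fit_elastic_net_logistic(
                X, y, alpha=params["alpha"], lam=params["lambda"],
                feature_names=self.feature_names, warm_start=warm_start)
        if self.kind == "group_lasso":
            return fit_group_lasso_logistic(
                X, y, groups=self.groups, lam=params["lambda"],
                feature_names=self.feature_names, warm_start=warm_start)
        raise ValueError(f"unknown penalty kind {self.kind!r}")


@dataclass
class CvSpec:
    outer_folds: int = 10
    inner_folds: int = 10
    repeats: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def _splitter(n_folds: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=n_folds, shuffle=True, random_state=int(seed))


def _split_with_fallback(X, y, n_folds: int, stratified: bool, seed: int):
    """Fold index pairs; non-stratified splits that lose a class in a
    training fold fall back to stratified splitting with a warning."""
    splits = list(_splitter(n_folds, stratified, seed).split(X, y))
    if not stratified:
        for tr, _ in splits:
            if len(np.unique(y[tr])) < 2:
                warnings.warn("a fold lost a class; falling back to "
                              "stratified splitting")
                splits = list(_splitter(n_folds, True, seed).split(X, y))
                break
    return splits


def _select_best(grid: list[dict], aucs: np.ndarray) -> int:
    """Grid point with the highest CV AUC; ties go to the larger lambda
    (the sparser model)."""
    best = np.flatnonzero(aucs >= aucs.max() - 1e-12)
    lams = np.array([grid[i].get("lambda", 0.0) for i in best])
    return int(best[np.argmax(lams)])


def _grid_cv_scores(X, y, spec: ModelSpec, grid: list[dict], n_folds: int,
                    stratified: bool, seed: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold scores per grid point; returns (aucs, oof_scores)
    with oof_scores of shape (len(grid), n)."""
    splits = _split_with_fallback(X, y, n_folds, stratified, seed)
    oof = np.empty((len(grid), len(y)))
    for tr, te in splits:
        warm = None
        prev_alpha = None
        for gi, params in enumerate(grid):
            if params.get("alpha") != prev_alpha:
                warm = None
            model = spec.fit(X[tr], y[tr], params, warm_start=warm)
            warm, prev_alpha = model, params.get("alpha")
            oof[gi, te] = predict_scores(model, X[te])
    aucs = np.array([compute_auc(oof[gi], y) for gi in range(len(grid))])
    return aucs, oof


def nested_cv_evaluate(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                       grid: list[dict], cv: CvSpec) -> dict:
    """Repeated nested CV estimate of out-of-sample AUC.

    Returns a dict with ``mean_auc`` (over repeats), ``repeat_aucs`` and the
    pooled out-of-fold ``scores`` per repeat.  Fully deterministic given
    ``cv.seed``.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = np.asarray(y).astype(int)
    _, n1, n0 = _check_two_class(y)
    if min(n1, n0) < cv.outer_folds:
        raise ValueError("fewer minority-class subjects than outer folds")
    seeds = _child_seeds(cv.seed, 2 * cv.repeats).reshape(cv.repeats, 2)
    repeat_aucs = []
    repeat_scores = []
    for r in range(cv.repeats):
        outer = _split_with_fallback(X, y, cv.outer_folds, cv.stratified,
                                     seeds[r, 0])
        oof = np.empty(len(y))
        for k, (tr, te) in enumerate(outer):
            inner_aucs, _ = _grid_cv_scores(
                X[tr], y[tr], spec, grid, cv.inner_folds, cv.stratified,
                (seeds[r, 1] + k) % (2 ** 31))
            best = _select_best(grid, inner_aucs)
            model = spec.fit(X[tr], y[tr], grid[best])
            oof[te] = predict_scores(model, X[te])
        repeat_aucs.append(compute_auc(oof, y))
        repeat_scores.append(oof)
    return {"mean_auc": float(np.mean(repeat_aucs)),
            "repeat_aucs": np.array(repeat_aucs),
            "scores": np.vstack(repeat_scores)}


def tune_final_model(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
                     grid: list[dict], folds: int = 10, stratified: bool = True,
                     seed: int = 0) -> dict:
    """Single k-fold CV over the grid on the whole training cohort, refit of
    the best point (ties toward larger lambda) on all rows.

    Returns ``model``, the selected ``params``, the grid CV ``aucs`` and the
    pooled out-of-fold ``cv_scores`` of the selected point (used as the
    training-cohort score set).
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y = np.asarray(y).astype(int)
    _check_two_class(y)
    aucs, oof = _grid_cv_scores(X, y, spec, grid, folds, stratified, seed)
    best = _select_best(grid, aucs)
    model = spec.fit(X, y, grid[best])
    return {"model": model, "params": grid[best], "cv_aucs": aucs,
            "cv_auc": float(aucs[best]), "cv_scores": oof[best]}


# ----------------------------------------------------------------------
# maxT permutation FWE correction
# ----------------------------------------------------------------------

@dataclass
class PermutationNull:
    max_auc: np.ndarray
    B: int
    seed: int
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))


def _rank_auc_perm(scores: np.ndarray, labels: np.ndarray, B: int,
                   rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Observed AUC plus B label-permutation AUCs, via the rank-sum formula
    (score ranks are fixed under permutation, so each draw is one matvec)."""
    labels, n1, n0 = _check_two_class(labels)
    ranks = rankdata(np.asarray(scores, dtype=float))
    offset = n1 * (n1 + 1) / 2.0
    observed = float((ranks[labels == 1].sum() - offset) / (n1 * n0))
    perm = rng.permuted(np.tile(labels, (B, 1)), axis=1)
    null = (perm @ ranks - offset) / (n1 * n0)
    return observed, null


def maxT_permutation_fwe(comparisons: Sequence[tuple[np.ndarray, np.ndarray]],
                         B: int = 10_000, seed: int = 0,
                         return_null: bool = False):
    """Family-wise-error corrected one-sided p-values for a family of
    (scores, labels) comparisons.

    Labels are permuted independently within each comparison's subject set;
    per permutation only the maximum AUC over the family is kept.  The
    p-value of comparison *c* is ``(1 + #{b: max_b >= observed_c}) / (B+1)``
    with minimum attainable value ``1 / (B+1)``.
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    if not comparisons:
        raise ValueError("empty comparison family")
    rng = np.random.default_rng(seed)
    observed = np.empty(len(comparisons))
    nulls = np.empty((len(comparisons), B))
    for c, (scores, labels) in enumerate(comparisons):
        observed[c], nulls[c] = _rank_auc_perm(scores, labels, B, rng)
    max_auc = nulls.max(axis=0)
    p_fwe = (1 + (max_auc[None, :] >= observed[:, None]).sum(axis=1)) / (B + 1)
    if return_null:
        return p_fwe, PermutationNull(max_auc=max_auc, B=B, seed=seed,
                                      observed=observed)
    return p_fwe
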