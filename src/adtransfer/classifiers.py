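"""Penalized logistic regression producing continuous AD scores.

Two penalties are used, matching the two model families of the analysis:

* elastic net for models built on a single feature group — objective
  ``(1/n) * NLL + lambda * (alpha * ||w||_1 + (1 - alpha)/2 * ||w||_2^2)``,
  solved by cyclic coordinate descent on the iteratively reweighted
  least-squares approximation (glmnet-style), deterministic for a fixed
  feature order;
* group lasso for combined models — objective
  ``(1/n) * NLL + lambda * sum_g sqrt(|g|) * ||w_g||_2``, solved by
  proximal gradient with block soft-thresholding and backtracking line
  search, which yields exactly-zero coefficient blocks for excluded groups.

The mean (not sum) log-likelihood convention makes ``lambda`` comparable
across training sets of different size (e.g. across CV folds).  The
intercept is never penalized.  Features are standardized to zero mean and
unit SD on the fitting rows only; zero-variance features are dropped and
recorded.  Predicted probabilities are the AD scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .tables import FeatureTable

logger = logging.getLogger(__name__)

_EPS_VAR = 1e-12
_MIN_IRLS_WEIGHT = 1e-5
_ETA_CLIP = 30.0


# ----------------------------------------------------------------------
# standardization
# ----------------------------------------------------------------------

@dataclass
class StandardizationParams:
    feature_names: list[str]   # retained features, in order
    means: np.ndarray
    sds: np.ndarray
    dropped: list[str] = field(default_factory=list)
    keep_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def fit_standardization(X: np.ndarray | FeatureTable,
                        feature_names: Sequence[str] | None = None
                        ) -> StandardizationParams:
    """Per-feature mean/SD on the fitting rows; zero-variance features are
    dropped (and logged)."""
    if isinstance(X, FeatureTable):
        feature_names = X.feature_names
        X = X.matrix()
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    keep = sds > _EPS_VAR
    dropped = [n for n, k in zip(feature_names, keep) if not k]
    if dropped:
        logger.info("dropping %d zero-variance features: %s%s", len(dropped),
                    dropped[:5], "..." if len(dropped) > 5 else "")
    return StandardizationParams(
        feature_names=[n for n, k in zip(feature_names, keep) if k],
        means=means[keep], sds=sds[keep], dropped=dropped,
        keep_indices=np.flatnonzero(keep))


def apply_standardization(X: np.ndarray | FeatureTable,
                          params: StandardizationParams) -> np.ndarray:
    """Standardize (any) rows with previously fitted parameters, returning
    only the retained columns in the fitted order."""
    if isinstance(X, FeatureTable):
        missing = [n for n in params.feature_names if n not in X.values.columns]
        if missing:
            raise KeyError(f"model features missing from table: {missing[:5]}")
        X = X.values[params.feature_names].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(params.feature_names) + len(params.dropped):
            X = X[:, params.keep_indices]  # fit-time layout: drop columns
        elif X.shape[1] != len(params.feature_names):
            raise ValueError("column count matches neither fit-time nor retained layout")
    return (X - params.means) / params.sds


# ----------------------------------------------------------------------
# elastic-net coordinate descent
# ----------------------------------------------------------------------

@njit(cache=True)
def _cd_inner(X, v, r, w, q, l1, l2, n, tol, max_pass):  # pragma: no cover - jit
    """Cyclic coordinate descent on the weighted least-squares surrogate
    ``(1/2n) sum_i v_i (z_i - b - x_i.w)^2 + l1 ||w||_1 + (l2/2) ||w||_2^2``.
    ``r`` holds the working residual ``z - b - X w`` and is updated in
    place; ``q[j] = (1/n) sum_i v_i x_ij^2``.  Returns the accumulated
    intercept shift."""
    btot = 0.0
    for _ in range(max_pass):
        maxd = 0.0
        for j in range(X.shape[1]):
            wj = w[j]
            s = 0.0
            for i in range(X.shape[0]):
                s += v[i] * X[i, j] * r[i]
            rho = s / n + wj * q[j]
            if rho > l1:
                wn = (rho - l1) / (q[j] + l2)
            elif rho < -l1:
                wn = (rho + l1) / (q[j] + l2)
            else:
                wn = 0.0
            d = wn - wj
            if d != 0.0:
                for i in range(X.shape[0]):
                    r[i] -= d * X[i, j]
                w[j] = wn
                ad = abs(d)
                if ad > maxd:
                    maxd = ad
        # unpenalized intercept: weighted mean of the residual
        sv = 0.0
        sr = 0.0
        for i in range(X.shape[0]):
            sv += v[i]
            sr += v[i] * r[i]
        db = sr / sv
        btot += db
        for i in range(X.shape[0]):
            r[i] -= db
        if maxd < tol and abs(db) < tol:
            break
    return btot


def _logistic_objective(Xs: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
                        penalty: float) -> float:
    eta = np.clip(Xs @ w + b, -_ETA_CLIP, _ETA_CLIP)
    nll = np.mean(np.log1p(np.exp(eta)) - y * eta)
    return nll + penalty


def _en_penalty(w: np.ndarray, alpha: float, lam: float) -> float:
    return lam * (alpha * np.abs(w).sum() + 0.5 * (1 - alpha) * (w ** 2).sum())


def _elastic_net_solve(Xs: np.ndarray, y: np.ndarray, alpha: float, lam: float,
                       w0: np.ndarray | None = None, b0: float | None = None,
                       tol: float = 1e-7, max_iter: int = 100
                       ) -> tuple[np.ndarray, float, int, bool]:
    """IRLS outer loop around the coordinate-descent inner solver, on
    already-standardized data.  Returns (w, b, n_iter, converged)."""
    n, p = Xs.shape
    w = np.zeros(p) if w0 is None else w0.copy()
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b = float(np.log(ybar / (1 - ybar))) if b0 is None else float(b0)
    l1 = lam * alpha
    l2 = lam * (1 - alpha)
    obj = _logistic_objective(Xs, y, w, b, _en_penalty(w, alpha, lam))
    history = [obj]
    converged = False
    for it in range(max_iter):
        eta = np.clip(Xs @ w + b, -_ETA_CLIP, _ETA_CLIP)
        pr = 1.0 / (1.0 + np.exp(-eta))
        v = np.maximum(pr * (1 - pr), _MIN_IRLS_WEIGHT)
        r = (y - pr) / v  # working residual about the current (w, b)
        q = (v[:, None] * Xs ** 2).mean(axis=0)
        w_old, b_old = w.copy(), b
        b = b_old + _cd_inner(Xs, v, r, w, q, l1, l2, float(n), tol, 1000)
        new_obj = _logistic_objective(Xs, y, w, b, _en_penalty(w, alpha, lam))
        # safeguard: the IRLS step is not guaranteed monotone; halve toward
        # the previous iterate until the penalized objective does not increase
        halvings = 0
        while new_obj > obj + 1e-12 and halvings < 25:
            w = (w + w_old) / 2.0
            b = (b + b_old) / 2.0
            new_obj = _logistic_objective(Xs, y, w, b, _en_penalty(w, alpha, lam))
            halvings += 1
        if new_obj > obj + 1e-12:
            w, b, new_obj = w_old, b_old, obj
            converged = True
            break
        delta = max(np.abs(w - w_old).max(initial=0.0), abs(b - b_old))
        obj = new_obj
        history.append(obj)
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {max_iter} IRLS iterations "
            f"(lambda={lam}, alpha={alpha}); possible separation at small lambda")
    return w, b, it + 1, converged, history


# ----------------------------------------------------------------------
# group-lasso proximal gradient
# ----------------------------------------------------------------------

def _block_soft_threshold(u: np.ndarray, thresholds: np.ndarray,
                          group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    norms = np.sqrt(np.bincount(group_idx, weights=u ** 2, minlength=n_groups))
    scale = np.zeros(n_groups)
    nz = norms > 0
    scale[nz] = np.maximum(0.0, 1.0 - thresholds[nz] / norms[nz])
    return u * scale[group_idx]


def _group_penalty(w: np.ndarray, lam: float, s_g: np.ndarray,
                   group_idx: np.ndarray, n_groups: int) -> float:
    norms = np.sqrt(np.bincount(group_idx, weights=w ** 2, minlength=n_groups))
    return lam * float(s_g @ norms)


def _group_lasso_solve(Xs: np.ndarray, y: np.ndarray, group_idx: np.ndarray,
                       lam: float, w0: np.ndarray | None = None,
                       b0: float | None = None, tol: float = 1e-7,
                       max_iter: int = 5000) -> tuple[np.ndarray, float, int, bool]:
    """Monotone proximal-gradient (block soft-thresholding) solver with
    backtracking line search on standardized data."""
    n, p = Xs.shape
    n_groups = int(group_idx.max()) + 1
    sizes = np.bincount(group_idx, minlength=n_groups)
    if (sizes == 0).any():
        raise ValueError("empty feature group")
    s_g = np.sqrt(sizes.astype(float))
    w = np.zeros(p) if w0 is None else w0.copy()
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b = float(np.log(ybar / (1 - ybar))) if b0 is None else float(b0)

    def smooth(wv, bv):
        eta = np.clip(Xs @ wv + bv, -_ETA_CLIP, _ETA_CLIP)
        return float(np.mean(np.log1p(np.exp(eta)) - y * eta)), eta

    step = 1.0
    f, eta = smooth(w, b)
    history = [f + _group_penalty(w, lam, s_g, group_idx, n_groups)]
    converged = False
    for it in range(max_iter):
        pr = 1.0 / (1.0 + np.exp(-eta))
        gw = Xs.T @ (pr - y) / n
        gb = float(np.mean(pr - y))
        while True:
            u = w - step * gw
            w_new = _block_soft_threshold(u, step * lam * s_g, group_idx, n_groups)
            b_new = b - step * gb
            f_new, eta_new = smooth(w_new, b_new)
            dw = w_new - w
            db = b_new - b
            quad = f + gw @ dw + gb * db + ((dw @ dw) + db * db) / (2 * step)
            if f_new <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        delta = max(np.abs(dw).max(initial=0.0), abs(db))
        w, b, f, eta = w_new, b_new, f_new, eta_new
        history.append(f + _group_penalty(w, lam, s_g, group_idx, n_groups))
        step *= 1.25  # optimistic step growth, re-shrunk by backtracking
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"group lasso did not converge in {max_iter} iterations "
                      f"(lambda={lam})")
    return w, b, it + 1, converged, history


# ----------------------------------------------------------------------
# model container and public fitting API
# ----------------------------------------------------------------------

@dataclass
class PenalizedLogisticModel:
    penalty_kind: str                       # "elastic_net" | "group_lasso"
    weights: np.ndarray                     # per retained feature
    intercept: float
    hyperparameters: dict
    standardization: StandardizationParams
    group_of: dict[str, str] = field(default_factory=dict)  # group lasso only
    n_iter: int = 0
    converged: bool = True
    fit_cohort: str = "training"
    objective_history: list[float] = field(default_factory=list, repr=False)

    @property
    def feature_names(self) -> list[str]:
        return self.standardization.feature_names

    def group_weight_norms(self) -> dict[str, float]:
        if not self.group_of:
            raise ValueError("not a grouped model")
        out: dict[str, float] = {}
        for name, w in zip(self.feature_names, self.weights):
            g = self.group_of[name]
            out[g] = out.get(g, 0.0) + w ** 2
        return {g: float(np.sqrt(v)) for g, v in out.items()}

    # -------------------------- serialization --------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format_version": 1,
            "penalty_kind": self.penalty_kind,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "hyperparameters": self.hyperparameters,
            "standardization": {
                "feature_names": self.standardization.feature_names,
                "means": self.standardization.means.tolist(),
                "sds": self.standardization.sds.tolist(),
                "dropped": self.standardization.dropped,
                "keep_indices": self.standardization.keep_indices.tolist(),
            },
            "group_of": self.group_of,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "fit_cohort": self.fit_cohort,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PenalizedLogisticModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        sp = StandardizationParams(
            feature_names=d["standardization"]["feature_names"],
            means=np.asarray(d["standardization"]["means"]),
            sds=np.asarray(d["standardization"]["sds"]),
            dropped=d["standardization"]["dropped"],
            keep_indices=np.asarray(d["standardization"].get("keep_indices", []),
                                    dtype=int))
        return cls(penalty_kind=d["penalty_kind"],
                   weights=np.asarray(d["weights"]), intercept=d["intercept"],
                   hyperparameters=d["hyperparameters"], standardization=sp,
                   group_of=d.get("group_of", {}), n_iter=d.get("n_iter", 0),
                   converged=d.get("converged", True),
                   fit_cohort=d.get("fit_cohort", "training"))


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"outcome must be coded 0/1, got values {sorted(uniq)[:5]}")
    return y.astype(float)


def fit_elastic_net_logistic(X: np.ndarray | FeatureTable, y: np.ndarray,
                             alpha: float, lam: float,
                             feature_names: Sequence[str] | None = None,
                             tol: float = 1e-7, max_iter: int = 100,
                             warm_start: PenalizedLogisticModel | None = None,
                             ) -> PenalizedLogisticModel:
    """Fit the elastic-net logistic model; ``alpha`` mixes L1 vs L2 and
    ``lam`` scales the penalty (intercept unpenalized)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = _validate_binary(y)
    params = fit_standardization(X, feature_names)
    Xs = apply_standardization(X, params)
    w0 = b0 = None
    if warm_start is not None and warm_start.feature_names == params.feature_names:
        w0, b0 = warm_start.weights, warm_start.intercept
    w, b, n_iter, conv, hist = _elastic_net_solve(Xs, y, alpha, lam, w0=w0, b0=b0,
                                                  tol=tol, max_iter=max_iter)
    return PenalizedLogisticModel(
        penalty_kind="elastic_net", weights=w, intercept=b,
        hyperparameters={"alpha": alpha, "lambda": lam},
        standardization=params, n_iter=n_iter, converged=conv,
        objective_history=hist)


def fit_group_lasso_logistic(X: np.ndarray | FeatureTable, y: np.ndarray,
                             groups: Sequence | None = None, lam: float = 0.0,
                             feature_names: Sequence[str] | None = None,
                             tol: float = 1e-7, max_iter: int = 5000,
                             warm_start: PenalizedLogisticModel | None = None,
                             ) -> PenalizedLogisticModel:
    """Fit the group-lasso logistic model; ``groups`` assigns every feature
    to one block (taken from the table's group mapping when omitted)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    y = _validate_binary(y)
    if isinstance(X, FeatureTable):
        feature_names = X.feature_names
        if groups is None:
            groups = [X.group_of[c] for c in feature_names]
    if groups is None:
        raise ValueError("groups must be given for array input")
    groups = list(groups)
    params = fit_standardization(X, feature_names)
    Xs = apply_standardization(X, params)
    name_to_group = dict(zip(feature_names or [f"f{j}" for j in range(len(groups))],
                             groups))
    retained_groups = [name_to_group[n] for n in params.feature_names]
    order: dict = {}
    group_idx = np.array([order.setdefault(g, len(order)) for g in retained_groups],
                         dtype=np.int64)
    w0 = b0 = None
    if warm_start is not None and warm_start.feature_names == params.feature_names:
        w0, b0 = warm_start.weights, warm_start.intercept
    w, b, n_iter, conv, hist = _group_lasso_solve(Xs, y, group_idx, lam, w0=w0,
                                                  b0=b0, tol=tol, max_iter=max_iter)
    return PenalizedLogisticModel(
        penalty_kind="group_lasso", weights=w, intercept=b,
        hyperparameters={"lambda": lam},
        standardization=params,
        group_of={n: g for n, g in zip(params.feature_names, retained_groups)},
        n_iter=n_iter, converged=conv, objective_history=hist)


def predict_scores(model: PenalizedLogisticModel,
                   X: np.ndarray | FeatureTable) -> np.ndarray:
    """AD scores: logistic(intercept + standardized features . weights),
    strictly inside (0, 1).  Columns the model dropped are ignored."""
    Xs = apply_standardization(X, model.standardization)
    eta = np.clip(Xs @ model.weights + model.intercept, -_ETA_CLIP, _ETA_CLIP)
    return 1.0 / (1.0 + np.exp(-eta))


def lambda_grid_elastic_net(X: np.ndarray, y: np.ndarray, alpha: float,
                            n_lambdas: int = 15, decades: float = 4.0
                            ) -> np.ndarray:
    """Log-spaced penalty grid from the smallest lambda that zeroes every
    weight (standardized data) down ``decades`` orders of magnitude."""
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > _EPS_VAR, X.std(axis=0), 1.0)
    y = np.asarray(y, dtype=float)
    lam_max = np.abs(Xs.T @ (y - y.mean())).max() / (len(y) * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_lambdas)


def lambda_grid_group_lasso(X: np.ndarray, y: np.ndarray,
                            group_idx: np.ndarray, n_lambdas: int = 15,
                            decades: float = 4.0) -> np.ndarray:
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > _EPS_VAR, X.std(axis=0), 1.0)
    y = np.asarray(y, dtype=float)
    g = Xs.T @ (y - y.mean()) / len(y)
    n_groups = int(group_idx.max()) + 1
    norms = np.sqrt(np.bincount(group_idx, weights=g ** 2, minlength=n_groups))
    s_g = np.sqrt(np.bincount(group_idx, minlength=n_groups).astype(float))
    lam_max = float((norms / s_g).max())
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_lambdas)
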