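"""Removal of nuisance variation: normal-aging effects and scan-site effects.

Age correction fits, for every feature, an ordinary least-squares line on
the *training-cohort healthy controls only* and subtracts the fitted age
component from every subject of both cohorts, so disease-related deviation
from age-expected values is preserved while normal aging is not.

Scan-site correction within the multi-site clinic cohort uses ComBat: a
location-and-scale batch model per feature, with covariate effects (age,
sex, years of education, clinical label and MMSE by default) protected, and
empirical-Bayes shrinkage of the per-site parameters (normal prior on the
additive effect, inverse-gamma prior on the multiplicative one,
moment-matched hyperparameters, iterative conditional updates).  The two
cohorts are never harmonized against each other: their clinical composition
differs, so site and group differences would be confounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, SubjectTable, check_alignment

DEFAULT_COMBAT_COVARIATES = ("age", "sex", "education", "label", "mmse")


# ----------------------------------------------------------------------
# age residualization
# ----------------------------------------------------------------------

@dataclass
class AgeModel:
    """Per-feature linear age trend estimated on training controls."""

    feature_names: list[str]
    intercept: np.ndarray
    slope: np.ndarray
    reference_age: float


def fit_age_model(features: FeatureTable, subjects: SubjectTable,
                  control_label: str = "HC") -> AgeModel:
    """Least-squares slope and intercept of every feature on age, using
    control subjects only."""
    check_alignment(features, subjects)
    is_control = subjects.labels == control_label
    if is_control.sum() < 3:
        raise ValueError("need at least 3 control subjects to fit age effects")
    ages = subjects.ages[is_control]
    if np.unique(ages).size < 2:
        raise ValueError("zero age variance among controls")
    y = features.matrix()[is_control]
    ref = float(ages.mean())
    a = ages - ref
    slope = (a @ (y - y.mean(axis=0))) / (a @ a)
    intercept = y.mean(axis=0)  # value at the reference age
    return AgeModel(feature_names=features.feature_names, intercept=intercept,
                    slope=slope, reference_age=ref)


def apply_age_correction(features: FeatureTable, subjects: SubjectTable,
                         model: AgeModel) -> FeatureTable:
    """Subtract the control-estimated age component from every row:
    ``out_ij = x_ij - slope_j * (age_i - reference_age)``."""
    check_alignment(features, subjects)
    if features.feature_names != model.feature_names:
        raise ValueError("feature set differs between age model and table")
    centered_age = subjects.ages - model.reference_age
    corrected = features.matrix() - np.outer(centered_age, model.slope)
    return features.with_values(corrected)


# ----------------------------------------------------------------------
# ComBat
# ----------------------------------------------------------------------

@dataclass
class CombatModel:
    feature_names: list[str]
    sites: list[str]
    covariates: tuple[str, ...]
    design_columns: list[str]
    beta: np.ndarray          # covariate coefficients, (n_design, n_features)
    grand_mean: np.ndarray    # per-feature site-weighted intercept
    var_pooled: np.ndarray    # per-feature pooled residual variance
    gamma_star: np.ndarray    # (n_sites, n_features) additive site effects
    delta_star: np.ndarray    # (n_sites, n_features) multiplicative (variance)
    gamma_hat: np.ndarray
    delta_hat: np.ndarray
    # EB hyperparameters per site
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    empirical_bayes: bool = True
    label_levels: list[str] = field(default_factory=list)


def _covariate_design(subjects: SubjectTable, covariates: tuple[str, ...],
                      label_levels: list[str] | None = None
                      ) -> tuple[np.ndarray, list[str], list[str]]:
    """Numeric design matrix (no intercept column) for the protected
    covariates; categorical factors enter as drop-first indicators."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    levels = label_levels
    for cov in covariates:
        values = subjects.data[cov]
        if cov == "sex":
            cols.append((values == "male").to_numpy(dtype=float))
            names.append("sex[male]")
        elif cov == "label":
            if levels is None:
                levels = sorted(values.unique())
            for lev in levels[1:]:
                cols.append((values == lev).to_numpy(dtype=float))
                names.append(f"label[{lev}]")
        else:
            cols.append(values.to_numpy(dtype=float))
            names.append(cov)
    design = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return design, names, (levels or [])


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2 if s2 > 0 else np.inf


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2 if s2 > 0 else np.inf


def _eb_site_update(z_site: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                    g_bar: float, t2: float, a: float, b: float,
                    tol: float = 1e-6, max_iter: int = 100
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior-mode updates for one site's
    additive (normal prior) and multiplicative (inverse-gamma prior)
    effects, as in the standard parametric ComBat."""
    n = z_site.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    if not np.isfinite(t2) or not np.isfinite(a) or not np.isfinite(b):
        return g_new, d_new
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        sum2 = ((z_site - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        if change < tol:
            break
    return g_new, d_new


def fit_combat(features: FeatureTable, subjects: SubjectTable,
               covariates: tuple[str, ...] = DEFAULT_COMBAT_COVARIATES,
               empirical_bayes: bool = True) -> CombatModel:
    """Fit the location-scale batch model with protected covariates.

    Each feature is regressed on site indicators plus the covariates; data
    are standardized by the covariate-adjusted, site-size-weighted grand
    mean and pooled variance; per-site location (gamma) and scale (delta)
    estimates are then shrunk by parametric empirical Bayes (disabled with
    ``empirical_bayes=False``, in which case the apply step exactly aligns
    per-site means and variances).
    """
    check_alignment(features, subjects)
    y = features.matrix()
    n, p = y.shape
    sites = sorted(pd.unique(subjects.sites))
    site_idx = {s: np.flatnonzero(subjects.sites == s) for s in sites}
    for s, idx in site_idx.items():
        if len(idx) < 3:
            raise ValueError(f"site {s!r} has fewer than 3 subjects")
    if subjects.data[list(set(covariates) & set(subjects.data.columns))].isna().any().any():
        raise ValueError("covariates contain missing values")

    x_cov, cov_names, label_levels = _covariate_design(subjects, covariates)
    site_design = np.column_stack(
        [(subjects.sites == s).astype(float) for s in sites])
    design = np.column_stack([site_design, x_cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"singular covariate design (rank {rank} < {design.shape[1]}); "
            f"columns: {[f'site[{s}]' for s in sites] + cov_names}")

    b_full, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_effects, beta = b_full[:len(sites)], b_full[len(sites):]
    n_sites = np.array([len(site_idx[s]) for s in sites], dtype=float)
    grand_mean = (n_sites / n) @ site_effects
    resid = y - design @ b_full
    var_pooled = (resid ** 2).mean(axis=0)
    if (var_pooled == 0).any():
        bad = [features.feature_names[j] for j in np.flatnonzero(var_pooled == 0)][:5]
        raise ValueError(f"zero pooled residual variance for features {bad}")

    stand_mean = grand_mean + x_cov @ beta
    z = (y - stand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.vstack([z[idx].mean(axis=0) for idx in site_idx.values()])
    delta_hat = np.vstack([z[idx].var(axis=0, ddof=1) for idx in site_idx.values()])
    if (delta_hat == 0).any():
        raise ValueError("a site has zero residual variance for some feature")

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    a_prior = np.array([_aprior(d) for d in delta_hat])
    b_prior = np.array([_bprior(d) for d in delta_hat])

    if empirical_bayes and len(sites) > 0:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for i, idx in enumerate(site_idx.values()):
            gamma_star[i], delta_star[i] = _eb_site_update(
                z[idx], gamma_hat[i], delta_hat[i],
                gamma_bar[i], tau2[i], a_prior[i], b_prior[i])
    else:
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()

    return CombatModel(
        feature_names=features.feature_names, sites=sites,
        covariates=tuple(covariates), design_columns=cov_names, beta=beta,
        grand_mean=grand_mean, var_pooled=var_pooled,
        gamma_star=gamma_star, delta_star=delta_star,
        gamma_hat=gamma_hat, delta_hat=delta_hat,
        gamma_bar=gamma_bar, tau2=tau2, a_prior=a_prior, b_prior=b_prior,
        empirical_bayes=empirical_bayes, label_levels=label_levels)


def apply_combat(features: FeatureTable, subjects: SubjectTable,
                 model: CombatModel) -> FeatureTable:
    """Remove the fitted site effects while keeping covariate-associated
    variation: standardize, subtract gamma*, divide by sqrt(delta*), and
    restore the covariate-predicted part."""
    check_alignment(features, subjects)
    if features.feature_names != model.feature_names:
        raise ValueError("feature set differs between ComBat model and table")
    unseen = set(subjects.sites) - set(model.sites)
    if unseen:
        raise ValueError(f"sites not present at fit time: {sorted(unseen)}")
    y = features.matrix()
    x_cov, _, _ = _covariate_design(subjects, model.covariates,
                                    label_levels=model.label_levels or None)
    stand_mean = model.grand_mean + x_cov @ model.beta
    z = (y - stand_mean) / np.sqrt(model.var_pooled)
    out = np.empty_like(z)
    for i, s in enumerate(model.sites):
        rows = subjects.sites == s
        if not rows.any():
            continue
        out[rows] = (z[rows] - model.gamma_star[i]) / np.sqrt(model.delta_star[i])
    harmonized = out * np.sqrt(model.var_pooled) + stand_mean
    return features.with_values(harmonized)


def harmonize_clinic(features: FeatureTable, subjects: SubjectTable,
                     covariates: tuple[str, ...] = DEFAULT_COMBAT_COVARIATES,
                     empirical_bayes: bool = True
                     ) -> tuple[FeatureTable, CombatModel]:
    """Convenience wrapper: fit and apply ComBat on one (clinic) cohort."""
    if pd.unique(subjects.sites).size < 2:
        warnings.warn("single-site cohort: ComBat is a near-identity here")
    model = fit_combat(features, subjects, covariates=covariates,
                       empirical_bayes=empirical_bayes)
    return apply_combat(features, subjects, model), model
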