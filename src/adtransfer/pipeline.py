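"""End-to-end study orchestration.

Runs the full transfer analysis: obtain the two cohorts (generated or read
from disk), remove normal-aging effects anchored on the training controls,
harmonize scan-site effects within the clinic cohort, tune and fit the 13
classification models on the training cohort (nine single-feature-group
elastic-net models plus four combined group-lasso models), transfer them
unchanged to the clinic cohort, evaluate all 52 comparisons (4 group
contrasts x 13 models) with maxT-permutation FWE correction and fixed-cutoff
metrics, and summarize feature-group importance for the combined models.

The clinic cohort is never used for any fitting step — not for the age
model, not for standardization, not for hyperparameter tuning; an assertion
on every fitted artifact enforces this.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import COMBINED_MODELS, FEATURE_GROUPS, FeatureTable, SubjectTable, \
    binary_outcome
from .synthetic import GeneratorConfig, SyntheticCohorts, generate_cohorts
from .harmonization import (
    DEFAULT_COMBAT_COVARIATES,
    apply_age_correction,
    fit_age_model,
    harmonize_clinic,
)
from .classifiers import (
    PenalizedLogisticModel,
    lambda_grid_elastic_net,
    lambda_grid_group_lasso,
    predict_scores,
)
from .evaluation import (
    CvSpec,
    ModelSpec,
    classification_metrics,
    maxT_permutation_fwe,
    nested_cv_evaluate,
    tune_final_model,
)

logger = logging.getLogger(__name__)

#: the four contrasts: (cohort, name, negative/less-severe, positive/more-severe)
CONTRASTS = (
    ("training", "HCvsAD", "HC", "AD"),
    ("clinic", "SMCvsMCI", "SMC", "MCI"),
    ("clinic", "MCIvsAD", "MCI", "AD"),
    ("clinic", "SMCvsAD", "SMC", "AD"),
)


def default_roster() -> dict[str, tuple[str, ...]]:
    """The 13 study models: each single feature group, then the combined
    per-modality and multimodal models."""
    roster: dict[str, tuple[str, ...]] = {g: (g,) for g in FEATURE_GROUPS}
    roster.update(COMBINED_MODELS)
    return roster


@dataclass
class StudyConfig:
    generator: GeneratorConfig | None = None
    roster: dict[str, tuple[str, ...]] = field(default_factory=default_roster)
    age_correction: bool = True
    harmonization_order: str = "age_then_combat"   # or "combat_then_age"
    combat_covariates: tuple[str, ...] = DEFAULT_COMBAT_COVARIATES
    empirical_bayes: bool = True
    # hyperparameter grids
    alphas: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    n_lambdas: int = 10
    lambda_decades: float = 4.0
    tune_folds: int = 10
    stratified: bool = True
    # training-cohort generalization estimate (repeated nested CV); off by
    # default because the transferred-model evaluation does not need it
    nested_cv: bool = False
    nested_spec: CvSpec | None = None
    permutations: int = 10_000
    cutoff: float = 0.5
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        known = set(FEATURE_GROUPS)
        for name, groups in self.roster.items():
            missing = set(groups) - known
            if missing:
                raise ValueError(f"model {name!r} references unknown feature "
                                 f"groups {sorted(missing)}")
        if self.harmonization_order not in ("age_then_combat", "combat_then_age"):
            raise ValueError("harmonization_order must be 'age_then_combat' "
                             "or 'combat_then_age'")


@dataclass
class StudyResult:
    config: StudyConfig
    training_subjects: SubjectTable
    clinic_subjects: SubjectTable
    training_scores: pd.DataFrame     # subjects x models (out-of-fold CV scores)
    clinic_scores: pd.DataFrame       # subjects x models (transferred scores)
    comparisons: pd.DataFrame
    importance_per_group: pd.DataFrame
    importance_per_feature: pd.DataFrame
    models: dict[str, PenalizedLogisticModel]
    selected_params: dict[str, dict]
    nested_cv_auc: dict[str, float] = field(default_factory=dict)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def _build_grid(kind: str, X: np.ndarray, y: np.ndarray,
                group_idx: np.ndarray | None, config: StudyConfig) -> list[dict]:
    if kind == "elastic_net":
        grid: list[dict] = []
        for alpha in config.alphas:
            lams = lambda_grid_elastic_net(X, y, alpha, config.n_lambdas,
                                           config.lambda_decades)
            grid.extend({"alpha": float(alpha), "lambda": float(l)} for l in lams)
        return grid
    lams = lambda_grid_group_lasso(X, y, group_idx, config.n_lambdas,
                                   config.lambda_decades)
    return [{"lambda": float(l)} for l in lams]


def run_study(config: StudyConfig | None = None,
              cohorts: SyntheticCohorts | None = None) -> StudyResult:
    """Run the complete analysis; deterministic given ``config.seed``."""
    config = config or StudyConfig()
    t0 = time.time()
    if cohorts is None:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        logger.info("stage cohorts: generating synthetic cohorts (seed %d)", gen.seed)
        cohorts = generate_cohorts(gen)
    train_subj, train_feat = cohorts.training_subjects, cohorts.training_features
    clinic_subj, clinic_feat = cohorts.clinic_subjects, cohorts.clinic_features

    def _age_stage(train_feat, clinic_feat):
        logger.info("stage age: fitting age model on training controls")
        age_model = fit_age_model(train_feat, train_subj)
        return (apply_age_correction(train_feat, train_subj, age_model),
                apply_age_correction(clinic_feat, clinic_subj, age_model),
                age_model)

    def _combat_stage(clinic_feat):
        logger.info("stage combat: harmonizing %d clinic sites",
                    len(set(clinic_subj.sites)))
        return harmonize_clinic(clinic_feat, clinic_subj,
                                covariates=config.combat_covariates,
                                empirical_bayes=config.empirical_bayes)

    age_model = combat_model = None
    if config.age_correction and config.harmonization_order == "age_then_combat":
        train_feat, clinic_feat, age_model = _age_stage(train_feat, clinic_feat)
        clinic_feat, combat_model = _combat_stage(clinic_feat)
    elif config.age_correction:
        clinic_feat, combat_model = _combat_stage(clinic_feat)
        train_feat, clinic_feat, age_model = _age_stage(train_feat, clinic_feat)
    else:
        clinic_feat, combat_model = _combat_stage(clinic_feat)

    y_train = binary_outcome(train_subj.labels, positive="AD", negative="HC")
    seeds = _child_seeds(config.seed, 2 * len(config.roster) + 1)
    perm_seed, model_seeds = seeds[0], seeds[1:]

    models: dict[str, PenalizedLogisticModel] = {}
    selected: dict[str, dict] = {}
    nested_auc: dict[str, float] = {}
    train_scores = pd.DataFrame(index=train_subj.data["subject_id"])
    clinic_scores = pd.DataFrame(index=clinic_subj.data["subject_id"])

    for mi, (name, groups) in enumerate(config.roster.items()):
        cols = train_feat.columns_of(groups)
        X = train_feat.values[cols].to_numpy(dtype=float)
        kind = "elastic_net" if len(groups) == 1 else "group_lasso"
        group_idx = train_feat.group_indices(cols) if kind == "group_lasso" else None
        spec = ModelSpec(kind=kind,
                         groups=[train_feat.group_of[c] for c in cols]
                         if kind == "group_lasso" else None,
                         feature_names=cols)
        grid = _build_grid(kind, X, y_train, group_idx, config)
        logger.info("stage train[%s]: %s, %d features, %d grid points",
                    name, kind, len(cols), len(grid))
        tuned = tune_final_model(X, y_train, spec, grid, folds=config.tune_folds,
                                 stratified=config.stratified,
                                 seed=model_seeds[2 * mi])
        model = tuned["model"]
        assert model.fit_cohort == "training", "clinic data must never be fit"
        models[name] = model
        selected[name] = tuned["params"]
        train_scores[name] = tuned["cv_scores"]
        clinic_scores[name] = predict_scores(model, clinic_feat)
        if config.nested_cv:
            cv = config.nested_spec or CvSpec(seed=model_seeds[2 * mi + 1])
            nested_auc[name] = nested_cv_evaluate(X, y_train, spec, grid, cv)["mean_auc"]

    # ------------------------------------------------------------------
    # the 4 x len(roster) comparison grid
    # ------------------------------------------------------------------
    logger.info("stage evaluate: %d comparisons, %d permutations",
                len(CONTRASTS) * len(config.roster), config.permutations)
    family: list[tuple[np.ndarray, np.ndarray]] = []
    rows: list[dict] = []
    for name in config.roster:
        for cohort, contrast, neg, pos in CONTRASTS:
            subj = train_subj if cohort == "training" else clinic_subj
            score_tab = train_scores if cohort == "training" else clinic_scores
            mask = np.isin(subj.labels, [neg, pos])
            scores = score_tab[name].to_numpy()[mask]
            labels = binary_outcome(subj.labels[mask], positive=pos, negative=neg)
            family.append((scores, labels))
            rows.append(dict(model=name, cohort=cohort, contrast=contrast,
                             positive=pos, negative=neg,
                             n_pos=int(labels.sum()),
                             n_neg=int(len(labels) - labels.sum())))
    p_fwe, null = maxT_permutation_fwe(family, B=config.permutations,
                                       seed=perm_seed, return_null=True)
    for row, (scores, labels), auc, p in zip(rows, family, null.observed, p_fwe):
        m = classification_metrics(scores, labels, cutoff=config.cutoff)
        row.update(auc=float(auc), p_fwe=float(p), sensitivity=m.sensitivity,
                   specificity=m.specificity, ppv=m.ppv, npv=m.npv)
    comparisons = pd.DataFrame(rows)

    per_group, per_feature = summarize_importance(
        {n: m for n, m in models.items() if m.penalty_kind == "group_lasso"})

    result = StudyResult(
        config=config, training_subjects=train_subj, clinic_subjects=clinic_subj,
        training_scores=train_scores, clinic_scores=clinic_scores,
        comparisons=comparisons, importance_per_group=per_group,
        importance_per_feature=per_feature, models=models,
        selected_params=selected, nested_cv_auc=nested_auc)
    if config.out_dir:
        _persist(result, train_feat, clinic_feat, Path(config.out_dir))
    logger.info("study complete in %.1f s", time.time() - t0)
    return result


def summarize_importance(models: dict[str, PenalizedLogisticModel]
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature standardized coefficients and per-group sums of absolute
    standardized coefficients for grouped (combined) models; a group whose
    block the penalty zeroed out has sum exactly 0 and is flagged excluded."""
    f_rows = []
    for name, model in models.items():
        if not model.group_of:
            raise ValueError(f"model {name!r} has no feature grouping")
        for feat, w in zip(model.feature_names, model.weights):
            f_rows.append(dict(model=name, feature=feat,
                               group=model.group_of[feat], beta=float(w)))
    per_feature = pd.DataFrame(f_rows)
    per_group = (per_feature.assign(sum_abs_beta=per_feature["beta"].abs())
                 .groupby(["model", "group"], sort=False)["sum_abs_beta"].sum()
                 .reset_index())
    per_group["excluded"] = per_group["sum_abs_beta"] == 0.0
    return per_group, per_feature


def _persist(result: StudyResult, train_feat: FeatureTable,
             clinic_feat: FeatureTable, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.training_subjects.to_tsv(out_dir / "training_subjects.tsv")
    result.clinic_subjects.to_tsv(out_dir / "clinic_subjects.tsv")
    train_feat.to_tsv(out_dir / "training_features_harmonized.tsv")
    clinic_feat.to_tsv(out_dir / "clinic_features_harmonized.tsv")
    result.training_scores.to_csv(out_dir / "training_scores.tsv", sep="\t")
    result.clinic_scores.to_csv(out_dir / "clinic_scores.tsv", sep="\t")
    result.comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    result.importance_per_group.to_csv(out_dir / "importance_groups.tsv",
                                       sep="\t", index=False)
    result.importance_per_feature.to_csv(out_dir / "importance_features.tsv",
                                         sep="\t", index=False)
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)
    for name, model in result.models.items():
        safe = name.replace(" ", "_").replace("/", "-")
        model.to_json(models_dir / f"{safe}.json")
    wide = result.comparisons.pivot(index="model", columns="contrast", values="auc")
    lines = ["AUC per model and contrast", wide.round(3).to_string(), "",
             f"permutations: {result.config.permutations}",
             f"seed: {result.config.seed}"]
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
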