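"""Age residualization and ComBat site harmonization."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from adtransfer import (
    GeneratorConfig,
    apply_age_correction,
    apply_combat,
    fit_age_model,
    fit_combat,
    generate_cohorts,
    harmonize_clinic,
)
from adtransfer.tables import FeatureTable, SubjectTable


def _subjects(n, sites, labels, ages=None, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "cohort": "clinic", "site": sites, "label": labels,
        "age": ages if ages is not None else rng.uniform(55, 85, n),
        "sex": rng.choice(["male", "female"], n),
        "education": rng.uniform(8, 16, n),
        "mmse": rng.uniform(20, 30, n),
        "cdr": rng.uniform(0, 1, n), "gds": rng.uniform(0, 6, n),
    })
    return SubjectTable(df)


def _training_subjects(n, ages, labels):
    rng = np.random.default_rng(1)
    df = pd.DataFrame({
        "subject_id": [f"t{i}" for i in range(n)], "cohort": "training",
        "site": "graz", "label": labels, "age": ages,
        "sex": rng.choice(["male", "female"], n),
        "education": rng.uniform(8, 16, n), "mmse": rng.uniform(20, 30, n),
        "cdr": 0.0, "gds": 1.0})
    return SubjectTable(df)


class TestAgeModel:
    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(0)
        n = 200
        ages = rng.uniform(55, 85, n)
        x = 0.5 * ages[:, None] + rng.normal(0, 0.1, (n, 3))
        subj = _training_subjects(n, ages, ["HC"] * n)
        feat = FeatureTable(pd.DataFrame(x, columns=["a", "b", "c"]),
                            {c: "Grey matter density" for c in "abc"})
        model = fit_age_model(feat, subj)
        assert np.all((model.slope > 0.45) & (model.slope < 0.55))
        corrected = apply_age_correction(feat, subj, model)
        r = np.corrcoef(corrected.values["a"], ages)[0, 1]
        assert abs(r) < 0.05

    def test_age_independent_features_untouched_up_to_intercept(self):
        rng = np.random.default_rng(1)
        n = 300
        ages = rng.uniform(55, 85, n)
        x = rng.standard_normal((n, 2))
        subj = _training_subjects(n, ages, ["HC"] * n)
        feat = FeatureTable(pd.DataFrame(x, columns=["a", "b"]),
                            {"a": "ALFF", "b": "ALFF"})
        model = fit_age_model(feat, subj)
        assert np.abs(model.slope).max() < 0.02
        out = apply_age_correction(feat, subj, model)
        assert np.abs(out.matrix() - x).max() < 0.02 * 20

    def test_opposite_slopes_recovered_symmetrically(self):
        rng = np.random.default_rng(2)
        n = 400
        ages = rng.uniform(55, 85, n)
        centered = ages - ages.mean()
        noise = rng.normal(0, 0.05, n)
        x = np.column_stack([centered + noise, -centered + noise])
        subj = _training_subjects(n, ages, ["HC"] * n)
        feat = FeatureTable(pd.DataFrame(x, columns=["up", "down"]),
                            {"up": "ALFF", "down": "ALFF"})
        model = fit_age_model(feat, subj)
        assert model.slope[0] == pytest.approx(-model.slope[1], abs=1e-3)
        assert model.slope[0] == pytest.approx(1.0, abs=0.02)

    def test_controls_only_enter_the_fit(self):
        rng = np.random.default_rng(3)
        n = 200
        ages = np.concatenate([rng.uniform(55, 85, n), rng.uniform(55, 85, n)])
        labels = ["HC"] * n + ["AD"] * n
        # AD rows carry a huge fake age trend that must not leak into the fit
        x = np.where(np.arange(2 * n)[:, None] < n,
                     rng.normal(0, 0.1, (2 * n, 1)),
                     5.0 * ages[:, None])
        subj = _training_subjects(2 * n, ages, labels)
        feat = FeatureTable(pd.DataFrame(x, columns=["f"]), {"f": "ALFF"})
        model = fit_age_model(feat, subj)
        assert abs(model.slope[0]) < 0.05

    def test_zero_slope_model_is_identity(self, small_cohorts):
        feat, subj = small_cohorts.training_features, small_cohorts.training_subjects
        model = fit_age_model(feat, subj)
        model.slope[:] = 0.0
        out = apply_age_correction(feat, subj, model)
        assert np.array_equal(out.matrix(), feat.matrix())

    def test_subject_at_reference_age_unchanged(self):
        rng = np.random.default_rng(4)
        n = 50
        ages = np.full(n, 70.0)
        ages[0] = 60.0  # some variance for the fit
        subj = _training_subjects(n, ages, ["HC"] * n)
        feat = FeatureTable(pd.DataFrame(rng.standard_normal((n, 2)),
                                         columns=["a", "b"]),
                            {"a": "ALFF", "b": "ALFF"})
        model = fit_age_model(feat, subj)
        model.reference_age = 70.0
        out = apply_age_correction(feat, subj, model)
        assert np.array_equal(out.matrix()[1:], feat.matrix()[1:])

    def test_zero_age_variance_rejected(self):
        subj = _training_subjects(10, np.full(10, 70.0), ["HC"] * 10)
        feat = FeatureTable(pd.DataFrame(np.random.default_rng(0).random((10, 1)),
                                         columns=["f"]), {"f": "ALFF"})
        with pytest.raises(ValueError, match="age variance"):
            fit_age_model(feat, subj)

    def test_commutes_with_constant_shift(self, small_cohorts):
        feat, subj = small_cohorts.training_features, small_cohorts.training_subjects
        model = fit_age_model(feat, subj)
        a = apply_age_correction(feat, subj, model).matrix() + 7.0
        shifted = feat.with_values(feat.matrix() + 7.0)
        model2 = fit_age_model(shifted, subj)
        b = apply_age_correction(shifted, subj, model2).matrix()
        assert np.allclose(a, b)


def _site_shift_cohort(n_per_site=100, p=20, add=2.0, mult=1.0, label_effect=0.0,
                       seed=0):
    """4-site cohort drawn from the location-scale batch model: per feature
    and site an additive shift ~ N(0, add^2) and a multiplicative residual
    scale exp(N(0, log(mult)^2)) (so ``mult`` is the typical scale factor),
    plus an optional clinical-label mean shift.  Label composition is
    balanced across sites so site means differ only through batch effects."""
    rng = np.random.default_rng(seed)
    sites = np.repeat([f"s{k}" for k in range(4)], n_per_site)
    n = len(sites)
    labels = np.tile(np.repeat(["SMC", "MCI", "AD"],
                               n_per_site // 3 + 1)[:n_per_site], 4)
    si = np.repeat(np.arange(4), n_per_site)
    gamma = rng.normal(0.0, add, (4, p))
    log_sd = np.log(mult) if mult > 1 else 0.0
    delta = np.exp(rng.normal(0.0, log_sd, (4, p))) if log_sd else np.ones((4, p))
    x = rng.standard_normal((n, p)) * delta[si] + gamma[si] \
        + label_effect * (labels == "AD")[:, None]
    subj = _subjects(n, sites, labels, seed=seed + 1)
    feat = FeatureTable(pd.DataFrame(x, columns=[f"f{j}" for j in range(p)]),
                        {f"f{j}": "Mean diffusivity" for j in range(p)})
    return feat, subj


class TestCombat:
    def test_additive_site_shift_removed(self):
        feat, subj = _site_shift_cohort(add=2.0)
        out, _ = harmonize_clinic(feat, subj)

        def site_spread(values):
            means = values.groupby(subj.sites).mean()
            return (means.max() - means.min()).mean()

        before = site_spread(feat.values.iloc[:, :10])
        after = site_spread(out.values.iloc[:, :10])
        assert after < 0.05 * before

    def test_multiplicative_site_effect_removed(self):
        feat, subj = _site_shift_cohort(add=0.0, mult=3.0, seed=3)
        before = feat.values.groupby(subj.sites).var().mean(axis=1)
        assert before.max() / before.min() > 1.5  # effect present going in
        out, _ = harmonize_clinic(feat, subj)
        after = out.values.groupby(subj.sites).var().mean(axis=1)
        ratio = after / after.mean()
        assert ratio.between(0.8, 1.25).all()

    def test_label_effect_preserved(self):
        feat, subj = _site_shift_cohort(add=2.0, label_effect=1.0, seed=5)
        out, _ = harmonize_clinic(feat, subj)
        is_ad = subj.labels == "AD"
        eff = out.matrix()[is_ad].mean(0) - out.matrix()[~is_ad].mean(0)
        assert 0.8 < eff.mean() < 1.2

    def test_no_eb_exactly_aligns_site_moments(self):
        feat, subj = _site_shift_cohort(add=1.5, mult=2.0, seed=7)
        out, _ = harmonize_clinic(feat, subj, covariates=(), empirical_bayes=False)
        means = out.values.groupby(subj.sites).mean().to_numpy()
        vars_ = out.values.groupby(subj.sites).var().to_numpy()
        assert np.abs(means - means[0]).max() < 1e-10
        assert np.abs(vars_ / vars_[0] - 1).max() < 1e-10

    def test_eb_shrinks_additive_estimates(self):
        feat, subj = _site_shift_cohort(add=0.5, seed=9)
        model = fit_combat(feat, subj)
        assert np.abs(model.gamma_star).mean() <= np.abs(model.gamma_hat).mean()

    def test_single_site_is_near_identity(self):
        rng = np.random.default_rng(11)
        n, p = 60, 8
        subj = _subjects(n, ["only"] * n, rng.choice(["SMC", "MCI", "AD"], n))
        feat = FeatureTable(pd.DataFrame(rng.standard_normal((n, p)),
                                         columns=[f"f{j}" for j in range(p)]),
                            {f"f{j}": "ALFF" for j in range(p)})
        with pytest.warns(UserWarning, match="single-site"):
            out, model = harmonize_clinic(feat, subj)
        assert np.abs(model.gamma_star).max() < 0.05
        assert np.abs(model.delta_star - 1).max() < 0.3
        assert np.abs(out.matrix() - feat.matrix()).max() < 0.25

    def test_unseen_site_rejected(self):
        feat, subj = _site_shift_cohort()
        model = fit_combat(feat, subj)
        other = subj.data.copy()
        other["site"] = "elsewhere"
        with pytest.raises(ValueError, match="sites not present"):
            apply_combat(feat, SubjectTable(other), model)

    def test_approximate_idempotence(self):
        # moderate batch effects: with extreme scale heterogeneity the EB
        # shrinkage deliberately leaves residual variance imbalance, so
        # near-idempotence is only expected in this regime
        feat, subj = _site_shift_cohort(add=2.0, mult=1.2, seed=13)
        once, _ = harmonize_clinic(feat, subj)
        twice, _ = harmonize_clinic(once, subj)
        rms = np.sqrt(((twice.matrix() - once.matrix()) ** 2).mean())
        scale = np.sqrt((once.matrix() ** 2).mean())
        assert rms < 0.01 * scale

    def test_singular_design_reported(self):
        feat, subj = _site_shift_cohort()
        dup = subj.data.copy()
        dup["mmse"] = dup["education"]  # perfectly collinear covariates
        with pytest.raises(ValueError, match="singular"):
            fit_combat(feat, SubjectTable(dup))


class TestCombatAgainstReferenceImplementation:
    def test_matches_sva_combat(self, tmp_path):
        """Independent oracle: Bioconductor sva's parametric ComBat on the
        same cohort must agree with this implementation."""
        cfg = GeneratorConfig(
            seed=3, feature_groups={"Grey matter density": 20},
            n_per_group={"training": {"HC": 20, "AD": 10},
                         "clinic": {"SMC": 30, "MCI": 30, "AD": 30}})
        c = generate_cohorts(cfg)
        subj, feat = c.clinic_subjects, c.clinic_features
        out, _ = harmonize_clinic(feat, subj)
        feat.values.to_csv(tmp_path / "feat.csv", index=False)
        subj.data.to_csv(tmp_path / "subj.csv", index=False)
        script = textwrap.dedent("""
            suppressMessages(library(sva))
            feat <- as.matrix(read.csv('feat.csv'))
            subj <- read.csv('subj.csv')
            mod <- model.matrix(~ age + factor(sex) + education + factor(label)
                                + mmse, data=subj)
            res <- ComBat(dat=t(feat), batch=subj$site, mod=mod, par.prior=TRUE)
            write.csv(t(res), 'r_combat.csv', row.names=FALSE)
        """)
        (tmp_path / "oracle.R").write_text(script)
        subprocess.run(["Rscript", "oracle.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        oracle = pd.read_csv(tmp_path / "r_combat.csv").to_numpy()
        assert np.abs(out.matrix() - oracle).max() < 1e-4
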