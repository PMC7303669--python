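"""Seeded synthetic cohorts and signals with the structure the analysis assumes.

Three generators stand in for the study's MRI-derived inputs:

* :func:`generate_cohorts` — two cohorts of subject metadata plus
  subjects-by-features tables: a single-site training sample (healthy
  controls vs AD) and a four-site memory-clinic sample (SMC / MCI / AD) with
  per-feature linear age effects, graded disease effects (AD > MCI > SMC),
  and additive plus multiplicative scan-site effects whose magnitude depends
  on the MRI modality (large for diffusion, moderate for anatomical,
  negligible for rs-fMRI).
* :func:`generate_roi_timeseries` — zero-mean Gaussian component time
  courses with a known sparse precision matrix, for the sparse
  partial-correlation estimator.
* :func:`generate_voxel_timeseries` — band-limited sinusoidal voxel signals
  with known low-frequency band power, for the ALFF estimator.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    CLINIC_LABELS,
    FEATURE_GROUPS,
    MODALITY_OF_GROUP,
    TRAINING_LABELS,
    FeatureTable,
    SubjectTable,
)

logger = logging.getLogger(__name__)

#: default group sizes reproduce the study's sample-size structure
DEFAULT_N_PER_GROUP: dict[str, dict[str, int]] = {
    "training": {"HC": 173, "AD": 76},
    "clinic": {"SMC": 67, "MCI": 61, "AD": 61},
}

CLINIC_SITES = ("clinic_A", "clinic_B", "clinic_C", "clinic_D")
TRAINING_SITE = "training_site"

#: demographic moments per (cohort, label): mean/sd pairs and male fraction,
#: mirroring the published sample descriptives
DEMOGRAPHICS: dict[tuple[str, str], dict] = {
    ("training", "HC"): dict(age=(66.1, 8.7), male=74 / 173, education=(11.5, 2.8),
                             mmse=(27.5, 1.8), cdr=(0.0, 0.0), gds=(2.0, 2.4)),
    ("training", "AD"): dict(age=(68.6, 8.6), male=30 / 76, education=(10.8, 3.2),
                             mmse=(20.4, 4.5), cdr=(0.82, 0.34), gds=(2.7, 2.6)),
    ("clinic", "SMC"): dict(age=(63.2, 10.3), male=48 / 67, education=(11.2, 3.4),
                            mmse=(28.2, 1.6), cdr=(0.34, 0.25), gds=(3.7, 2.8)),
    ("clinic", "MCI"): dict(age=(69.7, 8.3), male=35 / 61, education=(11.2, 3.4),
                            mmse=(26.9, 2.3), cdr=(0.53, 0.15), gds=(3.0, 2.4)),
    ("clinic", "AD"): dict(age=(72.5, 9.2), male=34 / 61, education=(10.6, 3.5),
                           mmse=(24.0, 2.7), cdr=(0.78, 0.25), gds=(3.2, 2.8)),
}

#: graded disease shifts (in residual-SD units) applied to affected features
DEFAULT_GROUP_EFFECT: dict[str, float] = {"HC": 0.0, "SMC": 0.4, "MCI": 1.2, "AD": 2.0}

#: per-modality scan-site effect magnitudes: additive SD (feature units) and
#: multiplicative log-SD, graded large / moderate / negligible
DEFAULT_SITE_ADDITIVE_SD = {"anatomical": 0.5, "diffusion": 2.0, "rsfmri": 0.0}
DEFAULT_SITE_MULTIPLICATIVE_SD = {"anatomical": 0.15, "diffusion": 0.4, "rsfmri": 0.0}

REFERENCE_AGE = 68.0  # centering constant for the linear age effects, years


def _default_feature_groups() -> dict[str, int]:
    return {g: spec["n_features"] for g, spec in FEATURE_GROUPS.items()}


def _default_n_per_group() -> dict[str, dict[str, int]]:
    return {c: dict(d) for c, d in DEFAULT_N_PER_GROUP.items()}


@dataclass
class GeneratorConfig:
    """Knobs of the cohort generator.

    ``group_effect`` maps a clinical label to a mean shift (in residual-SD
    units) added to the affected features; a per-feature-group override can
    be given via ``group_effect_overrides[group][label]``.  Site effects are
    parameterised per MRI modality.  ``within_group_rho`` is the
    exchangeable residual correlation among features of one group (an
    assumption; the study does not report feature covariance).
    """

    n_per_group: dict[str, dict[str, int]] = field(default_factory=_default_n_per_group)
    feature_groups: dict[str, int] = field(default_factory=_default_feature_groups)
    group_effect: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECT))
    group_effect_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    affected_fraction: float = 0.3
    age_slope_sd: float = 0.02
    site_additive_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_ADDITIVE_SD))
    site_multiplicative_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_MULTIPLICATIVE_SD))
    noise_sd: float = 1.0
    within_group_rho: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for cohort, counts in self.n_per_group.items():
            for label, n in counts.items():
                if n <= 0:
                    raise ValueError(f"non-positive count for {cohort}/{label}: {n}")
        unknown = set(self.feature_groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        unknown = set(self.group_effect_overrides) - set(self.feature_groups)
        if unknown:
            raise ValueError(f"effect overrides for unknown groups: {sorted(unknown)}")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if not 0.0 <= self.within_group_rho < 1.0:
            raise ValueError("within_group_rho must lie in [0, 1)")
        for name in ("noise_sd", "age_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for mapping in (self.site_additive_sd, self.site_multiplicative_sd):
            if any(v < 0 for v in mapping.values()):
                raise ValueError("site-effect SDs must be non-negative")

    def effect(self, group: str, label: str) -> float:
        override = self.group_effect_overrides.get(group, {})
        return override.get(label, self.group_effect.get(label, 0.0))


@dataclass
class SyntheticCohorts:
    training_subjects: SubjectTable
    training_features: FeatureTable
    clinic_subjects: SubjectTable
    clinic_features: FeatureTable

    def cohort(self, name: str) -> tuple[SubjectTable, FeatureTable]:
        if name == "training":
            return self.training_subjects, self.training_features
        if name == "clinic":
            return self.clinic_subjects, self.clinic_features
        raise KeyError(name)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float,
               hi: float, n: int) -> np.ndarray:
    """Normal draws clipped to a valid range (rejection would bias moments
    less, but clipped tails are negligible at these parameter values)."""
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _make_subjects(cohort: str, counts: Mapping[str, int], sites: tuple[str, ...],
                   rng: np.random.Generator) -> SubjectTable:
    rows = []
    for label, n in counts.items():
        demo = DEMOGRAPHICS[(cohort, label)]
        age = _truncnorm(rng, *demo["age"], 40.0, 95.0, n)
        sex = np.where(rng.random(n) < demo["male"], "male", "female")
        education = _truncnorm(rng, *demo["education"], 0.0, 25.0, n)
        mmse = _truncnorm(rng, *demo["mmse"], 0.0, 30.0, n)
        cdr = _truncnorm(rng, *demo["cdr"], 0.0, 3.0, n)
        gds = _truncnorm(rng, *demo["gds"], 0.0, 15.0, n)
        site = np.asarray(sites)[rng.integers(0, len(sites), size=n)] if len(sites) > 1 \
            else np.repeat(sites[0], n)
        for i in range(n):
            rows.append(dict(cohort=cohort, site=site[i], label=label, age=age[i],
                             sex=sex[i], education=education[i], mmse=mmse[i],
                             cdr=cdr[i], gds=gds[i]))
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"{cohort}_{i:04d}" for i in range(len(df))])
    return SubjectTable(df)


def generate_cohorts(config: GeneratorConfig | None = None) -> SyntheticCohorts:
    """Generate the training and clinic cohorts (metadata + feature tables).

    The value of feature *j* for subject *i* is

    ``baseline_j + slope_j * (age_i - 68) + gamma[site, j]
    + delta[site, j] * (effect(group_j, label_i) * affected_j + eps_ij)``

    i.e. the disease signal and residual noise are scaled by the
    multiplicative site factor and shifted by the additive one, matching the
    location-scale batch model the harmonization step assumes.  Feature-level
    parameters (baselines, age slopes, affected masks) are drawn once and
    shared by both cohorts, so a model trained on one transfers to the other.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)

    groups = list(config.feature_groups)
    n_feat = sum(config.feature_groups.values())
    feature_names: list[str] = []
    group_of: dict[str, str] = {}
    for g in groups:
        short = "".join(w[0] for w in g.split()).lower()
        for k in range(config.feature_groups[g]):
            name = f"{short}_{k:05d}"
            feature_names.append(name)
            group_of[name] = g
    group_idx = np.concatenate([
        np.full(config.feature_groups[g], gi) for gi, g in enumerate(groups)
    ])

    # feature-level parameters, shared across cohorts
    baseline = rng.normal(0.0, 1.0, n_feat)
    slope = rng.normal(0.0, config.age_slope_sd, n_feat)
    affected = rng.random(n_feat) < config.affected_fraction

    # per-label shift vector per feature
    shift_of_label: dict[str, np.ndarray] = {}
    for label in set(TRAINING_LABELS) | set(CLINIC_LABELS):
        per_group = np.array([config.effect(g, label) for g in groups])
        shift_of_label[label] = per_group[group_idx] * affected

    def _site_effects(sites: tuple[str, ...]) -> tuple[dict, dict]:
        gamma: dict[str, np.ndarray] = {}
        delta: dict[str, np.ndarray] = {}
        add_sd = np.array([config.site_additive_sd.get(
            MODALITY_OF_GROUP[g], 0.0) for g in groups])[group_idx]
        mul_sd = np.array([config.site_multiplicative_sd.get(
            MODALITY_OF_GROUP[g], 0.0) for g in groups])[group_idx]
        for s in sites:
            gamma[s] = rng.normal(0.0, 1.0, n_feat) * add_sd
            delta[s] = np.exp(rng.normal(0.0, 1.0, n_feat) * mul_sd)
        return gamma, delta

    def _features(subjects: SubjectTable, gamma: dict, delta: dict) -> FeatureTable:
        n = len(subjects)
        rho = config.within_group_rho
        noise = rng.normal(0.0, 1.0, (n, n_feat))
        if rho > 0:
            shared = rng.normal(0.0, 1.0, (n, len(groups)))
            noise = np.sqrt(rho) * shared[:, group_idx] + np.sqrt(1.0 - rho) * noise
        noise *= config.noise_sd
        shift = np.vstack([shift_of_label[l] for l in subjects.labels])
        values = noise + shift
        g_add = np.vstack([gamma[s] for s in subjects.sites])
        d_mul = np.vstack([delta[s] for s in subjects.sites])
        values = baseline + slope * (subjects.ages[:, None] - REFERENCE_AGE) \
            + g_add + d_mul * values
        return FeatureTable(pd.DataFrame(values, columns=feature_names), dict(group_of))

    train_subj = _make_subjects("training", config.n_per_group["training"],
                                (TRAINING_SITE,), rng)
    clinic_subj = _make_subjects("clinic", config.n_per_group["clinic"],
                                 CLINIC_SITES, rng)
    # the training site is the reference: no site effects
    ident = ({TRAINING_SITE: np.zeros(n_feat)}, {TRAINING_SITE: np.ones(n_feat)})
    clinic_gamma, clinic_delta = _site_effects(CLINIC_SITES)
    train_feat = _features(train_subj, *ident)
    clinic_feat = _features(clinic_subj, clinic_gamma, clinic_delta)
    return SyntheticCohorts(train_subj, train_feat, clinic_subj, clinic_feat)


# ----------------------------------------------------------------------
# component time courses with known sparse precision
# ----------------------------------------------------------------------

@dataclass
class RoiTimeSeriesSet:
    """Per-subject component-by-volume time courses and the generating
    precision matrix (shared across subjects)."""

    series: np.ndarray  # (n_subjects, components, volumes)
    tr: float
    true_precision: np.ndarray

    @property
    def n_components(self) -> int:
        return self.series.shape[1]


def _sparse_precision(k: int, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric positive-definite precision whose off-diagonal
    support has (approximately) the requested fraction of zeros."""
    prec = np.eye(k)
    iu = np.triu_indices(k, 1)
    keep = rng.random(len(iu[0])) < (1.0 - sparsity)
    vals = rng.uniform(0.2, 0.4, len(iu[0])) * rng.choice([-1.0, 1.0], len(iu[0]))
    vals[~keep] = 0.0
    prec[iu] = vals
    prec[(iu[1], iu[0])] = vals
    min_eig = np.linalg.eigvalsh(prec).min()
    if min_eig < 0.05:
        loading = 0.05 - min_eig
        logger.info("precision not sufficiently positive-definite; "
                    "adding %.3f diagonal loading", loading)
        prec += loading * np.eye(k)
    return prec


def generate_roi_timeseries(n_subjects: int, n_components: int = 70,
                            volumes: int = 150, tr: float = 3.0,
                            sparsity: float = 0.9, seed: int = 0) -> RoiTimeSeriesSet:
    """Zero-mean Gaussian component time courses drawn from a sparse
    precision; ``sparsity`` is the target fraction of zero off-diagonals
    (1 = diagonal precision, fully independent components)."""
    if volumes < 10:
        raise ValueError("need at least 10 volumes")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prec = _sparse_precision(n_components, sparsity, rng)
    cov = np.linalg.inv(prec)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_subjects, volumes, n_components))
    series = np.einsum("svk,jk->sjv", z, chol)
    return RoiTimeSeriesSet(series=series, tr=tr, true_precision=prec)


def population_partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial correlations implied by a precision matrix:
    ``r_ij = -P_ij / sqrt(P_ii * P_jj)``, zero diagonal."""
    d = np.sqrt(np.diag(precision))
    r = -precision / np.outer(d, d)
    np.fill_diagonal(r, 0.0)
    return r


# ----------------------------------------------------------------------
# band-limited voxel signals with known low-frequency power
# ----------------------------------------------------------------------

@dataclass
class VoxelTimeSeriesSet:
    series: np.ndarray  # (n_subjects, voxels, volumes)
    tr: float
    true_band_power: np.ndarray  # (n_subjects, voxels)


def generate_voxel_timeseries(n_subjects: int, n_voxels: int = 500,
                              volumes: int = 150, tr: float = 3.0,
                              band_power_profile: np.ndarray | None = None,
                              band: tuple[float, float] = (0.0, 0.1),
                              noise_sd: float = 0.0,
                              seed: int = 0) -> VoxelTimeSeriesSet:
    """Voxel signals built from sinusoids inside ``band`` whose power
    matches ``band_power_profile`` (default: lognormal per-voxel powers),
    plus optional white noise.  Tone frequencies are snapped to the
    Fourier grid so the generated in-band power is exact up to the noise."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels (normalization uses the mean)")
    nyquist = 1.0 / (2.0 * tr)
    f_lo, f_hi = band
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz above Nyquist {nyquist} Hz")
    rng = np.random.default_rng(seed)
    if band_power_profile is None:
        band_power_profile = rng.lognormal(0.0, 0.5, n_voxels)
    band_power_profile = np.asarray(band_power_profile, dtype=float)
    if band_power_profile.shape != (n_voxels,):
        raise ValueError("band_power_profile must have one value per voxel")

    freqs = np.fft.rfftfreq(volumes, d=tr)
    in_band = (freqs > 0) & (freqs >= f_lo) & (freqs <= f_hi) & (freqs < nyquist)
    if not in_band.any():
        raise ValueError("no Fourier frequencies inside the requested band")
    grid = freqs[in_band]

    t = np.arange(volumes) * tr
    series = np.empty((n_subjects, n_voxels, volumes))
    power = np.tile(band_power_profile, (n_subjects, 1))
    for s in range(n_subjects):
        f = grid[rng.integers(0, len(grid), n_voxels)]
        phase = rng.uniform(0.0, 2 * np.pi, n_voxels)
        amp = np.sqrt(2.0 * band_power_profile)
        series[s] = amp[:, None] * np.sin(2 * np.pi * f[:, None] * t + phase[:, None])
        if noise_sd > 0:
            series[s] += rng.normal(0.0, noise_sd, (n_voxels, volumes))
    return VoxelTimeSeriesSet(series=series, tr=tr, true_band_power=power)
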