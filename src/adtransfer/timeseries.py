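"""rs-fMRI feature computation at the signal level.

Two feature types are computed from resting-state signals:

* sparse partial correlations between component time courses, from an
  L1-penalized inverse covariance (graphical lasso) estimate — the penalty
  controls how many component pairs are conditionally dependent;
* normalized low-frequency band power (ALFF): per-voxel spectral power in
  the 0–0.1 Hz band, divided by the mean over all voxels so that the
  normalized values average exactly 1.

The penalty here is applied per off-diagonal entry of the standardized
(correlation-scale) covariance; equivalence to the absolute penalty value of
any particular legacy implementation is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.covariance import graphical_lasso

from .tables import FeatureTable
from .synthetic import RoiTimeSeriesSet, VoxelTimeSeriesSet


class ConvergenceError(RuntimeError):
    """Graphical-lasso coordinate descent failed to converge."""


@dataclass
class PartialCorrelationFeatures:
    """Symmetric partial-correlation matrix and its upper-triangle vector."""

    matrix: np.ndarray
    vector: np.ndarray
    penalty: float


@dataclass
class AlffFeatures:
    raw: np.ndarray          # per-voxel band power
    normalized: np.ndarray   # raw / mean(raw); averages exactly 1
    band: tuple[float, float]


def estimate_sparse_partial_correlations(series: np.ndarray,
                                         penalty: float,
                                         max_iter: int = 200,
                                         ) -> PartialCorrelationFeatures:
    """Estimate sparse partial correlations from a components-by-volumes
    matrix.

    The series is standardized per component, the penalized precision
    ``Theta`` is estimated on the resulting correlation matrix, and partial
    correlations are ``r_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)``.
    Larger penalties give no fewer zero entries.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D components x volumes matrix")
    if not np.isfinite(series).all():
        raise ValueError("series contains non-finite values")
    k, t = series.shape
    if t <= 3:
        raise ValueError("need more than 3 volumes")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")
    mean = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant component time course")
    z = (series - mean) / sd
    corr = z @ z.T / t
    try:
        _, prec = graphical_lasso(corr, alpha=penalty, max_iter=max_iter)
    except FloatingPointError as err:  # pragma: no cover - pathological input
        raise ConvergenceError(
            f"graphical lasso did not converge within {max_iter} iterations "
            f"at penalty {penalty}: {err}") from err
    r = -prec / np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return PartialCorrelationFeatures(matrix=r, vector=vectorize_upper_triangle(r),
                                      penalty=penalty)


def vectorize_upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Flatten the strict upper triangle in row-major (i < j) order;
    a k x k matrix yields k(k-1)/2 values."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    iu = np.triu_indices(matrix.shape[0], 1)
    return matrix[iu]


def devectorize_upper_triangle(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_upper_triangle` (symmetric, zero diagonal)."""
    vector = np.asarray(vector)
    m = len(vector)
    k = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if k * (k - 1) // 2 != m:
        raise ValueError(f"length {m} is not a triangular number")
    out = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    out[iu] = vector
    out[(iu[1], iu[0])] = vector
    return out


def compute_alff(voxel_series: np.ndarray, tr: float,
                 band: tuple[float, float] = (0.0, 0.1),
                 amplitude: bool = False) -> AlffFeatures:
    """Per-voxel power in ``band`` from a linearly detrended one-sided
    periodogram, normalized by the mean over voxels.

    The band sum runs over positive Fourier frequencies with
    ``f_lo <= f <= f_hi`` (the DC bin is never included).  With
    ``amplitude=True`` the square root of the band power is normalized
    instead (the classical amplitude convention); the default follows the
    power convention.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    if voxel_series.ndim != 2:
        raise ValueError("voxel_series must be voxels x volumes")
    n_vox, volumes = voxel_series.shape
    if volumes < 8:
        raise ValueError("need at least 8 volumes")
    if tr <= 0:
        raise ValueError("tr must be positive")
    f_lo, f_hi = band
    nyquist = 1.0 / (2.0 * tr)
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {f_hi} Hz above Nyquist {nyquist} Hz")
    freqs, power = periodogram_power(voxel_series, tr)
    in_band = (freqs > 0) & (freqs >= f_lo) & (freqs <= f_hi)
    raw = power[:, in_band].sum(axis=1)
    raw[voxel_series.var(axis=1) == 0] = 0.0  # constant series: exactly no power
    if amplitude:
        raw = np.sqrt(raw)
    mean_raw = raw.mean()
    if mean_raw == 0:
        raise ValueError("all voxels constant: ALFF normalization undefined")
    return AlffFeatures(raw=raw, normalized=raw / mean_raw, band=(f_lo, f_hi))


def periodogram_power(series: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum after linear detrending, scaled so the sum
    over positive frequencies equals the detrended series' variance
    (Parseval)."""
    freqs, pxx = sp_signal.periodogram(series, fs=1.0 / tr, detrend="linear",
                                       scaling="spectrum", axis=-1)
    return freqs, np.atleast_2d(pxx)


# ----------------------------------------------------------------------
# feature-table adapters
# ----------------------------------------------------------------------

def fc_feature_table(roi_set: RoiTimeSeriesSet, penalty: float) -> FeatureTable:
    """Partial-correlation features for every subject, as a table in the
    'Functional connectivity' group."""
    rows = [estimate_sparse_partial_correlations(s, penalty).vector
            for s in roi_set.series]
    k = roi_set.n_components
    iu = np.triu_indices(k, 1)
    names = [f"fc_{i:03d}_{j:03d}" for i, j in zip(*iu)]
    values = pd.DataFrame(np.vstack(rows), columns=names)
    return FeatureTable(values, {n: "Functional connectivity" for n in names})


def alff_feature_table(voxel_set: VoxelTimeSeriesSet,
                       band: tuple[float, float] = (0.0, 0.1),
                       amplitude: bool = False) -> FeatureTable:
    """Normalized ALFF for every subject, as a table in the 'ALFF' group."""
    rows = [compute_alff(s, voxel_set.tr, band=band, amplitude=amplitude).normalized
            for s in voxel_set.series]
    names = [f"alff_{v:05d}" for v in range(voxel_set.series.shape[1])]
    values = pd.DataFrame(np.vstack(rows), columns=names)
    return FeatureTable(values, {n: "ALFF" for n in names})
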