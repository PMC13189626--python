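"""Functional-connectivity quantification from node time series.

Three metrics, with the choice treated downstream as a hyperparameter:

* full Pearson correlation between node time series;
* ridge-regularized partial correlation, ``Omega = (S + rho * mean_diag * I)^-1``
  with partial r_ij = -Omega_ij / sqrt(Omega_ii Omega_jj) (rho = 0.5 by
  default, scale-free because the penalty multiplies the mean diagonal);
* tangent-space parameterization: each subject's Ledoit-Wolf-shrunk
  covariance is whitened by a group reference covariance estimated on
  training subjects only and mapped through the matrix logarithm,
  linearizing the SPD manifold around the reference.

Correlations may be variance-stabilized with the arctanh (Fisher z)
transform before vectorization; diagonals are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.covariance import LedoitWolf

__all__ = [
    "full_correlation",
    "partial_correlation_ridge",
    "fisher_z",
    "TangentProjector",
    "network_amplitudes",
    "vectorize_offdiag",
    "select_fc_metric",
]


def _check_ts(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be T x k")
    sd = ts.std(axis=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant node time series at column(s) {bad.tolist()}")
    return ts


def full_correlation(ts: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a T x k time-series matrix."""
    ts = _check_ts(ts)
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def partial_correlation_ridge(ts: np.ndarray, rho: float = 0.5) -> np.ndarray:
    """L2-regularized partial correlation between nodes.

    The sample covariance is ridge-stabilized before inversion; the
    regularization strength ``rho`` multiplies the mean diagonal of the
    covariance so the amount of shrinkage is independent of signal scale.
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    ts = _check_ts(ts)
    S = np.cov(ts, rowvar=False, ddof=0)
    if not np.all(np.isfinite(S)):
        raise ValueError("non-finite covariance")
    k = S.shape[0]
    omega = np.linalg.inv(S + rho * np.mean(np.diag(S)) * np.eye(k))
    d = np.sqrt(np.diag(omega))
    pr = -omega / np.outer(d, d)
    np.fill_diagonal(pr, 1.0)
    return pr


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Element-wise arctanh; off-diagonal values are clipped just inside
    (-1, 1) with a warning if any |r| reaches 1."""
    r = np.asarray(r, dtype=float)
    limit = 1.0 - 1e-12
    square = r.ndim == 2 and r.shape[0] == r.shape[1]
    offdiag = ~np.eye(r.shape[0], dtype=bool) if square else np.ones(r.shape, bool)
    if np.any(np.abs(r[offdiag]) >= 1.0):
        warnings.warn("clipping |r|>=1 before arctanh")
    z = np.arctanh(np.clip(r, -limit, limit))
    return z


def vectorize_offdiag(M: np.ndarray) -> np.ndarray:
    """Upper-triangle vectorization excluding the diagonal."""
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def network_amplitudes(ts: np.ndarray) -> np.ndarray:
    """Per-node standard deviation of the time series."""
    return _check_ts(ts).std(axis=0, ddof=0)


@dataclass
class TangentProjector:
    """Tangent-space projector around a training-set reference covariance."""

    C_ref: np.ndarray
    whitener: np.ndarray
    n_train: int

    @classmethod
    def fit(cls, train_timeseries: "list[np.ndarray]") -> "TangentProjector":
        """Estimate the reference as the Euclidean mean of per-subject
        Ledoit-Wolf covariances of z-scored time series."""
        if len(train_timeseries) < 2:
            raise ValueError("need at least two training subjects")
        covs = [cls._lw_cov(ts) for ts in train_timeseries]
        C_ref = np.mean(covs, axis=0)
        vals, vecs = linalg.eigh(C_ref)
        if np.any(vals <= 0):
            raise AssertionError("reference covariance not SPD")
        whitener = vecs @ np.diag(vals ** -0.5) @ vecs.T
        return cls(C_ref=C_ref, whitener=whitener, n_train=len(train_timeseries))

    @staticmethod
    def _lw_cov(ts: np.ndarray) -> np.ndarray:
        ts = _check_ts(ts)
        z = (ts - ts.mean(axis=0)) / ts.std(axis=0, ddof=0)
        return LedoitWolf(assume_centered=True).fit(z).covariance_

    def project(self, ts: np.ndarray, vectorize: bool = True) -> np.ndarray:
        """Tangent embedding ``logm(whitener @ Sigma_subj @ whitener)``.

        Returns the off-diagonal upper triangle by default.
        """
        sigma = self._lw_cov(ts)
        M = self.whitener @ sigma @ self.whitener
        M = (M + M.T) / 2.0
        vals, vecs = linalg.eigh(M)
        if np.any(vals <= 0):
            raise ValueError("whitened subject covariance not SPD")
        T = vecs @ np.diag(np.log(vals)) @ vecs.T
        T = (T + T.T) / 2.0
        return vectorize_offdiag(T) if vectorize else T


def select_fc_metric(inner_cv_scores: "dict[str, float]") -> str:
    """Pick the connectivity metric with the best inner-fold score (R2).

    Ties go to the tangent parameterization when it is among the leaders.
    """
    if not inner_cv_scores:
        raise ValueError("no metric scores supplied")
    best = max(inner_cv_scores.values())
    leaders = [m for m, s in inner_cv_scores.items() if s == best]
    if "tangent" in leaders:
        return "tangent"
    return leaders[0]
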