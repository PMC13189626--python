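"""Standardization and confound removal with train/test separation.

All scaling parameters and confound-regression coefficients are estimated
on training rows only and then applied unchanged to test rows, so no
statistic derived from the test set leaks into any fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Standardizer",
    "standardize_fit_apply",
    "ConfoundRegression",
    "regress_out",
    "build_confound_design",
]


@dataclass
class Standardizer:
    """Column means/SDs estimated on a training set."""

    mean: np.ndarray
    sd: np.ndarray
    dropped: np.ndarray  # boolean mask of zero-variance columns

    def apply(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, dtype=float)
        Z = (M - self.mean) / self.sd
        return Z[:, ~self.dropped] if self.dropped.any() else Z


def standardize_fit_apply(
    train: np.ndarray, test: "np.ndarray | None" = None
) -> tuple[np.ndarray, "np.ndarray | None", Standardizer]:
    """Z-score train and test with training means and SDs.

    Zero-variance training columns are dropped (with a warning) rather than
    divided by zero.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training set")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dropped = sd == 0
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} zero-variance column(s)")
    sd = np.where(dropped, 1.0, sd)
    params = Standardizer(mean=mean, sd=sd, dropped=dropped)
    train_std = params.apply(train)
    test_std = None
    if test is not None:
        test = np.asarray(test, dtype=float)
        if test.shape[1] != train.shape[1]:
            raise ValueError("test columns do not match train columns")
        test_std = params.apply(test)
    return train_std, test_std, params


@dataclass
class ConfoundRegression:
    """Per-feature least-squares confound coefficients fit on training rows."""

    beta: np.ndarray  # (n_confounds + 1, n_features); row 0 is intercept
    kept: np.ndarray  # confound columns retained after rank check

    def residualize(self, features: np.ndarray, confounds: np.ndarray) -> np.ndarray:
        C = np.column_stack(
            [np.ones(len(confounds)), np.asarray(confounds, float)[:, self.kept]]
        )
        return np.asarray(features, float) - C @ self.beta


def regress_out(
    features: np.ndarray,
    confounds: np.ndarray,
    fit_mask: np.ndarray,
) -> tuple[np.ndarray, ConfoundRegression]:
    """Remove linear confound effects, fitting on ``fit_mask`` rows only.

    Residuals are returned for all rows; test rows are residualized with the
    training coefficients.  Collinear confound columns are dropped with a
    warning before fitting.
    """
    F = np.asarray(features, dtype=float)
    C = np.asarray(confounds, dtype=float)
    mask = np.asarray(fit_mask, dtype=bool)
    if F.shape[0] != C.shape[0]:
        raise ValueError("features and confounds have different row counts")
    Ct = C[mask]
    # greedy rank check on the training design
    kept = []
    for j in range(C.shape[1]):
        cand = Ct[:, kept + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(cand)), cand])) == (
            len(kept) + 2
        ):
            kept.append(j)
    if len(kept) < C.shape[1]:
        warnings.warn(
            f"dropped {C.shape[1] - len(kept)} collinear confound column(s)"
        )
    kept = np.array(kept, dtype=int)
    design = np.column_stack([np.ones(mask.sum()), Ct[:, kept]])
    beta, *_ = np.linalg.lstsq(design, F[mask], rcond=None)
    reg = ConfoundRegression(beta=beta, kept=kept)
    return reg.residualize(F, C), reg


def build_confound_design(
    confounds: pd.DataFrame,
    categorical: "tuple[str, ...]" = ("site",),
) -> pd.DataFrame:
    """Numeric confound design: reference-coded dummies for categoricals.

    Numeric columns pass through unchanged; each categorical column is
    expanded into k-1 dummy indicators against its first (reference) level.
    """
    cols = {}
    for name in confounds.columns:
        if name in categorical:
            levels = sorted(pd.unique(confounds[name]))
            for lev in levels[1:]:
                cols[f"{name}_{lev}"] = (confounds[name] == lev).astype(float)
        else:
            cols[name] = pd.to_numeric(confounds[name]).astype(float)
    return pd.DataFrame(cols, index=confounds.index)
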