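"""Partial least squares regression (PLS1) via NIPALS.

The single-response PLS model decomposes a standardized predictor matrix
``X`` (n x p) into orthogonal latent scores and loadings,

    X = T P' + E,   T = X W*,   y = T c' + f,   y_hat = X B,  B = W* c',

where each weight vector ``w_a`` is the covariance-maximizing direction
``X' y`` of the current (deflated) predictor matrix, normalized to unit
length.  Components are extracted sequentially, deflating ``X`` after each
step so that the score vectors ``t_a`` are mutually orthogonal.  With a
scalar response the classical multi-Y algorithm collapses to this PLS1
form, which is numerically identical and simpler.

The number of components is the only hyperparameter; it is selected by
minimizing the mean absolute error across shuffled inner folds
(:func:`select_components`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["PLSModel", "PLSResults", "select_components"]


def _standardize_params(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    return mean, sd


@dataclass
class PLSResults:
    """Fitted PLS1 model: weights, loadings, coefficients and training scale.

    Attributes
    ----------
    W : (p, A) raw weight matrix (orthonormal columns).
    W_star : (p, A) transformed weights, ``W (P'W)^{-1}``, so ``T = X W*``.
    P : (p, A) X-loadings.
    c : (A,) y-weights.
    coef : (p,) regression coefficients on the standardized scale,
        ``B = W* c'``.
    r2_increment : (A,) training-R2 gain of each successive component.
    """

    W: np.ndarray
    W_star: np.ndarray
    P: np.ndarray
    c: np.ndarray
    coef: np.ndarray
    n_components: int
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    train_r2: float
    r2_increment: np.ndarray
    scores: np.ndarray = field(repr=False)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Predict the response for new rows, on the original y scale."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.coef.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model was trained "
                f"with {self.coef.shape[0]}"
            )
        Xs = (X_new - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Xs @ self.coef)

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Latent scores ``T_new = standardized(X_new) W*``."""
        Xs = (np.asarray(X_new, dtype=float) - self.x_mean) / self.x_sd
        return Xs @ self.W_star

    def weighted_loadings(self, weighting: str = "incremental") -> np.ndarray:
        """Summary X-loadings averaged over components, weighted by training R2.

        ``weighting='incremental'`` uses the R2 gained by each component
        (cumulative differences); ``'standalone'`` uses each component's
        solo R2.  The summary is sign-oriented to correlate positively with
        the coefficient vector.
        """
        if self.n_components == 0:
            raise ValueError("model has no components")
        if weighting == "incremental":
            w = self.r2_increment.copy()
        elif weighting == "standalone":
            # R2 of a one-component regression on t_a alone
            w = np.array(
                [
                    self.c[a] ** 2 * np.var(self.scores[:, a])
                    for a in range(self.n_components)
                ]
            )
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        w = np.clip(w, 0.0, None)
        if w.sum() <= 0:
            w = np.ones_like(w)
        # orient each loading vector by the sign of its y-weight so that
        # components pull in the direction of increasing y
        signed = self.P * np.sign(self.c)[None, :]
        summary = signed @ w / w.sum()
        if summary @ self.coef < 0:
            summary = -summary
        return summary


class PLSModel:
    """PLS1 regression model, fit by NIPALS on standardized data.

    Parameters
    ----------
    X : (n, p) predictor matrix (raw scale; standardization is internal
        and its parameters are stored with the results).
    y : (n,) response vector.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance")
        self.X = X
        self.y = y
        self.n, self.p = X.shape

    def fit(self, n_components: int, strict: bool = True) -> PLSResults:
        """Extract ``n_components`` NIPALS components.

        With ``strict=False`` extraction stops early (returning fewer
        components) if the deflated covariance vanishes before the
        requested count — useful while scanning a component grid.
        """
        A = int(n_components)
        rank = np.linalg.matrix_rank(self.X - self.X.mean(axis=0))
        if A < 1 or (strict and A > rank):
            raise ValueError(f"n_components must be in [1, rank(X)={rank}]")
        A = min(A, rank)

        x_mean, x_sd = _standardize_params(self.X)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        y_mean, y_sd = self.y.mean(), self.y.std(ddof=0)

        Xs = (self.X - x_mean) / x_sd
        ys = (self.y - y_mean) / y_sd

        Xd = Xs.copy()
        W = np.zeros((self.p, A))
        P = np.zeros((self.p, A))
        c = np.zeros(A)
        T = np.zeros((self.n, A))
        nw0 = np.linalg.norm(Xs.T @ ys)
        for a in range(A):
            w = Xd.T @ ys
            nw = np.linalg.norm(w)
            if nw <= max(1e-12 * nw0, 1e-300):
                # Krylov space saturated: the k-component solution already
                # coincides with the least-squares limit, so truncate
                A = a
                W, P, c, T = W[:, :A], P[:, :A], c[:A], T[:, :A]
                break
            w /= nw
            t = Xd @ w
            tt = t @ t
            p_a = Xd.T @ t / tt
            c_a = ys @ t / tt
            Xd -= np.outer(t, p_a)
            W[:, a], P[:, a], c[a], T[:, a] = w, p_a, c_a, t

        if A == 0:
            raise np.linalg.LinAlgError("X carries no covariance with y")
        W_star = W @ np.linalg.inv(P.T @ W)
        coef = W_star @ c

        # cumulative R2 per number of components (training data)
        resid = ys.copy()
        sst = ys @ ys
        r2_cum = np.zeros(A)
        for a in range(A):
            resid = resid - T[:, a] * c[a]
            r2_cum[a] = 1.0 - (resid @ resid) / sst
        r2_increment = np.diff(np.concatenate([[0.0], r2_cum]))

        return PLSResults(
            W=W,
            W_star=W_star,
            P=P,
            c=c,
            coef=coef,
            n_components=A,
            x_mean=x_mean,
            x_sd=x_sd,
            y_mean=y_mean,
            y_sd=y_sd,
            train_r2=float(r2_cum[-1]),
            r2_increment=r2_increment,
            scores=T,
        )


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    grid: "list[int] | None" = None,
    inner_folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the component count minimizing mean inner-fold validation MAE.

    Ties break toward the smaller (more parsimonious) count.  Grid values
    exceeding the inner-training rank are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if grid is None:
        grid = list(range(1, min(20, p, n - 1) + 1))
    if not grid:
        raise ValueError("empty component grid")
    grid = sorted(set(int(a) for a in grid))

    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    maes = {A: [] for A in grid}
    for tr, va in kf.split(X):
        max_rank = np.linalg.matrix_rank(X[tr] - X[tr].mean(axis=0))
        feasible = [A for A in grid if A <= max_rank]
        if not feasible:
            continue
        A_max = max(feasible)
        res = PLSModel(X[tr], y[tr]).fit(A_max, strict=False)
        A_max = res.n_components
        # score every component count from one sequential deflation pass:
        # t_new,a = Xd_new w_a, Xd_new <- Xd_new - t_new,a p_a',
        # y_hat(A) = y_mean + y_sd * sum_{a<=A} t_new,a c_a
        Xd = (X[va] - res.x_mean) / res.x_sd
        yhat_s = np.zeros(len(va))
        for a in range(A_max):
            t = Xd @ res.W[:, a]
            Xd -= np.outer(t, res.P[:, a])
            yhat_s += t * res.c[a]
            A = a + 1
            if A in maes:
                pred = res.y_mean + res.y_sd * yhat_s
                maes[A].append(np.mean(np.abs(y[va] - pred)))
    usable = {A: np.mean(v) for A, v in maes.items() if v}
    if not usable:
        raise ValueError("no grid value usable on any inner fold")
    best = min(usable, key=lambda A: (usable[A], A))
    return int(best)
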