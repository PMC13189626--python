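"""Hierarchical g-factor modeling of cognitive test scores.

A second-order general factor (g) underlies m first-order latent factors
which in turn underlie the 12 transformed cognitive scores.  The workflow
mirrors standard practice in differential psychology:

1. factorability checks — KMO sampling adequacy and Bartlett's sphericity;
2. parallel analysis to choose the number of first-order factors;
3. oblique (quartimin/oblimin) ML exploratory factor analysis, from which
   one anchor variable per factor (largest absolute loading) is taken;
4. a hierarchical confirmatory ML fit in which the anchor rows of the
   loading matrix are fixed at their EFA values for rotational
   identification, all other loadings are free, factors have unit variance
   with second-order structure ``Phi = gamma gamma' + diag(1 - gamma^2)``;
5. fit indices (chi2, CFI, TLI, RMSEA, SRMR, BIC) against the
   independence baseline, and Thurstone regression scores for g.

The implied covariance is ``Sigma = Lambda Phi Lambda' + Theta`` and the
discrepancy minimized is the ML fit function
``F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "kmo",
    "bartlett",
    "parallel_analysis",
    "efa_oblimin",
    "HierarchicalFactorModel",
    "HierarchicalFactorResults",
    "FitIndices",
]


# ---------------------------------------------------------------------------
# factorability diagnostics


def kmo(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    ``KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over i != j, where q
    are the anti-image partial correlations obtained from the inverse
    correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    off = ~np.eye(p, dtype=bool)
    r2 = np.sum(R[off] ** 2)
    if r2 == 0:
        raise ValueError("identity correlation matrix: KMO undefined (0/0)")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular correlation matrix; consider a ridge-stabilized "
            "estimate before KMO"
        ) from e
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    q2 = np.sum(Q[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett(R: np.ndarray, n: int) -> "dict[str, float]":
    """Bartlett's test of sphericity against the identity correlation.

    ``chi2 = -(n - 1 - (2p + 5)/6) ln|R|`` on ``p(p-1)/2`` degrees of
    freedom.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need n > p for Bartlett's test")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("|R| <= 0")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) / 2.0
    pval = float(stats.chi2.sf(chi2, df))
    return {"chi2": float(chi2), "df": df, "p": pval}


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations of each variable on the rest."""
    Rinv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(Rinv)


def parallel_analysis(
    data: np.ndarray,
    n_iter: int = 100,
    quantile_rule: str = "mean",
    seed: int = 0,
    method: str = "fa",
) -> int:
    """Number of factors by Horn's parallel analysis.

    Compares eigenvalues of the observed correlation matrix with the
    per-rank mean (or 95th percentile) of eigenvalues from ``n_iter``
    standard-normal datasets of the same shape.  ``method='fa'`` uses
    common-factor (reduced, SMC-on-diagonal) eigenvalues, which is the
    conventional criterion for choosing the number of factors;
    ``method='pc'`` uses raw correlation eigenvalues.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < p:
        warnings.warn("fewer rows than columns; parallel analysis unstable")

    def eigs(M: np.ndarray) -> np.ndarray:
        R = np.corrcoef(M, rowvar=False)
        if method == "fa":
            Rr = R.copy()
            np.fill_diagonal(Rr, _smc(R))
            return np.sort(np.linalg.eigvalsh(Rr))[::-1]
        return np.sort(np.linalg.eigvalsh(R))[::-1]

    obs = eigs(X)
    rng = np.random.default_rng(seed)
    ref = np.empty((n_iter, p))
    for i in range(n_iter):
        ref[i] = eigs(rng.standard_normal((n, p)))
    if quantile_rule == "mean":
        thresh = ref.mean(axis=0)
    elif quantile_rule == "p95":
        thresh = np.percentile(ref, 95, axis=0)
    else:
        raise ValueError("quantile_rule must be 'mean' or 'p95'")
    exceed = obs > thresh
    # leading run of exceedances
    k = 0
    for e in exceed:
        if not e:
            break
        k += 1
    return k


# ---------------------------------------------------------------------------
# exploratory stage


def efa_oblimin(data: np.ndarray, n_factors: int) -> np.ndarray:
    """Oblique (quartimin) ML exploratory factor loadings.

    ML extraction and gradient-projection rotation are delegated to
    statsmodels; returns the rotated p x m pattern matrix.
    """
    X = np.asarray(data, dtype=float)
    fa = Factor(X, n_factor=n_factors, method="ml").fit()
    L = np.asarray(fa.loadings)
    if n_factors == 1:
        return L
    L_rot, _ = rotate_factors(L, "quartimin")
    # orient each factor so its dominant loading is positive
    signs = np.sign(L_rot[np.argmax(np.abs(L_rot), axis=0), range(n_factors)])
    signs[signs == 0] = 1.0
    return L_rot * signs


def pick_anchors(loadings: np.ndarray) -> np.ndarray:
    """One anchor variable per factor: the largest |loading|, without reuse."""
    p, m = loadings.shape
    order = np.argsort(-np.abs(loadings), axis=0)
    anchors = np.full(m, -1)
    # assign greedily, strongest claims first
    claims = sorted(
        ((abs(loadings[order[0, j], j]), j) for j in range(m)), reverse=True
    )
    taken: set[int] = set()
    for _, j in claims:
        for i in order[:, j]:
            if i not in taken:
                anchors[j] = i
                taken.add(int(i))
                break
    if np.any(anchors < 0):
        raise ValueError("could not assign distinct anchors")
    return anchors


# ---------------------------------------------------------------------------
# hierarchical confirmatory model


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    tli: float
    rmsea: float
    srmr: float
    bic: float

    def as_dict(self) -> "dict[str, float]":
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "CFI": self.cfi,
            "TLI": self.tli,
            "RMSEA": self.rmsea,
            "SRMR": self.srmr,
            "BIC": self.bic,
        }


@dataclass
class HierarchicalFactorResults:
    """Converged hierarchical factor solution.

    ``Lambda`` are first-order loadings (p x m), ``gamma`` the loadings of
    the m factors on g, ``theta`` the uniquenesses.  ``scoring_weights``
    map standardized test scores to the Thurstone regression estimate of
    g; ``determinacy`` is the theoretical upper bound on the correlation
    between the estimated and true g.
    """

    Lambda: np.ndarray
    gamma: np.ndarray
    theta: np.ndarray
    anchors: np.ndarray
    fit: FitIndices
    scoring_weights: np.ndarray
    determinacy: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    n_obs: int
    converged: bool
    heywood: bool = False
    columns: "list[str] | None" = None
    fml: float = field(default=np.nan, repr=False)

    @property
    def psi(self) -> np.ndarray:
        return 1.0 - self.gamma**2

    def implied_sigma(self) -> np.ndarray:
        phi = np.outer(self.gamma, self.gamma) + np.diag(self.psi)
        return self.Lambda @ phi @ self.Lambda.T + np.diag(self.theta)

    def variance_explained(self) -> "dict[str, float]":
        """Two labeled variance summaries.

        ``g_share_of_test_variance``: mean squared g-loading of the tests
        (the share of standardized test variance carried by g).
        ``factor_share_of_test_variance``: mean communality — the share
        of standardized test variance carried by the first-order common
        factors together.
        """
        g_load = self.Lambda @ self.gamma
        phi = np.outer(self.gamma, self.gamma) + np.diag(self.psi)
        communal = np.einsum("ik,kl,il->i", self.Lambda, phi, self.Lambda)
        return {
            "g_share_of_test_variance": float(np.mean(g_load**2)),
            "factor_share_of_test_variance": float(np.mean(communal)),
        }

    def score(self, data: np.ndarray) -> np.ndarray:
        """Thurstone regression g scores for new rows, standardized with
        the training means/SDs stored in the results."""
        Z = (np.asarray(data, dtype=float) - self.x_mean) / self.x_sd
        return Z @ self.scoring_weights

    def summary(self) -> str:
        cols = self.columns or [f"x{i + 1}" for i in range(self.Lambda.shape[0])]
        m = self.Lambda.shape[1]
        lines = ["Hierarchical g-factor model (ML)", "=" * 48]
        header = "test".ljust(18) + "".join(f"F{j + 1}".rjust(8) for j in range(m))
        lines.append(header + "  uniq".rjust(8))
        for i, c in enumerate(cols):
            row = c[:17].ljust(18) + "".join(
                f"{self.Lambda[i, j]:8.3f}" for j in range(m)
            )
            lines.append(row + f"{self.theta[i]:8.3f}")
        lines.append("g loadings: " + "  ".join(f"{g:.3f}" for g in self.gamma))
        f = self.fit
        lines.append(
            f"chi2({f.df})={f.chi2:.1f} p={f.p:.3g}  CFI={f.cfi:.3f} "
            f"TLI={f.tli:.3f} RMSEA={f.rmsea:.3f} SRMR={f.srmr:.3f} "
            f"BIC={f.bic:.1f}"
        )
        lines.append(f"factor determinacy of g: {self.determinacy:.3f}")
        return "\n".join(lines)


class HierarchicalFactorModel:
    """ML hierarchical factor model for a battery of test scores.

    Parameters
    ----------
    data : (n, p) numeric array or DataFrame of test scores (rows with
        missing values are dropped listwise).
    n_factors : number of first-order factors; if None, chosen by
        parallel analysis.
    anchors : optional explicit anchor indices (one per factor); by
        default taken from the oblimin EFA solution.
    """

    def __init__(
        self,
        data,
        n_factors: "int | None" = None,
        anchors: "np.ndarray | None" = None,
        seed: int = 0,
    ):
        if isinstance(data, pd.DataFrame):
            self.columns = list(data.columns)
            X = data.to_numpy(dtype=float)
        else:
            self.columns = None
            X = np.asarray(data, dtype=float)
        keep = ~np.isnan(X).any(axis=1)
        self.X = X[keep]
        self.n, self.p = self.X.shape
        self.seed = seed
        self.n_factors = n_factors
        self.anchors = None if anchors is None else np.asarray(anchors, int)

    def fit(
        self,
        gtol: float = 1e-6,
        maxiter: int = 2000,
    ) -> HierarchicalFactorResults:
        m = self.n_factors
        if m is None:
            m = parallel_analysis(self.X, seed=self.seed)
            m = max(m, 1)
        x_mean = self.X.mean(axis=0)
        x_sd = self.X.std(axis=0, ddof=0)
        Z = (self.X - x_mean) / x_sd
        S = np.corrcoef(Z, rowvar=False)
        p = self.p

        if m == 1:
            efa_load = efa_oblimin(Z, 1)
        else:
            efa_load = efa_oblimin(Z, m)
        anchors = self.anchors if self.anchors is not None else pick_anchors(efa_load)
        if len(set(anchors.tolist())) != m:
            raise ValueError("anchors must be distinct")

        free_rows = np.array([i for i in range(p) if i not in set(anchors.tolist())])
        n_free_load = len(free_rows) * m

        def unpack(theta_vec):
            Lambda = np.empty((p, m))
            Lambda[anchors, :] = efa_load[anchors, :]
            Lambda[free_rows, :] = theta_vec[:n_free_load].reshape(len(free_rows), m)
            gamma = theta_vec[n_free_load : n_free_load + m]
            uniq = theta_vec[n_free_load + m :]
            return Lambda, gamma, uniq

        def fml(theta_vec):
            Lambda, gamma, uniq = unpack(theta_vec)
            phi = np.outer(gamma, gamma) + np.diag(1.0 - gamma**2)
            sigma = Lambda @ phi @ Lambda.T + np.diag(uniq)
            try:
                cho = linalg.cho_factor(sigma, check_finite=False)
            except linalg.LinAlgError:
                return 1e10
            logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
            trace = np.trace(linalg.cho_solve(cho, S, check_finite=False))
            sign_s, logdet_s = np.linalg.slogdet(S)
            val = logdet + trace - logdet_s - p
            return val if np.isfinite(val) else 1e10

        # start at the EFA solution with a strong general factor
        start_load = efa_load[free_rows, :].ravel()
        start_gamma = np.full(m, 0.7)
        start_uniq = np.clip(1.0 - np.sum(efa_load**2, axis=1), 0.05, 0.95)
        x0 = np.concatenate([start_load, start_gamma, start_uniq])
        bounds = (
            [(-1.5, 1.5)] * n_free_load
            + [(-0.999, 0.999)] * m
            + [(1e-6, 2.0)] * p
        )
        opt = optimize.minimize(
            fml,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "gtol": gtol, "maxfun": 200000},
        )
        Lambda, gamma, uniq = unpack(opt.x)
        if m == 1:
            # the factor covariance gamma gamma' + (1 - gamma^2) is the
            # scalar 1 regardless of gamma: the hierarchy collapses and the
            # second-order loading is fixed at 1 by convention
            gamma = np.array([1.0])
        heywood = bool(np.any(uniq <= 1.5e-6))
        if heywood:
            warnings.warn("Heywood case: uniqueness bounded at 1e-6")
        if not opt.success and opt.fun >= 1e9:
            raise RuntimeError(f"hierarchical fit failed: {opt.message}")

        # orient g positively: flip gamma (and g) so most tests load + on g
        g_load = Lambda @ gamma
        if np.sum(g_load) < 0:
            gamma = -gamma

        k_params = n_free_load + (m if m > 1 else 0) + p
        fitidx = self._fit_indices(Lambda, gamma, uniq, S, self.n, k_params)

        sigma = (
            Lambda @ (np.outer(gamma, gamma) + np.diag(1.0 - gamma**2)) @ Lambda.T
            + np.diag(uniq)
        )
        cov_gy = Lambda @ gamma
        weights = np.linalg.solve(sigma, cov_gy)
        determinacy = float(np.sqrt(cov_gy @ weights))

        return HierarchicalFactorResults(
            Lambda=Lambda,
            gamma=gamma,
            theta=uniq,
            anchors=anchors,
            fit=fitidx,
            scoring_weights=weights,
            determinacy=determinacy,
            x_mean=x_mean,
            x_sd=x_sd,
            n_obs=self.n,
            converged=bool(opt.success),
            heywood=heywood,
            columns=self.columns,
            fml=float(opt.fun),
        )

    @staticmethod
    def _fit_indices(Lambda, gamma, uniq, S, n, k_params) -> FitIndices:
        p = S.shape[0]
        phi = np.outer(gamma, gamma) + np.diag(1.0 - gamma**2)
        sigma = Lambda @ phi @ Lambda.T + np.diag(uniq)
        sign, logdet = np.linalg.slogdet(sigma)
        sign_s, logdet_s = np.linalg.slogdet(S)
        trace = np.trace(np.linalg.solve(sigma, S))
        F = logdet + trace - logdet_s - p
        F = max(F, 0.0)
        df = p * (p + 1) // 2 - k_params
        chi2 = (n - 1) * F
        pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

        # independence baseline
        F_b = -logdet_s  # Sigma_b = I for a correlation matrix
        chi2_b = (n - 1) * F_b
        df_b = p * (p - 1) // 2

        d = max(chi2 - df, 0.0)
        d_b = max(chi2_b - df_b, 0.0)
        cfi = 1.0 - d / max(d_b, d, 1e-12)
        if chi2_b / df_b - 1.0 > 0:
            tli = ((chi2_b / df_b) - (chi2 / df if df > 0 else 0.0)) / (
                chi2_b / df_b - 1.0
            )
            tli = min(tli, 1.0)
        else:
            tli = 1.0
        rmsea = np.sqrt(d / (df * (n - 1))) if df > 0 else 0.0
        resid = S - sigma
        iu = np.triu_indices(p)
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
        loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet + trace)
        bic = -2.0 * loglik + k_params * np.log(n)
        return FitIndices(
            chi2=float(chi2),
            df=int(df),
            p=pval,
            cfi=float(cfi),
            tli=float(tli),
            rmsea=float(rmsea),
            srmr=srmr,
            bic=float(bic),
        )
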