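"""Nested cross-validation, base PLSR models and stacked generalization.

The prediction design is a nested scheme with five outer folds and ten
inner folds.  Each outer fold is held out once as a test set while the
remaining folds form the training set; inner folds, drawn within each
outer training set, are used exclusively for hyperparameter selection
(PLSR component count by mean absolute error, stacking hyperparameters by
mean squared error).  The tuned model is refit on the full outer training
set and evaluated on the outer test set, so every subject receives
exactly one out-of-sample prediction per model.

Stacked (second-level) models take the base models' predicted g as
features.  For outer-training subjects those features are inner-fold
out-of-fold predictions (cross-fitting), so the stack cannot learn the
base models' training optimism; for outer-test subjects they are the
refit base models' test predictions.  Four algorithms are supported —
elastic net, random forest, RBF-kernel support vector regression, and
gradient-boosted trees — and the winner is the one with the highest mean
out-of-sample R-squared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import ParameterGrid
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .deconfound import regress_out, standardize_fit_apply
from .plsr import PLSModel

__all__ = [
    "FoldPlan",
    "make_fold_plan",
    "evaluate",
    "BaseModelResult",
    "run_base_model",
    "StackResult",
    "fit_stack",
    "select_algorithm",
    "DEFAULT_STACK_GRIDS",
    "ALGORITHM_TIE_ORDER",
]


# ---------------------------------------------------------------------------
# folds


@dataclass
class FoldPlan:
    """Outer/inner fold assignment for nested cross-validation.

    ``outer[i]`` is subject i's outer fold (0..k_outer-1); ``inner[f][i]``
    is the inner fold of subject i within outer-training set f, or -1 for
    subjects in outer-test fold f.
    """

    outer: np.ndarray
    inner: "dict[int, np.ndarray]"
    k_outer: int
    k_inner: int
    seed: int

    def train_mask(self, f: int) -> np.ndarray:
        return self.outer != f

    def test_mask(self, f: int) -> np.ndarray:
        return self.outer == f


def make_fold_plan(
    subject_ids, k_outer: int = 5, k_inner: int = 10, seed: int = 0
) -> FoldPlan:
    """Random near-equal partition (sizes differ by at most one),
    deterministic given the seed; inner partitions are drawn within each
    outer training set."""
    n = len(subject_ids)
    if n < k_outer:
        raise ValueError(f"need at least k_outer={k_outer} subjects, got {n}")
    rng = np.random.default_rng(seed)
    outer = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k_outer)):
        outer[chunk] = f
    inner = {}
    for f in range(k_outer):
        assign = np.full(n, -1, dtype=int)
        tr = np.flatnonzero(outer != f)
        perm_tr = rng.permutation(tr)
        for j, chunk in enumerate(np.array_split(perm_tr, k_inner)):
            assign[chunk] = j
        inner[f] = assign
    return FoldPlan(outer=outer, inner=inner, k_outer=k_outer, k_inner=k_inner, seed=seed)


# ---------------------------------------------------------------------------
# evaluation


def evaluate(y: np.ndarray, y_hat: np.ndarray) -> "dict[str, float]":
    """R2 (coefficient of determination), Pearson r, MAE and MSE."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    err = y - y_hat
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return {"R2": float("nan"), "r": float("nan"), "MAE": mae, "MSE": mse}
    r2 = 1.0 - float(np.sum(err**2)) / sst
    r = float(np.corrcoef(y, y_hat)[0, 1]) if np.std(y_hat) > 0 else float("nan")
    return {"R2": r2, "r": r, "MAE": mae, "MSE": mse}


def _mean_metrics(per_fold: "list[dict[str, float]]") -> "dict[str, float]":
    out = {}
    for k in per_fold[0]:
        vals = [m[k] for m in per_fold if not np.isnan(m[k])]
        out[k] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# base (first-level) PLSR models


@dataclass
class BaseModelResult:
    """Pooled out-of-sample predictions of one phenotype's PLSR model."""

    name: str
    test_pred: np.ndarray  # (n,) prediction from the fold where i was test
    oof_train_pred: "dict[int, np.ndarray]"  # per outer fold, NaN on test rows
    n_components: "dict[int, int]"
    per_fold_metrics: "list[dict[str, float]]"
    metrics: "dict[str, float]"
    deconfounded_test_features: "np.ndarray | None" = field(
        default=None, repr=False
    )


def _select_components_planned(X, y, grid, inner_ids, k_inner):
    """Component count minimizing mean inner-fold MAE on a fixed plan."""
    maes = {A: [] for A in grid}
    for j in range(k_inner):
        tr = inner_ids != j
        va = ~tr
        max_rank = min(np.sum(tr) - 1, X.shape[1])
        feasible = [A for A in grid if A <= max_rank]
        if not feasible:
            continue
        A_max = max(feasible)
        res = PLSModel(X[tr], y[tr]).fit(A_max, strict=False)
        A_max = res.n_components
        Xd = (X[va] - res.x_mean) / res.x_sd
        yhat_s = np.zeros(int(np.sum(va)))
        for a in range(A_max):
            t = Xd @ res.W[:, a]
            Xd -= np.outer(t, res.P[:, a])
            yhat_s += t * res.c[a]
            if (a + 1) in maes:
                pred = res.y_mean + res.y_sd * yhat_s
                maes[a + 1].append(np.mean(np.abs(y[va] - pred)))
    usable = {A: np.mean(v) for A, v in maes.items() if v}
    if not usable:
        raise ValueError("no usable component count")
    return min(usable, key=lambda A: (usable[A], A))


def run_base_model(
    name: str,
    X: np.ndarray,
    y_folds: np.ndarray,
    plan: FoldPlan,
    confound_design: "np.ndarray | None" = None,
    component_grid: "list[int] | None" = None,
    subject_mask: "np.ndarray | None" = None,
    keep_test_features: bool = False,
) -> BaseModelResult:
    """Nested-CV PLSR prediction of g from one feature block.

    Per outer fold: features (and confounds, when given) are standardized
    with training parameters, confounds are regressed out with training
    coefficients, the component count is chosen on the inner folds by
    MAE, the model is refit on the full outer training set and applied to
    the outer test set.  Inner out-of-fold training-set predictions are
    produced for stacking.  ``subject_mask`` restricts to subjects with
    valid data (others receive NaN everywhere).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    valid = np.ones(n, bool) if subject_mask is None else np.asarray(subject_mask, bool)
    if component_grid is None:
        component_grid = list(range(1, min(20, p) + 1))

    test_pred = np.full(n, np.nan)
    oof = {}
    n_comp = {}
    per_fold = []
    kept_features = np.full((n, p), np.nan) if keep_test_features else None
    for f in range(plan.k_outer):
        tr = plan.train_mask(f) & valid
        te = plan.test_mask(f) & valid
        Xf = X.copy()
        if confound_design is not None:
            C = np.asarray(confound_design, dtype=float)
            # standardize features and confounds on train, then residualize
            _, _, px = standardize_fit_apply(X[tr])
            _, _, pc = standardize_fit_apply(C[tr])
            Xs_all = px.apply(X)
            Cs_all = pc.apply(C)
            fit_rows = np.flatnonzero(tr)
            mask = np.zeros(n, bool)
            mask[fit_rows] = True
            Xf, _ = regress_out(Xs_all, Cs_all, mask)
        y = y_folds[f]
        grid = [A for A in component_grid if A <= min(np.sum(tr) - 1, Xf.shape[1])]
        inner_ids = plan.inner[f]
        A = _select_components_planned(
            Xf[tr], y[tr], grid, inner_ids[tr], plan.k_inner
        )
        n_comp[f] = int(A)
        res = PLSModel(Xf[tr], y[tr]).fit(A, strict=False)
        test_pred[te] = res.predict(Xf[te])
        if keep_test_features:
            kept_features[te] = Xf[te]
        per_fold.append(evaluate(y[te], test_pred[te]))

        # cross-fitted training predictions for the stack
        oof_f = np.full(n, np.nan)
        for j in range(plan.k_inner):
            fit_rows = tr & (inner_ids != j)
            val_rows = tr & (inner_ids == j)
            if val_rows.sum() == 0:
                continue
            r = PLSModel(Xf[fit_rows], y[fit_rows]).fit(
                min(A, int(np.sum(fit_rows)) - 1), strict=False
            )
            oof_f[val_rows] = r.predict(Xf[val_rows])
        oof[f] = oof_f

    return BaseModelResult(
        name=name,
        test_pred=test_pred,
        oof_train_pred=oof,
        n_components=n_comp,
        per_fold_metrics=per_fold,
        metrics=_mean_metrics(per_fold),
        deconfounded_test_features=kept_features,
    )


# ---------------------------------------------------------------------------
# stacked (second-level) models


DEFAULT_STACK_GRIDS: "dict[str, list[dict]]" = {
    "elastic_net": list(
        ParameterGrid({"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]})
    ),
    "random_forest": list(
        ParameterGrid(
            {"n_estimators": [200], "max_depth": [None], "max_features": ["sqrt"]}
        )
    ),
    "svr_rbf": list(ParameterGrid({"C": [1.0], "gamma": ["scale"], "epsilon": [0.1]})),
    "gbt": list(
        ParameterGrid(
            {
                "n_estimators": [300],
                "learning_rate": [0.05],
                "max_depth": [3],
                "subsample": [0.8],
            }
        )
    ),
}

#: deterministic preference order used to break exact R2 ties
ALGORITHM_TIE_ORDER = ["elastic_net", "svr_rbf", "random_forest", "gbt"]


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "elastic_net":
        return ElasticNet(max_iter=10000, random_state=seed, **params)
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    if algorithm == "svr_rbf":
        return SVR(kernel="rbf", **params)
    if algorithm == "gbt":
        return XGBRegressor(
            random_state=seed, n_jobs=1, verbosity=0, objective="reg:squarederror",
            **params,
        )
    raise ValueError(f"unknown stacking algorithm {algorithm!r}")


@dataclass
class StackResult:
    """Pooled out-of-sample predictions of one stacked model."""

    name: str
    algorithm: str
    test_pred: np.ndarray
    chosen_params: "dict[int, dict]"
    per_fold_metrics: "list[dict[str, float]]"
    metrics: "dict[str, float]"


def fit_stack(
    name: str,
    algorithm: str,
    train_features: "dict[int, np.ndarray]",
    test_features: np.ndarray,
    y_folds: np.ndarray,
    plan: FoldPlan,
    grid: "list[dict] | None" = None,
    seed: int = 0,
) -> StackResult:
    """Second-level model over base-model predictions.

    ``train_features[f]`` holds cross-fitted base predictions for
    outer-training subjects of fold f (NaN elsewhere); ``test_features``
    holds the refit base models' outer-test predictions.  Hyperparameters
    minimize mean inner-fold MSE (skipped when the grid has one point);
    the refit model predicts the outer test set.  Features are
    standardized with training parameters before fitting.
    """
    if grid is None:
        grid = DEFAULT_STACK_GRIDS[algorithm]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = test_features.shape[0]
    test_pred = np.full(n, np.nan)
    chosen = {}
    per_fold = []
    for f in range(plan.k_outer):
        F_tr_all = train_features[f]
        valid_tr = plan.train_mask(f) & ~np.isnan(F_tr_all).any(axis=1)
        valid_te = plan.test_mask(f) & ~np.isnan(test_features).any(axis=1)
        y = y_folds[f]
        inner_ids = plan.inner[f]

        if len(grid) == 1:
            best = grid[0]
        else:
            mses = []
            for params in grid:
                fold_mse = []
                for j in range(plan.k_inner):
                    fit_rows = valid_tr & (inner_ids != j)
                    val_rows = valid_tr & (inner_ids == j)
                    if val_rows.sum() == 0 or fit_rows.sum() < 2:
                        continue
                    Ftr, Fva, _ = standardize_fit_apply(
                        F_tr_all[fit_rows], F_tr_all[val_rows]
                    )
                    est = _make_estimator(algorithm, params, seed)
                    est.fit(Ftr, y[fit_rows])
                    pred = est.predict(Fva)
                    fold_mse.append(np.mean((y[val_rows] - pred) ** 2))
                mses.append(np.mean(fold_mse))
            best = grid[int(np.argmin(mses))]
        chosen[f] = dict(best)

        Ftr, Fte, _ = standardize_fit_apply(
            F_tr_all[valid_tr], test_features[valid_te]
        )
        est = _make_estimator(algorithm, best, seed)
        est.fit(Ftr, y[valid_tr])
        test_pred[valid_te] = est.predict(Fte)
        per_fold.append(evaluate(y[valid_te], test_pred[valid_te]))

    return StackResult(
        name=name,
        algorithm=algorithm,
        test_pred=test_pred,
        chosen_params=chosen,
        per_fold_metrics=per_fold,
        metrics=_mean_metrics(per_fold),
    )


def select_algorithm(per_algorithm_metrics: "dict[str, float]") -> str:
    """Highest mean out-of-sample R2; exact ties break by the fixed
    deterministic order."""
    if not per_algorithm_metrics:
        raise ValueError("no algorithms evaluated")
    best = max(per_algorithm_metrics.values())
    leaders = [a for a, v in per_algorithm_metrics.items() if v == best]
    for a in ALGORITHM_TIE_ORDER:
        if a in leaders:
            return a
    return leaders[0]
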