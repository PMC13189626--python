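"""Haufe-transform feature importance and bootstrap significance.

For linear models, backward-model weights are not interpretable as
activation patterns; the Haufe transformation replaces them with the
covariance between each (scaled, centred) feature and the model's
prediction.  With standardized features this reduces to the Pearson
correlation between feature and predicted g across pooled outer-fold test
rows, which is how importance is computed here — it depends only on the
features and the prediction, so any re-parameterization of the model that
leaves the prediction unchanged leaves the importance unchanged.

Predictive performance significance uses a paired bootstrap of Pearson's
r (resampling subjects with replacement) with a percentile confidence
interval; a model is significant if the interval excludes zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["haufe_importance", "bootstrap_ci"]


def haufe_importance(
    features: pd.DataFrame,
    y_hat: np.ndarray,
    block: "str | None" = None,
) -> pd.DataFrame:
    """Per-feature Pearson correlation with the pooled predicted g.

    Zero-variance features get NaN importance and an ``undefined`` flag
    rather than an error, so whole blocks can be processed uniformly.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(y_hat, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("features and predictions are not aligned")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = X.std(axis=0, ddof=0)
    sy = y.std(ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).mean(axis=0) / (sx * sy)
    out = pd.DataFrame(
        {
            "feature": features.columns,
            "r": r,
            "undefined": sx == 0,
            "n": len(y),
        }
    )
    if block is not None:
        out["block"] = block
    return out.sort_values("r", key=np.abs, ascending=False, ignore_index=True)


def bootstrap_ci(
    y: np.ndarray,
    y_hat: np.ndarray,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int = 0,
) -> "dict[str, float]":
    """Percentile bootstrap CI for Pearson's r between observed and
    predicted values; significance means the CI excludes zero.

    Degenerate resamples (zero variance in either vector) are redrawn and
    counted.
    """
    y = np.asarray(y, dtype=float).ravel()
    yh = np.asarray(y_hat, dtype=float).ravel()
    n = len(y)
    if n < 10 or len(yh) != n:
        raise ValueError("need >= 10 aligned pairs")
    r_hat = float(np.corrcoef(y, yh)[0, 1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    redraws = 0
    # vectorized in memory-bounded chunks; redraw degenerate resamples
    chunk = max(1, min(n_boot, 2_000_000 // max(n, 1)))
    filled = 0
    while filled < n_boot:
        m = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(m, n))
        ys = y[idx]
        yhs = yh[idx]
        sy = ys.std(axis=1)
        syh = yhs.std(axis=1)
        ok = (sy > 0) & (syh > 0)
        redraws += int((~ok).sum())
        num = ((ys - ys.mean(axis=1, keepdims=True)) * (
            yhs - yhs.mean(axis=1, keepdims=True)
        )).mean(axis=1)
        rs = np.where(ok, num / np.where(ok, sy * syh, 1.0), np.nan)
        rs = rs[ok]
        boots[filled : filled + len(rs)] = rs
        filled += len(rs)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boots, [100 * alpha, 100 * (1 - alpha)])
    return {
        "r_hat": r_hat,
        "lo": float(lo),
        "hi": float(hi),
        "significant": bool(lo > 0 or hi < 0),
        "n_redraws": redraws,
    }
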