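"""Commonality analysis: unique and common variance decomposition.

Given the observed g score and two predicted g scores (one from mental
health, one from a neuroimaging phenotype or stack), three least-squares
regressions are fit,

    Model 1:  g_obs ~ g_mh
    Model 2:  g_obs ~ g_brain
    Model 3:  g_obs ~ g_mh + g_brain

and their R-squared values decomposed as

    Unique_mh    = R2_joint - R2_brain
    Unique_brain = R2_joint - R2_mh
    Common       = R2_mh + R2_brain - R2_joint

with the headline statistic

    % of the cognition-mental-health relationship explained
        = 100 * Common / R2_mh.

Negative commonalities (classical suppression) are reported as-is with a
flag; truncating them would break the exact sum identity
``Unique_mh + Unique_brain + Common = R2_joint``.

The three-set variant adds a demographic block (age, sex, age^2,
age x sex, age^2 x sex) and expands R-squared over all seven nonempty
subsets of the three predictor sets by inclusion-exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "CommonalityAnalysis",
    "CommonalityResult",
    "ThreeSetResult",
    "pool_predictions",
    "make_demo_block",
    "performance_vs_explained",
]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R-squared of an OLS regression of y on X with intercept."""
    D = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    sst = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / sst)


def pool_predictions(
    prediction_sets: "dict[str, pd.Series]",
) -> pd.DataFrame:
    """Inner-join named per-subject prediction series on subject id.

    Mirrors the pooling of outer-fold test-set predictions back into one
    complete table; each analysis keeps only subjects present in every
    contributing model, so n can differ between analyses.
    """
    frames = [s.rename(name) for name, s in prediction_sets.items()]
    out = pd.concat(frames, axis=1, join="inner")
    if out.empty:
        raise ValueError("no subjects shared by all prediction sets")
    return out


@dataclass
class CommonalityResult:
    """Two-predictor variance decomposition of the observed g score."""

    r2_mh: float
    r2_brain: float
    r2_joint: float
    unique_mh: float
    unique_brain: float
    common: float
    pct_explained: float
    n_subjects: int
    suppression: bool
    pct_undefined: bool

    def summary(self) -> str:
        lines = [
            "Commonality analysis (two predictor sets)",
            "-" * 45,
            f"n subjects                {self.n_subjects}",
            f"R2 mental health          {self.r2_mh:.4f}",
            f"R2 neuroimaging           {self.r2_brain:.4f}",
            f"R2 joint                  {self.r2_joint:.4f}",
            f"Unique mental health      {self.unique_mh:.4f}",
            f"Unique neuroimaging       {self.unique_brain:.4f}",
            f"Common                    {self.common:.4f}",
        ]
        if self.pct_undefined:
            lines.append("% relationship explained  undefined (R2_mh = 0)")
        else:
            lines.append(f"% relationship explained  {self.pct_explained:.1f}")
        if self.suppression:
            lines.append("note: negative commonality (suppression) present")
        return "\n".join(lines)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "r2_mh": self.r2_mh,
                "r2_brain": self.r2_brain,
                "r2_joint": self.r2_joint,
                "unique_mh": self.unique_mh,
                "unique_brain": self.unique_brain,
                "common": self.common,
                "pct_explained": self.pct_explained,
                "n_subjects": self.n_subjects,
            }
        )


@dataclass
class ThreeSetResult:
    """Seven-component decomposition over (mental health, brain, demo)."""

    components: "dict[str, float]"
    r2_full: float
    r2_subsets: "dict[tuple, float]"
    n_subjects: int

    def summary(self) -> str:
        lines = ["Commonality analysis (three predictor sets)", "-" * 45]
        for k, v in self.components.items():
            lines.append(f"{k:<28}{v: .4f}")
        lines.append(f"{'R2 full model':<28}{self.r2_full: .4f}")
        return "\n".join(lines)


class CommonalityAnalysis:
    """Variance partitioning of the observed g score.

    Parameters
    ----------
    g_obs, g_mh, g_brain : aligned per-subject vectors (pooled outer-fold
        test predictions, used raw).
    demo : optional demographic design for the three-set decomposition.
    """

    def __init__(self, g_obs, g_mh, g_brain, demo: "np.ndarray | None" = None):
        self.g_obs = np.asarray(g_obs, dtype=float).ravel()
        self.g_mh = np.asarray(g_mh, dtype=float).ravel()
        self.g_brain = np.asarray(g_brain, dtype=float).ravel()
        n = len(self.g_obs)
        if not (len(self.g_mh) == len(self.g_brain) == n):
            raise ValueError("inputs must be aligned")
        if n < 3:
            raise ValueError("need at least 3 subjects")
        if np.var(self.g_obs) == 0:
            raise ValueError("observed g has zero variance")
        self.demo = None if demo is None else np.asarray(demo, dtype=float)

    def fit(self) -> CommonalityResult:
        y = self.g_obs
        r2_mh = _r2(y, self.g_mh[:, None])
        r2_brain = _r2(y, self.g_brain[:, None])
        r2_joint = _r2(y, np.column_stack([self.g_mh, self.g_brain]))
        unique_mh = r2_joint - r2_brain
        unique_brain = r2_joint - r2_mh
        common = r2_mh + r2_brain - r2_joint
        undefined = r2_mh <= 1e-12
        pct = float("nan") if undefined else 100.0 * common / r2_mh
        return CommonalityResult(
            r2_mh=r2_mh,
            r2_brain=r2_brain,
            r2_joint=r2_joint,
            unique_mh=unique_mh,
            unique_brain=unique_brain,
            common=common,
            pct_explained=pct,
            n_subjects=len(y),
            suppression=bool(min(unique_mh, unique_brain, common) < -1e-12),
            pct_undefined=bool(undefined),
        )

    def fit_three_set(self) -> ThreeSetResult:
        if self.demo is None:
            raise ValueError("no demographic block supplied")
        demo = self.demo
        if demo.ndim == 1:
            demo = demo[:, None]
        # drop rank-deficient demo columns
        keep = []
        for j in range(demo.shape[1]):
            cand = demo[:, keep + [j]]
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(len(cand)), cand])
            ) == len(keep) + 2:
                keep.append(j)
        demo = demo[:, keep]

        sets = [self.g_mh[:, None], self.g_brain[:, None], demo]
        r2 = {}
        for k in range(1, 4):
            for combo in combinations(range(3), k):
                X = np.column_stack([sets[i] for i in combo])
                r2[combo] = _r2(self.g_obs, X)
        R123 = r2[(0, 1, 2)]
        comp = {
            "unique_mh": R123 - r2[(1, 2)],
            "unique_brain": R123 - r2[(0, 2)],
            "unique_demo": R123 - r2[(0, 1)],
            "common_mh_brain": r2[(0, 2)] + r2[(1, 2)] - r2[(2,)] - R123,
            "common_mh_demo": r2[(0, 1)] + r2[(1, 2)] - r2[(1,)] - R123,
            "common_brain_demo": r2[(0, 1)] + r2[(0, 2)] - r2[(0,)] - R123,
        }
        comp["common_mh_brain_demo"] = R123 - sum(comp.values())
        return ThreeSetResult(
            components=comp,
            r2_full=R123,
            r2_subsets=r2,
            n_subjects=len(self.g_obs),
        )


def make_demo_block(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Demographic design (age, sex, age^2, age x sex, age^2 x sex), with
    age standardized before powers."""
    a = np.asarray(age, dtype=float)
    a = (a - a.mean()) / a.std(ddof=0)
    s = np.asarray(sex, dtype=float)
    return np.column_stack([a, s, a**2, a * s, a**2 * s])


def performance_vs_explained(
    performance: np.ndarray,
    pct: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> "dict[str, float]":
    """Correlation, across phenotypes, between predictive performance and
    the % of the cognition-mental-health relationship captured, with a
    percentile bootstrap confidence interval."""
    x = np.asarray(performance, dtype=float)
    y = np.asarray(pct, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 aligned phenotype points")
    if np.var(x) == 0 or np.var(y) == 0:
        return {"r": float("nan"), "lo": float("nan"), "hi": float("nan"),
                "undefined": True}
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(x), len(x))
        while np.var(x[idx]) == 0 or np.var(y[idx]) == 0:
            idx = rng.integers(0, len(x), len(x))
        boots[b] = np.corrcoef(x[idx], y[idx])[0, 1]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {"r": r, "lo": float(lo), "hi": float(hi), "undefined": False}
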