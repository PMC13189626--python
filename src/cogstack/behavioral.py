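"""Cognitive-score transformations and mental-health composite scoring.

Cognitive battery (12 scores).  Duration outcomes (reaction time, the two
trail-making completion times) are log(x)-transformed; the pairs-matching
incorrect-match count is log(x+1)-transformed; the prospective-memory
first-answer code is recoded so the target shape (3, orange circle) maps
to 1 and all non-target shapes (0, 1, 2) map to 0.  Negative raw values
mark invalid or abandoned trials and become missing everywhere; zero
becomes missing only where a zero cannot be a true score (fluid
intelligence, picture-vocabulary ability, and the two trail durations).

Mental-health items.  Questionnaire refusal codes (-818/-3 "prefer not to
answer", -121/-1 "do not know") are replaced with column medians computed
over valid responses.  Composite scores implemented with their full
clinical decision rules: AUDIT (10 items; consumption subscore items 1-3,
problems subscore items 4-10; never-drinkers' missing items 2-10 scored 0;
hazardous-use flag at >=8, dependence flag at >=15; log(x+1) variants) and
PCL-6 (sum of 6 items on a 6-29 range; PTSD-positive at >=14; risk bands
<=12 low, 13-16 increased, 17-25 high, >=26 very high).  Wellbeing scales
are monotonically reoriented so higher means more satisfied; the work/job
satisfaction item is dropped because its "not employed" response cannot be
ordered.  Other instrument sums (GAD-7, PHQ-9, N-12, PDS, RDS-4) are plain
item sums after imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COGNITIVE_COLUMNS",
    "LOG_COLUMNS",
    "LOG1P_COLUMNS",
    "ZERO_INVALID_COLUMNS",
    "REFUSAL_CODES",
    "transform_cognitive",
    "impute_refusals",
    "score_audit",
    "score_pcl6",
    "recode_wellbeing",
]

#: canonical analysis order of the 12 cognitive outcomes
COGNITIVE_COLUMNS = [
    "reaction_time",
    "fluid_intelligence",
    "numeric_memory",
    "trail_numeric",
    "trail_alphabetic",
    "symbol_digit",
    "paired_associate",
    "tower_rearranging",
    "matrix_completion",
    "pairs_matching_incorrect",
    "picture_vocabulary",
    "prospective_memory",
]

LOG_COLUMNS = ("reaction_time", "trail_numeric", "trail_alphabetic")
LOG1P_COLUMNS = ("pairs_matching_incorrect",)
#: tests where a zero score marks an invalid trial, not performance
ZERO_INVALID_COLUMNS = (
    "fluid_intelligence",
    "picture_vocabulary",
    "trail_numeric",
    "trail_alphabetic",
)

REFUSAL_CODES = (-818, -121, -3, -1)


def transform_cognitive(raw: pd.DataFrame) -> pd.DataFrame:
    """Map raw cognitive scores to the analysis scale.

    Expects the 12 canonical columns (any order, extras rejected);
    returns a new frame in canonical order with float dtype and NaN for
    missing.  Raises ``KeyError`` for missing columns and ``ValueError``
    for non-numeric cells.
    """
    missing = [c for c in COGNITIVE_COLUMNS if c not in raw.columns]
    if missing:
        raise KeyError(f"missing cognitive column(s): {missing}")
    out = {}
    for col in COGNITIVE_COLUMNS:
        s = raw[col]
        try:
            v = pd.to_numeric(s, errors="raise").astype(float).to_numpy()
        except (ValueError, TypeError) as e:
            bad = s[pd.to_numeric(s, errors="coerce").isna() & s.notna()]
            loc = bad.index[0] if len(bad) else "?"
            raise ValueError(f"non-numeric cell in {col!r} at row {loc}") from e
        v = np.where(v < 0, np.nan, v)  # negatives are invalid trials
        if col == "prospective_memory":
            # {0,1,2} non-target -> 0; {3} target orange circle -> 1
            v = np.where(np.isnan(v), np.nan, np.where(v == 3, 1.0, 0.0))
        elif col in LOG_COLUMNS:
            v = np.where(v == 0, np.nan, v) if col in ZERO_INVALID_COLUMNS else v
            v = np.where(v > 0, np.log(np.where(v > 0, v, 1.0)), np.nan)
        elif col in LOG1P_COLUMNS:
            v = np.log1p(v)
        elif col in ZERO_INVALID_COLUMNS:
            v = np.where(v == 0, np.nan, v)
        out[col] = v
    res = pd.DataFrame(out, index=raw.index)
    res.attrs["log_transformed"] = True  # provenance guard: apply once
    return res


def impute_refusals(
    items: pd.DataFrame, codes: "tuple[int, ...]" = REFUSAL_CODES
) -> tuple[pd.DataFrame, pd.Series]:
    """Replace refusal/don't-know codes with per-column medians.

    The median is computed over non-coded cells.  Returns the imputed
    frame and a per-column count of replacements.  A column consisting
    entirely of codes has no defined median and raises ``ValueError``.
    """
    out = items.copy().astype(float)
    counts = {}
    codes_arr = np.asarray(codes, dtype=float)
    for col in out.columns:
        v = out[col].to_numpy()
        coded = np.isin(v, codes_arr)
        counts[col] = int(coded.sum())
        if coded.any():
            valid = v[~coded & ~np.isnan(v)]
            if valid.size == 0:
                raise ValueError(f"column {col!r} entirely refusal-coded")
            out[col] = np.where(coded, np.median(valid), v)
    return out, pd.Series(counts, name="n_imputed")


_AUDIT_MAX = np.array([4, 4, 4, 4, 4, 4, 4, 4, 2, 2]) * 1.0  # items 9,10 score 0/2/4


def score_audit(
    items: pd.DataFrame, drinks_never: "pd.Series | np.ndarray"
) -> pd.DataFrame:
    """AUDIT alcohol-use scoring.

    ``items`` holds the ten AUDIT items in order (each 0-4); for
    participants whose screening answer is "never drinks", missing items
    2-10 are scored 0.  Returns raw and log(x+1) total/consumption/problem
    scores plus the hazardous-use (>=8) and dependence (>=15) flags.
    """
    if items.shape[1] != 10:
        raise ValueError("AUDIT requires exactly 10 item columns")
    X = items.to_numpy(dtype=float).copy()
    never = np.asarray(drinks_never, dtype=bool)
    X[never, 1:] = np.where(np.isnan(X[never, 1:]), 0.0, X[never, 1:])
    with np.errstate(invalid="ignore"):
        bad = (X < 0) | (X > _AUDIT_MAX[None, :])
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"AUDIT item {c + 1} out of range at row {items.index[r]}: {X[r, c]}"
        )
    audit = X.sum(axis=1)
    audit_c = X[:, :3].sum(axis=1)
    audit_p = X[:, 3:].sum(axis=1)
    return pd.DataFrame(
        {
            "audit": audit,
            "audit_c": audit_c,
            "audit_p": audit_p,
            "audit_log1p": np.log1p(audit),
            "audit_c_log1p": np.log1p(audit_c),
            "audit_p_log1p": np.log1p(audit_p),
            "hazardous": audit >= 8,
            "dependence": audit >= 15,
        },
        index=items.index,
    )


_PCL6_BANDS = [(6, 12, "low"), (13, 16, "increased"), (17, 25, "high"), (26, 29, "very_high")]


def score_pcl6(items: pd.DataFrame) -> pd.DataFrame:
    """PCL-6 post-traumatic stress screening score.

    Sum of six items with total range 6-29; risk bands low (<=12),
    increased (13-16), high (17-25), very high (>=26); PTSD status is
    positive at >=14.
    """
    if items.shape[1] != 6:
        raise ValueError("PCL-6 requires exactly 6 item columns")
    total = items.to_numpy(dtype=float).sum(axis=1)
    if np.any((total < 6) | (total > 29)):
        bad = np.argwhere((total < 6) | (total > 29))[0, 0]
        raise ValueError(
            f"PCL-6 total out of [6, 29] at row {items.index[bad]}: {total[bad]}"
        )
    band = np.empty(total.shape, dtype=object)
    for lo, hi, name in _PCL6_BANDS:
        band[(total >= lo) & (total <= hi)] = name
    return pd.DataFrame(
        {"pcl6": total, "risk_band": band, "ptsd_positive": total >= 14},
        index=items.index,
    )


def recode_wellbeing(
    items: pd.DataFrame, orientation_map: "dict[str, dict | str]"
) -> pd.DataFrame:
    """Orient wellbeing scales so higher = more satisfied.

    ``orientation_map`` maps each column to either ``'keep'``,
    ``'reverse'`` (x -> max + min - x on its observed scale bounds given
    as ``('reverse', lo, hi)``), ``'drop'``, or an explicit value->value
    dict.  Every column must be mapped; the work/job satisfaction scale is
    conventionally dropped because 'not employed' cannot be ordered.
    """
    unmapped = [c for c in items.columns if c not in orientation_map]
    if unmapped:
        raise KeyError(f"unmapped wellbeing column(s): {unmapped}")
    out = {}
    for col in items.columns:
        rule = orientation_map[col]
        v = items[col].astype(float)
        if rule == "keep":
            out[col] = v
        elif rule == "drop":
            continue
        elif isinstance(rule, dict):
            out[col] = v.map(lambda x: rule.get(x, np.nan))
        elif isinstance(rule, (tuple, list)) and rule[0] == "reverse":
            _, lo, hi = rule
            out[col] = lo + hi - v
        else:
            raise ValueError(f"unknown orientation rule for {col!r}: {rule!r}")
    return pd.DataFrame(out, index=items.index)
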