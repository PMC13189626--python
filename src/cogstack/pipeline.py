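"""End-to-end study pipeline: cohort -> g-factor -> base models ->
stacks -> commonality -> importance -> report.

:class:`StudyPipeline` is the model-level entry point: construct it from
a :class:`~cogstack.synthetic.CohortData` (or tables loaded from disk)
and call :meth:`~StudyPipeline.fit` to obtain a :class:`StudyResults`
carrying pooled predictions, per-model metrics, commonality
decompositions, the %-explained table, Haufe importances, bootstrap
significance and a reproducibility manifest.

Within every outer fold the g-factor model, all standardization and
deconfounding parameters, the tangent reference (when connectivity
features are used), PLSR component counts and stacking hyperparameters
are estimated on the training set only.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavioral import impute_refusals, transform_cognitive
from .commonality import (
    CommonalityAnalysis,
    make_demo_block,
    performance_vs_explained,
)
from .deconfound import build_confound_design
from .gfactor import HierarchicalFactorModel, bartlett, kmo, parallel_analysis
from .importance import bootstrap_ci, haufe_importance
from .stacking import (
    ALGORITHM_TIE_ORDER,
    fit_stack,
    make_fold_plan,
    run_base_model,
    select_algorithm,
)
from .synthetic import CohortData

__all__ = ["StudyPipeline", "StudyResults", "validate_config", "run_all"]


@dataclass
class StudyResults:
    """Everything the analysis computes, as tidy tables.

    ``predictions``: one row per subject x model (pooled outer-test
    predictions).  ``metrics``: one row per model x fold plus a pooled
    row.  ``commonality``: two-set decomposition per brain model;
    ``three_set``: seven components per stack.  ``pct_explained`` values
    are percentages; a row is flagged undefined when the mental-health
    model itself is not significant.
    """

    g_obs: pd.Series
    predictions: pd.DataFrame
    metrics: pd.DataFrame
    stack_algorithms: pd.DataFrame
    commonality: pd.DataFrame
    three_set: "dict[str, dict[str, float]]"
    importance: pd.DataFrame
    significance: pd.DataFrame
    perf_vs_pct: "dict[str, float]"
    gfactor_diagnostics: pd.DataFrame
    manifest: "dict"

    def pct_table(self) -> pd.DataFrame:
        return self.commonality[
            ["model", "pct_explained", "pct_defined", "n_subjects"]
        ]

    def summary(self) -> str:
        lines = ["Stacked prediction of g and commonality analysis", "=" * 52]
        lines.append(f"n subjects: {self.manifest['n_subjects']}  "
                     f"seed: {self.manifest['seed']}")
        lines.append("")
        lines.append("Pooled out-of-sample performance (mean over folds):")
        pooled = self.metrics[self.metrics["fold"] == "mean"]
        for _, row in pooled.iterrows():
            lines.append(
                f"  {row['model']:<22} R2={row['R2']:+.3f}  r={row['r']:+.3f}  "
                f"MAE={row['MAE']:.3f}  MSE={row['MSE']:.3f}"
            )
        lines.append("")
        lines.append("% of the cognition-mental-health relationship explained:")
        for _, row in self.commonality.iterrows():
            flag = "" if row["pct_defined"] else "  (undefined: MH model n.s.)"
            lines.append(
                f"  {row['model']:<22} {row['pct_explained']:6.1f}%{flag}"
            )
        if not np.isnan(self.perf_vs_pct.get("r", np.nan)):
            lines.append("")
            lines.append(
                "performance vs %-explained across phenotypes: "
                f"r={self.perf_vs_pct['r']:.3f} "
                f"[{self.perf_vs_pct['lo']:.3f}, {self.perf_vs_pct['hi']:.3f}]"
            )
        return "\n".join(lines)

    def write(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(d / "predictions.tsv", sep="\t", index=False)
        self.metrics.to_csv(d / "metrics.tsv", sep="\t", index=False)
        self.commonality.to_csv(d / "commonality.tsv", sep="\t", index=False)
        self.stack_algorithms.to_csv(
            d / "stack_algorithms.tsv", sep="\t", index=False
        )
        self.importance.to_csv(d / "importance.tsv", sep="\t", index=False)
        self.significance.to_csv(d / "significance.tsv", sep="\t", index=False)
        self.gfactor_diagnostics.to_csv(
            d / "gfactor_diagnostics.tsv", sep="\t", index=False
        )
        with open(d / "three_set_commonality.json", "w") as fh:
            json.dump(self.three_set, fh, indent=2)
        with open(d / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)
        with open(d / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


class StudyPipeline:
    """Two-level predictive modeling with commonality analysis.

    Parameters
    ----------
    cohort : aligned subject tables (synthetic or loaded from disk).
    k_outer, k_inner : nested cross-validation design (5 x 10).
    n_factors : first-order factor count; None runs parallel analysis
        per outer fold.
    stack_algorithms : subset of {elastic_net, random_forest, svr_rbf,
        gbt} evaluated for every stack.
    n_boot : bootstrap replicates for significance intervals.
    """

    def __init__(
        self,
        cohort: CohortData,
        k_outer: int = 5,
        k_inner: int = 10,
        seed: int = 0,
        n_factors: "int | None" = None,
        stack_algorithms: "tuple[str, ...]" = tuple(ALGORITHM_TIE_ORDER),
        component_grid: "list[int] | None" = None,
        n_boot: int = 5000,
        compute_importance: bool = True,
    ):
        self.cohort = cohort
        self.k_outer = k_outer
        self.k_inner = k_inner
        self.seed = seed
        self.n_factors = n_factors
        self.stack_algorithms = tuple(stack_algorithms)
        self.component_grid = component_grid
        self.n_boot = n_boot
        self.compute_importance = compute_importance

    def fit(self) -> StudyResults:
        t0 = time.time()
        cohort = self.cohort
        ids = pd.Index(cohort.subject_ids)
        n = len(ids)
        timings: dict[str, float] = {}

        # --- behavioral scoring ------------------------------------------
        cog = transform_cognitive(cohort.cognitive_raw)
        mh_items, _ = impute_refusals(cohort.mental_health_items)
        timings["behavioral"] = time.time() - t0

        # --- folds and per-fold g-factor ---------------------------------
        t = time.time()
        plan = make_fold_plan(ids, self.k_outer, self.k_inner, self.seed)
        cogv = cog.to_numpy()
        complete = ~np.isnan(cogv).any(axis=1)
        y_folds = np.full((self.k_outer, n), np.nan)
        diag_rows = []
        for f in range(self.k_outer):
            tr = plan.train_mask(f) & complete
            Xtr = cogv[tr]
            R = np.corrcoef(
                (Xtr - Xtr.mean(0)) / Xtr.std(0), rowvar=False
            )
            nf = self.n_factors
            if nf is None:
                nf = max(parallel_analysis(Xtr, seed=self.seed + f), 1)
            fm = HierarchicalFactorModel(Xtr, n_factors=nf, seed=self.seed + f)
            res = fm.fit()
            raw_scores = res.score(cogv[complete])
            tr_scores = res.score(Xtr)
            mu, sd = tr_scores.mean(), tr_scores.std(ddof=0)
            y_folds[f, complete] = (raw_scores - mu) / sd
            bart = bartlett(R, int(tr.sum()))
            diag_rows.append(
                {
                    "fold": f,
                    "n_train": int(tr.sum()),
                    "kmo": kmo(R),
                    "bartlett_p": bart["p"],
                    "n_factors": nf,
                    **res.fit.as_dict(),
                    "determinacy": res.determinacy,
                }
            )
        gfactor_diag = pd.DataFrame(diag_rows)
        timings["gfactor"] = time.time() - t

        # pooled observed g: the score each subject received as a test
        # subject of their own outer fold
        g_obs = np.full(n, np.nan)
        for f in range(self.k_outer):
            te = plan.test_mask(f)
            g_obs[te] = y_folds[f, te]
        valid_g = complete & ~np.isnan(g_obs)

        # --- base models ---------------------------------------------------
        t = time.time()
        # scanner confounds only: age and sex are study variables (they
        # re-enter the commonality analysis as a predictor set)
        conf_design = build_confound_design(
            cohort.confounds[["site", "acquisition_date"]]
        ).to_numpy()
        base = {}
        base["mh"] = run_base_model(
            "mh",
            mh_items.to_numpy(),
            y_folds,
            plan,
            confound_design=None,
            component_grid=self.component_grid,
            subject_mask=valid_g,
        )
        for name, tbl in cohort.feature_blocks.items():
            block_valid = valid_g & ~tbl.isna().any(axis=1).to_numpy()
            base[name] = run_base_model(
                name,
                tbl.to_numpy(),
                y_folds,
                plan,
                confound_design=conf_design,
                component_grid=self.component_grid,
                subject_mask=block_valid,
                keep_test_features=self.compute_importance,
            )
        timings["base_models"] = time.time() - t

        # --- stacks --------------------------------------------------------
        t = time.time()
        block_names = list(cohort.feature_blocks)
        stack_sets = {
            f"{mod}_stacked": names for mod, names in cohort.modalities.items()
        }
        if block_names:
            stack_sets["all_stacked"] = block_names
        stacks = {}
        algo_rows = []
        for si, (sname, members) in enumerate(stack_sets.items()):
            train_features = {
                f: np.column_stack([base[m].oof_train_pred[f] for m in members])
                for f in range(self.k_outer)
            }
            test_features = np.column_stack([base[m].test_pred for m in members])
            candidates = {}
            for ai, algo in enumerate(self.stack_algorithms):
                sr = fit_stack(
                    sname,
                    algo,
                    train_features,
                    test_features,
                    y_folds,
                    plan,
                    seed=self.seed + 1000 + 17 * si + ai,
                )
                candidates[algo] = sr
                algo_rows.append(
                    {"stack": sname, "algorithm": algo, **sr.metrics}
                )
            winner = select_algorithm(
                {a: sr.metrics["R2"] for a, sr in candidates.items()}
            )
            stacks[sname] = candidates[winner]
        timings["stacks"] = time.time() - t

        # --- pooled tables ---------------------------------------------------
        models: dict[str, np.ndarray] = {m: b.test_pred for m, b in base.items()}
        models.update({s: r.test_pred for s, r in stacks.items()})

        pred_rows = []
        for mname, pred in models.items():
            ok = ~np.isnan(pred)
            pred_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": ids[ok],
                        "model": mname,
                        "fold": plan.outer[ok],
                        "g_obs": g_obs[ok],
                        "g_pred": pred[ok],
                    }
                )
            )
        predictions = pd.concat(pred_rows, ignore_index=True)

        metric_rows = []
        for mname, obj in {**base, **stacks}.items():
            for f, mm in enumerate(obj.per_fold_metrics):
                metric_rows.append({"model": mname, "fold": str(f), **mm})
            metric_rows.append({"model": mname, "fold": "mean", **obj.metrics})
        metrics = pd.DataFrame(metric_rows)

        # --- significance ---------------------------------------------------
        t = time.time()
        sig_rows = []
        for mi, (mname, pred) in enumerate(models.items()):
            ok = ~np.isnan(pred) & ~np.isnan(g_obs)
            ci = bootstrap_ci(
                g_obs[ok],
                pred[ok],
                n_boot=self.n_boot,
                seed=self.seed + 2000 + mi,
            )
            sig_rows.append({"model": mname, **ci})
        significance = pd.DataFrame(sig_rows)
        mh_significant = bool(
            significance.loc[significance["model"] == "mh", "significant"].iloc[0]
        )
        timings["bootstrap"] = time.time() - t

        # --- commonality -----------------------------------------------------
        t = time.time()
        mh_pred = models["mh"]
        demo_all = make_demo_block(
            cohort.confounds["age"].to_numpy(),
            cohort.confounds["sex"].to_numpy(),
        )
        comm_rows = []
        three_set = {}
        for mname, pred in models.items():
            if mname == "mh":
                continue
            ok = ~np.isnan(pred) & ~np.isnan(mh_pred) & ~np.isnan(g_obs)
            ca = CommonalityAnalysis(
                g_obs[ok], mh_pred[ok], pred[ok], demo=demo_all[ok]
            )
            res = ca.fit()
            comm_rows.append(
                {
                    "model": mname,
                    **res.as_series().to_dict(),
                    "suppression": res.suppression,
                    "pct_defined": mh_significant and not res.pct_undefined,
                }
            )
            if mname in stacks:
                three_set[mname] = ca.fit_three_set().components
        commonality = pd.DataFrame(comm_rows)
        timings["commonality"] = time.time() - t

        # --- performance vs %-explained across individual phenotypes --------
        blocks_only = commonality[commonality["model"].isin(block_names)]
        if len(blocks_only) >= 3 and mh_significant:
            perf = [
                float(np.corrcoef(
                    g_obs[~np.isnan(models[m]) & ~np.isnan(g_obs)],
                    models[m][~np.isnan(models[m]) & ~np.isnan(g_obs)],
                )[0, 1])
                for m in blocks_only["model"]
            ]
            perf_vs = performance_vs_explained(
                np.array(perf),
                blocks_only["pct_explained"].to_numpy(),
                seed=self.seed + 3000,
            )
        else:
            perf_vs = {"r": float("nan"), "lo": float("nan"),
                       "hi": float("nan"), "undefined": True}

        # --- Haufe importance ------------------------------------------------
        t = time.time()
        imp_frames = []
        if self.compute_importance:
            for name, tbl in cohort.feature_blocks.items():
                b = base[name]
                ok = ~np.isnan(b.test_pred)
                feats = pd.DataFrame(
                    b.deconfounded_test_features[ok], columns=tbl.columns
                )
                imp_frames.append(haufe_importance(feats, b.test_pred[ok], block=name))
        importance = (
            pd.concat(imp_frames, ignore_index=True)
            if imp_frames
            else pd.DataFrame(columns=["feature", "r", "undefined", "n", "block"])
        )
        timings["importance"] = time.time() - t

        manifest = {
            "n_subjects": int(n),
            "seed": int(self.seed),
            "k_outer": self.k_outer,
            "k_inner": self.k_inner,
            "fold_plan_hash": hashlib.sha256(
                plan.outer.tobytes()
                + b"".join(plan.inner[f].tobytes() for f in range(self.k_outer))
            ).hexdigest(),
            "stack_algorithms": list(self.stack_algorithms),
            "stack_winners": {s: r.algorithm for s, r in stacks.items()},
            "n_boot": self.n_boot,
            "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        }

        return StudyResults(
            g_obs=pd.Series(g_obs, index=ids, name="g_obs"),
            predictions=predictions,
            metrics=metrics,
            stack_algorithms=pd.DataFrame(algo_rows),
            commonality=commonality,
            three_set=three_set,
            importance=importance,
            significance=significance,
            perf_vs_pct=perf_vs,
            gfactor_diagnostics=gfactor_diag,
            manifest=manifest,
        )


# ---------------------------------------------------------------------------
# config-driven runs


_CONFIG_SCHEMA = {
    "fixture": str,
    "n_subjects": int,
    "seed": int,
    "k_outer": int,
    "k_inner": int,
    "n_boot": int,
    "stack_algorithms": list,
    "output_dir": str,
    "write_cohort": bool,
}


def validate_config(config: dict) -> "list[str]":
    """Schema check; returns a list of error strings (empty = valid)."""
    errors = []
    if "seed" not in config:
        errors.append("missing required field: seed")
    for key, val in config.items():
        if key not in _CONFIG_SCHEMA:
            errors.append(f"unknown field: {key}")
            continue
        expect = _CONFIG_SCHEMA[key]
        if expect is int and isinstance(val, bool):
            errors.append(f"field {key}: expected int, got bool")
        elif not isinstance(val, expect):
            errors.append(f"field {key}: expected {expect.__name__}")
    if config.get("fixture", "default") not in {"tiny", "default", "null"}:
        errors.append("fixture must be one of tiny/default/null")
    if config.get("n_subjects", 1) <= 0:
        errors.append("n_subjects must be positive")
    for k, lo in (("k_outer", 2), ("k_inner", 2)):
        if k in config and config[k] < lo:
            errors.append(f"{k} must be >= {lo}")
    algos = config.get("stack_algorithms")
    if algos is not None:
        bad = set(algos) - set(ALGORITHM_TIE_ORDER)
        if bad:
            errors.append(f"unknown stack algorithms: {sorted(bad)}")
    return errors


def run_all(config: "dict | str", output_dir=None) -> StudyResults:
    """Execute the full pipeline from a config dict or YAML path."""
    import pathlib

    import yaml

    from .synthetic import make_fixture

    if isinstance(config, (str, pathlib.Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cohort = make_fixture(
        config.get("fixture", "default"), config.get("n_subjects")
    )
    pipe = StudyPipeline(
        cohort,
        k_outer=config.get("k_outer", 5),
        k_inner=config.get("k_inner", 10),
        seed=config["seed"],
        stack_algorithms=tuple(
            config.get("stack_algorithms", ALGORITHM_TIE_ORDER)
        ),
        n_boot=config.get("n_boot", 5000),
    )
    results = pipe.fit()
    out = output_dir or config.get("output_dir")
    if out is not None:
        results.write(out)
        if config.get("write_cohort", False):
            cohort.write(pathlib.Path(out) / "cohort")
    return results
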