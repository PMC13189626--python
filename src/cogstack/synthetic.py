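"""Synthetic cohort generator with analytically known variance structure.

The generator emulates the latent structure the downstream analysis
assumes, so every pipeline stage can be validated against closed-form
population values rather than restricted cohort data:

* a general-cognition factor g built from independent standard-normal
  sources: a source shared with mental health and (partially) with the
  brain-feature blocks, a mental-health-only source, one brain source per
  feature block, a cognition-only source, and demographic confounds (age,
  sex, scanning site);
* four first-order cognitive factors loading on g, and 12 raw test scores
  obtained by inverting the analysis transformations (durations are
  exponentiated from the log scale, counts rounded and clipped to their
  published ranges, the prospective-memory item drawn as a Bernoulli coded
  on the 0-3 raw scale) so the behavioral scoring module is exercised
  end to end;
* mental-health indicator items loading with heterogeneous signs on a
  single mental-health latent that correlates with g at a configurable
  level, with questionnaire refusal codes injected completely at random;
* brain feature blocks whose latent overlaps the mental-health-shared
  portion of g by a configurable share, with additive age/sex/site
  leakage into the features.

Every observed variable is linear in the independent sources plus a
strictly idiosyncratic noise term, so the population covariance matrix is
exact and :func:`theoretical_commonality` computes population R-squared
values, unique/common variance components, and the "% of the cognition-
mental-health relationship explained" statistic for every block and stack
by direct linear algebra.  These closed forms are the oracles the
acceptance checks use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .behavioral import COGNITIVE_COLUMNS, REFUSAL_CODES

__all__ = [
    "BlockSpec",
    "GenerativeConfig",
    "GroundTruth",
    "CohortData",
    "generate_cohort",
    "theoretical_commonality",
    "make_fixture",
    "default_config",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class BlockSpec:
    """One synthetic neuroimaging-phenotype feature block.

    ``signal_strength`` is the loading of the block latent on g-relevant
    sources; ``overlap_share`` is the fraction of that squared signal
    routed through the brain-wide view of the source shared with mental
    health (0 = the block sees only the brain-specific portion of g, 1 =
    only the shared-view portion).  ``demo_loading`` is the block
    latent's loading on the brain-wide demographic (aging) factor and
    ``site_loading`` its additive scanner-site shift;
    ``feature_site_leakage`` adds direct per-feature site leakage so
    deconfounding has per-feature work to do.
    """

    name: str
    pseudo_modality: str
    n_features: int
    signal_strength: float
    overlap_share: float
    demo_loading: float = -0.3
    site_loading: float = 0.08
    feature_loading: tuple = (0.25, 0.5)
    feature_site_leakage: float = 0.04

    def __post_init__(self):
        if not 0.0 <= self.overlap_share <= 1.0:
            raise ValueError(f"block {self.name!r}: overlap_share must be in [0, 1]")


@dataclass
class GenerativeConfig:
    """Full generative recipe for a synthetic cohort.

    ``source_weights`` are the loadings of g on its latent sources
    (shared, mh_only, cognition_only), ``brain_weights`` its per-block
    loadings, ``confound_weights`` its loadings on standardized age, sex
    and the scalar site effect; squares of all of these must sum to at
    most 1 (the remainder is g-specific residual).
    ``mh_latent_weights`` are the loadings of the mental-health latent on
    (shared, mh_only, age, sex); ``mh_signal`` the absolute loading of
    each mental-health item on that latent.
    """

    n_subjects: int = 5000
    factor_loadings: "np.ndarray | None" = None  # 12 x 4 pattern
    g_loadings: tuple = (0.8, 0.7, 0.6, 0.5)
    source_weights: "dict[str, float]" = field(
        default_factory=lambda: {
            "shared": 0.45,
            "mh_only": 0.10,
            "cognition_only": 0.60,
        }
    )
    brain_weights: "dict[str, float] | None" = None
    confound_weights: "dict[str, float]" = field(
        default_factory=lambda: {"age": -0.35, "sex": 0.10, "site": 0.05}
    )
    mh_latent_weights: "dict[str, float]" = field(
        default_factory=lambda: {
            "shared": 0.45,
            "mh_only": 0.25,
            "age": -0.30,
            "sex": 0.12,
        }
    )
    brain_view_alignment: "dict[str, float]" = field(
        default_factory=lambda: {"shared": 0.50, "age": 0.85, "sex": -0.10}
    )
    mh_signal: float = 0.30
    n_mh_items: int = 133
    mh_positive_frac: float = 0.6
    refusal_rate: float = 0.02
    blocks: "list[BlockSpec]" = field(default_factory=list)
    age_mean: float = 64.5
    age_sd: float = 7.6
    sex_p: float = 0.51
    n_sites: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0.0 < self.mh_signal < 1.0:
            raise ValueError("mh_signal must be in (0, 1)")
        if self.factor_loadings is None:
            self.factor_loadings = _default_factor_pattern()
        self.factor_loadings = np.asarray(self.factor_loadings, dtype=float)
        if self.factor_loadings.shape != (12, len(self.g_loadings)):
            raise ValueError("factor_loadings must be 12 x n_factors")
        if self.brain_weights is None:
            self.brain_weights = {b.name: 0.15 for b in self.blocks}
        self.validate()

    def validate(self) -> None:
        """Check that every implied variance is nonnegative."""
        total = sum(v**2 for v in self._g_weights().values())
        if total > 1.0 + 1e-9:
            raise ValueError(
                "implied variance of g exceeds 1: squared source, brain and "
                f"confound weights sum to {total:.4f}"
            )
        mh_total = sum(v**2 for v in self.mh_latent_weights.values())
        if mh_total > 1.0 + 1e-9:
            raise ValueError(
                f"implied variance of the mental-health latent is {mh_total:.4f} > 1"
            )
        va = self.brain_view_alignment
        if va["shared"] ** 2 > 1.0 + 1e-9 or va["age"] ** 2 + va["sex"] ** 2 > 1.0 + 1e-9:
            raise ValueError("brain_view_alignment weights imply variance > 1")
        for blk in self.blocks:
            used = blk.signal_strength**2 + blk.demo_loading**2 + blk.site_loading**2
            if used > 1.0 + 1e-9:
                raise ValueError(
                    f"block {blk.name!r}: implied latent variance {used:.4f} > 1"
                )
        for k, g in enumerate(self.g_loadings):
            if not 0.0 < g < 1.0:
                raise ValueError(f"g_loadings[{k}] must be in (0, 1)")

    def _g_weights(self) -> "dict[str, float]":
        w = {
            "shared": self.source_weights["shared"],
            "mh_only": self.source_weights["mh_only"],
            "cognition_only": self.source_weights["cognition_only"],
            "age": self.confound_weights["age"],
            "sex": self.confound_weights["sex"],
            "site": self.confound_weights["site"],
        }
        for b in self.blocks:
            w[f"brain:{b.name}"] = self.brain_weights[b.name]
        return w


def _default_factor_pattern() -> np.ndarray:
    """Simple-structure 12 x 4 pattern, three tests per factor.

    Duration/error outcomes (reaction time, trails, pairs-matching errors)
    load negatively: on the analysis scale, larger values mean worse
    performance.
    """
    L = np.zeros((12, 4))
    idx = {c: i for i, c in enumerate(COGNITIVE_COLUMNS)}
    assign = {
        # F1 processing speed
        "reaction_time": (0, -0.72),
        "symbol_digit": (0, 0.78),
        "trail_numeric": (0, -0.70),
        # F2 reasoning
        "fluid_intelligence": (1, 0.78),
        "matrix_completion": (1, 0.74),
        "tower_rearranging": (1, 0.70),
        # F3 memory
        "numeric_memory": (2, 0.72),
        "paired_associate": (2, 0.76),
        "pairs_matching_incorrect": (2, -0.62),
        # F4 verbal / executive
        "picture_vocabulary": (3, 0.74),
        "trail_alphabetic": (3, -0.70),
        "prospective_memory": (3, 0.60),
    }
    for col, (k, lam) in assign.items():
        L[idx[col], k] = lam
    return L


# ---------------------------------------------------------------------------
# the linear source model
#
# Observed variable = coefs . sources + sqrt(noise_var) * iid_noise, with
# independent unit-variance sources; covariances are exact inner products.


class _SourceModel:
    """Loading matrices of every modeled variable over the source basis."""

    def __init__(self, config: GenerativeConfig):
        self.config = config
        m_factors = len(config.g_loadings)
        self.names = (
            ["shared", "mh_only"]
            + [f"brain:{b.name}" for b in config.blocks]
            + ["cognition_only", "age", "sex", "site", "g_resid", "mh_resid"]
            + ["brain_view_resid", "brain_demo_resid"]
            + [f"block_resid:{b.name}" for b in config.blocks]
            + [f"factor_resid:{k}" for k in range(m_factors)]
        )
        self.index = {n: i for i, n in enumerate(self.names)}
        self.dim = len(self.names)
        ix = self.index

        # g: listed weights plus its own residual to unit variance
        gw = config._g_weights()
        g = np.zeros(self.dim)
        for k, v in gw.items():
            g[ix[k]] = v
        g[ix["g_resid"]] = np.sqrt(max(1.0 - g @ g, 0.0))
        self.g_vec = g

        # mental-health latent
        m = np.zeros(self.dim)
        for k, v in config.mh_latent_weights.items():
            m[ix[k]] = v
        m[ix["mh_resid"]] = np.sqrt(max(1.0 - m @ m, 0.0))
        self.m_vec = m

        # brain-wide intermediates: every block's overlap with the mental-
        # health-shared source and with demographics flows through these
        # two factors, so what a stack of blocks can recover saturates at
        # the view factors rather than growing without bound
        va = config.brain_view_alignment
        view = np.zeros(self.dim)
        view[ix["shared"]] = va["shared"]
        view[ix["brain_view_resid"]] = np.sqrt(max(1.0 - va["shared"] ** 2, 0.0))
        self.view_vec = view
        demo_f = np.zeros(self.dim)
        demo_f[ix["age"]] = va["age"]
        demo_f[ix["sex"]] = va["sex"]
        demo_f[ix["brain_demo_resid"]] = np.sqrt(
            max(1.0 - va["age"] ** 2 - va["sex"] ** 2, 0.0)
        )
        self.demo_factor_vec = demo_f

        # block latents
        self.block_vecs: dict[str, np.ndarray] = {}
        for blk in config.blocks:
            s_view = blk.signal_strength * np.sqrt(blk.overlap_share)
            s_own = blk.signal_strength * np.sqrt(1.0 - blk.overlap_share)
            v = s_view * view + blk.demo_loading * demo_f
            v[ix[f"brain:{blk.name}"]] = s_own
            v[ix["site"]] = blk.site_loading
            v[ix[f"block_resid:{blk.name}"]] = np.sqrt(max(1.0 - v @ v, 0.0))
            self.block_vecs[blk.name] = v

        # analysis-scale cognitive scores
        gamma = np.asarray(config.g_loadings, dtype=float)
        f_vecs = []
        for k in range(m_factors):
            fv = gamma[k] * g
            fv = fv.copy()
            fv[ix[f"factor_resid:{k}"]] = np.sqrt(1.0 - gamma[k] ** 2)
            f_vecs.append(fv)
        L = config.factor_loadings
        self.test_vecs = np.zeros((12, self.dim))
        for i in range(12):
            for k in range(m_factors):
                self.test_vecs[i] += L[i, k] * f_vecs[k]
        comm = np.einsum("ij,ij->i", self.test_vecs, self.test_vecs)
        if np.any(comm > 1.0 + 1e-9):
            bad = int(np.argmax(comm))
            raise ValueError(
                f"test {COGNITIVE_COLUMNS[bad]!r}: implied communality "
                f"{comm[bad]:.3f} > 1"
            )
        self.test_noise = np.clip(1.0 - comm, 0.0, None)

        # mental-health items
        lam = config.mh_signal
        self.item_signs = _mh_item_signs(config)
        self.item_loadings = np.outer(self.item_signs * lam, m)
        self.item_noise = np.full(config.n_mh_items, 1.0 - lam**2)

        # block features
        self.feature_loadings: dict[str, np.ndarray] = {}
        self.feature_noise: dict[str, np.ndarray] = {}
        for blk in config.blocks:
            h = _feature_loading_profile(blk)
            F = np.outer(h, self.block_vecs[blk.name])
            F[:, ix["site"]] += blk.feature_site_leakage
            tot = np.einsum("ij,ij->i", F, F)
            if np.any(tot > 1.0 + 1e-9):
                raise ValueError(
                    f"block {blk.name!r}: implied feature variance "
                    f"{tot.max():.3f} > 1"
                )
            self.feature_loadings[blk.name] = F
            self.feature_noise[blk.name] = np.clip(1.0 - tot, 1e-9, None)


def _mh_item_signs(config: GenerativeConfig) -> np.ndarray:
    rng = np.random.default_rng(987654321)  # fixed: part of the design
    return np.where(rng.random(config.n_mh_items) < config.mh_positive_frac, 1.0, -1.0)


def _feature_loading_profile(blk: BlockSpec) -> np.ndarray:
    # deterministic per-block profile, independent of the cohort seed
    key = sum(ord(c) * 31**i for i, c in enumerate(blk.name)) % (2**31)
    rng = np.random.default_rng(key)
    lo, hi = blk.feature_loading
    return rng.uniform(lo, hi, size=blk.n_features)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Population quantities implied by a configuration.

    ``expected_pct_explained`` maps each block, each pseudo-modality stack
    (``<modality>_stacked``) and ``all_stacked`` to the population % of
    the cognition-mental-health relationship carried by that predictor;
    ``expected_R2`` / ``expected_r`` map model names (``mh``, blocks,
    stacks) to population out-of-sample performance against the observed
    g score.
    """

    expected_r_mh: float
    expected_pct_explained: "dict[str, float]"
    expected_R2: "dict[str, float]"
    expected_r: "dict[str, float]"
    demo_share_of_mh_relationship: float
    brain_share_of_demo_common: float
    determinacy: float
    r2_mh_undefined: bool = False
    g_true: "np.ndarray | None" = None
    sources: "pd.DataFrame | None" = None

    def as_dict(self) -> dict:
        return {
            "expected_r_mh": self.expected_r_mh,
            "expected_pct_explained": dict(self.expected_pct_explained),
            "expected_R2": dict(self.expected_R2),
            "expected_r": dict(self.expected_r),
            "demo_share_of_mh_relationship": self.demo_share_of_mh_relationship,
            "brain_share_of_demo_common": self.brain_share_of_demo_common,
            "determinacy": self.determinacy,
            "r2_mh_undefined": self.r2_mh_undefined,
        }


def theoretical_commonality(config: GenerativeConfig) -> GroundTruth:
    """Closed-form population ground truth for a configuration.

    Derives the observed-g score direction (population Thurstone score:
    best linear predictor of g from the 12 analysis-scale test scores),
    the population best linear predictors of that score from the mental-
    health items and from each deconfounded feature block, population
    R-squared for every base and stacked model, the two-predictor
    commonality decomposition and %-explained for every block and stack,
    and the share of the cognition-mental-health relationship overlapping
    age and sex.  When the mental-health R-squared is zero, %-explained is
    flagged undefined (NaN).
    """
    sm = _SourceModel(config)

    # observed g score: BLP of g from the 12 test scores
    S_tt = sm.test_vecs @ sm.test_vecs.T + np.diag(sm.test_noise)
    s_tg = sm.test_vecs @ sm.g_vec
    w_t = np.linalg.solve(S_tt, s_tg)
    gobs_vec = sm.test_vecs.T @ w_t
    gobs_noise = float(w_t @ (sm.test_noise * w_t))
    var_gobs = float(gobs_vec @ gobs_vec) + gobs_noise
    determinacy = float((gobs_vec @ sm.g_vec) / np.sqrt(var_gobs))  # var(g)=1

    def blp(loadings: np.ndarray, noise: np.ndarray):
        """BLP of the observed g score from a variable group; returns
        (basis coefficient vector, idiosyncratic variance, R2)."""
        S = loadings @ loadings.T + np.diag(noise)
        s = loadings @ gobs_vec
        w = np.linalg.solve(S, s)
        vec, nvar = loadings.T @ w, float(w @ (noise * w))
        if float(vec @ vec) + nvar < 1e-12:
            nvar = 1.0  # zero-signal predictor: unit placeholder variance
        return vec, nvar, float(s @ w) / var_gobs

    mh_vec, mh_noise, r2_mh = blp(sm.item_loadings, sm.item_noise)
    undefined = r2_mh < 1e-12
    r_mh = 0.0 if undefined else float(np.sqrt(r2_mh))

    # the scanner-confound battery removed from MRI features covers site
    # (and acquisition date, which carries no signal here); age and sex are
    # study variables, not confounds, and stay in the features
    conf_idx = [sm.index["site"]]
    pred_vecs: dict[str, np.ndarray] = {}
    pred_noise: dict[str, float] = {}
    expected_R2: dict[str, float] = {"mh": r2_mh}
    expected_r: dict[str, float] = {"mh": r_mh}
    for blk in config.blocks:
        Fd = sm.feature_loadings[blk.name].copy()
        Fd[:, conf_idx] = 0.0  # population deconfounding
        vec, nvar, r2 = blp(Fd, sm.feature_noise[blk.name])
        pred_vecs[blk.name] = vec
        pred_noise[blk.name] = nvar
        expected_R2[blk.name] = r2
        expected_r[blk.name] = float(np.sqrt(max(r2, 0.0)))

    modalities: dict[str, list[str]] = {}
    for b in config.blocks:
        modalities.setdefault(b.pseudo_modality, []).append(b.name)
    stack_sets = {f"{mod}_stacked": names for mod, names in modalities.items()}
    if config.blocks:
        stack_sets["all_stacked"] = [b.name for b in config.blocks]
    for sname, names in stack_sets.items():
        Lk = np.array([pred_vecs[n] for n in names])
        nk = np.array([pred_noise[n] for n in names])
        vec, nvar, r2 = blp(Lk, nk)
        pred_vecs[sname] = vec
        pred_noise[sname] = nvar
        expected_R2[sname] = r2
        expected_r[sname] = float(np.sqrt(max(r2, 0.0)))

    def pct_explained(bvec, bnoise):
        if undefined:
            return float("nan")
        X = np.vstack([mh_vec, bvec])
        nz = np.array([mh_noise, bnoise])
        S = X @ X.T + np.diag(nz)
        s = X @ gobs_vec
        r2_joint = float(s @ np.linalg.solve(S, s)) / var_gobs
        r2_b = float((bvec @ gobs_vec) ** 2 / ((bvec @ bvec + bnoise) * var_gobs))
        return 100.0 * (r2_mh + r2_b - r2_joint) / r2_mh

    expected_pct = {
        name: pct_explained(pred_vecs[name], pred_noise[name]) for name in pred_vecs
    }

    # demographic overlap via the three-set decomposition with demo =
    # (age, sex); quadratic/interaction terms carry no population signal
    # because every modeled variable is linear in age and sex.
    demo_share = float("nan")
    brain_share = float("nan")
    if config.blocks and not undefined:
        demo = np.zeros((2, sm.dim))
        demo[0, sm.index["age"]] = 1.0
        demo[1, sm.index["sex"]] = 1.0
        comp = _three_set_components(
            gobs_vec,
            gobs_noise,
            [
                (np.atleast_2d(mh_vec), np.array([mh_noise])),
                (
                    np.atleast_2d(pred_vecs["all_stacked"]),
                    np.array([pred_noise["all_stacked"]]),
                ),
                (demo, np.zeros(2)),
            ],
        )
        mh_demo_overlap = comp["c_mh_demo"] + comp["c_mh_brain_demo"]
        demo_share = 100.0 * mh_demo_overlap / r2_mh
        brain_share = (
            100.0 * comp["c_mh_brain_demo"] / mh_demo_overlap
            if abs(mh_demo_overlap) > 1e-12
            else float("nan")
        )

    return GroundTruth(
        expected_r_mh=r_mh,
        expected_pct_explained=expected_pct,
        expected_R2=expected_R2,
        expected_r=expected_r,
        demo_share_of_mh_relationship=demo_share,
        brain_share_of_demo_common=brain_share,
        determinacy=determinacy,
        r2_mh_undefined=bool(undefined),
    )


def _three_set_components(y_vec, y_noise, sets):
    """Population three-set commonality components via subset R2s.

    ``sets`` lists (loading-matrix, noise-vector) predictor groups in the
    order (mental health, brain, demographics); components follow the
    classical inclusion-exclusion expansion over the seven nonempty
    subsets.
    """
    var_y = float(y_vec @ y_vec) + y_noise

    def r2_of(groups):
        Lk = np.vstack([g[0] for g in groups])
        nz = np.concatenate([g[1] for g in groups])
        S = Lk @ Lk.T + np.diag(nz)
        s = Lk @ y_vec
        return float(s @ np.linalg.solve(S, s)) / var_y

    r2 = {}
    for k in range(1, 4):
        for combo in combinations(range(3), k):
            r2[combo] = r2_of([sets[i] for i in combo])
    R123 = r2[(0, 1, 2)]
    u_mh = R123 - r2[(1, 2)]
    u_brain = R123 - r2[(0, 2)]
    u_demo = R123 - r2[(0, 1)]
    c_mh_brain = r2[(0, 2)] + r2[(1, 2)] - r2[(2,)] - R123
    c_mh_demo = r2[(0, 1)] + r2[(1, 2)] - r2[(1,)] - R123
    c_brain_demo = r2[(0, 1)] + r2[(0, 2)] - r2[(0,)] - R123
    c_all = R123 - u_mh - u_brain - u_demo - c_mh_brain - c_mh_demo - c_brain_demo
    return {
        "unique_mh": u_mh,
        "unique_brain": u_brain,
        "unique_demo": u_demo,
        "c_mh_brain": c_mh_brain,
        "c_mh_demo": c_mh_demo,
        "c_brain_demo": c_brain_demo,
        "c_mh_brain_demo": c_all,
        "r2_full": R123,
    }


# ---------------------------------------------------------------------------
# cohort container


@dataclass
class CohortData:
    """Aligned subject tables plus (for synthetic cohorts) the truth."""

    subject_ids: np.ndarray
    cognitive_raw: pd.DataFrame
    mental_health_items: pd.DataFrame
    feature_blocks: "dict[str, pd.DataFrame]"
    confounds: pd.DataFrame
    block_specs: "list[BlockSpec]"
    truth: "GroundTruth | None" = None
    config: "GenerativeConfig | None" = None

    def __post_init__(self):
        ids = pd.Index(self.subject_ids)
        if ids.has_duplicates:
            raise ValueError("duplicated subject ids")
        for name, tbl in [
            ("cognitive_raw", self.cognitive_raw),
            ("mental_health_items", self.mental_health_items),
            ("confounds", self.confounds),
            *self.feature_blocks.items(),
        ]:
            if not tbl.index.equals(ids):
                raise ValueError(f"table {name!r} is not aligned to subject_ids")

    @property
    def modalities(self) -> "dict[str, list[str]]":
        out: dict[str, list[str]] = {}
        for b in self.block_specs:
            out.setdefault(b.pseudo_modality, []).append(b.name)
        return out

    def write(self, directory) -> None:
        """Serialize as a directory of TSV tables plus a YAML manifest."""
        import pathlib

        import yaml

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cognitive_raw.to_csv(d / "cognitive_raw.tsv", sep="\t")
        self.mental_health_items.to_csv(d / "mental_health_items.tsv", sep="\t")
        self.confounds.to_csv(d / "confounds.tsv", sep="\t")
        for name, tbl in self.feature_blocks.items():
            tbl.to_csv(d / f"block_{name}.tsv", sep="\t")
        manifest = {
            "n_subjects": int(len(self.subject_ids)),
            "blocks": [
                {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(b).items()
                }
                for b in self.block_specs
            ],
            "seed": None if self.config is None else int(self.config.seed),
        }
        if self.truth is not None:
            manifest["ground_truth"] = _to_plain(self.truth.as_dict())
        with open(d / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: GenerativeConfig, with_truth: bool = True) -> CohortData:
    """Draw a cohort from the configured generative model.

    Deterministic given ``config.seed``.  Observed tables are the raw
    cognitive scores (inverse-transformed to their published scales),
    mental-health items with refusal codes injected completely at random,
    one subject x feature table per block, and the confound table (age in
    years, binary sex, categorical site, acquisition date in days).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    sm = _SourceModel(config)

    # confound draws replace their basis columns
    age_z = rng.standard_normal(n)
    sex_raw = (rng.random(n) < config.sex_p).astype(float)
    p = config.sex_p
    sex_z = (sex_raw - p) / np.sqrt(p * (1 - p))
    site_raw = rng.integers(0, config.n_sites, size=n)
    site_z = _site_shifts(config.n_sites)[site_raw]
    acq_date = rng.integers(0, 1500, size=n).astype(float)

    S = rng.standard_normal((n, sm.dim))
    S[:, sm.index["age"]] = age_z
    S[:, sm.index["sex"]] = sex_z
    S[:, sm.index["site"]] = site_z

    g_true = S @ sm.g_vec
    m_latent = S @ sm.m_vec

    tests = S @ sm.test_vecs.T + rng.standard_normal((n, 12)) * np.sqrt(sm.test_noise)
    cognitive_raw = _to_raw_cognitive(tests, rng)

    items = S @ sm.item_loadings.T + rng.standard_normal(
        (n, config.n_mh_items)
    ) * np.sqrt(sm.item_noise)
    if config.refusal_rate > 0:
        mask = rng.random(items.shape) < config.refusal_rate
        codes = rng.choice(np.asarray(REFUSAL_CODES, dtype=float), size=items.shape)
        items = np.where(mask, codes, items)
    mh = pd.DataFrame(items, columns=[f"mh_{j:03d}" for j in range(config.n_mh_items)])

    blocks = {}
    for blk in config.blocks:
        F = sm.feature_loadings[blk.name]
        X = S @ F.T + rng.standard_normal((n, blk.n_features)) * np.sqrt(
            sm.feature_noise[blk.name]
        )
        blocks[blk.name] = pd.DataFrame(
            X, columns=[f"{blk.name}_f{j:03d}" for j in range(blk.n_features)]
        )

    confounds = pd.DataFrame(
        {
            "age": config.age_mean + config.age_sd * age_z,
            "sex": sex_raw.astype(int),
            "site": np.array([f"site{s + 1}" for s in site_raw]),
            "acquisition_date": acq_date,
        }
    )
    ids = np.array([f"sub{str(i + 1).zfill(6)}" for i in range(n)])
    for tbl in (cognitive_raw, mh, confounds, *blocks.values()):
        tbl.index = pd.Index(ids, name="subject_id")

    truth = None
    if with_truth:
        truth = theoretical_commonality(config)
        truth.g_true = g_true
        truth.sources = pd.DataFrame(
            {
                "g_true": g_true,
                "mh_latent": m_latent,
                "shared": S[:, sm.index["shared"]],
                "mh_only": S[:, sm.index["mh_only"]],
            },
            index=pd.Index(ids, name="subject_id"),
        )

    return CohortData(
        subject_ids=ids,
        cognitive_raw=cognitive_raw,
        mental_health_items=mh,
        feature_blocks=blocks,
        confounds=confounds,
        block_specs=list(config.blocks),
        truth=truth,
        config=config,
    )


def _site_shifts(n_sites: int) -> np.ndarray:
    """Fixed zero-mean, unit-variance per-level site effects."""
    raw = np.linspace(-1.0, 1.0, n_sites)
    raw = raw - raw.mean()
    return raw / raw.std()


def _to_raw_cognitive(tests: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Invert the analysis transformations onto published raw scales.

    The factor pattern stores negative loadings for durations and error
    counts, so those analysis-scale latents are already oriented
    "higher = slower/worse" and map directly onto raw scales.
    """
    t = {c: tests[:, i] for i, c in enumerate(COGNITIVE_COLUMNS)}
    out = {}
    out["reaction_time"] = np.exp(6.4 + 0.2 * t["reaction_time"])
    out["trail_numeric"] = np.exp(5.4 + 0.3 * t["trail_numeric"])
    out["trail_alphabetic"] = np.exp(6.3 + 0.4 * t["trail_alphabetic"])
    out["pairs_matching_incorrect"] = np.round(
        np.expm1(np.clip(1.4 + 0.6 * t["pairs_matching_incorrect"], 0.0, 3.9))
    )
    out["fluid_intelligence"] = np.clip(
        np.round(6.6 + 2.0 * t["fluid_intelligence"]), 0, 13
    )
    out["numeric_memory"] = np.clip(np.round(6.8 + 1.3 * t["numeric_memory"]), 2, 12)
    out["symbol_digit"] = np.clip(np.round(18.9 + 5.2 * t["symbol_digit"]), 0, 37)
    out["paired_associate"] = np.clip(
        np.round(7.0 + 2.5 * t["paired_associate"]), 0, 10
    )
    out["tower_rearranging"] = np.clip(
        np.round(9.9 + 3.2 * t["tower_rearranging"]), 0, 18
    )
    out["matrix_completion"] = np.clip(
        np.round(8.0 + 2.1 * t["matrix_completion"]), 0, 15
    )
    out["picture_vocabulary"] = np.clip(0.4 + 0.1 * t["picture_vocabulary"], 0.0, 0.7)
    p_success = 1.0 / (1.0 + np.exp(-(1.8 + 1.6 * t["prospective_memory"])))
    success = rng.random(len(p_success)) < p_success
    fail_shape = rng.integers(0, 3, size=len(p_success))
    out["prospective_memory"] = np.where(success, 3, fail_shape).astype(float)
    return pd.DataFrame({c: out[c] for c in COGNITIVE_COLUMNS})


# ---------------------------------------------------------------------------
# fixtures


def default_config(n_subjects: int = 5000, seed: int = 20240717) -> GenerativeConfig:
    """The default study conditions: six feature blocks across three
    pseudo-modalities with graded signal and overlap, a mental-health
    latent whose item-based best predictor correlates with the observed
    g score at ~0.31, and demographic confounding shared across all of
    them."""
    blocks = [
        BlockSpec("dw_tract", "dwMRI", 90, 0.62, 0.50, demo_loading=-0.34),
        BlockSpec("dw_tbss", "dwMRI", 70, 0.30, 0.25, demo_loading=-0.15),
        BlockSpec("rs_ic_fc", "rsMRI", 120, 0.66, 0.58, demo_loading=-0.35),
        BlockSpec("rs_amplitude", "rsMRI", 55, 0.26, 0.30, demo_loading=-0.12),
        BlockSpec("smri_subcortical", "sMRI", 60, 0.68, 0.60, demo_loading=-0.38),
        BlockSpec("smri_cortical", "sMRI", 100, 0.32, 0.35, demo_loading=-0.16),
    ]
    return GenerativeConfig(
        n_subjects=n_subjects,
        blocks=blocks,
        source_weights={"shared": 0.52, "mh_only": 0.10, "cognition_only": 0.52},
        confound_weights={"age": -0.42, "sex": 0.10, "site": 0.05},
        mh_latent_weights={
            "shared": 0.50,
            "mh_only": 0.26,
            "age": -0.235,
            "sex": 0.08,
        },
        brain_weights={b.name: 0.20 for b in blocks},
        seed=seed,
    )


_FIXTURES = {"tiny", "default", "null"}


def make_fixture(name: str, n_subjects: "int | None" = None) -> CohortData:
    """Named reference cohorts: ``tiny`` (n=300, 2 blocks) for unit tests,
    ``default`` (n=5000, 6 blocks, 3 pseudo-modalities) for end-to-end
    checks, ``null`` (no associations anywhere) for calibration."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    if name == "tiny":
        cfg = default_config(n_subjects or 300, seed=101)
        cfg.blocks = [
            BlockSpec("block_a", "dwMRI", 20, 0.60, 0.45, demo_loading=-0.30),
            BlockSpec("block_b", "sMRI", 20, 0.55, 0.60, demo_loading=-0.35),
        ]
        cfg.brain_weights = {b.name: 0.15 for b in cfg.blocks}
        cfg.validate()
        return generate_cohort(cfg)
    if name == "default":
        return generate_cohort(default_config(n_subjects or 5000))
    cfg = default_config(n_subjects or 1000, seed=303)
    cfg.source_weights = {"shared": 0.0, "mh_only": 0.0, "cognition_only": 0.8}
    cfg.confound_weights = {"age": 0.0, "sex": 0.0, "site": 0.0}
    cfg.mh_latent_weights = {"shared": 0.0, "mh_only": 0.6, "age": 0.0, "sex": 0.0}
    cfg.brain_weights = {b.name: 0.0 for b in cfg.blocks}
    for b in cfg.blocks:
        b.signal_strength = 0.0
        b.demo_loading = 0.0
        b.site_loading = 0.0
        b.feature_site_leakage = 0.0
    cfg.validate()
    return generate_cohort(cfg)
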