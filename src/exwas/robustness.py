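"""Sensitivity suite: model-variant effect changes, per-cohort
meta-analysis with heterogeneity, and multi-exposure mutually adjusted
models.

Three checks of robustness for significant associations:

* refit under an alternative model (ancestry-restricted, zBMI-unadjusted)
  and compute the percent change in effect size,
  (effect_main - effect_alt) / effect_main x 100, flagging associations
  whose effect more than doubles (|change| > 100);
* refit within each recruitment cohort and combine by fixed- and
  random-effects inverse-variance meta-analysis (DerSimonian-Laird tau^2),
  with Cochran's Q and I^2 quantifying between-cohort heterogeneity;
* for features hit by several exposures, fit mutually adjusted
  multi-exposure models after pruning co-exposures that are too correlated
  (|r| >= 0.8) or share a correlation group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    CorrelationMatrix,
    CovariateTable,
    ExposomeTable,
    OmicsLayer,
    RunConfig,
    align_samples,
)
from .exwas_engine import (
    ModelSpec,
    SurrogateVariableSet,
    build_design,
    compute_surrogate_variables,
    exposure_design,
    ols_multi,
    _t_pvalues,
)

logger = logging.getLogger("exwas")

ASSOC_KEY = ("exposure", "period", "feature", "layer", "contrast")


@dataclass
class EffectChange:
    key: tuple
    effect_main: float
    effect_alt: float
    percent_change: float  # NaN when effect_main == 0
    flagged: bool


@dataclass
class MetaResult:
    key: tuple
    cohorts: pd.DataFrame  # columns: cohort, estimate, se, n, weight_pct
    beta_fixed: float
    se_fixed: float
    beta_random: float
    se_random: float
    tau2: float
    q: float
    i2: float  # percent; NaN with a single cohort


@dataclass
class MultiExposureSet:
    feature: str
    period: str
    layer: str
    exposures: list[str]
    exclusion_log: list[dict] = field(default_factory=list)
    joint: pd.DataFrame | None = None  # exposure, contrast, effect, se, p, single_effect, percent_change


# ---------------------------------------------------------------------------
# percent effect change
# ---------------------------------------------------------------------------

def percent_effect_change(effect_main: float, effect_alt: float, key: tuple = ()) -> EffectChange:
    """(main - alt)/main x 100; flagged when the magnitude exceeds 100
    ("more than a doubling").  Undefined (NaN) when the main effect is 0."""
    if effect_main == 0.0:
        logger.warning("percent change undefined for zero main effect (%s)", key)
        return EffectChange(key, effect_main, effect_alt, float("nan"), False)
    change = (effect_main - effect_alt) / effect_main * 100.0
    return EffectChange(key, effect_main, effect_alt, change, abs(change) > 100.0)


def compare_models(main: pd.DataFrame, alt: pd.DataFrame) -> pd.DataFrame:
    """Join two association tables on the association key and compute the
    percent effect change per row."""
    keys = list(ASSOC_KEY)
    merged = main.merge(alt, on=keys, suffixes=("_main", "_alt"))
    rows = []
    for _, r in merged.iterrows():
        ec = percent_effect_change(r["effect_main"], r["effect_alt"], tuple(r[k] for k in keys))
        rows.append(
            {**{k: r[k] for k in keys},
             "effect_main": ec.effect_main, "effect_alt": ec.effect_alt,
             "percent_change": ec.percent_change, "flagged": ec.flagged,
             "model_tag_main": r["model_tag_main"], "model_tag_alt": r["model_tag_alt"]}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------

def cohort_meta_analysis(per_cohort: pd.DataFrame, key: tuple = ()) -> MetaResult:
    """Fixed- and random-effects inverse-variance meta-analysis.

    Fixed effects: weights 1/se^2.  Between-cohort variance tau^2 by
    DerSimonian-Laird, max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w));
    random-effect weights 1/(se^2 + tau^2).  I^2 = max(0, (Q-(k-1))/Q) x 100
    (0 when Q = 0; NaN with a single cohort).
    """
    df = per_cohort.reset_index(drop=True)
    bad = df[~(df["se"] > 0) | ~np.isfinite(df["se"]) | ~np.isfinite(df["estimate"])]
    if len(bad):
        raise ValueError(f"non-positive or non-finite SE for cohort {bad['cohort'].iloc[0]!r}")
    k = len(df)
    est = df["estimate"].to_numpy(float)
    w = 1.0 / df["se"].to_numpy(float) ** 2
    beta_fixed = float(np.sum(w * est) / np.sum(w))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (est - beta_fixed) ** 2))
    if k == 1:
        meta = MetaResult(key, df, beta_fixed, se_fixed, beta_fixed, se_fixed,
                          0.0, 0.0, float("nan"))
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        wr = 1.0 / (df["se"].to_numpy(float) ** 2 + tau2)
        beta_random = float(np.sum(wr * est) / np.sum(wr))
        se_random = float(1.0 / np.sqrt(np.sum(wr)))
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
        meta = MetaResult(key, df, beta_fixed, se_fixed, beta_random, se_random,
                          tau2, q, i2)
    meta.cohorts = meta.cohorts.assign(weight_pct=100.0 * w / np.sum(w))
    return meta


def run_exwas_by_cohort(
    associations: pd.DataFrame,
    exposome: ExposomeTable,
    layers: dict[str, OmicsLayer],
    covariates: CovariateTable,
    spec: ModelSpec | None = None,
    svs_by_layer: dict[str, SurrogateVariableSet] | None = None,
    min_cohort_n: int = 50,
    sv_recompute_min_n: int = 100,
) -> list[MetaResult]:
    """Refit the given associations within each cohort and meta-analyse.

    Per-cohort models drop the cohort covariate.  Surrogate variables are
    recomputed within a cohort only when it has at least
    ``sv_recompute_min_n`` samples; otherwise the global SVs are reused
    restricted to the cohort's samples.  Cohorts with fewer than
    ``min_cohort_n`` usable samples are skipped (logged).
    """
    spec = spec or ModelSpec()
    cohort_spec = ModelSpec(
        main_covariates=spec.main_covariates,
        n_surrogate_variables=spec.n_surrogate_variables,
        adjust_zbmi=spec.adjust_zbmi,
        include_cohort=False,
        model_tag="by_cohort",
        sv_seed=spec.sv_seed,
    )
    cohorts = sorted(covariates.values["cohort"].unique())
    rows: list[dict] = []
    for cohort in cohorts:
        members = covariates.values.index[covariates.values["cohort"] == cohort]
        cov_c = covariates.subset(list(members))
        expo_c = exposome.subset([s for s in exposome.samples if s in set(members)])
        for layer_name, assoc in associations.groupby("layer", sort=False):
            layer = layers[layer_name]
            samples = align_samples(expo_c, cov_c, [layer])[layer_name]
            if len(samples) < min_cohort_n:
                logger.warning("cohort %s / layer %s: %d samples, skipped",
                               cohort, layer_name, len(samples))
                continue
            cov_sub = cov_c.subset(samples)
            base = build_design(cov_sub, cohort_spec.covariate_columns())
            if layer.genome_wide and cohort_spec.n_surrogate_variables not in (None, 0):
                if len(samples) >= sv_recompute_min_n:
                    sv = compute_surrogate_variables(
                        layer.subset(samples), cov_sub, cohort_spec
                    )
                    sv_vals = sv.values
                elif svs_by_layer and layer_name in svs_by_layer:
                    sv_vals = svs_by_layer[layer_name].values.loc[
                        [s for s in samples if s in svs_by_layer[layer_name].values.index]
                    ]
                else:
                    sv_vals = None
                if sv_vals is not None and sv_vals.shape[1] > 0:
                    base = pd.concat([base, sv_vals.loc[samples]], axis=1)
            Xbase = base.to_numpy(float)
            feats = assoc["feature"].unique().tolist()
            Y = layer.values.loc[samples, feats].to_numpy(float)
            for exposure in assoc["exposure"].unique():
                var = expo_c.variable(exposure)
                try:
                    xcols = exposure_design(var, expo_c.values[exposure].loc[samples])
                except ValueError:
                    logger.warning("cohort %s: degenerate exposure %s, skipped", cohort, exposure)
                    continue
                X = np.hstack([Xbase, xcols.to_numpy(float)])
                if X.shape[0] < X.shape[1] + 2:
                    continue
                try:
                    B, se, dfres = ols_multi(X, Y)
                except np.linalg.LinAlgError:
                    logger.warning("cohort %s: singular design for %s, skipped", cohort, exposure)
                    continue
                pv = _t_pvalues(B, se, dfres)
                for ci, cname in enumerate(xcols.columns):
                    contrast = (
                        cname[len(var.name) + 1:-1] if var.vartype == "categorical" else ""
                    )
                    ri = Xbase.shape[1] + ci
                    for j, feat in enumerate(feats):
                        rows.append(
                            {"cohort": cohort, "exposure": exposure, "period": var.period,
                             "feature": feat, "layer": layer_name, "contrast": contrast,
                             "estimate": float(B[ri, j]), "se": float(se[ri, j]),
                             "p": float(pv[ri, j]), "n": len(samples)}
                        )
    per_cohort = pd.DataFrame(rows)
    results: list[MetaResult] = []
    wanted = associations[list(ASSOC_KEY)].drop_duplicates()
    for _, krow in wanted.iterrows():
        key = tuple(krow[k] for k in ASSOC_KEY)
        sub = per_cohort[
            (per_cohort[list(ASSOC_KEY)] == pd.Series(dict(zip(ASSOC_KEY, key)))).all(axis=1)
        ] if len(per_cohort) else per_cohort
        if len(sub) == 0:
            logger.warning("no cohort estimates for %s", key)
            continue
        results.append(cohort_meta_analysis(sub[["cohort", "estimate", "se", "n"]], key))
    return results


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {**dict(zip(ASSOC_KEY, r.key)),
             "k_cohorts": len(r.cohorts), "beta_fixed": r.beta_fixed, "se_fixed": r.se_fixed,
             "beta_random": r.beta_random, "se_random": r.se_random,
             "tau2": r.tau2, "q": r.q, "i2": r.i2}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multi-exposure models
# ---------------------------------------------------------------------------

def _corr_magnitude(corr: CorrelationMatrix, a: str, b: str, scale: str) -> float:
    v = corr[a, b]
    if np.isnan(v):
        return 0.0
    mag = abs(v)
    if scale == "r2":
        i = corr.labels.index(a)
        j = corr.labels.index(b)
        if corr.method_per_pair[i, j] == "sqrt_r2":
            mag = mag**2
    return mag


def select_multi_exposure_sets(
    significant: pd.DataFrame,
    corr: CorrelationMatrix,
    exposome: ExposomeTable,
    config: RunConfig | None = None,
) -> list[MultiExposureSet]:
    """Choose, per feature and period, the exposures to adjust mutually.

    Candidates are the feature's significant exposures.  First, one
    representative per correlation group survives (smallest single-exposure
    p, ties broken lexicographically).  Then pairs correlated at or above
    the cutoff are pruned greedily, dropping the weaker (larger-p) member.
    Features left with fewer than two exposures are excluded.  The
    exclusion log records every drop.
    """
    config = config or RunConfig()
    out: list[MultiExposureSet] = []
    groups = {v.name: v.correlation_group for v in exposome.variables}
    best_p = (
        significant.groupby(["feature", "period", "layer", "exposure"], sort=False)["p"]
        .min()
        .reset_index()
    )
    for (feature, period, layer_name), sub in best_p.groupby(
        ["feature", "period", "layer"], sort=True
    ):
        cands = sub.sort_values(["p", "exposure"]).reset_index(drop=True)
        if len(cands) < 2:
            continue
        log: list[dict] = []
        for name in cands["exposure"]:
            if name not in groups:
                raise ValueError(f"exposure {name!r} missing from exposome metadata")
            if name not in corr.labels:
                raise ValueError(f"exposure {name!r} missing from correlation matrix")
        # one representative per correlation group (cands already p-ordered)
        seen: dict[str, str] = {}
        survivors: list[tuple[str, float]] = []
        for _, row in cands.iterrows():
            g = groups[row["exposure"]]
            if g in seen:
                log.append({"dropped": row["exposure"], "kept": seen[g],
                            "reason": f"same correlation_group {g!r}"})
            else:
                seen[g] = row["exposure"]
                survivors.append((row["exposure"], row["p"]))
        # greedy high-correlation pruning, strongest first
        kept: list[tuple[str, float]] = []
        for name, p in survivors:
            clash = next(
                (k for k, _ in kept
                 if _corr_magnitude(corr, name, k, config.correlation_scale)
                 >= config.correlation_cutoff),
                None,
            )
            if clash is not None:
                log.append({"dropped": name, "kept": clash,
                            "reason": f"correlation >= {config.correlation_cutoff}"})
            else:
                kept.append((name, p))
        if len(kept) < 2:
            continue
        out.append(
            MultiExposureSet(feature, period, layer_name, [k for k, _ in kept], log)
        )
    return out


def fit_multi_exposure(
    mset: MultiExposureSet,
    exposome: ExposomeTable,
    layer: OmicsLayer,
    covariates: CovariateTable,
    single: pd.DataFrame,
    spec: ModelSpec | None = None,
    svs: SurrogateVariableSet | None = None,
) -> MultiExposureSet:
    """One joint OLS with all selected exposures plus the standard
    covariates/SVs; percent change computed against each single-exposure
    effect.  A singular joint design is refit after dropping the collinear
    exposure (logged in the exclusion log)."""
    spec = spec or ModelSpec()
    samples = align_samples(exposome, covariates, [layer])[layer.layer]
    cov_sub = covariates.subset(samples)
    base = build_design(cov_sub, spec.covariate_columns())
    if svs is not None and svs.k > 0:
        base = pd.concat([base, svs.values.loc[samples]], axis=1)

    exposures = list(mset.exposures)
    while True:
        blocks, owners = [], []
        for name in exposures:
            xcols = exposure_design(
                exposome.variable(name), exposome.values[name].loc[samples]
            )
            blocks.append(xcols)
            owners += [name] * xcols.shape[1]
        design = pd.concat([base] + blocks, axis=1)
        X = design.to_numpy(float)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        dropped = exposures.pop()  # weakest survivor (selection kept p-order)
        mset.exclusion_log.append(
            {"dropped": dropped, "kept": "", "reason": "collinear in joint design"}
        )
        logger.warning("%s/%s: dropped collinear exposure %s", mset.feature, mset.period, dropped)
        if len(exposures) < 2:
            mset.exposures = exposures
            return mset

    y = layer.values.loc[samples, mset.feature].to_numpy(float)
    B, se, dfres = ols_multi(X, y)
    pv = _t_pvalues(B, se, dfres)
    p_base = base.shape[1]
    rows = []
    col_names = list(design.columns[p_base:])
    singles = single.set_index(["exposure", "feature", "period", "layer", "contrast"])
    for off, (name, cname) in enumerate(zip(owners, col_names)):
        var = exposome.variable(name)
        contrast = cname[len(name) + 1:-1] if var.vartype == "categorical" else ""
        i = p_base + off
        try:
            eff_single = float(
                singles.loc[(name, mset.feature, mset.period, mset.layer, contrast), "effect"]
            )
        except KeyError:
            eff_single = float("nan")
        change = (
            percent_effect_change(eff_single, float(B[i, 0])).percent_change
            if eff_single == eff_single and eff_single != 0.0 else float("nan")
        )
        rows.append(
            {"exposure": name, "contrast": contrast, "effect": float(B[i, 0]),
             "se": float(se[i, 0]), "p": float(pv[i, 0]),
             "single_effect": eff_single, "percent_change": change}
        )
    mset.exposures = exposures
    mset.joint = pd.DataFrame(rows)
    return mset
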