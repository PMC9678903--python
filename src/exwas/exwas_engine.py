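"""The ExWAS engine: per-pair adjusted linear models.

For every exposure x and molecular feature y, fit

    y ~ x/IQR(x) + cohort + sex + age + zBMI + ancestry + maternal education
        (+ layer technical covariates) (+ surrogate variables)

by ordinary least squares with classical two-sided t-tests.  Continuous
exposures are divided by their interquartile range, so the coefficient is
the per-IQR effect (a log2 fold change for log2-scale layers, a difference
in methylation level for methylation betas).  Categorical exposures enter
as reference-coded indicators, one association record per non-reference
level.

Genome-wide layers (methylation, expression, miRNA) additionally receive
surrogate variables: the top left singular vectors of the
covariate-residualized feature matrix, with the number of components chosen
by permutation parallel analysis.  These capture unmeasured structure such
as batch and blood cell composition.

Fitting is vectorized: one design factorization per exposure serves every
feature of a layer simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    CovariateTable,
    ExposomeTable,
    ExposureVariable,
    OmicsLayer,
    align_samples,
    iqr,
)

logger = logging.getLogger("exwas")

#: fixed column order of the interchange association table
RECORD_COLUMNS = (
    "exposure", "period", "family", "feature", "layer",
    "contrast", "effect", "se", "p", "n", "model_tag",
)


@dataclass
class ModelSpec:
    """Which model variant to fit.

    main_covariates
        covariate columns entered in every model (categorical columns are
        reference-coded automatically).
    n_surrogate_variables
        'auto' (permutation parallel analysis), an integer K, or 0/None to
        skip SV adjustment.  Applied to genome-wide layers only.
    restrict_ancestry
        if set, restrict the analysis to samples with this ancestry label.
    adjust_zbmi
        drop zBMI from the covariates when False (sensitivity variant).
    """

    main_covariates: tuple[str, ...] = (
        "cohort", "sex", "age", "zbmi", "ancestry", "maternal_education",
    )
    n_surrogate_variables: int | str | None = "auto"
    restrict_ancestry: str | None = None
    adjust_zbmi: bool = True
    include_cohort: bool = True
    model_tag: str = "main"
    min_extra_samples: int = 10
    sv_seed: int = 0

    def covariate_columns(self) -> tuple[str, ...]:
        cols = list(self.main_covariates)
        if not self.adjust_zbmi and "zbmi" in cols:
            cols.remove("zbmi")
        if not self.include_cohort and "cohort" in cols:
            cols.remove("cohort")
        return tuple(cols)


@dataclass
class SurrogateVariableSet:
    """Estimated surrogate variables for one genome-wide layer."""

    layer: str
    values: pd.DataFrame  # sample x K, unit-variance columns
    method_tag: str = "residual_svd_parallel_analysis"

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationRecord:
    exposure: str
    period: str
    family: str
    feature: str
    layer: str
    effect: float
    se: float
    p: float
    n: int
    contrast: str = ""
    model_tag: str = "main"

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("effect must be finite")
        if self.se <= 0:
            raise ValueError("standard error must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p-value must be in (0,1]")


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in RECORD_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def build_design(
    covariates: CovariateTable,
    columns: Sequence[str],
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intercept + reference-coded covariate design as a DataFrame."""
    df = covariates.values
    parts = [pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)]
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"covariate {col!r} not in covariate table")
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.to_frame(col).astype(float))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    if extra is not None:
        parts.append(extra.loc[df.index].astype(float))
    return pd.concat(parts, axis=1)


def exposure_design(var: ExposureVariable, values: pd.Series) -> pd.DataFrame:
    """Per-IQR scaled column for a continuous exposure; reference-coded
    indicator columns for a categorical one."""
    if var.vartype == "continuous":
        x = values.to_numpy(float)
        scale = iqr(x)
        if scale == 0.0:
            raise ValueError(f"degenerate exposure {var.name!r}: IQR is 0")
        return pd.DataFrame({var.name: x / scale}, index=values.index)
    cols = {}
    for level in var.levels[1:]:
        cols[f"{var.name}[{level}]"] = (values.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=values.index)


# ---------------------------------------------------------------------------
# OLS core (multi-outcome)
# ---------------------------------------------------------------------------

def ols_multi(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of every column of Y on X.

    Returns (coefficients p x m, standard errors p x m, residual df).
    Raises on singular designs, naming the collinear columns by index.
    """
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify offending columns by checking rank without each column
        collinear = [
            j for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(f"singular design; collinear columns {collinear}")
    if Y.ndim == 1:
        Y = Y[:, None]
    df = n - p
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ (X.T @ Y)
    resid = Y - X @ B
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    return B, se, df


def _t_pvalues(B: np.ndarray, se: np.ndarray, df: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.clip(p, np.finfo(float).tiny, 1.0)


# ---------------------------------------------------------------------------
# surrogate variables
# ---------------------------------------------------------------------------

def compute_surrogate_variables(
    layer: OmicsLayer,
    covariates: CovariateTable,
    spec: ModelSpec,
    n_permutations: int = 20,
) -> SurrogateVariableSet:
    """Residual-SVD surrogate variables for a genome-wide layer.

    The feature matrix is residualized on the known covariates and the top-K
    left singular vectors of the residual matrix become the SVs.  When K is
    'auto' it is chosen by permutation parallel analysis: component i is
    retained while its singular value exceeds the 95th percentile of the
    i-th singular values of ``n_permutations`` matrices whose columns are
    independently row-permuted (which destroys shared structure but keeps
    the marginals).
    """
    if not layer.genome_wide:
        raise ValueError(
            f"surrogate variables only apply to genome-wide layers, not {layer.layer!r}"
        )
    samples = [s for s in layer.samples if s in set(covariates.samples)]
    X = build_design(covariates.subset(samples), spec.covariate_columns()).to_numpy(float)
    Y = layer.values.loc[samples].to_numpy(float)
    n = len(samples)

    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = Y - X @ B
    resid = resid - resid.mean(axis=0)

    k_req = spec.n_surrogate_variables
    if k_req in (None, 0):
        return SurrogateVariableSet(layer.layer, pd.DataFrame(index=samples), "none")

    U, S, _ = np.linalg.svd(resid, full_matrices=False)
    if k_req == "auto":
        rng = np.random.default_rng(spec.sv_seed)
        max_k = min(10, len(S))
        perm_s = np.empty((n_permutations, max_k))
        for b in range(n_permutations):
            perm = np.empty_like(resid)
            for j in range(resid.shape[1]):
                perm[:, j] = resid[rng.permutation(n), j]
            perm_s[b] = np.linalg.svd(perm, compute_uv=False)[:max_k]
        # discrete 'higher' percentile: conservative with few permutations
        thresholds = np.percentile(perm_s, 95.0, axis=0, method="higher")
        k = 0
        for i in range(max_k):
            if S[i] > thresholds[i]:
                k += 1
            else:
                break
    else:
        k = int(k_req)
        if k >= n:
            raise ValueError(f"requested K={k} surrogate variables with only {n} samples")
    svs = U[:, :k] * np.sqrt(n)  # unit variance columns
    values = pd.DataFrame(svs, index=samples, columns=[f"SV{i+1}" for i in range(k)])
    logger.info("layer %s: %d surrogate variables retained", layer.layer, k)
    return SurrogateVariableSet(layer.layer, values)


# ---------------------------------------------------------------------------
# association fitting
# ---------------------------------------------------------------------------

def fit_single_association(
    var: ExposureVariable,
    x_values: pd.Series,
    y_values: pd.Series | pd.DataFrame,
    covariate_design: pd.DataFrame,
    layer: str = "protein",
    svs: SurrogateVariableSet | None = None,
    model_tag: str = "main",
    min_extra_samples: int = 10,
) -> list[AssociationRecord]:
    """Fit one exposure against one (or a few) feature vectors.

    Thin convenience wrapper over the vectorized core; run_exwas is the bulk
    path.
    """
    if isinstance(y_values, pd.Series):
        y_values = y_values.to_frame()
    samples = covariate_design.index
    xcols = exposure_design(var, x_values.loc[samples])
    design = pd.concat([covariate_design, xcols], axis=1)
    if svs is not None and svs.k > 0:
        design = pd.concat([design, svs.values.loc[samples]], axis=1)
    X = design.to_numpy(float)
    n, p = X.shape
    if n < p + min_extra_samples:
        raise ValueError(
            f"only {n} samples for {p} design columns (need {p + min_extra_samples})"
        )
    Y = y_values.loc[samples].to_numpy(float)
    B, se, df = ols_multi(X, Y)
    pvals = _t_pvalues(B, se, df)
    idx = [design.columns.get_loc(c) for c in xcols.columns]
    records = []
    for j, feat in enumerate(y_values.columns):
        for ci, cname in zip(idx, xcols.columns):
            contrast = cname[len(var.name) + 1:-1] if var.vartype == "categorical" else ""
            records.append(
                AssociationRecord(
                    exposure=var.name, period=var.period, family=var.family,
                    feature=str(feat), layer=layer,
                    effect=float(B[ci, j]), se=float(se[ci, j]), p=float(pvals[ci, j]),
                    n=n, contrast=contrast, model_tag=model_tag,
                )
            )
    return records


def run_exwas(
    exposome: ExposomeTable,
    layers: Sequence[OmicsLayer],
    covariates: CovariateTable,
    spec: ModelSpec | None = None,
    svs_by_layer: dict[str, SurrogateVariableSet] | None = None,
) -> pd.DataFrame:
    """Fit every exposure x feature (x contrast) model and return the
    interchange association table.

    Records are ordered by (period, layer, exposure, feature); per-record n
    reflects the layer's sample availability.  Surrogate variables are
    computed (or taken from ``svs_by_layer``) for genome-wide layers when
    the model spec asks for them.
    """
    spec = spec or ModelSpec()
    if spec.restrict_ancestry is not None:
        keep = covariates.values.index[
            covariates.values["ancestry"] == spec.restrict_ancestry
        ]
        covariates = covariates.subset(list(keep))
        exposome = exposome.subset([s for s in exposome.samples if s in set(keep)])

    sample_map = align_samples(exposome, covariates, layers)
    svs_by_layer = dict(svs_by_layer or {})

    all_rows: list[dict] = []
    for period in ("pregnancy", "childhood"):
        period_vars = exposome.for_period(period)
        if not period_vars:
            continue
        for layer in layers:
            samples = sample_map[layer.layer]
            cov_sub = covariates.subset(samples)
            base = build_design(cov_sub, spec.covariate_columns())
            min_n = base.shape[1] + 1 + spec.min_extra_samples
            if len(samples) < min_n:
                raise ValueError(
                    f"layer {layer.layer!r}: only {len(samples)} aligned samples "
                    f"(need >= {min_n})"
                )
            if layer.genome_wide and spec.n_surrogate_variables not in (None, 0):
                if layer.layer not in svs_by_layer:
                    svs_by_layer[layer.layer] = compute_surrogate_variables(
                        layer.subset(samples), cov_sub, spec
                    )
                sv = svs_by_layer[layer.layer]
                if sv.k > 0:
                    base = pd.concat([base, sv.values.loc[samples]], axis=1)
            Xbase = base.to_numpy(float)
            Y = layer.values.loc[samples].to_numpy(float)
            n = len(samples)
            feature_ids = list(layer.values.columns)
            for var in period_vars:
                xcols = exposure_design(var, exposome.values[var.name].loc[samples])
                X = np.hstack([Xbase, xcols.to_numpy(float)])
                B, se, df = ols_multi(X, Y)
                pvals = _t_pvalues(B, se, df)
                for ci, cname in enumerate(xcols.columns):
                    row_i = Xbase.shape[1] + ci
                    contrast = (
                        cname[len(var.name) + 1:-1] if var.vartype == "categorical" else ""
                    )
                    eff, serr, pv = B[row_i], se[row_i], pvals[row_i]
                    for j, feat in enumerate(feature_ids):
                        all_rows.append(
                            {
                                "exposure": var.name, "period": period,
                                "family": var.family, "feature": feat,
                                "layer": layer.layer, "contrast": contrast,
                                "effect": float(eff[j]), "se": float(serr[j]),
                                "p": float(pv[j]), "n": n,
                                "model_tag": spec.model_tag,
                            }
                        )
    out = pd.DataFrame(all_rows, columns=list(RECORD_COLUMNS))
    logger.info("ExWAS: %d association records (%s)", len(out), spec.model_tag)
    return out
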