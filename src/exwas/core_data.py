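"""Domain types and shared utilities for exposome-omics association studies.

The exposome side of the analysis is a sample-by-exposure table of mixed
continuous/categorical variables, each annotated with the exposure window
(pregnancy or childhood), an exposure family (metals, phthalates, diet, ...)
and a transform tag.  The molecular side is a set of sample-by-feature
matrices, one per omics layer (DNA methylation betas, log2 expression,
miRNA, plasma proteins, serum and urinary metabolites), with per-feature
genomic annotation where the layer supports it.

Everything downstream (the association engine, multiple-testing correction,
networks, cross-layer integration) consumes these containers, the IQR
transform and the mixed-type correlation matrix defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import contingency

logger = logging.getLogger("exwas")

PERIODS = ("pregnancy", "childhood")
LAYERS = ("methylation", "expression", "mirna", "protein", "serum_metab", "urine_metab")
#: layers measured genome-wide (BH-FDR correction); the rest are targeted panels
GENOME_WIDE_LAYERS = frozenset({"methylation", "expression", "mirna"})
#: families whose members each form their own correlation group
SINGLETON_GROUP_FAMILIES = frozenset({"diet", "metals", "parabens"})

#: float format that round-trips IEEE doubles exactly through text
FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Thresholds and conventions of one analysis run.

    alpha
        nominal per-layer significance level (BH-FDR level for genome-wide
        layers, numerator of the ENT-Bonferroni threshold for targeted ones).
    global_cutoff
        stringent p-value cutoff applied across every test of the run.
    correlation_cutoff
        exposure-exposure correlation above which two exposures are not
        mutually adjusted in multi-exposure models.
    correlation_scale
        'magnitude' compares sqrt(R^2) (all mixed-type entries live in [0,1])
        against ``correlation_cutoff``; 'r2' compares R^2 itself.
    cis_window
        half-width in bp of the cis window for CpG-transcript pairing.
    path_length_convention
        'edges' counts shortest paths in edges; 'nodes' counts nodes on the
        path (edges + 1).
    network_stats_on_display_subset
        compute topology statistics on the >=2-molecular-feature display
        subset instead of the full period network.
    replication_requires_sign
        cross-matrix replication requires sign agreement in addition to
        nominal significance.
    """

    alpha: float = 0.05
    global_cutoff: float = 1e-9
    correlation_cutoff: float = 0.8
    correlation_scale: str = "magnitude"
    cis_window: int = 500_000
    catalogue_p_cutoff: float = 0.01
    path_length_convention: str = "edges"
    network_stats_on_display_subset: bool = False
    replication_requires_sign: bool = True
    min_extra_samples: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

@dataclass
class ExposureVariable:
    """One exposure variable with its analysis metadata.

    ``correlation_group`` defaults to the exposure family except for members
    of the diet, metals and parabens families, which each form their own
    group (so e.g. two metals may be mutually adjusted but two congeners of
    the same organochlorine family may not).
    """

    name: str
    period: str
    family: str
    vartype: str = "continuous"
    levels: tuple[str, ...] | None = None
    transform: str = "none"
    correlation_group: str = ""

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValueError(f"{self.name}: unknown period {self.period!r}")
        if self.vartype not in ("continuous", "categorical"):
            raise ValueError(f"{self.name}: unknown vartype {self.vartype!r}")
        if self.vartype == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise ValueError(f"{self.name}: categorical exposure needs >=2 levels")
            self.levels = tuple(str(l) for l in self.levels)
        elif self.levels:
            raise ValueError(f"{self.name}: continuous exposure cannot declare levels")
        if not self.correlation_group:
            if self.family.lower() in SINGLETON_GROUP_FAMILIES:
                self.correlation_group = self.name
            else:
                self.correlation_group = self.family

    @property
    def reference_level(self) -> str | None:
        return self.levels[0] if self.levels else None

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.period)


@dataclass
class ExposomeTable:
    """Aligned sample-by-exposure table plus per-exposure metadata.

    ``values`` holds numeric columns for continuous exposures and string
    level codes for categorical ones; missing values are rejected
    (imputation happens upstream of this pipeline).
    """

    values: pd.DataFrame
    variables: list[ExposureVariable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate exposure names")
        if list(self.values.columns) != names:
            raise ValueError("exposome column order must match variable metadata order")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing values in exposure {bad!r}; impute upstream")
        for var in self.variables:
            if var.vartype == "categorical":
                col = self.values[var.name].astype(str)
                extra = set(col.unique()) - set(var.levels)
                if extra:
                    sample = self.values.index[col.isin(extra)][0]
                    raise ValueError(
                        f"exposure {var.name!r}, sample {sample!r}: level "
                        f"{sorted(extra)[0]!r} not among declared levels {var.levels}"
                    )
                self.values[var.name] = col

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def variable(self, name: str) -> ExposureVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def for_period(self, period: str) -> list[ExposureVariable]:
        return [v for v in self.variables if v.period == period]

    def subset(self, samples: Sequence[str]) -> "ExposomeTable":
        return ExposomeTable(self.values.loc[list(samples)].copy(), list(self.variables))


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------

@dataclass
class OmicsFeature:
    """One molecular feature (CpG, transcript cluster, miRNA, protein, metabolite)."""

    feature_id: str
    layer: str
    gene: str | None = None
    chrom: str | None = None
    position: int | None = None  # 1-based; CpG site or transcript TSS
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"{self.feature_id}: unknown layer {self.layer!r}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")


@dataclass
class OmicsLayer:
    """Sample-by-feature matrix for one molecular layer.

    ``scale`` records the value convention: 'beta_0_1' for methylation
    proportions, 'log2' for log2-transformed abundances (so per-IQR effects
    are log2 fold changes), 'raw' otherwise.
    """

    layer: str
    values: pd.DataFrame
    features: list[OmicsFeature] = field(default_factory=list)
    scale: str = "log2"
    technical_covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if not self.features:
            self.features = [OmicsFeature(f, self.layer) for f in self.values.columns]
        if [f.feature_id for f in self.features] != list(self.values.columns):
            raise ValueError("feature metadata order must match matrix columns")
        if self.scale == "beta_0_1":
            vals = self.values.to_numpy(float)
            if np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0:
                raise ValueError("beta_0_1 layer has values outside [0,1]")

    @property
    def genome_wide(self) -> bool:
        return self.layer in GENOME_WIDE_LAYERS

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature(self, feature_id: str) -> OmicsFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def subset(self, samples: Sequence[str]) -> "OmicsLayer":
        return OmicsLayer(
            self.layer,
            self.values.loc[list(samples)].copy(),
            list(self.features),
            self.scale,
            self.technical_covariate_names,
        )


@dataclass
class CovariateTable:
    """One row per sample: cohort, sex, age, zBMI, ancestry, maternal
    education plus any extra layer-specific technical columns."""

    values: pd.DataFrame

    REQUIRED = ("cohort", "sex", "age", "zbmi", "ancestry", "maternal_education")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.values.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        if self.values[list(self.REQUIRED)].isna().any().any():
            raise ValueError("missing values in covariates")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def subset(self, samples: Sequence[str]) -> "CovariateTable":
        return CovariateTable(self.values.loc[list(samples)].copy())


# ---------------------------------------------------------------------------
# IQR and correlation
# ---------------------------------------------------------------------------

def iqr(values: Sequence[float] | np.ndarray) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles.

    Continuous exposures enter the association models as x / IQR(x) so the
    regression coefficient is the effect per interquartile-range increase.
    A constant vector returns 0; downstream scaling must reject it.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise ValueError("iqr needs a 1-d vector of length >= 4")
    q1, q3 = np.percentile(arr, [25.0, 75.0], method="linear")
    return float(q3 - q1)


@dataclass
class CorrelationMatrix:
    """Symmetric mixed-type exposure correlation matrix.

    Continuous-continuous entries are Pearson r (signed); entries involving a
    categorical variable are magnitudes in [0,1] (sqrt of the linear-model
    R^2 for continuous-categorical, Cramér's V for categorical-categorical).
    Undefined entries (zero-variance variable) are NaN.
    """

    labels: list[str]
    values: np.ndarray
    method_per_pair: np.ndarray  # object array of method tags

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _eta_sqrt_r2(y: np.ndarray, groups: np.ndarray) -> float:
    """sqrt(R^2) of the linear model of continuous y on category indicators."""
    y = np.asarray(y, dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return np.nan
    ssb = 0.0
    for g in np.unique(groups):
        sub = y[groups == g]
        ssb += sub.size * (sub.mean() - y.mean()) ** 2
    r2 = ssb / sst
    return float(np.sqrt(min(max(r2, 0.0), 1.0)))


def _cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if min(tab.shape) < 2:
        return np.nan
    return float(contingency.association(tab, method="cramer", correction=False))


def exposure_correlation(table: ExposomeTable) -> CorrelationMatrix:
    """Pairwise exposure correlations with the mixed-type conventions.

    Pearson r for continuous pairs, sqrt(R^2) for continuous-categorical,
    Cramér's V for categorical pairs.  Zero-variance continuous variables
    yield NaN entries with a logged warning.
    """
    if len(table.samples) < 3:
        raise ValueError("need >= 3 samples for correlations")
    variables = table.variables
    n = len(variables)
    vals = np.eye(n)
    methods = np.empty((n, n), dtype=object)
    methods[:] = ""
    cols: dict[str, np.ndarray] = {}
    for v in variables:
        col = table.values[v.name].to_numpy()
        cols[v.name] = col.astype(float) if v.vartype == "continuous" else col.astype(str)
        if v.vartype == "continuous" and np.std(cols[v.name]) == 0.0:
            logger.warning("exposure %s has zero variance; correlations undefined", v.name)
    for i in range(n):
        vi = variables[i]
        for j in range(i + 1, n):
            vj = variables[j]
            xi, xj = cols[vi.name], cols[vj.name]
            if vi.vartype == "continuous" and vj.vartype == "continuous":
                method = "pearson"
                if np.std(xi) == 0.0 or np.std(xj) == 0.0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(xi, xj)[0, 1])
            elif vi.vartype == "categorical" and vj.vartype == "categorical":
                method = "cramers_v"
                r = _cramers_v(xi, xj)
            else:
                method = "sqrt_r2"
                y, g = (xi, xj) if vi.vartype == "continuous" else (xj, xi)
                r = _eta_sqrt_r2(y, g)
            vals[i, j] = vals[j, i] = r
            methods[i, j] = methods[j, i] = method
    return CorrelationMatrix([v.name for v in variables], vals, methods)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so 17-significant-digit text restores exact doubles
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def load_exposome(path: str | Path, metadata_path: str | Path) -> ExposomeTable:
    """Load an exposome matrix plus its per-exposure metadata table.

    The matrix is tab-delimited with a header row of exposure names and the
    first column holding sample IDs.  The metadata table has one row per
    exposure with columns name, period, family, vartype, levels ('|'-joined,
    empty for continuous), transform and optional correlation_group.
    Categorical columns are validated against the declared levels.
    """
    values = _read_matrix(path)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    variables = []
    for _, row in meta.iterrows():
        levels = tuple(row["levels"].split("|")) if row.get("levels", "") else None
        variables.append(
            ExposureVariable(
                name=row["name"],
                period=row["period"],
                family=row["family"],
                vartype=row["vartype"],
                levels=levels,
                transform=row.get("transform", "none") or "none",
                correlation_group=row.get("correlation_group", "") or "",
            )
        )
    declared = {v.name for v in variables}
    undeclared = [c for c in values.columns if c not in declared]
    if undeclared:
        raise ValueError(f"exposures in matrix missing from metadata: {undeclared}")
    # order metadata to the matrix columns
    order = {v.name: v for v in variables}
    variables = [order[c] for c in values.columns]
    for v in variables:
        if v.vartype == "continuous":
            values[v.name] = values[v.name].astype(float)
    return ExposomeTable(values, variables)


def save_exposome(table: ExposomeTable, path: str | Path, metadata_path: str | Path) -> None:
    write_matrix(table.values, path)
    rows = [
        {
            "name": v.name,
            "period": v.period,
            "family": v.family,
            "vartype": v.vartype,
            "levels": "|".join(v.levels) if v.levels else "",
            "transform": v.transform,
            "correlation_group": v.correlation_group,
        }
        for v in table.variables
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def load_omics_layer(
    path: str | Path,
    layer: str,
    scale: str = "log2",
    feature_path: str | Path | None = None,
) -> OmicsLayer:
    """Load one omics matrix and optional feature annotation table.

    The annotation table has columns feature_id, gene, chrom, position,
    strand (missing entries empty).
    """
    values = _read_matrix(path).astype(float)
    features: list[OmicsFeature] = []
    if feature_path is not None:
        ann = pd.read_csv(feature_path, sep="\t", dtype=str).fillna("")
        by_id = {row["feature_id"]: row for _, row in ann.iterrows()}
        for fid in values.columns:
            row = by_id.get(fid)
            if row is None:
                features.append(OmicsFeature(fid, layer))
            else:
                features.append(
                    OmicsFeature(
                        fid,
                        layer,
                        gene=row.get("gene") or None,
                        chrom=row.get("chrom") or None,
                        position=int(row["position"]) if row.get("position") else None,
                        strand=row.get("strand") or None,
                    )
                )
    return OmicsLayer(layer, values, features, scale)


def save_omics_layer(layer: OmicsLayer, path: str | Path, feature_path: str | Path | None = None) -> None:
    write_matrix(layer.values, path)
    if feature_path is not None:
        rows = [
            {
                "feature_id": f.feature_id,
                "gene": f.gene or "",
                "chrom": f.chrom or "",
                "position": "" if f.position is None else int(f.position),
                "strand": f.strand or "",
            }
            for f in layer.features
        ]
        pd.DataFrame(rows).to_csv(feature_path, sep="\t", index=False)


def load_covariates(path: str | Path) -> CovariateTable:
    df = _read_matrix(path)
    for col in ("age", "zbmi"):
        df[col] = df[col].astype(float)
    return CovariateTable(df)


def features_from_bed(path: str | Path, layer: str) -> list[OmicsFeature]:
    """Read BED-like (chrom, start, end, feature_id[, score, strand]) annotation.

    Coordinates are 0-based half-open.  Point features (CpGs) get
    position = start + 1; stranded features get a strand-aware TSS
    (start + 1 on '+', end on '-').
    """
    bed = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if bed.shape[1] < 4:
        raise ValueError("BED-like annotation needs >= 4 columns")
    out = []
    for _, row in bed.iterrows():
        chrom, start, end, fid = row[0], int(row[1]), int(row[2]), row[3]
        strand = row[5] if bed.shape[1] >= 6 and row[5] in ("+", "-") else None
        if strand == "-":
            pos = end  # 0-based half-open end == 1-based last base (TSS on '-')
        else:
            pos = start + 1
        out.append(OmicsFeature(fid, layer, chrom=chrom, position=pos, strand=strand))
    return out


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def align_samples(
    exposome: ExposomeTable,
    covariates: CovariateTable,
    layers: Iterable[OmicsLayer],
) -> dict[str, list[str]]:
    """Per-layer analysis sample lists: the intersection of exposome,
    covariate and layer samples, kept in exposome order.

    Layers may differ in coverage, so per-layer sample counts may differ;
    each association records the n actually used.
    """
    base = [s for s in exposome.samples if s in set(covariates.samples)]
    out: dict[str, list[str]] = {}
    for layer in layers:
        present = set(layer.samples)
        out[layer.layer] = [s for s in base if s in present]
    return out
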