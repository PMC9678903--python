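"""Synthetic mother-child cohort generator.

Emulates the statistical structure an exposome-omics association analysis
assumes: several recruitment cohorts; exposure families with
block-equicorrelated members; weakly correlated pregnancy/childhood copies
of the same exposure; omics layers with covariate signal, dense latent
factors (standing in jointly for batch effects and blood cell composition),
planted per-IQR linear effects; and an optional adiposity-confounding
scenario in which child adiposity (zBMI) drives both the blood level of a
lipophilic pollutant and an adipokine-like protein with no direct
pollutant-protein effect.

The generator makes no attempt to match any real cohort's exposure
distributions, detection limits or assay noise; it provides a fully seeded,
bit-reproducible test bed with known ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_data import (
    CovariateTable,
    ExposomeTable,
    ExposureVariable,
    GENOME_WIDE_LAYERS,
    OmicsFeature,
    OmicsLayer,
    iqr,
    save_exposome,
    save_omics_layer,
    write_matrix,
)

logger = logging.getLogger("exwas")

COHORT_NAMES = ("cohortA", "cohortB", "cohortC", "cohortD", "cohortE", "cohortF")


@dataclass
class FamilySpec:
    """One exposure family: ``n_exposures`` variables per period with
    within-family equicorrelation ``rho`` and ``n_categorical`` of them
    dichotomized by thresholding the latent Gaussian at its median."""

    family: str
    n_exposures: int
    rho: float = 0.3
    n_categorical: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"family {self.family}: rho must be in [0,1)")
        if self.n_categorical > self.n_exposures:
            raise ValueError(f"family {self.family}: n_categorical > n_exposures")


@dataclass
class LayerSpec:
    layer: str
    n_features: int
    scale: str = "log2"
    noise_sd: float = 0.5


@dataclass
class PlantedEffect:
    """A true linear exposure effect of ``beta_per_iqr`` per IQR increase.

    For the methylation layer the effect is added on the logit scale before
    squashing to (0,1); ``scale`` records this so tests can account for the
    (near-linear around a 0.5 baseline) mapping.
    """

    exposure: str
    period: str
    feature: str
    layer: str
    beta_per_iqr: float
    scale: str = "linear"


@dataclass
class ConfoundingSpec:
    """Adiposity scenario: zBMI -> pollutant and zBMI -> protein paths with a
    zero direct pollutant -> protein effect."""

    exposure: str = "pcb_lipo_sim"
    exposure_family: str = "organochlorines"
    feature: str = "protein_0000"
    zbmi_to_exposure: float = 0.6
    zbmi_to_feature: float = 0.6


@dataclass
class SimulationScenario:
    n_samples: int = 300
    n_cohorts: int = 6
    exposure_spec: list[FamilySpec] = field(default_factory=list)
    cross_period_correlation: float = 0.2
    omics_spec: list[LayerSpec] = field(default_factory=list)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    n_latent_factors: int = 0
    latent_loading_sd: float = 0.6
    latent_loading_density: float = 0.3
    confounding: ConfoundingSpec | None = None
    cohort_exposure_shift: float = 0.0
    cohort_effect_heterogeneity: float = 0.0
    n_shared_metabolites: int = 0
    shared_metabolite_loading: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cross_period_correlation < 1.0:
            raise ValueError("cross_period_correlation must be in [0,1)")
        if not 1 <= self.n_cohorts <= len(COHORT_NAMES):
            raise ValueError(f"n_cohorts must be in [1, {len(COHORT_NAMES)}]")
        layer_features = {
            (s.layer, f"{s.layer}_{i:04d}") for s in self.omics_spec for i in range(s.n_features)
        }
        for pe in self.planted_effects:
            if (pe.layer, pe.feature) not in layer_features:
                raise ValueError(f"planted effect targets unknown feature {pe.feature!r}")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    latent_factor_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    confounder_paths: list[tuple[str, str]] = field(default_factory=list)


def _rng_pair(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return np.random.default_rng(a), np.random.default_rng(b)


# ---------------------------------------------------------------------------
# exposome + covariates
# ---------------------------------------------------------------------------

def generate_cohort(scenario: SimulationScenario) -> tuple[ExposomeTable, CovariateTable, SyntheticTruth]:
    """Draw covariates and the two-period exposome for one synthetic cohort.

    Exposure families follow a block-equicorrelated Gaussian (correlation
    ``rho`` within a family, 0 across families); the childhood copy of each
    variable correlates with its pregnancy copy at the scenario's
    cross-period correlation.  Categorical exposures arise by thresholding
    the latent Gaussian at its median.  The returned truth records the
    confounder paths only; omics loadings are added by
    :func:`generate_multiomics`.
    """
    rng, _ = _rng_pair(scenario.seed)
    n = scenario.n_samples
    samples = [f"s{i:05d}" for i in range(n)]

    cohorts = np.array(COHORT_NAMES[: scenario.n_cohorts])
    cov = pd.DataFrame(
        {
            "cohort": cohorts[rng.integers(0, scenario.n_cohorts, n)],
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "age": rng.uniform(6.0, 11.0, n).round(2),
            "zbmi": rng.normal(0.0, 1.0, n),
            "ancestry": rng.choice(
                ["european", "pakistani", "other"], size=n, p=[0.90, 0.08, 0.02]
            ),
            "maternal_education": rng.choice(
                ["low", "medium", "high"], size=n, p=[0.25, 0.40, 0.35]
            ),
        },
        index=samples,
    )

    rho_p = scenario.cross_period_correlation
    columns: dict[str, np.ndarray | list[str]] = {}
    variables: list[ExposureVariable] = []

    def _family_block(spec: FamilySpec) -> np.ndarray:
        common = rng.normal(size=(n, 1))
        eps = rng.normal(size=(n, spec.n_exposures))
        return np.sqrt(spec.rho) * common + np.sqrt(1.0 - spec.rho) * eps

    for spec in scenario.exposure_spec:
        z_preg = _family_block(spec)
        z_indep = _family_block(spec)
        z_child = rho_p * z_preg + np.sqrt(1.0 - rho_p**2) * z_indep
        for period, z in (("pregnancy", z_preg), ("childhood", z_child)):
            if scenario.cohort_exposure_shift > 0.0:
                shifts = rng.normal(0.0, scenario.cohort_exposure_shift,
                                    (scenario.n_cohorts, spec.n_exposures))
                idx = np.searchsorted(cohorts, cov["cohort"].to_numpy())
                z = z + shifts[idx, :]
            for j in range(spec.n_exposures):
                name = f"{spec.family}_{j:02d}_{period[:4]}"
                categorical = j < spec.n_categorical
                if categorical:
                    levels = ("low", "high")
                    columns[name] = np.where(z[:, j] > np.median(z[:, j]), "high", "low").tolist()
                    variables.append(
                        ExposureVariable(name, period, spec.family, "categorical", levels)
                    )
                else:
                    columns[name] = z[:, j]
                    variables.append(ExposureVariable(name, period, spec.family))

    truth = SyntheticTruth()
    if scenario.confounding is not None:
        cf = scenario.confounding
        x = cf.zbmi_to_exposure * cov["zbmi"].to_numpy() + rng.normal(
            0.0, np.sqrt(max(1.0 - cf.zbmi_to_exposure**2, 0.05)), n
        )
        columns[cf.exposure] = x
        variables.append(ExposureVariable(cf.exposure, "childhood", cf.exposure_family))
        truth.confounder_paths += [("zbmi", cf.exposure), ("zbmi", cf.feature)]

    exposome = ExposomeTable(pd.DataFrame(columns, index=samples), variables)
    return exposome, CovariateTable(cov), truth


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------

def _intercepts(layer: str, scale: str, m: int, rng: np.random.Generator) -> np.ndarray:
    if scale == "beta_0_1":
        # logit-scale baseline near 0 => methylation baseline near 0.5
        return rng.normal(0.0, 0.4, m)
    if scale == "log2":
        return rng.normal(5.0, 1.0, m)
    return rng.normal(0.0, 1.0, m)


def generate_multiomics(
    scenario: SimulationScenario,
    exposome: ExposomeTable,
    covariates: CovariateTable,
    truth: SyntheticTruth | None = None,
) -> tuple[list[OmicsLayer], SyntheticTruth]:
    """Simulate every omics layer of the scenario on top of the cohort.

    Each feature is intercept + covariate signal + planted per-IQR exposure
    effects + latent-factor contribution (genome-wide layers) + Gaussian
    noise; the methylation layer is built on the logit scale and squashed
    through the inverse logit so values stay in (0,1).
    """
    _, rng = _rng_pair(scenario.seed)
    truth = truth or SyntheticTruth()
    n = scenario.n_samples
    samples = exposome.samples
    cov = covariates.values

    cohort_codes = pd.get_dummies(cov["cohort"], drop_first=True).to_numpy(float)
    sex = (cov["sex"] == "male").to_numpy(float)
    age = cov["age"].to_numpy(float)
    zbmi = cov["zbmi"].to_numpy(float)

    planted_by_layer: dict[str, list[PlantedEffect]] = {}
    for pe in scenario.planted_effects:
        planted_by_layer.setdefault(pe.layer, []).append(pe)

    het_factors: dict[tuple[str, str], np.ndarray] = {}
    cohort_names = sorted(cov["cohort"].unique())
    cohort_idx = cov["cohort"].map({c: i for i, c in enumerate(cohort_names)}).to_numpy()

    shared_latent = None
    if scenario.n_shared_metabolites > 0:
        shared_latent = rng.normal(size=(n, scenario.n_shared_metabolites))

    layers: list[OmicsLayer] = []
    for spec in scenario.omics_spec:
        m = spec.n_features
        feature_ids = [f"{spec.layer}_{i:04d}" for i in range(m)]
        y = np.tile(_intercepts(spec.layer, spec.scale, m, rng), (n, 1))

        # covariate signal (adjusted for in the association models)
        y += np.outer(age - age.mean(), rng.normal(0.0, 0.02, m))
        y += np.outer(sex - sex.mean(), rng.normal(0.0, 0.10, m))
        y += np.outer(zbmi, rng.normal(0.0, 0.05, m))
        if cohort_codes.shape[1]:
            y += cohort_codes @ rng.normal(0.0, 0.10, (cohort_codes.shape[1], m))

        if scenario.confounding is not None and scenario.confounding.feature in feature_ids:
            cf = scenario.confounding
            y[:, feature_ids.index(cf.feature)] += cf.zbmi_to_feature * zbmi

        if spec.layer in GENOME_WIDE_LAYERS and scenario.n_latent_factors > 0:
            k = scenario.n_latent_factors
            scores = rng.normal(size=(n, k))
            loadings = rng.normal(0.0, scenario.latent_loading_sd, (m, k))
            mask = rng.random((m, k)) < scenario.latent_loading_density
            loadings *= mask
            y += scores @ loadings.T
            truth.latent_factor_loadings[spec.layer] = loadings

        if shared_latent is not None and spec.layer in ("serum_metab", "urine_metab"):
            k = min(scenario.n_shared_metabolites, m)
            y[:, :k] += scenario.shared_metabolite_loading * shared_latent[:, :k]

        for pe in planted_by_layer.get(spec.layer, []):
            var = exposome.variable(pe.exposure)
            col = exposome.values[pe.exposure]
            if var.vartype == "continuous":
                x = col.to_numpy(float)
                x_iqr = iqr(x)
                if x_iqr == 0.0:
                    raise ValueError(f"planted exposure {pe.exposure} has zero IQR")
                dose = x / x_iqr
            else:
                dose = (col.to_numpy() != var.reference_level).astype(float)
            beta = np.full(n, pe.beta_per_iqr)
            if scenario.cohort_effect_heterogeneity > 0.0:
                key = (pe.exposure, pe.feature)
                if key not in het_factors:
                    het_factors[key] = 1.0 + rng.normal(
                        0.0, scenario.cohort_effect_heterogeneity, len(cohort_names)
                    )
                beta = beta * het_factors[key][cohort_idx]
            y[:, feature_ids.index(pe.feature)] += beta * dose
            truth.planted_effects.append(
                replace(pe, scale="logit" if spec.scale == "beta_0_1" else "linear")
            )

        y += rng.normal(0.0, spec.noise_sd, (n, m))
        if spec.scale == "beta_0_1":
            y = expit(y)

        features = _annotate_features(spec.layer, feature_ids, rng)
        layers.append(
            OmicsLayer(spec.layer, pd.DataFrame(y, index=samples, columns=feature_ids),
                       features, spec.scale)
        )
    return layers, truth


def _annotate_features(layer: str, feature_ids: list[str], rng: np.random.Generator) -> list[OmicsFeature]:
    """Methylation/expression features get random genomic coordinates and a
    gene label so cis-pairing and summaries are exercisable end to end."""
    features = []
    for i, fid in enumerate(feature_ids):
        if layer in ("methylation", "expression"):
            chrom = f"chr{1 + int(rng.integers(0, 22))}"
            pos = int(rng.integers(1, 50_000_000))
            strand = "+" if layer == "methylation" else ("+", "-")[int(rng.integers(0, 2))]
            features.append(
                OmicsFeature(fid, layer, gene=f"GENE_{layer[:4].upper()}_{i:04d}",
                             chrom=chrom, position=pos, strand=strand)
            )
        elif layer in ("mirna", "protein"):
            features.append(OmicsFeature(fid, layer, gene=f"GENE_{layer[:4].upper()}_{i:04d}"))
        else:
            features.append(OmicsFeature(fid, layer))
    return features


def generate_dataset(
    scenario: SimulationScenario,
) -> tuple[ExposomeTable, CovariateTable, list[OmicsLayer], SyntheticTruth]:
    """Convenience wrapper: cohort plus omics in one call."""
    exposome, covariates, truth = generate_cohort(scenario)
    layers, truth = generate_multiomics(scenario, exposome, covariates, truth)
    return exposome, covariates, layers, truth


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------

def mini_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """Small default scenario: 300 samples, 2 cohorts, 40 exposures over 7
    families (both periods), five layers of 500+100+50+30+50 features."""
    spec = dict(
        n_samples=300,
        n_cohorts=2,
        exposure_spec=[
            FamilySpec("metals", 5, rho=0.2),
            FamilySpec("organochlorines", 4, rho=0.6),
            FamilySpec("phthalates", 3, rho=0.4),
            FamilySpec("diet", 3, rho=0.2, n_categorical=1),
            FamilySpec("air_pollution", 2, rho=0.5),
            FamilySpec("meteorological", 2, rho=0.3),
            FamilySpec("tobacco", 1, rho=0.0, n_categorical=1),
        ],
        omics_spec=[
            LayerSpec("methylation", 500, scale="beta_0_1", noise_sd=0.5),
            LayerSpec("expression", 100, scale="log2", noise_sd=0.5),
            LayerSpec("serum_metab", 50, scale="log2", noise_sd=0.5),
            LayerSpec("protein", 30, scale="log2", noise_sd=0.5),
            LayerSpec("urine_metab", 50, scale="log2", noise_sd=0.5),
        ],
        seed=seed,
    )
    spec.update(overrides)
    return SimulationScenario(**spec)


# ---------------------------------------------------------------------------
# fixture output
# ---------------------------------------------------------------------------

def write_fixture_set(
    scenario: SimulationScenario,
    exposome: ExposomeTable,
    covariates: CovariateTable,
    layers: list[OmicsLayer],
    truth: SyntheticTruth,
    directory: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write all matrices, metadata and truth as tab-delimited text plus a
    manifest with the scenario hash and seed."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} exists and is non-empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    save_exposome(exposome, directory / "exposome.tsv", directory / "exposome_meta.tsv")
    write_matrix(covariates.values, directory / "covariates.tsv")
    for layer in layers:
        save_omics_layer(
            layer,
            directory / f"layer_{layer.layer}.tsv",
            directory / f"features_{layer.layer}.tsv",
        )
    pd.DataFrame(
        [
            {"exposure": pe.exposure, "period": pe.period, "feature": pe.feature,
             "layer": pe.layer, "beta": pe.beta_per_iqr, "scale": pe.scale}
            for pe in truth.planted_effects
        ],
        columns=["exposure", "period", "feature", "layer", "beta", "scale"],
    ).to_csv(directory / "truth.tsv", sep="\t", index=False)

    files = sorted(p.name for p in directory.iterdir() if p.name != "manifest.json")
    digests = {
        name: hashlib.sha256((directory / name).read_bytes()).hexdigest() for name in files
    }
    manifest = {"scenario_hash": scenario.hash(), "seed": scenario.seed, "files": digests}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote fixture set to %s (%d files)", directory, len(files) + 1)
    return directory
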