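"""Pipeline orchestration, catalogue export and plot-ready tables.

Stages run in method order — simulate/load, association scan, multiple-
testing correction, robustness, networks, cross-layer integration,
reports — each reading its inputs from and writing its outputs to one
run directory, so they can be driven individually from the command line
or end to end via :func:`run_pipeline`.  A manifest records the config
hash, input digests, stage timestamps and seeds; identical inputs
reproduce identical output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    GENOME_WIDE_LAYERS,
    CovariateTable,
    ExposomeTable,
    OmicsLayer,
    RunConfig,
    exposure_correlation,
    load_covariates,
    load_exposome,
    load_omics_layer,
)
from .exwas_engine import ModelSpec, run_exwas
from .multiple_testing import apply_correction, rules_table
from .robustness import (
    compare_models,
    fit_multi_exposure,
    meta_table,
    run_exwas_by_cohort,
    select_multi_exposure_sets,
)
from .association_network import (
    build_network,
    cluster_summary,
    detect_communities,
    export_network,
    network_statistics,
    summary_table,
)
from .cross_layer import (
    cross_matrix_replication,
    fit_eqtm,
    load_metabolite_map,
    pair_cis_eqtm,
)
from . import synthetic_cohort as sc

logger = logging.getLogger("exwas")

STAGES = ("simulate", "exwas", "correct", "robustness", "network", "crosslayer", "report")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class RunManifest:
    """Provenance for one run directory."""

    def __init__(self, outdir: Path, config: dict, seed: int | None):
        self.outdir = outdir
        self.data = {
            "version": __version__,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "seed": seed,
            "stages": {},
            "outputs": {},
        }

    def record_stage(self, name: str, outputs: list[Path]) -> None:
        self.data["stages"][name] = {"time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        for p in outputs:
            if p.exists():
                self.data["outputs"][str(p.relative_to(self.outdir))] = _digest(p)
        self.write()

    def write(self) -> None:
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# catalogue / external tables
# ---------------------------------------------------------------------------

def export_catalogue(flagged: pd.DataFrame, p_cutoff: float = 0.01) -> pd.DataFrame:
    """The web-catalogue view: all rows for targeted layers, genome-wide
    rows filtered to p < p_cutoff."""
    genome_wide = flagged["layer"].isin(GENOME_WIDE_LAYERS)
    return flagged[~genome_wide | (flagged["p"] < p_cutoff)].reset_index(drop=True)


def load_significant_associations(path: str | Path) -> pd.DataFrame:
    """Load an externally supplied significant-association table (the
    interchange schema: exposure, period, feature, layer, effect, p,
    optionally family/se/contrast)."""
    df = pd.read_csv(path, sep="\t")
    required = {"exposure", "period", "feature", "layer", "effect", "p"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return df


def summarize_catalogue(sig: pd.DataFrame, base_col: str | None = None) -> dict:
    """Headline counts of a significant-association table: totals by
    period, layer shares, per-exposure counts, and exposure-feature pairs
    significant in both periods (matched on ``base_col`` when the two
    periods use distinct variable names for the same exposure)."""
    out: dict = {"total": int(len(sig))}
    for period in ("pregnancy", "childhood"):
        sub = sig[sig["period"] == period]
        shares = (100.0 * sub["layer"].value_counts(normalize=True)).round(1).to_dict()
        out[period] = {
            "n_associations": int(len(sub)),
            "n_unique_exposures": int(sub["exposure"].nunique()),
            "n_unique_features": int(sub["feature"].nunique()),
            "layer_share_pct": shares,
            "per_exposure_counts": sub["exposure"].value_counts().to_dict(),
        }
    base = sig[base_col] if base_col else sig["exposure"]
    pairs = set(zip(base, sig["feature"], sig["period"]))
    preg = {(b, f) for b, f, p in pairs if p == "pregnancy"}
    child = {(b, f) for b, f, p in pairs if p == "childhood"}
    out["n_shared_pairs_across_periods"] = len(preg & child)
    return out


# ---------------------------------------------------------------------------
# plot-ready tables
# ---------------------------------------------------------------------------

def miami_table(records: pd.DataFrame, period: str, seed: int = 0) -> pd.DataFrame:
    """Signed -log10 p per record (sign of the effect), family grouping,
    layer colour key and a seeded jitter column for plotting."""
    sub = records[records["period"] == period].reset_index(drop=True)
    tiny = np.finfo(float).tiny
    p = sub["p"].to_numpy(float)
    n_under = int(np.sum(p <= 0))
    if n_under:
        logger.warning("miami: %d underflowed p-value(s) capped at %.3g", n_under, tiny)
    p = np.clip(p, tiny, 1.0)
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "exposure": sub["exposure"],
            "family": sub.get("family", ""),
            "feature": sub["feature"],
            "layer": sub["layer"],
            "signed_log10p": np.sign(sub["effect"].to_numpy()) * (-np.log10(p)),
            "jitter": rng.uniform(-0.3, 0.3, len(sub)),
        }
    )


def forest_table(meta_results: list) -> pd.DataFrame:
    """Per-cohort point estimates with 95% CIs and weights, plus pooled
    fixed- and random-effects rows (diamonds) with the I^2 annotation."""
    z = 1.959963984540054  # Phi^{-1}(0.975)
    rows = []
    for r in meta_results:
        key = dict(zip(("exposure", "period", "feature", "layer", "contrast"), r.key))
        for _, c in r.cohorts.iterrows():
            rows.append(
                {**key, "row_type": "cohort", "cohort": c["cohort"],
                 "estimate": c["estimate"],
                 "ci_low": c["estimate"] - z * c["se"],
                 "ci_high": c["estimate"] + z * c["se"],
                 "weight_pct": c["weight_pct"], "i2": np.nan}
            )
        for kind, b, s in (("fixed", r.beta_fixed, r.se_fixed),
                           ("random", r.beta_random, r.se_random)):
            rows.append(
                {**key, "row_type": kind, "cohort": "",
                 "estimate": b, "ci_low": b - z * s, "ci_high": b + z * s,
                 "weight_pct": 100.0, "i2": r.i2}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _scenario_from_config(config: dict, seed: int | None) -> sc.SimulationScenario:
    spec = dict(config.get("scenario") or {})
    spec.pop("preset", None)
    if seed is not None:
        spec["seed"] = seed
    for key, cls in (("exposure_spec", sc.FamilySpec), ("omics_spec", sc.LayerSpec),
                     ("planted_effects", sc.PlantedEffect)):
        if key in spec:
            spec[key] = [cls(**e) if isinstance(e, dict) else e for e in spec[key]]
    if isinstance(spec.get("confounding"), dict):
        spec["confounding"] = sc.ConfoundingSpec(**spec["confounding"])
    preset = (config.get("scenario") or {}).get("preset", "mini")
    if preset == "mini":
        return sc.mini_scenario(**spec)
    return sc.SimulationScenario(**spec)


def stage_simulate(config: dict, outdir: Path, seed: int | None) -> Path:
    scenario = _scenario_from_config(config, seed)
    exposome, covariates, layers, truth = sc.generate_dataset(scenario)
    fixtures = outdir / "fixtures"
    sc.write_fixture_set(scenario, exposome, covariates, layers, truth, fixtures,
                         overwrite=True)
    if scenario.n_shared_metabolites > 0:
        k = scenario.n_shared_metabolites
        pd.DataFrame(
            {"urine_feature": [f"urine_metab_{i:04d}" for i in range(k)],
             "serum_feature": [f"serum_metab_{i:04d}" for i in range(k)]}
        ).to_csv(fixtures / "metabolite_map.tsv", sep="\t", index=False)
    return fixtures


def load_inputs(config: dict, outdir: Path) -> tuple[ExposomeTable, CovariateTable, list[OmicsLayer]]:
    inputs = config.get("inputs")
    if inputs:
        root = Path(inputs.get("root", "."))
        for key in ("exposome", "exposome_meta", "covariates"):
            if not (root / inputs[key]).exists():
                raise FileNotFoundError(f"input file missing: {root / inputs[key]}")
        exposome = load_exposome(root / inputs["exposome"], root / inputs["exposome_meta"])
        covariates = load_covariates(root / inputs["covariates"])
        layers = []
        for ls in inputs["layers"]:
            path = root / ls["path"]
            if not path.exists():
                raise FileNotFoundError(f"layer file missing: {path}")
            feats = root / ls["features"] if ls.get("features") else None
            layers.append(load_omics_layer(path, ls["layer"], ls.get("scale", "log2"), feats))
        return exposome, covariates, layers
    fixtures = outdir / "fixtures"
    if not fixtures.exists():
        raise FileNotFoundError(f"{fixtures} not found; run the simulate stage first")
    exposome = load_exposome(fixtures / "exposome.tsv", fixtures / "exposome_meta.tsv")
    covariates = load_covariates(fixtures / "covariates.tsv")
    layers = []
    for path in sorted(fixtures.glob("layer_*.tsv")):
        name = path.stem.removeprefix("layer_")
        scale = "beta_0_1" if name == "methylation" else "log2"
        layers.append(load_omics_layer(path, name, scale, fixtures / f"features_{name}.tsv"))
    return exposome, covariates, layers


def _model_spec(config: dict, **overrides) -> ModelSpec:
    spec = dict(config.get("model") or {})
    spec.update(overrides)
    return ModelSpec(**spec)


def stage_exwas(config: dict, outdir: Path) -> Path:
    exposome, covariates, layers = load_inputs(config, outdir)
    records = run_exwas(exposome, layers, covariates, _model_spec(config))
    out = outdir / "associations.tsv"
    records.to_csv(out, sep="\t", index=False, float_format="%.17g")
    return out

def stage_correct(config: dict, outdir: Path) -> Path:
    run_cfg = _run_config(config)
    _, _, layers = load_inputs(config, outdir)
    records = pd.read_csv(outdir / "associations.tsv", sep="\t").fillna({"contrast": ""})
    flagged, rules = apply_correction(
        records, layers, run_cfg.alpha, run_cfg.global_cutoff
    )
    flagged.to_csv(outdir / "associations_flagged.tsv", sep="\t", index=False,
                   float_format="%.17g")
    rules_table(rules).to_csv(outdir / "correction_rules.tsv", sep="\t", index=False)
    return outdir / "associations_flagged.tsv"


def _run_config(config: dict) -> RunConfig:
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    return RunConfig(**{k: v for k, v in config.items() if k in fields})


def _read_flagged(outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(outdir / "associations_flagged.tsv", sep="\t")
    df["contrast"] = df["contrast"].fillna("").astype(str)
    return df


def stage_robustness(config: dict, outdir: Path, max_meta: int = 40) -> list[Path]:
    run_cfg = _run_config(config)
    exposome, covariates, layers = load_inputs(config, outdir)
    layer_map = {l.layer: l for l in layers}
    flagged = _read_flagged(outdir)
    sig = flagged[flagged["significant"]]
    outputs = []

    # zBMI-unadjusted comparison over the significant associations
    alt = run_exwas(exposome, layers, covariates,
                    _model_spec(config, adjust_zbmi=False, model_tag="no_zbmi"))
    keys = ["exposure", "period", "feature", "layer", "contrast"]
    alt_sig = alt.merge(sig[keys], on=keys)
    changes = compare_models(sig, alt_sig)
    changes.to_csv(outdir / "effect_change_zbmi.tsv", sep="\t", index=False,
                   float_format="%.17g")
    outputs.append(outdir / "effect_change_zbmi.tsv")

    # per-cohort meta-analysis for the top associations
    top = sig.sort_values(["p", "exposure", "feature"]).head(max_meta)
    if len(top) and covariates.values["cohort"].nunique() > 1:
        meta = run_exwas_by_cohort(top, exposome, layer_map, covariates,
                                   _model_spec(config))
        mt = meta_table(meta)
        mt.to_csv(outdir / "meta_analysis.tsv", sep="\t", index=False,
                  float_format="%.17g")
        forest_table(meta).to_csv(outdir / "forest.tsv", sep="\t", index=False,
                                  float_format="%.17g")
        outputs += [outdir / "meta_analysis.tsv", outdir / "forest.tsv"]

    # multi-exposure mutually adjusted models
    corr = exposure_correlation(exposome)
    msets = select_multi_exposure_sets(sig, corr, exposome, run_cfg)
    rows = []
    for mset in msets:
        fit_multi_exposure(mset, exposome, layer_map[mset.layer], covariates, sig,
                           _model_spec(config, n_surrogate_variables=0))
        if mset.joint is not None:
            for _, r in mset.joint.iterrows():
                rows.append({"feature": mset.feature, "period": mset.period,
                             "layer": mset.layer, **r.to_dict()})
    pd.DataFrame(rows).to_csv(outdir / "multi_exposure.tsv", sep="\t", index=False,
                              float_format="%.17g")
    outputs.append(outdir / "multi_exposure.tsv")
    return outputs


def stage_network(config: dict, outdir: Path) -> list[Path]:
    run_cfg = _run_config(config)
    flagged = _read_flagged(outdir)
    sig = flagged[flagged["significant"]]
    outputs = []
    stats_rows = []
    for period in ("pregnancy", "childhood"):
        if not (sig["period"] == period).any():
            continue
        net = build_network(sig, period)
        stats = network_statistics(net, run_cfg.path_length_convention,
                                   run_cfg.network_stats_on_display_subset)
        net = detect_communities(net)
        export_network(net, outdir, f"network_{period}")
        summaries = cluster_summary(net)
        summary_table(summaries).to_csv(outdir / f"clusters_{period}.tsv", sep="\t",
                                        index=False)
        stats_rows.append(
            {"period": period, "n_nodes": stats.n_nodes, "n_edges": stats.n_edges,
             "mean_degree": stats.mean_degree,
             "avg_shortest_path": stats.avg_shortest_path,
             "largest_component_pct": stats.largest_component_fraction,
             "n_components": len(stats.component_sizes),
             "modularity": net.modularity}
        )
        outputs += [outdir / f"network_{period}_nodes.tsv",
                    outdir / f"network_{period}_edges.tsv",
                    outdir / f"clusters_{period}.tsv"]
    pd.DataFrame(stats_rows).to_csv(outdir / "network_stats.tsv", sep="\t", index=False,
                                    float_format="%.17g")
    outputs.append(outdir / "network_stats.tsv")
    return outputs


def stage_crosslayer(config: dict, outdir: Path) -> list[Path]:
    run_cfg = _run_config(config)
    _, covariates, layers = load_inputs(config, outdir)
    layer_map = {l.layer: l for l in layers}
    flagged = _read_flagged(outdir)
    outputs = []
    if "methylation" in layer_map and "expression" in layer_map:
        pairs = pair_cis_eqtm(layer_map["methylation"].features,
                              layer_map["expression"].features, run_cfg.cis_window)
        eqtm = fit_eqtm(pairs, layer_map["methylation"], layer_map["expression"],
                        covariates, run_cfg.alpha)
        eqtm.to_csv(outdir / "eqtm.tsv", sep="\t", index=False, float_format="%.17g")
        outputs.append(outdir / "eqtm.tsv")
    map_path = outdir / "fixtures" / "metabolite_map.tsv"
    if map_path.exists() and {"urine_metab", "serum_metab"} <= set(layer_map):
        mmap = load_metabolite_map(map_path)
        sig = flagged[flagged["significant"]]
        rows = []
        for a, b, label in (("urine_metab", "serum_metab", "urine_to_serum"),
                            ("serum_metab", "urine_metab", "serum_to_urine")):
            use_map = mmap if a == "urine_metab" else {v: k for k, v in mmap.items()}
            frac, table = cross_matrix_replication(
                sig[sig["layer"] == a], flagged[flagged["layer"] == b], use_map,
                run_cfg.alpha, run_cfg.replication_requires_sign,
            )
            rows.append({"direction": label, "replication_pct": frac,
                         "n_discovery": len(table)})
        pd.DataFrame(rows).to_csv(outdir / "replication.tsv", sep="\t", index=False,
                                  float_format="%.17g")
        outputs.append(outdir / "replication.tsv")
    return outputs


def stage_report(config: dict, outdir: Path, seed: int | None) -> list[Path]:
    run_cfg = _run_config(config)
    flagged = _read_flagged(outdir)
    outputs = []
    cat = export_catalogue(flagged, run_cfg.catalogue_p_cutoff)
    cat.to_csv(outdir / "catalogue.tsv", sep="\t", index=False, float_format="%.17g")
    outputs.append(outdir / "catalogue.tsv")
    for period in ("pregnancy", "childhood"):
        mt = miami_table(flagged, period, seed or 0)
        mt.to_csv(outdir / f"miami_{period}.tsv", sep="\t", index=False,
                  float_format="%.17g")
        outputs.append(outdir / f"miami_{period}.tsv")
    sig = flagged[flagged["significant"]]
    (outdir / "summary.json").write_text(
        json.dumps(summarize_catalogue(sig), indent=2, sort_keys=True, default=str)
    )
    outputs.append(outdir / "summary.json")
    return outputs


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> Path:
    """Execute every stage in order; halt on the first failing stage with
    its name, keeping partial outputs."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(outdir, config, seed)
    try:
        stage = "simulate"
        if config.get("inputs") is None:
            fixtures = stage_simulate(config, outdir, seed)
            manifest.record_stage(stage, sorted(fixtures.iterdir()))
        stage = "exwas"
        manifest.record_stage(stage, [stage_exwas(config, outdir)])
        stage = "correct"
        manifest.record_stage(stage, [stage_correct(config, outdir)])
        stage = "robustness"
        manifest.record_stage(stage, stage_robustness(config, outdir))
        stage = "network"
        manifest.record_stage(stage, stage_network(config, outdir))
        stage = "crosslayer"
        manifest.record_stage(stage, stage_crosslayer(config, outdir))
        stage = "report"
        manifest.record_stage(stage, stage_report(config, outdir, seed))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    logger.info("pipeline complete: %s", outdir)
    return outdir
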