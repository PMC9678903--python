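"""Cross-layer and cross-matrix integration of association results.

Three analyses connect the molecular layers:

* cis-eQTM identification — each transcript cluster is paired with every
  CpG closer than the cis window (default 500 kb, strict) to its
  strand-aware transcription start site, and expression is regressed on
  methylation adjusted for age, sex and cohort, with BH-FDR across pairs;
* miRNA-target concordance — a significant exposure-miRNA association is
  corroborated when an experimentally validated target gene is nominally
  associated with the same exposure in the opposite direction (higher
  miRNA, lower target expression);
* cross-matrix replication — exposure-metabolite associations discovered
  in one biofluid replicate when the matched metabolite in the other fluid
  shows a nominally significant association with the same sign (direction-
  asymmetric: urine-to-serum and serum-to-urine have different
  denominators).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import CovariateTable, OmicsFeature, OmicsLayer
from .exwas_engine import build_design, ols_multi, _t_pvalues
from .multiple_testing import bh_fdr

logger = logging.getLogger("exwas")


@dataclass
class EqtmPair:
    cpg_id: str
    tc_id: str
    distance: int
    estimate: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    significant: bool = False


def _tss(feature: OmicsFeature) -> int | None:
    return feature.position


def pair_cis_eqtm(
    methylation_features: list[OmicsFeature],
    expression_features: list[OmicsFeature],
    window: int = 500_000,
) -> pd.DataFrame:
    """All same-chromosome CpG-transcript pairs with |CpG - TSS| < window.

    The bound is strict ("closer than").  Features lacking coordinates are
    skipped with a logged count.  TSS positions are expected to be already
    strand-resolved (see features_from_bed).
    """
    cpgs = [f for f in methylation_features if f.chrom and f.position]
    tcs = [f for f in expression_features if f.chrom and f.position]
    skipped = (len(methylation_features) - len(cpgs)) + (len(expression_features) - len(tcs))
    if skipped:
        logger.warning("cis pairing: skipped %d feature(s) without coordinates", skipped)
    by_chrom: dict[str, list[OmicsFeature]] = {}
    for f in cpgs:
        by_chrom.setdefault(f.chrom, []).append(f)
    rows = []
    for tc in tcs:
        tss = _tss(tc)
        for cpg in by_chrom.get(tc.chrom, []):
            dist = abs(cpg.position - tss)
            if dist < window:
                rows.append(
                    {"cpg": cpg.feature_id, "tc": tc.feature_id,
                     "chrom": tc.chrom, "distance": int(dist)}
                )
    return pd.DataFrame(rows, columns=["cpg", "tc", "chrom", "distance"])


def fit_eqtm(
    pairs: pd.DataFrame,
    methylation: OmicsLayer,
    expression: OmicsLayer,
    covariates: CovariateTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """OLS per CpG-transcript pair: expression ~ methylation + age + sex +
    cohort; BH-FDR across all pairs for the significance flag."""
    samples = [
        s for s in expression.samples
        if s in set(methylation.samples) and s in set(covariates.samples)
    ]
    base = build_design(covariates.subset(samples), ("age", "sex", "cohort"))
    Xbase = base.to_numpy(float)
    rows = []
    for _, pr in pairs.iterrows():
        m = methylation.values.loc[samples, pr["cpg"]].to_numpy(float)
        if np.std(m) == 0.0:
            logger.warning("eQTM: CpG %s has zero variance; pair dropped", pr["cpg"])
            continue
        y = expression.values.loc[samples, pr["tc"]].to_numpy(float)
        X = np.hstack([m[:, None], Xbase])
        B, se, df = ols_multi(X, y)
        p = _t_pvalues(B, se, df)
        rows.append(
            {"cpg": pr["cpg"], "tc": pr["tc"], "distance": pr["distance"],
             "estimate": float(B[0, 0]), "se": float(se[0, 0]), "p": float(p[0, 0])}
        )
    out = pd.DataFrame(rows, columns=["cpg", "tc", "distance", "estimate", "se", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] <= alpha
    else:
        out["q"] = []
        out["significant"] = []
    return out


# ---------------------------------------------------------------------------
# miRNA target concordance
# ---------------------------------------------------------------------------

def load_target_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column tab-delimited miRNA -> target gene table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        out.setdefault(r.iloc[0], set()).add(r.iloc[1])
    return out


def mirna_target_concordance(
    mirna_hits: pd.DataFrame,
    tc_records: pd.DataFrame,
    target_map: dict[str, set[str]],
    alpha_nominal: float = 0.05,
) -> pd.DataFrame:
    """Concordant (exposure, miRNA, gene) triples.

    A triple is retained when a target gene's transcript is nominally
    associated (p < alpha) with the same exposure and period as the miRNA
    and its effect sign is opposite to the miRNA's.  miRNAs absent from the
    target map contribute nothing (logged).
    """
    if "gene" not in tc_records.columns:
        raise ValueError("transcript records need a 'gene' column")
    tc = tc_records[tc_records["gene"].notna() & (tc_records["gene"] != "")]
    rows = []
    for _, hit in mirna_hits.iterrows():
        targets = target_map.get(hit["feature"])
        if not targets:
            logger.info("miRNA %s absent from target map", hit["feature"])
            continue
        cand = tc[
            (tc["exposure"] == hit["exposure"])
            & (tc["period"] == hit["period"])
            & tc["gene"].isin(targets)
        ]
        for _, t in cand.iterrows():
            if t["p"] < alpha_nominal and np.sign(t["effect"]) == -np.sign(hit["effect"]):
                rows.append(
                    {"exposure": hit["exposure"], "period": hit["period"],
                     "mirna": hit["feature"], "gene": t["gene"], "tc": t["feature"],
                     "mirna_effect": hit["effect"], "tc_effect": t["effect"],
                     "tc_p": t["p"]}
                )
    return pd.DataFrame(
        rows,
        columns=["exposure", "period", "mirna", "gene", "tc",
                 "mirna_effect", "tc_effect", "tc_p"],
    )


# ---------------------------------------------------------------------------
# cross-matrix replication
# ---------------------------------------------------------------------------

def load_metabolite_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def cross_matrix_replication(
    discovery: pd.DataFrame,
    lookup: pd.DataFrame,
    metabolite_map: dict[str, str],
    alpha_nominal: float = 0.05,
    require_sign: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Fraction (percent) of discovery associations replicating in the
    other biological matrix.

    A discovery association (significant in matrix A) replicates when the
    mapped feature's record for the same exposure and period in matrix B
    has p < alpha (and, by default, the same effect sign).  Discovery
    features without a mapping are excluded from the denominator (logged).
    An empty denominator yields NaN, not 0.
    """
    li = lookup.set_index(["exposure", "period", "feature"]).sort_index()
    rows = []
    n_unmapped = 0
    for _, d in discovery.iterrows():
        mapped = metabolite_map.get(d["feature"])
        if mapped is None:
            n_unmapped += 1
            continue
        try:
            other = li.loc[(d["exposure"], d["period"], mapped)]
        except KeyError:
            n_unmapped += 1
            continue
        if isinstance(other, pd.DataFrame):
            other = other.sort_values("p").iloc[0]
        ok = other["p"] < alpha_nominal
        if require_sign:
            ok = ok and np.sign(other["effect"]) == np.sign(d["effect"])
        rows.append(
            {"exposure": d["exposure"], "period": d["period"],
             "feature": d["feature"], "mapped_feature": mapped,
             "discovery_effect": d["effect"], "lookup_effect": other["effect"],
             "lookup_p": other["p"], "replicated": bool(ok)}
        )
    if n_unmapped:
        logger.info("replication: %d discovery record(s) without a mapped feature", n_unmapped)
    table = pd.DataFrame(
        rows,
        columns=["exposure", "period", "feature", "mapped_feature",
                 "discovery_effect", "lookup_effect", "lookup_p", "replicated"],
    )
    if table.empty:
        return float("nan"), table
    frac = 100.0 * table["replicated"].mean()
    return float(frac), table
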