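"""Layered multiple-testing correction for the association table.

Correction is applied independently for each exposure within each omics
layer.  Genome-wide layers (methylation, expression, miRNA) use
Benjamini-Hochberg FDR at level alpha.  Targeted layers (proteins, serum
and urinary metabolites) use a correlation-aware Bonferroni rule: the
nominal level divided by the effective number of tests (ENT), an
eigenvalue-based estimate of the number of independent features in the
panel.  On top of both, a stringent global cutoff (default 1e-09,
correcting for every test of the whole run) flags the strongest
associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_data import GENOME_WIDE_LAYERS, OmicsLayer

logger = logging.getLogger("exwas")


@dataclass
class CorrectionRule:
    """The significance rule applied to one layer."""

    layer: str
    method: str  # 'bh_fdr' | 'ent_bonferroni'
    alpha: float
    ent: float | None = None
    threshold: float | None = None  # per-test p cutoff (ent_bonferroni) or FDR level


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def effective_number_of_tests(values: pd.DataFrame | np.ndarray) -> float:
    """Eigenvalue-based effective number of tests (Li-Ji-type estimator).

    With eigenvalues lambda_i of the feature-feature Pearson correlation
    matrix, ENT = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].
    Fully correlated panels give 1, independent panels give the number of
    features.  Constant features are excluded with a warning.  Eigenvalues
    are rounded to 8 decimals first so exactly duplicated features are not
    inflated by floating-point noise in the integer/fraction split.
    """
    arr = values.to_numpy(float) if isinstance(values, pd.DataFrame) else np.asarray(values, float)
    if arr.ndim != 2 or arr.shape[1] < 2 or arr.shape[0] < 3:
        raise ValueError("need a sample x feature matrix with >=2 features, >=3 samples")
    sd = arr.std(axis=0)
    if np.any(sd == 0):
        logger.warning("ENT: excluding %d constant feature(s)", int(np.sum(sd == 0)))
        arr = arr[:, sd > 0]
        if arr.shape[1] < 2:
            return 1.0
    corr = np.corrcoef(arr, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(np.round(lam, 8), 0.0, None)
    ent = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return float(min(max(ent, 1.0), arr.shape[1]))


def layer_correction_rules(
    layers: Sequence[OmicsLayer], alpha: float = 0.05
) -> dict[str, CorrectionRule]:
    """One rule per layer; ENT is computed once per targeted layer on its
    analysis samples (a per-layer constant, not per exposure stratum)."""
    rules: dict[str, CorrectionRule] = {}
    for layer in layers:
        if layer.layer in GENOME_WIDE_LAYERS:
            rules[layer.layer] = CorrectionRule(layer.layer, "bh_fdr", alpha, None, alpha)
        else:
            ent = effective_number_of_tests(layer.values)
            rules[layer.layer] = CorrectionRule(
                layer.layer, "ent_bonferroni", alpha, ent, alpha / ent
            )
    return rules


def apply_correction(
    records: pd.DataFrame,
    layers: Sequence[OmicsLayer] | None = None,
    alpha: float = 0.05,
    global_cutoff: float = 1e-9,
    rules: dict[str, CorrectionRule] | None = None,
) -> tuple[pd.DataFrame, dict[str, CorrectionRule]]:
    """Flag significant records per (exposure, period, layer) stratum.

    Adds columns ``q`` (BH-adjusted p within the stratum; NaN for targeted
    layers), ``significant`` and ``passes_global``.  Flags depend only on
    stratum membership, never on record order.
    """
    if records.empty:
        raise ValueError("no records to correct")
    if rules is None:
        if layers is None:
            raise ValueError("provide either layers or precomputed rules")
        rules = layer_correction_rules(layers, alpha)
    out = records.copy()
    out["q"] = np.nan
    out["significant"] = False
    for (exposure, period, layer_name), idx in out.groupby(
        ["exposure", "period", "layer"], sort=False
    ).groups.items():
        rule = rules.get(layer_name)
        if rule is None:
            logger.warning("no correction rule for layer %r; stratum skipped", layer_name)
            continue
        pvals = out.loc[idx, "p"].to_numpy()
        if rule.method == "bh_fdr":
            q = bh_fdr(pvals)
            out.loc[idx, "q"] = q
            out.loc[idx, "significant"] = q <= rule.alpha
        else:
            out.loc[idx, "significant"] = pvals < rule.threshold
    out["passes_global"] = out["p"] < global_cutoff
    out["significant"] = out["significant"] | out["passes_global"]
    n_sig = int(out["significant"].sum())
    logger.info(
        "correction: %d/%d records significant (%d pass global %.1e)",
        n_sig, len(out), int(out["passes_global"].sum()), global_cutoff,
    )
    return out, rules


def rules_table(rules: dict[str, CorrectionRule]) -> pd.DataFrame:
    """Small per-layer summary (layer, method, ENT, threshold)."""
    return pd.DataFrame(
        [
            {
                "layer": r.layer,
                "method": r.method,
                "ent": np.nan if r.ent is None else r.ent,
                "threshold": r.threshold,
            }
            for r in rules.values()
        ]
    )
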