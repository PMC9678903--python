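"""Sensitivity suite: percent effect change, meta-analysis closed forms,
multi-exposure selection and mutually adjusted fits."""

import numpy as np
import pandas as pd
import pytest

from exwas import (
    CorrelationMatrix,
    ExposomeTable,
    ExposureVariable,
    FamilySpec,
    LayerSpec,
    ModelSpec,
    MultiExposureSet,
    PlantedEffect,
    RunConfig,
    SimulationScenario,
    cohort_meta_analysis,
    exposure_correlation,
    fit_multi_exposure,
    generate_dataset,
    percent_effect_change,
    run_exwas,
    run_exwas_by_cohort,
    select_multi_exposure_sets,
)


class TestPercentEffectChange:
    def test_doubling_flagged(self):
        ec = percent_effect_change(0.5, 1.2)
        assert ec.percent_change == pytest.approx(-140.0)
        assert ec.flagged

    def test_identity_not_flagged(self):
        ec = percent_effect_change(0.5, 0.5)
        assert ec.percent_change == 0.0
        assert not ec.flagged

    def test_partial_attenuation_not_flagged(self):
        ec = percent_effect_change(0.4, 0.1)
        assert ec.percent_change == pytest.approx(75.0)
        assert not ec.flagged

    def test_zero_main_effect_undefined(self):
        ec = percent_effect_change(0.0, 0.3)
        assert np.isnan(ec.percent_change)
        assert not ec.flagged


def _cohorts(rows):
    return pd.DataFrame(rows, columns=["cohort", "estimate", "se", "n"])


class TestMetaAnalysis:
    def test_two_identical_cohorts(self):
        meta = cohort_meta_analysis(
            _cohorts([("a", 0.3, 0.1, 100), ("b", 0.3, 0.1, 100)])
        )
        assert meta.beta_fixed == pytest.approx(0.3)
        assert meta.se_fixed == pytest.approx(0.1 / np.sqrt(2))
        assert meta.q == pytest.approx(0.0)
        assert meta.tau2 == 0.0
        assert meta.i2 == 0.0
        assert meta.beta_random == pytest.approx(meta.beta_fixed)
        assert meta.se_random == pytest.approx(meta.se_fixed)

    def test_opposed_effects_heterogeneity(self):
        meta = cohort_meta_analysis(
            _cohorts([("a", 0.5, 0.1, 100), ("b", -0.5, 0.1, 100)])
        )
        assert meta.beta_fixed == pytest.approx(0.0)
        assert meta.q == pytest.approx(50.0)
        assert meta.i2 == pytest.approx(98.0)

    def test_identical_estimates_any_ses(self):
        meta = cohort_meta_analysis(
            _cohorts([("a", 0.2, 0.05, 50), ("b", 0.2, 0.2, 60), ("c", 0.2, 0.11, 70)])
        )
        assert meta.i2 == 0.0
        assert meta.beta_random == pytest.approx(meta.beta_fixed)

    def test_fixed_beta_invariant_to_cohort_order(self):
        rows = [("a", 0.4, 0.1, 50), ("b", -0.1, 0.25, 60), ("c", 0.2, 0.07, 70)]
        m1 = cohort_meta_analysis(_cohorts(rows))
        m2 = cohort_meta_analysis(_cohorts(rows[::-1]))
        assert m1.beta_fixed == pytest.approx(m2.beta_fixed)
        assert m1.tau2 == pytest.approx(m2.tau2)
        assert m1.se_fixed <= min(r[2] for r in rows)

    def test_single_cohort_sentinel(self):
        meta = cohort_meta_analysis(_cohorts([("a", 0.3, 0.1, 100)]))
        assert meta.beta_fixed == meta.beta_random == pytest.approx(0.3)
        assert np.isnan(meta.i2)

    def test_nonpositive_se_names_cohort(self):
        with pytest.raises(ValueError, match="b"):
            cohort_meta_analysis(_cohorts([("a", 0.3, 0.1, 10), ("b", 0.1, 0.0, 10)]))

    def test_homogeneous_fixture_low_i2_heterogeneous_high(self):
        """Cohort-homogeneous planted effects give low I2; switching on the
        cohort-heterogeneity scenario raises it (directional)."""
        def median_i2(het):
            scen = SimulationScenario(
                n_samples=900, n_cohorts=3,
                exposure_spec=[FamilySpec("metals", 3, rho=0.2)],
                omics_spec=[LayerSpec("protein", 10, noise_sd=0.5)],
                planted_effects=[
                    PlantedEffect(f"metals_{j:02d}_chil", "childhood",
                                  f"protein_{j:04d}", "protein", 0.6)
                    for j in range(3)
                ],
                cohort_effect_heterogeneity=het, seed=42,
            )
            exposome, covariates, layers, _ = generate_dataset(scen)
            spec = ModelSpec(n_surrogate_variables=0)
            assoc = run_exwas(exposome, layers, covariates, spec)
            planted = assoc[
                assoc["exposure"].str.endswith("_chil")
                & (assoc["feature"].str[-1] == assoc["exposure"].str[7])
            ]
            metas = run_exwas_by_cohort(
                planted, exposome, {l.layer: l for l in layers}, covariates, spec
            )
            return float(np.median([m.i2 for m in metas]))

        assert median_i2(0.0) < median_i2(1.5)


def _toy_selection_inputs():
    """Three continuous exposures with a hand-built correlation matrix."""
    idx = [f"s{i}" for i in range(8)]
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        {n: rng.normal(size=8) for n in ("hg", "fish_intake", "pcb153", "pcb180", "c")},
        index=idx,
    )
    variables = [
        ExposureVariable("hg", "childhood", "metals"),
        ExposureVariable("fish_intake", "childhood", "diet"),
        ExposureVariable("pcb153", "childhood", "organochlorines"),
        ExposureVariable("pcb180", "childhood", "organochlorines"),
        ExposureVariable("c", "childhood", "meteorological"),
    ]
    table = ExposomeTable(values, variables)
    labels = list(values.columns)
    mat = np.eye(5)
    methods = np.full((5, 5), "pearson", dtype=object)

    def set_corr(a, b, v):
        i, j = labels.index(a), labels.index(b)
        mat[i, j] = mat[j, i] = v

    set_corr("hg", "fish_intake", 0.5)
    set_corr("pcb153", "pcb180", 0.9)
    corr = CorrelationMatrix(labels, mat, methods)
    return table, corr


def _sig(rows):
    df = pd.DataFrame(
        rows, columns=["exposure", "period", "feature", "layer", "p"]
    )
    df["contrast"] = ""
    df["effect"] = 0.5
    return df


class TestSelectMultiExposure:
    def test_uncorrelated_different_groups_both_survive(self):
        table, corr = _toy_selection_inputs()
        sig = _sig([
            ("hg", "childhood", "f1", "protein", 1e-4),
            ("fish_intake", "childhood", "f1", "protein", 1e-3),
        ])
        [mset] = select_multi_exposure_sets(sig, corr, table)
        assert sorted(mset.exposures) == ["fish_intake", "hg"]

    def test_same_group_collapses_to_one_and_feature_dropped(self):
        table, corr = _toy_selection_inputs()
        sig = _sig([
            ("pcb153", "childhood", "f1", "protein", 1e-4),
            ("pcb180", "childhood", "f1", "protein", 1e-3),
        ])
        sets = select_multi_exposure_sets(sig, corr, table)
        assert sets == []  # one survivor per group -> fewer than 2 exposures

    def test_greedy_high_correlation_pruning(self):
        table, corr = _toy_selection_inputs()
        # A=pcb153, B=pcb180 correlated 0.9 but B in another group here: rebuild
        table2, corr2 = _toy_selection_inputs()
        # use hg (metals), pcb153 (organochlorines), c (meteorological)
        # with corr(hg, pcb153) = 0.9 so the weaker of the pair drops
        i, j = corr2.labels.index("hg"), corr2.labels.index("pcb153")
        corr2.values[i, j] = corr2.values[j, i] = 0.9
        sig = _sig([
            ("hg", "childhood", "f1", "protein", 1e-5),
            ("pcb153", "childhood", "f1", "protein", 1e-3),
            ("c", "childhood", "f1", "protein", 1e-2),
        ])
        [mset] = select_multi_exposure_sets(sig, corr2, table2)
        assert mset.exposures == ["hg", "c"]
        assert any(e["dropped"] == "pcb153" for e in mset.exclusion_log)

    def test_missing_exposure_in_corr_rejected(self):
        table, corr = _toy_selection_inputs()
        sig = _sig([
            ("unknown", "childhood", "f1", "protein", 1e-4),
            ("hg", "childhood", "f1", "protein", 1e-3),
        ])
        table.variables.append(ExposureVariable("unknown", "childhood", "noise"))
        with pytest.raises(ValueError, match="unknown"):
            select_multi_exposure_sets(sig, corr, table)


class TestFitMultiExposure:
    @staticmethod
    def _planted_pair(confounded: bool, seed=77):
        """Two exposures and one feature; optionally B is a 0.9-correlated
        proxy of the true cause A with no direct effect of its own."""
        rng = np.random.default_rng(seed)
        n = 800
        idx = [f"s{i}" for i in range(n)]
        a = rng.normal(size=n)
        if confounded:
            b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        else:
            b = rng.normal(size=n)
        y = 0.5 * a + (0.0 if confounded else 0.4) * b + rng.normal(0, 0.5, n)
        values = pd.DataFrame({"expo_a": a, "expo_b": b}, index=idx)
        variables = [
            ExposureVariable("expo_a", "childhood", "metals"),
            ExposureVariable("expo_b", "childhood", "organochlorines"),
        ]
        exposome = ExposomeTable(values, variables)
        from exwas import CovariateTable, OmicsLayer

        covariates = CovariateTable(
            pd.DataFrame(
                {"cohort": rng.choice(["a", "b"], n),
                 "sex": rng.choice(["female", "male"], n),
                 "age": rng.uniform(6, 11, n), "zbmi": rng.normal(size=n),
                 "ancestry": ["european"] * n, "maternal_education": ["low"] * n},
                index=idx,
            )
        )
        layer = OmicsLayer("protein", pd.DataFrame({"prot": y}, index=idx))
        return exposome, covariates, layer

    def _fit(self, exposome, covariates, layer):
        spec = ModelSpec(n_surrogate_variables=0)
        single = run_exwas(exposome, [layer], covariates, spec)
        mset = MultiExposureSet("prot", "childhood", "protein",
                                ["expo_a", "expo_b"])
        return single, fit_multi_exposure(mset, exposome, layer, covariates,
                                          single, spec)

    def test_orthogonal_exposures_match_single_fits(self):
        exposome, covariates, layer = self._planted_pair(confounded=False)
        single, mset = self._fit(exposome, covariates, layer)
        joint = mset.joint.set_index("exposure")
        for name in ("expo_a", "expo_b"):
            s = single[single["exposure"] == name].iloc[0]
            assert joint.loc[name, "effect"] == pytest.approx(
                s["effect"], abs=2 * s["se"]
            )

    def test_confounded_proxy_attenuated(self):
        exposome, covariates, layer = self._planted_pair(confounded=True)
        single, mset = self._fit(exposome, covariates, layer)
        row = mset.joint.set_index("exposure").loc["expo_b"]
        assert row["percent_change"] > 25.0  # proxy loses >25% of its effect

    def test_categorical_member_design_size(self):
        exposome, covariates, layer = self._planted_pair(confounded=False)
        idx = exposome.samples
        rng = np.random.default_rng(0)
        exposome.values["smoke"] = rng.choice(["never", "past", "current"], len(idx))
        exposome.variables.append(
            ExposureVariable("smoke", "childhood", "tobacco", "categorical",
                             ("never", "past", "current"))
        )
        spec = ModelSpec(n_surrogate_variables=0)
        single = run_exwas(exposome, [layer], covariates, spec)
        mset = MultiExposureSet("prot", "childhood", "protein",
                                ["expo_a", "smoke"])
        fitted = fit_multi_exposure(mset, exposome, layer, covariates, single, spec)
        # 1 continuous column + (3-1) contrast columns
        assert len(fitted.joint) == 3
        assert sorted(fitted.joint["contrast"].unique()) == ["", "current", "past"]
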