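"""cis-eQTM pairing and fitting, miRNA-target concordance, and
cross-matrix replication."""

import numpy as np
import pandas as pd
import pytest

from exwas import (
    CovariateTable,
    OmicsFeature,
    OmicsLayer,
    cross_matrix_replication,
    fit_eqtm,
    mirna_target_concordance,
    pair_cis_eqtm,
)


def _cpg(fid, chrom, pos):
    return OmicsFeature(fid, "methylation", chrom=chrom, position=pos)


def _tc(fid, chrom, pos, gene=None):
    return OmicsFeature(fid, "expression", chrom=chrom, position=pos, gene=gene)


class TestCisPairing:
    def test_inside_window_paired(self):
        pairs = pair_cis_eqtm([_cpg("c1", "chr1", 100_000)],
                              [_tc("t1", "chr1", 550_000)])
        assert len(pairs) == 1
        assert pairs.iloc[0]["distance"] == 450_000

    def test_exactly_at_window_excluded(self):
        pairs = pair_cis_eqtm([_cpg("c1", "chr1", 100_000)],
                              [_tc("t1", "chr1", 600_000)])
        assert pairs.empty  # strict "closer than 500 kb"

    def test_different_chromosomes_never_paired(self):
        pairs = pair_cis_eqtm([_cpg("c1", "chr1", 100)], [_tc("t1", "chr2", 200)])
        assert pairs.empty

    def test_features_without_coordinates_skipped(self):
        pairs = pair_cis_eqtm(
            [_cpg("c1", "chr1", 100), OmicsFeature("c2", "methylation")],
            [_tc("t1", "chr1", 200)],
        )
        assert list(pairs["cpg"]) == ["c1"]

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(19)
        cpgs = [
            _cpg(f"c{i}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 2_000_000)))
            for i in range(100)
        ]
        tcs = [
            _tc(f"t{j}", f"chr{rng.integers(1, 4)}", int(rng.integers(1, 2_000_000)))
            for j in range(100)
        ]
        got = pair_cis_eqtm(cpgs, tcs, window=500_000)
        expected = {
            (c.feature_id, t.feature_id)
            for t in tcs for c in cpgs
            if c.chrom == t.chrom and abs(c.position - t.position) < 500_000
        }
        assert set(zip(got["cpg"], got["tc"])) == expected


def _cohort(n, seed=0):
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(n)]
    return idx, CovariateTable(
        pd.DataFrame(
            {"cohort": rng.choice(["a", "b"], n),
             "sex": rng.choice(["female", "male"], n),
             "age": rng.uniform(6, 11, n), "zbmi": rng.normal(size=n),
             "ancestry": ["european"] * n, "maternal_education": ["low"] * n},
            index=idx,
        )
    )


class TestFitEqtm:
    def test_noiseless_slope_recovered_exactly(self):
        idx, cov = _cohort(60)
        rng = np.random.default_rng(1)
        m = rng.uniform(0.2, 0.8, 60)
        meth = OmicsLayer("methylation", pd.DataFrame({"c1": m}, index=idx),
                          [_cpg("c1", "chr1", 1000)], scale="beta_0_1")
        expr = OmicsLayer("expression", pd.DataFrame({"t1": 2.0 * m}, index=idx),
                          [_tc("t1", "chr1", 2000)])
        pairs = pair_cis_eqtm(meth.features, expr.features)
        out = fit_eqtm(pairs, meth, expr, cov)
        assert out.iloc[0]["estimate"] == pytest.approx(2.0, abs=1e-10)

    def test_permutation_null_is_calibrated(self):
        idx, cov = _cohort(200, seed=2)
        rng = np.random.default_rng(3)
        n_pairs = 400
        meth_vals = rng.uniform(0.1, 0.9, (200, n_pairs))
        expr_vals = rng.normal(5, 1, (200, n_pairs))
        meth = OmicsLayer(
            "methylation",
            pd.DataFrame(meth_vals, index=idx,
                         columns=[f"c{i}" for i in range(n_pairs)]),
            [_cpg(f"c{i}", "chr1", 1000 + i) for i in range(n_pairs)],
            scale="beta_0_1",
        )
        expr = OmicsLayer(
            "expression",
            pd.DataFrame(expr_vals, index=idx,
                         columns=[f"t{i}" for i in range(n_pairs)]),
            [_tc(f"t{i}", "chr1", 1000 + i) for i in range(n_pairs)],
        )
        pairs = pd.DataFrame(
            {"cpg": [f"c{i}" for i in range(n_pairs)],
             "tc": [f"t{i}" for i in range(n_pairs)],
             "distance": 0}
        )
        out = fit_eqtm(pairs, meth, expr, cov)
        frac = (out["p"] < 0.05).mean()
        band = 2.5758 * np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(frac - 0.05) <= band

    def test_true_eqtms_recovered_at_fdr(self):
        idx, cov = _cohort(800, seed=4)
        rng = np.random.default_rng(5)
        n_pairs, n_true = 300, 10
        meth_vals = rng.uniform(0.1, 0.9, (800, n_pairs))
        expr_vals = rng.normal(0, 1, (800, n_pairs))
        # R^2 ~ 0.1: slope * sd(m) / sd(total) with sd(m)~0.23
        for i in range(n_true):
            expr_vals[:, i] += 1.5 * meth_vals[:, i]
        meth = OmicsLayer(
            "methylation",
            pd.DataFrame(meth_vals, index=idx,
                         columns=[f"c{i}" for i in range(n_pairs)]),
            scale="beta_0_1",
        )
        expr = OmicsLayer(
            "expression",
            pd.DataFrame(expr_vals, index=idx,
                         columns=[f"t{i}" for i in range(n_pairs)]),
        )
        pairs = pd.DataFrame(
            {"cpg": [f"c{i}" for i in range(n_pairs)],
             "tc": [f"t{i}" for i in range(n_pairs)],
             "distance": 0}
        )
        out = fit_eqtm(pairs, meth, expr, cov)
        hits = out[out["significant"]]
        true_ids = {f"c{i}" for i in range(n_true)}
        assert len(true_ids & set(hits["cpg"])) >= 8

    def test_zero_variance_cpg_dropped(self):
        idx, cov = _cohort(30)
        meth = OmicsLayer("methylation",
                          pd.DataFrame({"c1": np.full(30, 0.5)}, index=idx),
                          scale="beta_0_1")
        expr = OmicsLayer("expression",
                          pd.DataFrame({"t1": np.random.default_rng(0).normal(size=30)},
                                       index=idx))
        pairs = pd.DataFrame({"cpg": ["c1"], "tc": ["t1"], "distance": [0]})
        out = fit_eqtm(pairs, meth, expr, cov)
        assert out.empty


def _mirna_hit(effect=1.0):
    return pd.DataFrame(
        [{"exposure": "cu", "period": "childhood", "feature": "mir21",
          "layer": "mirna", "effect": effect, "p": 1e-6}]
    )


def _tc_records(effect, p, gene="GENEX"):
    return pd.DataFrame(
        [{"exposure": "cu", "period": "childhood", "feature": "tc1",
          "layer": "expression", "gene": gene, "effect": effect, "p": p}]
    )


class TestMirnaConcordance:
    def test_opposite_direction_retained(self):
        out = mirna_target_concordance(
            _mirna_hit(+1.0), _tc_records(-0.5, 0.01), {"mir21": {"GENEX"}}
        )
        assert len(out) == 1

    def test_same_direction_rejected(self):
        out = mirna_target_concordance(
            _mirna_hit(+1.0), _tc_records(+0.5, 0.01), {"mir21": {"GENEX"}}
        )
        assert out.empty

    def test_non_nominal_target_rejected(self):
        out = mirna_target_concordance(
            _mirna_hit(+1.0), _tc_records(-0.5, 0.2), {"mir21": {"GENEX"}}
        )
        assert out.empty

    def test_unmapped_mirna_contributes_nothing(self):
        out = mirna_target_concordance(
            _mirna_hit(), _tc_records(-0.5, 0.01), {"other": {"GENEX"}}
        )
        assert out.empty

    def test_cascade_simulation_detected(self):
        """Exposure raises the miRNA which lowers its target: the triple is
        retained in nearly all seeded replicates."""
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.normal(size=n)
            mirna = 0.8 * x + rng.normal(0, 0.5, n)
            target = -0.8 * mirna + rng.normal(0, 0.5, n)
            from scipy import stats as st
            bm, am, rm, pm, _ = st.linregress(x, mirna)
            bt, at, rt, pt, _ = st.linregress(x, target)
            hits = pd.DataFrame(
                [{"exposure": "e", "period": "childhood", "feature": "mir",
                  "layer": "mirna", "effect": bm, "p": pm}]
            )
            tcs = pd.DataFrame(
                [{"exposure": "e", "period": "childhood", "feature": "tc",
                  "layer": "expression", "gene": "G", "effect": bt, "p": pt}]
            )
            out = mirna_target_concordance(hits, tcs, {"mir": {"G"}})
            detected += len(out) == 1
        assert detected >= 18


class TestReplication:
    @staticmethod
    def _tables(signs_b, ps_b):
        discovery = pd.DataFrame(
            [{"exposure": "e", "period": "childhood", "feature": f"u{i}",
              "layer": "urine_metab", "effect": 1.0, "p": 1e-5}
             for i in range(len(signs_b))]
        )
        lookup = pd.DataFrame(
            [{"exposure": "e", "period": "childhood", "feature": f"s{i}",
              "layer": "serum_metab", "effect": signs_b[i], "p": ps_b[i]}
             for i in range(len(signs_b))]
        )
        mapping = {f"u{i}": f"s{i}" for i in range(len(signs_b))}
        return discovery, lookup, mapping

    def test_one_in_four_gives_25_percent(self):
        discovery, lookup, mapping = self._tables(
            [1.0, 1.0, -1.0, 1.0], [0.01, 0.5, 0.01, 0.9]
        )
        frac, table = cross_matrix_replication(discovery, lookup, mapping)
        assert frac == pytest.approx(25.0)
        assert len(table) == 4

    def test_sign_requirement_can_be_disabled(self):
        discovery, lookup, mapping = self._tables([-1.0], [0.01])
        frac_strict, _ = cross_matrix_replication(discovery, lookup, mapping)
        frac_loose, _ = cross_matrix_replication(discovery, lookup, mapping,
                                                 require_sign=False)
        assert frac_strict == 0.0
        assert frac_loose == 100.0

    def test_empty_discovery_is_nan(self):
        frac, table = cross_matrix_replication(
            pd.DataFrame(columns=["exposure", "period", "feature", "effect", "p"]),
            pd.DataFrame(columns=["exposure", "period", "feature", "effect", "p"]),
            {},
        )
        assert np.isnan(frac)

    def test_unmapped_features_excluded_from_denominator(self):
        discovery, lookup, mapping = self._tables([1.0, 1.0], [0.01, 0.01])
        del mapping["u1"]
        frac, table = cross_matrix_replication(discovery, lookup, mapping)
        assert len(table) == 1
        assert frac == pytest.approx(100.0)

    def test_correlated_matrices_replicate_more(self):
        """The same latent metabolite driving both fluids yields higher
        replication than independent fluids (directional)."""
        def run(correlated, seed):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.normal(size=n)
            frac_hits = []
            discovery_rows, lookup_rows, mapping = [], [], {}
            for i in range(12):
                latent = rng.normal(size=n)
                urine = latent + 0.6 * x + rng.normal(0, 0.8, n)
                if correlated:
                    serum = latent + 0.6 * x + rng.normal(0, 0.8, n)
                else:
                    serum = rng.normal(size=n) + 0.1 * x + rng.normal(0, 0.8, n)
                from scipy import stats as st
                bu, _, _, pu, _ = st.linregress(x, urine)
                bs, _, _, ps, _ = st.linregress(x, serum)
                discovery_rows.append(
                    {"exposure": "e", "period": "childhood", "feature": f"u{i}",
                     "layer": "urine_metab", "effect": bu, "p": pu}
                )
                lookup_rows.append(
                    {"exposure": "e", "period": "childhood", "feature": f"s{i}",
                     "layer": "serum_metab", "effect": bs, "p": ps}
                )
                mapping[f"u{i}"] = f"s{i}"
            frac, _ = cross_matrix_replication(
                pd.DataFrame(discovery_rows), pd.DataFrame(lookup_rows), mapping
            )
            return frac
        assert run(True, 7) > run(False, 7)
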