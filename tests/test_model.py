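"""Environment grouping, design construction and the REML fitter."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sparsegs.genomics import Grm
from sparsegs.model import (CovarianceSpec, EnvironmentGrouping,
                            MultiEnvGBLUP, build_design)
from sparsegs.reml import KroneckerTerm, MixedREML, USCovariance
from sparsegs.simulate import SimulationConfig, simulate_dataset


def _two_year_frame():
    rows = []
    for year in (2017, 2018):
        for loc, mgmt in (("Kiboko", "WW"), ("Kakamega", "WW"),
                          ("Kiboko", "WS")):
            rows.append({"location": loc, "management": mgmt, "year": year})
    return pd.DataFrame(rows)


class TestEnvironmentGrouping:
    def test_level_counts_match_study_design(self):
        df = _two_year_frame()
        assert EnvironmentGrouping("LMY").apply(df).nunique() == 6
        assert EnvironmentGrouping("MY").apply(df).nunique() == 4
        assert EnvironmentGrouping("M_plus").apply(df).nunique() == 2
        one_year = df[df["year"] == 2017]
        assert EnvironmentGrouping("LM").apply(one_year).nunique() == 3
        assert EnvironmentGrouping("M").apply(one_year).nunique() == 2

    def test_m_merges_locations_within_management(self):
        g = EnvironmentGrouping("M")
        assert g.label("Kiboko", "WW", 2017) == g.label("Kakamega", "WW",
                                                        2017)
        assert g.label("Kiboko", "WW", 2017) != g.label("Kiboko", "WS", 2017)

    def test_single_year_scheme_rejects_multi_year_data(self):
        df = _two_year_frame()
        for scheme in ("LM", "M"):
            with pytest.raises(ValueError, match="single-year"):
                EnvironmentGrouping(scheme).apply(df)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentGrouping("XYZ")


class TestCovarianceSpec:
    def test_factor_count_rule(self):
        spec = CovarianceSpec("FA")
        assert spec.resolve_m(2) == 1
        assert spec.resolve_m(3) == 1
        assert spec.resolve_m(4) == 2
        assert spec.resolve_m(6) == 2

    def test_explicit_m_validated(self):
        with pytest.raises(ValueError):
            CovarianceSpec("FA", m=3).resolve_m(3)


class TestBuildDesign:
    def test_dimension_contract(self, small_dataset, small_grm):
        design = build_design(small_dataset.phenotypes,
                              EnvironmentGrouping("LM"), small_grm)
        n = len(small_dataset.phenotypes)
        g = small_grm.n_lines
        assert design.Z1.shape == (n, 3 * g)
        assert design.X.shape[0] == n
        assert all(t.Z.shape[0] == n for t in design.iid_terms)

    def test_single_level_factor_dropped(self, small_dataset, small_grm):
        df = small_dataset.phenotypes.copy()
        df["tester"] = "T1"
        design = build_design(df, EnvironmentGrouping("LM"), small_grm)
        assert "tester" in design.dropped
        assert "tester" not in [t.name for t in design.iid_terms]

    def test_ungenotyped_line_rejected(self, small_dataset, small_grm):
        df = small_dataset.phenotypes.copy()
        df.loc[0, "line_id"] = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            build_design(df, EnvironmentGrouping("LM"), small_grm)

    def test_missing_column_named(self, small_dataset, small_grm):
        df = small_dataset.phenotypes.drop(columns=["block"])
        with pytest.raises(ValueError, match="block"):
            build_design(df, EnvironmentGrouping("LM"), small_grm)


@pytest.fixture(scope="module")
def fitted(small_dataset_module, small_grm_module):
    model = MultiEnvGBLUP(small_dataset_module.phenotypes, small_grm_module,
                          grouping="LM", structure="US")
    return model.fit()


@pytest.fixture(scope="module")
def small_dataset_module():
    cfg = SimulationConfig(n_families=6, family_size=20, n_chromosomes=4,
                           markers_per_chromosome=50, seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def small_grm_module(small_dataset_module):
    from sparsegs import compute_grm, filter_markers
    return compute_grm(filter_markers(small_dataset_module.marker_matrix))


class TestRemlFit:
    def test_em_loglike_never_decreases(self, small_dataset_module,
                                        small_grm_module):
        for structure in ("US", "FA"):
            res = MultiEnvGBLUP(small_dataset_module.phenotypes,
                                small_grm_module, grouping="LM",
                                structure=structure).fit(method="em",
                                                         max_iter=40)
            deltas = np.diff(res.loglike_trace)
            assert (deltas >= -1e-8).all()

    def test_record_order_invariance(self, small_dataset_module,
                                     small_grm_module, fitted):
        shuffled = small_dataset_module.phenotypes.sample(
            frac=1.0, random_state=7).reset_index(drop=True)
        res2 = MultiEnvGBLUP(shuffled, small_grm_module, grouping="LM",
                             structure="US").fit()
        assert res2.loglike == pytest.approx(fitted.loglike, abs=1e-4)
        np.testing.assert_allclose(res2.Go.to_numpy(),
                                   fitted.Go.to_numpy(), atol=1e-4)

    def test_environment_relabel_permutes_outputs(self, small_dataset_module,
                                                  small_grm_module, fitted):
        df = small_dataset_module.phenotypes.copy()
        # renaming a location permutes the sorted environment order but
        # must not change the science
        df["location"] = df["location"].replace({"Kiboko": "Zomba"})
        res2 = MultiEnvGBLUP(df, small_grm_module, grouping="LM",
                             structure="US").fit()
        assert res2.loglike == pytest.approx(fitted.loglike, abs=1e-3)
        h1 = fitted.heritability()
        h2 = res2.heritability()
        for env in h1.index:
            twin = env.replace("Kiboko", "Zomba")
            assert h2[twin] == pytest.approx(h1[env], abs=1e-3)

    def test_fully_correlated_go_reduces_to_main_effect_gblup(self, rng):
        # at FIXED variance parameters, Go = s2 * J with homogeneous R is a
        # single main genetic effect; BLUPs must match a one-kernel GBLUP
        n, g = 60, 30
        ids = [f"L{i}" for i in range(g)]
        A = rng.normal(size=(g, g))
        G = A @ A.T / g + np.eye(g) * 0.5
        u = np.linalg.cholesky(G) @ rng.normal(size=g)
        line = rng.integers(0, g, size=n)
        env = np.tile([0, 1], n // 2)
        y = u[line] + rng.normal(scale=0.7, size=n)

        s2g, s2e = 0.9, 0.49
        X = sp.csr_matrix(np.ones((n, 1)))
        Z1 = sp.csr_matrix((np.ones(n), (np.arange(n), env * g + line)),
                           shape=(n, 2 * g))
        eps = 1e-6
        go = np.full((2, 2), s2g) + eps * np.eye(2)
        kron_engine = MixedREML(y, X, [], KroneckerTerm(Z1, G,
                                                        USCovariance(go)),
                                env_index=env, n_envs=2)
        kron_engine.resid_var = np.array([s2e, s2e])
        kron_engine.iid_var = {}
        state = kron_engine._assemble(need_inverse=False)
        gebv_kron = state["sol"][1:].reshape(2, g)

        # fully correlated bivariate effect == one shared effect with
        # Var(u) = s2g * G; fit that as a one-environment kernel
        Zm = sp.csr_matrix((np.ones(n), (np.arange(n), line)), shape=(n, g))
        single = MixedREML(y, X, [], KroneckerTerm(
            Zm, G, USCovariance(np.array([[s2g]]))))
        single.resid_var = np.array([s2e])
        single.iid_var = {}
        gebv_single = single._assemble(need_inverse=False)["sol"][1:]

        np.testing.assert_allclose(gebv_kron[0], gebv_kron[1], atol=1e-4)
        np.testing.assert_allclose(gebv_kron[0], gebv_single, atol=1e-3)

    def test_duplicate_genotypes_get_identical_gebvs(self, small_grm_module,
                                                     small_dataset_module):
        grm = small_grm_module
        dup_vals = grm.values.copy()
        dup_vals[1, :] = dup_vals[0, :]
        dup_vals[:, 1] = dup_vals[:, 0]
        dup_vals[1, 1] = dup_vals[0, 0]
        dup = Grm(grm.line_ids, dup_vals)
        df = small_dataset_module.phenotypes
        # drop line 1's phenotypes so only its genotype (a perfect copy of
        # line 0's) determines its GEBV
        keep = df[df["line_id"] != grm.line_ids[1]]
        res = MultiEnvGBLUP(keep, dup, grouping="LM", structure="US").fit()
        np.testing.assert_allclose(
            res.gebv.loc[grm.line_ids[0]].to_numpy(),
            res.gebv.loc[grm.line_ids[1]].to_numpy(), atol=1e-5)

    def test_unrelated_unphenotyped_line_shrinks_to_zero(
            self, small_dataset_module, small_grm_module):
        grm = small_grm_module
        vals = np.zeros((grm.n_lines + 1, grm.n_lines + 1))
        vals[:grm.n_lines, :grm.n_lines] = grm.values
        vals[-1, -1] = 2.0
        ext = Grm(grm.line_ids + ["LONER"], vals)
        res = MultiEnvGBLUP(small_dataset_module.phenotypes, ext,
                            grouping="LM", structure="US").fit()
        assert np.abs(res.gebv.loc["LONER"].to_numpy()).max() < 1e-6

    def test_masked_sibs_recovered_positively(self, small_dataset_module,
                                              small_grm_module):
        df = small_dataset_module.phenotypes
        fam = small_dataset_module.marker_matrix.families()[0]
        members = sorted(small_dataset_module.phenotypes.loc[
            df["family"] == fam, "line_id"].unique())
        masked = members[:10]
        training = df[~df["line_id"].isin(masked)]
        res = MultiEnvGBLUP(training, small_grm_module, grouping="LM",
                            structure="US").fit()
        truth = small_dataset_module.true_genetic_values
        # model environment labels are "<loc>_<mgmt>", truth columns carry
        # the year suffix; correlate in every environment
        for raw in truth.columns:
            label = raw.rsplit("_", 1)[0]
            pred = res.gebv.loc[masked, label].to_numpy()
            true = truth.loc[masked, raw].to_numpy()
            assert np.corrcoef(pred, true)[0, 1] > 0.0


class TestResultsDerived:
    def test_heritability_arithmetic(self, fitted):
        h2 = fitted.heritability()
        go = np.diag(fitted.Go.to_numpy())
        se = fitted.resid_var.to_numpy()
        np.testing.assert_allclose(h2.to_numpy(), go / (go + se))

    @pytest.mark.parametrize("sg2, se2, expected", [
        (1.0, 1.0, 0.5),
        (0.3, 0.7, 0.3),
        (0.0, 1.0, 0.0),
    ])
    def test_heritability_cases(self, fitted, sg2, se2, expected):
        import dataclasses
        res = dataclasses.replace(
            fitted,
            Go=pd.DataFrame([[sg2]], index=["E1"], columns=["E1"]),
            resid_var=pd.Series([se2], index=["E1"]))
        assert res.heritability()["E1"] == pytest.approx(expected)

    def test_genetic_correlation_arithmetic(self, fitted):
        import dataclasses
        go = pd.DataFrame([[1.0, 0.5], [0.5, 4.0]],
                          index=["A", "B"], columns=["A", "B"])
        res = dataclasses.replace(fitted, Go=go)
        corr = res.genetic_correlations()
        assert corr.loc["A", "B"] == pytest.approx(0.25)
        assert corr.loc["A", "A"] == 1.0

    def test_zero_variance_environment_reported_missing(self, fitted):
        import dataclasses
        go = pd.DataFrame([[0.0, 0.0], [0.0, 4.0]],
                          index=["A", "B"], columns=["A", "B"])
        res = dataclasses.replace(fitted, Go=go)
        corr = res.genetic_correlations()
        assert np.isnan(corr.loc["A", "B"])
        assert corr.loc["B", "B"] == 1.0

    def test_rank_one_fa_correlations_are_unit(self):
        import dataclasses
        lam = np.array([[1.0], [-2.0], [0.5]])
        go = pd.DataFrame(lam @ lam.T, index=list("ABC"),
                          columns=list("ABC"))
        corr_vals = np.abs(go.to_numpy()
                           / np.sqrt(np.outer(np.diag(go), np.diag(go))))
        np.testing.assert_allclose(corr_vals, 1.0, atol=1e-12)

    def test_predict_unknown_line_named(self, fitted):
        with pytest.raises(KeyError, match="NOPE"):
            fitted.predict_gebv(["NOPE"])

    def test_summary_mentions_key_facts(self, fitted):
        text = fitted.summary()
        assert "US" in text and "logL" in text
        assert "plot heritability" in text
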