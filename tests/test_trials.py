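"""Trial mixed models: BLUEs vs GLS oracles, heritability, correlations."""

import numpy as np
import pandas as pd
import pytest

import kernelgp as kg
from kernelgp.trials import (
    EstimabilityError,
    VarianceComponents,
    estimate_H2,
    fit_blues,
    genotype_correlations,
    reflectance_blues,
)

from conftest import toy_plot_table


class TestFitBlues:
    def test_zero_variance_ratios_give_arithmetic_means(self, toy_table):
        df, _ = toy_table
        blue = fit_blues(df, "environment", "yield", scope_id="2020 Toy",
                         fixed_gamma={})
        means = df.groupby("genotype")["yield"].mean()
        np.testing.assert_allclose(blue.values.sort_index(), means.sort_index(),
                                   atol=1e-9)

    def test_constant_response(self):
        df, _ = toy_plot_table(sigma=0.0)
        df["yield"] = 7.5
        blue = fit_blues(df, "environment", "yield", scope_id="2020 Toy")
        np.testing.assert_allclose(blue.values, 7.5, atol=1e-9)
        assert blue.zero_variance

    def test_matches_gls_oracle_at_fixed_components(self):
        # 3 genotypes x 2 reps with non-trivial design effects; BLUEs at known
        # variance ratios must equal the direct GLS solve
        rng = np.random.default_rng(42)
        rows = []
        g_eff = {"g1": -5.0, "g2": 0.0, "g3": 5.0}
        for rep in (1, 2):
            for pos, g in enumerate(["g1", "g2", "g3"]):
                rows.append({"env_id": "e", "location": "l", "year": 2020,
                             "genotype": g, "replicate": rep,
                             "block": pos // 2 + 1, "column": pos + 1,
                             "yield": 50 + g_eff[g] + rng.normal(0, 2)})
        df = pd.DataFrame(rows)
        gamma = {"replicate": 0.5, "replicate:block": 0.25, "column": 0.1}
        blue = fit_blues(df, "environment", "yield", scope_id="e",
                         fixed_gamma=gamma)

        # independent dense GLS oracle
        X = pd.get_dummies(df["genotype"]).to_numpy(float)
        def Z(cols):
            key = df[cols].astype(str).agg("/".join, axis=1)
            return pd.get_dummies(key).to_numpy(float)
        V = (np.eye(len(df))
             + 0.5 * Z(["replicate"]) @ Z(["replicate"]).T
             + 0.25 * Z(["replicate", "block"]) @ Z(["replicate", "block"]).T
             + 0.1 * Z(["column"]) @ Z(["column"]).T)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ df["yield"].to_numpy())
        np.testing.assert_allclose(blue.values.to_numpy(), beta, atol=1e-6)

    def test_shift_scale_equivariance(self, toy_table):
        df, _ = toy_plot_table(sigma=3.0, seed=5)
        base = fit_blues(df, "environment", "yield", scope_id="2020 Toy")
        df2 = df.copy()
        df2["yield"] = 2.5 * df2["yield"] - 40.0
        scaled = fit_blues(df2, "environment", "yield", scope_id="2020 Toy")
        np.testing.assert_allclose(scaled.values, 2.5 * base.values - 40.0,
                                   rtol=1e-6, atol=1e-6)

    def test_disconnected_design_raises(self):
        rows = []
        for g, rep in (("a", 1), ("b", 1), ("c", 2), ("d", 2)):
            rows.append({"env_id": "e", "location": "l", "year": 2020,
                         "genotype": g, "replicate": rep, "block": 1,
                         "column": 1, "yield": 1.0})
        rows.append({"env_id": "e", "location": "l", "year": 2020,
                     "genotype": "a", "replicate": 3, "block": 1,
                     "column": 1, "yield": 1.0})
        with pytest.raises(EstimabilityError, match="genotypes"):
            fit_blues(pd.DataFrame(rows), "environment", "yield", scope_id="e")

    def test_loglik_not_below_boundary_candidates(self, toy_table):
        df, _ = toy_plot_table(sigma=4.0, seed=11)
        from kernelgp.trials import _DesignFit

        design = _DesignFit(df, "environment", genotype_fixed=True)
        y = df["yield"].to_numpy(float)
        fit, eng = design.fit(y)
        for cand in (np.zeros(3), np.ones(3)):
            assert fit.loglik >= eng.profiled_loglik(cand) - 1e-8

    def test_location_and_global_scopes(self, small_study):
        plots = small_study["plots"]
        loc = fit_blues(plots, "location", "yield", scope_id="Testfield")
        glo = fit_blues(plots, "global", "yield")
        assert len(loc.values) == len(glo.values)
        # pooling years strengthens the genetic signal
        truth = small_study["truth"].true_breeding_values.mean(axis=1)
        r = np.corrcoef(glo.values.sort_index(),
                        truth.loc[glo.values.sort_index().index])[0, 1]
        assert r > 0.8


class TestHeritability:
    def test_direct_formula(self):
        vc = VarianceComponents({"genotype": 1.0, "residual": 1.0}, 2)
        assert estimate_H2(vc) == pytest.approx(2.0 / 3.0)
        vc = VarianceComponents({"genotype": 3.0, "residual": 0.0}, 2)
        assert estimate_H2(vc) == 1.0

    def test_undefined_when_no_variance(self):
        with pytest.raises(ValueError):
            estimate_H2(VarianceComponents({"genotype": 0.0, "residual": 0.0}, 2))

    def test_monotonicity_grid(self):
        for s2e in (0.5, 1.0, 2.0):
            h = [estimate_H2(VarianceComponents({"genotype": g, "residual": s2e}, 2))
                 for g in (0.5, 1.0, 2.0, 4.0)]
            assert np.all(np.diff(h) > 0)
        for r in (1, 2, 4):
            assert estimate_H2(VarianceComponents(
                {"genotype": 1.0, "residual": 1.0}, r)) == pytest.approx(r / (r + 1))
        h = [estimate_H2(VarianceComponents({"genotype": 1.0, "residual": e}, 2))
             for e in (0.5, 1.0, 2.0)]
        assert np.all(np.diff(h) < 0)

    def test_recovery_from_simulated_trial(self):
        ests = []
        for seed in (0, 1):
            sc = kg.small_scenario(seed=seed, n_genotypes=250, n_markers=600,
                                   n_environments=1, h2=0.8)
            mk = kg.simulate_markers(sc)
            tr = kg.simulate_genetic_values(mk, sc)
            plots = kg.simulate_trials(tr, sc)
            vc = kg.fit_genotype_variance(plots, "environment", "yield",
                                          scope_id=sc.environments[0].env_id)
            ests.append(estimate_H2(vc))
        assert np.mean(ests) == pytest.approx(0.8, abs=0.07)


class TestReflectanceBlues:
    def test_one_table_per_camera_date_band(self, small_study):
        sc = small_study["scenario"]
        env = sc.environments[0].env_id
        tables = reflectance_blues(small_study["reflectance"], env)
        n_flights = len(sc.flight_schedule[env])
        assert len(tables) == n_flights * 5
        assert {t.band for t in tables} == {"red", "green", "blue", "RedEdge", "NIR"}

    def test_noiseless_reflectance_recovered_exactly(self):
        import datetime as dt

        from kernelgp.simulate import EnvironmentSpec, Flight, SimulationScenario

        env = EnvironmentSpec(env_id="2020 T", location="T", year=2020,
                              n_genotypes_present=10)
        sc = SimulationScenario(
            n_genotypes=10, n_markers=50, environments=[env],
            h2_target_per_env={"2020 T": 0.9},
            flight_schedule={"2020 T": [Flight(dt.date(2020, 7, 10), "cam",
                                               ("red",))]},
            band_loading_profile={"red": {"grain_filling": 1.5}},
            band_specific_sd={}, band_noise={}, band_baseline={"red": 10.0},
            reflectance_design_sd=0.0, seed=2)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        refl = kg.simulate_reflectance(tr, sc)
        tables = reflectance_blues(refl, "2020 T")
        g = tr.true_breeding_values["2020 T"]
        gs = (g - g.mean()) / g.std(ddof=0)
        expected = 10.0 + 1.5 * gs
        got = tables[0].values.sort_index()
        np.testing.assert_allclose(got, expected.loc[got.index], atol=1e-7)

    def test_band_heritability_orders_with_configuration(self, small_study):
        # NIR is configured with the weakest loadings and the most noise, so its
        # estimated plot-level heritability must come out lowest on every date
        sc = small_study["scenario"]
        env = sc.environments[0].env_id
        refl = small_study["reflectance"]
        from kernelgp.trials import reflectance_columns

        h2 = {}
        for col in reflectance_columns(refl):
            vc = kg.fit_genotype_variance(refl[refl[col].notna()], "environment",
                                          col, scope_id=env)
            h2[col] = estimate_H2(vc)
        by_date = {}
        for col, val in h2.items():
            cam, date, band = col.split("__")
            by_date.setdefault(date, {})[band] = val
        for date, bands in by_date.items():
            worst = min(bands, key=bands.get)
            assert worst == "NIR", (date, bands)


class TestGenotypeCorrelations:
    def test_self_and_identical(self, env_blue_tables):
        b = env_blue_tables[0]
        C = genotype_correlations([b, b])
        np.testing.assert_allclose(C.to_numpy(), 1.0, atol=1e-12)

    def test_small_intersection_reported_missing(self, env_blue_tables):
        import copy

        a = env_blue_tables[0]
        b = copy.copy(env_blue_tables[1])
        b.values = b.values.iloc[:2]
        b.scope_id = "tiny"
        C = genotype_correlations([a, b])
        assert np.isnan(C.loc[a.scope_id, "tiny"])

    def test_mean_correlation_matches_attenuated_truth(self, small_study,
                                                       env_blue_tables):
        # BLUE-level correlations are the truth-level correlation attenuated by
        # sqrt(H2_i H2_j); assert against that model-derived expectation
        sc = small_study["scenario"]
        truth = small_study["truth"]
        C = genotype_correlations(env_blue_tables).to_numpy()
        n = C.shape[0]
        obs = C[np.triu_indices(n, 1)].mean()
        tb = truth.true_breeding_values
        Ct = tb.corr().to_numpy()[np.triu_indices(n, 1)].mean()
        h2 = [truth.realized_h2[e.env_id] for e in sc.environments]
        att = np.mean([np.sqrt(h2[i] * h2[j])
                       for i in range(n) for j in range(i + 1, n)])
        assert obs == pytest.approx(Ct * att, abs=0.1)
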