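"""Generator contracts: domains, determinism, and emulation fidelity."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import kernelgp as kg
from kernelgp.simulate import (
    EnvironmentSpec,
    Flight,
    LayoutError,
    ScenarioError,
    SimulationScenario,
    growth_stage,
    make_default_scenario,
)


def single_env_scenario(seed=0, n=12, m=20, h2=0.8, **kw):
    env = EnvironmentSpec(env_id="2020 T", location="T", year=2020,
                          n_genotypes_present=n, **kw)
    return SimulationScenario(n_genotypes=n, n_markers=m, environments=[env],
                              h2_target_per_env={"2020 T": h2}, seed=seed)


class TestMarkers:
    def test_domain_and_determinism(self):
        sc = single_env_scenario(seed=3, n=4, m=3)
        sc.missing_fraction = 0.0
        a = kg.simulate_markers(sc)
        b = kg.simulate_markers(sc)
        assert a.calls.shape == (4, 3)
        assert np.isin(a.calls, (0.0, 1.0, 2.0)).all()
        np.testing.assert_array_equal(a.calls, b.calls)

    def test_maf_spectrum_spans_qc_threshold(self):
        sc = single_env_scenario(seed=1, n=100, m=2000)
        sc.maf_range = (0.01, 0.5)
        mk = kg.simulate_markers(sc)
        calls = mk.calls.copy()
        calls[calls == 1.0] = np.nan
        p = np.nanmean(calls, axis=0) / 2
        maf = np.minimum(p, 1 - p)
        assert (maf < 0.05).sum() > 20 and (maf > 0.05).sum() > 20

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ScenarioError):
            single_env_scenario(n=1)
        with pytest.raises(ScenarioError):
            single_env_scenario(m=0)


def multi_env_scenario(seed, rho, n=300, m=2000, n_envs=11):
    envs, h2 = [], {}
    for k in range(n_envs):
        e = f"{2010 + k} T"
        envs.append(EnvironmentSpec(env_id=e, location="T", year=2010 + k,
                                    n_genotypes_present=n))
        h2[e] = 0.8
    return SimulationScenario(n_genotypes=n, n_markers=m, environments=envs,
                              h2_target_per_env=h2, genetic_correlation=rho,
                              seed=seed)


class TestGeneticValues:
    def test_perfect_correlation_gives_identical_vectors(self):
        sc = multi_env_scenario(0, 1.0, n=30, m=200, n_envs=3)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        tb = tr.true_breeding_values
        np.testing.assert_allclose(tb.iloc[:, 0], tb.iloc[:, 1], atol=1e-9)

    def test_zero_correlation_near_independent(self):
        vals = []
        for seed in range(3):
            sc = multi_env_scenario(seed, 0.0, n=300, m=1000, n_envs=4)
            mk = kg.simulate_markers(sc)
            tb = kg.simulate_genetic_values(mk, sc).true_breeding_values
            C = tb.corr().to_numpy()
            vals.append(C[np.triu_indices(4, 1)].mean())
        assert abs(np.mean(vals)) < 0.1

    def test_target_correlation_recovered(self):
        # the stated emulation target: mean pairwise r of true values near 0.77
        vals = []
        for seed in range(5):
            sc = multi_env_scenario(seed, 0.77, n=300, m=2000, n_envs=11)
            mk = kg.simulate_markers(sc)
            tb = kg.simulate_genetic_values(mk, sc).true_breeding_values
            C = tb.corr().to_numpy()
            vals.append(C[np.triu_indices(11, 1)].mean())
        assert 0.72 <= np.mean(vals) <= 0.82

    def test_bad_correlation_rejected(self):
        with pytest.raises(ScenarioError):
            multi_env_scenario(0, 1.2, n=10, m=20, n_envs=2)


class TestTrials:
    def test_alpha_lattice_layout_counts(self):
        sc = single_env_scenario(n=12, m=30)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        plots = kg.simulate_trials(tr, sc)
        assert len(plots) == 24  # 12 genotypes x 2 replicates
        per_rep = plots.groupby("replicate")["block"].nunique()
        assert (per_rep == 2).all()  # block size 6 -> 2 blocks per replicate
        sizes = plots.groupby(["replicate", "block"]).size()
        assert (sizes == 6).all()

    def test_noiseless_limit_reproduces_genetic_values(self):
        sc = single_env_scenario(n=10, m=50, h2=1.0,
                                 replicate_effect_sd=0.0, block_effect_sd=0.0,
                                 column_effect_sd=0.0, yield_baseline=0.0)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        plots = kg.simulate_trials(tr, sc)
        g = tr.true_breeding_values["2020 T"]
        np.testing.assert_allclose(
            plots["yield"].to_numpy(),
            g.loc[plots["genotype"]].to_numpy(), atol=1e-9)

    def test_block_size_larger_than_panel_rejected(self):
        sc = single_env_scenario(n=4, m=10, block_size=6)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        with pytest.raises(LayoutError):
            kg.simulate_trials(tr, sc)

    def test_determinism(self):
        sc = single_env_scenario(seed=9, n=12, m=30)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        a = kg.simulate_trials(tr, sc)
        b = kg.simulate_trials(tr, sc)
        pd.testing.assert_frame_equal(a, b)

    def test_variance_bookkeeping(self):
        # empirical decomposition matches configured components within 10%
        tot_emp, tot_cfg, gen_emp, gen_cfg = [], [], [], []
        for seed in range(5):
            sc = single_env_scenario(seed=seed, n=300, m=500, h2=0.8)
            mk = kg.simulate_markers(sc)
            tr = kg.simulate_genetic_values(mk, sc)
            plots = kg.simulate_trials(tr, sc)
            c = tr.true_variance_components["2020 T"]
            cfg = (c["sigma2_G"] + c["sigma2_e"] + c["sigma2_replicate"]
                   + c["sigma2_block"] + c["sigma2_column"])
            tot_emp.append(plots["yield"].var(ddof=0))
            tot_cfg.append(cfg)
            means = plots.groupby("genotype")["yield"].mean()
            gen_emp.append(means.var(ddof=0))
            # entry means carry genetic variance plus non-genetic noise / r
            gen_cfg.append(c["sigma2_G"] + (cfg - c["sigma2_G"]) / 2)
        assert np.mean(tot_emp) == pytest.approx(np.mean(tot_cfg), rel=0.10)
        assert np.mean(gen_emp) == pytest.approx(np.mean(gen_cfg), rel=0.15)


class TestReflectance:
    def test_no_signal_limit_is_constant_per_response(self):
        sc = single_env_scenario(n=8, m=30)
        sc.flight_schedule = {"2020 T": [Flight(dt.date(2020, 7, 10), "cam")]}
        sc.band_loading_profile = {b: {} for b in ("red", "green", "blue",
                                                   "RedEdge", "NIR")}
        sc.band_specific_sd = {}
        sc.band_noise = {}
        sc.band_baseline = {"red": 10.0}
        sc.reflectance_design_sd = 0.0
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        refl = kg.simulate_reflectance(tr, sc)
        col = refl["cam__2020-07-10__red"]
        np.testing.assert_allclose(col, 10.0)

    def test_flight_outside_window_rejected(self):
        sc = single_env_scenario(n=8, m=30)
        with pytest.raises(ScenarioError):
            sc.flight_schedule = {"2020 T": [Flight(dt.date(2020, 2, 1), "cam")]}
            sc.__post_init__()

    def test_shares_layout_with_trials(self):
        sc = kg.small_scenario(seed=4, n_genotypes=20, n_markers=60,
                               n_environments=1)
        mk = kg.simulate_markers(sc)
        tr = kg.simulate_genetic_values(mk, sc)
        plots = kg.simulate_trials(tr, sc)
        refl = kg.simulate_reflectance(tr, sc)
        key = ["env_id", "genotype", "replicate", "block", "column"]
        env = plots["env_id"].iloc[0]
        pd.testing.assert_frame_equal(
            plots.loc[plots.env_id == env, key].reset_index(drop=True),
            refl[key].reset_index(drop=True))


class TestGrowthStage:
    def test_stage_progression(self):
        window = (dt.date(2020, 4, 25), dt.date(2020, 6, 15),
                  dt.date(2020, 8, 10), dt.date(2020, 8, 25))
        assert growth_stage(dt.date(2020, 5, 10), window)[0] == "vegetative"
        assert growth_stage(dt.date(2020, 7, 15), window)[0] == "grain_filling"
        assert growth_stage(dt.date(2020, 8, 20), window)[0] == "maturation"


class TestDefaultScenario:
    def test_emulated_study_conditions(self):
        sc = make_default_scenario(0)
        assert len(sc.environments) == 11
        counts = [e.n_genotypes_present for e in sc.environments]
        assert min(counts) == 98 and max(counts) == 296
        assert all(e.n_replicates == 2 for e in sc.environments)
        assert all(e.block_size == 6 for e in sc.environments)
        h2 = list(sc.h2_target_per_env.values())
        assert min(h2) == 0.63 and max(h2) == 0.92
        flights = {}
        for env_id, fls in sc.flight_schedule.items():
            for fl in fls:
                flights.setdefault((env_id, fl.camera), 0)
                flights[(env_id, fl.camera)] += 1
        assert min(flights.values()) == 4 and max(flights.values()) == 22
        assert len(flights) == 5

    def test_every_camera_season_has_a_july_flight(self):
        sc = make_default_scenario(1)
        for env_id, fls in sc.flight_schedule.items():
            cams = {f.camera for f in fls}
            for cam in cams:
                assert any(f.date.month == 7 for f in fls if f.camera == cam)
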