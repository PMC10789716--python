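import numpy as np
import pandas as pd
import pytest

import kernelgp as kg


@pytest.fixture(scope="session")
def small_study():
    """A reduced multi-environment study shared across test modules."""
    sc = kg.small_scenario(seed=7, n_genotypes=60, n_markers=400,
                           n_environments=3, n_flights=3)
    markers = kg.simulate_markers(sc)
    truth = kg.simulate_genetic_values(markers, sc)
    plots = kg.simulate_trials(truth, sc)
    reflectance = kg.simulate_reflectance(truth, sc)
    return {"scenario": sc, "markers": markers, "truth": truth,
            "plots": plots, "reflectance": reflectance}


@pytest.fixture(scope="session")
def small_G(small_study):
    filtered, _ = kg.filter_markers(small_study["markers"])
    return kg.compute_G(filtered)


@pytest.fixture(scope="session")
def env_blue_tables(small_study):
    sc = small_study["scenario"]
    return [kg.fit_blues(small_study["plots"], "environment", "yield",
                         scope_id=e.env_id) for e in sc.environments]


def toy_plot_table(n_genotypes=6, n_reps=2, block_size=3, sigma=0.0, seed=0,
                   env_id="2020 Toy"):
    """Small balanced trial with known additive effects, for oracle tests."""
    rng = np.random.default_rng(seed)
    genos = [f"g{i}" for i in range(1, n_genotypes + 1)]
    g_eff = rng.normal(0, 10, n_genotypes)
    rows = []
    for rep in range(1, n_reps + 1):
        order = rng.permutation(n_genotypes)
        for pos, gi in enumerate(order):
            rows.append({
                "env_id": env_id, "location": "Toy", "year": 2020,
                "genotype": genos[gi], "replicate": rep,
                "block": pos // block_size + 1, "column": pos % 3 + 1,
                "yield": 100.0 + g_eff[gi] + rng.normal(0, sigma),
            })
    return pd.DataFrame(rows), pd.Series(g_eff, index=genos)


@pytest.fixture
def toy_table():
    return toy_plot_table()
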