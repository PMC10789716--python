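"""Cross-validation scenarios and performance metrics.

Two schemes, both repeated for a configurable number of iterations (200 in the
full protocol) with refitting on every training split:

* single-environment: a random 80/20 genotype partition of one response
  vector (an environment, location or global BLUE table);
* multi-environment: two whole environments are drawn as the test set together
  with 20% of all genotypes; the test records are the test genotypes inside
  the test environments and the training records are the remaining genotypes
  inside the remaining environments, so the test set is double-blind (neither
  its genotypes nor its environments were seen in training).

Metrics per iteration: Pearson correlation between predicted and observed
values (rTRN/rTST) and root mean squared error sqrt(sum (obs-pred)^2 / N)
(rmseTRN/rmseTST).  Iterations whose observed or predicted vector has zero
variance contribute no correlation (excluded from the mean, counted), but
still contribute rmse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .blup import ModelSpec, predict, reml_fit

__all__ = [
    "CVConfig",
    "MetricsRecord",
    "split_single_env",
    "split_multi_env",
    "compute_metrics",
    "run_cv",
]

_S_SINGLE, _S_MULTI = 101, 202


class CVError(RuntimeError):
    pass


@dataclass
class CVConfig:
    scenario: str = "single_environment"  # or "multi_environment"
    n_iterations: int = 200
    test_genotype_fraction: float = 0.20
    n_test_environments: int = 2
    base_seed: int = 0

    def __post_init__(self):
        if self.scenario not in ("single_environment", "multi_environment"):
            raise ValueError(f"unknown CV scenario {self.scenario!r}")
        if not 0.0 < self.test_genotype_fraction < 1.0:
            raise ValueError("test_genotype_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class MetricsRecord:
    """Per-iteration CV metrics and their means."""

    table: pd.DataFrame  # iteration, rTRN, rTST, rmseTRN, rmseTST
    n_iterations: int
    n_excluded: dict[str, int] = field(default_factory=dict)
    n_failed: int = 0
    n_redraws: int = 0

    @property
    def means(self) -> dict[str, float]:
        out = {}
        for col in ("rTRN", "rTST", "rmseTRN", "rmseTST"):
            out[col] = float(self.table[col].mean(skipna=True))
        return out

    def __getattr__(self, name):
        if name in ("rTRN", "rTST", "rmseTRN", "rmseTST"):
            return self.means[name]
        raise AttributeError(name)


def _rng(base_seed: int, stream: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng([int(base_seed) & 0x7FFFFFFF, stream, int(iteration)])


def _test_size(n: int, fraction: float) -> int:
    return max(int(round(fraction * n)), 1)


def split_single_env(
    genotypes: Sequence[str], config: CVConfig, iteration: int
) -> tuple[list[str], list[str]]:
    """Seeded random 80/20 genotype partition (order within sets preserved)."""
    genotypes = list(genotypes)
    if len(genotypes) < 5:
        raise ValueError("need at least 5 genotypes to split")
    rng = _rng(config.base_seed, _S_SINGLE, iteration)
    n_test = _test_size(len(genotypes), config.test_genotype_fraction)
    test_idx = set(rng.choice(len(genotypes), size=n_test, replace=False).tolist())
    train = [g for i, g in enumerate(genotypes) if i not in test_idx]
    test = [g for i, g in enumerate(genotypes) if i in test_idx]
    return train, test


def split_multi_env(
    records: pd.DataFrame, config: CVConfig, iteration: int, max_redraws: int = 100
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Double-blind environment + genotype split.

    Test records: test genotypes within test environments.  Train records: the
    other genotypes within the other environments.  Records mixing the two
    (train genotypes in test environments or vice versa) are used in neither.
    """
    envs = sorted(records["env_id"].astype(str).unique())
    genos = sorted(records["genotype"].astype(str).unique())
    if len(envs) < 3:
        raise ValueError("multi-environment CV needs at least 3 environments")
    if len(genos) < 5:
        raise ValueError("need at least 5 genotypes")
    if config.n_test_environments >= len(envs):
        raise ValueError("n_test_environments must be < number of environments")
    rng = _rng(config.base_seed, _S_MULTI, iteration)
    n_test_g = _test_size(len(genos), config.test_genotype_fraction)
    redraws = 0
    while True:
        test_envs = set(rng.choice(envs, size=config.n_test_environments,
                                   replace=False).tolist())
        test_genos = set(rng.choice(genos, size=n_test_g, replace=False).tolist())
        env_col = records["env_id"].astype(str)
        geno_col = records["genotype"].astype(str)
        test_mask = env_col.isin(test_envs) & geno_col.isin(test_genos)
        per_env_counts = env_col[test_mask].value_counts()
        if all(per_env_counts.get(e, 0) > 0 for e in test_envs):
            break
        redraws += 1
        if redraws > max_redraws:
            raise CVError("could not draw a valid double-blind split")
    train_mask = ~env_col.isin(test_envs) & ~geno_col.isin(test_genos)
    info = {"test_envs": sorted(test_envs), "n_test_genotypes": n_test_g,
            "redraws": redraws}
    return records[train_mask], records[test_mask], info


def compute_metrics(observed: np.ndarray, predicted: np.ndarray) -> dict[str, float]:
    """Pearson r (NaN when either vector is degenerate) and rmse."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if obs.std() == 0 or pred.std() == 0:
        return {"r": np.nan, "rmse": rmse}
    return {"r": float(np.corrcoef(obs, pred)[0, 1]), "rmse": rmse}


SpecFactory = Callable[[pd.DataFrame], ModelSpec]


def run_cv(
    records: pd.DataFrame,
    spec: ModelSpec | SpecFactory,
    config: CVConfig,
    max_failure_fraction: float = 0.10,
) -> MetricsRecord:
    """Full cross-validation: split, refit by REML on the training records
    only, predict both sets, and aggregate the four metrics."""
    records = records.reset_index(drop=True)
    rows = []
    excluded = {"rTRN": 0, "rTST": 0}
    failures = 0
    redraws = 0
    for it in range(config.n_iterations):
        if config.scenario == "single_environment":
            genos = sorted(records["genotype"].astype(str).unique())
            train_g, test_g = split_single_env(genos, config, it)
            gcol = records["genotype"].astype(str)
            train = records[gcol.isin(train_g)]
            test = records[gcol.isin(test_g)]
        else:
            train, test, info = split_multi_env(records, config, it)
            redraws += info["redraws"]
        model_spec = spec(train) if callable(spec) else spec
        try:
            fit = reml_fit(train, model_spec)
            if not fit.converged:
                raise CVError("REML did not converge")
            pred_trn = predict(fit, train)
            pred_tst = predict(fit, test)
        except (CVError, np.linalg.LinAlgError):
            failures += 1
            rows.append({"iteration": it, "rTRN": np.nan, "rTST": np.nan,
                         "rmseTRN": np.nan, "rmseTST": np.nan, "failed": True})
            continue
        m_trn = compute_metrics(train["y"].to_numpy(), pred_trn)
        m_tst = compute_metrics(test["y"].to_numpy(), pred_tst)
        if np.isnan(m_trn["r"]):
            excluded["rTRN"] += 1
        if np.isnan(m_tst["r"]):
            excluded["rTST"] += 1
        rows.append({"iteration": it, "rTRN": m_trn["r"], "rTST": m_tst["r"],
                     "rmseTRN": m_trn["rmse"], "rmseTST": m_tst["rmse"],
                     "failed": False})
    if failures > max_failure_fraction * config.n_iterations:
        raise CVError(
            f"{failures}/{config.n_iterations} CV iterations failed to converge"
        )
    table = pd.DataFrame(rows)
    return MetricsRecord(
        table=table,
        n_iterations=config.n_iterations,
        n_excluded=excluded,
        n_failed=failures,
        n_redraws=redraws,
    )
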