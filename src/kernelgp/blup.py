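"""Multi-kernel BLUP: y = mu 1 + sum_t u_t + e with u_t ~ N(0, K_t sigma2_t).

The five model families of the analysis are instances of this one form:

* G           genotype effect with the genomic kernel
* M           genotype effect with a multispectral kernel
* G+E, M+E    plus an environment effect with the yield-covariance kernel K_E
* G+M         two genotype effects (genomic + multispectral)
* G+M+E       all three

Variance components are estimated by profiled REML (see ``_reml``); every id
carried by a kernel receives a BLUP whether or not it has training records, so
predictions for unobserved genotypes/environments are the joint-normal
conditional expectations through the kernel cross-covariance, obtained by
augmenting the random-effect design with empty rows rather than post-hoc
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._reml import MultiKernelREML, RandomTerm, reml_loglik_dense
from .kernels import Kernel

__all__ = ["ModelTerm", "ModelSpec", "FitResult", "reml_fit", "predict", "loglik_oracle"]


class ModelError(ValueError):
    pass


@dataclass
class ModelTerm:
    name: str
    kernel: Kernel
    index: str  # record column mapping records to kernel ids ("genotype" | "env_id")


@dataclass
class ModelSpec:
    terms: list[ModelTerm]

    def __post_init__(self):
        if not self.terms:
            raise ModelError("a model needs at least one kernel term")
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ModelError("duplicate term names")


@dataclass
class FitResult:
    mu: float
    variance_components: dict[str, float]   # per term plus "residual"
    blups: dict[str, pd.Series]             # term -> id -> effect (all kernel ids)
    reml_loglik: float
    converged: bool
    n_iterations: int
    term_index: dict[str, str] = field(default_factory=dict)  # term -> record column


def _validate_records(records: pd.DataFrame, require_y: bool) -> pd.DataFrame:
    df = records.copy()
    if "genotype" not in df.columns:
        raise ModelError("records need a 'genotype' column")
    if "env_id" not in df.columns:
        df["env_id"] = None
    if require_y:
        if "y" not in df.columns:
            raise ModelError("records need a 'y' column")
        y = df["y"].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ModelError("response contains non-finite values")
    dup = df.duplicated(subset=["genotype", "env_id"])
    if dup.any():
        pair = df.loc[dup, ["genotype", "env_id"]].iloc[0].tolist()
        raise ModelError(f"duplicate (genotype, env) record: {pair}")
    return df


def _term_rows(df: pd.DataFrame, term: ModelTerm) -> np.ndarray:
    if term.index not in df.columns:
        raise ModelError(f"records have no column {term.index!r} for term {term.name!r}")
    pos = {g: i for i, g in enumerate(term.kernel.ids)}
    vals = df[term.index].astype(str)
    unknown = sorted(set(vals) - set(pos))
    if unknown:
        raise ModelError(
            f"term {term.name!r}: record ids missing from kernel: {unknown[:10]}"
        )
    return np.array([pos[v] for v in vals], dtype=int)


def reml_fit(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit the intercept + kernel random effects model by REML."""
    df = _validate_records(records, require_y=True)
    if len(df) < 3:
        raise ModelError("need at least 3 records")
    y = df["y"].to_numpy(dtype=float)
    X = np.ones((len(df), 1))
    terms = []
    loadings = {}
    for t in spec.terms:
        L = t.kernel.loading_factor()
        rows = _term_rows(df, t)
        loadings[t.name] = L
        terms.append(RandomTerm(name=t.name, F=L[rows]))
    engine = MultiKernelREML(y, X, terms)
    fit = engine.fit()
    comps = dict(fit.sigma2_terms)
    comps["residual"] = fit.sigma2_resid
    blups = {}
    for t in spec.terms:
        u = loadings[t.name] @ fit.coef_terms[t.name]
        blups[t.name] = pd.Series(u, index=list(t.kernel.ids), name=t.name)
    return FitResult(
        mu=float(fit.beta[0]),
        variance_components=comps,
        blups=blups,
        reml_loglik=fit.loglik,
        converged=fit.converged,
        n_iterations=fit.n_evaluations,
        term_index={t.name: t.index for t in spec.terms},
    )


def predict(fit: FitResult, targets: pd.DataFrame) -> np.ndarray:
    """mu + sum of term BLUPs at each target record's index values."""
    df = _validate_records(targets, require_y=False)
    out = np.full(len(df), fit.mu, dtype=float)
    for name, blup in fit.blups.items():
        col = fit.term_index[name]
        vals = df[col].astype(str)
        unknown = sorted(set(vals) - set(blup.index.astype(str)))
        if unknown:
            raise ModelError(f"term {name!r}: unknown target ids {unknown[:10]}")
        out += blup.reindex(vals).to_numpy(dtype=float)
    return out


def loglik_oracle(
    records: pd.DataFrame, spec: ModelSpec, variances: dict[str, float]
) -> float:
    """Exact restricted log-likelihood at fixed variances, by dense factorization.

    ``variances`` maps each term name to sigma2_t and "residual" to sigma2.
    Serves as the independent oracle for the profiled Woodbury path.
    """
    df = _validate_records(records, require_y=True)
    y = df["y"].to_numpy(dtype=float)
    n = len(df)
    bad = [k for k, v in variances.items() if v < 0]
    if bad:
        raise ModelError(f"negative variances for {bad}")
    if all(v == 0 for v in variances.values()):
        raise ModelError("all variances are zero")
    V = float(variances["residual"]) * np.eye(n)
    for t in spec.terms:
        rows = _term_rows(df, t)
        V += float(variances[t.name]) * t.kernel.values[np.ix_(rows, rows)]
    return reml_loglik_dense(y, np.ones((n, 1)), V)
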