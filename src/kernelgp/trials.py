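"""Plot-level mixed models for multi-environment trials.

Produces adjusted genotype means (BLUEs) at three scopes, with genotype fixed
and the design factors random, estimated by REML:

* environment scope:  y = mu + genotype + R + R:B + C + e
* location scope:     y = mu + genotype + Y + Y:R + Y:R:B + Y:C + e
* global scope:       y = mu + genotype + L + Y:L + Y:L:R + Y:L:R:B + Y:L:C + e

(R replicate, B incomplete block nested in replicate, C field column, Y year,
L location).  Broad-sense heritability on an entry-mean basis is
sigma2_G / (sigma2_G + sigma2_e / r), with the genotypic variance estimated by
refitting the same model with genotype as a random effect.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._reml import MultiKernelREML, RandomTerm

__all__ = [
    "PLOT_COLUMNS",
    "BlueTable",
    "VarianceComponents",
    "EstimabilityError",
    "EmptyResultError",
    "validate_plot_table",
    "parse_response_name",
    "reflectance_columns",
    "fit_blues",
    "fit_genotype_variance",
    "estimate_H2",
    "reflectance_blues",
    "genotype_correlations",
]

PLOT_COLUMNS = ("env_id", "location", "year", "genotype", "replicate", "block", "column")

_SCOPES = ("environment", "location", "global")


class EstimabilityError(ValueError):
    pass


class EmptyResultError(ValueError):
    pass


@dataclass
class VarianceComponents:
    """REML variance components of one trial-model fit (genotype random)."""

    components: dict[str, float]  # includes "genotype" and "residual"
    n_replicates: int

    @property
    def sigma2_G(self) -> float:
        return self.components["genotype"]

    @property
    def sigma2_e(self) -> float:
        return self.components["residual"]


@dataclass
class BlueTable:
    """Adjusted genotype means for one scope and one response."""

    scope: str                      # environment | location | global
    scope_id: str | None            # env_id, location name, or None
    response_name: str
    values: pd.Series               # genotype -> BLUE
    n_obs: pd.Series                # genotype -> record count
    zero_variance: bool = False
    variance_components: dict[str, float] = field(default_factory=dict)
    # reflectance metadata (None for yield)
    camera: str | None = None
    date: dt.date | None = None
    band: str | None = None

    @property
    def env_id(self) -> str | None:
        return self.scope_id if self.scope == "environment" else None

    def values_by_genotype(self) -> pd.Series:
        return self.values

    @property
    def name(self) -> str | None:
        return self.scope_id


def validate_plot_table(df: pd.DataFrame, response: str | None = None) -> None:
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table is missing required columns {missing}")
    key = ["env_id", "genotype", "replicate"]
    if response is not None:
        sub = df.loc[df[response].notna(), key]
    else:
        sub = df[key]
    dup = sub.duplicated()
    if dup.any():
        first = sub[dup].iloc[0].tolist()
        raise ValueError(f"duplicate (env, genotype, replicate) record: {first}")


def parse_response_name(name: str) -> tuple[str, dt.date, str] | None:
    """`camera__YYYY-MM-DD__band` -> (camera, date, band); None if not reflectance."""
    parts = name.split("__")
    if len(parts) != 3:
        return None
    camera, date_s, band = parts
    try:
        date = dt.date.fromisoformat(date_s)
    except ValueError as exc:
        raise ValueError(f"unparseable date in response column {name!r}") from exc
    return camera, date, band


def reflectance_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if len(str(c).split("__")) == 3]


def _check_connected(df: pd.DataFrame, group_cols: list[str]) -> None:
    """Genotypes must be linked to each other through shared design groups."""
    groups = df[group_cols].astype(str).agg("/".join, axis=1)
    geno = df["genotype"].astype(str)
    parent: dict[str, str] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for g, grp in zip(geno, groups):
        ra, rb = find("g:" + g), find("grp:" + grp)
        if ra != rb:
            parent[ra] = rb
    roots = {find("g:" + g) for g in geno.unique()}
    if len(roots) > 1:
        comp: dict[str, list[str]] = {}
        for g in geno.unique():
            comp.setdefault(find("g:" + g), []).append(g)
        smallest = min(comp.values(), key=len)
        raise EstimabilityError(
            f"design is disconnected; genotypes {sorted(smallest)[:10]} are not "
            f"linked to the rest of the trial"
        )


def _random_term_layout(scope: str) -> list[tuple[str, list[str]]]:
    if scope == "environment":
        return [("replicate", ["replicate"]),
                ("replicate:block", ["replicate", "block"]),
                ("column", ["column"])]
    if scope == "location":
        return [("year", ["year"]),
                ("year:replicate", ["year", "replicate"]),
                ("year:replicate:block", ["year", "replicate", "block"]),
                ("year:column", ["year", "column"])]
    if scope == "global":
        return [("location", ["location"]),
                ("year:location", ["year", "location"]),
                ("year:location:replicate", ["year", "location", "replicate"]),
                ("year:location:replicate:block", ["year", "location", "replicate", "block"]),
                ("year:location:column", ["year", "location", "column"])]
    raise ValueError(f"unknown scope {scope!r}; expected one of {_SCOPES}")


def _scope_subset(df: pd.DataFrame, scope: str, scope_id: str | None) -> pd.DataFrame:
    if scope == "environment":
        if scope_id is None:
            raise ValueError("environment scope requires an env_id")
        out = df[df["env_id"].astype(str) == str(scope_id)]
    elif scope == "location":
        if scope_id is None:
            raise ValueError("location scope requires a location name")
        out = df[df["location"].astype(str) == str(scope_id)]
    elif scope == "global":
        out = df
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if out.empty:
        raise EmptyResultError(f"no records for scope {scope}/{scope_id}")
    return out


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _build_terms(df: pd.DataFrame, scope: str) -> list[RandomTerm]:
    terms = []
    for name, cols in _random_term_layout(scope):
        key = df[cols].astype(str).agg("/".join, axis=1)
        codes, uniques = pd.factorize(key, sort=True)
        terms.append(RandomTerm(name=name, F=_indicator(codes, len(uniques))))
    return terms


class _DesignFit:
    """A trial design with cached Gram matrices, refittable per response."""

    def __init__(self, df: pd.DataFrame, scope: str, genotype_fixed: bool):
        self.scope = scope
        self.df = df
        geno_codes, geno_levels = pd.factorize(df["genotype"].astype(str), sort=True)
        self.genotypes = list(geno_levels)
        terms = _build_terms(df, scope)
        if genotype_fixed:
            X = _indicator(geno_codes, len(geno_levels))
        else:
            X = np.ones((len(df), 1))
            terms = [RandomTerm("genotype", _indicator(geno_codes, len(geno_levels)))] + terms
        self.genotype_fixed = genotype_fixed
        self.engine = MultiKernelREML(np.zeros(len(df)), X, terms)
        self._warm: np.ndarray | None = None

    def fit(self, y: np.ndarray, fixed_gamma: dict[str, float] | None = None):
        eng = self.engine.with_response(y)
        if fixed_gamma is not None:
            gamma = np.array([fixed_gamma.get(t.name, 0.0) for t in eng.terms])
            ll = eng.profiled_loglik(gamma)
            return eng._at_optimum(gamma, ll, True, 1), eng
        fit = eng.fit(init_gamma=self._warm)
        if self._warm is None:
            self._warm = fit.gamma.copy()
        else:
            self._warm = 0.5 * (self._warm + fit.gamma)
        return fit, eng


def fit_blues(
    table: pd.DataFrame,
    scope: str,
    response_name: str,
    scope_id: str | None = None,
    fixed_gamma: dict[str, float] | None = None,
    _design: "_DesignFit | None" = None,
    **blue_meta,
) -> BlueTable:
    """REML-adjusted genotype means (genotype fixed, design factors random).

    ``fixed_gamma`` pins the variance ratios sigma2_t/sigma2_e instead of
    estimating them (ratio 0 for every term gives the OLS genotype means).
    """
    validate_plot_table(table, response=response_name)
    if response_name not in table.columns:
        raise ValueError(f"response column {response_name!r} not in table")
    df = _scope_subset(table, scope, scope_id)
    df = df[df[response_name].notna()]
    if df.empty:
        raise EmptyResultError(f"response {response_name!r} is all-missing in scope")
    if df["genotype"].nunique() < 2:
        raise EstimabilityError("need at least 2 genotypes with records")
    group_cols = (["replicate"] if scope == "environment" else
                  ["env_id", "replicate"])
    _check_connected(df, group_cols)

    y = df[response_name].to_numpy(dtype=float)
    zero_var = float(np.var(y)) <= 1e-12 * (1.0 + float(np.mean(y)) ** 2)
    design = _design if _design is not None else _DesignFit(df, scope, genotype_fixed=True)
    fit, _ = design.fit(y, fixed_gamma=fixed_gamma)
    values = pd.Series(fit.beta, index=design.genotypes, name=response_name)
    n_obs = df.groupby(df["genotype"].astype(str)).size().reindex(design.genotypes)
    comps = dict(fit.sigma2_terms)
    comps["residual"] = fit.sigma2_resid
    return BlueTable(
        scope=scope,
        scope_id=scope_id,
        response_name=response_name,
        values=values,
        n_obs=n_obs,
        zero_variance=bool(zero_var),
        variance_components=comps,
        **blue_meta,
    )


def fit_genotype_variance(
    table: pd.DataFrame,
    scope: str,
    response_name: str,
    scope_id: str | None = None,
    _design: "_DesignFit | None" = None,
) -> VarianceComponents:
    """Variance components with genotype refitted as a random effect."""
    validate_plot_table(table, response=response_name)
    df = _scope_subset(table, scope, scope_id)
    df = df[df[response_name].notna()]
    if df.empty:
        raise EmptyResultError(f"response {response_name!r} is all-missing in scope")
    y = df[response_name].to_numpy(dtype=float)
    design = _design if _design is not None else _DesignFit(df, scope, genotype_fixed=False)
    fit, _ = design.fit(y)
    comps = dict(fit.sigma2_terms)
    comps["residual"] = fit.sigma2_resid
    r = int(df.groupby(df["genotype"].astype(str)).size().median())
    return VarianceComponents(components=comps, n_replicates=max(r, 1))


def estimate_H2(components: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability sigma2_G / (sigma2_G + sigma2_e/r)."""
    s2g, s2e, r = components.sigma2_G, components.sigma2_e, components.n_replicates
    if s2g < 0 or s2e < 0 or r < 1:
        raise ValueError("variances must be non-negative and r >= 1")
    if s2g == 0 and s2e == 0:
        raise ValueError("heritability undefined: both variances are zero")
    return s2g / (s2g + s2e / r)


def reflectance_blues(
    table: pd.DataFrame, env_id: str, camera: str | None = None
) -> list[BlueTable]:
    """One BLUE table per (camera, date, band) present in one environment.

    Fits the environment-scope model for each reflectance response; designs are
    shared between responses observed on the same plots, so repeated fits reuse
    the cached cross-products.
    """
    cols = reflectance_columns(table)
    if camera is not None:
        cols = [c for c in cols if parse_response_name(c)[0] == camera]
    env_df = table[table["env_id"].astype(str) == str(env_id)]
    out: list[BlueTable] = []
    design_cache: dict[bytes, _DesignFit] = {}
    for col in cols:
        sub = env_df[env_df[col].notna()]
        if sub.empty:
            continue
        mask_key = sub.index.to_numpy().tobytes()
        design = design_cache.get(mask_key)
        if design is None:
            design = _DesignFit(sub, "environment", genotype_fixed=True)
            design_cache[mask_key] = design
        cam, date, band = parse_response_name(col)
        out.append(
            fit_blues(
                sub, "environment", col, scope_id=env_id, _design=design,
                camera=cam, date=date, band=band,
            )
        )
    if not out:
        raise EmptyResultError(f"no reflectance responses for environment {env_id!r}")
    return out


def genotype_correlations(blues: Sequence[BlueTable], min_shared: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations of genotype BLUEs on shared genotypes."""
    if len(blues) < 2:
        raise ValueError("need at least 2 BLUE tables")
    labels = []
    for b in blues:
        lab = b.scope_id if b.scope_id is not None else b.scope
        labels.append(str(lab))
    if len(set(labels)) != len(labels):
        labels = [f"{lab}#{i}" for i, lab in enumerate(labels)]
    mat = pd.DataFrame(np.eye(len(blues)), index=labels, columns=labels)
    for i in range(len(blues)):
        for j in range(i + 1, len(blues)):
            a, b = blues[i].values, blues[j].values
            shared = a.index.intersection(b.index)
            if len(shared) < min_shared:
                r = np.nan
            else:
                x, yv = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
                if x.std() == 0 or yv.std() == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, yv)[0, 1])
            mat.iloc[i, j] = mat.iloc[j, i] = r
    return mat
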