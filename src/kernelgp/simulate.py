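"""Synthetic multi-environment wheat trial generator.

Emulates the statistical structure of a Nordic spring-wheat breeding panel
evaluated for grain yield (g·m⁻²) across 11 year/location environments, with
SNP markers and UAV multispectral reflectance time series:

* biallelic markers coded 0/1/2 on a mostly inbred panel descending from a
  small founder set (random biparental mosaics), so the genomic relationship
  matrix carries the family structure genomic prediction relies on;
  configurable heterozygous and missing call fractions give marker QC work;
* additive per-environment genetic values from shared + environment-specific
  marker effects, mixed to hit a target mean inter-environment genetic
  correlation (compound-symmetry G×E);
* alpha-lattice field trials (2 replicates, block size 6 by default) with
  replicate, incomplete-block and column effects, the plot error variance
  chosen so the expected entry-mean heritability sigma2_G/(sigma2_G+sigma2_e/r)
  matches each environment's target;
* plot-level reflectance per flight and band, where the genetic loading on
  yield varies with growth stage (peaking during grain filling) and each band
  additionally carries a band-specific genetic signal plus band noise; NIR is
  configured least heritable by default.

All randomness derives from the scenario seed through named streams, so every
generator is bit-reproducible and any environment can be regenerated alone.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kernels import BANDS, MarkerMatrix, scale_columns

__all__ = [
    "EnvironmentSpec",
    "Flight",
    "SimulationScenario",
    "TruthRecord",
    "ScenarioError",
    "LayoutError",
    "growth_stage",
    "simulate_markers",
    "simulate_genetic_values",
    "simulate_trials",
    "simulate_reflectance",
    "make_default_scenario",
]

GROWTH_STAGES = ("vegetative", "heading", "grain_filling", "maturation")
# stage boundaries as fractions of the sowing -> maturity window
_STAGE_BREAKS = (0.45, 0.60, 0.85)

# rng stream tags (kept below 2**31)
_S_MARKERS, _S_EFFECTS, _S_PRESENCE, _S_LAYOUT, _S_TRIAL, _S_REFL, _S_LATENT = range(7)


class ScenarioError(ValueError):
    pass


class LayoutError(ScenarioError):
    pass


@dataclass(frozen=True)
class Flight:
    date: dt.date
    camera: str
    bands: tuple[str, ...] = BANDS


@dataclass
class EnvironmentSpec:
    """One year/location field trial."""

    env_id: str
    location: str
    year: int
    n_genotypes_present: int
    n_replicates: int = 2
    block_size: int = 6
    n_columns: int = 24
    # (sowing, heading, maturity, harvest)
    season_window: tuple[dt.date, dt.date, dt.date, dt.date] = None  # type: ignore
    yield_baseline: float = 520.0
    replicate_effect_sd: float = 15.0
    block_effect_sd: float = 12.0
    column_effect_sd: float = 10.0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ScenarioError(f"{self.env_id}: n_replicates must be >= 1")
        if self.block_size < 2:
            raise ScenarioError(f"{self.env_id}: block_size must be >= 2")
        if self.n_genotypes_present < 2:
            raise ScenarioError(f"{self.env_id}: need >= 2 genotypes")
        if self.season_window is None:
            y = self.year
            self.season_window = (
                dt.date(y, 4, 25),
                dt.date(y, 6, 15),
                dt.date(y, 8, 10),
                dt.date(y, 8, 25),
            )
        s, h, m, hv = self.season_window
        if not (s < h < m < hv):
            raise ScenarioError(f"{self.env_id}: season dates must be strictly ordered")


@dataclass
class SimulationScenario:
    n_genotypes: int
    n_markers: int
    environments: list[EnvironmentSpec]
    h2_target_per_env: Mapping[str, float]
    genetic_correlation: float = 0.77
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_founders: int = 30
    missing_fraction: float = 0.02
    het_fraction: float = 0.01
    genetic_sd: float = 40.0
    flight_schedule: Mapping[str, Sequence[Flight]] = field(default_factory=dict)
    band_loading_profile: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    band_specific_sd: Mapping[str, float] = field(default_factory=dict)
    band_noise: Mapping[str, float] = field(default_factory=dict)
    band_baseline: Mapping[str, float] = field(default_factory=dict)
    reflectance_design_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 2 or self.n_markers < 1:
            raise ScenarioError("n_genotypes >= 2 and n_markers >= 1 required")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ScenarioError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.genetic_correlation <= 1.0:
            raise ScenarioError("genetic_correlation must be in [0, 1]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ScenarioError("missing_fraction must be in [0, 1)")
        if not 0.0 <= self.het_fraction < 1.0:
            raise ScenarioError("het_fraction must be in [0, 1)")
        env_ids = [e.env_id for e in self.environments]
        if len(set(env_ids)) != len(env_ids):
            raise ScenarioError("duplicate environment ids")
        for e in self.environments:
            h2 = self.h2_target_per_env.get(e.env_id)
            if h2 is None or not (0.0 < h2 <= 1.0):
                raise ScenarioError(f"{e.env_id}: h2 target must be in (0, 1]")
            if e.n_genotypes_present > self.n_genotypes:
                raise ScenarioError(f"{e.env_id}: more genotypes present than in panel")
        for env_id, flights in self.flight_schedule.items():
            spec = self.environment(env_id)
            sowing, _, _, harvest = spec.season_window
            for fl in flights:
                if not (sowing <= fl.date <= harvest):
                    raise ScenarioError(
                        f"flight {fl.date} ({env_id}/{fl.camera}) outside season "
                        f"window {sowing}..{harvest}"
                    )

    def environment(self, env_id: str) -> EnvironmentSpec:
        for e in self.environments:
            if e.env_id == env_id:
                return e
        raise ScenarioError(f"unknown environment {env_id!r}")

    @property
    def genotype_ids(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genotypes + 1)]


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery tests."""

    true_breeding_values: pd.DataFrame  # genotypes x environments (g/m^2, centered)
    env_genotypes: dict[str, list[str]]
    realized_h2: dict[str, float]
    true_variance_components: dict[str, dict[str, float]]
    band_genetic_loadings: pd.DataFrame  # env, camera, date, band, stage, loading


def _rng(scenario: SimulationScenario, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(scenario.seed) & 0x7FFFFFFF, stream, *extra])


def growth_stage(date: dt.date, season_window) -> tuple[str, float]:
    """Stage name and fractional position in the sowing -> maturity window."""
    sowing, _, maturity, _ = season_window
    frac = (date - sowing).days / max((maturity - sowing).days, 1)
    if frac < _STAGE_BREAKS[0]:
        return GROWTH_STAGES[0], frac
    if frac < _STAGE_BREAKS[1]:
        return GROWTH_STAGES[1], frac
    if frac < _STAGE_BREAKS[2]:
        return GROWTH_STAGES[2], frac
    return GROWTH_STAGES[3], frac


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def simulate_markers(scenario: SimulationScenario) -> MarkerMatrix:
    """Biallelic 0/1/2 calls on an inbred panel bred from a founder set.

    Per marker, an allele frequency is drawn from ``maf_range`` and inbred
    founder haplotypes are drawn Bernoulli at that frequency; each panel line
    is a random biparental mosaic of two founders (an independent inheritance
    draw per marker).  The resulting family relatedness is what gives the
    genomic kernel its predictive structure.  ``het_fraction`` of calls are
    then recoded heterozygous and ``missing_fraction`` set missing.
    """
    rng = _rng(scenario, _S_MARKERS)
    n, m = scenario.n_genotypes, scenario.n_markers
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, size=m)
    nf = max(int(scenario.n_founders), 2)
    founders = (rng.random((nf, m)) < maf[None, :]).astype(float)  # haploid 0/1
    parents = rng.integers(0, nf, size=(n, 2))
    inherit = rng.random((n, m)) < 0.5
    calls = 2.0 * np.where(
        inherit, founders[parents[:, 0], :], founders[parents[:, 1], :]
    )
    if scenario.het_fraction > 0:
        het = rng.random((n, m)) < scenario.het_fraction
        calls[het] = 1.0
    if scenario.missing_fraction > 0:
        miss = rng.random((n, m)) < scenario.missing_fraction
        calls[miss] = np.nan
    width = len(str(m))
    marker_ids = [f"m{j:0{width}d}" for j in range(1, m + 1)]
    return MarkerMatrix(scenario.genotype_ids, marker_ids, calls)


# ---------------------------------------------------------------------------
# genetic values
# ---------------------------------------------------------------------------

def simulate_genetic_values(
    markers: MarkerMatrix, scenario: SimulationScenario
) -> TruthRecord:
    """Additive per-environment genetic values with compound G×E correlation.

    Each environment's values are W(sqrt(rho) b_common + sqrt(1-rho) b_env)
    on column-scaled calls W, then standardized per environment to the target
    genetic standard deviation, which leaves pairwise correlations at rho.
    """
    if markers.n_genotypes < 2 or markers.n_markers < 1:
        raise ScenarioError("marker matrix is empty")
    rho = scenario.genetic_correlation
    rng = _rng(scenario, _S_EFFECTS)
    W, _ = scale_columns(markers.calls)
    m = W.shape[1]
    b_common = rng.standard_normal(m)
    g = {}
    for spec in scenario.environments:
        b_env = rng.standard_normal(m)
        raw = W @ (np.sqrt(rho) * b_common + np.sqrt(1.0 - rho) * b_env)
        sd = raw.std(ddof=0)
        if sd <= 0:
            raise ScenarioError("degenerate marker matrix: no genetic variance")
        g[spec.env_id] = (raw - raw.mean()) / sd * scenario.genetic_sd
    tbv = pd.DataFrame(g, index=markers.genotype_ids)

    presence_rng = _rng(scenario, _S_PRESENCE)
    env_genotypes: dict[str, list[str]] = {}
    realized_h2: dict[str, float] = {}
    components: dict[str, dict[str, float]] = {}
    for spec in scenario.environments:
        chosen = presence_rng.choice(
            markers.n_genotypes, size=spec.n_genotypes_present, replace=False
        )
        chosen.sort()
        present = [markers.genotype_ids[i] for i in chosen]
        env_genotypes[spec.env_id] = present
        h2 = scenario.h2_target_per_env[spec.env_id]
        s2_G = float(tbv.loc[present, spec.env_id].to_numpy().var(ddof=0))
        r = spec.n_replicates
        s2_e = r * s2_G * (1.0 - h2) / h2
        components[spec.env_id] = {
            "sigma2_G": s2_G,
            "sigma2_e": s2_e,
            "sigma2_replicate": spec.replicate_effect_sd**2,
            "sigma2_block": spec.block_effect_sd**2,
            "sigma2_column": spec.column_effect_sd**2,
        }
        realized_h2[spec.env_id] = s2_G / (s2_G + s2_e / r) if s2_G + s2_e > 0 else np.nan

    loadings = _band_loading_table(scenario)
    return TruthRecord(
        true_breeding_values=tbv,
        env_genotypes=env_genotypes,
        realized_h2=realized_h2,
        true_variance_components=components,
        band_genetic_loadings=loadings,
    )


def _band_loading_table(scenario: SimulationScenario) -> pd.DataFrame:
    rows = []
    for env_id, flights in scenario.flight_schedule.items():
        spec = scenario.environment(env_id)
        for fl in flights:
            stage, frac = growth_stage(fl.date, spec.season_window)
            for band in fl.bands:
                profile = scenario.band_loading_profile.get(band, {})
                rows.append(
                    {
                        "env_id": env_id,
                        "camera": fl.camera,
                        "date": fl.date,
                        "band": band,
                        "stage": stage,
                        "stage_fraction": frac,
                        "loading": float(profile.get(stage, 0.0)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["env_id", "camera", "date", "band", "stage", "stage_fraction", "loading"],
    )


# ---------------------------------------------------------------------------
# field layout and trials
# ---------------------------------------------------------------------------

def _alpha_lattice_layout(
    scenario: SimulationScenario, truth: TruthRecord, spec: EnvironmentSpec
) -> pd.DataFrame:
    genotypes = truth.env_genotypes[spec.env_id]
    n = len(genotypes)
    if spec.block_size > n:
        raise LayoutError(
            f"{spec.env_id}: block size {spec.block_size} exceeds genotype count {n}"
        )
    env_idx = [e.env_id for e in scenario.environments].index(spec.env_id)
    rng = _rng(scenario, _S_LAYOUT, env_idx)
    rows = []
    plot = 0
    for rep in range(1, spec.n_replicates + 1):
        order = rng.permutation(n)
        for pos, gi in enumerate(order):
            rows.append(
                {
                    "env_id": spec.env_id,
                    "location": spec.location,
                    "year": spec.year,
                    "genotype": genotypes[gi],
                    "replicate": rep,
                    "block": pos // spec.block_size + 1,
                    "column": plot % spec.n_columns + 1,
                }
            )
            plot += 1
    return pd.DataFrame(rows)


def simulate_trials(truth: TruthRecord, scenario: SimulationScenario) -> pd.DataFrame:
    """Plot-level grain-yield table over all environments (long/wide hybrid:
    one row per plot with a ``yield`` column)."""
    missing = [e.env_id for e in scenario.environments
               if e.env_id not in truth.env_genotypes]
    if missing:
        raise ScenarioError(f"truth does not cover environments {missing}")
    frames = []
    for env_idx, spec in enumerate(scenario.environments):
        layout = _alpha_lattice_layout(scenario, truth, spec)
        comp = truth.true_variance_components[spec.env_id]
        rng = _rng(scenario, _S_TRIAL, env_idx)
        rep_eff = rng.normal(0.0, spec.replicate_effect_sd, size=spec.n_replicates)
        n_blocks = int(layout["block"].max())
        blk_eff = rng.normal(0.0, spec.block_effect_sd, size=(spec.n_replicates, n_blocks))
        col_eff = rng.normal(0.0, spec.column_effect_sd, size=spec.n_columns)
        err = rng.normal(0.0, np.sqrt(comp["sigma2_e"]), size=len(layout))
        g = truth.true_breeding_values.loc[layout["genotype"], spec.env_id].to_numpy()
        layout["yield"] = (
            spec.yield_baseline
            + g
            + rep_eff[layout["replicate"].to_numpy() - 1]
            + blk_eff[layout["replicate"].to_numpy() - 1, layout["block"].to_numpy() - 1]
            + col_eff[layout["column"].to_numpy() - 1]
            + err
        )
        frames.append(layout)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reflectance
# ---------------------------------------------------------------------------

def simulate_reflectance(truth: TruthRecord, scenario: SimulationScenario) -> pd.DataFrame:
    """Plot-level reflectance table for every scheduled flight and band.

    Per plot:  baseline(band, stage) + loading(band, stage) * standardized
    genetic value + band-specific genetic latent + small design effects + band
    noise.  Wide layout: one ``camera__date__band`` column per response.
    """
    if not scenario.flight_schedule:
        raise ScenarioError("scenario has no flight schedule")
    frames = []
    env_ids = [e.env_id for e in scenario.environments]
    for env_id, flights in scenario.flight_schedule.items():
        if not flights:
            continue
        spec = scenario.environment(env_id)
        env_idx = env_ids.index(env_id)
        layout = _alpha_lattice_layout(scenario, truth, spec)
        genotypes = truth.env_genotypes[env_id]
        g = truth.true_breeding_values.loc[genotypes, env_id].to_numpy()
        sd = g.std(ddof=0)
        g_std = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
        g_std = pd.Series(g_std, index=genotypes)

        latent_rng = _rng(scenario, _S_LATENT, env_idx)
        latents = {
            band: pd.Series(latent_rng.standard_normal(len(genotypes)), index=genotypes)
            for band in BANDS
        }
        rng = _rng(scenario, _S_REFL, env_idx)
        d_sd = scenario.reflectance_design_sd
        rep_eff = rng.normal(0.0, d_sd, size=spec.n_replicates)
        n_blocks = int(layout["block"].max())
        blk_eff = rng.normal(0.0, d_sd, size=(spec.n_replicates, n_blocks))
        col_eff = rng.normal(0.0, d_sd, size=spec.n_columns)
        design = (
            rep_eff[layout["replicate"].to_numpy() - 1]
            + blk_eff[layout["replicate"].to_numpy() - 1, layout["block"].to_numpy() - 1]
            + col_eff[layout["column"].to_numpy() - 1]
        )
        new_cols: dict[str, np.ndarray] = {}
        out = layout
        for fl in sorted(flights, key=lambda f: (f.camera, f.date)):
            sowing, _, _, harvest = spec.season_window
            if not (sowing <= fl.date <= harvest):
                raise ScenarioError(f"flight {fl.date} outside season window of {env_id}")
            stage, _ = growth_stage(fl.date, spec.season_window)
            for band in fl.bands:
                lam = float(scenario.band_loading_profile.get(band, {}).get(stage, 0.0))
                kappa = float(scenario.band_specific_sd.get(band, 0.0))
                noise_sd = float(scenario.band_noise.get(band, 0.0))
                base = float(scenario.band_baseline.get(band, 0.0))
                noise = (rng.normal(0.0, noise_sd, size=len(out))
                         if noise_sd > 0 else np.zeros(len(out)))
                vals = (
                    base
                    + lam * g_std.loc[out["genotype"]].to_numpy()
                    + kappa * latents[band].loc[out["genotype"]].to_numpy()
                    + design
                    + noise
                )
                new_cols[f"{fl.camera}__{fl.date.isoformat()}__{band}"] = vals
        frames.append(pd.concat([out, pd.DataFrame(new_cols, index=out.index)], axis=1))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# default scenario (the emulated study conditions)
# ---------------------------------------------------------------------------

_DEFAULT_ENVS = [
    # (env_id, location, year, n_genotypes, h2, yield baseline g/m^2)
    ("2015 Vollebekk", "Vollebekk", 2015, 157, 0.92, 520.0),
    ("2016 Staur", "Staur", 2016, 100, 0.71, 590.0),
    ("2016 Vollebekk", "Vollebekk", 2016, 98, 0.73, 515.0),
    ("2017 Staur", "Staur", 2017, 240, 0.83, 789.0),
    ("2017 Vollebekk", "Vollebekk", 2017, 240, 0.63, 505.0),
    ("2019 Staur", "Staur", 2019, 220, 0.83, 585.0),
    ("2019 Vollebekk", "Vollebekk", 2019, 220, 0.81, 525.0),
    ("2020 Staur", "Staur", 2020, 288, 0.68, 600.0),
    ("2020 Vollebekk", "Vollebekk", 2020, 288, 0.73, 530.0),
    ("2021 Vollebekk", "Vollebekk", 2021, 293, 0.84, 535.0),
    ("2022 Vollebekk", "Vollebekk", 2022, 296, 0.90, 510.0),
]

# flights per environment and camera (year, location, camera, count)
_DEFAULT_FLIGHTS = [
    ("2019 Vollebekk", "micasense", 7),
    ("2019 Staur", "micasense", 4),
    ("2020 Vollebekk", "micasense", 12),
    ("2021 Vollebekk", "micasense", 8),
    ("2021 Vollebekk", "phantom4", 22),
]

# genetic loading on standardized yield breeding value, by growth stage
DEFAULT_BAND_LOADING = {
    "red": {"vegetative": 0.50, "heading": 0.70, "grain_filling": 0.90, "maturation": 0.25},
    "green": {"vegetative": 0.50, "heading": 0.70, "grain_filling": 0.85, "maturation": 0.25},
    "blue": {"vegetative": 0.40, "heading": 0.60, "grain_filling": 0.75, "maturation": 0.20},
    "RedEdge": {"vegetative": 0.50, "heading": 0.80, "grain_filling": 1.00, "maturation": 0.30},
    "NIR": {"vegetative": 0.30, "heading": 0.40, "grain_filling": 0.50, "maturation": 0.10},
}
DEFAULT_BAND_SPECIFIC_SD = {"red": 0.50, "green": 0.50, "blue": 0.45,
                            "RedEdge": 0.60, "NIR": 0.25}
DEFAULT_BAND_NOISE = {"red": 0.70, "green": 0.70, "blue": 0.75,
                      "RedEdge": 0.70, "NIR": 1.60}
DEFAULT_BAND_BASELINE = {"red": 10.0, "green": 12.0, "blue": 8.0,
                         "RedEdge": 25.0, "NIR": 40.0}


def _spread_flight_dates(year: int, count: int) -> list[dt.date]:
    """Evenly spread data-capture dates from late May to late August."""
    start = dt.date(year, 5, 25).toordinal()
    end = dt.date(year, 8, 20).toordinal()
    if count == 1:
        return [dt.date.fromordinal((start + end) // 2)]
    return [dt.date.fromordinal(int(round(o)))
            for o in np.linspace(start, end, count)]


def make_default_scenario(seed: int) -> SimulationScenario:
    """The emulated study conditions: 11 environments (genotype counts and
    heritability targets per trial), 2 replicates, block size 6, 4–22 flights
    per environment/camera season and five reflectance bands."""
    envs = [
        EnvironmentSpec(
            env_id=e, location=loc, year=yr, n_genotypes_present=n,
            yield_baseline=base,
        )
        for (e, loc, yr, n, _h2, base) in _DEFAULT_ENVS
    ]
    h2 = {e: h for (e, _l, _y, _n, h, _b) in _DEFAULT_ENVS}
    schedule: dict[str, list[Flight]] = {}
    for env_id, camera, count in _DEFAULT_FLIGHTS:
        year = next(y for (e, _l, y, _n, _h, _b) in _DEFAULT_ENVS if e == env_id)
        schedule.setdefault(env_id, []).extend(
            Flight(date=d, camera=camera) for d in _spread_flight_dates(year, count)
        )
    return SimulationScenario(
        n_genotypes=300,
        n_markers=20000,
        environments=envs,
        h2_target_per_env=h2,
        genetic_correlation=0.77,
        flight_schedule=schedule,
        band_loading_profile=DEFAULT_BAND_LOADING,
        band_specific_sd=DEFAULT_BAND_SPECIFIC_SD,
        band_noise=DEFAULT_BAND_NOISE,
        band_baseline=DEFAULT_BAND_BASELINE,
        seed=int(seed),
    )


def small_scenario(
    seed: int = 0,
    n_genotypes: int = 60,
    n_markers: int = 400,
    n_environments: int = 3,
    n_flights: int = 3,
    h2: float = 0.8,
) -> SimulationScenario:
    """A reduced scenario with the same structure, for tests and examples."""
    envs = []
    h2_map = {}
    for k in range(n_environments):
        env_id = f"{2019 + k} Testfield"
        envs.append(
            EnvironmentSpec(
                env_id=env_id, location="Testfield", year=2019 + k,
                n_genotypes_present=n_genotypes, n_columns=10,
                yield_baseline=520.0 + 40.0 * ((k % 3) - 1),
            )
        )
        h2_map[env_id] = h2
    schedule = {
        envs[0].env_id: [
            Flight(date=d, camera="micasense")
            for d in _spread_flight_dates(envs[0].year, n_flights)
        ]
    }
    return SimulationScenario(
        n_genotypes=n_genotypes,
        n_markers=n_markers,
        environments=envs,
        h2_target_per_env=h2_map,
        flight_schedule=schedule,
        band_loading_profile=DEFAULT_BAND_LOADING,
        band_specific_sd=DEFAULT_BAND_SPECIFIC_SD,
        band_noise=DEFAULT_BAND_NOISE,
        band_baseline=DEFAULT_BAND_BASELINE,
        seed=int(seed),
    )
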