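"""Analysis campaigns: model comparison, band importance, flight timing, and
the minimal one-flight RGB/multispectral setup.

Every driver takes an :class:`AnalysisDataset` (kernels + BLUE tables, built
either from synthetic data via :func:`prepare_dataset` or from user tables)
and a :class:`~kernelgp.evaluation.CVConfig`, and returns an
:class:`ExperimentReport` whose cells hold the per-iteration CV metrics for
one point of the factor grid (model x M-matrix origin, band x origin,
flight date, camera setup).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import simulate
from .blup import ModelSpec, ModelTerm
from .evaluation import CVConfig, MetricsRecord, run_cv
from .kernels import BANDS, RGB_BANDS, Kernel, compute_G, compute_KE, compute_KM, filter_markers
from .simulate import SimulationScenario, growth_stage
from .trials import BlueTable, fit_blues, reflectance_blues

__all__ = [
    "AnalysisDataset",
    "ExperimentCell",
    "ExperimentReport",
    "prepare_dataset",
    "run_model_comparison",
    "run_band_importance",
    "run_timing_importance",
    "run_minimal_setup",
]

_S_JULY = 303

SINGLE_ENV_MODELS = ("G", "M", "G+M")
MULTI_ENV_MODELS = ("G", "M", "G+E", "G+M", "M+E", "G+M+E")


@dataclass
class ExperimentCell:
    keys: dict
    metrics: MetricsRecord | None = None
    note: str | None = None


@dataclass
class ExperimentReport:
    name: str
    cells: list[ExperimentCell] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = dict(c.keys)
            if c.metrics is not None:
                row.update(c.metrics.means)
                row["n_iterations"] = c.metrics.n_iterations
            row["note"] = c.note or ""
            rows.append(row)
        return pd.DataFrame(rows)

    def cell(self, **keys) -> ExperimentCell:
        for c in self.cells:
            if all(c.keys.get(k) == v for k, v in keys.items()):
                return c
        raise KeyError(f"no cell with {keys}")


@dataclass
class AnalysisDataset:
    """Everything the drivers need: kernels, BLUE tables, season metadata."""

    G: Kernel
    KE: Kernel
    env_blues: dict[str, BlueTable]                       # env -> yield BLUEs
    band_blues: dict[tuple[str, str], list[BlueTable]]    # (env, camera) -> tables
    season_windows: dict[str, tuple] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    _km_cache: dict = field(default_factory=dict, repr=False)

    @property
    def origins(self) -> list[tuple[str, str]]:
        return sorted(self.band_blues.keys())

    def km(self, origin: tuple[str, str], bands=None, dates=None) -> Kernel:
        key = (origin, tuple(sorted(bands)) if bands else None,
               tuple(sorted(str(d) for d in dates)) if dates else None)
        if key not in self._km_cache:
            self._km_cache[key] = compute_KM(
                self.band_blues[origin], band_subset=bands, date_subset=dates
            )
        return self._km_cache[key]

    def origin_dates(self, origin: tuple[str, str]) -> list[dt.date]:
        return sorted({t.date for t in self.band_blues[origin]})

    def origin_bands(self, origin: tuple[str, str]) -> list[str]:
        return sorted({t.band for t in self.band_blues[origin]})

    def response_single(self, env_id: str) -> pd.DataFrame:
        blue = self.env_blues[env_id]
        return pd.DataFrame(
            {"genotype": blue.values.index, "env_id": env_id,
             "y": blue.values.to_numpy()}
        )

    def response_multi(self) -> pd.DataFrame:
        return pd.concat(
            [self.response_single(e) for e in sorted(self.env_blues)],
            ignore_index=True,
        )

    def restrict_to_kernel(self, records: pd.DataFrame, kernel: Kernel) -> pd.DataFrame:
        keep = records["genotype"].astype(str).isin(set(kernel.ids))
        return records[keep].reset_index(drop=True)

    def model_spec(self, model: str, km: Kernel | None = None) -> ModelSpec:
        terms = []
        parts = model.split("+")
        if "G" in parts:
            terms.append(ModelTerm("G", self.G, "genotype"))
        if "M" in parts:
            if km is None:
                raise ValueError(f"model {model} needs a multispectral kernel")
            terms.append(ModelTerm("M", km, "genotype"))
        if "E" in parts:
            terms.append(ModelTerm("E", self.KE, "env_id"))
        if not terms:
            raise ValueError(f"unknown model {model!r}")
        return ModelSpec(terms)


def prepare_dataset(
    scenario: SimulationScenario,
    origins: list[tuple[str, str]] | None = None,
) -> AnalysisDataset:
    """Simulate a full study and fit everything the campaigns need.

    ``origins`` optionally restricts the (environment, camera) pairs for which
    reflectance BLUEs are fitted (they dominate run time).
    """
    markers = simulate.simulate_markers(scenario)
    truth = simulate.simulate_genetic_values(markers, scenario)
    plots = simulate.simulate_trials(truth, scenario)
    refl = simulate.simulate_reflectance(truth, scenario)

    filtered, audit = filter_markers(markers)
    G = compute_G(filtered)

    env_blues = {
        e.env_id: fit_blues(plots, "environment", "yield", scope_id=e.env_id)
        for e in scenario.environments
    }
    KE = compute_KE(list(env_blues.values()))

    all_origins = sorted(
        {(env_id, fl.camera)
         for env_id, fls in scenario.flight_schedule.items() for fl in fls}
    )
    wanted = origins if origins is not None else all_origins
    band_blues = {}
    for env_id, camera in wanted:
        band_blues[(env_id, camera)] = reflectance_blues(refl, env_id, camera=camera)

    seasons = {e.env_id: e.season_window for e in scenario.environments}
    return AnalysisDataset(
        G=G,
        KE=KE,
        env_blues=env_blues,
        band_blues=band_blues,
        season_windows=seasons,
        provenance={
            "seed": scenario.seed,
            "n_markers_kept": audit.n_kept,
            "n_genotypes": scenario.n_genotypes,
            "environments": [e.env_id for e in scenario.environments],
        },
    )


def _origin_label(origin: tuple[str, str]) -> str:
    return f"{origin[0]} [{origin[1]}]"


def _single_env_cell(dataset, model, origin, km, config) -> ExperimentCell:
    env_id = origin[0]
    records = dataset.response_single(env_id)
    if km is not None:
        records = dataset.restrict_to_kernel(records, km)
    spec = dataset.model_spec(model, km)
    metrics = run_cv(records, spec, config)
    return ExperimentCell(
        keys={"scenario": "single_environment", "model": model,
              "origin": _origin_label(origin), "env": env_id},
        metrics=metrics,
    )


def _multi_env_cell(dataset, model, origin, km, config) -> ExperimentCell:
    records = dataset.response_multi()
    if km is not None:
        records = dataset.restrict_to_kernel(records, km)
    spec = dataset.model_spec(model, km)
    metrics = run_cv(records, spec, config)
    return ExperimentCell(
        keys={"scenario": "multi_environment", "model": model,
              "origin": _origin_label(origin) if origin else ""},
        metrics=metrics,
    )


def run_model_comparison(
    dataset: AnalysisDataset,
    config: CVConfig,
    origins: list[tuple[str, str]] | None = None,
    scenarios: tuple[str, ...] = ("single_environment", "multi_environment"),
) -> ExperimentReport:
    """G / M / G+M on single-environment CV and the six model families on
    multi-environment CV, with each multispectral-kernel origin as a column."""
    origins = origins if origins is not None else dataset.origins
    report = ExperimentReport(
        name="model_comparison",
        provenance={"base_seed": config.base_seed, "n_iterations": config.n_iterations},
    )
    if "single_environment" in scenarios:
        cfg = CVConfig(scenario="single_environment",
                       n_iterations=config.n_iterations,
                       test_genotype_fraction=config.test_genotype_fraction,
                       base_seed=config.base_seed)
        for origin in origins:
            km = dataset.km(origin)
            for model in SINGLE_ENV_MODELS:
                try:
                    report.cells.append(
                        _single_env_cell(dataset, model, origin,
                                         km if "M" in model.split("+") else None, cfg)
                    )
                except Exception as exc:  # cell-level failure note
                    report.cells.append(ExperimentCell(
                        keys={"scenario": "single_environment", "model": model,
                              "origin": _origin_label(origin), "env": origin[0]},
                        note=f"failed: {exc}",
                    ))
    if "multi_environment" in scenarios:
        cfg = CVConfig(scenario="multi_environment",
                       n_iterations=config.n_iterations,
                       test_genotype_fraction=config.test_genotype_fraction,
                       n_test_environments=config.n_test_environments,
                       base_seed=config.base_seed)
        for model in MULTI_ENV_MODELS:
            with_m = "M" in model.split("+")
            model_origins = origins if with_m else [None]
            for origin in model_origins:
                km = dataset.km(origin) if with_m else None
                try:
                    report.cells.append(
                        _multi_env_cell(dataset, model, origin, km, cfg))
                except Exception as exc:
                    report.cells.append(ExperimentCell(
                        keys={"scenario": "multi_environment", "model": model,
                              "origin": _origin_label(origin) if origin else ""},
                        note=f"failed: {exc}",
                    ))
    return report


def run_band_importance(
    dataset: AnalysisDataset,
    config: CVConfig,
    origins: list[tuple[str, str]] | None = None,
    scenarios: tuple[str, ...] = ("single_environment", "multi_environment"),
    bands: tuple[str, ...] = BANDS,
) -> ExperimentReport:
    """Single-band multispectral kernels (all flight dates) through both CV
    scenarios, one cell per band x origin."""
    origins = origins if origins is not None else dataset.origins
    report = ExperimentReport(
        name="band_importance",
        provenance={"base_seed": config.base_seed, "n_iterations": config.n_iterations},
    )
    for origin in origins:
        available = set(dataset.origin_bands(origin))
        for band in bands:
            if band not in available:
                report.cells.append(ExperimentCell(
                    keys={"band": band, "origin": _origin_label(origin)},
                    note="band not available in this origin",
                ))
                continue
            km = dataset.km(origin, bands={band})
            if "single_environment" in scenarios:
                cfg = CVConfig(scenario="single_environment",
                               n_iterations=config.n_iterations,
                               base_seed=config.base_seed)
                cell = _single_env_cell(dataset, "M", origin, km, cfg)
                cell.keys["band"] = band
                report.cells.append(cell)
            if "multi_environment" in scenarios:
                cfg = CVConfig(scenario="multi_environment",
                               n_iterations=config.n_iterations,
                               n_test_environments=config.n_test_environments,
                               base_seed=config.base_seed)
                cell = _multi_env_cell(dataset, "M", origin, km, cfg)
                cell.keys["band"] = band
                report.cells.append(cell)
    return report


def run_timing_importance(
    dataset: AnalysisDataset,
    config: CVConfig,
    origins: list[tuple[str, str]] | None = None,
) -> ExperimentReport:
    """Single-date, all-band multispectral kernels on single-environment CV,
    ordered by flight date with a growth-stage annotation."""
    origins = origins if origins is not None else dataset.origins
    report = ExperimentReport(
        name="timing_importance",
        provenance={"base_seed": config.base_seed, "n_iterations": config.n_iterations},
    )
    cfg = CVConfig(scenario="single_environment", n_iterations=config.n_iterations,
                   base_seed=config.base_seed)
    for origin in origins:
        window = dataset.season_windows.get(origin[0])
        for date in dataset.origin_dates(origin):
            try:
                km = dataset.km(origin, dates={date})
                cell = _single_env_cell(dataset, "M", origin, km, cfg)
            except Exception as exc:
                cell = ExperimentCell(
                    keys={"origin": _origin_label(origin)}, note=f"failed: {exc}")
            cell.keys["date"] = date.isoformat()
            if window is not None:
                stage, frac = growth_stage(date, window)
                cell.keys["stage"] = stage
                cell.keys["stage_fraction"] = round(frac, 3)
            report.cells.append(cell)
    report.cells.sort(key=lambda c: (c.keys.get("origin", ""), c.keys.get("date", "")))
    return report


def plot_timing_profile(report: ExperimentReport, path) -> None:
    """Test-set prediction ability against flight date, colored by growth
    stage, one panel per origin (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_frame()
    df = df[df["note"] == ""]
    origins = sorted(df["origin"].unique())
    stage_colors = {"vegetative": "#74c476", "heading": "#fdae6b",
                    "grain_filling": "#efd469", "maturation": "#bcbddc"}
    fig, axes = plt.subplots(len(origins), 1, figsize=(7, 2.8 * len(origins)),
                             squeeze=False)
    for ax, origin in zip(axes.ravel(), origins):
        sub = df[df["origin"] == origin].sort_values("date")
        colors = [stage_colors.get(s, "gray") for s in sub["stage"]]
        ax.scatter(sub["date"], sub["rTST"], c=colors, zorder=3)
        ax.plot(sub["date"], sub["rTST"], color="0.6", lw=1, zorder=2)
        ax.set_title(origin)
        ax.set_ylabel("rTST")
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_band_heatmap(report: ExperimentReport, path) -> None:
    """Band x origin heatmap of test-set prediction ability (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.to_frame()
    df = df[df["note"] == ""]
    pivot = df.pivot_table(index="band", columns="origin", values="rTST")
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * pivot.shape[1],
                                    1.2 + 0.5 * pivot.shape[0]))
    im = ax.imshow(pivot.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=30, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            ax.text(j, i, f"{pivot.iat[i, j]:.2f}", ha="center", va="center",
                    color="white", fontsize=8)
    fig.colorbar(im, ax=ax, label="rTST")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


DEFAULT_SUITE_ORIGINS = (("2020 Vollebekk", "micasense"),
                         ("2021 Vollebekk", "phantom4"))


def run_headline_suite(
    seed: int,
    n_iterations: int = 50,
    origins: tuple[tuple[str, str], ...] = DEFAULT_SUITE_ORIGINS,
    scenario: SimulationScenario | None = None,
) -> dict[str, dict]:
    """One pass over the four campaigns on the default synthetic study.

    Simulates the 11-environment preset, restricts the reflectance work to
    ``origins`` (fitting band BLUEs dominates run time), and returns a flat
    mapping of headline quantities, each as ``{"value": float, "n": int}``
    where n is the number of CV iterations (or seeds/pairs) behind the value.
    Single-environment numbers are means over the origins; the
    multi-environment multispectral kernels come from the first origin.
    """
    scenario = scenario if scenario is not None else simulate.make_default_scenario(seed)
    dataset = prepare_dataset(scenario, origins=list(origins))
    cfg_s = CVConfig(scenario="single_environment", n_iterations=n_iterations,
                     base_seed=seed)
    cfg_m = CVConfig(scenario="multi_environment", n_iterations=n_iterations,
                     base_seed=seed)
    out: dict[str, dict] = {}

    def put(key, value, n):
        out[key] = {"value": float(round(float(value), 4)), "n": int(n)}

    # --- single-environment model comparison (per-origin mean) -------------
    singles: dict[str, list[float]] = {m: [] for m in SINGLE_ENV_MODELS}
    for origin in origins:
        km = dataset.km(origin)
        for model in SINGLE_ENV_MODELS:
            cell = _single_env_cell(
                dataset, model, origin, km if "M" in model.split("+") else None, cfg_s)
            singles[model].append(cell.metrics.means["rTST"])
    for model, vals in singles.items():
        put(f"single_env_rTST_{model.replace('+', '')}", np.mean(vals),
            n_iterations * len(origins))

    # --- multi-environment model families -----------------------------------
    m_origin = origins[0]
    km0 = dataset.km(m_origin)
    for model in MULTI_ENV_MODELS:
        km = km0 if "M" in model.split("+") else None
        cell = _multi_env_cell(dataset, model, m_origin if km is not None else None,
                               km, cfg_m)
        put(f"multi_env_rTST_{model.replace('+', '')}",
            cell.metrics.means["rTST"], n_iterations)

    # --- band importance (single-environment, per-origin mean) --------------
    for band in BANDS:
        vals = []
        for origin in origins:
            km = dataset.km(origin, bands={band})
            cell = _single_env_cell(dataset, "M", origin, km, cfg_s)
            vals.append(cell.metrics.means["rTST"])
        put(f"band_rTST_{band}", np.mean(vals), n_iterations * len(origins))

    # --- flight timing (first origin, grain filling vs post-maturity) -------
    timing = run_timing_importance(dataset, cfg_s, origins=[m_origin])
    by_stage: dict[str, list[float]] = {}
    for cell in timing.cells:
        if cell.metrics is None:
            continue
        by_stage.setdefault(cell.keys["stage"], []).append(cell.metrics.means["rTST"])
    for stage in ("grain_filling", "maturation"):
        if stage in by_stage:
            put(f"timing_rTST_{stage}", np.mean(by_stage[stage]),
                n_iterations * len(by_stage[stage]))

    # --- minimal July setup: five-band vs RGB kernels ------------------------
    minimal = run_minimal_setup(dataset, cfg_s, origins=list(origins))
    for setup in ("MS", "RGB"):
        vals = [c.metrics.means["rTST"] for c in minimal.cells
                if c.metrics is not None and c.keys.get("setup") == setup]
        if vals:
            put(f"minimal_rTST_{setup}", np.mean(vals), n_iterations * len(vals))
    return out


def run_minimal_setup(
    dataset: AnalysisDataset,
    config: CVConfig,
    origins: list[tuple[str, str]] | None = None,
) -> ExperimentReport:
    """One July flight per origin: full five-band kernel versus the simulated
    three-band RGB camera, on single-environment CV."""
    origins = origins if origins is not None else dataset.origins
    report = ExperimentReport(
        name="minimal_setup",
        provenance={"base_seed": config.base_seed, "n_iterations": config.n_iterations},
    )
    cfg = CVConfig(scenario="single_environment", n_iterations=config.n_iterations,
                   base_seed=config.base_seed)
    for k, origin in enumerate(origins):
        july = [d for d in dataset.origin_dates(origin) if d.month == 7]
        if not july:
            report.cells.append(ExperimentCell(
                keys={"origin": _origin_label(origin)},
                note="no July flight in this origin",
            ))
            continue
        rng = np.random.default_rng([int(config.base_seed) & 0x7FFFFFFF, _S_JULY, k])
        date = july[int(rng.integers(len(july)))]
        for setup, bands in (("MS", tuple(BANDS)), ("RGB", tuple(RGB_BANDS))):
            avail = set(dataset.origin_bands(origin))
            use = tuple(b for b in bands if b in avail)
            km = dataset.km(origin, bands=set(use), dates={date})
            cell = _single_env_cell(dataset, "M", origin, km, cfg)
            cell.keys.update({"setup": setup, "date": date.isoformat(),
                              "bands": "+".join(use)})
            report.cells.append(cell)
    return report
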