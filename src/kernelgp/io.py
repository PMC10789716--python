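"""Readers and writers for the tabular formats of the pipeline.

Conventions
-----------
* Marker matrix: CSV with genotypes as rows (first column ``genotype``) and
  markers as columns, calls in {0,1,2} or empty for missing; or a VCF whose
  biallelic GT fields are mapped to 0/1/2 (heterozygous -> 1, ``./.`` ->
  missing).  Multi-allelic sites are skipped with a logged count.
* Plot table: CSV with columns env_id, location, year, genotype, replicate,
  block, column, plus response columns — ``yield`` and/or wide reflectance
  columns named ``camera__YYYY-MM-DD__band``.
* Kernels: CSV with the id list as both header row and first column.
* Floats are written with 6 significant digits; round-tripping recovers
  values within 1e-6 relative.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import MetricsRecord
from .kernels import Kernel, MarkerMatrix
from .simulate import EnvironmentSpec, Flight, SimulationScenario
from .trials import PLOT_COLUMNS, BlueTable, parse_response_name, validate_plot_table

log = logging.getLogger("kernelgp")

FLOAT_FMT = "%.6g"

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "read_plot_table",
    "write_plot_table",
    "read_kernel",
    "write_kernel",
    "write_blue_table",
    "read_blue_table",
    "write_metrics",
    "write_report",
    "scenario_to_yaml",
    "scenario_from_yaml",
    "provenance_block",
]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def read_marker_table(path, fmt: str | None = None) -> MarkerMatrix:
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".bcf") or str(path).endswith(
            ".vcf.gz") else "csv"
    if fmt == "csv":
        return _read_marker_csv(path)
    if fmt == "vcf":
        return _read_marker_vcf(path)
    raise ValueError(f"unknown marker format {fmt!r}")


def _read_marker_csv(path: Path) -> MarkerMatrix:
    df = pd.read_csv(path, index_col=0)
    calls = df.to_numpy(dtype=float)
    bad = ~(np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: call for genotype {df.index[i]!r}, marker "
            f"{df.columns[j]!r} is {calls[i, j]!r}, not in {{0,1,2,NA}}"
        )
    return MarkerMatrix(
        genotype_ids=[str(g) for g in df.index],
        marker_ids=[str(m) for m in df.columns],
        calls=calls,
    )


def _read_marker_vcf(path: Path) -> MarkerMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        # default cyvcf2 coding: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        hom_alt = 2.0 if getattr(vcf, "gts012", False) else 3.0
        calls = np.select([gt == 0, gt == 1, gt == hom_alt], [0.0, 1.0, 2.0],
                          default=np.nan)
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        columns.append(calls)
    if n_skipped:
        log.info("skipped %d non-biallelic sites in %s", n_skipped, path)
    if not columns:
        raise ParseError(f"{path}: no biallelic records")
    return MarkerMatrix(samples, marker_ids, np.column_stack(columns))


def write_marker_table(markers: MarkerMatrix, path) -> None:
    markers.to_frame().to_csv(path, index_label="genotype", float_format="%.0f")


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------

def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col in df.columns:
        if col in PLOT_COLUMNS or col == "yield":
            continue
        parsed = parse_response_name(str(col))
        if parsed is None and not str(col).startswith("Unnamed"):
            raise ParseError(
                f"{path}: column {col!r} is neither a design column, 'yield', "
                f"nor a camera__date__band response"
            )
    validate_plot_table(df)
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# kernels and BLUEs
# ---------------------------------------------------------------------------

def write_kernel(kernel: Kernel, path) -> None:
    # 8 significant digits: keeps the entrywise 1e-6 round-trip contract for
    # kernel entries above 1 (e.g. G diagonals at m/n)
    kernel.to_frame().to_csv(path, index_label="id", float_format="%.8g")


def read_kernel(path, entity_kind: str = "genotype") -> Kernel:
    df = pd.read_csv(path, index_col=0)
    ids = [str(i) for i in df.index]
    if ids != [str(c) for c in df.columns]:
        raise ParseError(f"{path}: kernel row and column ids differ")
    vals = df.to_numpy(dtype=float)
    vals = 0.5 * (vals + vals.T)  # 6-digit writing can break exact symmetry
    return Kernel(entity_kind=entity_kind, ids=ids, values=vals,
                  provenance={"path": str(path)})


def write_blue_table(blue: BlueTable, path) -> None:
    df = pd.DataFrame({
        "genotype": blue.values.index,
        "value": blue.values.to_numpy(),
        "n_obs": blue.n_obs.reindex(blue.values.index).to_numpy(),
    })
    df["scope"] = blue.scope
    df["scope_id"] = blue.scope_id or ""
    df["response"] = blue.response_name
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_blue_table(path) -> BlueTable:
    df = pd.read_csv(path)
    for col in ("genotype", "value", "scope", "response"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    values = pd.Series(df["value"].to_numpy(), index=df["genotype"].astype(str))
    n_obs = pd.Series(
        df["n_obs"].to_numpy() if "n_obs" in df else np.ones(len(df)),
        index=values.index,
    )
    scope_id = df["scope_id"].iloc[0] if "scope_id" in df and len(df) else None
    if isinstance(scope_id, float) and np.isnan(scope_id):
        scope_id = None
    return BlueTable(
        scope=str(df["scope"].iloc[0]),
        scope_id=str(scope_id) if scope_id not in (None, "") else None,
        response_name=str(df["response"].iloc[0]),
        values=values,
        n_obs=n_obs,
    )


# ---------------------------------------------------------------------------
# metrics and reports
# ---------------------------------------------------------------------------

def write_metrics(metrics: MetricsRecord, path) -> None:
    metrics.table.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_report(report, path) -> None:
    """ExperimentReport, MetricsRecord, BlueTable or Kernel -> CSV."""
    if isinstance(report, MetricsRecord):
        write_metrics(report, path)
    elif isinstance(report, Kernel):
        write_kernel(report, path)
    elif isinstance(report, BlueTable):
        write_blue_table(report, path)
    elif hasattr(report, "to_frame"):
        report.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    else:
        raise TypeError(f"do not know how to write {type(report).__name__}")


# ---------------------------------------------------------------------------
# scenario config
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: SimulationScenario, path) -> None:
    def encode(obj):
        if isinstance(obj, dt.date):
            return obj.isoformat()
        if isinstance(obj, tuple):
            return [encode(x) for x in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [encode(x) for x in obj]
        if dataclasses.is_dataclass(obj):
            return encode(dataclasses.asdict(obj))
        return obj

    doc = encode(dataclasses.asdict(scenario))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    envs = []
    for e in doc.pop("environments"):
        e["season_window"] = tuple(
            dt.date.fromisoformat(d) if isinstance(d, str) else d
            for d in e["season_window"]
        )
        envs.append(EnvironmentSpec(**e))
    schedule = {}
    for env_id, flights in (doc.pop("flight_schedule") or {}).items():
        schedule[env_id] = [
            Flight(date=dt.date.fromisoformat(f["date"]) if isinstance(f["date"], str)
                   else f["date"],
                   camera=f["camera"], bands=tuple(f["bands"]))
            for f in flights
        ]
    doc["maf_range"] = tuple(doc.get("maf_range", (0.01, 0.5)))
    return SimulationScenario(environments=envs, flight_schedule=schedule, **doc)


def provenance_block(config: dict, seed: int) -> dict:
    """Reproducibility stamp written next to every CLI output."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str)
    return {
        "version": __version__,
        "seed": int(seed),
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "config": config,
    }
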