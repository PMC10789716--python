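"""Relationship kernels: genomic (G), environmental (K_E) and multispectral (K_M).

All three kernels are scaled cross-products ``A A' / n`` of a column-scaled
rectangular matrix:

* G: rows = genotypes, columns = quality-checked biallelic markers coded 0/2
  (heterozygotes treated as missing), divided by the number of genotypes.
* K_E: rows = environments, columns = per-genotype yield BLUEs (genotypes seen
  in at least two environments), divided by the number of environments.
* K_M: rows = genotypes of one environment/camera, columns = per-genotype BLUEs
  of each reflectance band at each flight date, divided by the number of
  genotypes.  Band and date subsets give the single-band, single-date and
  RGB-camera variants.

Column scaling is mean 0 / population standard deviation 1, with missing cells
imputed by the column mean (neutral after centering) and zero-variance columns
set identically to zero and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "Kernel",
    "MarkerFilterAudit",
    "filter_markers",
    "scale_columns",
    "compute_G",
    "compute_KE",
    "compute_KM",
    "align_kernel",
]

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8

BANDS = ("red", "green", "blue", "RedEdge", "NIR")
RGB_BANDS = ("red", "green", "blue")


class KernelError(ValueError):
    pass


@dataclass
class MarkerMatrix:
    """Genotype x marker call matrix; calls in {0, 1, 2} with NaN for missing."""

    genotype_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # float array, NaN = missing

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != m:
            raise KernelError("id lists do not match call-matrix dimensions")
        if len(set(self.genotype_ids)) != n or len(set(self.marker_ids)) != m:
            raise KernelError("duplicate genotype or marker ids")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise KernelError(
                f"call at genotype {self.genotype_ids[bad[0]]!r}, marker "
                f"{self.marker_ids[bad[1]]!r} is not in {{0,1,2,NA}}"
            )

    @property
    def n_genotypes(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.genotype_ids, columns=self.marker_ids)


@dataclass
class Kernel:
    """Symmetric similarity matrix over an ordered id list of one entity kind."""

    entity_kind: str  # "genotype" | "environment"
    ids: list[str]
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise KernelError("kernel matrix does not match id list")
        if len(set(self.ids)) != n:
            raise KernelError("duplicate kernel ids")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL * max(1.0, float(np.max(np.abs(self.values), initial=0.0))):
            raise KernelError(f"kernel not symmetric (max asymmetry {asym:.3g})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue_ratio(self) -> float:
        w = np.linalg.eigvalsh(self.values)
        top = max(w[-1], 0.0)
        return float(w[0] / top) if top > 0 else 0.0

    def loading_factor(self, tol: float = 1e-10) -> np.ndarray:
        """L with K = L L' (eigen square root, near-zero modes dropped).

        Cached after the first call (kernels are treated as immutable).
        """
        cached = self.__dict__.get("_loading_cache")
        if cached is not None and cached[0] == tol:
            return cached[1]
        w, U = np.linalg.eigh(self.values)
        top = max(float(w[-1]), 0.0)
        keep = w > tol * max(top, 1.0) if top > 0 else w > tol
        if not keep.any():
            L = np.zeros((self.n, 1))
        else:
            L = U[:, keep] * np.sqrt(w[keep])
        self.__dict__["_loading_cache"] = (tol, L)
        return L

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class MarkerFilterAudit:
    """Per-marker record of the quality-control decisions."""

    table: pd.DataFrame  # marker, maf, missing_fraction, n_het_recoded, kept, reason

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())


def filter_markers(
    raw: MarkerMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[MarkerMatrix, MarkerFilterAudit]:
    """Marker quality control.

    Heterozygous calls (1) are recoded to missing first; then markers with a
    missing fraction >= ``max_missing`` or minor allele frequency <= ``min_maf``
    (computed on the non-missing {0,2} calls) are removed.
    """
    if raw.n_markers == 0 or raw.n_genotypes == 0:
        raise KernelError("empty marker matrix")
    calls = raw.calls.copy()
    het = calls == 1.0
    calls[het] = np.nan
    n = raw.n_genotypes
    missing_frac = np.isnan(calls).sum(axis=0) / n
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(calls, axis=0) / 2.0  # frequency of the "2" allele
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf = np.where(np.isnan(maf), 0.0, maf)
    # epsilon guards keep knife-edge fractions (e.g. an exact 0.05) on the
    # side the thresholds intend despite binary rounding
    eps = 1e-9
    keep = (missing_frac < max_missing - eps) & (maf > min_maf + eps)
    reasons = np.select(
        [missing_frac >= max_missing - eps, maf <= min_maf + eps],
        ["missing_fraction", "maf"],
        default="",
    )
    # a marker can fail both; report both
    both = (missing_frac >= max_missing) & (maf <= min_maf)
    reasons = np.where(both, "missing_fraction+maf", reasons)
    audit = MarkerFilterAudit(
        pd.DataFrame(
            {
                "marker": raw.marker_ids,
                "maf": maf,
                "missing_fraction": missing_frac,
                "n_het_recoded": het.sum(axis=0),
                "kept": keep,
                "reason": reasons,
            }
        )
    )
    if not keep.any():
        raise KernelError("marker filtering removed all markers")
    kept_ids = [m for m, k in zip(raw.marker_ids, keep) if k]
    return MarkerMatrix(list(raw.genotype_ids), kept_ids, calls[:, keep]), audit


def scale_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise standardization with mean imputation of missing cells.

    Returns ``(scaled, degenerate_flags)``; zero-variance columns come back as
    all zeros with their flag set.  The standard deviation uses the population
    (1/n) denominator.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise KernelError("need a 2-D matrix with at least 2 rows")
    X = X.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)  # all-missing column
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    centered = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    degenerate = sd <= 1e-12 * (np.abs(col_mean) + 1.0)
    sd_safe = np.where(degenerate, 1.0, sd)
    out = centered / sd_safe
    out[:, degenerate] = 0.0
    return out, degenerate


def compute_G(markers: MarkerMatrix) -> Kernel:
    """Genomic relationship matrix W W' / n_genotypes from column-scaled calls."""
    if markers.n_genotypes < 2:
        raise KernelError("need at least 2 genotypes")
    W, degenerate = scale_columns(markers.calls)
    G = (W @ W.T) / markers.n_genotypes
    return Kernel(
        entity_kind="genotype",
        ids=list(markers.genotype_ids),
        values=G,
        provenance={
            "type": "G",
            "n_markers": markers.n_markers,
            "n_degenerate_columns": int(degenerate.sum()),
        },
    )


def _blue_series(table) -> pd.Series:
    # BlueTable duck-typing: anything with .values_by_genotype() or a Series
    if hasattr(table, "values_by_genotype"):
        return table.values_by_genotype()
    return pd.Series(table)


def compute_KE(env_blues: Sequence, min_environments: int = 2) -> Kernel:
    """Environmental covariance kernel P P' / n_environments.

    ``env_blues`` is a list of environment-scope yield BLUE tables.  P has one
    row per environment and one column per genotype seen in at least two
    environments; missing cells are mean-imputed and columns scaled.
    """
    if len(env_blues) < 2:
        raise KernelError("need at least 2 environments")
    series = {}
    for t in env_blues:
        env = getattr(t, "scope_id", None) or getattr(t, "name", None)
        if env is None:
            raise KernelError("environment BLUE table without an environment id")
        series[env] = _blue_series(t)
    P_df = pd.DataFrame(series).T  # environments x genotypes
    presence = P_df.notna().sum(axis=0)
    keep = presence[presence >= min_environments].index
    if len(keep) == 0:
        raise KernelError("no genotype is present in >= 2 environments")
    P_df = P_df[keep]
    P, _ = scale_columns(P_df.to_numpy())
    n_env = P_df.shape[0]
    K = (P @ P.T) / n_env
    return Kernel(
        entity_kind="environment",
        ids=[str(e) for e in P_df.index],
        values=K,
        provenance={"type": "KE", "n_genotypes_used": int(len(keep))},
    )


def compute_KM(
    band_blues: Sequence,
    band_subset: Iterable[str] | None = None,
    date_subset: Iterable | None = None,
) -> Kernel:
    """Multispectral kernel C C' / n_genotypes for one environment and camera.

    Each element of ``band_blues`` is a reflectance BLUE table carrying
    ``band``, ``date``, ``env_id`` and ``camera`` attributes.  C has genotypes
    as rows and one column per retained (band, date) BLUE vector.
    """
    if not band_blues:
        raise KernelError("no reflectance BLUE tables supplied")
    envs = {getattr(t, "env_id", None) for t in band_blues}
    cams = {getattr(t, "camera", None) for t in band_blues}
    if len(envs) != 1 or len(cams) != 1:
        raise KernelError("K_M requires BLUEs from a single environment and camera")
    env_id, camera = envs.pop(), cams.pop()

    available_bands = {t.band for t in band_blues}
    available_dates = {t.date for t in band_blues}
    bands = set(band_subset) if band_subset is not None else available_bands
    dates = set(date_subset) if date_subset is not None else available_dates
    missing_bands = bands - available_bands
    missing_dates = dates - available_dates
    selected = [t for t in band_blues if t.band in bands and t.date in dates]
    if not selected:
        raise KernelError(
            f"empty band/date selection for K_M ({env_id}/{camera}): "
            f"missing bands {sorted(missing_bands)}, missing dates "
            f"{sorted(str(d) for d in missing_dates)}"
        )
    cols = {f"{t.camera}__{t.date}__{t.band}": _blue_series(t) for t in selected}
    C_df = pd.DataFrame(cols)
    C, _ = scale_columns(C_df.to_numpy())
    n_geno = C_df.shape[0]
    if n_geno < 2:
        raise KernelError("need at least 2 genotypes for K_M")
    K = (C @ C.T) / n_geno
    return Kernel(
        entity_kind="genotype",
        ids=[str(g) for g in C_df.index],
        values=K,
        provenance={
            "type": "KM",
            "env": env_id,
            "camera": camera,
            "bands": sorted(bands & available_bands),
            "dates": sorted(str(d) for d in (dates & available_dates)),
            "n_columns": len(cols),
        },
    )


def align_kernel(kernel: Kernel, ids: Sequence[str]) -> Kernel:
    """Principal sub-kernel in the requested id order."""
    pos = {g: i for i, g in enumerate(kernel.ids)}
    unknown = [g for g in ids if g not in pos]
    if unknown:
        raise KernelError(f"ids not present in kernel: {unknown}")
    idx = np.array([pos[g] for g in ids], dtype=int)
    return Kernel(
        entity_kind=kernel.entity_kind,
        ids=list(ids),
        values=kernel.values[np.ix_(idx, idx)],
        provenance=dict(kernel.provenance),
    )
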