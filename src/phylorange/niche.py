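"""Niche-breadth and dispersal predictors.

Computes the five per-species predictors of the comparative analysis from
upstream raw inputs: climate niche breadth (PCA of bioclimatic variables +
one-class-SVM hypervolumes on the first four axes, with optional capping of
occupied cells), diet niche breadth (Faith's PD over host-plant genera),
habitat niche breadth (count of broad habitat types used for reproduction),
a wingspan index, and the ordinal dispersal-tendency class.  Also includes
occurrence-record cleaning and environmental-grid aggregation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from . import phylo

__all__ = [
    "HABITAT_TYPES",
    "PCAProjection",
    "HypervolumeModel",
    "clean_occurrences",
    "aggregate_grid",
    "env_pca_project",
    "svm_hypervolume",
    "climate_niche_breadth",
    "diet_niche_breadth",
    "habitat_niche_breadth",
    "wingspan_index",
    "dispersal_class",
]

#: The seven broad reproductive habitat types.
HABITAT_TYPES = (
    "wetlands",
    "sparsely_vegetated_land",
    "grasslands",
    "shrubland",
    "forest",
    "mixed_cultivated_land",
    "arable_land",
)

BIOCLIM = [f"bio{i}" for i in range(1, 20)]

MAX_UNCERTAINTY_M = 10_000.0
MIN_YEAR = 1980
MIN_CELLS = 5  # below this, hypervolumes are imputed


def clean_occurrences(records: pd.DataFrame) -> pd.DataFrame:
    """Filter raw occurrence records.

    Removes exact duplicate (species, lon, lat) rows, records with zero
    longitude or latitude, coordinate uncertainty above 10 km, and records
    collected before 1980.  Row order of survivors is preserved.  Missing
    uncertainty or year values are retained (the filter only removes rows
    that demonstrably violate a rule).
    """
    required = ["species", "lon", "lat"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise KeyError(f"occurrence table is missing columns: {missing}")
    records = records.copy()
    for col in ("lon", "lat", "year", "uncertainty_m"):
        if col in records.columns and not np.issubdtype(records[col].dtype, np.number):
            converted = pd.to_numeric(records[col], errors="coerce")
            bad = records.index[converted.isna() & records[col].notna()]
            if len(bad):
                raise ValueError(f"unparseable {col!r} values at rows {bad.tolist()[:5]}")
            records[col] = converted
    out = records
    bad_lon = (out["lon"] < -180) | (out["lon"] > 180)
    bad_lat = (out["lat"] < -90) | (out["lat"] > 90)
    if bool(bad_lon.any()) or bool(bad_lat.any()):
        rows = out.index[bad_lon | bad_lat].tolist()
        raise ValueError(f"coordinates out of range at rows {rows[:5]}")
    keep = (out["lon"] != 0) & (out["lat"] != 0)
    if "uncertainty_m" in out.columns:
        keep &= ~(out["uncertainty_m"] > MAX_UNCERTAINTY_M)
    if "year" in out.columns:
        keep &= ~(out["year"] < MIN_YEAR)
    out = out[keep]
    return out[~out.duplicated(subset=["species", "lon", "lat"])]


def _grid_resolution(values: np.ndarray) -> float:
    """Infer the grid step from sorted unique coordinates."""
    uniq = np.unique(values)
    if len(uniq) < 2:
        return 1.0
    steps = np.diff(uniq)
    return float(np.min(steps[steps > 1e-12]))


def aggregate_grid(fine: pd.DataFrame, factor: int, resolution: Optional[float] = None) -> pd.DataFrame:
    """Aggregate a fine environmental grid to a coarser one by block means.

    ``fine`` holds one row per cell with ``lon``/``lat`` cell centres and the
    19 bioclimatic columns.  Each block of ``factor x factor`` fine cells is
    collapsed to its latitude-weighted mean (weights ``cos(latitude)`` of the
    fine-cell centres, i.e. the area-weighted mean on a geographic grid);
    missing fine cells are simply absent from both sums.  The coarse cell
    centre is the centre of the block footprint.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    cols = [c for c in BIOCLIM if c in fine.columns]
    if not cols:
        raise KeyError("no bioclimatic columns (bio1..bio19) in the grid")
    res = resolution if resolution is not None else _grid_resolution(fine["lon"].to_numpy())
    lon0 = float(fine["lon"].min()) - res / 2.0
    lat0 = float(fine["lat"].min()) - res / 2.0
    ix = np.round((fine["lon"].to_numpy() - res / 2.0 - lon0) / res).astype(int)
    iy = np.round((fine["lat"].to_numpy() - res / 2.0 - lat0) / res).astype(int)
    if not (np.allclose(lon0 + (ix + 0.5) * res, fine["lon"], atol=res * 1e-6)
            and np.allclose(lat0 + (iy + 0.5) * res, fine["lat"], atol=res * 1e-6)):
        raise ValueError("cell centres do not lie on a regular grid of the given resolution")
    w = np.cos(np.deg2rad(fine["lat"].to_numpy()))
    block = pd.DataFrame({"bx": ix // factor, "by": iy // factor})
    data = fine[cols].multiply(w, axis=0)
    data[["bx", "by"]] = block
    sums = data.groupby(["bx", "by"], sort=True).sum()
    wsum = pd.Series(w).groupby([block["bx"], block["by"]]).sum()
    coarse = sums[cols].div(wsum, axis=0).reset_index()
    cres = res * factor
    coarse["lon"] = lon0 + (coarse.pop("bx") + 0.5) * cres
    coarse["lat"] = lat0 + (coarse.pop("by") + 0.5) * cres
    return coarse[["lon", "lat"] + cols]


@dataclass
class PCAProjection:
    """Centring/scaling constants and the 4-axis loading matrix."""

    mean: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # (n_vars, 4), orthonormal columns
    explained_variance: np.ndarray
    n_fitted: int
    columns: list[str]

    def project(self, grid: pd.DataFrame) -> np.ndarray:
        """4-D principal-component scores for arbitrary grid cells."""
        Z = (grid[self.columns].to_numpy(dtype=float) - self.mean) / self.scale
        return Z @ self.loadings


def env_pca_project(grid: pd.DataFrame, n_sample: int = 10_000, seed: int = 0) -> PCAProjection:
    """Fit a 4-axis PCA of the bioclimatic variables on a random cell sample.

    Variables are centred and scaled to unit variance on the sample before
    the eigendecomposition (the 19 variables mix units).  Scores for any
    cell are obtained through :meth:`PCAProjection.project`.  Sign
    convention: each loading vector's largest-magnitude entry is positive.
    """
    cols = [c for c in BIOCLIM if c in grid.columns]
    if len(cols) == 0:
        raise KeyError("no bioclimatic columns (bio1..bio19) in the grid")
    complete = grid[cols].dropna()
    rng = np.random.default_rng(seed)
    if len(complete) > n_sample:
        idx = rng.choice(len(complete), size=n_sample, replace=False)
        sample = complete.to_numpy(dtype=float)[np.sort(idx)]
    else:
        sample = complete.to_numpy(dtype=float)
    mean = sample.mean(axis=0)
    scale = sample.std(axis=0, ddof=1)
    constant = [cols[i] for i in np.flatnonzero(scale < 1e-12)]
    if constant:
        raise ValueError(f"constant variables cannot be scaled: {constant}")
    Z = (sample - mean) / scale
    # SVD of the standardized sample: columns of V are the loading vectors
    _, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:4].T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(4)])
    loadings = loadings * flip
    var = (svals[:4] ** 2) / (len(sample) - 1)
    return PCAProjection(
        mean=mean, scale=scale, loadings=loadings,
        explained_variance=var, n_fitted=len(sample), columns=cols,
    )


class InsufficientPointsError(ValueError):
    """Fewer than the minimum number of distinct points for a hypervolume."""


@dataclass
class HypervolumeModel:
    """A fitted one-class-SVM niche boundary and its Monte-Carlo volume."""

    volume: float
    nu: float
    gamma: float
    n_points: int
    mc_samples: int
    seed: int
    svm: OneClassSVM


def svm_hypervolume(
    scores: np.ndarray,
    nu: float = 0.05,
    gamma: Optional[float] = None,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> HypervolumeModel:
    """Estimate the niche hypervolume of a 4-D point cloud.

    A one-class SVM with Gaussian kernel is fitted to the points; the
    enclosed volume is estimated by uniform Monte-Carlo sampling of the
    bounding box expanded by one kernel lengthscale per side (volume = box
    volume x fraction of samples classified inside).  When ``gamma`` is not
    given it is set adaptively so the kernel lengthscale is twice the mean
    point spacing ``(bbox_volume / n)^(1/d)``, which keeps volume estimates
    scale-equivariant and close to unbiased for compact uniform clouds; the
    same adaptivity bounds the box-to-volume ratio, so a fixed
    ``mc_samples`` yields roughly uniform relative precision across scales.
    Deterministic for a fixed seed.
    """
    pts = np.unique(np.asarray(scores, dtype=float), axis=0)
    if pts.ndim != 2:
        raise ValueError("scores must be a 2-D point matrix")
    n, d = pts.shape
    if n < MIN_CELLS:
        raise InsufficientPointsError(
            f"need >= {MIN_CELLS} distinct points for a hypervolume, got {n}"
        )
    span = pts.max(axis=0) - pts.min(axis=0)
    bbox = float(np.prod(np.maximum(span, 1e-12)))
    if gamma is None:
        spacing = (bbox / n) ** (1.0 / d)
        gamma = 1.0 / (2.0 * (2.0 * spacing) ** 2)
    ell = 1.0 / np.sqrt(2.0 * gamma)
    svm = OneClassSVM(nu=nu, gamma=gamma).fit(pts)
    lo = pts.min(axis=0) - ell
    hi = pts.max(axis=0) + ell
    box = float(np.prod(hi - lo))
    n_mc = int(mc_samples)
    rng = np.random.default_rng(seed)
    inside = 0
    chunk = 200_000
    for start in range(0, n_mc, chunk):
        m = min(chunk, n_mc - start)
        samp = rng.uniform(lo, hi, size=(m, d))
        inside += int((svm.predict(samp) == 1).sum())
    return HypervolumeModel(
        volume=box * inside / n_mc, nu=nu, gamma=float(gamma),
        n_points=n, mc_samples=n_mc, seed=seed, svm=svm,
    )


def _occupied_cells(occ: pd.DataFrame, grid: pd.DataFrame, resolution: float) -> pd.DataFrame:
    """Map occurrences to the distinct grid cells containing them.

    Cell membership uses half-open intervals [west, east) x [south, north)
    around each cell centre; occurrences falling in cells absent from the
    grid are dropped.
    """
    gx = np.floor(grid["lon"].to_numpy() / resolution).astype(np.int64)
    gy = np.floor(grid["lat"].to_numpy() / resolution).astype(np.int64)
    cell_row = {key: i for i, key in enumerate(zip(gx.tolist(), gy.tolist()))}
    ox = np.floor(occ["lon"].to_numpy() / resolution).astype(np.int64)
    oy = np.floor(occ["lat"].to_numpy() / resolution).astype(np.int64)
    rows = sorted({cell_row[k] for k in zip(ox.tolist(), oy.tolist()) if k in cell_row})
    return grid.iloc[rows]


def climate_niche_breadth(
    occurrences: pd.DataFrame,
    grid: pd.DataFrame,
    pca: PCAProjection,
    resolution: float,
    cap: Optional[int] = None,
    n_replicates: int = 10,
    seed: int = 0,
    nu: float = 0.05,
    gamma: Optional[float] = None,
) -> pd.DataFrame:
    """Per-species climate-niche hypervolumes from cleaned occurrences.

    Each species' occurrences are snapped to distinct grid cells whose 4-D
    PCA scores feed :func:`svm_hypervolume`.  With ``cap=None`` a single
    unconstrained volume per species is returned (column ``climate_nb``);
    with a cap (e.g. 50 cells), ``n_replicates`` volumes are computed per
    species from capped random subsamples without replacement (columns
    ``climate_nb_rep1..``; species at or under the cap keep identical
    volumes across replicates).  Species occupying fewer than five cells
    (including zero occurrences) are flagged and assigned the minimum volume
    computed among the remaining species in the same run (per replicate in
    capped mode).
    """
    if "species" not in occurrences.columns:
        raise KeyError("occurrence table needs a 'species' column")
    cell_scores: dict[str, np.ndarray] = {}
    for sp, block in occurrences.groupby("species", sort=True):
        cells = _occupied_cells(block, grid, resolution)
        cell_scores[sp] = pca.project(cells) if len(cells) else np.empty((0, 4))

    species = sorted(cell_scores)
    n_cols = n_replicates if cap is not None else 1
    cols = (
        [f"climate_nb_rep{k + 1}" for k in range(n_replicates)]
        if cap is not None
        else ["climate_nb"]
    )
    values = pd.DataFrame(np.nan, index=pd.Index(species, name="species"), columns=cols)
    flagged = pd.Series(False, index=values.index, name="imputed")
    for sp in species:
        scores = cell_scores[sp]
        if len(np.unique(scores, axis=0)) < MIN_CELLS:
            flagged[sp] = True
            continue
        # Seeds are derived from the run seed and the cell-set content, so
        # two species with identical cell sets get identical volumes.
        crc = zlib.crc32(np.ascontiguousarray(scores).tobytes())
        for k in range(n_cols):
            sub = scores
            if cap is not None and len(scores) > cap:
                rng_k = np.random.default_rng([seed, crc, k])
                pick = rng_k.choice(len(scores), size=cap, replace=False)
                sub = scores[np.sort(pick)]
            elif cap is not None and k > 0:
                values.iloc[values.index.get_loc(sp), k] = values.iloc[
                    values.index.get_loc(sp), 0
                ]
                continue
            hv = svm_hypervolume(
                sub, nu=nu, gamma=gamma,
                seed=int((seed + crc + 7919 * k) % (2**31 - 1)),
            )
            values.iloc[values.index.get_loc(sp), k] = hv.volume
    if flagged.all():
        raise ValueError("no species has enough occupied cells to compute any hypervolume")
    minima = values.loc[~flagged].min(axis=0)
    values.loc[flagged, :] = minima.to_numpy()
    values["imputed"] = flagged
    return values


def diet_niche_breadth(
    host_table: Mapping[str, Iterable[str]], host_tree
) -> pd.Series:
    """Faith's PD of each species' host-plant genus set on the host tree."""
    tips = set(phylo.tip_labels(host_tree))
    out = {}
    for sp in sorted(host_table):
        genera = set(host_table[sp])
        if not genera:
            raise ValueError(f"species {sp!r} has an empty host-genus set")
        missing = sorted(genera - tips)
        if missing:
            raise KeyError(f"species {sp!r}: genera absent from host tree: {missing}")
        out[sp] = phylo.faith_pd(host_tree, genera)
    return pd.Series(out, name="diet_nb")


def habitat_niche_breadth(habitat_table: Mapping[str, Iterable[str]]) -> pd.Series:
    """Number of distinct broad habitat types used for reproduction (1..7)."""
    out = {}
    for sp in sorted(habitat_table):
        types = set(habitat_table[sp])
        if not types:
            raise ValueError(f"species {sp!r} has no habitat types listed")
        unknown = sorted(types - set(HABITAT_TYPES))
        if unknown:
            raise ValueError(f"species {sp!r}: unknown habitat types {unknown}")
        out[sp] = len(types)
    return pd.Series(out, name="habitat_nb")


def wingspan_index(records: pd.DataFrame) -> pd.Series:
    """Wingspan (mm) per species from per-source min/max measurements.

    Per source the geometric mean ``sqrt(min * max)`` is taken; per species
    these are averaged arithmetically across sources.  If any source reports
    female-specific values, only female-specific sources are used (female
    size is what matters for colonisation).  ``sex_scope`` is ``"female"``
    or ``"both"``.
    """
    required = ["species", "min_mm", "max_mm"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise KeyError(f"wingspan table is missing columns: {missing}")
    bad = records.index[
        (records["min_mm"] <= 0) | (records["min_mm"] > records["max_mm"])
    ].tolist()
    if bad:
        raise ValueError(f"invalid wingspan records (need 0 < min <= max) at rows {bad[:5]}")
    recs = records.copy()
    recs["g"] = np.sqrt(recs["min_mm"] * recs["max_mm"])
    out = {}
    for sp, block in recs.groupby("species", sort=True):
        if "sex_scope" in block.columns and (block["sex_scope"] == "female").any():
            block = block[block["sex_scope"] == "female"]
        out[sp] = float(block["g"].mean())
    return pd.Series(out, name="wingspan_mm")


_CLASS_LABELS = {"sedentary": 1, "moderately_mobile": 2, "dispersive": 3}


def dispersal_class(raw) -> int:
    """Map a nine-level dispersal score or a class label to the ordinal 1..3.

    Levels 1-3 -> 1 (sedentary), 4-6 -> 2 (moderately mobile), 7-9 -> 3
    (dispersive); the three class labels pass through.
    """
    if isinstance(raw, str):
        key = raw.strip().lower().replace(" ", "_")
        if key not in _CLASS_LABELS:
            raise ValueError(f"unknown dispersal label {raw!r}")
        return _CLASS_LABELS[key]
    level = int(raw)
    if level != raw or not 1 <= level <= 9:
        raise ValueError(f"dispersal score must be an integer in 1..9, got {raw!r}")
    return (level - 1) // 3 + 1
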