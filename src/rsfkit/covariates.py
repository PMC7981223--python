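"""Covariate derivation for resource-selection models.

Everything a use-availability design needs from rasters and vectors: terrain
metrics (ruggedness, northness, slope) from a DEM, circular moving-window
(focal) smoothing at candidate radii, Euclidean distance grids to vector
features, exponential distance decay, standardization, a Pearson
collinearity screen, and the movement-based rule that turns daily step
distances into the candidate smoothing radii.

Conventions
-----------
* The terrain ruggedness index (TRI) of a cell is the square root of the sum
  of squared elevation differences between the cell and its eight
  neighbours; border cells use the neighbours that exist.
* Slope and aspect use Horn's third-order finite differences; aspect enters
  models as *northness* = cos(aspect), in [-1, 1], with flat cells mapped
  to 0.
* A circular window of radius ``r`` contains every cell whose centre lies
  within ``r`` metres of the target cell centre; the centre cell is always a
  member, so any radius below the cell size gives the identity window.
* Distance decay is ``exp(-d / alpha)`` with ``alpha`` the mean distance at
  used locations, capped at 6,400 m.
* Standardization uses the sample (n-1) standard deviation, with moments
  taken from a fixed set of reference (training) rows and reapplied
  verbatim elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "DecayParams",
    "ScaleCandidateSet",
    "ScalingRecord",
    "compute_tri",
    "compute_aspect_northness",
    "compute_slope",
    "focal_mean",
    "log_ruggedness",
    "distance_grid",
    "compute_alpha",
    "decay_transform",
    "standardize",
    "correlation_screen",
    "compute_candidate_radii",
]

ALPHA_CAP_M = 6400.0  # 6.4 km cap on the decay range


@dataclass(frozen=True)
class DecayParams:
    """Exponential decay range for one distance feature class."""

    feature_class: str
    alpha: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= ALPHA_CAP_M:
            raise ValueError(
                f"alpha must lie in (0, {ALPHA_CAP_M}] m, got {self.alpha}"
            )


@dataclass(frozen=True)
class ScaleCandidateSet:
    """Candidate moving-window radii for one multi-scale variable."""

    variable: str
    radii: tuple[float, ...]
    season: str = ""

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in radii):
            raise ValueError("candidate radii must be strictly positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("candidate radii must be strictly increasing")
        object.__setattr__(self, "radii", radii)


@dataclass
class ScalingRecord:
    """Frozen per-column standardization moments (training reference rows)."""

    means: pd.Series
    sds: pd.Series

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.means.index if c not in df.columns]
        if missing:
            raise ValueError(f"columns missing from frame: {missing}")
        out = df.copy()
        for c in self.means.index:
            out[c] = (df[c] - self.means[c]) / self.sds[c]
        return out

    def transform_grid(self, grid: RasterGrid, column: str) -> RasterGrid:
        return grid.with_values((grid.values - self.means[column]) / self.sds[column])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.means.index, "mean": self.means.values, "sd": self.sds.values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScalingRecord":
        return cls(
            means=pd.Series(df["mean"].values, index=df["column"]),
            sds=pd.Series(df["sd"].values, index=df["column"]),
        )


# ---------------------------------------------------------------------------
# terrain metrics
# ---------------------------------------------------------------------------

_NEIGHBOUR_SHIFTS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def _require_3x3(dem: RasterGrid) -> None:
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must have at least 3x3 cells")


def compute_tri(dem: RasterGrid) -> RasterGrid:
    """Terrain ruggedness index: sqrt of summed squared neighbour differences.

    Border cells use whichever of the eight neighbours exist; a cell whose
    whole neighbourhood is nodata comes out nodata.
    """
    _require_3x3(dem)
    z = dem.values
    nr, nc = z.shape
    ssq = np.zeros_like(z)
    nvalid = np.zeros_like(z)
    centre_valid = np.isfinite(z)
    for dr, dc in _NEIGHBOUR_SHIFTS:
        shifted = np.full_like(z, np.nan)
        rs_src = slice(max(dr, 0), nr + min(dr, 0))
        cs_src = slice(max(dc, 0), nc + min(dc, 0))
        rs_dst = slice(max(-dr, 0), nr + min(-dr, 0))
        cs_dst = slice(max(-dc, 0), nc + min(-dc, 0))
        shifted[rs_dst, cs_dst] = z[rs_src, cs_src]
        ok = np.isfinite(shifted) & centre_valid
        diff = np.where(ok, shifted - z, 0.0)
        ssq += diff * diff
        nvalid += ok
    out = np.where(centre_valid & (nvalid > 0), np.sqrt(ssq), np.nan)
    return dem.with_values(out, name="tri")


def _horn_gradients(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward) by Horn's method, edge-replicated."""
    z = np.pad(dem.values, 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    cs = dem.cell_size
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    # row 0 is north, so the "top" 3x3 row is the northern one
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    return gx, gy


def compute_slope(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees (Horn finite differences)."""
    _require_3x3(dem)
    gx, gy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope = np.where(np.isfinite(dem.values), slope, np.nan)
    return dem.with_values(slope, name="slope")


def compute_aspect_northness(dem: RasterGrid) -> RasterGrid:
    """cos(aspect): +1 for north-facing (downslope due north) cells, -1 south.

    Flat cells (zero gradient) are 0 by convention.
    """
    _require_3x3(dem)
    gx, gy = _horn_gradients(dem)
    mag = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        northness = np.where(mag > 0, -gy / mag, 0.0)
    northness = np.where(np.isfinite(dem.values), northness, np.nan)
    return dem.with_values(northness, name="northness")


# ---------------------------------------------------------------------------
# focal smoothing and transforms
# ---------------------------------------------------------------------------

def _disk_kernel(radius: float, cell_size: float) -> np.ndarray:
    """0/1 membership kernel: cell centres within ``radius`` of the centre."""
    reach = int(radius // cell_size)
    offs = np.arange(-reach, reach + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dist2 = (dx * cell_size) ** 2 + (dy * cell_size) ** 2
    kern = (dist2 <= radius**2).astype(float)
    kern[reach, reach] = 1.0  # centre always a member
    return kern


def focal_mean(grid: RasterGrid, radius: float) -> RasterGrid:
    """Circular moving-window mean.

    The window shrinks at grid edges and around nodata cells: the mean is
    taken over valid member cells only. A radius below the cell size reduces
    to the identity.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    kern = _disk_kernel(radius, grid.cell_size)
    valid = grid.valid_mask.astype(float)
    filled = np.where(grid.valid_mask, grid.values, 0.0)
    num = ndimage.convolve(filled, kern, mode="constant", cval=0.0)
    den = ndimage.convolve(valid, kern, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    out = np.where(grid.valid_mask, out, np.nan)
    return grid.with_values(out)


def log_ruggedness(tri: RasterGrid) -> RasterGrid:
    """log(TRI + 1); maps TRI = 0 to 0 and is monotone increasing."""
    vals = tri.values
    if np.nanmin(vals) < 0:
        raise ValueError("TRI must be nonnegative")
    return tri.with_values(np.log1p(vals), name="log_ruggedness")


# ---------------------------------------------------------------------------
# distances and decay
# ---------------------------------------------------------------------------

def distance_grid(features, template: RasterGrid) -> RasterGrid:
    """Euclidean distance (m) from each cell centre to the nearest feature.

    ``features`` is a sequence of shapely geometries (points for sites and
    mesic centres, linestrings for roads/streams). Polygons are reduced to
    their centroid point.
    """
    geoms = [
        g.centroid if g.geom_type in ("Polygon", "MultiPolygon") else g
        for g in features
    ]
    if not geoms:
        raise ValueError("feature set is empty")
    union = shapely.union_all(geoms)
    X, Y = template.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, union).reshape(template.shape)
    d = np.where(template.valid_mask, d, np.nan)
    return template.with_values(d)


def compute_alpha(used_distances, feature_class: str = "") -> DecayParams:
    """Decay range: mean distance at used locations, capped at 6,400 m."""
    d = np.asarray(used_distances, dtype=float)
    if d.size == 0:
        raise ValueError("used_distances is empty")
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    alpha = min(float(np.mean(d)), ALPHA_CAP_M)
    return DecayParams(feature_class=feature_class, alpha=max(alpha, np.finfo(float).tiny))


def decay_transform(dist, alpha: float):
    """exp(-d / alpha), in (0, 1] and strictly decreasing in d."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if isinstance(dist, RasterGrid):
        return dist.with_values(decay_transform(dist.values, alpha))
    d = np.asarray(dist, dtype=float)
    if np.nanmin(d) < 0:
        raise ValueError("distances must be nonnegative")
    return np.exp(-d / alpha)


# ---------------------------------------------------------------------------
# standardization and screening
# ---------------------------------------------------------------------------

def standardize(
    df: pd.DataFrame,
    reference: np.ndarray | pd.Series | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Centre/scale columns to mean 0, sample SD 1 on the reference rows.

    Parameters
    ----------
    df : DataFrame
        Rows to transform.
    reference : boolean mask over rows, optional
        Rows whose moments define the transform (training used+available);
        defaults to all rows. The returned :class:`ScalingRecord` reapplies
        those moments verbatim to any other rows or grids.
    """
    cols = list(columns) if columns is not None else list(df.columns)
    ref = df if reference is None else df.loc[np.asarray(reference, dtype=bool)]
    means = ref[cols].mean()
    sds = ref[cols].std(ddof=1)
    bad = sds.index[(sds <= 0) | ~np.isfinite(sds)].tolist()
    if bad:
        raise ValueError(f"zero-variance column(s) on reference rows: {bad}")
    record = ScalingRecord(means=means, sds=sds)
    out = df.copy()
    out[cols] = (df[cols] - means) / sds
    return out, record


def correlation_screen(
    df: pd.DataFrame, threshold: float = 0.7, priority: list[str] | None = None
) -> list[str]:
    """Greedy Pearson |r| screen.

    Columns are visited in priority order (named columns first, the rest in
    frame order); a column is kept only if its |r| with every already-kept
    column is at or below the threshold. Returns the retained column names.
    """
    if df.shape[1] < 2:
        return list(df.columns)
    priority = priority or []
    order = [c for c in priority if c in df.columns]
    order += [c for c in df.columns if c not in order]
    corr = df[order].corr().abs()
    kept: list[str] = []
    for c in order:
        if all(corr.loc[c, k] <= threshold for k in kept):
            kept.append(c)
    return [c for c in df.columns if c in kept]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_candidate_radii(
    step_distances: dict[str, np.ndarray], season: str, variable: str = ""
) -> ScaleCandidateSet:
    """Movement-based candidate window radii.

    Radii are the across-individual averages of each individual's minimum,
    mean and maximum daily step distance, rounded to the nearest metre (half
    up). For the summer season an extra radius of half the maximum (again
    rounded half up) is inserted, reflecting the wide range of summer
    movements.
    """
    mins, means, maxs = [], [], []
    for ind, steps in step_distances.items():
        steps = np.asarray(steps, dtype=float)
        if steps.size == 0:
            warnings.warn(f"individual {ind!r} has no step distances; excluded")
            continue
        mins.append(steps.min())
        means.append(steps.mean())
        maxs.append(steps.max())
    if not mins:
        raise ValueError("no individual contributed step distances")
    radii = [
        _round_half_up(float(np.mean(mins))),
        _round_half_up(float(np.mean(means))),
        _round_half_up(float(np.mean(maxs))),
    ]
    if season == "summer":
        radii.append(_round_half_up(float(np.mean(maxs)) / 2.0))
    radii = sorted(set(radii))
    return ScaleCandidateSet(variable=variable, radii=tuple(radii), season=season)
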