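"""Synthetic sagebrush landscapes and telemetry with known selection truth.

Everything downstream of data acquisition — covariate derivation, design
assembly, the Bayesian RSF, validation and mapping — can be exercised
without any real rasters or telemetry by generating:

* spatially autocorrelated shrub-cover and elevation fields (smoothed white
  noise with a configurable correlation range),
* vector features: road and stream polylines, mesic-area centres, and a
  release site (the "pseudo-lek" translocated birds are drawn to),
* two shrub epochs, the later one carrying a smooth localized loss of cover
  centred near the release site,
* daily telemetry and nest locations drawn from a known resource-selection
  function, with per-individual random intercepts and an exponential
  release-site attraction term.

Locations are drawn independently per day — selection is conditioned on
habitat only, with no movement kernel — but consecutive-day step distances
are still well defined and feed the movement-based window-radius rule.
Coordinates are continuous (projected metres): a used cell is jittered
uniformly within the cell, matching telemetry semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from . import covariates as cov
from .raster import RasterGrid

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "SimulationTruth",
    "generate_landscape",
    "generate_shrub_epochs",
    "simulate_individuals",
    "simulate_nests",
    "step_distances",
    "build_covariate_stack",
    "true_linear_predictor",
]

NEST_BROOD_RADII = (60.0, 331.0, 887.0)
SUMMER_RADII = (111.0, 767.0, 1503.0, 3005.0)

LOCATION_COLUMNS = [
    "individual_id", "date", "x", "y", "life_stage", "group", "year", "used",
]


@dataclass
class LandscapeConfig:
    """Geometry and texture of a synthetic landscape.

    The default extent is 3.6 x 3.6 km of 30-m cells (120 x 120), large
    enough that the nest/brood candidate window radii (60/331/887 m) are all
    resolvable but small enough for fast simulation.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 3600.0, 3600.0)
    cell_size: float = 30.0
    shrub_mean: float = 15.0       # percent cover, typical RAP big-sage values
    shrub_sd: float = 8.0
    shrub_range_m: float = 300.0   # autocorrelation range of the cover field
    elev_base: float = 800.0       # metres ASL
    elev_relief: float = 60.0
    elev_range_m: float = 400.0
    n_roads: int = 3
    n_streams: int = 3
    n_mesic: int = 5

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"degenerate extent {self.extent}")
        for span in (x1 - x0, y1 - y0):
            if abs(span / self.cell_size - round(span / self.cell_size)) > 1e-9:
                raise ValueError("extent must divide into whole cells")


@dataclass
class LandscapeBundle:
    """Grids plus vector features sharing one geometry."""

    shrub_epoch_early: RasterGrid
    shrub_epoch_late: RasterGrid
    elevation: RasterGrid
    roads: list
    streams: list
    mesic_centers: list
    release_sites: list
    seed: int
    config: LandscapeConfig = field(default_factory=LandscapeConfig)

    def __post_init__(self) -> None:
        for g in (self.shrub_epoch_late, self.elevation):
            if not self.shrub_epoch_early.same_geometry(g):
                raise ValueError("all grids must share extent and cell size")
        for g in (self.shrub_epoch_early, self.shrub_epoch_late):
            if np.nanmin(g.values) < 0 or np.nanmax(g.values) > 100:
                raise ValueError("shrub percent cover must lie in [0, 100]")
        if not np.all(np.isfinite(self.elevation.values)):
            raise ValueError("elevation must be finite everywhere")

    def shrub(self, epoch: str = "late") -> RasterGrid:
        if epoch not in ("early", "late"):
            raise ValueError(f"unknown epoch {epoch!r}")
        return self.shrub_epoch_early if epoch == "early" else self.shrub_epoch_late


@dataclass
class SimulationTruth:
    """Generating RSF: coefficients on the standardized covariate scale.

    ``beta`` maps covariate names (``shrub``, ``rugged``, ``elevation``,
    ``northness``, ``road``, ``water``, ``mesic``) to coefficients;
    multi-scale variables (``shrub``, ``rugged``) are evaluated at
    ``true_scale``. Distance features enter as exp(-d/alpha) with the
    ``alphas`` ranges. ``release_effect`` is the coefficient on the
    (standardized) release-site decay; ``re_sd`` the SD of per-individual
    intercepts.
    """

    beta: dict[str, float]
    true_scale: dict[str, float]
    alphas: dict[str, float] = field(
        default_factory=lambda: {"road": 800.0, "water": 800.0,
                                 "mesic": 600.0, "release_site": 600.0}
    )
    re_sd: float = 0.0
    release_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.re_sd < 0:
            raise ValueError("re_sd must be nonnegative")


def default_truth(season: str = "nest") -> SimulationTruth:
    """A plausibly sage-grouse-like generating RSF used throughout testing:
    selection for shrub cover and mesic proximity, against rugged ground."""
    radii = NEST_BROOD_RADII if season in ("nest", "brood") else SUMMER_RADII
    return SimulationTruth(
        beta={
            "shrub": 1.0,
            "rugged": -0.8,
            "elevation": -0.5,
            "northness": 0.2,
            "road": -0.4,
            "water": 0.3,
            "mesic": 0.5,
        },
        true_scale={"shrub": radii[1], "rugged": radii[1]},
        re_sd=0.3 if season in ("brood", "summer") else 0.0,
        release_effect=0.8 if season in ("nest", "brood") else 0.0,
    )


# ---------------------------------------------------------------------------
# fields and features
# ---------------------------------------------------------------------------

def _autocorrelated_field(rng: np.random.Generator, shape, range_m: float,
                          cell_size: float) -> np.ndarray:
    """Unit-variance smoothed white noise; range 0 returns the raw noise."""
    noise = rng.standard_normal(shape)
    if range_m <= 0:
        return noise
    smoothed = gaussian_filter(noise, sigma=range_m / cell_size, mode="reflect")
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def generate_landscape(config: LandscapeConfig | None = None,
                       seed: int = 0) -> LandscapeBundle:
    """Build a seeded landscape: both shrub epochs start identical; apply
    :func:`generate_shrub_epochs` to introduce a localized loss."""
    config = config or LandscapeConfig()
    x0, y0, x1, y1 = config.extent
    cs = config.cell_size
    ncols = round((x1 - x0) / cs)
    nrows = round((y1 - y0) / cs)
    rng = np.random.default_rng(seed)

    shrub_f = _autocorrelated_field(rng, (nrows, ncols), config.shrub_range_m, cs)
    shrub = np.clip(config.shrub_mean + config.shrub_sd * shrub_f, 0.0, 100.0)
    elev_f = _autocorrelated_field(rng, (nrows, ncols), config.elev_range_m, cs)
    elev = config.elev_base + config.elev_relief * elev_f

    origin = (x0 + cs / 2.0, y0 + cs / 2.0)
    shrub_grid = RasterGrid(shrub, origin=origin, cell_size=cs, name="shrub")
    elev_grid = RasterGrid(elev, origin=origin, cell_size=cs, name="elevation")

    def random_crossing_line() -> LineString:
        # a gently bending polyline crossing the full extent
        horizontal = rng.random() < 0.5
        ts = np.linspace(0.0, 1.0, 5)
        lo = rng.uniform(0.2, 0.8)
        wiggle = rng.normal(0.0, 0.08, size=5)
        if horizontal:
            pts = [(x0 + t * (x1 - x0), y0 + (lo + w) * (y1 - y0))
                   for t, w in zip(ts, wiggle)]
        else:
            pts = [(x0 + (lo + w) * (x1 - x0), y0 + t * (y1 - y0))
                   for t, w in zip(ts, wiggle)]
        return LineString(pts)

    roads = [random_crossing_line() for _ in range(max(config.n_roads, 1))]
    streams = [random_crossing_line() for _ in range(max(config.n_streams, 1))]
    mesic = [Point(rng.uniform(x0 + 0.1 * (x1 - x0), x1 - 0.1 * (x1 - x0)),
                   rng.uniform(y0 + 0.1 * (y1 - y0), y1 - 0.1 * (y1 - y0)))
             for _ in range(max(config.n_mesic, 1))]
    release = [Point(0.5 * (x0 + x1), 0.5 * (y0 + y1))]

    return LandscapeBundle(
        shrub_epoch_early=shrub_grid,
        shrub_epoch_late=shrub_grid.with_values(shrub.copy()),
        elevation=elev_grid,
        roads=roads,
        streams=streams,
        mesic_centers=mesic,
        release_sites=release,
        seed=seed,
        config=config,
    )


def generate_shrub_epochs(
    landscape: LandscapeBundle,
    loss_center: tuple[float, float] | None = None,
    loss_magnitude: float = 8.0,
    loss_radius: float = 900.0,
    seed: int | None = None,
) -> tuple[RasterGrid, RasterGrid]:
    """Derive a late shrub epoch carrying a smooth localized cover loss.

    The deficit is a raised-cosine bump: ``loss_magnitude`` percent at
    ``loss_center`` (defaulting to the release site, where habitat loss was
    concentrated), tapering smoothly to zero at ``loss_radius`` and beyond.
    The bundle's late epoch is replaced in place and both grids returned.
    """
    if loss_radius <= 0:
        raise ValueError("loss_radius must be positive")
    if not 0 <= loss_magnitude <= 100:
        raise ValueError("loss_magnitude must lie in [0, 100]")
    early = landscape.shrub_epoch_early
    if loss_center is None:
        p = landscape.release_sites[0]
        loss_center = (p.x, p.y)
    xmin, ymin, xmax, ymax = early.extent
    if not (xmin <= loss_center[0] <= xmax and ymin <= loss_center[1] <= ymax):
        raise ValueError("loss_center outside the landscape extent")
    X, Y = early.cell_centers()
    d = np.hypot(X - loss_center[0], Y - loss_center[1])
    deficit = np.where(
        d < loss_radius,
        loss_magnitude * 0.5 * (1.0 + np.cos(np.pi * d / loss_radius)),
        0.0,
    )
    late_vals = np.clip(early.values - deficit, 0.0, 100.0)
    late = early.with_values(late_vals, name="shrub")
    landscape.shrub_epoch_late = late
    return early, late


# ---------------------------------------------------------------------------
# covariate stacks at truth / candidate scales
# ---------------------------------------------------------------------------

def build_covariate_stack(
    landscape: LandscapeBundle,
    radii: dict[str, tuple[float, ...]] | None = None,
    epoch: str = "late",
) -> dict[str, RasterGrid]:
    """Raw covariate grids keyed by name.

    Multi-scale variables get one grid per radius under ``"var@radius"``
    (shrub cover smoothed directly; ruggedness log-transformed before
    smoothing); distance grids are raw metres under ``"d_<feature>"`` and
    are decay-transformed later, once alpha is known from used locations.
    """
    radii = radii or {"shrub": NEST_BROOD_RADII, "rugged": NEST_BROOD_RADII}
    dem = landscape.elevation
    stack: dict[str, RasterGrid] = {}
    shrub = landscape.shrub(epoch)
    logtri = cov.log_ruggedness(cov.compute_tri(dem))
    for r in radii.get("shrub", ()):
        stack[f"shrub@{int(r)}"] = cov.focal_mean(shrub, r)
    for r in radii.get("rugged", ()):
        stack[f"rugged@{int(r)}"] = cov.focal_mean(logtri, r)
    stack["elevation"] = dem
    stack["northness"] = cov.compute_aspect_northness(dem)
    stack["d_road"] = cov.distance_grid(landscape.roads, dem)
    stack["d_water"] = cov.distance_grid(landscape.streams, dem)
    stack["d_mesic"] = cov.distance_grid(landscape.mesic_centers, dem)
    stack["d_release"] = cov.distance_grid(landscape.release_sites, dem)
    return stack


def _standardize_grid(vals: np.ndarray) -> np.ndarray:
    sd = np.nanstd(vals, ddof=1)
    return (vals - np.nanmean(vals)) / sd if sd > 0 else np.zeros_like(vals)


def true_linear_predictor(landscape: LandscapeBundle, truth: SimulationTruth,
                          epoch: str = "late") -> RasterGrid:
    """Cellwise x'beta_true with covariates at the generating scales,
    standardized over the landscape's cells."""
    radii = {v: (truth.true_scale[v],) for v in truth.true_scale}
    stack = build_covariate_stack(landscape, radii=radii, epoch=epoch)
    lp = np.zeros(landscape.elevation.shape)
    for var, beta in truth.beta.items():
        if beta == 0:
            continue
        if var in truth.true_scale:
            grid = stack[f"{var}@{int(truth.true_scale[var])}"]
            lp += beta * _standardize_grid(grid.values)
        elif var in ("elevation", "northness"):
            lp += beta * _standardize_grid(stack[var].values)
        elif var in ("road", "water", "mesic"):
            dec = cov.decay_transform(stack[f"d_{var}"].values, truth.alphas[var])
            lp += beta * _standardize_grid(dec)
        else:
            raise ValueError(f"unknown covariate in truth: {var!r}")
    if truth.release_effect != 0.0:
        dec = cov.decay_transform(
            stack["d_release"].values, truth.alphas["release_site"]
        )
        lp += truth.release_effect * _standardize_grid(dec)
    return landscape.elevation.with_values(lp, name="true_lp")


# ---------------------------------------------------------------------------
# telemetry simulation
# ---------------------------------------------------------------------------

def _draw_cells(lp: RasterGrid, n: int, rng: np.random.Generator,
                offset: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Sample n cells with probability proportional to exp(lp + offset)."""
    z = lp.values + offset
    z = z - np.nanmax(z)
    w = np.where(np.isfinite(z), np.exp(z), 0.0).ravel()
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all cell weights are zero or non-finite")
    idx = rng.choice(w.size, size=n, p=w / total)
    return np.unravel_index(idx, lp.shape)


def _jitter_xy(lp: RasterGrid, rows, cols, rng) -> tuple[np.ndarray, np.ndarray]:
    cs = lp.cell_size
    x0, y0 = lp.origin
    x = x0 + np.asarray(cols) * cs + rng.uniform(-cs / 2, cs / 2, size=len(cols))
    y = y0 + (lp.nrows - 1 - np.asarray(rows)) * cs + rng.uniform(
        -cs / 2, cs / 2, size=len(rows))
    return x, y


def simulate_individuals(
    landscape: LandscapeBundle,
    truth: SimulationTruth,
    n_individuals: int,
    days_per_individual: int,
    seed: int = 0,
    life_stage: str = "summer",
    year: int = 2017,
    start_date: str = "2017-06-01",
) -> pd.DataFrame:
    """Daily telemetry from the generating RSF.

    Each individual j receives gamma_j ~ Normal(0, re_sd^2); each day's
    location is a cell drawn with probability proportional to
    exp(x'beta_true + gamma_j), jittered uniformly within the cell. Days are
    consecutive, so per-individual step distances are one fewer than
    locations.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    lp = true_linear_predictor(landscape, truth)
    dates = pd.date_range(start_date, periods=days_per_individual, freq="D")
    frames = []
    for j in range(n_individuals):
        gamma = rng.normal(0.0, truth.re_sd) if truth.re_sd > 0 else 0.0
        rows, cols = _draw_cells(lp, days_per_individual, rng, offset=gamma)
        x, y = _jitter_xy(lp, rows, cols, rng)
        frames.append(pd.DataFrame({
            "individual_id": f"bird_{j:03d}",
            "date": dates.strftime("%Y-%m-%d"),
            "x": x,
            "y": y,
            "life_stage": life_stage,
            "group": "translocated",
            "year": year,
            "used": 1,
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_nests(
    landscape: LandscapeBundle,
    truth: SimulationTruth,
    n_per_group: dict[str, int],
    group_betas: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    years: dict[str, dict[int, int]] | None = None,
) -> pd.DataFrame:
    """One used nest point per nest, drawn as in :func:`simulate_individuals`
    but with no random intercepts; rows carry the group tag and year.

    ``group_betas`` optionally overrides the truth's coefficient set per
    group (e.g. a release-site attraction only for translocated birds);
    ``years`` optionally splits each group's count across calendar years.
    """
    valid_groups = {"resident", "translocated"}
    bad = set(n_per_group) - valid_groups
    if bad:
        raise ValueError(f"unknown group tag(s): {sorted(bad)}")
    rng = np.random.default_rng(seed)
    frames = []
    for group in sorted(n_per_group):
        n = n_per_group[group]
        g_truth = truth
        if group_betas and group in group_betas:
            over = group_betas[group]
            g_truth = SimulationTruth(
                beta={**truth.beta, **{k: v for k, v in over.items()
                                       if k != "release_effect"}},
                true_scale=truth.true_scale,
                alphas=truth.alphas,
                re_sd=0.0,
                release_effect=over.get("release_effect", truth.release_effect),
            )
        lp = true_linear_predictor(landscape, g_truth)
        rows, cols = _draw_cells(lp, n, rng)
        x, y = _jitter_xy(lp, rows, cols, rng)
        if years and group in years:
            year_col = np.repeat(
                list(years[group].keys()), list(years[group].values())
            )
            if len(year_col) != n:
                raise ValueError("per-year counts must sum to the group count")
        else:
            year_col = np.full(n, 2017)
        dates = pd.date_range("2017-05-01", periods=n, freq="D")
        frames.append(pd.DataFrame({
            "individual_id": [f"{group}_nest_{i:03d}" for i in range(n)],
            "date": dates.strftime("%Y-%m-%d"),
            "x": x,
            "y": y,
            "life_stage": "nest",
            "group": group,
            "year": year_col,
            "used": 1,
        }))
    return pd.concat(frames, ignore_index=True)


def step_distances(locations: pd.DataFrame) -> dict[str, np.ndarray]:
    """Consecutive-day Euclidean step lengths per individual (metres)."""
    out: dict[str, np.ndarray] = {}
    for ind, g in locations.sort_values("date").groupby("individual_id"):
        dx = np.diff(g["x"].to_numpy())
        dy = np.diff(g["y"].to_numpy())
        out[ind] = np.hypot(dx, dy)
    return out
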