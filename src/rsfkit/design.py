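"""Used/available design assembly for second-order RSFs.

The use-availability contrast is built here: daily thinning, the
minimum-location filters, the minimum-convex-polygon (MCP) availability
domain, uniform 5:1 background sampling, covariate attachment at every
candidate window radius, exponential decay of distance covariates, and
unit-level train/test splits (nests split by nest; broods and summer birds
by individual, so no unit leaks across partitions).

Each used point owns its block of ``ratio`` available points (a shared
``pair_id``), which keeps the availability ratio exact within any partition
of the used points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon

from . import covariates as cov
from .raster import RasterGrid

__all__ = [
    "DesignMatrix",
    "thin_one_per_day",
    "filter_min_locations",
    "mcp_boundary",
    "sample_available",
    "split_train_test",
    "assemble_design",
    "screen_design",
    "MIN_LOCATIONS",
    "SCREEN_PRIORITY",
]

# collinearity screen: ruggedness and elevation outrank the rest (they are
# retained when a correlated pair must lose a member); the release-site
# decay is exempt — it is the nuisance control, never screened out
SCREEN_PRIORITY = ["rugged", "elevation", "shrub", "northness",
                   "mesic", "water", "road"]

MIN_LOCATIONS = {"nest": 0, "brood": 5, "summer": 10}

# distance grids in a covariate stack and their decayed design-column names
DISTANCE_FEATURES = {
    "d_road": "road",
    "d_water": "water",
    "d_mesic": "mesic",
    "d_release": "release",
}


@dataclass
class DesignMatrix:
    """Standardized used/available rows ready for model fitting.

    Attributes
    ----------
    df : DataFrame
        One row per used or available record: ``used`` (1 used / 0 available),
        ``individual_id``, ``pair_id``, ``split`` ('train'/'test'), group and
        year tags, and one standardized column per covariate (multi-scale
        variables have one column per candidate radius, named
        ``var@radius``).
    scale_groups : dict
        variable -> list of its candidate column names.
    scaling : ScalingRecord
        Frozen training-row moments, reapplied to any prediction grid.
    alphas : dict
        feature class -> fitted DecayParams (mean used distance, capped).
    """

    df: pd.DataFrame
    covariate_columns: list[str]
    scale_groups: dict[str, list[str]] = field(default_factory=dict)
    scaling: cov.ScalingRecord | None = None
    alphas: dict[str, cov.DecayParams] = field(default_factory=dict)
    season: str = ""

    @property
    def y(self) -> np.ndarray:
        return self.df["used"].to_numpy(dtype=float)

    def rows(self, split: str | None = None) -> pd.DataFrame:
        if split is None:
            return self.df
        return self.df[self.df["split"] == split]

    def X(self, split: str | None = None, columns: list[str] | None = None):
        return self.rows(split)[columns or self.covariate_columns]

    def check_ratio(self, ratio: int = 5) -> bool:
        for _, part in self.df.groupby("split", dropna=False):
            n_used = int((part["used"] == 1).sum())
            n_avail = int((part["used"] == 0).sum())
            if n_avail != ratio * n_used:
                return False
        return True


# ---------------------------------------------------------------------------
# filtering and thinning
# ---------------------------------------------------------------------------

def thin_one_per_day(locations: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Keep exactly one row per (individual, date), chosen uniformly."""
    if locations["date"].isna().any():
        raise ValueError("locations carry missing dates")
    rng = np.random.default_rng(seed)
    keep = []
    for _, g in locations.groupby(["individual_id", "date"], sort=True):
        keep.append(g.index[rng.integers(len(g))])
    return locations.loc[sorted(keep)].reset_index(drop=True)


def filter_min_locations(locations: pd.DataFrame, life_stage: str) -> pd.DataFrame:
    """Drop individuals below the life-stage minimum (5 brood / 10 summer);
    nests are unfiltered."""
    min_n = MIN_LOCATIONS.get(life_stage)
    if min_n is None:
        raise ValueError(f"unknown life stage {life_stage!r}")
    if min_n == 0:
        return locations.reset_index(drop=True)
    counts = locations.groupby("individual_id").size()
    keep = counts.index[counts >= min_n]
    out = locations[locations["individual_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no individual met the {min_n}-location minimum")
    return out


# ---------------------------------------------------------------------------
# availability domain and sampling
# ---------------------------------------------------------------------------

def mcp_boundary(locations: pd.DataFrame) -> Polygon:
    """Minimum convex polygon (convex hull) of the used coordinates."""
    used = locations[locations.get("used", 1) == 1] if "used" in locations else locations
    pts = MultiPoint(list(zip(used["x"], used["y"])))
    if len(pts.geoms) < 3:
        raise ValueError("MCP needs at least 3 points")
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("points are collinear; MCP is degenerate")
    return hull


def sample_available(boundary: Polygon, n_used: int, ratio: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Uniform points over the boundary polygon, ``ratio`` per used point.

    Rejection sampling from the bounding box; returns an (ratio*n_used, 2)
    array ordered so that block i belongs to used point i.
    """
    if n_used < 1:
        raise ValueError("n_used must be >= 1")
    if boundary.is_empty or boundary.area <= 0:
        raise ValueError("degenerate availability polygon")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = boundary.bounds
    need = ratio * n_used
    out = np.empty((need, 2))
    got = 0
    while got < need:
        m = max(2 * (need - got), 64)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        import shapely
        inside = shapely.contains(boundary, shapely.points(xs, ys))
        take = min(int(inside.sum()), need - got)
        out[got:got + take, 0] = xs[inside][:take]
        out[got:got + take, 1] = ys[inside][:take]
        got += take
    return out


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

def split_train_test(locations: pd.DataFrame, fraction_train: float = 2.0 / 3.0,
                     unit: str = "individual_id", seed: int = 0) -> pd.DataFrame:
    """Tag used rows 'train'/'test' at the unit level.

    Nests split by nest (each nest is its own unit); broods and summer birds
    by individual, so every row of a unit shares one tag. The train count is
    round(fraction * units), and both partitions must keep >= 2 units.
    """
    units = locations[unit].unique()
    if len(units) < 3:
        raise ValueError("need at least 3 units to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.sort(units))
    n_train = int(np.floor(fraction_train * len(units) + 0.5))
    if n_train < 2 or len(units) - n_train < 2:
        raise ValueError(
            f"split leaves fewer than 2 units in a partition "
            f"({n_train} train / {len(units) - n_train} test)"
        )
    train_units = set(perm[:n_train])
    out = locations.copy()
    out["split"] = np.where(out[unit].isin(train_units), "train", "test")
    return out


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def assemble_design(
    used: pd.DataFrame,
    available_xy: np.ndarray,
    stack: dict[str, RasterGrid],
    season: str = "",
    standardize: bool = True,
) -> DesignMatrix:
    """Attach covariates to used and available points and standardize.

    Points are attached to the cell containing them (no interpolation).
    Distance covariates are decay-transformed with alpha = the mean distance
    over the *used* rows (capped at 6.4 km). Standardization moments come
    from training rows when a ``split`` column is present, otherwise from
    all rows, and are frozen in the returned scaling record. Rows landing on
    nodata cells are dropped with a reported count.
    """
    used = used.reset_index(drop=True)
    n_used = len(used)
    ratio, rem = divmod(len(available_xy), n_used)
    if rem != 0:
        raise ValueError("available points must be a whole multiple of used points")

    pair = np.repeat(np.arange(n_used), ratio)
    avail = pd.DataFrame({
        "individual_id": used["individual_id"].to_numpy()[pair],
        "date": used["date"].to_numpy()[pair],
        "x": available_xy[:, 0],
        "y": available_xy[:, 1],
        "group": used["group"].to_numpy()[pair] if "group" in used else "",
        "year": used["year"].to_numpy()[pair] if "year" in used else 0,
        "used": 0,
        "pair_id": pair,
    })
    if "split" in used.columns:
        avail["split"] = used["split"].to_numpy()[pair]
    u = used.copy()
    u["pair_id"] = np.arange(n_used)
    u["used"] = 1
    rows = pd.concat([u, avail], ignore_index=True)
    # covariate attachment at the containing cell
    cols: list[str] = []
    for name, grid in stack.items():
        rows[name] = grid.sample(rows["x"].to_numpy(), rows["y"].to_numpy())

    # exponential decay of distance covariates, alpha from used rows
    alphas: dict[str, cov.DecayParams] = {}
    for dcol, feat in DISTANCE_FEATURES.items():
        if dcol not in stack:
            continue
        used_d = rows.loc[rows["used"] == 1, dcol].dropna()
        alphas[feat] = cov.compute_alpha(used_d.to_numpy(), feature_class=feat)
        rows[feat] = cov.decay_transform(rows[dcol].to_numpy(), alphas[feat].alpha)
        rows = rows.drop(columns=dcol)
        cols.append(feat)
    cols = [c for c in stack if not c.startswith("d_")] + cols

    n_before = len(rows)
    rows = rows.dropna(subset=cols).reset_index(drop=True)
    dropped = n_before - len(rows)
    if dropped:
        warnings.warn(f"dropped {dropped} row(s) on nodata cells")

    # a window radius spanning the whole grid (or a degenerate feature
    # layout) yields a constant column: drop it rather than standardize it
    ref = (rows["split"] == "train").to_numpy() if "split" in rows else None
    ref_rows = rows if ref is None else rows.loc[ref]
    sds = ref_rows[cols].std(ddof=1)
    flat = [c for c in cols if not np.isfinite(sds[c]) or sds[c] <= 0]
    if flat:
        warnings.warn(f"dropping zero-variance column(s): {flat}")
        cols = [c for c in cols if c not in flat]

    scale_groups: dict[str, list[str]] = {}
    for c in cols:
        if "@" in c:
            scale_groups.setdefault(c.split("@")[0], []).append(c)

    scaling = None
    if standardize:
        rows, scaling = cov.standardize(rows, reference=ref, columns=cols)

    return DesignMatrix(
        df=rows,
        covariate_columns=cols,
        scale_groups=scale_groups,
        scaling=scaling,
        alphas=alphas,
        season=season,
    )


def expand_group_interactions(design: DesignMatrix, covariates: list[str],
                              groups: tuple[str, str] = ("resident",
                                                         "translocated")
                              ) -> tuple[DesignMatrix, dict[str, tuple[str, str]]]:
    """Let selected coefficients vary by group (contrast model).

    Each named covariate column c is replaced by two interaction columns
    ``c|group`` (c where the row's group matches, else 0). Returns the new
    design and a map covariate -> (column_a, column_b) whose paired
    posterior draws feed the group contrast P(beta_a > beta_b).
    """
    from copy import deepcopy

    new = deepcopy(design)
    mapping: dict[str, tuple[str, str]] = {}
    for c in covariates:
        if c not in new.covariate_columns:
            raise ValueError(f"unknown design column {c!r}")
        pair = []
        for g in groups:
            col = f"{c}|{g}"
            new.df[col] = np.where(new.df["group"] == g, new.df[c], 0.0)
            pair.append(col)
        idx = new.covariate_columns.index(c)
        new.covariate_columns = (new.covariate_columns[:idx] + pair
                                 + new.covariate_columns[idx + 1:])
        mapping[c] = tuple(pair)
    return new, mapping


def screen_design(design: DesignMatrix, threshold: float = 0.7,
                  priority: list[str] | None = None,
                  exempt: tuple[str, ...] = ("release",)) -> DesignMatrix:
    """Apply the Pearson |r| > threshold screen at the variable level.

    Each multi-scale variable is represented by its middle candidate column;
    the lower-priority member of every offending pair is dropped (all of its
    candidate columns with it). Exempt variables are always retained.
    """
    priority = priority if priority is not None else SCREEN_PRIORITY
    reps: dict[str, str] = {}
    for c in design.covariate_columns:
        var = c.split("@")[0]
        if var in exempt:
            continue
        if var in design.scale_groups:
            cand = design.scale_groups[var]
            reps[var] = cand[len(cand) // 2]
        else:
            reps[var] = c
    rep_frame = design.df[list(reps.values())]
    rep_frame.columns = list(reps.keys())
    kept = set(cov.correlation_screen(rep_frame, threshold, priority))
    dropped = set(reps) - kept
    if dropped:
        warnings.warn(f"collinearity screen dropped: {sorted(dropped)}")
    keep_cols = [c for c in design.covariate_columns
                 if c.split("@")[0] in kept or c.split("@")[0] in exempt]
    design.covariate_columns = keep_cols
    design.scale_groups = {v: g for v, g in design.scale_groups.items()
                           if v in kept or v in exempt}
    return design
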