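"""Spatial RSF products.

Seasonal selection surfaces w(x) = exp(sum_k beta_k x_k) are projected over
the covariate stack at the selected scales, with the intercept, random
intercepts and the release-site decay term (a nuisance tied to the
translocation, not to habitat) omitted. Each w surface is put on a bounded
relative scale by the logistic transform p = w / (1 + w); the annual
composite is the cellwise geometric mean of the three seasonal p surfaces;
and habitat change between shrub epochs is the difference of p surfaces
computed with the late versus early shrub layer (all other covariates held
at their late-epoch values). All surfaces are relative indices of
selection, not absolute probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import covariates as cov
from .design import DISTANCE_FEATURES, DesignMatrix
from .raster import RasterGrid

__all__ = [
    "prediction_stack",
    "rsf_surface",
    "logistic_surface",
    "annual_composite",
    "change_surface",
    "change_by_selection_class",
]

DEFAULT_DROP = ("release",)


def prediction_stack(stack: dict[str, RasterGrid],
                     design: DesignMatrix) -> dict[str, RasterGrid]:
    """Standardized grids keyed by design column name.

    Distance grids are decay-transformed with the alphas fitted from the
    design's used locations, then every column is standardized with the
    design's frozen training scaling record.
    """
    if design.scaling is None:
        raise ValueError("design carries no scaling record")
    out: dict[str, RasterGrid] = {}
    for name, grid in stack.items():
        if name.startswith("d_"):
            feat = DISTANCE_FEATURES[name]
            if feat not in design.scaling.means.index:
                continue
            dec = cov.decay_transform(grid, design.alphas[feat].alpha)
            out[feat] = design.scaling.transform_grid(dec, feat)
        elif name in design.scaling.means.index:
            out[name] = design.scaling.transform_grid(grid, name)
        # columns absent from the scaling record were dropped from the
        # design (zero variance or screened out) and cannot enter a model
    # escalated quadratic columns: square the standardized base column,
    # then apply the frozen moments of the squared column
    for colname in design.covariate_columns:
        if colname.endswith("_sq") and colname[:-3] in out:
            base = out[colname[:-3]]
            out[colname] = design.scaling.transform_grid(
                base.with_values(base.values**2), colname)
    return out


def _model_terms(model, drop):
    est = getattr(model, "model_", model)
    for v in est.var_names_:
        if v in drop:
            continue
        yield v, est.selected_scales_[v], float(est.coef_[v])


def rsf_surface(model, pred_stack: dict[str, RasterGrid],
                drop: tuple[str, ...] = DEFAULT_DROP,
                season: str = "") -> RasterGrid:
    """Cellwise w(x) over a standardized prediction stack.

    ``drop`` names model variables excluded from the surface (the
    release-site decay by default); quadratic terms (``<col>_sq``) are
    derived from their base column on the fly.
    """
    template = next(iter(pred_stack.values()))
    lp = np.zeros(template.shape)
    valid = np.ones(template.shape, dtype=bool)
    for var, colname, beta in _model_terms(model, drop):
        if colname not in pred_stack:
            raise ValueError(
                f"prediction stack lacks column {colname!r} "
                "(scale mismatch between model and stack?)")
        grid_vals = pred_stack[colname].values
        lp += beta * grid_vals
        valid &= np.isfinite(grid_vals)
    w = np.where(valid, np.exp(lp), np.nan)
    return template.with_values(w, name=f"w_{season}" if season else "w")


def logistic_surface(w: RasterGrid) -> RasterGrid:
    """p = w / (1 + w): strictly increasing, in (0, 1)."""
    vals = w.values
    if np.nanmin(vals) <= 0:
        raise ValueError("w surface must be strictly positive")
    return w.with_values(vals / (1.0 + vals), name=w.name.replace("w", "p", 1))


def annual_composite(p_nest: RasterGrid, p_brood: RasterGrid,
                     p_summer: RasterGrid) -> RasterGrid:
    """Cellwise geometric mean of the three seasonal p surfaces."""
    for other in (p_brood, p_summer):
        if not p_nest.same_geometry(other):
            raise ValueError("composite inputs are not aligned")
    stack = np.stack([p_nest.values, p_brood.values, p_summer.values])
    if np.nanmin(stack) <= 0 or np.nanmax(stack) >= 1:
        raise ValueError("p surfaces must lie in (0, 1)")
    comp = np.exp(np.mean(np.log(stack), axis=0))
    comp = np.where(np.all(np.isfinite(stack), axis=0), comp, np.nan)
    return p_nest.with_values(comp, name="p_annual")


def change_surface(model, pred_stack_late: dict[str, RasterGrid],
                   pred_stack_early: dict[str, RasterGrid],
                   drop: tuple[str, ...] = DEFAULT_DROP) -> RasterGrid:
    """Delta = p(late shrub) - p(early shrub), per cell, in (-1, 1).

    The two stacks must differ only in the shrub layer(s): the change
    surface isolates the effect of shrub-cover change under current
    selection, so a difference in any other layer is rejected.
    """
    for name, grid in pred_stack_late.items():
        if name.startswith("shrub"):
            continue
        other = pred_stack_early.get(name)
        if other is None or not np.allclose(
                grid.values, other.values, equal_nan=True):
            raise ValueError(f"stacks differ in non-shrub layer {name!r}")
    p_late = logistic_surface(rsf_surface(model, pred_stack_late, drop=drop))
    p_early = logistic_surface(rsf_surface(model, pred_stack_early, drop=drop))
    delta = p_late.values - p_early.values
    return p_late.with_values(delta, name="delta_p")


def change_by_selection_class(delta: RasterGrid, p: RasterGrid,
                              n_classes: int = 5) -> pd.DataFrame:
    """Mean habitat change within quantile classes of current selection.

    Classes are equal-count quantile bins of p (class 1 = lowest selection);
    the table reports each class's cell count and mean delta.
    """
    if not delta.same_geometry(p):
        raise ValueError("delta and p grids are not aligned")
    ok = np.isfinite(delta.values) & np.isfinite(p.values)
    pv = p.values[ok]
    dv = delta.values[ok]
    # rank-based classing gives counts differing by at most 1 even with ties
    order = np.argsort(pv, kind="mergesort")
    cls = np.empty(len(pv), dtype=int)
    cls[order] = (np.arange(len(pv)) * n_classes) // len(pv)
    rows = []
    for c in range(n_classes):
        sel = cls == c
        rows.append({
            "selection_class": c + 1,
            "n_cells": int(sel.sum()),
            "mean_delta": float(dv[sel].mean()) if sel.any() else np.nan,
            "mean_p": float(pv[sel].mean()) if sel.any() else np.nan,
        })
    return pd.DataFrame(rows)
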