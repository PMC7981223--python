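"""Out-of-sample validation of fitted RSFs.

Held-out calibration follows the quantile-bin construction: the fitted
w(x) is evaluated at withheld available and used points, the availability
w values define 10 quantile bins, the expected used count per bin is the
total withheld used count apportioned by the bin's share of summed
availability weight, and the observed counts are regressed on the expected
counts (slope and R^2) alongside the Spearman correlation of observed
counts with bin rank. A well-calibrated model has slope near 1 and both
correlation statistics near 1; the acceptance thresholds used for model
escalation are Spearman > .75, R^2 > .75 and slope in [0.8, 1.2].

Used-habitat calibration (UHC) compares the density of a covariate at
withheld used points against an envelope of densities obtained by
repeatedly resampling withheld available points with probability
proportional to w under posterior draws — a misspecified covariate shows an
observed curve escaping the envelope.

When calibration fails, quadratic terms are escalated one predictor at a
time, most influential (largest |posterior mean|) first, until the
thresholds pass or predictors run out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import covariates as cov
from .model import ModelConfig, TwoStageRSF, two_stage_fit

__all__ = [
    "CalibrationResult",
    "UHCResult",
    "ValidationThresholds",
    "EscalationResult",
    "predict_w",
    "calibration_bins",
    "validate_model",
    "uhc_envelope",
    "escalate_quadratic",
    "plot_calibration",
    "plot_uhc",
]


@dataclass(frozen=True)
class ValidationThresholds:
    """Pass bands for held-out calibration."""

    spearman: float = 0.75
    r2: float = 0.75
    slope_low: float = 0.8
    slope_high: float = 1.2

    def passes(self, result: "CalibrationResult") -> bool:
        return (
            result.spearman > self.spearman
            and result.r2 > self.r2
            and self.slope_low <= result.slope <= self.slope_high
        )


@dataclass
class CalibrationResult:
    """10-bin observed/expected used counts with summary statistics."""

    boundaries: np.ndarray        # bin edges over availability w
    observed: np.ndarray          # used counts per bin
    expected: np.ndarray          # expected used counts per bin
    slope: float
    intercept: float
    r2: float
    spearman: float
    slope_no_intercept: float = np.nan

    @property
    def n_bins(self) -> int:
        return len(self.observed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(1, self.n_bins + 1),
            "observed": self.observed,
            "expected": self.expected,
        })


@dataclass
class UHCResult:
    """Predicted-density envelope versus observed use for one covariate."""

    covariate: str
    grid: np.ndarray
    observed_density: np.ndarray
    availability_density: np.ndarray
    envelope_low: np.ndarray      # pointwise 2.5th percentile
    envelope_high: np.ndarray     # pointwise 97.5th percentile
    coverage: float               # fraction of grid with observed inside


def predict_w(coef: pd.Series, rows: pd.DataFrame,
              drop: tuple[str, ...] = ()) -> np.ndarray:
    """w(x) = exp(sum_k beta_k x_k) from posterior-mean coefficients.

    ``coef`` is indexed by column name; the intercept never appears here and
    any ``drop`` names are excluded. Rows must already carry the training
    standardization.
    """
    lp = np.zeros(len(rows))
    for name, b in coef.items():
        if name in drop:
            continue
        if name not in rows.columns:
            raise ValueError(f"rows lack column {name!r} (scaling mismatch?)")
        lp += b * rows[name].to_numpy(dtype=float)
    return np.exp(lp)


def calibration_bins(w_available, w_used, n_bins: int = 10) -> CalibrationResult:
    """Quantile-bin calibration of held-out used counts.

    Bin edges are the ``n_bins``-quantiles of w over the withheld available
    points; the expected used count in a bin is the total used count times
    that bin's share of summed availability weight. Tied quantiles that
    collapse a bin merge it into its neighbour with a warning.
    """
    w_avail = np.asarray(w_available, dtype=float)
    w_use = np.asarray(w_used, dtype=float)
    if w_avail.size == 0 or w_use.size == 0:
        raise ValueError("both w sets must be nonempty")
    edges = np.quantile(w_avail, np.linspace(0.0, 1.0, n_bins + 1))
    uniq = np.unique(edges)
    if len(uniq) < len(edges):
        warnings.warn("tied w quantiles: collapsed bin(s) merged with neighbours")
    edges = uniq
    if len(edges) < 2:  # constant w: a single degenerate bin set
        edges = np.array([edges[0], edges[0]])
    nb = len(edges) - 1
    # half-open bins, last bin closed; out-of-range used w clips to end bins
    a_idx = np.clip(np.searchsorted(edges, w_avail, side="right") - 1, 0, nb - 1)
    u_idx = np.clip(np.searchsorted(edges, w_use, side="right") - 1, 0, nb - 1)
    wsum = np.bincount(a_idx, weights=w_avail, minlength=nb)
    expected = len(w_use) * wsum / w_avail.sum()
    observed = np.bincount(u_idx, minlength=nb).astype(float)

    if np.ptp(expected) > 0 and np.ptp(observed) > 0:
        fit = stats.linregress(expected, observed)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue**2
        rho = stats.spearmanr(observed, np.arange(nb)).statistic
    else:  # degenerate: no spread in one margin
        slope = intercept = r2 = rho = np.nan
    slope_ni = float(np.sum(expected * observed) / np.sum(expected**2))
    return CalibrationResult(
        boundaries=edges, observed=observed, expected=expected,
        slope=float(slope), intercept=float(intercept), r2=float(r2),
        spearman=float(rho), slope_no_intercept=slope_ni,
    )


def validate_model(model, design, drop: tuple[str, ...] = (),
                   n_bins: int = 10) -> CalibrationResult:
    """Calibration of a fitted model on the design's withheld rows."""
    test = design.rows("test")
    w = model.predict_w(test[design.covariate_columns], drop=drop)
    y = test["used"].to_numpy()
    return calibration_bins(w[y == 0], w[y == 1], n_bins=n_bins)


# ---------------------------------------------------------------------------
# used-habitat calibration
# ---------------------------------------------------------------------------

def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.ptp(values) == 0:
        # degenerate sample: a spike at the single value
        out = np.zeros_like(grid)
        j = int(np.argmin(np.abs(grid - values.mean())))
        if len(grid) > 1:
            out[j] = 1.0 / abs(grid[1] - grid[0])
        return out
    return stats.gaussian_kde(values)(grid)


def uhc_envelope(model, design, covariate: str, M: int = 1000,
                 seed: int = 0, n_grid: int = 512,
                 drop: tuple[str, ...] = ()) -> UHCResult:
    """Used-habitat calibration envelope for one covariate.

    For each of M posterior draws, w is computed at the withheld available
    points, n_used_test of them are resampled with probability proportional
    to w, and the covariate's kernel density estimated on a fixed grid; the
    envelope is the pointwise 2.5-97.5 percentile band over draws. The
    observed density comes from the withheld used points.
    """
    if M < 2:
        raise ValueError("M must be >= 2 for a defined envelope")
    rng = np.random.default_rng(seed)
    est = model.model_ if isinstance(model, TwoStageRSF) else model
    test = design.rows("test")
    avail = test[test["used"] == 0]
    used = test[test["used"] == 1]
    xa = avail[covariate].to_numpy(dtype=float)
    xu = used[covariate].to_numpy(dtype=float)
    pooled = np.concatenate([xa, xu])
    lo, hi = np.percentile(pooled, [0.5, 99.5])
    if hi <= lo:
        lo, hi = pooled.min() - 1.0, pooled.max() + 1.0
    grid = np.linspace(lo, hi, n_grid)

    beta = est.posterior_["beta"]           # (C, T, K)
    C, T, K = beta.shape
    flat = beta.reshape(C * T, K)
    pick = rng.integers(0, C * T, size=M)
    cols = [est.selected_scales_[v] for v in est.var_names_]
    keep = np.array([v not in drop for v in est.var_names_])
    Xa = avail[cols].to_numpy(dtype=float)

    dens = np.empty((M, n_grid))
    n_take = len(xu)
    for m in range(M):
        bm = flat[pick[m]] * keep
        w = np.exp(Xa @ bm)
        p = w / w.sum()
        idx = rng.choice(len(xa), size=n_take, replace=True, p=p)
        dens[m] = _kde_on_grid(xa[idx], grid)
    lo_env = np.percentile(dens, 2.5, axis=0)
    hi_env = np.percentile(dens, 97.5, axis=0)
    obs = _kde_on_grid(xu, grid)
    inside = (obs >= lo_env) & (obs <= hi_env)
    return UHCResult(
        covariate=covariate, grid=grid, observed_density=obs,
        availability_density=_kde_on_grid(xa, grid),
        envelope_low=lo_env, envelope_high=hi_env,
        coverage=float(inside.mean()),
    )


# ---------------------------------------------------------------------------
# quadratic escalation
# ---------------------------------------------------------------------------

@dataclass
class EscalationResult:
    """Outcome of the quadratic-escalation loop."""

    model: object
    design: object
    calibration: CalibrationResult
    quadratic_terms: list[str] = field(default_factory=list)
    passed: bool = False
    history: list[CalibrationResult] = field(default_factory=list)


def _add_quadratic(design, column: str):
    """Append the standardized square of a (standardized) design column."""
    from copy import deepcopy

    new = deepcopy(design)
    sq = f"{column}_sq"
    raw = new.df[column].to_numpy(dtype=float) ** 2
    new.df[sq] = raw
    ref = (new.df["split"] == "train").to_numpy() if "split" in new.df else None
    new.df, rec = cov.standardize(new.df, reference=ref, columns=[sq])
    new.covariate_columns = list(new.covariate_columns) + [sq]
    if new.scaling is not None:
        new.scaling.means = pd.concat([new.scaling.means, rec.means])
        new.scaling.sds = pd.concat([new.scaling.sds, rec.sds])
    return new, sq


def escalate_quadratic(
    design,
    config: ModelConfig | None = None,
    thresholds: ValidationThresholds | None = None,
    base_model: TwoStageRSF | None = None,
    drop: tuple[str, ...] = (),
) -> EscalationResult:
    """Add quadratic terms until held-out calibration passes.

    The base two-stage fit is validated first; while it fails and un-squared
    predictors remain, the square of the not-yet-squared predictor with the
    largest |posterior mean| is added (on the selected-scale column), the
    model refitted with scales held at the stage-1 selection, and the
    calibration recomputed. Exhausting all predictors without passing is a
    reported outcome, not an error.
    """
    thresholds = thresholds or ValidationThresholds()
    config = config or ModelConfig()
    model = base_model if base_model is not None else two_stage_fit(design, config)
    calib = validate_model(model, design, drop=drop)
    history = [calib]
    added: list[str] = []
    cur_design = design
    cur_model = model
    selected = dict(model.selected_scales_)

    while not thresholds.passes(calib):
        coefs = cur_model.coef_
        candidates = [
            v for v in coefs.index
            if not v.endswith("_sq") and f"{selected.get(v, v)}_sq" not in added
        ]
        if not candidates:
            return EscalationResult(
                model=cur_model, design=cur_design, calibration=calib,
                quadratic_terms=added, passed=False, history=history)
        target = max(candidates, key=lambda v: abs(coefs[v]))
        target_col = selected.get(target, target)
        cur_design, sq = _add_quadratic(cur_design, target_col)
        added.append(sq)
        # refit with stage-1 scales frozen: single-candidate design
        frozen = type(cur_design)(
            df=cur_design.df,
            covariate_columns=[selected.get(v, v) for v in model.stage1_.var_names_]
            + added,
            scale_groups={},
            scaling=cur_design.scaling,
            alphas=cur_design.alphas,
            season=cur_design.season,
        )
        from .model import fit_rsf
        cur_model = fit_rsf(frozen, config, sample_scales=False)
        cur_model.selected_scales_ = {c: c for c in frozen.covariate_columns}
        selected = {}
        cur_design = frozen
        calib = validate_model(cur_model, cur_design, drop=drop)
        history.append(calib)

    return EscalationResult(
        model=cur_model, design=cur_design, calibration=calib,
        quadratic_terms=added, passed=True, history=history)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_calibration(result: CalibrationResult, path=None, title=""):
    """Observed versus expected used counts per quantile bin, with the 1:1
    line; returns the matplotlib figure (saved when ``path`` given)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(result.expected, result.observed, color="tab:blue", zorder=3)
    lim = max(result.expected.max(), result.observed.max()) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="1:1")
    ax.plot([0, lim], [result.intercept, result.intercept + result.slope * lim],
            color="tab:red", lw=1.5,
            label=f"fit (slope {result.slope:.2f})")
    ax.set_xlabel("expected used count")
    ax.set_ylabel("observed used count")
    ax.set_title(title or
                 f"Spearman {result.spearman:.2f}, R2 {result.r2:.2f}")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_uhc(result: UHCResult, path=None):
    """Observed-use density against the predicted envelope and the
    availability density for one covariate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(result.grid, result.envelope_low, result.envelope_high,
                    alpha=0.3, color="tab:blue", label="predicted 95% envelope")
    ax.plot(result.grid, result.observed_density, color="black", lw=1.5,
            label="observed use")
    ax.plot(result.grid, result.availability_density, color="tab:gray",
            ls=":", lw=1.2, label="availability")
    ax.set_xlabel(result.covariate)
    ax.set_ylabel("density")
    ax.set_title(f"coverage {result.coverage:.2f}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
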