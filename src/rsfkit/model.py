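"""Bayesian lasso RSF estimators.

The use-availability contrast is fitted as a Bernoulli logistic regression

    g(x) = beta_0 + beta_1 x_1 + ... + beta_K x_K (+ gamma_j)

with Laplace (lasso) priors on the coefficients, a conjugate
Gamma(a + K, b + sum|beta|) Gibbs update for the shrinkage rate lambda, an
optional per-individual random intercept gamma_j with Uniform(0, U) prior on
its SD, and a latent categorical indicator per multi-scale covariate that
selects which smoothing radius's column enters the linear predictor
(Bayesian latent indicator scale selection with a shared coefficient). The
fitted RSF discards the intercept and any nuisance terms:
w(x) = exp(sum_k beta_k x_k).

Two estimators in the scikit-learn idiom:

:class:`BayesianLassoRSF`
    one MCMC fit (optionally with scale indicators sampled);
:class:`TwoStageRSF`
    stage 1 samples the indicators, stage 2 refits with each multi-scale
    variable fixed at its modal radius — the configuration used for mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._mcmc import run_chain

__all__ = [
    "ModelConfig",
    "BayesianLassoRSF",
    "TwoStageRSF",
    "log_posterior",
    "update_lambda_gibbs",
    "gelman_rubin",
    "influence_flags",
    "group_contrast",
    "posterior_summary",
    "fit_rsf",
    "two_stage_fit",
]

RHAT_BOUND = 1.05
INFLUENCE_PROB = 0.85


@dataclass
class ModelConfig:
    """MCMC settings; the defaults are the full production configuration
    (three chains of 30,000 iterations, 15,000 burn-in, thin 5)."""

    chains: int = 3
    iterations: int = 30_000
    burn_in: int = 15_000
    thin: int = 5
    lasso_a: float = 0.01
    lasso_b: float = 0.01
    random_intercepts: bool = False
    re_upper: float = 10.0
    intercept_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("burn_in must lie in [0, iterations)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.lasso_a <= 0 or self.lasso_b <= 0:
            raise ValueError("lasso hyperprior a, b must be positive")

    @classmethod
    def reduced(cls, **kw) -> "ModelConfig":
        """A short test profile: 3 chains of 5,000 iterations, 2,500 burn-in."""
        base = dict(iterations=5_000, burn_in=2_500)
        base.update(kw)
        return cls(**base)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class BayesianLassoRSF(BaseEstimator):
    """Bayesian lasso use-availability logistic RSF.

    Parameters
    ----------
    scale_groups : dict[str, list[str]], optional
        Multi-scale variables: name -> its candidate column names in X.
        Columns not listed enter as ordinary single-column covariates.
    sample_scales : bool
        Sample the latent scale indicators (stage 1); with False each
        multi-scale variable uses its first (or only) candidate column.
    random_intercepts : bool
        Include per-individual intercepts (pass ``groups`` to :meth:`fit`).
    chains, iterations, burn_in, thin, lasso_a, lasso_b, re_upper,
    intercept_sd : see :class:`ModelConfig`.
    random_state : int
        Base seed; per-chain seeds are derived from it.

    Attributes
    ----------
    var_names_ : list of fitted variable names (one shared coefficient each)
    coef_ : Series of posterior-mean coefficients per variable
    posterior_ : dict of draw arrays, chain-major:
        ``beta0`` (C,T), ``beta`` (C,T,K), ``lambda`` (C,T),
        ``scales`` (C,T,K), ``gamma`` (C,T,m), ``sigma_gamma`` (C,T)
    scale_probs_ : DataFrame of posterior radius probabilities per variable
    selected_scales_ : dict variable -> modal candidate column
    rhat_ : Series of Gelman-Rubin statistics for monitored parameters
    converged_ : bool, all finite rhat below 1.05
    """

    def __init__(self, chains=3, iterations=30_000, burn_in=15_000, thin=5,
                 lasso_a=0.01, lasso_b=0.01, random_intercepts=False,
                 re_upper=10.0, intercept_sd=10.0, scale_groups=None,
                 sample_scales=True, random_state=0):
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.lasso_a = lasso_a
        self.lasso_b = lasso_b
        self.random_intercepts = random_intercepts
        self.re_upper = re_upper
        self.intercept_sd = intercept_sd
        self.scale_groups = scale_groups
        self.sample_scales = sample_scales
        self.random_state = random_state

    # -- structure ----------------------------------------------------------
    def _variable_layout(self, columns: list[str]):
        groups = dict(self.scale_groups or {})
        grouped_cols = {c for cols in groups.values() for c in cols}
        missing = grouped_cols - set(columns)
        if missing:
            raise ValueError(f"scale_groups reference unknown columns: {sorted(missing)}")
        var_names, var_columns = [], []
        seen = set()
        for c in columns:
            if c in seen:
                continue
            owner = next((v for v, cols in groups.items() if c in cols), None)
            if owner is not None:
                var_names.append(owner)
                var_columns.append(list(groups[owner]))
                seen.update(groups[owner])
            else:
                var_names.append(c)
                var_columns.append([c])
                seen.add(c)
        return var_names, var_columns

    # -- fitting ------------------------------------------------------------
    def fit(self, X, y, groups=None):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xf):
            raise ValueError("X and y disagree in length")
        if not np.all(np.isfinite(Xf.to_numpy())):
            raise ValueError("X contains non-finite values")
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")
        ModelConfig(chains=self.chains, iterations=self.iterations,
                    burn_in=self.burn_in, thin=self.thin,
                    lasso_a=self.lasso_a, lasso_b=self.lasso_b)  # validates

        columns = list(Xf.columns)
        var_names, var_columns = self._variable_layout(columns)
        K = len(var_names)
        maxc = max(len(c) for c in var_columns)
        col_idx = {c: i for i, c in enumerate(columns)}
        var_cols = np.full((K, maxc), -1, dtype=np.int64)
        var_ncand = np.zeros(K, dtype=np.int64)
        for k, cols in enumerate(var_columns):
            var_ncand[k] = len(cols)
            for c, name in enumerate(cols):
                var_cols[k, c] = col_idx[name]
        s_init = np.zeros(K, dtype=np.int64)

        use_re = bool(self.random_intercepts)
        if use_re:
            if groups is None:
                raise ValueError("random_intercepts=True requires groups")
            codes, levels = pd.factorize(np.asarray(groups))
            n_groups = len(levels)
            self.group_levels_ = list(levels)
        else:
            codes = np.zeros(len(y), dtype=np.int64)
            n_groups = 1
            self.group_levels_ = []

        Xmat = np.ascontiguousarray(Xf.to_numpy(dtype=float))
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.chains) % (2**31 - 1)
        draws = [run_chain(
            y, Xmat, var_cols, var_ncand, s_init,
            codes.astype(np.int64), n_groups, use_re,
            bool(self.sample_scales),
            self.iterations, self.burn_in, self.thin,
            self.lasso_a, self.lasso_b, self.intercept_sd, self.re_upper,
            int(seeds[c]),
        ) for c in range(self.chains)]

        self.posterior_ = {
            "beta0": np.stack([d[0] for d in draws]),
            "beta": np.stack([d[1] for d in draws]),
            "lambda": np.stack([d[2] for d in draws]),
            "scales": np.stack([d[3] for d in draws]),
            "gamma": np.stack([d[4] for d in draws]),
            "sigma_gamma": np.stack([d[5] for d in draws]),
        }
        self.var_names_ = var_names
        self.var_columns_ = var_columns
        self.columns_ = columns
        self.n_features_in_ = len(columns)

        beta = self.posterior_["beta"]  # (C, T, K)
        self.coef_ = pd.Series(beta.reshape(-1, K).mean(axis=0), index=var_names)

        # posterior scale probabilities and modal candidate per variable
        probs, modal = {}, {}
        sc = self.posterior_["scales"]
        for k, v in enumerate(var_names):
            nc = int(var_ncand[k])
            if nc < 2:
                modal[v] = var_columns[k][0]
                continue
            counts = np.bincount(sc[:, :, k].ravel(), minlength=nc).astype(float)
            p = counts / counts.sum()
            probs[v] = pd.Series(p, index=var_columns[k])
            modal[v] = var_columns[k][int(np.argmax(p))]
        self.scale_probs_ = (
            pd.DataFrame(probs).T if probs else pd.DataFrame()
        )
        self.selected_scales_ = modal

        # convergence over monitored parameters
        mon = {"beta0": self.posterior_["beta0"]}
        for k, v in enumerate(var_names):
            mon[f"beta[{v}]"] = beta[:, :, k]
        mon["lambda"] = self.posterior_["lambda"]
        if use_re:
            mon["sigma_gamma"] = self.posterior_["sigma_gamma"]
        rhat, flags = gelman_rubin(mon)
        self.rhat_ = rhat
        self.rhat_undefined_ = flags
        finite = rhat.dropna()
        self.converged_ = bool((finite < RHAT_BOUND).all()) and not any(
            flags.values())
        if not self.converged_:
            warnings.warn(
                f"MCMC convergence flag failed: max rhat = {finite.max():.4f}"
                if len(finite) else "MCMC convergence undefined")
        return self

    # -- prediction ---------------------------------------------------------
    def predict_w(self, X, drop: tuple[str, ...] = ()) -> np.ndarray:
        """RSF value w(x) = exp(sum_k beta_k x_k).

        The intercept and random intercepts never enter; variables named in
        ``drop`` (e.g. the release-site decay) are excluded. Multi-scale
        variables use their modal-scale column.
        """
        self._check_fitted()
        Xf = _as_frame(X)
        lp = np.zeros(len(Xf))
        for v in self.var_names_:
            if v in drop:
                continue
            col = self.selected_scales_[v]
            if col not in Xf.columns:
                raise ValueError(f"prediction frame lacks column {col!r}")
            lp += self.coef_[v] * Xf[col].to_numpy(dtype=float)
        return np.exp(lp)

    def predict_proba(self, X):
        """Relative-selection scale: p = w / (1 + w), two-column sklearn shape."""
        w = self.predict_w(X)
        p1 = w / (1.0 + w)
        return np.column_stack([1.0 - p1, p1])

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise ValueError("estimator is not fitted")

    # -- posterior accessors -------------------------------------------------
    def beta_draws(self, variable: str) -> np.ndarray:
        self._check_fitted()
        k = self.var_names_.index(variable)
        return self.posterior_["beta"][:, :, k].ravel()

    def influence_flags(self) -> set[str]:
        self._check_fitted()
        return influence_flags(
            {v: self.beta_draws(v) for v in self.var_names_})

    def summary(self) -> pd.DataFrame:
        self._check_fitted()
        draws = {"beta0": self.posterior_["beta0"].ravel()}
        for v in self.var_names_:
            draws[f"beta[{v}]"] = self.beta_draws(v)
        draws["lambda"] = self.posterior_["lambda"].ravel()
        if self.random_intercepts:
            draws["sigma_gamma"] = self.posterior_["sigma_gamma"].ravel()
        return posterior_summary(draws)


class TwoStageRSF(BaseEstimator):
    """Two-stage fit: scale selection, then refit at the modal scales.

    Stage 1 samples the latent scale indicators; the modal radius of each
    multi-scale variable is frozen and stage 2 refits the model with exactly
    one column per variable. Mapping and validation use the stage-2 fit.

    Attributes
    ----------
    stage1_, model_ : the two fitted :class:`BayesianLassoRSF` estimators
    scale_posterior_ : DataFrame, stage-1 radius probabilities (rows sum to 1)
    selected_scales_ : dict variable -> selected column name
    rhat_, converged_ : stage-2 diagnostics (stage 1 must also converge)
    """

    def __init__(self, chains=3, iterations=30_000, burn_in=15_000, thin=5,
                 lasso_a=0.01, lasso_b=0.01, random_intercepts=False,
                 re_upper=10.0, intercept_sd=10.0, scale_groups=None,
                 random_state=0):
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.lasso_a = lasso_a
        self.lasso_b = lasso_b
        self.random_intercepts = random_intercepts
        self.re_upper = re_upper
        self.intercept_sd = intercept_sd
        self.scale_groups = scale_groups
        self.random_state = random_state

    def _stage(self, sample_scales, scale_groups, seed_offset):
        return BayesianLassoRSF(
            chains=self.chains, iterations=self.iterations,
            burn_in=self.burn_in, thin=self.thin,
            lasso_a=self.lasso_a, lasso_b=self.lasso_b,
            random_intercepts=self.random_intercepts, re_upper=self.re_upper,
            intercept_sd=self.intercept_sd, scale_groups=scale_groups,
            sample_scales=sample_scales,
            random_state=self.random_state + seed_offset,
        )

    def fit(self, X, y, groups=None):
        Xf = _as_frame(X)
        self.stage1_ = self._stage(True, self.scale_groups, 0).fit(
            Xf, y, groups=groups)
        self.scale_posterior_ = self.stage1_.scale_probs_
        self.selected_scales_ = dict(self.stage1_.selected_scales_)

        # stage 2: one column per variable, indicators off
        keep = [self.selected_scales_[v] for v in self.stage1_.var_names_]
        self.columns_stage2_ = keep
        self.model_ = self._stage(False, None, 1).fit(
            Xf[keep], y, groups=groups)
        self.rhat_ = self.model_.rhat_
        self.converged_ = bool(self.stage1_.converged_ and self.model_.converged_)
        self.coef_ = self.model_.coef_
        self.var_names_ = self.model_.var_names_
        return self

    def predict_w(self, X, drop: tuple[str, ...] = ()) -> np.ndarray:
        return self.model_.predict_w(X, drop=drop)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


# ---------------------------------------------------------------------------
# free-function layer over the estimators
# ---------------------------------------------------------------------------

def log_posterior(beta0, beta, lam, X, y, a=0.01, b=0.01,
                  gamma=None, groups=None, sigma_gamma=None,
                  re_upper=10.0, intercept_sd=10.0) -> float:
    """Unnormalized log posterior of one parameter state.

    Bernoulli log-likelihood of the logistic model, plus Laplace(lambda)
    log-priors on the coefficients, the Gamma(a, b) log-prior on lambda, the
    Normal(0, sigma_gamma^2) terms for random intercepts with the
    Uniform(0, U) prior on sigma_gamma, and the Normal(0, intercept_sd^2)
    intercept prior.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates")
    if X.shape[1] != beta.size:
        raise ValueError("beta length does not match design columns")
    eta = beta0 + X @ beta
    if gamma is not None:
        gamma = np.asarray(gamma, dtype=float)
        eta = eta + gamma[np.asarray(groups, dtype=int)]
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    lp = beta.size * np.log(lam / 2.0) - lam * np.sum(np.abs(beta))
    lp += a * np.log(b) - _lgamma(a) + (a - 1.0) * np.log(lam) - b * lam
    lp += -beta0**2 / (2.0 * intercept_sd**2) \
        - 0.5 * np.log(2.0 * np.pi * intercept_sd**2)
    if gamma is not None:
        if sigma_gamma is None or not 0 < sigma_gamma < re_upper:
            return -np.inf
        lp += float(np.sum(
            -gamma**2 / (2.0 * sigma_gamma**2)
            - 0.5 * np.log(2.0 * np.pi * sigma_gamma**2)))
        lp += -np.log(re_upper)
    return ll + lp


def _lgamma(x: float) -> float:
    from math import lgamma
    return lgamma(x)


def update_lambda_gibbs(beta, a=0.01, b=0.01, rng=None) -> float:
    """Draw lambda from its exact full conditional Gamma(a + K, b + sum|beta|)
    under K Laplace(0, lambda) coefficient priors."""
    beta = np.asarray(beta, dtype=float)
    rng = np.random.default_rng() if rng is None else rng
    shape = a + beta.size
    rate = b + float(np.sum(np.abs(beta)))
    return float(rng.gamma(shape, 1.0 / rate))


def gelman_rubin(draws_by_chain) -> tuple[pd.Series, dict[str, bool]]:
    """Gelman-Rubin rhat per parameter.

    ``draws_by_chain`` maps parameter name -> (chains, draws) array (a bare
    array is treated as one unnamed parameter). With W the mean within-chain
    variance, B/n the variance of the chain means and
    Vhat = ((n-1)/n) W + B/n, rhat = sqrt(Vhat / W). A parameter with W = 0
    is undefined and flagged rather than reported.
    """
    if not isinstance(draws_by_chain, dict):
        draws_by_chain = {"param": np.asarray(draws_by_chain)}
    vals, flags = {}, {}
    for name, arr in draws_by_chain.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"{name}: need >=2 chains of >=2 draws")
        n = arr.shape[1]
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        if W == 0.0:
            vals[name] = np.nan
            flags[name] = True
            continue
        vhat = (n - 1) / n * W + B_over_n
        vals[name] = float(np.sqrt(vhat / W))
        flags[name] = False
    return pd.Series(vals, dtype=float), flags


def influence_flags(draws: dict[str, np.ndarray],
                    prob: float = INFLUENCE_PROB) -> set[str]:
    """Covariates with >= 85% posterior probability of beta > 0 or < 0
    (boundary inclusive)."""
    out = set()
    for name, d in draws.items():
        p_pos = float(np.mean(np.asarray(d) > 0))
        if p_pos >= prob or p_pos <= 1.0 - prob:
            out.add(name)
    return out


def group_contrast(draws_a, draws_b) -> float:
    """P(beta_a > beta_b) from paired (same-iteration) posterior draws."""
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("contrast draws must be paired (equal counts)")
    return float(np.mean(a > b))


def posterior_summary(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean, median, and 68%/95% equal-tailed credible intervals."""
    rows = {}
    for name, d in draws.items():
        d = np.asarray(d, dtype=float).ravel()
        q = np.percentile(d, [2.5, 16, 50, 84, 97.5])
        rows[name] = {
            "mean": d.mean(), "median": q[2],
            "ci68_low": q[1], "ci68_high": q[3],
            "ci95_low": q[0], "ci95_high": q[4],
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# design-level entry points
# ---------------------------------------------------------------------------

def _design_fit_inputs(design, split="train"):
    rows = design.rows(split)
    X = rows[design.covariate_columns]
    y = rows["used"].to_numpy(dtype=float)
    groups = rows["individual_id"].to_numpy()
    return X, y, groups


def fit_rsf(design, config: ModelConfig | None = None,
            sample_scales: bool = True) -> BayesianLassoRSF:
    """Fit the lasso RSF to a design's training rows."""
    config = config or ModelConfig()
    X, y, groups = _design_fit_inputs(design)
    est = BayesianLassoRSF(
        chains=config.chains, iterations=config.iterations,
        burn_in=config.burn_in, thin=config.thin,
        lasso_a=config.lasso_a, lasso_b=config.lasso_b,
        random_intercepts=config.random_intercepts,
        re_upper=config.re_upper, intercept_sd=config.intercept_sd,
        scale_groups=design.scale_groups, sample_scales=sample_scales,
        random_state=config.seed,
    )
    return est.fit(X, y, groups=groups if config.random_intercepts else None)


def two_stage_fit(design, config: ModelConfig | None = None) -> TwoStageRSF:
    """Scale selection then refit at modal scales, on the training rows."""
    config = config or ModelConfig()
    X, y, groups = _design_fit_inputs(design)
    est = TwoStageRSF(
        chains=config.chains, iterations=config.iterations,
        burn_in=config.burn_in, thin=config.thin,
        lasso_a=config.lasso_a, lasso_b=config.lasso_b,
        random_intercepts=config.random_intercepts,
        re_upper=config.re_upper, intercept_sd=config.intercept_sd,
        scale_groups=design.scale_groups, random_state=config.seed,
    )
    return est.fit(X, y, groups=groups if config.random_intercepts else None)
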