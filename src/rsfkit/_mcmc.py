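"""Numba MCMC kernel for the Bayesian lasso use-availability logistic model.

One kernel runs one chain of the Gibbs-within-Metropolis sampler:

* intercept and per-variable coefficients: Gaussian random-walk Metropolis,
  step sizes adapted toward 0.44 acceptance during burn-in only;
* the lasso rate ``lambda``: exact conjugate Gamma draw,
  Gamma(a + K, b + sum_k |beta_k|);
* the latent scale indicator of each multi-scale variable: categorical
  Gibbs over its candidate columns, the shared coefficient applying to
  whichever column is selected (uniform prior over candidates);
* per-individual random intercepts: random-walk Metropolis, with the
  random-effect SD updated by Metropolis under a Uniform(0, U) prior.

The linear predictor is maintained incrementally (one O(n) pass per scalar
update) and the cached log-likelihood is refreshed from scratch
periodically to stop float drift.
"""

import numpy as np
from numba import njit

__all__ = ["run_chain"]


@njit(cache=True)
def _softplus(x):
    # log(1 + exp(x)), stable on both tails
    if x > 0.0:
        return x + np.log1p(np.exp(-x))
    return np.log1p(np.exp(x))


@njit(cache=True)
def _loglik(eta, y):
    ll = 0.0
    for i in range(eta.shape[0]):
        ll += y[i] * eta[i] - _softplus(eta[i])
    return ll


@njit(cache=True)
def _loglik_shift_const(eta, y, d):
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i] + d
        ll += y[i] * e - _softplus(e)
    return ll


@njit(cache=True)
def _loglik_shift_col(eta, y, x, d):
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i] + d * x[i]
        ll += y[i] * e - _softplus(e)
    return ll


@njit(cache=True)
def run_chain(
    y,            # (n,) float64 0/1
    X,            # (n, p) float64, standardized candidate columns
    var_cols,     # (K, maxc) int64, -1 padded: candidate column per variable
    var_ncand,    # (K,) int64
    s_init,       # (K,) int64 initial candidate index
    group_of_row, # (n,) int64 individual index, or all zeros
    n_groups,     # int
    use_re,       # bool
    sample_scales,# bool
    n_iter, burn, thin,          # ints
    a, b,                        # lasso hyperprior
    intercept_sd, re_upper,      # priors
    seed,
):
    np.random.seed(seed)
    n = y.shape[0]
    K = var_cols.shape[0]

    beta0 = 0.0
    beta = np.zeros(K)
    lam = 1.0
    s = s_init.copy()
    gamma = np.zeros(n_groups)
    sigma = 1.0

    eta = np.empty(n)
    for i in range(n):
        eta[i] = beta0 + (gamma[group_of_row[i]] if use_re else 0.0)
    ll = _loglik(eta, y)

    # rows grouped by individual for O(rows_of_j) random-intercept updates
    order = np.argsort(group_of_row, kind="mergesort")
    grp_ptr = np.zeros(n_groups + 1, dtype=np.int64)
    for i in range(n):
        grp_ptr[group_of_row[i] + 1] += 1
    for j in range(n_groups):
        grp_ptr[j + 1] += grp_ptr[j]

    n_scalar = 1 + K + (n_groups + 1 if use_re else 0)
    step = np.full(n_scalar, 0.2)
    acc = np.zeros(n_scalar)
    tries = np.zeros(n_scalar)

    n_keep = (n_iter - burn) // thin
    out_beta0 = np.empty(n_keep)
    out_beta = np.empty((n_keep, K))
    out_lam = np.empty(n_keep)
    out_s = np.empty((n_keep, K), dtype=np.int64)
    out_gamma = np.empty((n_keep, n_groups if use_re else 1))
    out_sigma = np.empty(n_keep)

    kept = 0
    for it in range(n_iter):
        # ---- intercept (Normal(0, intercept_sd^2) prior) ----
        prop = beta0 + step[0] * np.random.normal()
        d = prop - beta0
        ll_new = _loglik_shift_const(eta, y, d)
        lpr = (beta0 * beta0 - prop * prop) / (2.0 * intercept_sd * intercept_sd)
        tries[0] += 1.0
        if np.log(np.random.random()) < ll_new - ll + lpr:
            beta0 = prop
            for i in range(n):
                eta[i] += d
            ll = ll_new
            acc[0] += 1.0

        # ---- coefficients (Laplace(lambda) prior) ----
        for k in range(K):
            col = var_cols[k, s[k]]
            prop = beta[k] + step[1 + k] * np.random.normal()
            d = prop - beta[k]
            ll_new = _loglik_shift_col(eta, y, X[:, col], d)
            lpr = -lam * (abs(prop) - abs(beta[k]))
            tries[1 + k] += 1.0
            if np.log(np.random.random()) < ll_new - ll + lpr:
                beta[k] = prop
                for i in range(n):
                    eta[i] += d * X[i, col]
                ll = ll_new
                acc[1 + k] += 1.0

        # ---- lambda: exact conjugate Gamma(a + K, b + sum|beta|) ----
        sab = 0.0
        for k in range(K):
            sab += abs(beta[k])
        lam = np.random.gamma(a + K, 1.0 / (b + sab))

        # ---- latent scale indicators: categorical Gibbs ----
        if sample_scales:
            for k in range(K):
                nc = var_ncand[k]
                if nc < 2:
                    continue
                cur = s[k]
                cur_col = var_cols[k, cur]
                logp = np.empty(nc)
                for c in range(nc):
                    if c == cur:
                        logp[c] = ll
                    else:
                        ccol = var_cols[k, c]
                        acc_ll = 0.0
                        for i in range(n):
                            e = eta[i] + beta[k] * (X[i, ccol] - X[i, cur_col])
                            acc_ll += y[i] * e - _softplus(e)
                        logp[c] = acc_ll
                mx = logp.max()
                w = np.exp(logp - mx)
                w /= w.sum()
                u = np.random.random()
                csum = 0.0
                new = nc - 1
                for c in range(nc):
                    csum += w[c]
                    if u <= csum:
                        new = c
                        break
                if new != cur:
                    ncol = var_cols[k, new]
                    for i in range(n):
                        eta[i] += beta[k] * (X[i, ncol] - X[i, cur_col])
                    s[k] = new
                    ll = logp[new]

        # ---- random intercepts ----
        if use_re:
            for j in range(n_groups):
                gj = gamma[j]
                prop = gj + step[1 + K + j] * np.random.normal()
                d = prop - gj
                dll = 0.0
                for t in range(grp_ptr[j], grp_ptr[j + 1]):
                    i = order[t]
                    e_old = eta[i]
                    e_new = e_old + d
                    dll += y[i] * d - _softplus(e_new) + _softplus(e_old)
                lpr = (gj * gj - prop * prop) / (2.0 * sigma * sigma)
                tries[1 + K + j] += 1.0
                if np.log(np.random.random()) < dll + lpr:
                    gamma[j] = prop
                    for t in range(grp_ptr[j], grp_ptr[j + 1]):
                        eta[order[t]] += d
                    ll += dll
                    acc[1 + K + j] += 1.0
            # sigma_gamma: Metropolis under Uniform(0, re_upper)
            idx = 1 + K + n_groups
            prop = sigma + step[idx] * np.random.normal()
            tries[idx] += 1.0
            if 0.0 < prop < re_upper:
                lr = 0.0
                for j in range(n_groups):
                    g2 = gamma[j] * gamma[j]
                    lr += (-np.log(prop) - g2 / (2.0 * prop * prop)
                           + np.log(sigma) + g2 / (2.0 * sigma * sigma))
                if np.log(np.random.random()) < lr:
                    sigma = prop
                    acc[idx] += 1.0

        # ---- adaptation (burn-in only, batches of 50) ----
        if it < burn and (it + 1) % 50 == 0:
            for q in range(n_scalar):
                if tries[q] > 0.0:
                    rate = acc[q] / tries[q]
                    step[q] *= np.exp(rate - 0.44)
                    if step[q] < 1e-3:
                        step[q] = 1e-3
                    elif step[q] > 10.0:
                        step[q] = 10.0
                acc[q] = 0.0
                tries[q] = 0.0

        # periodic exact refresh of the cached log-likelihood
        if (it + 1) % 1000 == 0:
            ll = _loglik(eta, y)

        # ---- record ----
        if it >= burn and (it - burn) % thin == 0:
            out_beta0[kept] = beta0
            for k in range(K):
                out_beta[kept, k] = beta[k]
                out_s[kept, k] = s[k]
            out_lam[kept] = lam
            if use_re:
                for j in range(n_groups):
                    out_gamma[kept, j] = gamma[j]
            else:
                out_gamma[kept, 0] = 0.0
            out_sigma[kept] = sigma if use_re else 0.0
            kept += 1

    return out_beta0, out_beta, out_lam, out_s, out_gamma, out_sigma
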