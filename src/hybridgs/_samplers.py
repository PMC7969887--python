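"""Numba Gibbs-sampler kernels for whole-genome marker-effect regression.

Both samplers operate on a residual vector updated in place as marker
effects change (the standard single-site Gibbs scheme), so one sweep over
m markers costs O(n m).  Seeding uses numba's per-thread NumPy legacy RNG,
giving bit-reproducible chains for a fixed (seed, chain length).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_scaled_inv_chi2(df, scale):
    # scaled-inverse-chi2(df, scale) = df*scale / chi2(df)
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _sample_inv_gaussian(mu, lam):
    # Michael, Schucany & Haas (1976) transformation method; for very
    # large mu/lam the subtraction cancels catastrophically, so clamp
    v = np.random.standard_normal()
    w = v * v
    x = mu + (mu * mu * w) / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * mu * lam * w + mu * mu * w * w
    )
    if not np.isfinite(x) or x <= 0.0:
        x = 1e-12 * mu if mu > 0.0 else 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=True)
def bayes_b_chain(X, y, pi, nu, s2_beta_scale, nu_e, s2_e_scale,
                  n_iter, burn_in, thin, seed):
    """Spike-and-slab (BayesB) single-site Gibbs sampler.

    Each column's effect is exactly zero with prior probability ``pi``;
    otherwise normal with its own variance carrying a scaled-inverse-chi2
    prior (a scaled-t slab).  Returns posterior means of mu and beta, the
    posterior inclusion frequency per column, and the posterior mean
    residual variance.
    """
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    mu = y.mean()
    beta = np.zeros(m)
    sigma2_beta = np.full(m, s2_beta_scale)
    sigma2_e = y.var() + 1e-12
    r = y - mu  # residual, kept consistent with current state

    n_keep = 0
    mu_sum = 0.0
    beta_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    s2e_sum = 0.0

    for it in range(n_iter):
        # intercept
        r += mu
        mu = r.mean() + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        r -= mu

        for j in range(m):
            if xtx[j] <= 0.0:
                beta[j] = 0.0
                continue
            # add current effect back into residual
            bj = beta[j]
            rhs = 0.0
            if bj != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * bj
            for i in range(n):
                rhs += X[i, j] * r[i]
            c = xtx[j]
            s2b = sigma2_beta[j]
            # log Bayes factor of inclusion vs exclusion
            v1 = c * s2b + sigma2_e
            log_odds = (np.log(1.0 - pi) - np.log(pi)
                        - 0.5 * np.log(v1 / sigma2_e)
                        + 0.5 * rhs * rhs * s2b / (sigma2_e * v1))
            p_incl = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p_incl:
                prec = c + sigma2_e / s2b
                mean = rhs / prec
                sd = np.sqrt(sigma2_e / prec)
                bj = mean + sd * np.random.standard_normal()
                beta[j] = bj
                for i in range(n):
                    r[i] -= X[i, j] * bj
                sigma2_beta[j] = _sample_scaled_inv_chi2(
                    nu + 1.0, (nu * s2_beta_scale + bj * bj) / (nu + 1.0))
            else:
                beta[j] = 0.0
                sigma2_beta[j] = _sample_scaled_inv_chi2(nu, s2_beta_scale)

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        sigma2_e = _sample_scaled_inv_chi2(
            nu_e + n, (nu_e * s2_e_scale + sse) / (nu_e + n))

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
            mu_sum += mu
            s2e_sum += sigma2_e
            for j in range(m):
                beta_sum[j] += beta[j]
                if beta[j] != 0.0:
                    incl_sum[j] += 1.0

    return (mu_sum / n_keep, beta_sum / n_keep, incl_sum / n_keep,
            s2e_sum / n_keep)


@njit(cache=True)
def bayes_lasso_chain(X, y, lambda2_init, gamma_shape, gamma_rate,
                      nu_e, s2_e_scale, n_iter, burn_in, thin, seed):
    """Bayesian Lasso Gibbs sampler (double-exponential prior on effects).

    Uses the scale-mixture-of-normals representation: beta_j ~ N(0,
    tau2_j * sigma2_e), 1/tau2_j inverse-Gaussian, lambda^2 with a gamma
    hyperprior.  Returns posterior means of mu, beta, lambda^2, sigma2_e.
    """
    np.random.seed(seed)
    n, m = X.shape
    xtx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    mu = y.mean()
    beta = np.zeros(m)
    tau2 = np.full(m, 1.0)
    lambda2 = lambda2_init
    sigma2_e = y.var() + 1e-12
    r = y - mu

    n_keep = 0
    mu_sum = 0.0
    beta_sum = np.zeros(m)
    lam_sum = 0.0
    s2e_sum = 0.0

    for it in range(n_iter):
        r += mu
        mu = r.mean() + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        r -= mu

        for j in range(m):
            if xtx[j] <= 0.0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            if bj != 0.0:
                for i in range(n):
                    r[i] += X[i, j] * bj
            rhs = 0.0
            for i in range(n):
                rhs += X[i, j] * r[i]
            prec = xtx[j] + 1.0 / tau2[j]
            mean = rhs / prec
            sd = np.sqrt(sigma2_e / prec)
            bj = mean + sd * np.random.standard_normal()
            beta[j] = bj
            for i in range(n):
                r[i] -= X[i, j] * bj
            # tau2_j update via inverse-Gaussian on 1/tau2_j
            b2 = bj * bj
            if b2 < 1e-300:
                b2 = 1e-300
            ig_mu = np.sqrt(lambda2 * sigma2_e / b2)
            if ig_mu > 1e8:  # effect ~ 0: tau2 bounded away from 0 below
                ig_mu = 1e8
            inv_tau2 = _sample_inv_gaussian(ig_mu, lambda2)
            if inv_tau2 < 1e-12:
                inv_tau2 = 1e-12
            elif inv_tau2 > 1e12:
                inv_tau2 = 1e12
            tau2[j] = 1.0 / inv_tau2

        tau2_total = 0.0
        for j in range(m):
            tau2_total += tau2[j]
        lambda2 = np.random.gamma(gamma_shape + m,
                                  1.0 / (gamma_rate + 0.5 * tau2_total))

        sse = 0.0
        for i in range(n):
            sse += r[i] * r[i]
        bterm = 0.0
        for j in range(m):
            bterm += beta[j] * beta[j] / tau2[j]
        df = nu_e + n + m
        sigma2_e = _sample_scaled_inv_chi2(
            df, (nu_e * s2_e_scale + sse + bterm) / df)

        if it >= burn_in and (it - burn_in) % thin == 0:
            n_keep += 1
            mu_sum += mu
            lam_sum += lambda2
            s2e_sum += sigma2_e
            for j in range(m):
                beta_sum[j] += beta[j]

    return (mu_sum / n_keep, beta_sum / n_keep, lam_sum / n_keep,
            s2e_sum / n_keep)
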