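"""Numba Gibbs kernels for the Bayesian whole-genome regressions.

Both samplers work on centered dosages with the residual vector updated
in place per marker, so one full sweep costs O(n*m).  Seeding happens
inside the jitted function (numba keeps its own RNG state per thread),
which makes same-seed runs bit-identical.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_scaled_inv_chi2(df, scale_times_df):
    # scale_times_df = nu * S2 (+ beta^2 where applicable)
    return scale_times_df / np.random.chisquare(df)


@njit(cache=True)
def bayesb_gibbs(
    Z, y, n_iter, burn_in, thin, seed, nu, S2, nu_e, Se2, pi_a, pi_b
):
    """BayesB: per-marker point-mass/scaled-t mixture with sampled pi.

    Returns posterior-mean beta and mu plus thinned chains of
    (pi, sigma2_e, sigma2_g).
    """
    np.random.seed(seed)
    n, m = Z.shape
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    beta = np.zeros(m)
    sigma2_j = np.full(m, nu * S2 / (nu - 2.0))
    pi = 0.5
    mu = y.mean()
    e = y - mu
    se2 = Se2 if Se2 > 0 else 1.0

    n_keep = (n_iter - burn_in) // thin
    pi_chain = np.empty(n_keep)
    se2_chain = np.empty(n_keep)
    sg2_chain = np.empty(n_keep)
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    kept = 0

    for it in range(1, n_iter + 1):
        # intercept
        mu_new = mu + e.sum() / n + np.random.normal() * np.sqrt(se2 / n)
        for i in range(n):
            e[i] -= mu_new - mu
        mu = mu_new

        n_in = 0
        for j in range(m):
            zj2 = zz[j]
            if zj2 <= 0.0:
                continue
            bj = beta[j]
            rz = bj * zj2
            for i in range(n):
                rz += Z[i, j] * e[i]
            v = zj2 * sigma2_j[j]
            log_odds = (
                np.log(pi / (1.0 - pi))
                - 0.5 * np.log(1.0 + v / se2)
                + 0.5 * sigma2_j[j] * rz * rz / (se2 * (se2 + v))
            )
            if log_odds > 35.0:
                p1 = 1.0
            elif log_odds < -35.0:
                p1 = 0.0
            else:
                p1 = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < p1:
                cvar = se2 / (zj2 + se2 / sigma2_j[j])
                cmean = rz / (zj2 + se2 / sigma2_j[j])
                bnew = cmean + np.random.normal() * np.sqrt(cvar)
                n_in += 1
            else:
                bnew = 0.0
            if bnew != bj:
                diff = bj - bnew
                for i in range(n):
                    e[i] += Z[i, j] * diff
                beta[j] = bnew
            # marker variance: slab posterior when in, prior draw when out
            if bnew != 0.0:
                sigma2_j[j] = _sample_scaled_inv_chi2(
                    nu + 1.0, nu * S2 + bnew * bnew
                )
            else:
                sigma2_j[j] = _sample_scaled_inv_chi2(nu, nu * S2)

        pi = np.random.beta(pi_a + n_in, pi_b + (m - n_in))
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se2 = (sse + nu_e * Se2) / np.random.chisquare(n + nu_e)

        if it > burn_in and (it - burn_in) % thin == 0:
            gbar = 0.0
            for i in range(n):
                gbar += y[i] - mu - e[i]
            gbar /= n
            sg2 = 0.0
            for i in range(n):
                gi = y[i] - mu - e[i] - gbar
                sg2 += gi * gi
            sg2 /= n - 1
            pi_chain[kept] = pi
            se2_chain[kept] = se2
            sg2_chain[kept] = sg2
            for j in range(m):
                beta_sum[j] += beta[j]
            mu_sum += mu
            kept += 1

    return (
        beta_sum / max(kept, 1),
        mu_sum / max(kept, 1),
        pi_chain,
        se2_chain,
        sg2_chain,
    )


@njit(cache=True)
def _inv_gauss(mean, lam):
    # Michael-Schucany-Haas transform
    v = np.random.normal()
    w = v * v
    x = mean + (mean * mean * w) / (2.0 * lam) - (
        mean / (2.0 * lam)
    ) * np.sqrt(4.0 * mean * lam * w + mean * mean * w * w)
    if np.random.random() <= mean / (mean + x):
        return x
    return mean * mean / x


@njit(cache=True)
def blasso_gibbs(
    Z, y, n_iter, burn_in, thin, seed, lam2_init, lam_shape, lam_rate
):
    """Bayesian LASSO (Park-Casella): double-exponential via exponential
    mixing of marker-effect variances, gamma hyperprior on lambda^2.

    Returns posterior-mean beta and mu plus thinned chains of
    (lambda, sigma2_e, sigma2_g).
    """
    np.random.seed(seed)
    n, m = Z.shape
    zz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zz[j] = s

    beta = np.zeros(m)
    tau2 = np.ones(m)
    lam2 = lam2_init
    mu = y.mean()
    e = y - mu
    se2 = np.var(y) * 0.5 + 1e-12

    n_keep = (n_iter - burn_in) // thin
    lam_chain = np.empty(n_keep)
    se2_chain = np.empty(n_keep)
    sg2_chain = np.empty(n_keep)
    beta_sum = np.zeros(m)
    mu_sum = 0.0
    kept = 0

    for it in range(1, n_iter + 1):
        mu_new = mu + e.sum() / n + np.random.normal() * np.sqrt(se2 / n)
        for i in range(n):
            e[i] -= mu_new - mu
        mu = mu_new

        for j in range(m):
            zj2 = zz[j]
            if zj2 <= 0.0:
                continue
            bj = beta[j]
            rz = bj * zj2
            for i in range(n):
                rz += Z[i, j] * e[i]
            prec = zj2 + 1.0 / tau2[j]
            bnew = rz / prec + np.random.normal() * np.sqrt(se2 / prec)
            diff = bj - bnew
            for i in range(n):
                e[i] += Z[i, j] * diff
            beta[j] = bnew

        # mixing variances and lambda^2
        sum_tau2 = 0.0
        for j in range(m):
            b2 = beta[j] * beta[j]
            if b2 < 1e-12:
                b2 = 1e-12
            inv_t = _inv_gauss(np.sqrt(lam2 * se2 / b2), lam2)
            if inv_t < 1e-10:
                inv_t = 1e-10
            tau2[j] = 1.0 / inv_t
            sum_tau2 += tau2[j]
        lam2 = np.random.gamma(lam_shape + m, 1.0 / (lam_rate + sum_tau2 / 2.0))

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sb = 0.0
        for j in range(m):
            sb += beta[j] * beta[j] / tau2[j]
        se2 = (sse + sb) / np.random.chisquare(n - 1.0 + m)

        if it > burn_in and (it - burn_in) % thin == 0:
            gbar = 0.0
            for i in range(n):
                gbar += y[i] - mu - e[i]
            gbar /= n
            sg2 = 0.0
            for i in range(n):
                gi = y[i] - mu - e[i] - gbar
                sg2 += gi * gi
            sg2 /= n - 1
            lam_chain[kept] = np.sqrt(lam2)
            se2_chain[kept] = se2
            sg2_chain[kept] = sg2
            for j in range(m):
                beta_sum[j] += beta[j]
            mu_sum += mu
            kept += 1

    return (
        beta_sum / max(kept, 1),
        mu_sum / max(kept, 1),
        lam_chain,
        se2_chain,
        sg2_chain,
    )
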