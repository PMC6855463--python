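"""Estimator fronts for the Bayesian whole-genome regressions."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from ._gibbs import bayesb_gibbs, blasso_gibbs

__all__ = ["BayesB", "BayesianLasso"]


class _MarkerSampler(RegressorMixin, BaseEstimator):
    """Shared plumbing: centering, validation, prediction, chains."""

    def __init__(self, n_iter=10000, burn_in=2000, thin=10, seed=0):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed

    def _prepare(self, Z, y):
        Z = check_array(Z, ensure_all_finite=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != Z.shape[0]:
            raise ValueError("Z rows and y length differ")
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        p = (Z.mean(axis=0) + 1.0) / 2.0
        center = 2.0 * (p - 0.5)
        Zc = np.asfortranarray(Z - center)  # column access in the kernels
        return Zc, y, center

    def _finish(self, center, beta, mu, se2_chain, sg2_chain):
        self.center_ = center
        self.beta_ = beta
        self.mu_ = float(mu)
        self.sigma2_e_ = float(se2_chain.mean())
        self.sigma2_g_ = float(sg2_chain.mean())
        h2 = sg2_chain / (sg2_chain + se2_chain)
        self.h2_genomic_ = float(h2.mean())
        self.n_markers_ = len(beta)

    def predict(self, Z_new):
        check_is_fitted(self, "beta_")
        Z_new = check_array(Z_new, ensure_all_finite=True)
        if Z_new.shape[1] != self.n_markers_:
            raise ValueError(
                f"marker-set mismatch: fit used {self.n_markers_} markers, "
                f"got {Z_new.shape[1]}"
            )
        return self.mu_ + (Z_new - self.center_) @ self.beta_

    def predict_gebv(self, Z_new):
        return self.predict(Z_new) - self.mu_


class BayesB(_MarkerSampler):
    """BayesB: spike at zero plus a scaled-t slab with marker-specific
    variances; the nonnull probability pi is sampled under a Beta prior.

    Parameters
    ----------
    n_iter, burn_in, thin : MCMC run-length settings (defaults
        10000 / 2000 / 10).
    seed : int
        Same-seed runs are bit-identical.
    nu : float, default 5
        Slab degrees of freedom.
    r2 : float, default 0.5
        Prior share of phenotypic variance attributed to markers; fixes
        the slab scale.
    pi_prior : (a, b), default (2, 2)
        Beta prior counts on the nonnull probability (mildly favouring
        pi around 0.5).
    """

    def __init__(
        self,
        n_iter=10000,
        burn_in=2000,
        thin=10,
        seed=0,
        nu=5.0,
        r2=0.5,
        pi_prior=(2.0, 2.0),
    ):
        super().__init__(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
        self.nu = nu
        self.r2 = r2
        self.pi_prior = pi_prior

    def fit(self, Z, y):
        Zc, y, center = self._prepare(Z, y)
        var_y = y.var()
        msx = float(np.sum(Zc.var(axis=0)))
        # slab scale from the prior-R2 heuristic at pi ~ 0.5
        S2 = self.r2 * var_y * (self.nu - 2.0) / (self.nu * 0.5 * max(msx, 1e-12))
        nu_e, Se2 = 4.0, (1.0 - self.r2) * var_y
        beta, mu, pi_c, se2_c, sg2_c = bayesb_gibbs(
            Zc,
            y,
            int(self.n_iter),
            int(self.burn_in),
            int(self.thin),
            int(self.seed),
            float(self.nu),
            float(S2),
            nu_e,
            float(Se2),
            float(self.pi_prior[0]),
            float(self.pi_prior[1]),
        )
        self._finish(center, beta, mu, se2_c, sg2_c)
        self.pi_ = float(pi_c.mean())
        self.chains_ = {"pi": pi_c, "sigma2_e": se2_c, "sigma2_g": sg2_c}
        self.gebv_ = Zc @ beta
        return self


class BayesianLasso(_MarkerSampler):
    """Bayesian LASSO (Park-Casella hierarchy).

    Marker effects carry a double-exponential prior implemented through
    exponential mixing of normal variances; lambda^2 has a gamma
    hyperprior (weakly informative by default) and the posterior mean of
    lambda is reported.
    """

    def __init__(
        self,
        n_iter=10000,
        burn_in=2000,
        thin=10,
        seed=0,
        lam_shape=1.0,
        lam_rate=1e-4,
        r2=0.5,
    ):
        super().__init__(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed)
        self.lam_shape = lam_shape
        self.lam_rate = lam_rate
        self.r2 = r2

    def fit(self, Z, y):
        Zc, y, center = self._prepare(Z, y)
        msx = float(np.sum(Zc.var(axis=0)))
        # start lambda^2 where the prior marker variance matches r2
        lam2_init = 2.0 * max(msx, 1e-12) * (1.0 - self.r2) / self.r2
        beta, mu, lam_c, se2_c, sg2_c = blasso_gibbs(
            Zc,
            y,
            int(self.n_iter),
            int(self.burn_in),
            int(self.thin),
            int(self.seed),
            float(lam2_init),
            float(self.lam_shape),
            float(self.lam_rate),
        )
        self._finish(center, beta, mu, se2_c, sg2_c)
        self.lambda_ = float(lam_c.mean())
        self.chains_ = {"lambda": lam_c, "sigma2_e": se2_c, "sigma2_g": sg2_c}
        self.gebv_ = Zc @ beta
        return self
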