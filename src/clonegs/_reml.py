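"""Shared REML machinery.

Two engines are provided:

* :class:`MixedModelREML` — a dense mixed-model-equations engine for models
  with several independent random factors (the stage-1 clonal model).  The
  REML log-likelihood is evaluated through the Cholesky factor of the MME
  coefficient matrix, which also yields BLUEs, BLUPs and exact PEVs, and is
  maximised over log variance components with a derivative-free simplex
  search (robust to boundary components at desk scale).
* :func:`eigen_reml` — the single-kernel shortcut used by G-BLUP/RKHS:
  rotate the model into the eigenbasis of the relationship matrix, profile
  out the genetic variance and optimise the one remaining ratio.

Both parameterise the residual as sigma2_e and random factors k as
sigma2_k, with y = Xb + sum_k Z_k u_k + e, u_k ~ N(0, sigma2_k I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


class SingularFixedDesignError(ValueError):
    """Fixed-effect design is rank deficient (confounded levels)."""

    def __init__(self, aliased_levels):
        self.aliased_levels = list(aliased_levels)
        super().__init__(
            "singular fixed-effect design; aliased levels: "
            + ", ".join(map(str, self.aliased_levels))
        )


class RemlConvergenceError(RuntimeError):
    def __init__(self, last_params, message="REML did not converge"):
        self.last_params = last_params
        super().__init__(message)


@dataclass
class RemlResult:
    beta: np.ndarray  # fixed effects
    u: list  # list of BLUP vectors per random factor
    pev: list  # list of PEV vectors per random factor
    sigma2: np.ndarray  # variance components, residual last
    loglik: float  # REML log-likelihood (up to a constant)
    n_iter: int
    converged: bool


class MixedModelREML:
    """REML for y = Xb + sum_k Z_k u_k + e with independent random factors.

    Parameters
    ----------
    X : ndarray (n, p)
        Full-column-rank fixed design.  A rank check runs at construction;
        aliased columns raise :class:`SingularFixedDesignError` naming the
        offending column labels.
    Z_list : list of ndarray (n, q_k)
        Incidence matrices of the random factors.
    y : ndarray (n,)
    fixed_names : sequence, optional
        Column labels for X used in the singularity diagnostic.
    """

    def __init__(self, X, Z_list, y, fixed_names=None):
        self.X = np.asarray(X, dtype=float)
        self.Z_list = [np.asarray(Z, dtype=float) for Z in Z_list]
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        self.q = [Z.shape[1] for Z in self.Z_list]
        self._check_rank(fixed_names)
        W = np.hstack([self.X] + self.Z_list)
        self._W = W
        self._WtW = W.T @ W
        self._Wty = W.T @ self.y
        self._yty = float(self.y @ self.y)

    def _check_rank(self, fixed_names):
        # QR with pivoting exposes aliased columns by tiny diagonal of R
        _, R, piv = linalg.qr(self.X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(self.X.shape) * np.finfo(float).eps
        bad = piv[diag < tol] if (diag < tol).any() else []
        if len(bad):
            names = fixed_names if fixed_names is not None else range(self.p)
            raise SingularFixedDesignError([list(names)[j] for j in bad])

    # -- likelihood -------------------------------------------------------
    def _assemble(self, sigma2):
        """MME coefficient matrix C and RHS for given variance components."""
        s2e = sigma2[-1]
        C = self._WtW / s2e
        offset = self.p
        for k, qk in enumerate(self.q):
            idx = slice(offset, offset + qk)
            C[idx, idx] += np.eye(qk) / sigma2[k]
            offset += qk
        return C, self._Wty / s2e

    def _profiled(self, log_gamma):
        """Profiled -2 REML log-likelihood over variance ratios
        gamma_k = sigma2_k / sigma2_e (sigma2_e concentrated out), plus the
        implied residual variance.

        With C* the MME coefficient matrix at unit residual variance,
        -2l = (n-p) log(S/(n-p)) + sum_k q_k log gamma_k + log|C*| + (n-p)
        where S = y'y - theta'W'y.
        """
        gamma = np.exp(np.clip(log_gamma, -25.0, 25.0))
        C = self._WtW.copy()
        offset = self.p
        for k, qk in enumerate(self.q):
            idx = slice(offset, offset + qk)
            C[idx, idx] += np.eye(qk) / gamma[k]
            offset += qk
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            return 1e300, np.nan
        theta = linalg.cho_solve((L, True), self._Wty)
        S = max(self._yty - theta @ self._Wty, 1e-300)
        s2e = S / (self.n - self.p)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        val = (
            (self.n - self.p) * np.log(s2e)
            + float(np.dot(self.q, np.clip(log_gamma, -25.0, 25.0)))
            + logdet
            + (self.n - self.p)
        )
        return val, s2e

    def fit(self, max_iter=200, tol=1e-8) -> RemlResult:
        k = len(self.q)
        best = None
        for start in (0.0, np.log(0.1), np.log(10.0)):
            res = optimize.minimize(
                lambda t: self._profiled(t)[0],
                np.full(k, start),
                method="Nelder-Mead",
                options={
                    "xatol": tol,
                    "fatol": 1e-12,
                    "maxiter": max_iter * k * 20,
                },
            )
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise RemlConvergenceError(np.exp(best.x))
        log_gamma = np.clip(best.x, -25.0, 25.0)
        _, s2e = self._profiled(log_gamma)
        sigma2 = np.append(np.exp(log_gamma) * s2e, s2e)
        beta, u, pev = self.solve(sigma2)
        return RemlResult(
            beta=beta,
            u=u,
            pev=pev,
            sigma2=sigma2,
            loglik=-0.5 * best.fun,
            n_iter=best.nit,
            converged=bool(best.success),
        )

    def _profiled_ml(self, log_gamma):
        """Profiled -2 ML log-likelihood (fixed effects at GLS, residual
        variance concentrated out): n log(S/n) + log|Z'Z + G*^-1| +
        sum_k q_k log gamma_k + n."""
        lg = np.clip(log_gamma, -25.0, 25.0)
        gamma = np.exp(lg)
        C = self._WtW.copy()
        offset = self.p
        for k, qk in enumerate(self.q):
            idx = slice(offset, offset + qk)
            C[idx, idx] += np.eye(qk) / gamma[k]
            offset += qk
        try:
            L = linalg.cholesky(C, lower=True)
            Lz = linalg.cholesky(C[self.p :, self.p :], lower=True)
        except linalg.LinAlgError:
            return 1e300, np.nan
        theta = linalg.cho_solve((L, True), self._Wty)
        S = max(self._yty - theta @ self._Wty, 1e-300)
        val = (
            self.n * np.log(S / self.n)
            + 2.0 * np.sum(np.log(np.diag(Lz)))
            + float(np.dot(self.q, lg))
            + self.n
        )
        return val, S / self.n

    def fit_ml(self, max_iter=200, tol=1e-9):
        """Maximum-likelihood variance components and log-likelihood (up to
        the -n/2 log(2 pi) constant), for likelihood-ratio tests of fixed
        effects."""
        k = len(self.q)
        if k == 0:
            # OLS: closed form
            beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
            S = float(np.sum((self.y - self.X @ beta) ** 2))
            return -0.5 * (self.n * np.log(max(S, 1e-300) / self.n) + self.n)
        best = None
        for start in (0.0, np.log(0.1), np.log(10.0)):
            res = optimize.minimize(
                lambda t: self._profiled_ml(t)[0],
                np.full(k, start),
                method="Nelder-Mead",
                options={"xatol": tol, "fatol": 1e-12,
                         "maxiter": max_iter * k * 20},
            )
            if best is None or res.fun < best.fun:
                best = res
        if not np.isfinite(best.fun):
            raise RemlConvergenceError(np.exp(best.x))
        return -0.5 * best.fun

    def solve(self, sigma2):
        """Solve Henderson's equations at fixed variance components.

        Returns fixed effects, per-factor BLUPs, and per-factor PEVs taken
        from the corresponding diagonal blocks of the inverse coefficient
        matrix.
        """
        C, rhs = self._assemble(sigma2)
        L = linalg.cholesky(C, lower=True)
        theta = linalg.cho_solve((L, True), rhs)
        Cinv = linalg.cho_solve((L, True), np.eye(C.shape[0]))
        beta = theta[: self.p]
        u, pev, offset = [], [], self.p
        for qk in self.q:
            u.append(theta[offset : offset + qk])
            pev.append(np.diag(Cinv)[offset : offset + qk].copy())
            offset += qk
        return beta, u, pev


# -- single-kernel engine -------------------------------------------------

@dataclass
class KernelRemlResult:
    mu: float
    sigma2_g: float
    sigma2_e: float
    delta: float  # sigma2_e / sigma2_g
    loglik: float
    alpha: np.ndarray  # (K + delta I)^-1 (y - mu); GEBV = K @ alpha


def eigen_reml(K, y, ridge=1e-8, bounds=(-12.0, 12.0)) -> KernelRemlResult:
    """REML for y = 1*mu + g + e, g ~ N(0, sigma2_g K), via eigenrotation.

    K must be symmetric PSD of the same order as y.  The likelihood is
    profiled so that only log(delta) with delta = sigma2_e/sigma2_g is
    optimised (golden-section/Brent scalar search).
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("kernel/response dimension mismatch")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel matrix must be symmetric")
    if np.ptp(y) == 0:
        raise ValueError("constant response; variance components undefined")
    vals, vecs = linalg.eigh(K)
    vals = np.maximum(vals, 0.0) + ridge
    yt = vecs.T @ y
    xt = vecs.T @ np.ones(n)

    def profile(log_delta):
        delta = np.exp(log_delta)
        lam = vals + delta
        xx = np.sum(xt * xt / lam)
        xy = np.sum(xt * yt / lam)
        mu = xy / xx
        r = yt - mu * xt
        s2g = float(np.sum(r * r / lam) / (n - 1))
        n2ll = (
            (n - 1) * np.log(s2g)
            + np.sum(np.log(lam))
            + np.log(xx)
            + (n - 1)
        )
        return n2ll, mu, s2g, delta

    res = optimize.minimize_scalar(
        lambda t: profile(t)[0], bounds=bounds, method="bounded",
        options={"xatol": 1e-10},
    )
    n2ll, mu, s2g, delta = profile(res.x)
    lam = vals + delta
    r = yt - mu * xt
    alpha = vecs @ (r / lam)
    return KernelRemlResult(
        mu=float(mu),
        sigma2_g=s2g,
        sigma2_e=s2g * delta,
        delta=float(delta),
        loglik=-0.5 * n2ll,
        alpha=alpha,
    )
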