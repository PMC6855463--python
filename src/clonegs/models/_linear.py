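"""REML-based genomic prediction estimators (RR-BLUP, G-BLUP, RKHS).

All three fit the single-kernel mixed model y = 1*mu + g + e by REML via
eigendecomposition of the relationship matrix.  RR-BLUP is the marker-space
parameterisation of the same model: with VanRaden-centered dosages Zc and
G = Zc Zc'/c, the ridge solution with lambda = sigma2_e/sigma2_beta yields
GEBVs identical to the G-BLUP fit (sigma2_g = c * sigma2_beta).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .._reml import eigen_reml
from ..containers import KinshipMatrix

__all__ = ["KernelBLUP", "GBLUP", "RKHS", "RRBLUP"]


class KernelBLUP(RegressorMixin, BaseEstimator):
    """BLUP on a precomputed relationship kernel.

    ``fit(K, y)`` takes the training-by-training kernel block;
    ``predict(K_new)`` takes new-by-training kernel rows and returns
    ``mu_ + K_new @ alpha_`` (the conditional-expectation projection,
    which reproduces the fitted GEBVs on the training block itself).

    Attributes (after fit): ``mu_``, ``alpha_``, ``gebv_``,
    ``sigma2_g_``, ``sigma2_e_``, ``h2_genomic_``, ``loglik_``.
    """

    expected_kind = None  # subclasses may pin a KinshipMatrix kind

    def __init__(self, ridge=1e-8):
        self.ridge = ridge

    def _unwrap(self, K):
        if isinstance(K, KinshipMatrix):
            if self.expected_kind and K.kind != self.expected_kind:
                raise ValueError(
                    f"{type(self).__name__} expects a {self.expected_kind} "
                    f"kernel, got {K.kind}"
                )
            K = K.values
        return check_array(K, ensure_all_finite=True)

    def fit(self, K, y):
        K = self._unwrap(K)
        y = np.asarray(y, dtype=float).ravel()
        if K.shape[0] != K.shape[1] or K.shape[0] != len(y):
            raise ValueError("fit needs the square training kernel block")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        if K.shape[0] > 1 and np.allclose(K, K.flat[0]):
            raise ValueError("degenerate kernel (all entries equal): no contrast")
        res = eigen_reml(K, y, ridge=self.ridge)
        self.mu_ = res.mu
        self.alpha_ = res.alpha
        self.sigma2_g_ = res.sigma2_g
        self.sigma2_e_ = res.sigma2_e
        self.h2_genomic_ = res.sigma2_g / (res.sigma2_g + res.sigma2_e)
        self.loglik_ = res.loglik
        self.gebv_ = K @ res.alpha
        self.n_train_ = len(y)
        return self

    def predict(self, K_new):
        check_is_fitted(self, "alpha_")
        K_new = self._unwrap(K_new)
        if K_new.shape[1] != self.n_train_:
            raise ValueError("K_new columns must index the training individuals")
        return self.mu_ + K_new @ self.alpha_

    def predict_gebv(self, K_new):
        """GEBVs (deviations, no intercept) for new kernel rows."""
        return self.predict(K_new) - self.mu_


class GBLUP(KernelBLUP):
    """G-BLUP: additive genomic relationship matrix as the kernel."""

    expected_kind = "additive_G"


class RKHS(KernelBLUP):
    """RKHS regression with the Gaussian kernel (additive + non-additive)."""

    expected_kind = "gaussian_K"


class RRBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP of marker effects.

    ``fit(Z, y)`` takes the complete dosage matrix (codes -1/0/1);
    variance components are obtained by REML through the equivalent
    G-BLUP model and back-transformed (sigma2_beta = sigma2_g / c with
    c = 2*sum(p(1-p))).

    Attributes: ``beta_`` (marker effects), ``mu_``, ``sigma2_beta_``,
    ``sigma2_e_``, ``sigma2_g_``, ``h2_genomic_``, ``gebv_``.
    """

    def __init__(self, ridge=1e-8, min_train=20):
        self.ridge = ridge
        self.min_train = min_train

    def fit(self, Z, y):
        Z = check_array(Z, ensure_all_finite=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != Z.shape[0]:
            raise ValueError("Z rows and y length differ")
        if len(y) < self.min_train:
            raise ValueError(f"need at least {self.min_train} training records")
        if np.ptp(y) == 0:
            raise ValueError("constant response")
        p = (Z.mean(axis=0) + 1.0) / 2.0
        c = 2.0 * float(np.sum(p * (1.0 - p)))
        if c <= 0:
            raise ValueError("all markers monomorphic")
        Zc = Z - 2.0 * (p - 0.5)
        G = Zc @ Zc.T / c
        res = eigen_reml(G, y, ridge=self.ridge)
        self.center_ = 2.0 * (p - 0.5)
        self.mu_ = res.mu
        self.beta_ = Zc.T @ res.alpha / c
        self.sigma2_g_ = res.sigma2_g
        self.sigma2_beta_ = res.sigma2_g / c
        self.sigma2_e_ = res.sigma2_e
        self.h2_genomic_ = res.sigma2_g / (res.sigma2_g + res.sigma2_e)
        self.gebv_ = Zc @ self.beta_
        self.n_markers_ = Z.shape[1]
        return self

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
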