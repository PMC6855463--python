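"""Genomic prediction methods.

Estimators: :class:`RRBLUP`, :class:`GBLUP`, :class:`RKHS`,
:class:`BayesB`, :class:`BayesianLasso` — scikit-learn style, with
``fit``/``predict``/``predict_gebv`` and fitted attributes
(``mu_``, ``gebv_``, ``sigma2_g_``, ``sigma2_e_``, ``h2_genomic_``,
``beta_`` for marker methods, chains for the samplers).

The ``fit_*`` functions wrap the estimators into the
:class:`~clonegs.containers.GsFit` record used by the cross-validation
and comparison layers.
"""

from __future__ import annotations

import numpy as np

from ..containers import GenotypeMatrix, GsFit, KinshipMatrix
from ._bayes import BayesB, BayesianLasso
from ._linear import GBLUP, RKHS, RRBLUP, KernelBLUP
from .diagnostics import RafteryLewisResult, raftery_lewis

__all__ = [
    "RRBLUP",
    "GBLUP",
    "RKHS",
    "BayesB",
    "BayesianLasso",
    "KernelBLUP",
    "fit_rrblup",
    "fit_gblup",
    "fit_rkhs",
    "fit_bayesb",
    "fit_blasso",
    "predict_gebv",
    "raftery_lewis",
    "RafteryLewisResult",
    "METHODS",
]


def _as_Z(Z):
    return Z.dosages if isinstance(Z, GenotypeMatrix) else np.asarray(Z, float)


def fit_rrblup(y_d, Z, ids=None) -> GsFit:
    est = RRBLUP().fit(_as_Z(Z), y_d)
    return GsFit(
        method="RRBLUP",
        mu=est.mu_,
        training_ids=list(ids) if ids is not None else list(range(len(y_d))),
        gebv_train=est.gebv_,
        sigma2_g=est.sigma2_g_,
        sigma2_e=est.sigma2_e_,
        h2_genomic=est.h2_genomic_,
        beta=est.beta_,
        sigma2_beta=est.sigma2_beta_,
        estimator=est,
    )


def _fit_kernel(method, cls, y_d, K, ids) -> GsFit:
    est = cls().fit(K, y_d)
    return GsFit(
        method=method,
        mu=est.mu_,
        training_ids=list(ids) if ids is not None else list(range(len(y_d))),
        gebv_train=est.gebv_,
        sigma2_g=est.sigma2_g_,
        sigma2_e=est.sigma2_e_,
        h2_genomic=est.h2_genomic_,
        g=est.gebv_,
        estimator=est,
    )


def fit_gblup(y_d, K: KinshipMatrix, ids=None) -> GsFit:
    return _fit_kernel("GBLUP", GBLUP, y_d, K, ids)


def fit_rkhs(y_d, K: KinshipMatrix, ids=None) -> GsFit:
    return _fit_kernel("RKHS", RKHS, y_d, K, ids)


def fit_bayesb(
    y_d, Z, n_iter=10000, burn_in=2000, thin=10, seed=0, ids=None
) -> GsFit:
    est = BayesB(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed).fit(
        _as_Z(Z), y_d
    )
    return GsFit(
        method="BAYESB",
        mu=est.mu_,
        training_ids=list(ids) if ids is not None else list(range(len(y_d))),
        gebv_train=est.gebv_,
        sigma2_g=est.sigma2_g_,
        sigma2_e=est.sigma2_e_,
        h2_genomic=est.h2_genomic_,
        beta=est.beta_,
        pi=est.pi_,
        chains=est.chains_,
        estimator=est,
    )


def fit_blasso(
    y_d, Z, n_iter=10000, burn_in=2000, thin=10, seed=0, ids=None
) -> GsFit:
    est = BayesianLasso(n_iter=n_iter, burn_in=burn_in, thin=thin, seed=seed).fit(
        _as_Z(Z), y_d
    )
    return GsFit(
        method="BLASSO",
        mu=est.mu_,
        training_ids=list(ids) if ids is not None else list(range(len(y_d))),
        gebv_train=est.gebv_,
        sigma2_g=est.sigma2_g_,
        sigma2_e=est.sigma2_e_,
        h2_genomic=est.h2_genomic_,
        beta=est.beta_,
        lam=est.lambda_,
        chains=est.chains_,
        estimator=est,
    )


def predict_gebv(fit: GsFit, Z_new_or_K_rows) -> np.ndarray:
    """GEBVs for new individuals.

    Marker methods take a dosage matrix over the training marker set;
    kernel methods take kernel rows linking the new individuals to the
    training individuals (columns in training order).
    """
    est = fit.estimator
    if est is None:
        raise ValueError("GsFit carries no estimator; refit required")
    arr = _as_Z(Z_new_or_K_rows)
    return est.predict_gebv(arr)


#: method registry used by the CV layer
METHODS = {
    "RRBLUP": fit_rrblup,
    "GBLUP": fit_gblup,
    "RKHS": fit_rkhs,
    "BAYESB": fit_bayesb,
    "BLASSO": fit_blasso,
}
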