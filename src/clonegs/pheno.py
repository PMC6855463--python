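"""Stage-1 phenotype modelling for clonal trials.

Fits, per trait, the clonal mixed model

    y_ijl = mu + c_i + beta_j + r_l(j) + e_ijl

with clone ``c_i`` random, location-year combination ``beta_j`` fixed
(reference-level coding), replicate-within-location-year ``r_l(j)`` random,
and an i.i.d. plot residual, by REML.  Clone BLUPs and their exact
prediction error variances come from the inverse coefficient matrix of
Henderson's mixed-model equations; deregression divides each BLUP by its
reliability ``1 - PEV/sigma2_clone`` so the shrinkage is removed before
the values are used as genomic-selection responses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._reml import MixedModelREML, SingularFixedDesignError  # noqa: F401
from .containers import ClonalEstimates

__all__ = [
    "fit_clonal_lmm",
    "deregress",
    "phenotypic_heritability",
    "SingularFixedDesignError",
]


def _indicator(codes: pd.Series) -> tuple[np.ndarray, list]:
    levels = list(pd.unique(codes))
    lut = {lev: j for j, lev in enumerate(levels)}
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), [lut[c] for c in codes]] = 1.0
    return Z, levels


def fit_clonal_lmm(
    trials: pd.DataFrame, trait: str, reliability_floor: float = 0.05
) -> ClonalEstimates:
    """Fit the clonal mixed model for one trait and return clone summaries.

    Parameters
    ----------
    trials : DataFrame
        Plot records with columns ``clone``, ``location``, ``year``,
        ``rep`` and the trait column.  Missing trait values are dropped.
    trait : str
        Name of the trait column to model.
    reliability_floor : float
        Clones with reliability at or below this value are flagged as
        unusable for GS training (deregression diverges as reliability
        approaches zero).
    """
    if trait not in trials.columns:
        raise KeyError(f"trait column {trait!r} not in trial table")
    d = trials.loc[trials[trait].notna()].reset_index(drop=True)
    if d["clone"].nunique() < 2:
        raise ValueError("need records for at least 2 clones")
    y = d[trait].to_numpy(dtype=float)

    ly = d["location"].astype(str) + ":" + d["year"].astype(str)
    ly_levels = list(pd.unique(ly))
    # reference-level coding keeps the intercept identifiable
    X = np.ones((len(d), 1))
    names = ["intercept"]
    for lev in ly_levels[1:]:
        X = np.hstack([X, (ly == lev).to_numpy(dtype=float)[:, None]])
        names.append(f"ly[{lev}]")

    Z_clone, clones = _indicator(d["clone"])
    Z_rep, rep_levels = _indicator(d["rep"].astype(str))

    engine = MixedModelREML(X, [Z_clone, Z_rep], y, fixed_names=names)
    res = engine.fit()
    s2c, s2r, s2e = res.sigma2

    blup = res.u[0]
    pev = np.maximum(res.pev[0], 0.0)
    reliability = np.clip(1.0 - pev / s2c, 0.0, 1.0) if s2c > 0 else np.zeros_like(pev)

    table = pd.DataFrame(
        {
            "clone": clones,
            "blup": blup,
            "pev": pev,
            "reliability": reliability,
            "deregressed": np.nan,
            "flagged": False,
        }
    ).sort_values("clone").reset_index(drop=True)

    est = ClonalEstimates(
        trait=trait,
        table=table,
        sigma2_clone=float(s2c),
        sigma2_rep=float(s2r),
        sigma2_resid=float(s2e),
        grand_mean=float(res.beta[0]),
        fixed_effects=dict(zip(names, res.beta)),
        reliability_floor=reliability_floor,
        converged=res.converged,
    )
    est.h2_phen = phenotypic_heritability(est)
    return deregress(est)


def deregress(estimates: ClonalEstimates) -> ClonalEstimates:
    """Populate deregressed BLUPs: deregressed = BLUP / (1 - PEV/sigma2_c).

    Clones whose reliability is at or below the configured floor are
    flagged (kept in the table, excluded by :meth:`training_frame`); a
    reliability of zero (PEV >= sigma2_clone) carries no information and
    is flagged rather than dropped.
    """
    if estimates.sigma2_clone <= 0:
        raise ValueError("sigma2_clone must be positive to deregress")
    t = estimates.table
    rel = t["reliability"].to_numpy()
    dereg = np.full(len(t), np.nan)
    ok = rel > 0
    dereg[ok] = t.loc[ok, "blup"].to_numpy() / rel[ok]
    t["deregressed"] = dereg
    t["flagged"] = rel <= estimates.reliability_floor
    return estimates


def phenotypic_heritability(
    estimates: ClonalEstimates, basis: str = "plot", n_reps: float | None = None
) -> float:
    """Phenotypic (broad-sense, clone-level) heritability.

    ``basis='plot'`` (default) returns sigma2_c / (sigma2_c + sigma2_rep +
    sigma2_resid); ``basis='entry_mean'`` divides the non-genetic terms by
    the effective replicate number ``n_reps``.
    """
    s2c, s2r, s2e = (
        estimates.sigma2_clone,
        estimates.sigma2_rep,
        estimates.sigma2_resid,
    )
    if s2c <= 0 and s2r <= 0 and s2e <= 0:
        raise ValueError("all variance components are zero")
    if basis == "plot":
        return float(s2c / (s2c + s2r + s2e))
    if basis == "entry_mean":
        if not n_reps or n_reps <= 0:
            raise ValueError("entry_mean basis needs n_reps > 0")
        return float(s2c / (s2c + (s2r + s2e) / n_reps))
    raise ValueError(f"unknown basis {basis!r}")
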