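"""Method-comparison statistics on cross-validation output.

* :func:`deviance_analysis` — linear mixed models on a fold-level metric
  (methods fixed; the cross-validation unit random; optionally the
  training-x-validation population interaction random), fitted by ML,
  with each term tested by a likelihood-ratio chi-square against the
  reduced model and method means separated by Tukey's studentized-range
  test with a compact letter display.
* :func:`gebv_correlation_matrix` — Pearson correlations of GEBV vectors
  between methods (and against stage-1 BLUPs when supplied).
* :func:`kappa_selection` — Cohen's Kappa of top-fraction selections
  between two GEBV rankings over a grid of selection proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import MixedModelREML

__all__ = [
    "DevianceTable",
    "deviance_analysis",
    "gebv_correlation_matrix",
    "kappa_selection",
    "cohen_kappa_binary",
    "tukey_letters",
]


@dataclass
class DevianceTable:
    response: str
    terms: pd.DataFrame  # term, df, deviance, p_value
    method_means: pd.DataFrame  # method, mean, se, letter


def _indicator(codes: pd.Series) -> np.ndarray:
    levels = pd.unique(codes)
    return (codes.to_numpy()[:, None] == levels[None, :]).astype(float)


def _ml_loglik(data, with_method, vc_terms):
    """Exact profiled ML log-likelihood of the deviance model: method as a
    fixed factor (reference coding) and crossed random intercepts for the
    listed variance-component columns."""
    y = data["y"].to_numpy(dtype=float)
    X = np.ones((len(data), 1))
    if with_method:
        X = np.hstack([X, _indicator(data["method"])[:, 1:]])
    Z_list = [_indicator(data[col]) for col in vc_terms.values()]
    return MixedModelREML(X, Z_list, y).fit_ml()


def tukey_letters(means: pd.Series, se_diff: float, df_resid: float, alpha=0.05):
    """Compact letter display from pairwise studentized-range tests.

    ``se_diff`` is the standard error of a difference between two method
    means (balanced design).  Returns (letters dict, p-value frame).
    """
    names = list(means.sort_values(ascending=False).index)
    k = len(names)
    pvals = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            qstat = abs(means[names[i]] - means[names[j]]) / (
                se_diff / np.sqrt(2.0)
            )
            p = stats.studentized_range.sf(qstat, k, df_resid)
            pvals.iloc[i, j] = pvals.iloc[j, i] = p
    # insert-and-absorb letter algorithm on the sorted means
    groups = []  # each group: set of mutually non-distinct methods
    for i, name in enumerate(names):
        placed = False
        for g in groups:
            if all(pvals.loc[name, other] > alpha for other in g):
                g.append(name)
                placed = True
        if not placed:
            g = [name] + [
                other
                for other in names[:i]
                if pvals.loc[name, other] > alpha
            ]
            groups.append(sorted(g, key=names.index))
    # drop groups contained in others, assign letters in mean order
    groups = [
        g
        for g in groups
        if not any(set(g) < set(h) for h in groups if h is not g)
    ]
    groups.sort(key=lambda g: names.index(g[0]))
    letters = {n: "" for n in names}
    for letter, g in zip("ABCDEFGHIJKLMNOPQRSTUVWXYZ", groups):
        for n in g:
            letters[n] += letter
    return letters, pvals


def deviance_analysis(
    cv: pd.DataFrame,
    response: str = "predictive_ability",
    with_structure: bool = False,
    alpha: float = 0.05,
) -> DevianceTable:
    """LRT deviance analysis of a CV metric and Tukey mean separation.

    The full model is ``response ~ method`` (fixed) with a random
    cross-validation unit (replicate x fold), plus, when
    ``with_structure``, a random training-x-validation population
    interaction (validation cluster x absent cluster).  Each term's
    deviance is twice the ML log-likelihood gap to the model without it
    (chi-square reference; 1 df for the random terms).
    """
    if response not in cv.columns:
        raise ValueError(f"response {response!r} not in CV results")
    d = cv.loc[cv[response].notna()].copy()
    if d.empty:
        raise ValueError(f"response {response!r} entirely missing")
    if d["method"].nunique() < 2:
        raise ValueError("need at least 2 methods")
    if d["replicate"].nunique() < 2:
        raise ValueError(
            "need at least 2 replicates (cross-validation effect inestimable)"
        )
    d["y"] = d[response].astype(float)
    d["cv_unit"] = (
        d["replicate"].astype(str) + ":" + d["fold"].astype(str)
    )
    vc = {"cv": "cv_unit"}
    if with_structure:
        d["structure_unit"] = (
            d["validation_cluster"].astype(str)
            + ":"
            + d["absent_cluster"].astype(str)
        )
        vc["structure"] = "structure_unit"

    full = _ml_loglik(d, True, vc)
    n_methods = d["method"].nunique()
    terms = []

    ll_no_m = _ml_loglik(d, False, vc)
    dev = max(2.0 * (full - ll_no_m), 0.0)
    df_m = n_methods - 1
    terms.append(
        {
            "term": "methods",
            "df": df_m,
            "deviance": dev,
            "p_value": stats.chi2.sf(dev, df_m),
        }
    )
    for name, label in [("cv", "cross_validation"), ("structure", "population_structure")]:
        if name not in vc:
            continue
        reduced = {k: v for k, v in vc.items() if k != name}
        ll_red = _ml_loglik(d, True, reduced)
        dev = max(2.0 * (full - ll_red), 0.0)
        terms.append(
            {
                "term": label,
                "df": 1,
                "deviance": dev,
                "p_value": stats.chi2.sf(dev, 1),
            }
        )

    # Tukey on method means; balanced CV output, residual MS from the
    # method+unit two-way layout
    means = d.groupby("method")["y"].mean()
    reps = d.groupby("method")["y"].count()
    n_per = int(reps.min())
    resid = d["y"] - d.groupby("method")["y"].transform("mean") - d.groupby(
        "cv_unit"
    )["y"].transform("mean") + d["y"].mean()
    df_resid = max(len(d) - n_methods - d["cv_unit"].nunique() + 1, 1)
    ms_resid = float((resid**2).sum() / df_resid)
    se_mean = np.sqrt(ms_resid / n_per)
    se_diff = np.sqrt(2.0 * ms_resid / n_per)
    letters, _ = tukey_letters(means, se_diff, df_resid, alpha=alpha)
    method_sd = d.groupby("method")["y"].std()
    method_means = pd.DataFrame(
        {
            "method": means.index,
            "mean": means.to_numpy(),
            "se": [float(method_sd[m]) / np.sqrt(reps[m]) for m in means.index],
            "letter": [letters[m] for m in means.index],
        }
    ).sort_values("mean", ascending=False).reset_index(drop=True)
    method_means.attrs["se_mean_pooled"] = float(se_mean)
    return DevianceTable(
        response=response,
        terms=pd.DataFrame(terms),
        method_means=method_means,
    )


def gebv_correlation_matrix(
    gebvs: dict[str, np.ndarray], blups: np.ndarray | None = None
) -> pd.DataFrame:
    """Pearson correlation matrix of GEBV vectors across methods.

    All vectors must cover the same individuals in the same order; when
    ``blups`` is given it enters as an extra ``BLUP`` column/row.
    """
    data = {k: np.asarray(v, float) for k, v in gebvs.items()}
    if blups is not None:
        data["BLUP"] = np.asarray(blups, float)
    lengths = {len(v) for v in data.values()}
    if len(lengths) != 1:
        raise ValueError("GEBV vectors differ in length")
    if lengths.pop() < 3:
        raise ValueError("need at least 3 common individuals")
    frame = pd.DataFrame(data)
    return frame.corr(method="pearson")


def cohen_kappa_binary(sel_a: np.ndarray, sel_b: np.ndarray) -> float:
    """Cohen's Kappa of two binary selection vectors."""
    a = np.asarray(sel_a, bool)
    b = np.asarray(sel_b, bool)
    n = len(a)
    po = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def kappa_selection(
    gebv_a, gebv_b, sp_grid=None, ids=None
) -> pd.DataFrame:
    """Kappa of top-fraction selections between two rankings.

    For each selection proportion SP the top ``ceil(SP * n)`` individuals
    by each GEBV vector are coded 1 and the rest 0; ties in GEBV break by
    id order (deterministic).  Default SP grid: 1% to 30% in 1% steps.
    """
    a = np.asarray(gebv_a, float)
    b = np.asarray(gebv_b, float)
    if len(a) != len(b):
        raise ValueError("GEBV vectors differ in length")
    n = len(a)
    if sp_grid is None:
        sp_grid = np.arange(0.01, 0.301, 0.01)
    sp_grid = np.asarray(list(sp_grid), float)
    if np.ceil(sp_grid.min() * n) < 1:
        raise ValueError("smallest SP selects nobody")
    order_ids = np.arange(n) if ids is None else np.argsort(np.asarray(ids))
    # stable ranking: sort by (-gebv, id order)
    rank_a = np.lexsort((order_ids, -a))
    rank_b = np.lexsort((order_ids, -b))
    rows = []
    for sp in sp_grid:
        k = int(np.ceil(sp * n))
        sel_a = np.zeros(n, bool)
        sel_b = np.zeros(n, bool)
        sel_a[rank_a[:k]] = True
        sel_b[rank_b[:k]] = True
        rows.append({"sp": sp, "n_selected": k, "kappa": cohen_kappa_binary(sel_a, sel_b)})
    return pd.DataFrame(rows)
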