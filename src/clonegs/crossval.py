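"""Population-structure-aware cross-validation designs and fold metrics.

Four strategies:

* ``S1_random`` — plain k-fold (default 5 folds, 3 replicates) ignoring
  structure; per replicate the validation folds partition all ids.
* ``S2_within_cluster`` — training and validation drawn from the same
  cluster (k-fold inside each cluster; 3 folds, 3 replicates).
* ``S3_leave_cluster_out`` — validate on one fold-part of a cluster,
  train on one fold-part of every *other* cluster (a ``full_training``
  switch uses the other clusters in full instead).
* ``S4_three_cluster_training`` — as S3 but one further cluster is also
  left out of training; every choice of absent cluster is enumerated.

Per fold, four evaluation quantities are computed: predictive ability
(correlation of validation GEBVs with validation BLUPs), bias (regression
slope of training response on training GEBVs; >1 means effects were
underestimated), prediction accuracy (predictive ability divided by the
square root of the phenotypic heritability) and the genomic heritability
of the training fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClonalEstimates, GenotypeMatrix, KinshipMatrix
from .markers import additive_G, gaussian_K
from .models import METHODS, predict_gebv

STRATEGIES = (
    "S1_random",
    "S2_within_cluster",
    "S3_leave_cluster_out",
    "S4_three_cluster_training",
)

__all__ = [
    "CVPlan",
    "CVEntry",
    "make_cv_plan",
    "run_cv",
    "predictive_ability",
    "bias",
    "accuracy",
    "STRATEGIES",
]


@dataclass
class CVEntry:
    replicate: int
    fold: int
    validation_cluster: int | None
    absent_cluster: int | None
    training_ids: list
    validation_ids: list


@dataclass
class CVPlan:
    strategy: str
    folds: int
    replicates: int
    seed: int
    entries: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def _partition(ids, folds, rng):
    ids = np.asarray(ids)
    perm = rng.permutation(len(ids))
    return [ids[part] for part in np.array_split(perm, folds)]


def make_cv_plan(
    strategy: str,
    ids,
    cluster_labels=None,
    folds: int | None = None,
    replicates: int = 3,
    seed: int = 0,
    full_training: bool = False,
) -> CVPlan:
    """Build a seeded cross-validation plan.

    ``cluster_labels`` (id -> cluster) is required for S2-S4.  Default
    fold counts follow the study design: 5 for S1, 3 for S2-S4.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    ids = list(ids)
    if folds is None:
        folds = 5 if strategy == "S1_random" else 3
    rng = np.random.default_rng(seed)
    plan = CVPlan(strategy=strategy, folds=folds, replicates=replicates, seed=seed)

    if strategy == "S1_random":
        if folds > len(ids):
            raise ValueError("more folds than individuals")
        for rep in range(replicates):
            parts = _partition(ids, folds, rng)
            for f, val in enumerate(parts):
                train = np.setdiff1d(ids, val)
                plan.entries.append(
                    CVEntry(rep, f, None, None, list(train), list(val))
                )
        return plan

    if cluster_labels is None:
        raise ValueError(f"{strategy} requires cluster labels")
    labels = pd.Series(cluster_labels)
    labels = labels.loc[ids]
    clusters = sorted(labels.unique())
    need = {"S2_within_cluster": 2, "S3_leave_cluster_out": 2,
            "S4_three_cluster_training": 3}[strategy]
    if len(clusters) < need:
        raise ValueError(f"{strategy} needs at least {need} clusters")
    smallest = labels.value_counts().min()
    if folds > smallest:
        raise ValueError(
            f"folds={folds} exceeds the smallest cluster size ({smallest})"
        )

    for rep in range(replicates):
        # one fold-partition per cluster, shared across entries of this rep
        parts = {c: _partition(labels.index[labels == c], folds, rng) for c in clusters}
        for f in range(folds):
            for vc in clusters:
                val = parts[vc][f]
                if strategy == "S2_within_cluster":
                    train = np.concatenate(
                        [parts[vc][g] for g in range(folds) if g != f]
                    )
                    plan.entries.append(
                        CVEntry(rep, f, vc, None, list(train), list(val))
                    )
                elif strategy == "S3_leave_cluster_out":
                    others = [c for c in clusters if c != vc]
                    if full_training:
                        train = np.concatenate(
                            [np.concatenate(parts[c]) for c in others]
                        )
                    else:
                        train = np.concatenate([parts[c][f] for c in others])
                    plan.entries.append(
                        CVEntry(rep, f, vc, None, list(train), list(val))
                    )
                else:  # S4: enumerate each absent cluster
                    others = [c for c in clusters if c != vc]
                    for absent in others:
                        kept = [c for c in others if c != absent]
                        if full_training:
                            train = np.concatenate(
                                [np.concatenate(parts[c]) for c in kept]
                            )
                        else:
                            train = np.concatenate([parts[c][f] for c in kept])
                        plan.entries.append(
                            CVEntry(rep, f, vc, absent, list(train), list(val))
                        )
    return plan


# -- metrics --------------------------------------------------------------

def predictive_ability(gebv_val, blup_val):
    """Pearson correlation of validation GEBVs with validation BLUPs."""
    a = np.asarray(gebv_val, float)
    b = np.asarray(blup_val, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in predictive-ability inputs")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def bias(gebv_train, y_train_deregressed, literal_sd: bool = False):
    """Dispersion bias of training GEBVs.

    Default: regression slope cov(GEBV, y)/var(GEBV) (slope > 1 means the
    marker effects were underestimated).  ``literal_sd=True`` divides the
    covariance by the GEBV standard deviation instead.
    """
    g = np.asarray(gebv_train, float)
    y = np.asarray(y_train_deregressed, float)
    if len(g) != len(y) or len(g) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if g.std() == 0:
        warnings.warn("zero GEBV variance in bias computation")
        return np.nan
    cov = float(np.cov(g, y)[0, 1])
    return cov / float(g.std(ddof=1)) if literal_sd else cov / float(
        g.var(ddof=1)
    )


def accuracy(r_yy, h2_phen):
    """Prediction accuracy: predictive ability / sqrt(h2_phen)."""
    if not 0.0 < h2_phen <= 1.0:
        raise ValueError("h2_phen must be in (0, 1]")
    return float(r_yy) / float(np.sqrt(h2_phen))


# -- runner ---------------------------------------------------------------

def run_cv(
    plan: CVPlan,
    method: str,
    geno: GenotypeMatrix,
    estimates: ClonalEstimates,
    trait: str | None = None,
    kernels: dict | None = None,
    mcmc: dict | None = None,
    min_validation: int = 3,
) -> pd.DataFrame:
    """Run one genomic prediction method over a CV plan.

    Training responses are the deregressed BLUPs of the training ids
    (reliability-flagged clones excluded); validation is scored against
    the BLUPs of the validation ids.  The same plan (hence identical
    train/validation memberships) can be served to every method.

    Returns a tidy frame with one row per plan entry.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    trait = trait or estimates.trait
    table = estimates.table.set_index("clone")
    sample_index = {s: i for i, s in enumerate(geno.samples)}

    if kernels is None:
        kernels = {}
    if method == "GBLUP" and "additive_G" not in kernels:
        kernels["additive_G"] = additive_G(geno)
    if method == "RKHS" and "gaussian_K" not in kernels:
        kernels["gaussian_K"] = gaussian_K(geno)
    mcmc = mcmc or {}

    rows = []
    for entry in plan:
        train = [
            s
            for s in entry.training_ids
            if s in table.index and not table.loc[s, "flagged"]
        ]
        val = [s for s in entry.validation_ids if s in table.index]
        row = {
            "strategy": plan.strategy,
            "method": method,
            "trait": trait,
            "replicate": entry.replicate,
            "fold": entry.fold,
            "validation_cluster": entry.validation_cluster,
            "absent_cluster": entry.absent_cluster,
            "n_train": len(train),
            "n_val": len(val),
            "predictive_ability": np.nan,
            "bias": np.nan,
            "accuracy": np.nan,
            "h2_genomic": np.nan,
        }
        if len(val) < min_validation or len(train) < 3:
            warnings.warn(
                f"fold ({entry.replicate},{entry.fold}) too small; metrics missing"
            )
            rows.append(row)
            continue
        y_train = table.loc[train, "deregressed"].to_numpy(float)
        blup_val = table.loc[val, "blup"].to_numpy(float)

        if method in ("GBLUP", "RKHS"):
            km = kernels["additive_G" if method == "GBLUP" else "gaussian_K"]
            K_tt = km.submatrix(train)
            fit = METHODS[method](y_train, K_tt, ids=train)
            gebv_val = predict_gebv(fit, km.submatrix(val, train))
        else:
            Z = geno.dosages
            tr_idx = [sample_index[s] for s in train]
            va_idx = [sample_index[s] for s in val]
            kwargs = dict(ids=train)
            if method in ("BAYESB", "BLASSO"):
                kwargs.update(mcmc)
                kwargs.setdefault("seed", plan.seed + 7919 * entry.replicate + entry.fold)
            fit = METHODS[method](y_train, Z[tr_idx], **kwargs)
            gebv_val = predict_gebv(fit, Z[va_idx])

        r = predictive_ability(gebv_val, blup_val)
        row.update(
            predictive_ability=r,
            bias=bias(fit.gebv_train, y_train),
            accuracy=accuracy(r, estimates.h2_phen)
            if np.isfinite(r)
            else np.nan,
            h2_genomic=fit.h2_genomic,
        )
        rows.append(row)
    return pd.DataFrame(rows)
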