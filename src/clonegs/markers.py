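"""Marker QC, imputation, relationship kernels and genomic summaries.

The QC order is call-rate filter -> modal imputation -> MAF filter; the
kernels are the VanRaden additive relationship matrix

    G = Zc Zc' / (2 * sum_i p_i (1 - p_i)),   Zc = Z - 2(p - 0.5)

and the Gaussian kernel

    K = exp(-h * D / median(D))

where D holds squared Euclidean distances between dosage rows and the
median is taken over off-diagonal entries.  An uncentered variant of G
(plain ZZ' over the same denominator) is available behind a flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import GenotypeMatrix, KinshipMatrix

__all__ = [
    "filter_call_rate",
    "impute_naive",
    "filter_maf",
    "qc_pipeline",
    "additive_G",
    "gaussian_K",
    "ld_r2",
    "heterozygosity",
]


def filter_call_rate(
    geno: GenotypeMatrix, min_rate: float = 0.90
) -> GenotypeMatrix:
    """Drop markers whose fraction of observed calls is below ``min_rate``."""
    if not 0.0 < min_rate <= 1.0:
        raise ValueError("min_rate must be in (0, 1]")
    rate = 1.0 - np.isnan(geno.dosages).mean(axis=0)
    keep = np.where(rate >= min_rate)[0]
    if keep.size == 0:
        warnings.warn("call-rate filter removed every marker")
    out = geno.take_markers(keep)
    out.qc_report = {
        "call_rate": {"retained": int(keep.size), "removed": geno.n_markers - int(keep.size)}
    }
    return out


def impute_naive(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the per-marker modal dosage (ties -> 0)."""
    d = geno.dosages.copy()
    for j in np.where(np.isnan(d).any(axis=0))[0]:
        col = d[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(
                f"marker {geno.markers['id'].iloc[j]} has no observed calls; "
                "apply the call-rate filter first"
            )
        codes, counts = np.unique(obs, return_counts=True)
        top = counts == counts.max()
        fill = 0.0 if top.sum() > 1 else float(codes[np.argmax(counts)])
        col[np.isnan(col)] = fill
    out = GenotypeMatrix(list(geno.samples), geno.markers.copy(), d)
    out.qc_report = getattr(geno, "qc_report", {})
    return out


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers with minor allele frequency below ``min_maf`` (inclusive
    boundary: a marker exactly at the threshold is kept)."""
    if np.isnan(geno.dosages).any():
        raise ValueError("impute before the MAF filter (missing calls present)")
    p = geno.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(maf >= min_maf - 1e-12)[0]
    out = geno.take_markers(keep)
    report = dict(getattr(geno, "qc_report", {}))
    report["maf"] = {"retained": int(keep.size), "removed": geno.n_markers - int(keep.size)}
    out.qc_report = report
    return out


def qc_pipeline(
    geno: GenotypeMatrix, min_call_rate: float = 0.90, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Call-rate filter, modal imputation, MAF filter, in that order."""
    return filter_maf(impute_naive(filter_call_rate(geno, min_call_rate)), min_maf)


def _centered(dosages: np.ndarray, p: np.ndarray) -> np.ndarray:
    return dosages - 2.0 * (p - 0.5)


def additive_G(
    geno: GenotypeMatrix,
    center: bool = True,
    ridge: float = 1e-6,
    scale_mean_diag: bool = False,
) -> KinshipMatrix:
    """VanRaden additive genomic relationship matrix.

    With ``center=False`` the literal uncentered cross-product ZZ' over the
    same denominator is returned instead.  ``scale_mean_diag=True`` divides
    G by its mean diagonal so that the genetic variance attached to it is
    on the individual scale; in structured panels the global-frequency
    denominator otherwise inflates the diagonal above 1 and the fitted
    variance ratio understates the genetic share.
    """
    Z = geno.dosages
    if np.isnan(Z).any():
        raise ValueError("additive_G needs complete (imputed) dosages")
    p = geno.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; G denominator is zero")
    Zc = _centered(Z, p) if center else Z
    G = Zc @ Zc.T / denom
    if scale_mean_diag:
        G /= np.diag(G).mean()
    G[np.diag_indices_from(G)] += ridge
    G = (G + G.T) / 2.0
    return KinshipMatrix(
        samples=list(geno.samples),
        values=G,
        kind="additive_G",
        n_markers=geno.n_markers,
        denominator=denom,
    )


def gaussian_K(
    geno: GenotypeMatrix, h: float = 1.0, squared: bool = True
) -> KinshipMatrix:
    """Gaussian kernel on marker distances, bandwidth-scaled by the
    off-diagonal median distance.  ``squared=False`` uses plain Euclidean
    distances instead of squared ones."""
    Z = geno.dosages
    if np.isnan(Z).any():
        raise ValueError("gaussian_K needs complete (imputed) dosages")
    d = pdist(Z, metric="sqeuclidean" if squared else "euclidean")
    med = float(np.median(d))
    if med <= 0:
        raise ValueError("all individuals identical; median distance is zero")
    K = np.exp(-h * squareform(d) / med)
    return KinshipMatrix(
        samples=list(geno.samples),
        values=K,
        kind="gaussian_K",
        n_markers=geno.n_markers,
        bandwidth=h,
        denominator=med,
    )


def ld_r2(geno: GenotypeMatrix, chromosome: str) -> pd.DataFrame:
    """Squared Pearson correlation for every within-chromosome marker pair.

    Returns a tidy table (marker_a, marker_b, distance_bp, r2); pairs
    involving a zero-variance marker are skipped with a warning.
    """
    on = np.where(geno.markers["chrom"].to_numpy() == chromosome)[0]
    if on.size < 2:
        raise ValueError(f"need >=2 markers on {chromosome}")
    Z = geno.dosages[:, on]
    if np.isnan(Z).any():
        Z = np.where(np.isnan(Z), np.nanmean(Z, axis=0), Z)
    sd = Z.std(axis=0)
    if (sd == 0).any():
        warnings.warn(
            f"{int((sd == 0).sum())} zero-variance markers skipped on {chromosome}"
        )
    ok = np.where(sd > 0)[0]
    corr = np.atleast_2d(np.corrcoef(Z[:, ok].T))
    ids = geno.markers["id"].to_numpy()[on[ok]]
    pos = geno.markers["pos"].to_numpy()[on[ok]]
    ia, ib = np.triu_indices(len(ok), k=1)
    return pd.DataFrame(
        {
            "marker_a": ids[ia],
            "marker_b": ids[ib],
            "distance_bp": np.abs(pos[ib] - pos[ia]),
            "r2": corr[ia, ib] ** 2,
        }
    )


def heterozygosity(geno: GenotypeMatrix) -> tuple[pd.Series, pd.Series]:
    """(per-individual multilocus heterozygosity, per-marker observed Ho).

    Both are fractions of heterozygous (dosage 0) calls among observed
    calls.
    """
    het = geno.dosages == 0
    obs = ~np.isnan(geno.dosages)
    with np.errstate(invalid="ignore"):
        per_ind = het.sum(axis=1) / obs.sum(axis=1)
        per_marker = het.sum(axis=0) / obs.sum(axis=0)
    return (
        pd.Series(per_ind, index=geno.samples, name="multilocus_het"),
        pd.Series(per_marker, index=geno.markers["id"].to_numpy(), name="Ho"),
    )
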