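"""Core in-memory containers shared across the pipeline.

The package moves three kinds of data between stages: marker dosages with
their genomic map (:class:`GenotypeMatrix`), plot-level phenotype records
(a plain :class:`pandas.DataFrame`, see :data:`TRIAL_COLUMNS`), and the
clone-level summaries produced by the stage-1 mixed model
(:class:`ClonalEstimates`).  Relationship matrices carry provenance in
:class:`KinshipMatrix` so downstream models can check they were handed the
kernel they expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Required columns of a plot-level trial table.  Trait observations live in
#: additional columns (any name not in this set is treated as a trait).
TRIAL_COLUMNS = ("clone", "location", "year", "rep", "block", "design")


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with a marker map.

    Dosages are coded -1 (homozygous reference), 0 (heterozygous),
    +1 (homozygous alternate); ``nan`` marks a missing call.

    Parameters
    ----------
    samples : list of str
        Individual identifiers (rows).
    markers : pandas.DataFrame
        One row per marker with columns ``chrom``, ``pos`` (1-based),
        ``id``, ``ref``, ``alt``; sorted by (chrom, pos).
    dosages : ndarray of shape (n_samples, n_markers)
        Float array with values in {-1, 0, 1, nan}.
    """

    samples: list
    markers: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (-1.0, 0.0, 1.0)).all():
            raise ValueError("dosage codes must be in {-1, 0, 1} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given marker positions."""
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers.copy(),
            dosages=self.dosages[index, :].copy(),
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return (np.nanmean(self.dosages, axis=0) + 1.0) / 2.0


@dataclass
class KinshipMatrix:
    """Symmetric relationship matrix with provenance.

    ``kind`` is ``"additive_G"`` (VanRaden additive relationship) or
    ``"gaussian_K"`` (Gaussian kernel on marker distances).
    """

    samples: list
    values: np.ndarray
    kind: str
    n_markers: int = 0
    bandwidth: float = np.nan  # h for gaussian_K
    denominator: float = np.nan  # 2*sum(p(1-p)) for G, median(D) for K

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix not square/consistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")

    def submatrix(self, rows, cols=None) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.samples)}
        r = np.array([idx[s] for s in rows])
        c = r if cols is None else np.array([idx[s] for s in cols])
        return self.values[np.ix_(r, c)]


@dataclass
class ClonalEstimates:
    """Stage-1 clone-level summaries for a single trait.

    ``table`` has one row per clone with columns ``clone``, ``blup``,
    ``pev``, ``reliability``, ``deregressed``, ``flagged`` (bool; True when
    the clone carries no usable information for GS training).
    Variance components are on the plot basis: ``sigma2_clone`` is the
    clonal (total genetic) variance, ``sigma2_rep`` the replicate-within-
    trial variance and ``sigma2_resid`` the plot residual.
    """

    trait: str
    table: pd.DataFrame
    sigma2_clone: float
    sigma2_rep: float
    sigma2_resid: float
    grand_mean: float
    fixed_effects: dict = field(default_factory=dict)
    h2_phen: float = np.nan
    reliability_floor: float = 0.05
    converged: bool = True

    def training_frame(self) -> pd.DataFrame:
        """Rows usable as GS training responses (deregressed, unflagged)."""
        t = self.table
        return t.loc[~t["flagged"]].reset_index(drop=True)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the synthetic-data generator."""

    true_breeding_values: pd.DataFrame  # clone x trait
    true_total_genetic_values: pd.DataFrame  # clone x trait
    qtl_indices: np.ndarray
    qtl_effects: pd.DataFrame  # per trait additive effects at QTL
    cluster_labels: pd.Series  # clone -> cluster (0-based)
    realized_h2: dict  # trait -> plot-basis narrow-sense h2


@dataclass
class GsFit:
    """Result of one genomic prediction fit.

    ``method`` is one of RRBLUP, GBLUP, RKHS, BAYESB, BLASSO.  Marker
    methods populate ``beta`` (allele-substitution effects); kernel methods
    populate ``g`` (genetic values for the training individuals).  Bayesian
    fits keep thinned chains of the sampled variances for diagnostics.
    """

    method: str
    mu: float
    training_ids: list
    gebv_train: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2_genomic: float
    beta: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    sigma2_beta: Optional[float] = None
    pi: Optional[float] = None
    lam: Optional[float] = None
    chains: dict = field(default_factory=dict)
    estimator: object = None
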