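"""Seeded synthetic data with the structure of a clonal breeding study.

Genotypes follow an island model: per-cluster allele frequencies are drawn
from a Balding-Nichols distribution around an ancestral frequency, with a
single divergence parameter (Fst) per cluster, and genotypes are
Hardy-Weinberg draws within cluster.  Phenotypes are generated from a
sparse QTL architecture with optional dominance and additive-x-additive
epistasis, replicated through multi-environment trials (randomized
complete blocks or augmented block designs with repeated checks), and
scaled so that the plot-basis narrow-sense heritability hits a target.

The generator records a :class:`~clonegs.containers.SimulationTruth` so
parameter-recovery tests can compare estimates against the simulated
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, SimulationTruth


@dataclass
class TrialLayout:
    """One field trial: design ('RCBD' or 'ABD'), replicate/block count,
    location and year."""

    design: str
    n_reps: int
    location: str
    year: int

    def __post_init__(self):
        if self.design not in ("RCBD", "ABD"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _default_layouts():
    # Mirrors a multi-environment clonal series: RCBD trials with 3 reps
    # plus augmented-design trials where only checks repeat (10+ blocks).
    return [
        TrialLayout("RCBD", 3, "locA", 2011),
        TrialLayout("RCBD", 3, "locA", 2012),
        TrialLayout("ABD", 10, "locB", 2013),
        TrialLayout("ABD", 10, "locB", 2014),
    ]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults emulate a germplasm-bank training population: five divergent
    clusters totalling 888 clones (sizes 162/175/185/155/211), biallelic
    SNPs with a 5% MAF floor spread over 18 chromosomes, ~10% missing
    calls, and a low-heritability trait (plot-basis narrow-sense h2 0.34)
    with a substantial non-additive component, evaluated in RCBD and
    augmented-block trials.
    """

    n_clusters: int = 5
    fst: float | Sequence[float] = 0.15
    n_per_cluster: Sequence[int] = (162, 175, 185, 155, 211)
    n_markers: int = 2000
    n_chromosomes: int = 18
    maf_floor: float = 0.05
    missing_rate: float = 0.10
    n_qtl: int = 100
    h2_additive: float | Sequence[float] = 0.34
    nonadditive_fraction: float | Sequence[float] = 0.30
    directional_dominance: float = 1.0  # mean of dominance effects, in SD units
    rep_variance_fraction: float = 0.2  # share of non-genetic variance in reps
    env_effect_scale: float = 0.5  # location-year shifts vs non-genetic SD
    n_checks: int = 5  # clones replicated in every ABD block
    trial_layouts: list = field(default_factory=_default_layouts)
    seed: int = 0

    def __post_init__(self):
        self.trial_layouts = [
            t if isinstance(t, TrialLayout) else TrialLayout(*t)
            for t in self.trial_layouts
        ]
        if len(self.n_per_cluster) != self.n_clusters:
            raise ValueError("n_per_cluster length must equal n_clusters")
        if any(n <= 0 for n in self.n_per_cluster):
            raise ValueError("empty cluster requested (n_per_cluster contains 0)")
        for prop, name in [
            (self.maf_floor, "maf_floor"),
            (self.missing_rate, "missing_rate"),
        ]:
            if not 0.0 <= prop < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if ((fst < 0) | (fst >= 1)).any():
            raise ValueError("fst must be in [0, 1)")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        for h2, naf in zip(self.h2_list(), self.nonadditive_list()):
            if not 0.0 < h2 <= 1.0:
                raise ValueError("h2_additive must be in (0, 1]")
            if not 0.0 <= naf < 1.0:
                raise ValueError("nonadditive_fraction must be in [0, 1)")
            if h2 > (1.0 - naf) + 1e-12:
                raise ValueError(
                    "h2_additive cannot exceed the additive share of genetic "
                    f"variance (1 - nonadditive_fraction = {1 - naf:.3f})"
                )
            if naf > 0 and self.n_qtl < 2:
                raise ValueError("nonadditive_fraction > 0 needs n_qtl >= 2")

    # traits may be one or several; scalars mean a single trait
    def h2_list(self):
        return list(np.atleast_1d(np.asarray(self.h2_additive, dtype=float)))

    def nonadditive_list(self):
        naf = np.atleast_1d(np.asarray(self.nonadditive_fraction, dtype=float))
        h2 = self.h2_list()
        if len(naf) == 1 and len(h2) > 1:
            naf = np.repeat(naf, len(h2))
        if len(naf) != len(h2):
            raise ValueError("h2_additive / nonadditive_fraction length mismatch")
        return list(naf)

    def trait_names(self):
        return [f"trait_{i + 1}" for i in range(len(self.h2_list()))]

    def fst_per_cluster(self):
        fst = np.atleast_1d(np.asarray(self.fst, dtype=float))
        if len(fst) == 1:
            fst = np.repeat(fst, self.n_clusters)
        if len(fst) != self.n_clusters:
            raise ValueError("fst length must be 1 or n_clusters")
        return fst


def _marker_map(n_markers: int, n_chromosomes: int) -> pd.DataFrame:
    chrom = np.arange(n_markers) % n_chromosomes + 1
    chrom.sort()
    pos = np.empty(n_markers, dtype=int)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        pos[chrom == c] = np.arange(1, k + 1) * 1000  # 1 kb grid
    return pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "id": [f"snp_{i + 1}" for i in range(n_markers)],
            "ref": "A",
            "alt": "T",
        }
    )


def simulate_structured_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a structured dosage panel under the island (Balding-Nichols) model.

    Returns dosages coded {-1, 0, 1} with missing calls inserted at
    ``config.missing_rate``.  The realized minor allele frequency of every
    marker (before missingness) respects ``config.maf_floor``: markers
    falling below the floor are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    n = int(np.sum(config.n_per_cluster))
    m = config.n_markers
    fst = config.fst_per_cluster()
    labels = np.repeat(np.arange(config.n_clusters), config.n_per_cluster)

    dosages = np.empty((n, m))
    todo = np.arange(m)
    for _ in range(100):
        k = len(todo)
        p_anc = rng.uniform(config.maf_floor + 0.05, 1 - config.maf_floor - 0.05, k)
        geno = np.empty((n, k))
        for c in range(config.n_clusters):
            F = fst[c]
            if F > 0:
                a = p_anc * (1 - F) / F
                b = (1 - p_anc) * (1 - F) / F
                p_c = rng.beta(a, b)
            else:
                p_c = p_anc
            rows = labels == c
            geno[rows] = rng.binomial(2, p_c, size=(int(rows.sum()), k)) - 1.0
        dosages[:, todo] = geno
        maf_ok = _maf(dosages[:, todo]) >= config.maf_floor
        todo = todo[~maf_ok]
        if todo.size == 0:
            break
    else:  # pragma: no cover - pathological configs only
        raise RuntimeError("could not satisfy maf_floor after 100 rounds")

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    samples = [f"clone_{i + 1:04d}" for i in range(n)]
    gm = GenotypeMatrix(samples, _marker_map(m, config.n_chromosomes), dosages)
    gm.cluster_labels = pd.Series(labels, index=samples, name="cluster")
    return gm


def _maf(d: np.ndarray) -> np.ndarray:
    p = (np.nanmean(d, axis=0) + 1) / 2
    return np.minimum(p, 1 - p)


def _complete(dosages: np.ndarray, rng) -> np.ndarray:
    """Genetic values need complete dosages; fill missing with the marker mode."""
    d = dosages.copy()
    if np.isnan(d).any():
        for j in np.where(np.isnan(d).any(axis=0))[0]:
            col = d[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                fill = 0.0
            else:
                codes, counts = np.unique(obs, return_counts=True)
                best = counts == counts.max()
                fill = 0.0 if best.sum() > 1 else codes[np.argmax(counts)]
            col[np.isnan(col)] = fill
    return d


def _scaled(x: np.ndarray, target_var: float) -> np.ndarray:
    v = x.var()
    if v <= 0 or target_var <= 0:
        return np.zeros_like(x)
    return (x - x.mean()) * np.sqrt(target_var / v)


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate plot-level trial records and the simulation truth.

    Genetic architecture per trait: additive effects at ``n_qtl`` sampled
    markers; dominance deviations at the same QTL and additive-x-additive
    effects on random QTL pairs supply the non-additive fraction (split
    half and half).  Clonal propagation means the whole genotypic value
    (additive + non-additive) repeats across plots of a clone, so the
    stage-1 "clone" variance is the total genetic variance; the target
    ``h2_additive`` is the plot-basis narrow-sense ratio
    V_A / (V_G + sigma2_rep + sigma2_resid).
    """
    if not config.trial_layouts:
        raise ValueError("trial_layouts must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    n = geno.n_samples
    Z = _complete(geno.dosages, rng)
    qtl = np.sort(rng.choice(geno.n_markers, size=config.n_qtl, replace=False))

    traits = config.trait_names()
    h2s, nafs = config.h2_list(), config.nonadditive_list()
    tbv = pd.DataFrame(index=geno.samples, columns=traits, dtype=float)
    tgv = pd.DataFrame(index=geno.samples, columns=traits, dtype=float)
    effects = pd.DataFrame(index=[geno.markers["id"][q] for q in qtl])
    realized_h2 = {}
    env = {}  # trait -> (sigma2_rep, sigma2_resid, sigma2_ly)

    Zq = Z[:, qtl]
    het = (Zq == 0).astype(float)
    for trait, h2, naf in zip(traits, h2s, nafs):
        a = rng.normal(size=config.n_qtl)
        add = Zq @ a
        add = add - add.mean()
        V_A = add.var()
        if V_A <= 0:
            raise ValueError("degenerate additive variance; increase n_qtl/markers")
        nonadd = np.zeros(n)
        if naf > 0:
            V_NA = V_A * naf / (1.0 - naf)
            # directional (mean-shifted) dominance emulates the inbreeding
            # depression / heterosis typical of outcrossing clonal crops
            dom = het @ rng.normal(config.directional_dominance, 1.0, config.n_qtl)
            pairs = rng.choice(config.n_qtl, size=(max(config.n_qtl // 2, 1), 2))
            pairs = pairs[pairs[:, 0] != pairs[:, 1]]
            if len(pairs) == 0:
                pairs = np.array([[0, 1]])
            epi = (Zq[:, pairs[:, 0]] * Zq[:, pairs[:, 1]]) @ rng.normal(
                size=len(pairs)
            )
            nonadd = _scaled(dom, V_NA / 2) + _scaled(epi, V_NA / 2)
        total = add + nonadd
        V_G = total.var()
        V_P = V_A / h2  # plot-basis phenotypic variance implied by target
        V_env = max(V_P - V_G, 0.0)
        s2_rep = V_env * config.rep_variance_fraction
        s2_res = V_env - s2_rep
        s2_ly = (config.env_effect_scale**2) * V_env
        tbv[trait] = add
        tgv[trait] = total
        effects[trait] = a
        env[trait] = (s2_rep, s2_res, s2_ly)
        realized_h2[trait] = float(V_A / (V_G + V_env)) if (V_G + V_env) else 1.0

    records = []
    check_idx = np.arange(min(config.n_checks, n))
    for t_i, layout in enumerate(config.trial_layouts):
        ly_key = (layout.location, layout.year, t_i)
        if layout.design == "RCBD":
            plot_plan = [
                (i, r + 1, r + 1)
                for r in range(layout.n_reps)
                for i in range(n)
            ]
        else:  # ABD: checks in every block, test entries once, random block
            entries = np.setdiff1d(np.arange(n), check_idx)
            blocks = rng.integers(1, layout.n_reps + 1, size=len(entries))
            plot_plan = [
                (int(c), b + 1, b + 1)
                for b in range(layout.n_reps)
                for c in check_idx
            ] + [(int(e), int(b), int(b)) for e, b in zip(entries, blocks)]
        # per-trait environment draws for this trial
        ly_eff = {tr: rng.normal(0, np.sqrt(env[tr][2])) for tr in traits}
        rep_eff = {
            tr: rng.normal(0, np.sqrt(env[tr][0]), size=layout.n_reps + 1)
            for tr in traits
        }
        for i, rep, block in plot_plan:
            row = {
                "clone": geno.samples[i],
                "location": layout.location,
                "year": layout.year,
                "rep": f"{ly_key[0]}_{ly_key[1]}_t{t_i}_r{rep}",
                "block": block,
                "design": layout.design,
            }
            for tr in traits:
                s2_res = env[tr][1]
                row[tr] = (
                    tgv[tr].iloc[i]
                    + ly_eff[tr]
                    + rep_eff[tr][rep - 1]
                    + rng.normal(0, np.sqrt(s2_res))
                )
            records.append(row)

    trials = pd.DataFrame.from_records(records)
    labels = getattr(
        geno,
        "cluster_labels",
        pd.Series(np.zeros(n, dtype=int), index=geno.samples, name="cluster"),
    )
    truth = SimulationTruth(
        true_breeding_values=tbv,
        true_total_genetic_values=tgv,
        qtl_indices=qtl,
        qtl_effects=effects,
        cluster_labels=labels,
        realized_h2=realized_h2,
    )
    return trials, truth


def simulate_study(config: SimulationConfig):
    """Convenience: genotypes + phenotypes + truth in one seeded call."""
    geno = simulate_structured_genotypes(config)
    trials, truth = simulate_phenotypes(geno, config)
    return geno, trials, truth
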