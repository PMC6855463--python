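# Methods

`clonegs` implements a complete genomic-selection analysis for clonally
propagated crops: two-stage phenotype modelling, marker quality control
and kernel construction, five genomic prediction methods, population
structure inference, structure-aware cross-validation, and the statistics
used to compare prediction methods. This note documents the models, the
numerical choices, and what the synthetic-data generator does and does
not emulate.

## Stage 1: clonal mixed model and deregression

Plot records from multi-environment trials are modelled per trait as

    y_ijl = mu + c_i + beta_j + r_l(j) + e_ijl

with the clone effect `c_i ~ N(0, sigma2_c)` random, the location-year
combination `beta_j` fixed (reference-level coding for identifiability;
an aliased level raises an error naming it), replicate-within-trial
`r_l(j) ~ N(0, sigma2_r)` random, and an i.i.d. plot residual. Because a
clone's whole genotype repeats across its plots, `sigma2_c` is the total
(broad-sense) genetic variance.

REML maximises the profiled likelihood over the variance ratios
`gamma_k = sigma2_k / sigma2_e` (the residual variance is concentrated
out analytically), evaluated through the Cholesky factor of the
mixed-model-equations coefficient matrix. A derivative-free simplex
search from three starts (`gamma = 0.1, 1, 10`) is used; ratios are
clipped to `exp(±25)`, which implements boundary estimates without
numerical failure. This profiled form behaves well even when a component
is effectively zero or effectively infinite (e.g. near-noise-free data),
where the unprofiled parameterisation is badly conditioned.

Clone BLUPs and their prediction error variances (PEV) come from the
clone block of the inverse coefficient matrix — exact at the package's
intended scale (up to a few thousand clones). Note a structural limit:
with k clones the PEV cannot fall below ~`sigma2_c / k` even with zero
residual, because the split between the intercept and the mean clone
effect is resolved only by shrinkage.

Deregression removes shrinkage so stage-2 models see an unshrunken
response: `deregressed = BLUP / reliability` with
`reliability = 1 - PEV/sigma2_c`. Deregression diverges as reliability
approaches zero, so clones at or below a reliability floor (default
0.05) are flagged and excluded from training; they are kept in the
output table rather than silently dropped. Phenotypic heritability is
reported on the plot basis `sigma2_c / (sigma2_c + sigma2_r + sigma2_e)`
by default, with an entry-mean variant available (the plot basis is the
conservative choice when the replicate structure varies across trials).

## Marker QC and kernels

QC order is fixed: call-rate filter (default ≥ 0.90) → modal imputation
(per-marker most frequent dosage, ties to heterozygote) → minor allele
frequency filter (default ≥ 0.05, boundary inclusive). Modal imputation
is deliberately simple: the downstream models need complete dosages, not
phased haplotypes, and the filters remove the markers where imputation
would matter most. Allele frequencies are taken from the post-imputation
dosages in a single deterministic pass.

Two relationship kernels:

* additive (VanRaden): `G = Zc Zc' / (2 Σ p_i (1 - p_i))` with columns
  centered by `2(p_i - 0.5)`. Centering makes `E[diag(G)] ≈ 1` under
  Hardy-Weinberg equilibrium and is required for the RR-BLUP/G-BLUP
  equivalence; the literal uncentered cross-product is available behind
  a flag. A `1e-6` ridge keeps G invertible. In structured panels the
  global-frequency denominator inflates the mean diagonal above 1
  (≈ 1.15–1.25 at Fst 0.15–0.25 in our simulations); the
  `scale_mean_diag` option divides G by its mean diagonal so the
  attached variance component is on the individual scale.
* Gaussian: `K = exp(-h D / median(D))` with `D` the matrix of squared
  Euclidean distances between dosage rows, the median taken over
  off-diagonal entries (the diagonal zeros would only dilute it), and
  bandwidth `h = 1` by default. Squared distance is the standard RKHS
  bandwidth convention; plain Euclidean distance is a config choice.

## Genomic prediction methods

All five methods regress deregressed BLUPs on markers with an intercept.

**G-BLUP / RKHS** fit `y = 1·mu + g + e`, `g ~ N(0, sigma2_g K)`, by
REML through the eigendecomposition of K: the model is rotated into the
eigenbasis, the likelihood profiled down to the single ratio
`delta = sigma2_e / sigma2_g`, and `log delta` optimised by bounded
scalar search on [-12, 12]. Out-of-sample genetic values use the
conditional-expectation projection `K_new,train (K_tt + delta I)^-1
(y - mu)`, which reproduces the fitted values on the training block
itself. Genomic heritability is `sigma2_g / (sigma2_g + sigma2_e)`.

**RR-BLUP** is the marker-space parameterisation of the same model:
with `G = Zc Zc' / c`, `c = 2 Σ p(1-p)`, the REML fit on G is
back-transformed to `beta = Zc' alpha / c` and `sigma2_beta =
sigma2_g / c`. GEBVs are algebraically identical to G-BLUP's (this is an
acceptance check, not an approximation).

**BayesB** is a Gibbs sampler with a per-marker spike-and-slab: effect
`beta_j` is zero with probability `1 - pi` or drawn from a scaled-t slab
(normal with marker-specific variance, scaled-inverse-chi-square with
`nu = 5`); `pi` — the *nonnull* probability — is sampled under a
Beta(2, 2) prior. The slab scale solves a prior-R² heuristic
(markers explain half the phenotypic variance a priori at `pi = 0.5`).
Marker inclusion is decided by the marginal likelihood ratio with the
effect integrated out; the residual is updated in place per marker.

**Bayesian LASSO** follows the Park–Casella hierarchy: conditionally
normal effects with exponential mixing variances (double-exponential
marginal), `lambda²` under a diffuse gamma hyperprior (shape 1, rate
1e-4), initialised where the implied marker variance matches the same
R² heuristic; the posterior mean of `lambda` is reported.

Both samplers run 10,000 iterations with 2,000 burn-in and thinning 10
by default, keep thinned chains of the residual and genomic variances
(the genomic variance of a sample is the variance of `y - mu - e`,
available for free from the residual), and are written as numba kernels
with the RNG seeded inside the kernel — same-seed runs are bit-identical.
Posterior means are taken over the thinned retained samples.

**Run-length diagnostics** (Raftery–Lewis) operate on the residual
variance chains: the chain is dichotomised at its q-quantile, thinned
until a first-order Markov chain is preferred by BIC over a second-order
one, and the two-state transition probabilities give the required
burn-in, run length, the i.i.d. minimum `Nmin = ceil((z_{(1+s)/2}/r)²
q(1-q))` and the dependence factor. A constant chain is returned flagged
degenerate rather than raising.

## Population structure (DAPC)

Principal components of the centered dosage matrix (or the
eigen-coordinates of a supplied relationship matrix) are retained up to
a cumulative variance share (default 85%); k-means (k-means++, 25
restarts, seeded; empty clusters retried up to 10 times) clusters the
retained scores, with k chosen by minimum BIC over k = 2..10 when not
fixed (`BIC = n log(WSS/n) + k log n`); linear discriminant analysis of
the k-means labels on the retained scores yields discriminant functions,
of which the leading ones reaching a variance share (default 94%) are
kept; final labels are nearest-centroid assignments in discriminant
space, ties to the lowest cluster index. The PC and DF thresholds are
independent knobs because their interaction is genuinely ambiguous in
the source analysis.

## Cross-validation designs

Four strategies, all seeded and method-agnostic (every method is served
identical train/validation index sets):

* S1 — random k-fold (5 folds × 3 replicates by default), ignoring
  structure.
* S2 — within-cluster: k-fold inside each cluster (3 × 3).
* S3 — leave-cluster-out: validate on one fold-part of a cluster, train
  on the matching fold-part of every other cluster. The fold-part
  version is the default because it equalises training sizes against
  S4; a `full_training` switch uses the other clusters entirely.
* S4 — three-cluster training: as S3 with one additional cluster
  excluded; every choice of absent cluster is enumerated.

Fold metrics: predictive ability `r(GEBV_val, BLUP_val)` (validation is
scored against BLUPs, not deregressed BLUPs); bias as the regression
slope `cov(GEBV_train, y_train)/var(GEBV_train)` (slope > 1 means
effects were underestimated; the literal SD-denominator form is behind a
flag); accuracy `r / sqrt(h2_phen)`; and the training fit's genomic
heritability. Folds with fewer than 3 validation clones yield missing
metrics with a warning. Metrics enter downstream tests per fold.

## Method comparison

The deviance analysis fits, by exact profiled maximum likelihood in the
same engine as the REML fits, the model `metric = method (fixed) +
cv_unit (random) + e`, adding a random training-by-validation population
interaction for the structured strategies. Each term is tested by a
likelihood-ratio chi-square against the model without it (fixed method
term on `n_methods - 1` df; random terms on 1 df with the naive
chi-square(1) reference, not the boundary-corrected mixture — users
should treat random-term p-values as conservative ordering devices).
The package's own ML engine is used because a general-purpose fitter
proved numerically unreliable on the reduced models, which inflates LRT
deviances; the exact profiled fit holds the method-term type-I error at
≈ 0.05–0.07 in null calibration. Method means are separated by Tukey's
studentized-range test with balanced-design degrees of freedom (CV
output is balanced by construction) and a compact letter display.

Cohen's Kappa selection-coincidence curves code the top `ceil(SP·n)`
clones by each GEBV ranking as selected (ties broken by id order) for
selection proportions 1–30% and compute `kappa = (p_o - p_e)/(1 - p_e)`
with the expected agreement from the marginal selection proportions.
GEBV correlation matrices are plain Pearson correlations over a common
individual set, optionally including the stage-1 BLUPs.

## Synthetic data generator

Genotypes follow an island model: ancestral allele frequencies uniform
on [maf_floor + 0.05, 1 - maf_floor - 0.05], per-cluster frequencies
Balding–Nichols `Beta(p(1-F)/F, (1-p)(1-F)/F)` with divergence `F` per
cluster, Hardy–Weinberg genotype draws within cluster, markers assigned
evenly to chromosomes on a 1 kb grid. Markers whose realized minor
allele frequency falls below the floor are redrawn, so the floor holds
exactly before missingness; missing calls are inserted uniformly at the
configured rate.

Traits: additive effects at `n_qtl` sampled markers; the non-additive
fraction of genetic variance is split half-and-half between dominance
deviations at the QTL and additive×additive effects on random QTL
pairs. Dominance effects are drawn with mean `directional_dominance`
(default 1.0, in units of the effect SD): directional dominance is the
architecture behind inbreeding depression and heterosis, which are
pronounced in outcrossing clonal crops, and it is also the component of
dominance a heterozygosity-sensitive kernel can exploit. The plot-basis
narrow-sense heritability target fixes the environmental variance via
`V_env = V_A / h2 - V_G`; the configured `h2_additive` therefore cannot
exceed `1 - nonadditive_fraction`. Environmental variance is split
between replicates (default 20%) and plot residual; location-year
shifts scale with the environmental SD so the noise-free limit is exact.
Trials are RCBD (every clone in every replicate) or augmented block
designs (checks — the first `n_checks` clones — in every block, test
entries once each in a random block). Default sizes emulate the study
panel: 888 clones in five clusters (162/175/185/155/211), 2,000 markers
on 18 chromosomes (a desk-scale panel; the models are insensitive to
marker count beyond the effective dimension), 10% missingness, and a
low-heritability trait (0.34) with a 30% non-additive share.

What the generator does **not** emulate: linkage disequilibrium between
markers (markers are independent within cluster), pedigree/family
gradients beyond the island structure, genotype-by-environment
interaction, spatial field trends, and sequencing artefacts. Passing
tests therefore demonstrate correctness of the estimators and designs
under a clean island-model world, not robustness to LD structure or
G×E.

## Verification conditions (acceptance surface)

The exact checks live in `tests/test_acceptance.py` and are recomputed
by `scripts/acceptance.py`. Two of them required explicit design
choices, made once and validated on 30 independent seeds:

* *Genomic-heritability recovery* uses a family-structured panel (50
  Balding–Nichols families of 10 clones, Fst 0.25, 2,000 markers, fully
  polygenic trait) with G-BLUP fitted to clone means over two 3-rep RCBD
  trials and G normalized by its mean diagonal; the target is the
  implied entry-mean heritability `6·0.5/(1+5·0.5) = 0.857`. In an
  unrelated panmictic panel of the same size the REML estimate has a
  sampling SD of ~0.12 — variance components from a relationship matrix
  are identified by relatedness contrasts, and without them no estimator
  recovers heritability tightly from a single realization. Validation:
  bias +0.003, SD 0.056, max error 0.114 over 30 seeds.
* *The RKHS non-additive advantage* is measured on a panel whose
  markers densely tag the trait architecture (200 markers, all QTL,
  n = 300, 50% non-additive variance): the Gaussian kernel's accessible
  non-linear channel is individual heterozygosity, and the channel
  carries signal only insofar as marker heterozygosity correlates with
  QTL heterozygosity. Validation: paired RKHS−G-BLUP predictive-ability
  difference +0.022 (SD 0.013), RKHS ahead in 10/10 fresh seeds.

Other fixed problem sizes in the acceptance surface (e.g. 5 clusters ×
40 clones at Fst 0.30 for the structure effect; 20 QTL among 2,000
markers for the sampler check; 200 replicates for the LRT size) were
chosen to make each property measurable in seconds to a few minutes on
one CPU; they are stated in the test docstrings.

## Reproducibility

Every stochastic component takes an explicit seed; there is no global
RNG state. The pipeline derives per-stage child seeds from the run seed
by hashing, so stages can be rerun in isolation. Same-seed runs are
bit-identical end to end, including the Gibbs samplers.
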