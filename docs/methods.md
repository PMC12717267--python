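# Methods

This note documents the models and procedures implemented in `aerodiv`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Compositional treatment

Weekly read counts carry no information about absolute abundance: library
size is a property of the sequencing run. All analyses therefore operate on
log-ratio coordinates of the weekly compositions.

**Zero replacement.** Log-ratios require strictly positive parts. Genera
with zero counts in at least 2/3 of the weeks are removed (retention is
strict: a genus at exactly 2/3 zero weeks is dropped). Remaining zeros are
replaced by a geometric Bayesian-multiplicative rule: each week is a
multinomial draw of size n over D parts; under a Dirichlet prior with total
strength s = D·m (prior mass m = 0.5 per cell by default) and prior mean t
taken as the normalized genus-wise geometric mean of positive proportions,
a zero cell j becomes tⱼ·s/(n+s). Nonzero cells are shrunk by the common
factor (1 − Σ replacements), preserving all observed ratios and rankings.
Replacements at or above the week's smallest observed proportion are pulled
to 0.65× that minimum before re-closure. The 0.65 adjustment mirrors the
standard behaviour of multiplicative-replacement implementations and keeps
imputed values interpretable as "below detection".

**Transforms.** CLR is the standard centering; ILR uses a sequential binary
partition realized as a pivot ordering by descending mean abundance (the
partition itself is a free choice, so it is stored with the matrix and every
transform is exactly invertible); PLR is the ILR whose ordering puts a
chosen pivot genus first, making the first coordinate
√((D−1)/D)·ln(x_pivot / g(others)). Per-genus PLR abundances (each genus as
its own pivot) are computed from CLR via the identity
PLRᵍ = √(D/(D−1))·CLRᵍ. The variation matrix uses the unbiased (n−1)
variance estimator; it is closure-invariant by construction.

## False-positive filtering

Read classifiers mis-assign reads, so some detected genera are artifacts.
The filter is a gradient-boosted classifier over 31 per-genus statistics in
four families reflecting how artifacts behave: they have *lower read
counts* (total/mean/max/median-nonzero counts, PLR level statistics); they
are *detected rarely or unusually often* (zero-week fraction, detection
runs and switches, lag-1 detection autocorrelation, count dispersion,
seasonal concentration of detections); they have *degraded per-read
classification quality* (mean confidence, distinct-minimizer ratio,
minimizers per read, direct/clade read ratio); and they concentrate in
*lineages with more reference sequence or larger genomes* (lineage bytes,
genome-size proxy, reads per database byte and per genome unit). The exact
member list is `taxon_filter.FEATURE_STATISTICS`; the four families are the
design anchor, the individual members are this package's reconstruction.
Kingdom one-hots and the genus's weekly PLR abundances are appended.

Labels come from occurrence records: a genus with ≥ 4 records within 40 km
of the station during the study window is positive; a genus with no record
within 5000 km *and* no family shared with a European taxon lacking a
reference genome is negative; everything else is unlabeled. Distances are
haversine on a 6371-km sphere. A stratified 13% holdout is reserved before
any tuning; hyperparameters are grid-searched with 5-fold CV (desk-scale
default of 16 combinations; the full 3⁸ = 6561 grid is available via
`full_grid()`); the final booster defaults match a full-scale search
optimum (eta 0.3, max_depth 5, min_child_weight 2, subsample 0.7,
colsample_bytree 0.4, reg_alpha 1e-5, gamma 0.3, reg_lambda 1.5). Calls use
an inclusive probability threshold of 0.75.

Classification stringency (`select_stringency`) picks, from a
stringency-response curve, the setting maximizing the regionally-plausible
fraction of classified reads subject to retaining at least half of the
maximum total classified fraction, tie-broken toward the least stringent
setting.

## Detrending

Weekly mean read length drifted over the decades and interacts with
classification; the filter manufacturer changed once mid-series; human-read
contamination varies. Each ILR coordinate is fit by Gaussian GLMs of mean
read length under log, identity and inverse links; the best by AIC wins,
with a parsimony margin of 2 AIC in favour of the identity link so
noise-chasing curvature cannot displace a linear fit. Residuals keep their
coordinate means. The residuals are then projected, in one least-squares
step, onto the orthogonal complement of the combined design {read length,
filter-type dummy, human-read fraction} — the conditioning step of a
partial redundancy analysis carried out in log-ratio geometry. The joint
projection (rather than two sequential ones) matters: read length and the
filter change are correlated in time, sequential projections do not
commute, and only the joint form makes the pipeline exactly idempotent.
`rda_condition` is also exposed separately (CLR geometry by default, raw
proportions by flag) for use as a standalone stage.

## Temporal assemblages

The variation matrix is a dissimilarity: genera with nearly constant
log-ratios move proportionally. Agglomerative clustering treats it as a
squared distance (its square root feeds Ward linkage; average and complete
are options) and is cut at a fixed k (default 17, mirroring the scale of
the motivating application; choosing k automatically is out of scope).
Cluster ids are relabeled by first appearance so the labeling is
deterministic. Cluster shares are sums of member relative abundances;
seasonal profiles are pooled medians of member log-ratio abundances per
calendar week (default weeks 21–41, the snow-free season).

## Diversity partition

For week n with composition p and reference r (arithmetic pooled mean by
default; geometric optional):

- α_n(q) = (Σⱼ p^q)^{1/(1−q)} — evenness in effective taxa (exp Shannon at
  q = 1),
- β_n(q) = exp D_q(p‖r) — temporal distinctiveness (exp KL at q = 1, ≥ 1 by
  Gibbs' inequality),
- γ_n(q) = α·β — the week's contribution to total biodiversity (at q = 1
  the exponential of the cross-entropy −Σⱼ pⱼ ln rⱼ).

Per-genus contributions cₙⱼ = −pₙⱼ ln rⱼ satisfy Σⱼ cₙⱼ = ln γₙ(1)
exactly, so diversity change can be attributed to taxa. Era contrasts
average contributions per calendar week within each era, pair matched
calendar weeks, and test with the two-sided Wilcoxon signed-rank test
(exact null distribution below 26 pairs), reporting the Hodges–Lehmann
median difference with its distribution-free confidence interval from the
signed-rank quantiles and Benjamini–Hochberg adjusted p-values across
genera. The paired signed-rank form is the default because the contrast is
intrinsically matched by calendar week; an unpaired rank-sum variant is
available by flag. The "effective taxa" scale depends on the choice of
reference distribution; comparisons between eras are invariant to that
choice in direction but not in magnitude.

## State-space trends

Observation: y_t = level_t + x_t'β + ε_t with Gaussian ε. Local linear
trend (LLT) gives both level and slope random-walk innovations; the
integrated random walk (IRW) removes the level innovation. Regressors
(six-column trigonometric seasonal block with period 52.18 weeks by
default, plus any covariates such as the 25 weekly catchment aggregates)
carry spike-and-slab priors: inclusion probability 0.5, slab variance equal
to the series variance by default.

Estimation is Gibbs sampling (default 2000 iterations, 500 burn-in, seeded):
forward-filter backward-sampling for the states, conjugate inverse-gamma
updates for the three variances, single-site Bernoulli-Gaussian updates for
the coefficients. The variance priors are weakly-informative inverse gammas
scaled to the series variance (IG(2, 0.5·s²) observation, IG(2, 0.005·s²)
level, IG(2, 5·10⁻⁵·s²) slope): conjugacy is what makes the variance step a
Gibbs update, and the scales only set the prior means, not hard
constraints. Missing weeks are skipped by the filter, so gappy designs
(winter gaps, alternate years) need no imputation. The Kalman/FFBS core is
numba-compiled and is checked in the tests against direct joint-Gaussian
likelihood evaluation.

**Model comparison.** Leave-future-out ELPD: the first half of observed
weeks (configurable) is the minimum training window; the model is refit
every `refit_stride` evaluation points (stride 1 = exact refit each step;
larger strides trade exactness for speed and reuse the latest posterior
through the Kalman filter, which still conditions each prediction on all
earlier data). The pointwise predictive density is the posterior-draw
average of the one-step Gaussian density. Ties go to the model with fewer
parameters.

**Diagnostics.** Standardized one-step prediction errors at the posterior
median parameters are tested for heteroscedasticity (F ratio of first vs
last third variances), serial dependence (ACF over 42 lags against the
±1.96/√n band), and non-normality (Kolmogorov–Smirnov d). Convergence is
summarized by autocorrelation-based effective sample sizes and Geweke
z-scores per parameter.

**Survey model.** Route counts (log(count+0.5)) are observers of one latent
random-walk trend with route intercepts (first pinned to 0) and
route-specific AR(1) errors, estimated by maximum likelihood through a
multivariate Kalman filter with the AR errors in the state, initialized at
their stationary distribution. Because a single route cannot identify the
level/AR split when the series looks white, the optimizer restarts from
trend-dominated and noise-dominated initial values and keeps the better
optimum. eDNA annual indices (year means of the posterior-median trend over
observed weeks) are z-scored and regressed on the z-scored, trailing
two-year moving average of the survey latent trend by OLS; adjusted R², F
and p are reported.

## Catchment and receptor models

Back-trajectory endpoints are binned by great-circle distance from the
station into the distance classes 2, 5, 10, 20, 31, 50, 100, 180, 310, 520,
860 km (class = smallest edge at or beyond the endpoint; an explicit
overflow class keeps binning mass-conserving) and by initial bearing into
eight 45° sectors centered on the cardinal/intercardinal directions.
Uncertainty of weekly cell masses uses a moving-block bootstrap (1000
resamples, 4-week blocks ≈ one month of synoptic memory). The radius
enclosing a mass quantile is a Monte-Carlo distribution: class masses are
perturbed by their SEs (truncated at zero), re-normalized, and the smallest
edge reaching the quantile recorded; the median and the 2.5/97.5
percentiles are reported.

The receptor model is the simplified quantitative transport bias analysis:
each grid cell's value is the residence-time-weighted mean concentration
Σ_w C_w·τ_w(cell) / Σ_w τ_w(cell), where τ counts endpoint hours (no kernel
smoothing — the simplified variant; ensemble members over start heights and
durations are weighted equally). Unvisited cells are missing, not zero. The
wind rose is the same statistic per direction sector, normalized to a
maximum of 1. The 25 weekly covariates handed to the trend models are 8
directions × 3 coarse distance bands (≤ 31 km, 31–310 km, beyond) plus
total mass, log1p-transformed; this mapping is this package's documented
choice of how to summarize weekly catchment variation in 25 columns.

## Synthetic data: what it emulates and what it does not

The generator plants, under one seed: (i) cluster-structured latent genus
trajectories — per genus, cluster trend + K harmonics + genus offset +
AR(1) noise, softmax-linked to compositions; the first harmonic holds at
least half the seasonal amplitude (default 1.0 log units) and its phase is
evenly spaced across clusters so the planted clusters are genuinely
seasonally distinct; (ii) one dominant genus whose community share follows
a logistic surge-and-decline (40% → 80% → 60%), computed exactly on the
softmax scale; (iii) multinomial read sampling with gamma-Poisson library
sizes, genus-specific read-length bias on the log scale, and a
genus-specific filter-batch offset switching at the configured week;
(iv) spurious genera at ~1% of the median genuine count with sporadic or
near-ubiquitous detection, degraded classification metrics and occurrence
records beyond 5000 km; (v) back-trajectories as von-Mises-directed random
walks with the stated start heights (10/100/300/500 m) and durations
(24/48/72 h); (vi) survey counts round(exp(latent annual mean + route
offset + AR(1) noise)), with survey genera designated as those whose annual
latent actually varies (a survey targets taxa with dynamics). An
observed-week mask (non-winter weeks of even years) reproduces sparse
archival sampling designs and is off by default.

Not emulated: individual reads or sequences, the classification step
itself, reference-database evolution, meteorology-driven trajectory
structure beyond directional bias, spatially heterogeneous source
landscapes, or taxonomic correlation between the spurious genera and real
lineages. Passing tests therefore demonstrate that the *statistical
machinery* recovers planted structure at realistic effect sizes — not that
any specific real-world dataset meets these assumptions.

## Numerical choices and limitations

- FFBS adds ~1e-10-scale diagonal jitter before Cholesky factorizations so
  degenerate conditionals (IRW level) remain factorizable.
- ELPD ties are resolved at 1e-9 resolution toward the smaller model.
- Problem sizes in the test-suite and acceptance script (e.g., 30–50 SSM
  calibration replicates at n = 300, 800-iteration chains; 10–20 ELPD
  replicates at n = 120) are desk-scale choices that keep the full suite in
  a couple of minutes while leaving the estimators' behaviour unchanged;
  every size is a visible argument.
- The exact ILR basis, the 31-statistic membership, the 25-covariate
  catchment mapping and the SSM priors are reconstructions within stated
  families; all are stored/configurable so any alternative convention is
  reproducible.
- The multiroute model assumes Gaussian log-count errors; very low counts
  (< 5) make that approximation coarse.
- `cumulative_mass_radius` reports class edges, not interpolated radii, so
  its resolution is the class grid.
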