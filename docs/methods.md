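# Methods

This note documents the statistical machinery in `reactnorm`, the choices
that were genuinely open, and what the synthetic data can and cannot show.

## Joint regression

Reaction norms are estimated by regressing each genotype's line means on
the centred environmental mean `I_j` (population mean per environment minus
the grand mean).  The grand mean is the *unweighted* mean of the
environment means, which is robust to mild imbalance from missing
genotypes and equals the mean of all line means when the data are
complete.  Because the regressor is itself the population mean, fitted
slopes average exactly 1 and fitted intercepts average the grand mean on
complete data; both identities are enforced by tests at 1e-8.

Genotypes are fitted on their non-missing environments only and dropped
with a warning below three usable values — never imputed.  Averaging
replicates into line means is the reader's job (`io.read_phenotypes` with
the long layout does it with an arithmetic mean).

**Two environments.**  A regression on two points is vacuous, so pairs use
the averaging/difference rule: intercept `(Y_1 + Y_2)/2`, slope
`(Y_2 − Y_1)/(I_2 − I_1)` with the higher-mean environment second.
Standardising by ΔI puts the statistic on the OLS-slope scale; since ΔI is
a positive constant shared by all genotypes, every Pearson correlation
computed from these slopes is identical to one computed from raw
differences.

## Subset consistency

All subsets of size 2 … n−1 are enumerated (501 for nine environments).
Each subset is re-analysed as if it were the whole experiment: the
environmental means are recomputed *within the subset* and re-centred.
One consequence is worth stating precisely: a subset's intercept is the
genotype's expected value at the subset's average environment,
`μ_i + β_i · mean_subset(I)` on the whole-set scale.  For an asymmetric
subset this mixes slope into intercept, so intercept correlations with the
whole set fall below 1 even for noise-free data whenever slopes are
heterogeneous — slope correlations are unaffected by the re-centring.
This mixing is a property of the estimand, not an estimation error, and it
is why intercept consistency of even very wide subsets is slightly below
slope consistency in noiseless checks.

Subset ranges are reported on the whole-set environmental-mean scale
(`range_fraction` ∈ [0, 1]) so they are comparable across subsets.  The
scan records per-subset estimation failures instead of aborting.

Two summary curves describe consistency against range: an OLS fit of
`y = a + b·x^(−1/3)` (the cube-root law; `x` must be positive), and one
smoothing spline per environment-sample-size group.  The spline penalty is
chosen by generalized cross-validation over a 21-point log grid; the GCV
denominator needs the trace of the smoother matrix, which is obtained
exactly by smoothing the unit vectors (the smoother is linear in `y`).
Duplicate abscissae — common, since many subsets share extreme members —
are collapsed to weighted means.  Groups with fewer than four distinct
points fall back to a straight line with a logged notice.

## Ridge-regression BLUP and REML

The prediction model is `y = 1m + Zu + e` with `u ~ N(0, σ²_u I_p)` and
`e ~ N(0, σ²_e I_n)`; `Z` holds marker codes in {−1, 0, +1} with missing
codes mean-imputed per marker (simple, deterministic, and adequate for
inbred panels with low missingness).  The variance ratio λ = σ²_e/σ²_u is
estimated by restricted maximum likelihood: after projecting out the
intercept with an orthonormal basis, the kernel `ZZᵀ` is eigendecomposed
once, making the restricted likelihood a cheap scalar function of λ.  The
profile is evaluated on a 25-point grid over log₁₀λ ∈ [−6, 6] (ties
resolved toward more shrinkage) and refined by golden-section search
between the neighbours of the grid optimum.  At the optimum, effects are
the standard ridge solution `û = Zᵀ(ZZᵀ + λI)⁻¹(y − 1m̂)`, verified in
tests against the closed form `(ZᵀZ + λI)⁻¹Zᵀ(y − 1m̂)` and against a
naive matrix-inversion evaluation of the restricted likelihood.

**Cross-validation accuracy is the mean of per-fold Pearson correlations**,
not the correlation of pooled out-of-fold predictions.  Pooling looks
attractive with ten folds of ~20 genotypes, but each fold's predictions
are anchored at that fold's training mean, and the training mean is
anti-correlated with the held-out values; under a null (markers unrelated
to the target) the pooled correlation is biased to roughly −0.2 rather
than 0.  Per-fold correlations are unbiased at the null and average away
their extra noise across folds.  Fold assignment is a seeded shuffle into
contiguous blocks; the seed is recorded in every `CVResult`.

Two scenarios are supported: *within* (reference = parameters estimated
from the same subset) and *whole* (reference = whole-set estimates, the
question being how well a cheap subset-trained model transfers).

## Environmental indices

Daily growing degree days clamp Tmax and Tmin separately into
[base, ceiling] (defaults 10 / 37.8 °C) before averaging — the standard
capped-GDD convention — so the daily value lies in [0, 27.8] °C·day.
Day length is astronomical: Spencer's Fourier series for solar
declination and sunrise/sunset at zenith 90.833°, clamped to [0, 24] h
toward the poles; a `day_length` column in the weather table overrides it.
Photothermal time is daily GDD × day length.

A window index averages daily values over an inclusive window of
days-after-planting, with the planting date as day 0 (so "18–43 days
after planting" is the 26 days planting+18 … planting+43).  The mean
(rather than the sum) makes windows of different lengths comparable in the
window search; a `aggregate="sum"` switch is exposed since either
convention is defensible.  The window search scores every (start ≤ end)
pair on the grid by the Pearson correlation between window indices across
environments and the observed environmental means, returning the full
surface and the argmax of |r| (ties: earliest start, then shortest
window).

## Simulated environment grids and variance partitioning

`build_env_grid` enumerates every daily planting date inside each site's
window for each year.  The bundled sorghum-style design uses four
site-sets (two temperate, one tropical summer set and one tropical winter
set whose window rolls across the year boundary) × 7 years × 51 daily
dates = 1428 environments; a windows-inclusive count of 51 days is the
only reading consistent with that total, so the winter window ends 20
January.  The rice-style design is 6 sites × 3 years × 93 dates = 1674.
The same index family and window is applied to every cell — an explicit
constant-index assumption, surfaced in the log, since no trial was
actually grown in those cells.

Variance partitioning is sequential (Type-I) ANOVA on categorical main
effects in a stated order (site → year → planting date; within site:
year → planting date), implemented directly with least squares on dummy
matrices: the minimum-norm solver keeps confounded factors well-defined
(they simply receive their incremental sum of squares), where
formula-based ANOVA would fail.  On the balanced grids produced by
`build_env_grid` the factors are orthogonal and the order does not matter;
tests verify both the order-invariance and agreement with statsmodels'
sequential ANOVA on clean designs.  Percentages are invariant to affine
transforms of the index and sum to 100.

Per-site distributions report moments and a Gaussian KDE on one common
grid so sites can be overlaid; configured site groups can be merged (the
rice-style design pools two pairs of nearby sites with overlapping
distributions).

## Synthetic data: what it emulates, and what it does not

`simulate_biparental_genotypes` produces RIL populations as a two-state
Markov chain along each chromosome (switch probability 2r/(1+2r), with r
from Haldane's map function at the inter-marker spacing — the standard
inflation of the recombination fraction accumulated over selfing), and
BIL populations as two gamete chains with the donor allele held at 25%
stationary frequency.  Defaults: 10 chromosomes of 150 cM.

`simulate_study` draws sparse marker effects (10 QTL per parameter,
disjoint between intercept and slope by default so their prediction
accuracies are separately meaningful), scales them to target genetic
standard deviations, and centres the genetic values so the population
means equal the stated baselines — joint regression identifies slopes
only relative to their population mean (fixed at 1), so an uncentred
generator would make "truth" unrecoverable by construction.  Environment
indices are evenly spaced over the index range and centred; phenotypes are
`μ_i + β_i I_j` plus iid Gaussian noise.

Default scale mirrors a sorghum flowering-time study: trait in GDD,
baseline intercept 2000 GDD with genetic sd ≈ 80 GDD, baseline slope 1
with genetic sd ≈ 0.15, environmental-mean range 950 GDD (the span from
the coolest to the warmest observed environment), residual sd 30 GDD, and
nine environments.  The test population is 64 lines × 200 markers for
speed, with `full_scale=True` switching to 237 × 1462.

`simulate_weather` builds daily series as site mean + seasonal sinusoid +
year effect + daily noise, with tmax/tmin a fixed ±5 °C around the mean.
Latitude controls the structure: the site mean holds at 27 °C through the
tropics and declines 0.6 °C per degree beyond |lat| 20°; the seasonal
half-amplitude is 15 °C at a 45° reference scaling with (lat/45)² (real
seasonal amplitude is a few degrees in the tropics and ~15 °C at
temperate continental sites — far from linear in latitude); interannual
variability scales the same way (1.5 °C reference sd × (0.2 + (lat/45)²)).
These choices give the generator the qualitative structure the
environmental-variability analysis probes: temperate sites deliver wide,
year-dependent index distributions while tropical sites are narrow and
repeatable, without pushing temperate summers so far past the GDD ceiling
that clamping erases their variability.

What passing tests on this generator show: the estimators, scans,
predictors and partitions behave correctly on data that satisfy the linear
reaction-norm model with additive marker effects and a single dominant
environmental gradient.  What they do not show: robustness to nonlinear
reaction norms, genotype-specific environmental drivers, epistasis,
correlated residuals between nearby environments, or real weather
(fronts, droughts, autocorrelation) — conclusions about field data still
require field data.

## Numerical conventions and degenerate inputs

- Pearson correlations return NaN (never raise) when either side has zero
  variance; the subset scan records such subsets with their error.
- Environments with identical means raise singular-design errors for both
  the regression and the pair rule.
- A marker matrix whose rows are all identical is rejected as degenerate;
  a constant `y` yields zero effects and mean = the constant.
- Grids: REML log₁₀λ ∈ [−6, 6]; spline GCV λ ∈ [1e−6, 1e4]; both chosen to
  bracket any plausibly identifiable value at these problem sizes.
- All generators and the CV splitter are pure functions of (config, seed);
  every CLI stage writes `run_config.yaml` with its seed.

Problem sizes in the default test runs (64 lines, 200 markers, 9
environments, 3-year weather series) keep the full suite and the
acceptance script to a few seconds each while preserving the structure of
the full-scale designs; the enumeration-based quantities (501 subsets,
1428/1674 simulated environments) are computed at full size.
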