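# Methods

`paleosize` implements the analysis chain for testing whether the body size
of fossil benthic communities tracked seawater temperature across a
hyperthermal event, using bed-by-bed bivalve/brachiopod occurrence data and
shell-calcite oxygen isotopes from the same stratigraphic levels. This note
records the models, the defaults and why, the numerical choices, and what
the synthetic data can and cannot demonstrate.

## Shell size and imputation

Shell size is `log2(sqrt(L * W))` for brachiopods and `log2(sqrt(L * H))`
for bivalves (mm): the geometric mean of two linear dimensions compresses
shape variation into a single length scale, and the log2 transform makes a
unit step a size doubling. Unmeasured specimens receive a size by a
two-step fallback: (1) the mean log2 size of measured conspecifics in the
same sample; (2) the mean of the per-sample species means in the nearest
sampled level below and the nearest above that contain measured
conspecifics (one side alone if only one exists); otherwise the record is
dropped, which also removes species never measured anywhere.

Choices worth making explicit:

- Imputation means are arithmetic means **on the log2 scale**, keeping the
  imputed values consistent with the downstream statistics, which all
  operate on log2 sizes.
- "Nearest level below/above" is by stratigraphic height among levels with
  measured conspecifics, not strictly adjacent beds; on sparse series this
  degrades gracefully instead of dropping records.
- Step (2) averages the two per-sample species means, not the pooled
  specimens, weighting both neighbour levels equally regardless of their
  sample sizes.

## Community statistics

Per sample and faunal group (`all`, `bivalves`, `brachiopods` — the latter
meaning articulate brachiopods; an optional boolean `articulate` column is
honoured, otherwise all brachiopod records count): the mean log2 size, the
first/third quartiles (linear interpolation between order statistics, the
"type 7" convention — the most widespread default), and the count.
A centered three-point moving average with shrinking end windows is
provided for display only and never feeds an analysis.

*Common species* are those with at least `min_per_level = 3` specimens in
each of at least `min_levels = 3` samples. A level with fewer than three
specimens does not count toward the level quota under the default
`per_level` rule; the `any_level` rule (species present at ≥ 3 levels and
reaching ≥ 3 specimens somewhere) is available because occurrence datasets
differ in how sparse levels were tallied. Common species are classified
*larger* or *smaller* against the unweighted mean of the species' mean
sizes; a species exactly at the cutoff classifies as smaller (strict `>`),
a deterministic rule on a measure-zero event. The percent-larger statistic
is 100 x (individuals of larger-class common species) / (individuals of all
common species) per sample.

## Palaeothermometry

Measurements failing trace-element screening (Mn/Ca > 0.1 or Fe/Ca >
1 mmol/mol; *exceeding* means strictly greater, and missing ratios pass by
default) are excluded as diagenetically altered. Accepted values are
averaged per level (rhynchonellid and oyster substrates pooled without
offsets — inter-substrate differences in this material are within
individual-level scatter), with 2·SE uncertainties using the n−1 standard
deviation. Temperature follows the brachiopod-calcite calibration

    T (°C) = 16.192 − 3.468 · (δ18O_calcite − δ18O_seawater − Mg)

with δ18O_seawater = −1.0 ‰ V-SMOW and the Mg term a pass-through permil
offset defaulting to 0 (at the ~0.4 wt% MgCO3 of this material the effect
is negligible, and no standard wt%→‰ conversion exists). The analysis
quantity ΔT (temperature change against the lowermost sample) is invariant
to both constants, which is asserted by test.

## The correlation procedure

For a faunal response series and the δ18O predictor, at lag 0 (same level)
or lag 1 (predictor from the immediately preceding usable level; rows with
a missing value in either series are deleted *before* lagging):

1. **Trend diagnostics** of each series against its level rank: OLS slope
   and p-value (the decision statistic) with Spearman rank correlation
   reported for comparison.
2. **Autocorrelation diagnostics** of the OLS residuals of
   response ~ predictor: ACF (1/n normalisation) and Durbin–Watson.
   "Serious" autocorrelation means DW outside [1.5, 2.5] or any lag ≥ 1 ACF
   value beyond the 1.96/√n white-noise band. A variant running the check
   on response ~ time residuals is selectable (`dw_on`).
3. **Generalized differencing** of *both* series when a significant trend
   and serious autocorrelation coincide (`trigger_combine = "and"`; the
   `"or"` reading is selectable): OLS-detrend against level rank, estimate
   the lag-1 residual autocorrelation ρ, return `r[t] − ρ·r[t−1]`.
4. **ARIMA order selection** on the current OLS residuals: d from a
   KPSS-only stationarity check (the internal convention of automatic
   ARIMA selection), then a stepwise AICc search over p, q ≤ 2 starting
   from {(0,d,0), (1,d,0), (0,d,1), (2,d,2)} with single-step neighbour
   moves; candidates are visited in order of increasing p+q then p and must
   strictly improve the AICc, so ties resolve toward the smaller model.
   The exhaustive grid is available (`stepwise=False`) but compares more
   models and is correspondingly more prone to spurious orders at n ≈ 30.
   A confirmation then re-checks the ARIMA residuals with the stricter
   KPSS-non-rejection **and** ADF-rejection battery (d capped at 5). If
   either step signals a unit root, both series are generalized-differenced
   and the selection repeats once with d = 0.
5. **GLS with ARMA(p,q) errors** on the aligned pair: the error correlation
   matrix is the Toeplitz matrix of the ARMA autocovariance; for fixed ARMA
   parameters the coefficients have the closed-form GLS solution, and the
   ARMA parameters are estimated by profile restricted maximum likelihood
   (REML, the `nlme::gls` convention; plain ML selectable) over a
   stationarity/invertibility-constrained parameterisation, optimised by
   Nelder–Mead from the origin. Reported per fit: the slope with a
   two-sided t-type test on n − 2 degrees of freedom, the residual standard
   error (whitened RSS on n − 2 df), and the correlation between the
   intercept and slope *estimators* from the coefficient covariance — the
   "correlation" column of the report tables. This implementation was
   checked against `nlme::gls` with `corARMA` and agrees to six decimals in
   slope, SE, p, sigma, ARMA coefficients and estimator correlation.

Significance is p ≤ 0.05 throughout (a p of exactly 0.050 counts).
Regressions with fewer than 4 usable pairs, constant predictors, and
zero-variance residual series raise staged errors naming the pipeline
stage. All decisions (differencing, selected order) are logged.

Known operating characteristics at the default synthetic conditions (mean
community size vs the observed δ18O series, lag 0): the empirical type-I
error of the complete procedure is ≈ 0.10 over 200 replicates — slightly
above nominal because re-estimating a spuriously selected MA structure
inside the GLS shrinks the slope standard error, a post-selection effect
intrinsic to the procedure (the R reference machinery reproduces the same
p-values on such replicates) — and power against the default composition
effect is ≈ 1.0 over 100 replicates.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with defaults describing a bed-by-bed sampled epicontinental hyperthermal
section:

| parameter | default | rationale |
|---|---|---|
| `n_levels` | 30 | typical number of sampled carbonate beds |
| `excursion_start/end` | 10, 20 | an interior event window one-third of the section |
| `d18o_baseline` | −1.0 ‰ | Early Jurassic shallow-shelf calcite values |
| `d18o_amplitude` | −1.0 ‰ | the printed magnitude of the event shift (~3.5 °C) |
| `d18o_level_sd` | 0.1 ‰ | smooth (AR(1)) geological level-to-level noise |
| `d18o_obs_sd` | 0.15 ‰ | per-specimen reproducibility-scale scatter |
| `isotope_specimens_per_level` | 4 | few shells per level pass screening |
| species pool | 13 bivalves + 7 brachiopods | the field ratio of identified species, scaled |
| `species_mean_log2` ~ N(3.5, 1.0) | | species geometric means ~3–45 mm |
| `within_species_sd` | 0.45 log2 | intraspecific size scatter |
| `individuals_per_level` | 115 | ~3,450 specimens over 30 levels |
| `beta_abund` | −0.25 /°C/log2 | composition effect: log-weight loss of large species when warm |
| `beta_size` | −0.03 log2/°C | mild within-species plasticity |
| `missing_fraction` | 0.3 | share of specimens without direct measurements |

Species abundances per level are multinomial with softmax weights
`base + beta_abund·(T − T_ref)·(species mean − pool mean)`, keeping
per-level totals fixed so that composition change is isolated from
sampling-intensity change (mirroring standardized bulk sampling).
Individual log2 sizes are Gaussian around
`species mean + beta_size·(T − T_ref)`; the two dimensions realise the
drawn geometric mean at a species-specific aspect ratio. The two
mechanisms are separable by construction and tested as such. Missingness
is completely at random (exact-count by default for determinism; a
binomial option exists), with one measured specimen per species protected
so imputation step (3) only triggers when a species is genuinely
unmeasured.

What the generator does **not** emulate: taphonomic transport and
size-sorting, facies-driven preservation differences, extinction and
origination dynamics, ontogenetic age structure, and size-biased
missingness (available as an option but off by default). Passing tests
therefore show the statistical machinery behaves correctly under the
analysis' own assumptions — not that those assumptions hold for any
particular field dataset.

## Problem sizes used in the test suite

Simulation-based checks run at the default 30-level, 115-individuals-
per-level conditions: 200 replicates for the type-I studies, 100 for the
power study, and single seeded datasets elsewhere; the stationarity and
order-selection checks use n = 200–300 synthetic series. Fast I/O and CLI
round-trips use a reduced 16-level configuration.

## Limitations

- The lag grid is {0, 1} by design; longer ecological lags are out of scope.
- The ARIMA search is capped at p, q ≤ 2 — series of ~30 samples cannot
  support richer structure.
- The KPSS/ADF battery is asymptotic; at n ≲ 30 the ADF test is
  underpowered, which is why the selection step uses the KPSS-only rule and
  the strict battery serves as a confirmation.
- Imputation borrows neighbouring-level means and can induce a small
  positive autocorrelation in community series when the imputed-adjacent
  share is large.
- `estimate_correlation` reports the estimator correlation induced by an
  uncentered predictor; it is a property of the design, not of the series,
  and is isolated in one reporting function so another definition can be
  substituted.
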