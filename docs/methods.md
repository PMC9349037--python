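# Methods

This note documents the models inside `exposim`, the design of the
synthetic geography, the numerical choices, and what the test suite does
and does not establish.

## 1. The simulation chain

One replicate runs four steps:

1. **True exposure.** One joint draw of annual-average PM₁₀ at every
   location (monitors, mothers, district offices, neighbourhood centres,
   tract centroids, grid points) from a Gaussian random field
   Z(s) = µ + x(s)ᵀβ + W(s) + ε(s). W has exponential covariance
   σ² exp(−3h/φ); ε is N(0, τ²), independent per point. All point sets see
   the *same* field realisation — required for exposure prediction to be
   meaningful — via a shared table of unique coordinates. Two mothers at
   one tract centroid share W but draw independent nuggets (the nugget is
   micro-scale/measurement variability, not shared structure).
2. **Outcome.** Bernoulli LBW status per mother with
   logit p = α + β·Z(home), β = ln(1.0033), α solved by Brent root-finding
   so mean(p) equals the baseline prevalence (default 5%), to 10⁻¹⁰.
3. **Exposure assignment.** Nine methods as described in the README.
   Measurement-based methods use the 25 background monitors; LUR/UK use
   all 37. UK detrends monitor values by OLS on the covariates, estimates
   a Matheron semivariogram of the residuals (8 equal-width bins to half
   the maximum inter-monitor distance; quantile bins as a fallback for
   very small networks), fits the exponential model by Cressie-weighted
   least squares from a deterministic 5×5×5 multi-start grid, then solves
   the universal-kriging system with drift [1, x].
4. **Inference.** Maximum-likelihood logistic regression of status on each
   assigned exposure; Wald 95% CIs. Over replicates: bias, RMSE, ASE on
   the log-odds slope (×100 for display), CP, and TPR (significantly
   positive slopes under predicted vs under true exposure, two-sided
   p < 0.05 and slope > 0). Non-converged or degenerate fits (e.g.
   constant assigned exposure in a one-district region) are flagged,
   excluded, and counted.

Seeding is counter-based: the stream for (scenario, replicate) is
`SeedSequence(master_seed, spawn_key=(scenario_index, replicate))`, so
results are independent of execution order and checkpoint-resumed runs
reproduce uninterrupted ones bit for bit.

## 2. Scenario parameters

The eight scenarios' (nugget, partial sill, range) triplets and
mean-structure labels are fixed constants of the package (ES1
1.00/30.94/5885 m … ES8 6.86/3.60/1004 m; ES8 is the triplet estimated
from the Seoul regulatory network that motivates the study). The range
column is read as the **practical range** (correlation ≈ 0.05 at φ), i.e.
ρ(h) = exp(−3h/φ) — the dominant reporting convention in air-pollution
geostatistics; the parameter-range convention exp(−h/φ) is a one-switch
toggle (`convention="parameter"`) carried consistently through simulation,
variogram fitting, and kriging.

The drift coefficients β are not published, only the qualitative labels.
They are calibrated per region: equal magnitudes, alternating signs,
scaled so Var(xᵀβ) over tract centroids equals q/(1−q)·(τ²+σ²) with the
mean-structure share q = 0 / 0.30 / 0.50 for none / moderate / dominant.
The shares were chosen once against two published summary statistics: with
share q, a perfect drift predictor has correlation ≈ √q with the true
field, and the reported LUR correlations of 0.60–0.65 under a dominant
mean structure imply q ≈ 0.4–0.5; q = 0.50 simultaneously puts the ES8
true-exposure SD (≈ 4.6 µg/m³) at the lower edge of the reported 4.66–6.45
µg/m³ band, which ES8 — the scenario with the smallest total variance —
plausibly attains. Larger shares (e.g. 0.7) are incompatible with the
printed correlations for any geography.

Overall mean µ = 52 µg/m³, a typical Seoul-era annual PM₁₀ level; it
shifts no operating characteristic.

## 3. The synthetic geography

No real geographic data are distributed, so the region is generated:

* A square of side 25 km is tessellated into districts on a near-square
  grid (5×5 at full scale); each district is tessellated into its share of
  neighbourhoods. Tessellation guarantees the partition/nesting
  invariants exactly.
* **Birth weights** per neighbourhood are Gamma(2, 1) draws —
  right-skewed, as birth counts across administrative units are.
* **Census tract centroids** are allocated to neighbourhoods in proportion
  to birth weight (at least one each) and scattered uniformly within.
  Census tracts are near-equal-population units, so their spatial density
  must track population; this is precisely what makes district averages of
  tract-centroid predictions (UKCA) population-representative, versus the
  spatially-uniform 1-km grid (UKGA).
* **Mothers** are tract centroids sampled per district (demand ∝ district
  birth weight) with probability proportional to the neighbourhood birth
  weight, with replacement by default (46,007 mothers vs 16,230 centroids
  at full scale force repetition). Homes are sampled once and fixed over
  all replicates.
* **Monitors**: one urban-background monitor near each district centre
  (jittered); roadside monitors uniform over the region. **District
  offices** are placed in each district's highest-birth-weight
  neighbourhood — civic centres sit in populated quarters, and this
  placement is what gives office-based prediction (UKD) its
  population-oriented character.
* **Covariates**: five standardised surfaces, each a superposition of 40
  Gaussian bumps with log-uniform widths between 2% and 30% of the extent,
  plus 10% white noise, sharing a latent "urbanicity" surface with
  loadings 0.8…0.4 (pairwise correlations ≈ 0.4–0.8, as real land-use
  predictor sets have). The multi-scale widths matter: sub-district
  texture keeps monitor-based prediction honestly imperfect, while the
  regional component preserves a between-district signal — both features
  of the real data summarised by the published correlation and SD ranges.
  Covariates are evaluated once per unique coordinate, so co-located
  points always agree.

Counts, extent, covariate count and seed are all configurable
(`RegionConfig`); `FULL_SCALE` carries the real study's counts, the
desk-scale default (5 districts / 20 neighbourhoods / 800 tracts / 2,000
mothers / 5+3 monitors / 100 grid points) runs a full scenario in seconds.

## 4. Numerical choices

* **GRF factorisation**: dense Cholesky of the no-nugget covariance over
  unique coordinates with jitter 10⁻⁸σ² (escalated ×100 up to three times,
  then a hard error naming the scenario and point count). The factor
  depends only on geography × scenario and is cached, so a replicate costs
  one matrix-vector product. Dense factorisation caps practical unique
  counts at a few thousand; full-scale (~17k unique points) exposure
  simulation is out of the default path, which is why the experiments run
  on scaled geographies.
* **Variogram fitting**: objective Σ Nⱼ(γ̂ⱼ − γ(hⱼ))²/γ(hⱼ)², bounded
  L-BFGS-B refinement of the best three grid starts; moment-estimate
  fallback (flagged on the result) if the optimiser fails. Bin abscissae
  are mean pair distances per bin (the gstat/geoR convention), not edge
  midpoints. On dense data, geometric bins (fine near the origin) identify
  short-range structure better; a single 1,500-point realisation still
  cannot pin a nugget that is 3% of the sill to better than ±1 or so —
  that scatter is ergodic field-level noise, not estimator error, and the
  test suite treats it as such.
* **Kriging**: one LU factorisation of the augmented (covariance + drift)
  system per replicate, solved against all targets at once; with zero
  nugget the predictor interpolates monitors exactly; kriging variances
  are clipped at zero.
* **Logistic fits**: statsmodels `Logit` (Newton), verified in tests
  against an independent hand-written Newton–Raphson solver to 10⁻⁸.
* **Tie-breaks**: nearest-monitor ties go to the lowest monitor id; a
  mother within 10⁻⁹ m of a monitor takes that monitor's value in IDWA.

## 5. Experiment sizes

The shipped experiments are scaled so that the statistics they estimate
are informative: TE unbiasedness at 5 districts / 1,000 tracts / 5,000
mothers × 1,000 replicates; coverage at 2,000 mothers × 1,000 replicates;
the address-availability contrasts on a full-shape geography (25
districts, 100 neighbourhoods, 2,500 tracts, 25+12 monitors) with 20,000
mothers × 500 matched-seed replicates — mothers are kept near the
full-scale 46,007 because TPR is a power statistic and collapses into
count noise at small n. Full-scale geography is configurable but not run
by default.

## 6. What the synthetic data do and do not show

The generator reproduces the *structure* of the motivating study —
hierarchical administrative nesting, a one-monitor-per-district background
network, population-weighted homes fixed across replicates, covariates
shared between generation and prediction — and is calibrated to published
summary ranges (true-exposure SD band; prediction-truth correlation
ranges). It does not reproduce Seoul's actual boundaries, monitor
coordinates, collinearity pattern of the real GIS variables, or the real
birth distribution. Consequently, operating characteristics that depend
only on correct model specification (TE rows, coverage probabilities)
transfer quantitatively; method contrasts (relative biases, TPR orderings)
transfer directionally; exact bias magnitudes for individual prediction
methods are geography-specific and should not be compared digit-for-digit
with the motivating study's tables.

Known limitations, inherited by design: a single year (no temporal
variation), no confounders or covariate-adjusted health models, no
mobility or workplace exposure, unweighted district aggregation (a
population-weighting switch would be a natural extension), Gaussian fields
only, and Wald (not cluster-robust) standard errors even though
district-level assignments are constant within district.
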