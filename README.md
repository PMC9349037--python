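# exposim

A Monte-Carlo laboratory for a question that haunts air-pollution
epidemiology: **what happens to health-effect estimates when residential
addresses are only known to the district?**

Cohorts and administrative health databases often record addresses at a
coarse administrative level (district, zip code) for confidentiality.
Modern exposure models (land-use regression, kriging) can predict pollutant
concentrations at exact homes — but that precision is wasted, or worse,
when homes are unknown. `exposim` simulates the whole chain for the
motivating example of long-term PM₁₀ exposure and low birth weight (LBW) in
a Seoul-like study region, and measures how each exposure-assignment
strategy distorts the logistic health-effect estimate.

## The model

**True exposure.** Annual-average PM₁₀ at location *s* is a Gaussian random
field

&nbsp;&nbsp;&nbsp;&nbsp;Z(s) = µ + x(s)ᵀβ + W(s) + ε(s),

with x(s) five standardised geographic covariates, W a zero-mean GRF with
exponential covariance σ² exp(−3h/φ) (partial sill σ², practical range φ),
and ε ~ N(0, τ²) a per-point nugget. Eight environmental scenarios
(ES1–ES8) span mean-structure strength (none / moderate / dominant) and the
spatial vs non-spatial variance split, e.g. ES1 (τ², σ², φ) = (1.00, 30.94,
5885 m) down to ES8 (6.86, 3.60, 1004 m) with a dominant mean structure.

**Outcome.** Each mother's LBW status is Bernoulli with
logit P(Y=1) = α + β·Z(home), β = ln(RR) with true RR = 1.0033 per µg/m³,
and α calibrated so the mean event probability equals the baseline
prevalence (5%).

**Exposure assignment.** Per replicate, monitor values are observed at 25
urban-background (one per district) + 12 roadside sites, and each mother is
assigned an exposure under nine methods — with complete addresses: nearest
monitor (NM), inverse-distance-weighted average (IDWA), land-use regression
(LUR), universal kriging (UK); with district-only addresses: area average
of monitors (AA), UK prediction at the district office (UKD), and district
means of UK predictions at neighbourhood centres (UKNA), census-tract
centroids (UKCA), or 1-km grid points (UKGA). The UK step re-estimates an
exponential variogram from the monitors (OLS detrend, Matheron estimator,
Cressie-weighted least squares) each replicate.

**Operating characteristics.** Over replicates, each method × scenario cell
is summarised by the mean RR, bias, RMSE and average standard error of the
log-odds slope (reported ×100), 95%-CI coverage probability (CP), and the
true positive rate (TPR): significantly positive findings under predicted
exposure relative to those under true exposure.

## Worked example

```python
from exposim import RegionConfig, StudyConfig, SimulationStudy

cfg = StudyConfig(
    region=RegionConfig(n_districts=5, n_neighbourhoods=20, n_tracts=800,
                        n_mothers=2000, n_roadside_monitors=3,
                        n_grid_points=100, seed=0),
    scenarios=("ES8",), methods=("TE", "UK", "AA", "UKCA"),
    n_replicates=200, master_seed=42)
results = SimulationStudy(cfg).run()
print(results.summary().round(4).to_string(index=False))
```

prints

```
scenario method  mean_rr  bias_x100  rmse_x100  ase_x100    cp  tpr  n_replicates  n_nonconverged
     ES8     TE   1.0025    -0.1025     2.0562    2.2708 0.975  1.0           200               0
     ES8     UK   1.0022    -0.1432     2.6147    2.2652 0.945  1.2           200               0
     ES8     AA   1.0014    -0.2237     2.7956    2.4750 0.945  1.6           200               0
     ES8   UKCA   0.9986    -0.6309     5.8759    4.5495 0.905  1.8           200               0
```

Read it as: fitting on the mothers' *true* exposure (TE) recovers the
generating RR of 1.0033 up to Monte-Carlo noise with nominal coverage;
mother-level universal kriging (UK) stays close; the single-monitor area
average (AA) attenuates the effect (negative bias); and at this small desk
scale (5 districts, 2,000 mothers) every estimate is noisy — the
operating-characteristic contrasts between district-level methods sharpen
at the full-shape geometry (25 districts, 37 monitors, tens of thousands of
mothers) used by `scripts/acceptance.py` and the acceptance tests.

A `StudyResults` also exposes the per-replicate fits (`results.fits`), CSV
export (`results.to_csv(dir)`), and a run manifest. The same pipeline is
scriptable from the shell:

```bash
exposim geography --seed 4 --out region_out       # build + export a region
exposim run --scenarios ES2,ES8 --replicates 200 --seed 1 --out study_out
exposim summarize study_out/fits.csv --config study_out/../study.yaml
```

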