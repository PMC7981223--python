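# rsfkit

Multi-scale Bayesian resource-selection-function (RSF) modelling for
wildlife telemetry, built around the workflow used to map nesting,
brood-rearing and summer habitat of translocated greater sage-grouse:
use–availability logistic regression with lasso shrinkage priors,
latent-indicator selection of the spatial scale at which each habitat
variable acts, calibration-based out-of-sample validation, and raster
habitat surfaces including epoch-difference change maps.

The package ships a first-class synthetic-landscape module, so the entire
pipeline — covariate engineering, design assembly, MCMC, validation,
mapping — runs end-to-end against data with known truth, no downloads
required.

## The model

Used locations (`y = 1`) are contrasted with random background locations
(`y = 0`, five per used point) in a Bernoulli logistic model

    g(x) = β₀ + β₁x₁ + … + β_K x_K (+ γ_j)

with standardized covariates, an optional per-individual random intercept
γ_j ~ Normal(0, σ_γ²), and Laplace (lasso) priors β_k ~ Laplace(0, λ) whose
rate gets a Gamma(0.01, 0.01) hyperprior and an exact conjugate
Gamma(a + K, b + Σ|β_k|) Gibbs update. The fitted RSF discards the
intercept:

    ŵ(x) = exp(β̂₁x₁ + … + β̂_K x_K)

Shrub cover and (log-transformed) terrain ruggedness are *multi-scale*
covariates: each is smoothed in circular moving windows at candidate radii
derived from daily movement distances (60/331/887 m for nesting and
brood-rearing; 111/767/1,503/3,005 m for summer), and a latent categorical
indicator chooses per iteration which radius's column enters the linear
predictor (Bayesian latent indicator scale selection). A two-stage fit
first estimates the posterior probability of each radius, then refits with
each variable fixed at its modal radius. Distance covariates (roads, water,
mesic areas, the release-site "pseudo-lek") enter as exponential decays
exp(−d/α) with α the mean distance at used locations, capped at 6.4 km.

Validation is calibration-based: ŵ is evaluated at withheld individuals'
used and available points, availability deciles define 10 bins, and
observed used counts are compared with expected counts (slope, R²,
Spearman). If calibration fails (Spearman ≤ .75, R² ≤ .75 or slope outside
[0.8, 1.2]), used-habitat-calibration (UHC) envelopes diagnose misspecified
covariates and quadratic terms are escalated, most influential predictor
first, until the thresholds pass.

Mapping applies the logistic transform p = ŵ/(1 + ŵ) (release-site term and
random intercepts omitted), composites the three seasonal surfaces by
cellwise geometric mean, and differences p computed under late versus early
shrub epochs to map habitat change under current selection.

## Worked example

Simulate 30 brood-rearing females (5 daily locations each) from a known
RSF on a seeded 120 × 120-cell landscape, build the 5:1 design, run the
two-stage fit, and validate on the withheld third of individuals:

```python
from rsfkit import (LandscapeConfig, generate_landscape, generate_shrub_epochs,
                    simulate_individuals, ModelConfig, two_stage_fit,
                    validate_model)
from rsfkit.landscape import default_truth, NEST_BROOD_RADII
from rsfkit.pipeline import build_season_design

scape = generate_landscape(LandscapeConfig(), seed=11)
generate_shrub_epochs(scape)                      # carve the late-epoch shrub loss
truth = default_truth("brood")                    # known generating RSF
birds = simulate_individuals(scape, truth, n_individuals=30,
                             days_per_individual=5, seed=12,
                             life_stage="brood")

design = build_season_design(scape, birds, "brood", seed=13,
                             radii=NEST_BROOD_RADII)
model = two_stage_fit(design, ModelConfig.reduced(random_intercepts=True,
                                                  seed=14))
print("selected scales:", model.selected_scales_)
print(model.model_.summary().round(2).to_string())
calib = validate_model(model, design)
print(f"calibration: Spearman={calib.spearman:.2f}  "
      f"R2={calib.r2:.2f}  slope={calib.slope:.2f}")
```

Output:

```
selected scales: {'shrub': 'shrub@331', 'rugged': 'rugged@60', 'elevation': 'elevation', 'northness': 'northness', 'road': 'road', 'water': 'water', 'mesic': 'mesic', 'release': 'release'}
                 mean  median  ci68_low  ci68_high  ci95_low  ci95_high
beta0           -1.88   -1.88     -2.02      -1.74     -2.17      -1.59
beta[shrub@331]  0.54    0.53      0.38       0.70      0.21       0.85
beta[rugged@60] -0.68   -0.68     -0.82      -0.56     -0.93      -0.43
beta[elevation] -0.10   -0.09     -0.22       0.02     -0.33       0.13
beta[northness]  0.26    0.25      0.13       0.39      0.03       0.51
beta[road]      -0.24   -0.23     -0.38      -0.09     -0.53       0.03
beta[water]      0.07    0.07     -0.04       0.19     -0.15       0.32
beta[mesic]      0.34    0.33      0.21       0.46      0.11       0.60
beta[release]    0.25    0.25      0.09       0.41     -0.01       0.55
lambda           3.18    2.96      1.98       4.44      1.20       6.09
sigma_gamma      0.12    0.11      0.06       0.19      0.03       0.31
calibration: Spearman=0.77  R2=0.83  slope=0.91
```

The generating truth selects for shrub cover (at the 331-m scale) and mesic
proximity and against rugged ground; the stage-1 indicator recovers the
331-m shrub radius, the coefficient signs match the truth, and held-out
calibration lands inside the Spearman/R² > .75 and slope ∈ [0.8, 1.2]
bands. (`ModelConfig.reduced()` is a 3 × 5,000-iteration test profile; the
production configuration `ModelConfig()` runs 3 chains × 30,000 iterations
with 15,000 burn-in, thinned by 5.)

The full pipeline — three seasons, composite and change surfaces, the
bookkeeping ledger, all CSV/ASCII-grid/GeoJSON outputs — runs from a YAML
config via the CLI:

```bash
rsf run-all --config demo.yaml --outdir out/
rsf simulate --seed 3 --outdir out/       # synthetic inputs only
```

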