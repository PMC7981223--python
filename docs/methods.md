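# Methods

This note records the statistical model, the numerical and design choices
behind it, what the synthetic-data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Use–availability model

The design contrasts used telemetry/nest locations (`y = 1`) with uniform
random background points from the availability domain (`y = 0`), five per
used point. The availability domain is the minimum convex polygon (MCP) of
the relevant population's used locations; background points are drawn
uniformly by rejection sampling from the MCP's bounding box. Each used
point owns its block of five available points, so the 5:1 ratio holds
exactly within any partition of the used points — in particular within the
train and test partitions, keeping the held-out calibration's own
background independent of fitting.

The observation model is Bernoulli logistic:
g(x) = β₀ + Σ_k β_k x_k (+ γ_j), with all covariates standardized to mean
0 and sample (n−1) SD 1 using moments computed on the *training* rows only
and frozen — reapplied verbatim to test rows and to prediction rasters, so
no information leaks from the withheld individuals. The RSF itself is the
intercept-free exponential ŵ(x) = exp(Σ β̂_k x_k), using posterior means.

Under this generative story the logistic coefficients consistently estimate
the exponential-RSF coefficients: used density is proportional to
w(x) × availability density, so the log-odds of "used" versus "available"
is x'β plus a constant.

## Priors and MCMC

* Coefficients: Laplace(0, λ) (lasso) shared across all habitat terms,
  including any escalated quadratic columns. Guards against overfitting at
  the small used-location counts typical of translocation studies.
* λ: Gamma(a = 0.01, b = 0.01) hyperprior, chosen as a conventional
  diffuse choice; its full conditional under K Laplace priors is exactly
  Gamma(a + K, b + Σ|β_k|) and is sampled by a Gibbs step.
* Intercept: Normal(0, 10²), excluded from the lasso (it is discarded for
  the RSF anyway).
* Random intercepts (brood and summer models): γ_j ~ Normal(0, σ_γ²) per
  individual, with σ_γ ~ Uniform(0, 10) on the SD scale.
* Continuous parameters move by per-parameter Gaussian random-walk
  Metropolis. Step sizes adapt toward 0.44 acceptance in batches of 50
  iterations **during burn-in only**; adaptation is frozen afterwards so
  the retained draws come from a fixed-kernel chain.
* The latent scale indicator of each multi-scale variable is drawn from its
  categorical full conditional (uniform prior over candidate radii): the
  likelihood is evaluated with the shared coefficient applied to each
  candidate column in turn. This fixed-dimension construction is the
  standard way to implement indicator-based scale selection; no
  trans-dimensional moves are needed because the coefficient is shared.
* Production configuration: 3 chains × 30,000 iterations, 15,000 burn-in,
  thin 5 (9,000 retained draws). `ModelConfig.reduced()` (3 × 5,000,
  2,500 burn-in) is a test profile with the same structure.
* Convergence: Gelman–Rubin r̂ per monitored parameter (intercept, each
  coefficient, λ, σ_γ), with W the mean within-chain variance, B/n the
  variance of chain means, V̂ = ((n−1)/n)W + B/n and r̂ = √(V̂/W). All
  monitored parameters must satisfy r̂ < 1.05; a failing fit is returned
  with `converged_ = False` and a warning, never silently.
* The linear predictor is maintained incrementally (one O(n) pass per
  scalar update) and the cached log-likelihood is recomputed from scratch
  every 1,000 iterations to stop floating-point drift.

The kernel is numba-compiled and seeded per chain from the estimator's
`random_state`, so identical seeds reproduce retained draws bit-for-bit.

## Two-stage fitting and the post-hoc contrast

Stage 1 samples the scale indicators; the modal radius per multi-scale
variable is then frozen and stage 2 refits with exactly one column per
variable. Mapping and validation use the stage-2 fit. The stage-1 indicator
frequencies are reported as posterior scale probabilities (rows sum to 1).

For the resident/translocated contrast, influential covariates (≥ 85%
posterior probability of β above or below 0, boundary inclusive) can be
expanded into group-specific interaction columns
(`design.expand_group_interactions`); the contrast statistic is the
fraction of paired draws with β_group_a > β_group_b, with > 0.95 or < 0.05
read as strong evidence of a difference.

## Covariate engineering

* **TRI** (terrain ruggedness): per cell, √Σ(squared elevation differences
  to the eight neighbours). Border cells use the neighbours that exist
  rather than nodata-padding, so edges stay defined. Ruggedness enters
  models as log(TRI + 1) — the +1 keeps flat cells at exactly 0 and avoids
  −∞ — and is focal-smoothed *after* the log transform.
* **Slope/aspect**: Horn third-order finite differences. Aspect enters as
  northness = cos(aspect) ∈ [−1, 1] (flat cells 0), because a raw circular
  degree cannot enter a linear predictor coherently. Slope is computed only
  to feed the collinearity screen.
* **Focal smoothing**: circular window = all cells whose centres lie within
  the radius of the target cell centre, centre always included; the window
  shrinks at edges and around nodata (mean over valid members). Any radius
  below the cell size is the identity. Shrub percent cover is smoothed
  directly (untransformed).
* **Distances**: exact Euclidean distance from cell centres to the nearest
  feature geometry (points, polyline segments; polygons reduced to their
  centroid, matching the "centre of mesic area" convention). Decay
  transform exp(−d/α) with α = min(mean distance at used locations,
  6,400 m), fitted per feature class from the design's used rows.
* **Candidate radii**: across-individual averages of per-individual
  minimum, mean and maximum daily step distances, rounded to the nearest
  metre half-up (3,005/2 = 1,502.5 → 1,503); summer additionally gets half
  the maximum radius. Individuals with no steps are excluded with a
  warning.
* **Collinearity screen**: greedy Pearson |r| > 0.7 at the variable level
  (multi-scale variables represented by their middle radius), priority
  order ruggedness, elevation, shrub, then the rest; the release-site decay
  is exempt because it is the nuisance control for release-site attraction,
  not a habitat hypothesis. Dropped variables lose all candidate columns.
* Zero-variance columns (e.g. a smoothing radius spanning the entire
  grid) are dropped from the design with a warning rather than
  standardized.

## Validation

* **Calibration**: bin edges are the deciles of ŵ over the withheld
  *available* points (availability-based bins make expected counts
  well-defined); expected used count per bin = n_used,test × the bin's
  share of summed availability weight; observed = withheld used counts.
  Reported: slope and R² of the observed-on-expected regression (with
  intercept; the intercept-suppressed slope is also emitted), and the
  Spearman correlation of observed counts with bin rank. Tied deciles merge
  bins with a warning; out-of-range used values clip into the end bins.
  Totals are conserved exactly (observed) and to 1e−9 (expected).
* **UHC envelopes**: for each of M posterior draws, ŵ at withheld available
  points, weighted resampling of n_used,test of them, Gaussian KDE
  (Silverman bandwidth) on a 512-point grid spanning the pooled 0.5–99.5
  percentiles; envelope = pointwise 2.5/97.5 percentiles; coverage = the
  fraction of grid points where the observed-use density lies inside.
* **Quadratic escalation**: while calibration fails (Spearman ≤ .75,
  R² ≤ .75 or slope outside [0.8, 1.2]) and un-squared predictors remain,
  the square of the not-yet-squared predictor with the largest |posterior
  mean| (standardized scale) is added, the model refitted with stage-1
  scales frozen, and calibration recomputed. Exhausting predictors is a
  reported outcome, not an error.

## Mapping

Surfaces use the stage-2 coefficients at the selected scales with the
intercept, random intercepts and the release-site decay omitted (the
release term is a translocation nuisance, not habitat). The "logistic
transform" is read as p = w/(1 + w), i.e. the inverse-logit of the
intercept-free linear predictor — the intercept-free form is a deliberate
choice where the convention is ambiguous, and all p surfaces are relative
selection indices, not absolute probabilities. The annual composite is the
cellwise geometric mean of the three seasonal p surfaces (computed on the
logistic scale, in that order). The change surface is Δ = p(late shrub) −
p(early shrub) with every non-shrub covariate held at late-epoch values and
both shrub layers smoothed at the selected scale; differing non-shrub
layers are rejected. Swapping epochs negates Δ exactly. Change summaries
report mean Δ within equal-count quantile classes of current p.

Rasters are cell-centre registered grids in projected metres, written as
single-band ESRI ASCII text grids (nodata −9999); vectors as GeoJSON;
tables as CSV with multi-scale columns named `var@radius`.

## Synthetic-data generator

The generator defines the study conditions for every test:

* Covariate fields are unit-variance Gaussian-smoothed white noise with
  configurable correlation range (shrub: mean 15%, SD 8, range 300 m —
  typical big-sagebrush cover; elevation: 800 ± 60 m, range 400 m), on a
  3.6-km (120 × 120 × 30 m) window by default. Vector features: 3 roads, 3
  streams (gently bending polylines crossing the extent), 5 mesic centres,
  1 central release site — about one linear feature per 1.2 km, chosen so
  that distance-decay fields have the moderate cross-correlations of a real
  study area rather than the near-collinear gradients that sparser features
  produce in a window this small.
* The late shrub epoch subtracts a raised-cosine deficit peaking at the
  release site and vanishing beyond the loss radius (default 8% over
  900 m), emulating localized shrub loss near the release area.
* Telemetry: daily locations are drawn independently per day, cell
  probabilities ∝ exp(x'β_true + γ_j) at the generating scales (with an
  exponential release-site attraction term), then jittered uniformly within
  the cell. There is no movement kernel — the models condition on habitat
  only — but consecutive-day step distances are still defined and feed the
  radius rule. Note that a per-individual intercept cancels in the
  within-landscape choice probabilities; it is retained for structural
  faithfulness, and the fitted random intercept instead absorbs
  per-individual imbalance in the assembled design.
* The default truth (selection for shrub at the middle radius and for
  mesic proximity; against ruggedness, elevation and roads; release
  attraction with 600-m decay; σ_γ = 0.3) gives strong but realistic
  selection contrast.

What the generator does **not** emulate: GPS fix error, duty cycles,
detection failure, mortality, temporal autocorrelation of movement,
year-varying shrub rasters within an epoch, and functional responses to
changing availability. Passing tests therefore demonstrate the estimator
and pipeline recover a known habitat-only generative process at realistic
sample sizes — not robustness to the observation artifacts of real
telemetry.

## Problem sizes and Monte-Carlo noise

The headline synthetic experiment uses a 120 × 120-cell landscape, 30
individuals × 5 daily locations (~150 used points), 5:1 availability, a
2/3–1/3 split by individual, and the production MCMC configuration; it
completes in well under a minute on one CPU. With ~50 withheld used points
spread over 10 bins, the calibration statistics carry irreducible binomial
noise: computing the calibration with the *true* generating w in place of
the fitted model shows the slope varying with SD ≈ 0.2 around 1 across
seeds. A single seeded run inside the slope band is therefore evidence of
calibration, while a marginal excursion at another seed is compatible with
binning noise rather than misfit; Spearman and R² are more stable. The
unit-test suite checks the replicate-level version of this property at a
larger withheld count (300), where the noise ceiling is well clear of the
thresholds.

## Known limitations

* Metropolis-within-Gibbs mixes more slowly than gradient-based samplers
  for strongly correlated coefficient pairs; the collinearity screen keeps
  the design away from the worst cases, and r̂ is always checked.
* The MCP availability domain is shared across seasons and years; the
  generator emits one boundary for all years.
* Nest designs look up shrub at a single epoch ("late" by default);
  year-matched shrub lookup is a configuration choice, not automatic.
* Distance to mesic polygons uses the centroid, not the polygon edge.
* Escalated quadratic terms square the *standardized* base column and are
  then re-standardized; surfaces reproduce this exactly, but the squared
  column is no longer a pure quadratic on the raw scale.
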