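# Methods

## The estimation problem

Orang-utans build a fresh sleeping nest roughly daily, and nests persist
for months, so the standing crop of nests along a line transect is an
indirect index of ape abundance. `nestdensity` implements the full chain
from raw perpendicular-distance records to ape density:

1. **Detection.** Nests at distance x from the transect line are
   detected with probability g(x), g(0) = 1. Distances are aggregated
   into 4 m classes and truncated at 40 m (wide outliers otherwise
   dominate the fit; spiking at zero makes exact distances unreliable).
   The detection function is estimated by maximising the multinomial
   likelihood over distance classes, with cell probabilities
   π_i = ∫_{bin i} g / ∫_0^w g.
2. **Nest density.** D_nest = N / (L·2w), with N the truncated nest
   count, L the transect length (km) and w the *effective strip width*
   ESW = ∫_0^w ĝ(x) dx (m, converted internally).
3. **Ape density.** D_ape = D_nest / (p·r·t), where p is the proportion
   of nest-building individuals (default 0.85), r the nest production
   rate (1.00 nests/individual/day) and t the mean nest decay time
   (259 days). The product p·r·t is the expected number of standing
   nests per individual; all three values are borrowed from other study
   sites, which motivates the sensitivity analysis.

## Detection-function details

Candidate models are the six conventional key/series pairs: uniform key
with cosine or simple-polynomial adjustments, half-normal
(g = exp(−x²/2σ²)) with cosine or Hermite adjustments, hazard-rate
(g = 1 − exp(−(x/σ)^−b)) with cosine or simple-polynomial adjustments.
Series terms are cos(jπx/w), (x/w)^{2j} and H_{2j}(x/σ); orders start at
j = 1 for the uniform key and j = 2 for scaled keys, where a first-order
term would be redundant with the key's own scale parameter. The adjusted
shape key·(1 + Σ a_j·series_j) is rescaled to 1 at x = 0.

Numerical choices:

- Cell integrals use fixed 16-node Gauss–Legendre quadrature per bin
  (the integrands are smooth on 4 m intervals); the final ESW uses
  adaptive quadrature at relative tolerance 1e-8.
- Optimisation is bounded L-BFGS-B on log σ (and log b), with five
  deterministic multi-starts on a log-spaced σ grid from w/20 to w —
  hazard-rate likelihoods can be multimodal. Adjustment terms are added
  forward (0–3), each warm-started from the previous solution, keeping
  the AIC-best count.
- Parameter points where the adjusted shape turns non-positive anywhere
  (including g(0) ≤ 0) are given −∞ likelihood; fits whose ĝ increases
  by more than 1e-6 on a 200-point grid are flagged non-monotone and
  excluded from model selection.
- Selection is minimum AIC; ties within 1e-6 go to the fewer-parameter
  fit, then to the fixed key order (uniform, half-normal, hazard-rate).
- Degenerate data (a single occupied distance class) leave σ
  unidentified — the likelihood plateaus as σ → 0 — so such fits are
  flagged `at_boundary` rather than trusted.
- Distances exactly equal to the truncation width fall in no half-open
  bin and are discarded; ties at the boundary are otherwise ambiguous.
- χ² goodness of fit merges classes rightward until every expected
  count is ≥ 0.5; df = classes − 1 − parameters, floored at 1.

## Sensitivity analysis

Each conversion parameter gets low/medium/high levels — t: 202/259/602
days, r: 0.84/1.00/1.16, p: 0.82/0.85/0.88 — crossed into a 3³ = 27
factorial grid of density estimates per transect. Three subsets fix one
parameter at medium while the other two vary (9 combinations each; the
three subsets overlap in 8 combinations, covering 19 of the 27). Because
density is monotone decreasing in each parameter, subset extrema always
occur at corner combinations, which the tests verify by brute force.
Ranges are reported over transect-level estimates, not pooled habitat
means: that is the only reading under which the published extreme values
are recoverable from the per-transect table. Histogram output uses
0.25 ind/km² bins (a reporting choice; nothing downstream consumes it).

## Habitat comparisons

Transect-level densities and encounter rates are compared across the
three strata with one-way ANOVA and Tukey HSD, gated (report-only) by
Shapiro–Wilk and Bartlett diagnostics. Comparing raw encounter rates
between strata is justified by a χ² homogeneity test of the
perpendicular-distance distributions on the habitat × distance-class
contingency table, with classes merged rightward until all expected
counts are ≥ 1. Note a standard homogeneity test on k strata × m classes
has (k−1)(m−1) degrees of freedom; a 3-strata comparison therefore
cannot produce df = 2 unless the classes are collapsed to two.

## Multimodel covariate inference

Transect density (or encounter rate) is regressed on six continuous
predictors (canopy height mean and SD, vertical layer count, Shannon
index of the plant-area profile, forest cover, distance to continuous
forest) plus the habitat factor, with logged forest as the reference
level. Following the standard information-theoretic protocol:

- Continuous predictors are standardised to mean 0, sd 0.5
  (x → (x−mean)/(2·sd)); dummies are centred only. This makes effect
  sizes directly comparable across continuous and binary terms.
- Pairs with |Pearson r| ≥ 0.7 (strict) may not co-occur in a model;
  terms with generalised VIF ≥ 5 are flagged. GVIF uses the
  correlation-determinant formulation, which handles the multi-column
  habitat block; the raw GVIF is thresholded (not GVIF^(1/2df)).
- All term subsets are fitted by OLS (habitat dummies enter as a
  block), including the intercept-only model. AICc counts the residual
  variance as a parameter: k = columns + intercept + 1.
- Akaike weights w_m = exp(−Δ_m/2)/Σ exp(−Δ/2) feed *full*
  (zero-substitution) model averaging: a term absent from a model
  contributes β = 0 with variance 0, shrinking weakly supported effects
  toward zero. Unconditional standard errors use the Burnham–Anderson
  combination Σ w_m·√(var_m + (β_m − β̄)²); CIs are β̄ ± 1.96·se (normal
  multiplier — the model set has no single residual df).
- Cook's distance on the global model flags rows with D > 1; averaged
  coefficients are reported with and without flagged rows.

The original study's covariates derive from embargoed airborne-LiDAR
rasters, so the published coefficient values cannot be reproduced here;
the machinery is validated instead against a brute-force enumeration
oracle (agreement to 1e-10) and by sign-recovery simulations.

## The synthetic-survey generator

The generator emulates the study conditions: true densities
2.32/2.35/0.82 ind/km² in logged forest, salvage-logged remnants and
oil-palm remnants; half-normal detection with σ = 12.4 m per stratum
(ESW ≈ 15.5 m at 40 m truncation, matching the published strip widths);
conversion truth (0.85, 1.00, 259); a default plan of 12/10/6 transects
of 1.6 km (the field design's stratum proportions at its mean transect
length). Nest counts are Poisson with mean D·p·r·t·L·2·(strip width);
placement is uniform across a 60 m half-strip so that the 40 m
truncation genuinely discards records when the detection process has
wide support; detection is Bernoulli thinning by g(x); decay classes
A–E come from a uniform age on (0, t) thresholded at the 0.1/0.3/0.6/
0.85 quantiles (deterministic but cosmetic — estimation never filters
on decay class, since the standing-crop method counts all nests).

Covariates are drawn from habitat-specific normals chosen to mimic a
degradation gradient (taller, more variable canopy in logged forest;
low cover and large forest distances in oil palm). Realised density is
the habitat truth plus configured linear effects of plan-mean-centred
predictors plus Gaussian noise (sd 0.4 ind/km², a moderate
within-stratum heterogeneity roughly matching the published
between-transect spread), floored at zero. The default truth has a
single non-zero effect: +0.15 ind/km² per metre of canopy-height SD.

What the generator does *not* emulate: spatial clustering of nests
(the estimator assumes uniform availability), nest reuse beyond the
scalar r, detection heterogeneity between observers or habitats, and
any real relationship between canopy structure and detectability.
Passing recovery tests therefore show the estimator chain is
self-consistent under its own assumptions, not that those assumptions
hold in real forest.

## Problem sizes used in validation

Recovery checks use 100 replicates: detection recovery at n = 1000
distances per replicate; covariate sign recovery at ~200 transects;
end-to-end recovery at 30 transects per habitat, which keeps each
stratum near the 60–80-nest floor recommended for great-ape detection
functions while giving stable habitat means. The replicated analysis
drivers use 20 replicates for illustration.

## Known limitations

- Published transect lengths and strip widths are printed rounded
  (1 dp), so a handful of the published per-transect encounter rates
  and two densities differ from the recomputed values in the final
  digit; summaries agree to the printed precision.
- No analytic (delta-method) variance for density: uncertainty is the
  empirical between-transect spread, as in the source analysis.
- Unbinned (exact-distance) likelihoods and covariate-dependent
  detection are out of scope.
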