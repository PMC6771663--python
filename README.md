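# nestdensity

Orang-utan density estimation from standing-crop nest counts: binned
line-transect distance sampling, nest-to-ape density conversion,
parameter sensitivity, habitat comparisons, and AICc multimodel
covariate inference.

Great apes build sleeping nests that persist for months, so nest counts
along line transects are the standard indirect index of orang-utan
abundance. Converting counts to animal density takes two steps:

    D_nest = N / (L · 2w)          w = effective strip width, ∫₀ʷ ĝ(x) dx
    D_ape  = D_nest / (p · r · t)

where ĝ is a detection function fitted to binned perpendicular
distances (uniform, half-normal or hazard-rate key with cosine,
simple-polynomial or Hermite adjustments, selected by AIC), and
p·r·t — proportion of nest builders × nests per individual per day ×
nest decay time in days — is the expected number of standing nests per
individual. Because p, r and t are typically borrowed from other study
sites, the package propagates low/medium/high levels of each through a
27-combination sensitivity grid. Habitat contrasts use one-way ANOVA
with Tukey HSD, and covariate effects on density are inferred by
all-subsets OLS with Gelman standardisation, collinearity screening,
AICc ranking and full model averaging.

The package ships the per-transect summary of a 2017 nest survey across
a degraded Bornean landscape (28 transects in continuous logged forest,
salvage-logged forest remnants, and remnant patches in oil palm), plus
a synthetic-survey generator with known truth for validating every
stage, since the survey's raw distances and LiDAR covariates are
embargoed.

## Worked example

```python
from nestdensity.datasets import (
    SABAH_ESW_BY_HABITAT, SABAH_PARAMS, load_sabah_counts,
)
from nestdensity.density import estimate_from_counts, habitat_summary

estimates = estimate_from_counts(
    load_sabah_counts(), SABAH_ESW_BY_HABITAT, SABAH_PARAMS
)
print(habitat_summary(estimates).round(2).to_string(index=False))
```

prints

```
         habitat  n_transects  mean   sd   se  min  max
   logged_forest           12  2.32 0.84 0.24 1.25 4.52
  salvage_logged           10  2.36 0.61 0.19 1.16 2.98
oil_palm_remnant            6  0.82 0.50 0.20 0.09 1.37
       landscape           28  2.01 0.93 0.18 0.09 4.52
```

i.e. recently salvage-logged remnants hold essentially the same
orang-utan density as the neighbouring logged forest (≈2.3 ind/km²),
while forest remnants inside oil-palm estates hold about a third of
that (0.82 ind/km²); the landscape-wide mean over all transects is
2.01 ind/km², with per-transect estimates spanning 0.09–4.52 ind/km².

The numbered scripts under `analysis/` run the full study: the
per-transect table and habitat summaries (`01`), the (p, r, t)
sensitivity grid (`02`), habitat comparison tests (`03`), simulation
recovery of densities and strip widths (`04`), and multimodel covariate
inference on synthetic covariates (`05`). Each writes its tables under
`results/`. The same stages are available as a CLI
(`nestdensity run-all --config cfg.yaml`, `nestdensity simulate`,
`nestdensity estimate --published`, …).

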