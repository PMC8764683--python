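# Methods

## Status model

The package treats the aggregate abundance *B* of a seabed community as
logistic (Schaefer) with carrying capacity *K* and an additional mortality
term for trawling: each pass of a gear removes a proportion *d* of the
community, and passes arrive at the cell's annual swept-area ratio *F*.
Under chronic trawling the long-term state is taken as the equilibrium

    RBS = B/K = max(0, 1 − F·d/R),  with RBS = 1 exactly when F = 0.

This equilibrium stands in for the full dynamics: it assumes trawling
intensity is stationary on ecological timescales and that the community
is near its balance point. The clamp at 0 and the exact 1 at *F* = 0 are
guaranteed in floating point because downstream area accounting tests
equality with 0 and 1 (untrawled and depleted area classes).

Two spatial scales of parameters are distinguished. *d* and *r* apply at
the scale of a trawl track; *D* and *R* at the grid-cell scale (~1 km²).
With random trawl placement within a cell, *D* = *d* but overlapping
passes slow the effective recovery:

    R = r·d / (−ln(1 − d)),   R < r,  R → r as d → 0.

`dynamics.simulate_cell` verifies this by brute force: patches grow
logistically (Euler step, `dt ≤ 0.1/r` enforced) and receive Poisson trawl
events at rate *F* per patch-year, each multiplying patch abundance by
(1 − *d*). The long-run patch-mean B/K (time average over the final half
of the run) matches the closed form within Monte Carlo error; a
`fixed_track` mode concentrates all passes on a patch subset and shows how
aggregation within a cell raises the cell mean above the random-placement
equilibrium (trawled patches saturate at low abundance while the rest
recover). `equilibrium_vs_simulation` averages 5 independent replicates
per (d, F) combination so that the comparison's own Monte Carlo error
(sd ≈ 0.01 for a single 20-patch, 200-year run, with occasional larger
excursions when a patch is knocked very low) is small relative to the
0.03 agreement band it checks.

Units: *F* is per year (dimensionless swept-area ratio), *R* per year,
*d* per trawl pass, sensitivity *d/R* in years, penetration depth in cm.

## Depletion stage

Experimental impact studies report lnRR, the natural-log ratio of
abundance after trawling to before/reference abundance. The model is

    lnRR ~ gear intercept + gear slope · log10(days + 1) + (1 | study),

fitted with statsmodels MixedLM. The gear intercept at time 0 is the
immediate impact *i*; depletion is *d* = 1 − e^*i*. This is the minimal
structure consistent with an immediate impact plus recovery toward 0;
random slopes or nesting can be layered on, but with typical study counts
per gear (~10) the random intercept is what the data support. Natural-scale
SEs and 95% CLs of *d* come from sampling the intercept's normal
distribution and back-transforming (the point estimate is truncated at 0
with a warning if *i* > 0). Gears with fewer than two studies, or no
record within 30 days of trawling, are rejected rather than fitted.

Penetration depths are modelled on the log scale as additive
gear-component and habitat factors, `log(PD) ~ component:gear + habitat`.
Whole-gear depth per habitat is the width-weighted sum of component depths
(components absent for a gear have width 0; widths summing below 1 leave
the remainder non-penetrating; above 1 + 1e−9 is an error). Width
proportions are input data carried on the records, so a study reporting a
single component can be width-corrected at ingest, and record-level
`include_flag` columns implement study exclusions without hard-coding
study names.

Depletion transfers to gear × habitat combinations through an OLS
regression of gear-mean *d* on ln(gear-mean PD), where the gear-mean PD
weights habitats by the frequency of studies per habitat in the impact
meta-analysis (so the depth means the same habitat mixture as the *d* it
is paired with). Predictions are clipped to [0, 0.999] since *d* is a
proportion. The regression is unweighted by default (the gear means have
similar precision); a WLS option exists for sensitivity analysis.

Uncertainty is propagated with a 2,000-sample Monte Carlo: sampled
intercepts → sampled *d* per gear; sampled component depths (log-normal,
SD = SE) aggregated with the same width weights → sampled gear × habitat
depths; per replicate a gear-mean depth is drawn by choosing a habitat in
proportion to study frequency; 2,000 regressions are fitted (vectorised
closed-form OLS) and each predicts *d* at that replicate's sampled
gear × habitat depth, so depth uncertainty enters the prediction
distribution. Sample SDs give approximate SEs and the 2.5/97.5% quantiles
the 95% CLs. Degenerate replicates (no spread in log depth) are dropped
and counted; more than 1% aborts. All streams derive from explicit seeds
and are bit-reproducible.

## Recovery stage

Gradient studies sample relative abundance across sites spanning a
trawling gradient. Equating the equilibrium model with the observed
log-linear decline gives the fitted form

    log10(B/K) ~ b · dF + (1 | study),   dF = F · Σ_h frac_h · d_{gear,h}

with no fixed intercept: B/K is defined relative to the untrawled state,
so the mean response at dF = 0 is 0, and random study intercepts absorb
the calibration offsets introduced by within-study standardisation.
A free-intercept option exists for sensitivity analysis. Sediment enters
as interactions only — `b(g, s, m) = b0 + b_G·g + b_M·m` (sand baseline) —
so composition modifies the rate of decline, not the level.

The slope converts to the annual recovery rate of the untrawled community
via R = dF₀/(1 − 10^(b·dF₀)) evaluated at dF₀ = 1e−9, computed with
`expm1` (the naïve form underflows); at that dF₀ it equals the analytic
limit −1/(b ln 10) to better than 1e−6 relative. Evaluating near zero
intensity deliberately yields the slower recovery of pre-trawling
community compositions rather than the faster rates of trawl-selected
resilient biota. Confidence limits evaluate the transform at b ± 1.96·SE
with the composition-dependent SE (delta method on the coefficient
covariance); the lower CL of R comes from the more negative slope and is
the precautionary band carried through the assessment.

When no gradient data are supplied, a clearly-labelled synthetic default
slope fixture is used: vertex slopes back-derived from reference vertex
recovery rates 0.29 (gravel), 0.54 (sand) and 0.68 (mud) per year via the
limit formula, with vertex SEs back-derived from lower-CL rates 0.25,
0.386 and 0.48. The sand values follow the approximately constant product
of recovery rate and maximum community longevity across habitats
(longevities 18, 10, 8 years; lower-CL 22, 14, 11). Vertex SEs are
interpolated linearly in the fractions. The fixture is overridable and its
provenance is flagged in pipeline metadata.

## Habitat surfaces and grid assessment

Cells carry gravel/sand/mud percentages (validated to sum to 100 ± 0.1;
converted to fractions once at ingest). Categorical classes use the rule
gravel% > 30 (strict) → gravel, else sand% > mud% → sand, else mud (ties
to mud). Depletion and penetration depth vary continuously as
fraction-weighted means of the three habitat values; recovery varies
through the composition-dependent slope. `param_surface` exports these on
a ternary lattice (default 5% steps) together with sensitivity and
F_crit.

Per-cell status: per-gear terms F·d/R are summed (assessment gears are
otter trawl, beam trawl and towed dredge; hydraulic dredges appear in the
meta-analyses only), with `rbs_mean` using the mean recovery and
`rbs_lcl`/`rbs_ucl` the lower/upper-CL recovery. Swept-area ratios are
scaled by 100/coverage% per gear to correct for incomplete effort-data
coverage (assumes the collated data are spatially representative).
Cells missing from either grid are excluded with a warning, not imputed.

Regional summaries: the headline mean is area-weighted (cells near 1 km²
but varying); the simple mean is also reported. The ordered status–area
curve sorts cells by status descending against cumulative area; its area
equals the area-weighted mean to machine precision. The lower-CL band
sorts the cells' `rbs_lcl` values independently, guaranteeing a monotone
band. Category areas use half-open intervals [lo, hi) at boundaries
0.8/0.6/0.4 with the exact-1 and exact-0 classes pulled out first
(boundaries configurable). Per-gear status reductions attribute each
cell's terms directly when they sum below 1 and rescale them
proportionally when the status is clamped at 0, so gear reductions always
sum to 1 − mean RBS. Threshold risk reads the mean and CL curves at an
area percentile (default 80%), treats the band as a normal 95% interval
(sd = (ucl − lcl)/3.92 — the only distributional information available)
and reports P(RBS < threshold); a degenerate band gives a 0/1 step with
0.5 exactly at the threshold.

Footprint metrics work on per-cell total SAR: the uniform footprint is
Σ A·min(F, 1) (a cell with F = 1 contributes its area under either
branch); sensitive-biota areas use strict comparisons F > 0.35
(extirpation of biota with sensitivity 2.86) and F < 0.07 (status > 0.8
retained). The equivalent threshold inverts the survival curve of area
over descending distinct F at the uniform-footprint area, interpolating
linearly between adjacent distinct F values and returning the exact F at
an exact crossing.

Cross-region scaling fits logit(mean RBS) on log10(regional SAR) by OLS —
the logit keeps predictions inside (0, 1) and monotone; mean status is
clipped to [1e−4, 1 − 1e−4] before the transform (clip recorded in fit
metadata) and zero-SAR regions are pinned at status 1 and excluded. The
functional form is a package choice among monotone bounded alternatives;
the fit object is pluggable. Status vs stock exploitation (f/f_MSY) uses
plain OLS for both the all-stocks and regional-means fits.

## Synthetic data

The generators emulate the qualitative structure of real inputs, not any
particular region:

- **Effort**: a smoothed latent Gaussian field on the cell lattice is
  rank-normalised; the lowest quantile (default 2/3) of cells is
  untrawled, and trawled cells map to a log-normal SAR (sdlog 1.5, meanlog
  set so the all-cell mean is 0.42/y). Smoothing (moving-average window,
  default 3 cells) produces the spatial aggregation of effort observed at
  super-cell scales; the probability-integral transform keeps the marginal
  exactly log-normal. Per-gear SAR is the cell total scaled by the gear
  mix, so gear fields are proportional within a cell.
- **Sediment**: per-component gamma fields (shapes = Dirichlet
  concentrations, default (2, 4, 3)) smoothed on the lattice and
  normalised per cell; marginal means track the Dirichlet parameters to
  within ~2%.
- **Impact experiments**: lnRR centred on the true gear impact at time 0,
  recovering linearly in log10(days + 1) to 0 at one year, with study
  random intercepts (sd 0.15) and record noise (sd 0.2).
- **Penetration depths**: log-normal around true component depths times a
  habitat multiplier (mud deeper, gravel shallower).
- **Gradient studies**: study compositions cycle gravel-, sand- and
  mud-dominated Dirichlet draws — mirroring how comparative studies are
  conducted on grounds classified by sediment habitat — so the vertex
  recovery rates are identified rather than extrapolated. Default 40
  studies × 20 sites matches the scale of the real evidence base
  (~700 records). Site intensities are log-normal (meanlog 0.3, sdlog 1.0,
  chronically trawled grounds) plus one untrawled reference site per
  study. The response is b(composition)·dF — capped at 0 because true
  relative abundance cannot exceed carrying capacity — plus a study-level
  calibration offset (sd 0.05) and symmetric log-scale measurement noise
  (sd 0.1); sampled values may exceed 0 even though the underlying B/K
  never does, exactly as estimated abundance ratios can.

What passing tests on these data do and do not show: parameter recovery
and the structural identities demonstrate that the estimators are
consistent and the accounting exact under the generators' assumptions
(random within-cell trawling, log-linear gradients, lognormal noise).
They do not validate those assumptions against any real region, nor the
space-for-time substitution inherent in gradient-based recovery
estimation.

## Numerical choices and limitations

- Monte Carlo sample count defaults to 2,000 everywhere; quantile
  estimates at that size carry ~2% relative noise in CI widths (the
  reproducibility test therefore compares the across-target mean width
  between 2,000 and 20,000 samples).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived seeds use `SeedSequence` and stay
  below 2³¹.
- Problem sizes used by the test suite — 10⁴-cell grids for structural
  identities, 100 meta-replicates for CI coverage, 5 replicates per
  factorial cell for the simulator comparison — were chosen so the whole
  suite completes in well under a minute per module while leaving the
  statistical checks well-powered.
- The equilibrium assessment has no transient dynamics: a region whose
  effort changed recently is mis-stated until the benthos re-equilibrates.
- Depletion–depth transfer assumes the log-linear relationship holds
  across habitats within a gear; habitat enters only through depth and
  the recovery slope.
- The threshold-risk normal approximation uses only the 95% band; heavy
  tails in cell-status distributions are not captured.
- No spatial interpolation of sparse sediment samples is provided; cells
  without sediment data are dropped, not imputed.
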