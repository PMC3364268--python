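# Methods

## The estimand

The pipeline estimates the portion of resident-nekton standing stock on a
flooded marsh surface that is attributable to a managed riverine flood
pulse. Three metrics are carried in parallel: numerical density
(ind m⁻²), dry-weight biomass (g DW m⁻²) and energy density (cal m⁻²).
The attribution is hydrological, not mechanistic: a reference marsh,
hydrologically separated from the river inflow, stands in for the
counterfactual "no pulse" water level, under the assumption that without
the diversion the inflow basin would flood simultaneously with, and to
roughly the same depths as, the reference basin.

## Subsidy classification

Each 1 m² drop sample from the inflow area is classified by two
conditions evaluated against hourly stage records:

1. **Reference dry.** The reference marsh is not flooded (depth ≤ 0) at
   the gauge reading nearest the sample time (ties to the earlier
   reading). Flooding is strict: a stage exactly at marsh elevation is dry.
2. **Reference wet but inflow deeper.** The reference is flooded at the
   sample time, but the inflow area's *daily mean depth* — the mean over
   all hourly readings of the sample's calendar day, dry readings counted
   as zero — exceeds the *maximum daily mean flood depth* of the reference
   over the whole pulse window, where each reference day's mean is taken
   over flooded readings only.

A sample meeting either condition is subsidized. The two averaging
conventions differ deliberately ("water level" vs "depth of flooding") and
both are switchable (`ref_day_mean`, `inflow_day_mean`). The averaging
window for the inflow mean is a genuine design choice — instantaneous,
daily, and per-pulse readings were all defensible — and the calendar day
was adopted because hourly gauges aggregate naturally to days and daily
means match how such hydrographs are usually presented. Pulse windows are
half-open `[start, end)`; calendar days follow the series' local naive
timestamps. A per-area datum offset (mm) can be applied on read for
gauges on investigator-created datums; default 0.

Useful consequences that the tests exploit: classification is
deterministic and order-independent; raising the inflow stage uniformly
can never un-subsidize a sample; and if inflow and reference series are
identical, no sample taken while the reference is flooded can be
subsidized (its daily mean cannot strictly exceed the window maximum of
its own flooded-only daily means).

## Wet:dry allometry

Per species, dry weight is regressed on wet weight over individuals
(ordinary least squares via statsmodels). The intercept is kept only if
its two-sided t-test rejects zero at α = 0.05; otherwise the model is
refit through the origin. For through-origin fits the reported r² uses
the uncentered total sum of squares (the convention OLS software applies
to no-constant models — centred r² is not comparable there). Pooled
sample weighings of *n* individuals convert as
DW = n·b₀ + b₁·WW_pooled, because the line is fitted per individual and a
pooled weighing sums individuals. Negative predictions (tiny weights with
a negative intercept) are floored at zero with a logged warning.

## Energetics

A species' energy density is the grand mean over all its pellet
replicates, pooled across collection dates (one value per species; SE over
replicates, undefined for a single pellet). Sample standing stock is
restricted to the six dominant residents (*Palaemonetes paludosus*,
*Heterandria formosa*, *Gambusia affinis*, *Lucania parva*, *Poecilia
latipinna*, *Cyprinodon variegatus*) for all three metrics alike, so
density, biomass and energy describe the same assemblage; the inclusion
set is configurable. Energy per sample is exactly
Σ_s biomass(s)·energy(s) with no intermediate rounding.

## Subsidy algebra and error propagation

Proportions are ratios of totals (mass-weighted), not means of per-sample
ratios. Per-pulse proportions are averaged across pulses (with two pulses
the SE reduces to |p₁ − p₂|/2); inflow means pool all samples of all
pulses. The scaled subsidy is Z = X̄·Y/100 with

    Z_err = Z · sqrt((X_err/X̄)² + (Y_err/Y)²)      (default, quadrature)

Published SE algebra for such ratio-scaled estimates is not always
explicit about how the two relative errors combine, so `error_rule`
also offers `product` (Z·(X_err/X̄)·(Y_err/Y)) and `mean-only`
(Z·X_err/X̄). All internals are kept at full precision; rounding (1 dp
for metrics and percentages) happens only in report rendering, guarding
against double rounding.

## The synthetic world

The generator supplies every input with known ground truth.

**Water levels.** Reference stage = marsh + mean offset + semidiurnal tide
(amplitude 90 mm, period 12.42 h) + meteorological component + observation
noise (sd 8 mm). The meteorological component is an exponentially smoothed
Gaussian process (stationary sd 55 mm, e-folding timescale 48 h) shared
between areas — weather is regional. The inflow adds a trapezoidal pulse
hydrograph (plateau 300 mm above the inflow marsh, 42 h ramps) and damps
the tide by 85% inside pulse windows, emulating how river inflow obscures
tidal periodicity. The trapezoid is a pragmatic choice: observed pulse
stages show a sustained high plateau, and the functional form of the ramps
is not identifiable from such records. The default stage events start
~2.5 days after each sampling window opens — released river water takes
time to stack up on the marsh — so the inflow marsh is flooded for
roughly 80–85% of the sampling windows while the reference floods ~20% of
hours, and the pooled subsidized-sample share lands near 90%, matching
the regime of field campaigns of this design (~91–92% subsidized, n ≈
66–75 per pulse).

**Campaign.** Up to 5 samples per calendar day at distinct random flooded
hours of the inflow marsh. Per-sample species counts are negative binomial
(dispersion k ≈ 0.2–0.3, strongly aggregated, as marsh nekton are) with
mean = configured density × min(depth, 450 mm)/225 mm — density increases
linearly with flooded depth up to a saturation depth, a modeling choice;
the field literature reports assembly but no functional response. The
distributional family is likewise a choice; count data of this kind are
conventionally overdispersed. Individual lengths are lognormal; pooled wet
weight is Σ a·Lᵇ with 5% multiplicative weighing noise (cubic power law,
condition factors typical of small cyprinodontiforms and the
slimmer-bodied grass shrimp). The default community apportions ~40 ind m⁻²
across the six dominants by their observed abundance shares plus two minor
taxa (~5% of abundance). Environmental covariates (salinity, DO,
temperature, turbidity) are drawn uniformly within ranges typical of
low-salinity deltaic marshes; they are reported but never enter the
classification.

**Ground truth.** Subsidized flags are computed by a pandas-based
reimplementation of the two-condition rule
(`synthetic.independent_subsidized_flags`) sharing no code with the
hydrology classifier, so pipeline-vs-truth agreement is a real oracle
test. It assumes sample times on the hourly grid (true for generated
campaigns).

**Wet/dry and pellets.** Wet weights are uniform within per-species
collection ranges; DW = intercept + slope·WW + Gaussian noise,
rejection-resampled into 0 < DW < WW. Residual sds are back-solved from
target r² values (`residual_sd_for_r2`); truncation at small wet weights
raises realized r² slightly above target, which is acceptable since the
targets only set the noise scale. Pellet energies are Gaussian around the
species truth with sd reconstructed from reported SEs (sd = SE·√n).

## What passing tests do and do not show

The synthetic world validates the *pipeline*: that classification
implements the stated rule exactly, that regression and aggregation
recover configured truths, and that a known subsidized fraction p of
metric mass is recovered without bias. It does not validate the *field
assumption* that reference hydrology is a faithful counterfactual, nor
does it reproduce one notable field pattern: because generated catch
scales with depth, subsidized (deep) samples carry disproportionately more
stock, so the mass-weighted subsidized proportions (~95–99%) exceed the
sample-count share (~90%), whereas field data can show the reverse when
shallow unsubsidized samples hold dense catches. Real gauge records also
contain gaps, datum drift and storm surges that the generator omits; the
classifier does no gap-filling beyond nearest-reading lookup.

## Numerical choices and degenerate inputs

- Nearest-reading stage lookup breaks ties toward the earlier reading;
  lookups outside the span ± 1 h raise.
- A reference window with no flooded day has an undefined maximum mean
  depth; condition 2 then cannot arise (condition 1 already applies).
- Zero overall metric totals yield proportion 0 with a warning; single
  pulses or single replicates yield undefined SEs reported as missing.
- Regression requires ≥ 3 individuals and nonzero wet-weight variance.
- Fixed seeds make every generator bit-reproducible; the run seed spawns
  four fixed offsets for the hydrology, campaign, wet/dry and pellet
  streams.
- Problem sizes in the default study: ~1,270 hourly readings per gauge,
  ~145 samples over two pulse windows, ~3,000 wet/dry individuals, 58
  pellets — the scale of a two-pulse field season, which keeps the full
  test suite and acceptance run fast.

## Known limitations

- The two-condition rule attributes flooding, not fish: it assumes
  assembled nekton track water access instantaneously.
- Energy densities are static per species; reproductive seasonality and
  size dependence of caloric content are out of scope.
- No ash-free dry weight correction; no tidal harmonic analysis; no
  hydrodynamic model of the diversion discharge.
- The error rules propagate SEs through the final product only; sampling
  covariance between X̄ and Y (both computed from the same samples) is
  ignored, as is conventional for this estimator.
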