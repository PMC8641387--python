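# Methods

`devwild` implements a cross-national screening analysis: do countries whose
Sustainable Development Goal (SDG) indicators improved faster over a study
window also show more positive wildlife population abundance trends?  The
pipeline has four stages — trend derivation, panel homogenization,
preprocessing/orientation, and univariate Bayesian mixed-model screening —
plus a synthetic-data generator with planted ground truth that makes the
whole chain testable without any external data.

## 1. Trend derivation

Every yearly series (a population's abundance, or one country's values of
one indicator) is reduced to a single *mean annual change*.

**Transforms.** Abundance values are log10-transformed.  Exact zeros are
first replaced by `zero_replacement_frac` (default 1%) of the series mean
over all observed values; an all-zero series is rejected.  Indicators in
monetary or population-size units (`log_required`) are log10-transformed
after a positive shift when the cross-country minimum is at or below zero;
indicators that take negative values anywhere across countries
(governance-index style) are shifted by `-(cross-country minimum) +
shift_eps` so the same constant applies panel-wide.  Because a common shift
is affine, it leaves annual changes of unlogged indicators untouched.

**Model chain.** Series with fewer than six observations get an ordinary
least-squares line; gap years are filled by linear interpolation between
adjacent observations, and annual changes are read from the
observed/interpolated series (a config switch `linear_changes_from: fitted`
reads them from the regression line instead).  Series with six or more
observations get a penalized natural cubic regression spline ('cr' basis:
knots at quantiles of the observed years, Green–Silverman curvature
penalty) with basis dimension `ceil(n_obs / 2)` and the penalty weight
chosen by GCV on a 33-point logarithmic grid.  Predictions at every integer
year in the observed span give the annual changes as consecutive
differences.  Linear functions span the penalty null space, so noiseless
linear series are reproduced exactly on both paths; the spline is
cross-checked against mgcv's `s(x, k, bs="cr")` in the test suite.

**Quality filters.** A fit is retained iff (a) R² > 0.5, where R² is
uniformly the squared Pearson correlation between fitted and observed
values at observed years (defined as 0 for constant or degenerate fits,
which are logged separately), and (b) the series covers at least five years
inside the study window (default 1996–2015).  Annual changes are clipped to
the window; the trend is their arithmetic mean.  `n < 6` counts actual
observations, not span years — the only reading under which the
two-observation minimum and the n-threshold are both meaningful.  Fitting
uses all observations and only the changes are clipped, since series are
short and discarding out-of-window observations before fitting would waste
most of the information in boundary-straddling series.

## 2. Panel homogenization

Retained trends form a sparse country × indicator availability table.  It
is pruned to a complete block by a fixed-order pass: (1) drop countries
holding fewer than `ceil(min_indicator_fraction × n_indicators)` indicators
(default one half — 21 of 42 at full scale); (2) drop indicators whose
associated wildlife-population total over the remaining countries that hold
them is below `min_populations_per_indicator` (default 160); (3) drop
remaining countries lacking any retained indicator.  Populations are
counted after the trend-quality filters, since homogenization operates on
derived trends.  The pass is repeated until nothing changes: a single pass
is not idempotent in edge cases (step 2 counts populations over the
pre-step-3 country set), and iterating to the fixpoint preserves the step
order while making re-application a guaranteed no-op.  Every removal is
recorded with its pass, step, metric and threshold.

Birds and mammals are homogenized, assembled and modelled as fully separate
datasets, so their country and indicator sets can differ.

## 3. Orientation and normalization

Within the homogenized block, each indicator's trends are oriented
(multiplied by −1 where flagged, so that greater values always mean
progress) and then z-scored across countries.  Orientation precedes
normalization, so flipping a flag exactly negates the z-scores.  The SD
uses the sample convention (`ddof=1`; configurable).  Indicators with zero
cross-country SD are excluded with a logged reason.  Pairwise Pearson
correlations between oriented indicator trends (pairwise-complete, minimum
overlap 3 countries) are reported because the indicators are strongly
inter-correlated — the reason the screening is univariate rather than a
joint multi-indicator model.

Each retained wildlife trend is cross-joined with the oriented trends of
the indicators available in its country, together with log10 country land
area and log10 1996 human population density as covariates.

## 4. The hierarchical model

Per indicator and taxon class:

    y_i ~ Normal(b0 + b1 x_i + b2 logArea_i + b3 logHPD_i
                 + u_species[i] + u_order[i] + u_region[i], sigma^2)

with y the wildlife trend (log10 units/yr), x the oriented z-scored
indicator trend, N(0, 1000) priors on all fixed effects (intercept
included; the prior is wide enough that including the intercept is
immaterial, and symmetry keeps the model sign-reparametrization exact), and
Gamma(shape=1, rate=5e-5) priors on the residual and random-effect
precisions — essentially flat over the relevant range.  Grouping factors
with fewer than two levels are dropped with a note.  Populations of the
same species share one species intercept across countries; regions attach
to populations via country metadata.

**Inference.** The model is linear-Gaussian throughout, so a Gibbs sampler
with conjugate full conditionals (multivariate normal for the fixed-effect
block, independent normals per random-intercept level, gammas for
precisions) draws from the exact posterior.  Defaults: 4 chains × 5000
iterations, 1000 burn-in, thin 1, deterministic zero initialization, chain
seeds spawned from one seed.  Covariate columns are centered internally (a
pure intercept reparametrization that improves mixing; reported slopes and
intercept are on the original scale).  Convergence is summarized by
split-R̂ (computed on half-chains, so it is defined for a single chain) and
bulk effective sample size (arviz); fits with R̂ > 1.05 are flagged
non-converged and barred from support claims.

**Orientation equivariance.** The posterior is exactly invariant under
jointly negating a design column and its coefficient.  The per-indicator
driver therefore samples on the canonical (un-inverted) indicator scale and
maps the reported summary through `beta -> sign * beta` (CI bounds swapped
and negated).  Toggling an indicator's invert flag thus negates its
reported posterior mean *exactly*, not merely to Monte-Carlo error — no
stochastic sampler run twice on mirrored inputs could achieve that
draw-by-draw.

**Reporting.** Per indicator: posterior mean, SD, equal-tailed 95% credible
interval, a `support` flag (interval excludes zero, convergence required),
the companion proportional-change scale `10^beta − 1` summarized over
draws, and variance-component means.  No multiplicity correction is applied
— screening is by per-indicator intervals, and any correction is left to
the user.

## 5. Synthetic data

The generator emulates the two data sources: short, noisy, strictly
positive abundance series with interior gap years and heterogeneous
lengths and start years, and country-level indicator panels with
per-country linear drifts.  A population's true log10-abundance slope is

    s_p = sum_j beta_j z_cj + u_species + u_order + u_region + e_p

with z the oriented z-scored true indicator drift, u's drawn once per
level, and e_p idiosyncratic population-level variation.  Defaults (the
study conditions): 30 low/lower-middle-income countries × 10 populations ×
6 indicators over 1996–2015; series lengths 10–20 years with 10% interior
gap probability; observation noise 0.15 on the log10 scale; indicator
drifts N(0, 0.05²) observed with noise 0.05 and 5% whole-series masking;
random-intercept SDs 0.15 (species), 0.05 (order and region); population
SD 0.3 — population-level heterogeneity is the dominant variance component,
as is typical of abundance-trend compilations.  Planted defaults:
+0.5 on GDP per capita and +0.4 on (inverted) human population density,
zero elsewhere.  Monetary indicators are emitted as powers of ten of a
linear latent series so the pipeline's log transform recovers linearity;
one governance-style indicator takes negative values to exercise the shift
path.  Species are grouped within countries by default (~3 populations per
species) and can be pooled across countries (`species_scope="global"`).
Gap years never remove the first or last observation, so span-based checks
stay interpretable.  The generator writes plain CSVs plus a `truth.json`
holding every planted quantity, and its output is byte-identical under a
fixed seed.

It does not attempt to mimic the real Living Planet Database's taxonomic
composition, spatial clustering, or real World Bank value distributions;
passing tests demonstrate correctness and calibration of the *procedure*
under a known generative model, not performance on real data.

The default pipeline configuration uses a step-2 homogenization cut of 50
populations: the full-scale analysis value of 160 would empty a ~150
population-per-taxon synthetic panel by construction, and under fixpoint
iteration the cut must also hold on the post-complete-case panel (roughly
half the countries, ~80 populations per taxon).  The
`HomogenizationParams` dataclass itself defaults to 160.

## 6. Parameter-recovery experiment

The calibration experiment (`devwild.experiments`) replicates the full
pipeline on panels with **one population per country** (330 countries,
species pooled across countries, three indicators with planted effects
+0.8, 0.0, 0.0, indicator drift mean 0.15 so nearly every indicator trend
survives the R² filter).  This design makes the fitted univariate model
nest the generative model exactly.  That matters: with clustered
populations (the paper-scale default), a nonzero country-level effect of
one indicator leaves country-correlated residual structure in every other
indicator's univariate fit, which no species/order/region random intercept
absorbs — for m populations per country the ratio of true to nominal
sampling SD of a null coefficient is roughly sqrt((m·b² + s²)/(b² + s²)),
about 3 at m = 10, b = 0.8.  The paper-scale default run therefore
*illustrates* this anticonservativeness of univariate screening (planted
nulls can reach "support"), while the one-population design isolates what
the experiment is meant to certify: calibration of the sampler and the
support rule.  Replicate fits use 2 chains × 1500 iterations (ESS ≈ 2000
per fit); the test suite runs 100 replicates and the acceptance script 40,
with all seeds derived from one master seed.

## Known limitations

- Trend-fit uncertainty is not propagated into the regression (point
  trends only, matching the analysis design); with very small residual
  variation this surfaces as mild interval under-coverage.
- Univariate screening with clustered populations and no country-level
  random effect is anticonservative for null indicators whenever some other
  indicator has a real effect (quantified above).
- The R²-based retention filter truncates near-zero trends, a weak
  selection on the response.
- GCV occasionally undersmooths short noisy series; the basis dimension
  cap (`ceil(n/2)`) bounds the damage.
- The Gibbs sampler mixes slowly when group intercepts are nearly
  collinear with a country-level covariate and residual variance is small;
  non-converged fits are flagged and excluded from support claims rather
  than repaired.
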