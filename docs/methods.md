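# Methods

This note records the statistical model, the generative assumptions of the
simulators, and the numerical and design choices made where the procedure
was genuinely open.

## Learning-curve model and estimation

The response is the arcsine-transformed block success rate
y = arcsin √p of each bee over consecutive blocks of 10 counted visits
(x = 10, 20, …, 60).  The arcsine square-root map is the standard
variance-stabiliser for binomial proportions; it sends [0, 1] to [0, π/2]
and its inverse is sin².  A plain arcsin(p) variant is available behind the
`variant` switch of `arcsine_transform` for sensitivity checks.

The full model is a linear mixed model with fixed effects
{intercept i, learning slope l on ln x, group intercept offsets s_t, s_c,
group × ln x interactions c_t, c_c} and independent per-bee random
intercepts and slopes.  The experience predictor is the natural logarithm
of the counted-visit number (an `identity` transform is available through
`ModelSpec.predictor_transform`).  Group coding: the bar-rewards group is
the baseline (T = C = 0), the circle/cross-rewards group sets T = 1 and the
control group C = 1; the interaction columns are T·ln x and C·ln x.

Estimation is maximum likelihood on the Gaussian marginal, not REML,
because AIC comparisons across fixed-effect structures are invalid under
REML.  The per-bee marginal covariance is σ²(I + g_b 11′ + g_r zz′) with
variance ratios g_b = σ_b²/σ², g_r = σ_r²/σ² and z the ln x vector.  Fixed
effects (GLS) and the residual variance are profiled out; the ratios are
optimised on the log scale with a floor of 1e-10 (a floored ratio is
snapped to exactly zero when that does not worsen the likelihood), starting
Nelder-Mead polish runs from the best points of a fixed coarse grid, so the
fit is deterministic.  Bees sharing the same block layout share one
covariance factorisation, which keeps a full fit of the canonical design
(216 rows, 36 bees) under 0.1 s.  The profiled residual variance is floored
at 1e-12 so that perfect (noise-free) fits remain finitely comparable.
With both variance components switched off the fit reduces exactly to
ordinary least squares (verified to 1e-8 against a least-squares oracle);
with random intercepts only it matches statsmodels MixedLM (ML) to 1e-6.

Bookkeeping: deviance = −2 log L including Gaussian constants;
k = active fixed effects + active variance components + 1 residual
variance; AIC = deviance + 2k exactly.  Only differences between nested
fits are ever interpreted, and Δk equals the number of parameters whose
removal defines a comparison.

## Model simplification ladder

Comparisons run strictly in the order: (1) drop the per-bee random slopes;
(2) drop the group × experience interactions; (3) *only if* step 2 accepted
the no-interaction model, drop the group terms; (4) drop the learning
slope.  Each step starts from the standing best model.  The decision
follows AIC — the simpler model is kept unless it raises AIC by more than
`aic_threshold` (default 2; configurable, e.g. to 6 for a more
conservative rule) — while the deviance change with its chi-square
reference (df = parameters removed) is reported alongside.  Dropping the
random-slope variance is treated as an ordinary 1-df chi-square with no
boundary-mixture correction, matching how such ladders conventionally
report plain df.  When interactions are retained, the ladder stops and
per-group models y = i + l·ln x + b_n test the effect of experience within
each group by removing l.

A note on the reporting identity: for every comparison
ΔAIC = Δdeviance − 2Δk holds by construction.  Published tables in this
literature occasionally contain a pair violating the identity
(e.g. ΔAIC 0.3 with Δdeviance 1.6 at df 1, which would require ΔAIC −0.4);
such entries are treated as typographical and are not reproduction targets.

## Test-phase analysis

Each bee contributes one arcsine success proportion over its 20 counted
test landings.  With one observation per bee, a model with bee as a random
factor is identical to plain one-way ANOVA, which is what is implemented
(explicit sums of squares; F on (groups − 1, bees − groups) df).  Nests are
recorded in the data but not modelled.  Tukey HSD pairwise tests use the
studentized-range distribution at the ANOVA's within-group df
(statsmodels `pairwise_tukeyhsd`); the compact letter display assigns a
letter to each maximal clique of the not-significantly-different graph,
ordered by descending group mean, so groups share a letter exactly when
they are statistically indistinguishable.  A fully degenerate table (zero
variance everywhere) returns F = 0, p = 1 and a single shared letter.

## Visit-level simulator

The simulator reproduces the data-collection protocol: flowers in a flight
arena (16 = 8 rewarding + 8 nonrewarding "small" flowers with cleaning and
refilling at the end of each foraging bout; 6 = 3 + 3 "large" flowers
refilled and relocated after the bee departs), bout lengths drawn from a
Poisson truncated at 1 with means 10.53 (small) and 6.97 (large) landings
per bout — the distribution itself is a modelling choice; only the means
are constrained by the protocol — and uniform flower choice, optionally
tilted toward rewarding positions by a `spatial_bias` parameter that ramps
in over the first six bouts to emulate spatial learning in arenas whose
flower positions cannot be fully re-randomised.

Success is generated on the arcsine scale: bee n's probability of a correct
action at counted visit x is sin²(θ) with
θ = clamp(i + gᵢ + b_n + (g_s + r_n)·ln x, 0, π/2), where (gᵢ, g_s) are the
group's intercept shift and slope and b_n, r_n are zero-mean Gaussian bee
deviations.  The outcome (correct/incorrect) is drawn directly and the
probed flag derived from it and the flower's reward designation; this is
behaviourally equivalent to simulating a separate probe decision, and the
records still carry probed/rewarding/counted fields so that the scoring and
revisit-exclusion code is exercised end to end.  Probing any filled well
(sucrose or water) marks the flower emptied for revisit accounting.  In the
large arena a flower is refilled and relocated as soon as the bee lands
elsewhere, so exactly the immediately repeated landings are uncounted; the
protocol's timing ("refilled whilst the bee was flying elsewhere") admits
other operationalisations, but this one is deterministic and matches the
stated counting rule.  Uncounted landings are emitted with their own
records so the revisit filter can be verified against the generator
(`filter_revisits` is idempotent and reproduces the simulator's flags).
In the test phase every well holds water and a bee performs at its
end-of-learning level (the curve evaluated at x = 60); correctness is
scored against the reward scheme of the preceding learning phase.

Generative defaults (chosen once): control groups are flat at 50 % success
(θ = π/4, zero slope); reward groups start at chance over the first block
and reach ≈85 % success by visit 60 (baseline intercept π/4 − 0.498,
slope 0.216 per ln-visit), the qualitative shape of published bumblebee
learning curves; bee deviations have SD 0.10 (intercept) and 0.03 (slope)
radians; 12 bees per group drawn from four nests.  One global seed spawns
independent per-bee substreams, so cohorts are bit-reproducible.

### What the block-level generator is for

Blockwise arcsine success of 10-visit binomial counts is a slightly biased
estimator of the generative curve evaluated at the block-end regressor:
arcsin √ of a binomial mean carries Jensen bias at n = 10, and the curve's
log-curvature within a block shifts the block mean away from the endpoint
value.  The estimand of the block-level regression on visit-level data is
therefore the least-squares projection of the exact block expectations —
verified in the tests with a Poisson-binomial enumeration oracle — not the
generative coefficients themselves.  For parameter-*recovery* studies the
package provides `simulate_series`, which draws block responses directly
from the mixed model (Gaussian residuals on the arcsine scale, default
residual SD 0.16 ≈ 1/(2√10), the binomial sampling noise of a 10-visit
proportion after arcsine stabilisation).  Fits to it are correctly
specified, and recovery of all six fixed effects within 3 Monte-Carlo
standard errors across 100 cohorts is part of the acceptance suite.
Passing those tests demonstrates the estimator is consistent and the
pipeline unbiased under its own assumptions; real conditioning data add
features (sequential dependence between landings, motivation drift,
unbalanced revisit exclusion) that neither generator models.

## Thermograph generation and survey statistics

A thermograph is a temperature grid (°C) with a boolean flower mask (disc
of the configured diameter; 21 °C ambient outside).  Heated regions — edge
annulus, central bar, centre-radiating cross, centre disc — are defined by
a single width parameter solved analytically on the continuous disc so
that every shape attains the same heated-area fraction (default 0.25,
matching a ≤3 cm² heating element on a 40 mm flower).  Patterns are drawn
rotated 17° to the pixel grid; an axis-aligned bar would quantise to whole
pixel rows and break the area match at coarse resolution, and a real
camera never aligns with the pattern axes anyway.  Plateau temperatures
(default 33 °C hot / 25 °C cold, ≈8 °C range) are blended by a logistic
profile of the signed distance to the region boundary with a 1 mm edge
scale — the true edge profile of a heated lid is not documented, and any
smooth monotone profile preserves the plateau statistics.  Optional i.i.d.
Gaussian sensor noise is seeded per spec.  Point measurements are
idealised as exact pixel max/min; camera spot-size averaging is out of
scope.  With these defaults, paired circle/bar (and cross/bar) flowers
match in heated pixel fraction within 2 %, in mean flower temperature
within 0.1 °C, and in within-flower range within 2 % — the three "no
alternative cue" constraints.

The survey generator draws one within-flower contrast per species from a
gamma distribution (shape 1.1652, scale 2.6783), calibrated so that about
55 % of species meet the inclusive ≥2 °C detectability threshold with a
detectable-subset mean near 4.9 °C; the detectable-subset SD (≈2.8 °C)
follows from those two constraints rather than being matched separately.
Each species is rendered as a thermograph with a randomly chosen pattern
shape and its range measured from the image.  Survey summaries count
species at or above the threshold, display the proportion as a whole
percent, and report the mean and sample (n − 1) SD over the detectable
subset only.  One range value per species is taken as given; averaging
multiple thermographs per species is not modelled.

## Calibration and problem sizes

The likelihood-ratio machinery was checked by simulation at the canonical
design: the per-group experience test on flat (null) visit-level cohorts
rejects at close to the nominal 5 % level, and ladders on cohorts with
group-dependent learning retain the interaction terms in essentially all
replicates.  The shipped test suite runs 200 null replicates for the
calibration check, 100 cohorts for parameter recovery, 60 for the
pseudo-true projection check, 50 for nested-deviance monotonicity and 30
for ladder power — sizes chosen to keep Monte-Carlo error well inside each
test's tolerance while the whole suite completes in a couple of minutes.

## Known limitations

- The Gaussian block-level likelihood is an approximation to the underlying
  binomial counts; the package deliberately follows the arcsine-LMM
  analysis rather than a binomial GLMM, so conclusions inherit that
  approximation.
- Random intercepts and slopes are independent by default; a covariance
  term is not implemented.
- The simulator has no physical model of flight, heat transfer, scent
  marks or electrostatics, and assumes cleanly labelled records (no
  ambiguous landings).
- Revisit exclusion in the large arena assumes refill-and-relocate happens
  before any non-consecutive return; slower refills would uncount more
  landings than the simulator does.
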