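# Methods

`caresae` estimates subnational, yearly levels of two composite
healthcare-quality metrics — facility **readiness** (proportion of required
items available on assessment day) and **process quality** (proportion of
clinical diagnostic protocols adhered to in sick-child consultations or
vignettes) — from a series of complex facility surveys, using a two-stage
small-area approach.

## Stage 1: design-weighted direct estimation

Facility-level metric values are aggregated to (area, year, survey) cells
with the Hájek estimator

    p̂ = Σ wᵢ yᵢ / Σ wᵢ ,

where `wᵢ` is the facility's sampling weight (inverse inclusion
probability).  Its design-based variance uses the with-replacement
linearised form, treating facilities as PSUs within design strata:

    zₕᵢ = wₕᵢ (yₕᵢ − p̂) / Σ w ,   v = Σₕ nₕ/(nₕ−1) Σᵢ (zₕᵢ − z̄ₕ)² .

Strata with a single sampled facility are pooled into one certainty stratum
for variance estimation (a lone singleton contributes zero).  Estimates are
carried to the logit scale with the delta-method variance
`v / (p̂(1−p̂))²`.

Degenerate cells are kept rather than dropped: boundary estimates
(p̂ ∈ {0,1}) receive the continuity correction `p̃ = (n·p̂ + 0.5)/(n+1)` and a
variance floor `p̃(1−p̃)/n`; interior cells where all facilities tie (design
variance numerically zero) receive the same floor.  Cells with a single
facility are flagged unusable: they are excluded from the model likelihood
but retained for reporting.  Consultation-level process scores are averaged
to a facility mean before weighting, so a facility with many observed
consultations is not overweighted beyond its survey weight.

## Stage 2: area-level space-time smoothing

The logit-scale direct estimates are modelled as Gaussian observations with
known sampling variances (the area-level / Fay–Herriot form):

    y_{a,t,s} ~ N(θ_{a,t} + δ_s , V_{a,t,s})
    θ_{a,t}  = α + x_{a,t}'β + b_a + φ_t + γ_t

with seven structures crossing three switches:

| model | area effect `b` | covariates `β` | survey effects `δ` |
|-------|-----------------|----------------|--------------------|
| M1    | IID             | –              | –                  |
| M2    | IID             | –              | yes                |
| M3    | IID             | yes            | –                  |
| M4    | IID             | yes            | yes                |
| M5    | BYM2            | –              | –                  |
| M6    | BYM2            | –              | yes                |
| M7    | BYM2            | yes            | yes                |

Year effects are IID (`φ`) plus a first-order random walk (`γ`, the
path-graph intrinsic prior) in every model; prediction years beyond the last
survey extrapolate through the RW1 with variance growing in the horizon.
The BYM2 area effect combines an unstructured and an ICAR component with a
total standard deviation and mixing fraction; the ICAR is scaled so the
geometric mean of its marginal variances is one.  ICAR, RW1 and survey
effects carry sum-to-zero constraints (per connected component for the
ICAR), identifying `α` and `θ` as the cross-instrument consensus level.  No
space-time interaction term is included.  Covariates are centred and scaled
to unit variance over the prediction grid; zero-variance columns are dropped
with a warning.

Default priors (config-overridable): half-normal(0, 1) on every
random-effect standard deviation, N(0, 5²) on intercept and slopes,
Uniform(0, 1) on the BYM2 mixing fraction.  Survey effects are one IID
(sum-to-zero) effect per instrument wave.  Instrument offsets are only
identified against year effects when instruments overlap in time — the
bundled generator therefore fields both instrument families in one year, as
real survey series do.

## Inference

Conditional on the variance parameters, the model is linear-Gaussian with
known observation variances, so the latent field integrates out in closed
form.  Fitting proceeds in two exact stages:

1. adaptive random-walk Metropolis (Haario-style covariance adaptation,
   frozen after warm-up) on the 3–5 transformed hyperparameters, targeting
   the analytically marginalised posterior; per-iteration cost is one
   Cholesky of a ~50-dimensional matrix, so a fit takes well under a second;
2. for each retained hyperparameter draw, one exact draw of the latent field
   from its Gaussian conditional.

This yields exact joint posterior draws — the only approximation is MCMC on
the low-dimensional marginal — and makes the hundreds of refits required by
hold-one-area-out cross-validation affordable.  Constrained blocks are
parameterised in spectral (ICAR/RW1) or Helmert (survey) sum-to-zero bases,
so constraints hold exactly by construction; the marginalised likelihood is
verified in the tests against a dense Gaussian-integral oracle, and the
joint density against a dense covariance-matrix oracle, at 1e-8.

Defaults: 1500 warm-up iterations, 6000 post-warm-up states thinned to 1000
retained draws (cross-validation refits use 600/1600/400).  Split-chain
R-hat and bulk effective sample size are reported for every hyperparameter;
non-convergence is flagged, never silent.  Area-year summaries (posterior
mean and 2.5/97.5 percentiles) are computed on the probability scale after
the inverse-logit transform.  Reported intervals are for the latent θ, not a
posterior predictive of a new survey estimate.

## Model comparison

WAIC, DIC and the mean negative log conditional predictive ordinate (LCPO)
are computed from the pointwise log-likelihood matrix.  CPO uses the
harmonic-mean identity with importance weights truncated at √S times their
mean, which controls the estimator's heavy right tail; the tests verify it
against brute-force leave-one-cell-out refits.  Selection takes the smallest
WAIC, with ties broken by LCPO, then DIC, then the smallest model id.

## Hold-one-area-out validation

Validation cells are the usable cells whose design precision (1/variance)
strictly exceeds the median precision per metric — sparse cells' direct
estimates are too noisy to serve as a benchmark.  For each target area-year,
every survey cell of that area-year is removed, the model refitted, and each
held-out cell scored against the refit posterior predictive of the *direct
estimate*: latent θ, plus the held-out instrument's survey effect, plus
sampling noise drawn as Student-t with the cell's design degrees of freedom
(facilities minus strata) scaled by the cell's estimated standard error —
the t accounts for the variance itself being estimated from few facilities.
Summaries are the mean error, mean absolute error, and empirical coverage of
the 50/80/95% predictive intervals, all on the probability scale.

### What calibration does and does not show

Nominal coverage is the mathematically expected outcome only under
self-consistency: the truth's variance components drawn from the fitted
priors, and the Gaussian observation model adequate (moderate proportions,
enough facilities per cell that the estimated design variance is reliable).
The calibration test therefore draws variance components and instrument
offsets from the model's priors (scales 0.5, survey 0.3 — surfaces stay in
the realistic 10–90% range) and surveys ~38 facilities per cell, a density
comparable to the larger real facility surveys (~45–65 per area).

At the sparse default conditions (~6 facilities per cell, comparable to the
smallest real survey waves) coverage falls below nominal: filtering
validation cells on *estimated* precision selects cells whose variance
estimates are biased low, so predictive intervals are too narrow relative to
the benchmark.  This is a property of the validation construct, not of the
estimator — the latent surface's own intervals remain conservative — and is
what one should expect whenever hold-out predictions are benchmarked against
noisy direct estimates from very small survey cells.  Passing the
calibration test therefore shows the
machinery is self-consistent in the data-dense regime; it does not promise
nominal coverage against noisy direct estimates in very sparse surveys.

## Synthetic data generator

The generator emulates SPA/SDI-style facility assessment series: a frame
stratified by facility type × managing authority × area, Bernoulli sampling
within stratum at wave-specific fractions (weights = 1/fraction; hospitals a
census), two instrument families with systematic logit-scale offsets
(default ±0.25, overlapping in one year), binary item and protocol
indicators driven by latent area-year surfaces with scaled-ICAR spatial,
RW1 + IID temporal, and covariate structure, facility-level IID logit
heterogeneity (sd 0.3), and a truncated-Poisson(3) number of observed
consultations per facility.  Default scale: 4×4 rook lattice, 8 years,
12 readiness items, 15 protocols, ~12 frame facilities per area.

It does not emulate: nonresponse, GPS/geography beyond adjacency,
item-level correlation beyond the facility effect, provider-level vignette
weighting (vignette-like records are treated as observed consultations),
frame errors, or boundary changes.  Passing tests on these fixtures
demonstrates estimator and model correctness under the stated design, not
robustness to those real-world complications.

## Numerical choices

- Hyperparameters are sampled as log-sds (logit for the mixing fraction),
  bounded at |·| ≤ 8 where the half-normal prior carries no mass, keeping
  the normal-equation Cholesky well posed; a failed factorisation returns
  −inf rather than aborting.
- Sum-to-zero violations in explicit-density evaluation return −inf
  (constraint enforced exactly, not penalised).
- All randomness derives from one run seed through named CRC-keyed
  substreams, so adding draws to one stage does not perturb another; equal
  seeds give byte-identical output files.
- Ties in model selection are impossible in floating point for fitted
  models but are defined deterministically anyway.

## Known limitations

- The likelihood treats estimated design variances as known (standard for
  area-level models); with very few facilities per cell this understates
  uncertainty.
- No space-time interaction: an area-specific trend away from the shared
  trend is smoothed over.
- Survey effects are exchangeable across waves; a long-run drift within one
  instrument family would be absorbed by year effects.
- The unit-level (facility-level) model is out of scope, as are
  geostatistical (continuous-space) models and weight calibration/raking.
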