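# Methods

## Model

All estimation rests on the non-replacement (depletion-aware) form of
the Holling type II functional response.  During a trial of duration `T`
(hr) a single predator removes prey from an initial stock `N0`; prey are
not replaced, so the instantaneous consumption rate falls as prey are
eaten.  Integrating the type II rate over the trial gives Rogers' random
predator equation

    Ne = N0 (1 − exp(a (Ne h − T)))

with attack rate `a` (cage/hr: the volume-specific search/capture
efficiency, the low-density slope of the response) and handling time `h`
(hr/prey: the time to attack, consume and process one item, setting the
asymptotic maximum `T/h`).  The equation is implicit in `Ne`; the
explicit solution on the principal Lambert W branch is

    Ne = N0 − W(a h N0 exp(−a (T − h N0))) / (a h).

The Lambert argument is always positive, so the principal branch is the
only real solution and `Ne ∈ [0, N0]` always.  Two analytic limits avoid
0/0 at the boundary of the parameter space: `a = 0` gives `Ne = 0` and
`h = 0` gives exponential depletion `Ne = N0 (1 − e^{−aT})`.  For
numerical robustness the Lambert argument is handled in log space; when
its logarithm exceeds 500 (steep responses visited transiently during
optimization), `W` is evaluated by Newton iteration on
`w + log w = log x`, which is accurate to machine precision in that
regime.

The differential counterpart is the population dynamic model

    dN/dt = − a N P / (1 + a h N),

integrated with LSODA (rtol 1e-8, atol 1e-10; the high-attack-rate
scenarios are locally stiff as `N → 0`).  For `P = 1` the eaten total
`N0 − N(T)` equals the Lambert-W solution exactly; the test suite
asserts agreement to `1e-6·N0` over random parameter draws, which is
the package's central internal consistency check.  Positivity of `N` is
preserved by the dynamics (the right-hand side vanishes at `N = 0`),
never by clipping.

Type III and generalized forms replace the constant attack rate with a
density-dependent coefficient `a(N0) = b N0^q`, evaluated at the initial
density and substituted into the same non-replacement integral (`q = 1`
fixed for the Hassell form; `q` free in the generalized form; `q = 0`
recovers type II).  Evaluating `a(N)` at `N0` rather than tracking it
along the depletion trajectory is the common convention for fitting
sigmoid responses to non-replacement data; it nests type II exactly and
keeps the Lambert-W solution applicable.

## Estimation

**Classification.**  Binomial GLMs with logit links model the proportion
of prey eaten as a function of prey density.  A significantly negative
first-order term (linear model) indicates type II; a significantly
positive first-order term followed by a significantly negative
second-order term (quadratic model) indicates type III.  When neither
sign pattern is significant the result is labelled `equivocal` and an
AIC table across the fitted type II / Hassell / generalized forms is
attached, with the arbitrated choice preferring the simpler type II form
unless a sigmoid form improves AIC by more than 2.  All significance
thresholds default to α = 0.05.  All-zero consumption is reported as
`undeterminable`, not raised.

**Likelihood.**  Each trial contributes a binomial term with `N0`
exposures and success probability `p = Ne_expected / N0`, the Rogers
expectation clamped to `[1e-9, 1 − 1e-9]`.  The binomial likelihood is
exactly the generating process of the synthetic data's default noise
model, so parameter recovery is a well-specified check.  Parameters are
optimized on the log scale (enforcing positivity) by Nelder–Mead from a
3×3 multi-start grid (`a ∈ {0.1, 1, 5}` × `h ∈ {0.001, 0.05, 0.3}`),
keeping the best likelihood; the optimum is verified in the tests
against an exhaustive grid search.  Standard errors come from the
observed information (numerical Hessian on the natural scale); a
singular Hessian flags the fit and leaves the SEs NaN rather than
inventing values.  Datasets with zero total consumption return the
boundary fit `a = 0`, flagged.

**Bootstrap.**  Uncertainty per experimental group is non-parametric:
trials are resampled with replacement stratified by density (each
density stratum keeps its replicate count), refit, and the draws floored
at 0; 20 draws per group by default, with the count exposed for
diagnostic use.  Refits start from the full-data point estimate — the
resamples perturb the data mildly, so the point estimate is the relevant
basin, and this keeps 20 refits per group cheap.  Whether the original
study resampled trials, residuals or simulated parametrically is not
documented; trial resampling is the most assumption-free choice.

**Cross-group comparison.**  Bootstrapped draws are compared across
species × predator size × prey size with a Gamma GLM (log link — stable
for strictly positive right-skewed draws) and F-tests via analysis of
deviance with type III sums of squares (each term dropped from the full
model in turn, Pearson-χ² dispersion).  The Gamma family needs a
strictly positive response, so draws capped at exactly 0 are replaced by
the smallest positive draw; groups consisting only of zeros are excluded
with a warning.

## Body-mass-ratio scaling

Bootstrapped `a` and `h` are regressed, per predator species, on the
log10 predator–prey body-mass ratio (computed from group mean masses).
Attack rates are log10-transformed — zero draws are dropped with a
logged count, since log10(0) is undefined — and handling times are
log10(x+1)-transformed so that zero draws map to 0.  Candidate
polynomials of degree 1–3 are fit by OLS on an orthogonal (QR) basis for
numerical stability, with coefficients reported on the raw power basis;
the degree minimizing the Gaussian AICc, `AIC + 2k(k+1)/(n−k−1)`, is
selected.  The residual sum of squares is floored at round-off scale so
that a noise-free fit does not send every candidate's likelihood to
infinity; at the floor the AICc penalty alone selects the simplest
degree.  For quadratic winners with negative curvature the analytic peak
`−b1/(2 b2)` is reported; for cubic winners the interior maximum of the
fitted curve within the data range, if one exists.

## Prey-depletion bias study

The validation study asks whether depletion biases the estimator.  Prey
depletion is simulated deterministically from the population dynamic
model over durations {0.2, 0.5, 1.0, 1.5} hr and densities
{2, 4, 8, 16, 32, 64}, with `a ∈ {0.45, 1.00, 5.00}` at `h = 0.01` and
`h ∈ {0.002, 0.01, 0.30}` at `a = 1.00` (the shared intermediate setting
appears once), `P = 1` throughout.  Eaten totals are rounded
half-away-from-zero (the convention is configurable) and replicated
three times per density — identically, since the model is deterministic;
the identical replicates shrink the fitted SEs exactly as the protocol
implies.  The random predator equation is refit to each duration ×
setting cell and the estimate ± SE interval is checked for overlap with
the input value; the depletion fraction is total eaten over total
initial prey.

Two conventions for "SE overlap" are exposed via `se_multiplier`: plain
±1 SE (the library default) and ±1.96 SE (95%-style Wald intervals).
The study's qualitative conclusion — estimates overlap inputs everywhere
except the single cell with the shortest duration and largest handling
time (0.2 hr, `a = 1.00`, `h = 0.30`, where almost nothing is eaten) —
holds exactly under the ±1.96 SE convention.  Under plain ±1 SE the same
exceptional cell is flagged, plus up to three marginal misses: the
high-attack-rate cells (`a = 5`) at the shortest and longest durations
and the large-handling-time cell at 1.5 hr, all of which are within
2 SE.  The acceptance test therefore evaluates uniqueness of the
exception at ±1.96 SE and bounds the miss count at ±1 SE.

One grid cell deserves note: at `a = 5, h = 0.01`, duration 1.5 hr,
every density except 64 is fully depleted after rounding.  The binomial
likelihood then increases monotonically in `a` (its supremum is not
attained at any finite attack rate), the observed information is
singular and the Wald SE is undefined.  The convention adopted is that
an undefined SE corresponds to an unbounded Wald interval — the overlap
flag is recorded true — while the fit is flagged non-converged and never
dropped.  This mirrors the behaviour of off-the-shelf ML fitters, which
report enormous SEs from a near-singular Hessian at such cells.

## Synthetic data

The generator emulates the cage experiment: largemouth bass and bluegill
in three size classes (group mean masses 1.70/4.95/11.38 g and
1.65/5.45/12.29 g) preying on tilapia in three size classes
(0.018/0.035/0.075 g), densities {2, 4, 8, 16, 32} with 64 added for
small prey, three replicates per density, 1-hr trials, zero background
mortality (predator-free controls always show 100% survival).  Masses
are group constants, matching an analysis based on group mean masses.

Default ground truths give each group a type II response whose attack
rate follows a hump over log10 mass ratio (peak `a = 1` cage/hr at ratio
10^2.1) and whose handling time declines from ~0.3 to ~0.01 hr/prey over
the observed ratio range (≈22–683) — realistic magnitudes for small fish
in 1-hr cage trials, and the qualitative scaling structure the design
exists to detect.

Two noise models are provided.  `binomial` (default) draws
`Ne ~ Binomial(N0, Ne_expected/N0)` — exactly the estimator's likelihood,
making recovery tests clean.  `event_process` simulates a
continuous-time capture process with state-dependent rate
`a N / (1 + a h N)` and exponential waiting times, so depletion feeds
back on the rate; its mean agrees with the closed form to within 5% when
depletion is below ~50% (asserted in the tests), and it probes
robustness to a generating process the likelihood does not exactly
match.  What passing tests show is therefore estimator correctness and
calibration *under the stated model family*; real feeding data add
sources of dispersion (individual predator variation, arena effects,
prey behaviour) that neither noise model emulates.

## Problem sizes and determinism

Every stochastic stage takes an explicit seed and identical seeds give
byte-identical outputs; the bias study is entirely deterministic.  The
test suite uses the experiment's own scale (18 trials per group, 18
groups, 20 bootstrap draws) for pipeline checks, 50 synthetic groups for
the coverage check, and 10,000-replicate single-density designs for
Monte-Carlo mean checks.

## Known limitations

- The Wald (observed-information) SEs are asymptotic; at 18 trials per
  group they are approximate, which is why the bootstrap is first-class.
- Saturated designs (every prey eaten at almost all densities) have no
  finite MLE for `a`; such fits are flagged, not repaired.
- No predator interference or ratio dependence: `P` enters the depletion
  model linearly, and multi-predator trials are out of scope.
- The generalized/Hassell forms fix the density dependence at the
  initial density; responses whose shape changes within a trial are not
  representable.
- Gamma-GLM F-tests on bootstrap draws treat draws as independent
  observations, as in the original protocol; they understate uncertainty
  relative to a hierarchical treatment of the 20-draws-per-group
  structure.
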