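# Methods

## The task being modelled

`peershift` simulates and fits a *social delay-discounting task*. A
participant repeatedly chooses between a smaller amount of money now and
a larger amount after a delay. Choices identify the hyperbolic discount
rate *k* via the present value

    V = R / (1 + k·D)

with reward *R*, delay *D* in days, and *k* per day. Because discount
rates are approximately log-normal across people, all modelling happens
on the natural log of *k*. Every offer pair has an *indifference point*
ln k\* = ln((R_delayed/R_now − 1)/D): an agent with log-k below it takes
the delayed option.

The session has three phases:

1. **Self (60 trials).** 30 offers from a fixed standard set whose
   indifference points are evenly spaced over the supported log-k range,
   interleaved (even/odd trial indices) with 30 offers chosen
   adaptively.
2. **Learning about the other (20–60 trials).** The participant chooses
   on behalf of a partner and gets correct/incorrect feedback. The
   partner is a deterministic value maximizer whose log-k is displaced
   exactly one population SD from the participant's phase-1 estimate —
   toward the population mean with probability 2/3, away with 1/3. The
   phase ends at the first trial ≥ 20 at which at least 8 of the last 10
   answers were correct, or at trial 60.
3. **Post (60 trials).** Alternating mini-blocks of 10 self trials and
   10 other trials (self first, three blocks each). The *social shift*
   is log k_self(phase 3) − log k_self(phase 1); re-signed by the
   partner's direction it becomes the susceptibility measure (positive =
   moved toward the partner).

## Choice model: preference uncertainty

Agents hold a Gaussian belief N(μ, σ²) over their own log-k and *sample
a fresh value from it on every trial*, then choose deterministically by
value. Choice variability therefore reflects uncertainty about one's
own preference, not post-decision noise: the probability of choosing
the delayed option is the probit

    P(delayed) = (1 − λ)·Φ((ln k* − μ)/σ) + λ/2,

where σ is the **preference uncertainty** and λ a uniform lapse rate
(default 0; it exists so that degenerate all-one-option datasets have
finite likelihood during fitting). The Monte-Carlo sampling account and
this closed form are verified against each other in the tests.

## Adaptive design

Phase 1 maintains a discretized posterior over log-k: 200 uniform grid
points on [ln 10⁻⁴, ln 1] per day (spanning indifference horizons from
under a week to several years), uniform prior. After each choice the
posterior is updated with the probit likelihood evaluated at each grid
point with an assumed design noise σ_design = 1.0 (log-k units; the
subject's true σ is fitted later, never assumed). Adaptive trials
present the candidate pair minimizing the *expected posterior Shannon
entropy*, averaging the two possible choices under the posterior
predictive; ties break to the lowest pool index. The candidate pool is
a 7 × 40 factorial of delays {7, 14, 30, 60, 120, 180, 365} days and
amount ratios log-spaced so the pool's indifference points tile the
grid. The same machinery learns the partner's log-k in phase 2, with
the deterministic-partner step likelihood smoothed by a 0.05 lapse so
no feedback sequence has zero likelihood.

## Social update: informational conformity

Self and partner log-k are modelled as draws from a shared reference
distribution N(m, σ_ref²) around a latent common mean m with a flat
hyperprior; σ_ref is the **relevance of the other**. Marginalizing m
and the partner's log-k, the phase-2 posterior N(μ_O, s_O²) over the
partner yields a predictive for one's own log-k, N(μ_O, s_O² + 2σ_ref²),
which combines with the prior preference belief N(μ, σ²) by precision
weighting. The posterior mean is μ + w·(μ_O − μ) with shift weight

    w = σ² / (σ² + 2σ_ref² + s_O²),   0 ≤ w < 1,

increasing in preference uncertainty and decreasing in σ_ref and in
s_O². This is the informational-conformity ("copy when uncertain")
mechanism: the closed form is checked against numerical double-grid
marginalization to < 10⁻³ in the posterior mean over a 125-point sweep.
The update is applied **once**, after phase 2, with the final partner
posterior; under Gaussian conjugacy a one-shot update is equivalent for
phase-3 behaviour to incremental updating, and it keeps phase 3 i.i.d.
given the updated belief. The flat hyperprior is a deliberate default;
a proper population hyperprior would add shrinkage toward the
population mean and can be emulated by treating the population as an
additional observed "partner".

Note the hierarchical-Gaussian chain here is one concrete instantiation
of the preference-coupling idea; other factorizations with the same
qualitative ordering (more uncertain → larger shift; less relevant →
smaller shift) exist.

## Fitting

Per phase of self choices, (μ, σ) is estimated by MAP on a 60 × 40 grid
(μ on the design bounds, σ log-spaced on [0.05, 5]) with weak priors
μ ~ N(population mean, 2 × population SD) and σ ~ logNormal(0, 1),
refined by Nelder–Mead in (μ, ln σ) from the grid optimum (likelihood
tolerance 10⁻⁶). The priors prevent boundary blow-ups on degenerate
subjects and can be switched off for pure MLE. Estimates whose grid
optimum sits on a search edge, or whose data contain fewer than 10
choices or only one option type, carry a boundary flag; refinement is
skipped there so degenerate fits stay pinned at the edge. Choice
probabilities are floored at 10⁻¹² in the log-likelihood for float
safety. Phase-3 log-k uses phase-3 *self* trials only.

σ_ref is then estimated by maximizing the likelihood of phase-3 self
choices under the social-update-predicted belief, on a 60-point
log-spaced grid over [0.05, 10] with bounded scalar refinement. When
the learned partner mean is within 0.1 of the subject's own fit, or the
fitted preference uncertainty is below 0.05, σ_ref carries no signal
and the estimate is flagged unidentifiable rather than reported as
meaningful.

Expected estimator quality at task size (60 trials per phase), from the
recovery pipeline: log-k correlates with truth at r ≈ 0.98; preference
uncertainty at r ≈ 0.75–0.8 (information-limited — only the handful of
standard-set offers falling within ±2σ of μ constrain σ); σ_ref is
recovered with its median within a factor of 2 of truth. Fitting is
fully deterministic given the data.

## Synthetic cohort

The generator emulates the developmental structure the analyses need,
with defaults chosen once to be typical of the discounting literature
and to give a 300-subject cohort clear qualitative signal; none are
estimates from any empirical sample:

| parameter | default | meaning |
|---|---|---|
| ages | Uniform(14.10, 24.99) y | cross-sectional adolescent range |
| log-k | N(ln 0.01, 1.5²) | population discount-rate distribution |
| σ_pref | softplus(2.2 − 0.095·age + ε), ε ~ N(0, 0.3²) | ≈ 1.2 at 14 y, ≈ 0.65 at 25 y |
| σ_ref | logN(ln 0.7, 0.3²) | relevance of the other |
| follow-up | N(1.48, 0.30²) y, truncated [0.98, 2.62] | T1 → T2 interval |
| decline | 0.08 + 0.03·(25 − age) per year (softplus-argument units) | within-person uncertainty decline, steeper when younger |

The softplus link keeps every width positive; the decline acts on the
softplus argument, so every subject's uncertainty strictly decreases
between sessions and younger subjects decline faster. The decline
magnitudes were fixed by a pilot power check so that the three
qualitative signs below are detected reliably at n = 300. An optional
retest fraction gives a subsample a third, ~6-month, session. Partners
are re-assigned at every timepoint from that timepoint's own phase-1
estimate.

What the generator does **not** emulate: age-dependent lapse rates or
model misfit (real younger participants are fit less well than this
generative model implies), discount-rate drift with age, attrition,
session-order or practice effects, questionnaire and neural variables.
Passing the end-to-end tests therefore shows the pipeline recovers the
structure *it* generates — a self-consistency and power statement, not
evidence about any empirical cohort.

## Analysis stages

The shift table has one row per subject × timepoint; rows with boundary
flags are excluded from correlations by default (listwise deletion, no
imputation). Correlations are Pearson r with seeded percentile
bootstrap CIs (2000 resamples default). The mediation stage
(age → preference uncertainty → susceptibility) is the
product-of-coefficients decomposition: OLS paths a, b, c, c′, indirect
effect a·b, proportion mediated a·b/c, all bootstrapped over subjects.
This is deliberately *not* an SEM estimator with robust standard
errors; published standardized coefficients from real cohorts are not
comparison targets for it. The proportion mediated is reported missing
when the total effect is numerically zero.

## Numerical choices and degenerate inputs

- Natural logarithms everywhere (beliefs, grids, shifts).
- Exact indifference ties: a simulated *subject* is at p = 0.5 and the
  Bernoulli draw decides; the deterministic *partner* (and the phase-2
  learner policy) take the delayed option at exact indifference.
- Grid posteriors must stay normalized to 1 within 10⁻¹⁰; a zero total
  likelihood (possible only with a noiseless, lapse-free likelihood)
  raises rather than silently renormalizing.
- Offer amounts are rounded to 2 decimals (currency); standard-set
  indifference targets are kept 1% inside the grid bounds so rounding
  cannot push them outside.
- `relative_shift = shift / log k_phase1` inherits the sign of its
  (typically negative) denominator — documented, not "fixed".

## Problem sizes

Default analysis scales — 200 subjects for parameter recovery, 300
subjects × 2 timepoints for the end-to-end cohort, 10⁵ draws for the
sampling-equivalence check, 125-point sweeps for the closed-form
oracle — are the package's standard desk-scale settings: large enough
that the qualitative effects are stable across seeds, small enough to
run on a laptop in minutes.

## Known limitations

- σ_pref recovery is bounded near r ≈ 0.8 by task information, not by
  the optimizer; longer sessions or σ-targeted adaptive designs would
  be needed to do better.
- σ_ref is weakly identified in single sessions (it enters only through
  the scalar shift weight) and is biased low when the true shift is
  small; only its order of magnitude should be interpreted.
- The cohort's qualitative findings are sign reproductions on synthetic
  data; effect magnitudes are artifacts of the generator defaults.
- The one-shot social update ignores any within-phase-3 dynamics of
  preference change.
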