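# Methods

## Model

Disease progression is a continuous-time Markov chain over four states,
WELL → NSTEMI → STEMI → DEAD, with only forward transitions (six in all:
the three out of WELL, two out of NSTEMI, one out of STEMI). DEAD is
absorbing. Each intensity is log-linear in three covariates,

    log q_l = β0_l + β1_l (Age − 67) + β2_l Sex + β3_l Indigenous ,

with sex coded male = 1 and ethnicity Indigenous = 1, so intercepts are
per-year log intensities for a 67-year-old non-Indigenous woman. Age is
integer-valued and advances only at whole years since baseline, making the
intensities piecewise-constant within a year; all interval transition
probabilities are matrix exponentials `P(Δt) = exp(ΔtQ)` with Q rebuilt at
each interval's start age. All six transitions carry all three covariates;
the model makes no sparsity assumption about which transitions an effect
may touch.

Observed states are emitted from true states through a row-stochastic
misclassification matrix with exactly four error channels — WELL↔NSTEMI in
both directions and NSTEMI↔STEMI in both directions. There is no
WELL↔STEMI channel (a two-step clinical error) and death is recorded
without error. Each error probability is constrained to [0, 0.5); the
upper bound is the standard label-switching guard that keeps the "true"
state labels identified. At the zero boundary the model degenerates to an
ordinary fully observed panel Markov model, which the code supports both
in the likelihood and as a fitting mode (`fix_emissions`).

## Cohort construction

Admission records enter as long-format CSV rows (patient, ISO date,
primary ICD-10 code, age, sex, Indigenous status, first-ever flag, death
date). I21.4 codes NSTEMI; I21.0–I21.3 code STEMI; I21.9/I21.A are
"unspecified MI" and are dropped as events (a year containing only such
admissions is treated as a censored year; such years before the first
usable observation are dropped, since a series must open with an observed
state). Any other code is the WELL state — absence of MI, not good health.

Filters, in order: records with unparseable or missing fields are rejected
and counted; patients whose first-ever admission predates the study window
(input flag) are dropped; patients whose index admission's primary
diagnosis is not ICD-10 chapter IX are dropped; and by default only
patients with at least one NSTEMI/STEMI admission are kept. Admissions are
then annualized — one observation per calendar year, the most severe state
seen that year winning (the forward-only model cannot represent a
within-year improvement, so severity resolution keeps the series
consistent) — and gap years receive censored rows.

Two timing conventions matter:

* **Death** is kept at its exact (fractional-year) time and contributes the
  transition-then-instantaneous-jump density
  `Σ_i α_i Σ_j P(Δt)[i,j] q_{j,DEAD}`; an interval-censored alternative
  (`death_mode="interval"`) treats death as known only to fall inside the
  interval. Exact is the default: registry death dates are day-resolved.
* **Censored rows** are inserted at every integer year strictly between two
  consecutive rows, counting the death row as a row. The patient is
  provably alive at whole years before the death time, and the convention
  keeps every likelihood interval at most one year long, so yearly age
  updates never straddle an interval.

The baseline observed state is conditioned on as the true state (delayed
enrolment is handled by starting the process at the first hospitalization
rather than at disease onset). An optional mode applies the emission
matrix at baseline too, starting from a uniform prior over live states;
it is off by default and exists for sensitivity analysis.

## Likelihood

A standard scaled forward recursion over the three live states, with the
per-interval weights: emission column for observed rows, ones for censored
rows, and the death density above for the death row. Per-step
renormalization with an accumulated log scale prevents underflow. An
observation sequence that is impossible under the forward-only structure
returns −∞ rather than raising.

The production path packs the cohort into flat arrays, deduplicates
(age, sex, ethnicity, Δt) profiles so each distinct profile costs one
matrix exponential, and runs in a numba-compiled kernel (~0.6 ms per
evaluation at 2000 patients). The matrix exponential inside the kernel is
scaling-and-squaring with a degree-16 Taylor series after bringing the
norm below 0.25 — for these 4×4 generators the truncation error is far
below double precision; it is pinned against `scipy.linalg.expm` at 1e-12
in the tests, and the public `transition_probability` uses scipy directly.
A plain numpy reference implementation (`series_loglik`) and a brute-force
hidden-path enumeration oracle (tests) provide two independent routes the
kernel must agree with at 1e-10.

## Priors and sampler

* Death-transition intercepts: Normal(log 0.0065, 0.5). Hospital
  registries miss deaths that occur before any admission, biasing death
  intensities downward; anchoring the three death intercepts to a
  population crude death rate (0.0065/year is a documented Australian
  magnitude; it is a configurable argument, not a constant) pulls them
  toward population-consistent values.
* Other intercepts: Normal(0, 10); covariate effects: Normal(0, 2);
  logit(e_k): Normal(−4, 2), centering the error channels near 2% with a
  hard truncation at e = 0.5.

Sampling is blockwise random-walk Metropolis on the unconstrained scale
(β as-is, e on the logit scale): one block per transition (its four
coefficients) plus one emission block. During burn-in each block adapts
its scalar step size toward 30% acceptance every 25 iterations and
re-estimates its proposal covariance from the accumulated chain history
every 200 iterations (Haario-style); both are frozen at the end of
burn-in, so the post-burn-in chain is a valid Markov chain. The
covariance adaptation is essential: a transition's intercept and its
covariate effects are strongly correlated a posteriori, and isotropic
proposals mix more than an order of magnitude more slowly along those
ridges (effective sample sizes of ~5 versus ~500 at equal cost in our
n = 2000 experiments). Chains start from crude data-based rates (event
counts over exposure) with covariate effects at zero and emissions at 2%.
Defaults are 4 chains × 20,000 iterations with 50% burn-in; the seed is
mandatory and all randomness flows from it. Posterior summaries are
pooled post-burn-in means and equal-tailed 95% intervals; effective sample
sizes come from arviz.

## Synthetic-data generator

The generator reads the model generatively and adds a minimal observation
mechanism. Study conditions (defaults): six annual waves starting 2010;
baseline age ~ Normal(67, 12) truncated to [18, 100] and integerized;
60% male (a typical MI-cohort split; the source cohort's split is not
published); 3.9% Indigenous; baseline state drawn as (WELL, NSTEMI, STEMI)
= (0.60, 0.28, 0.12); true parameters of published magnitude (female
non-Indigenous rates 8.46/1.29/2.82/2.42/5.08/4.64 %/year, the
corresponding male and Indigenous rate ratios, age relative risks of
1.5%/year for STEMI entry and 3%/year for death transitions, emissions
0.011/0.037/0.015/0.027). Each live year after baseline produces an
admission with probability 0.7 (gap probability 0.3 exercises the
censored-row machinery; the real admission process is unmodelled, and a
Bernoulli gap is the minimal stand-in). Observed states pass through the
emission matrix and map to codes (NSTEMI → I21.4, STEMI → a random
I21.0–I21.3, WELL → a random non-MI cardiac code); deaths emit exact
dates. The baseline observation is exempt from misclassification by
default so the generator matches the likelihood's error-free-baseline
conditioning; a flag turns baseline misclassification on.

What the generator does **not** emulate: admission timing correlated with
disease activity (sicker patients are admitted more, not Bernoulli),
coding-practice drift over time, pre-hospital deaths (absent from records
— which is exactly why the death-rate prior exists), comorbidities, and
I21.9/I21.A usage. Passing recovery tests therefore demonstrates internal
consistency of pipeline + likelihood + sampler under the model's own
assumptions, not robustness to real-world misspecification.

## Scaled-down experiment sizes

The recovery study runs 20 replicates of n = 2000 patients × 6 waves with
single chains of 3000 iterations (50% burn-in), plus one matched n = 200
fit for the contraction check; these sizes give stable coverage behaviour
(≥80% of intercept and emission parameters inside their 95% intervals)
while keeping the whole suite inexpensive. Desk arithmetic, the
likelihood oracle (200 random series × length ≤ 5), matrix-exponential
identities (100 random generators) and simulator consistency (10⁴
trajectories) use the sizes stated in the tests.

## Numerical and design choices

* Within-year severity resolution (most severe admission wins) — the
  forward-only chain cannot move back within a year.
* Same-year admission and death: both rows are kept, the admission at its
  year index and death at its exact time (nudged one day if the dates
  coincide, to keep times strictly increasing).
* Reporting profiles fix age at the cohort mean (67) and the non-varied
  covariate at the cohort mode (male, non-Indigenous); table entries are
  `exp` of posterior-mean linear predictors, rendered to two decimals with
  full precision retained underneath.
* MI entry-risk summaries: risk(NSTEMI) = q1 (direct entry), risk(STEMI) =
  q2 + q4 (entries from WELL and NSTEMI). The prevalence corrections are
  flow accounting over the four error channels: ΔNSTEMI = (e2+e3) −
  (e1+e4), ΔSTEMI = e4 − e3, with ΔNSTEMI + ΔSTEMI = e2 − e1 identically.
* Chi-square tests on descriptive tables use the uncorrected Pearson
  statistic; the unit of analysis is the person-year observation (death
  rows count once, censored rows not at all). Age bands are <55, 55–64,
  65–74, 75+, and direct age standardization uses the pooled cohort age
  distribution as the internal standard.
* The proposal covariance floor (1e-8 jitter), the overflow guard on the
  log-intensity linear predictor (>50 rejects the point), and the e = 0
  boundary (allowed in the likelihood, excluded from the sampled support)
  are the only numerical guards.

## Known limitations

* Ascertainment: the ≥1-MI cohort filter conditions on an outcome;
  fitting a filtered cohort against generator truth would be biased, so
  recovery experiments fit the unfiltered simulated cohort
  (`require_mi=False`). For real use the filter defines the target
  population and the estimands are conditional on it.
* Weakly identified directions (notably ethnicity effects with ~4%
  Indigenous patients, and the NSTEMI→STEMI intensity, which competes with
  the e3/e4 error channels) are prior-influenced at moderate n; their
  wide credible sets are the honest output.
* Yearly piecewise-constant age means a death interval's intensity is
  evaluated at the interval's start age.
* No smoothing/decoding (backward algorithm, Viterbi) and no model
  comparison machinery are provided.
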