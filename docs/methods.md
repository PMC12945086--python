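# Methods

## The recommender

Each behavior is an independent arm of a beta–Bernoulli bandit with counters
*N* (times selected and reviewed) and *a* (times performed). The posterior of
the completion probability under the uniform Beta(1, 1) prior is
Beta(a + 1, N − a + 1); an evening's suggestion list is one fresh Thompson
draw per arm, sorted descending. Key behavioral consequences: with little
data the ranking is near-random (exploration); as reviews accumulate the
posterior concentrates at a/N and reliably completed behaviors dominate the
top (exploitation). Convergence has a user-visible flip side — the top of the
list stops changing — which `suggestion_diversity` quantifies as the count of
distinct arms entering the top 3 over a window of days.

Design choices that the problem statement leaves open, fixed here:

- **Counter timing.** N and a change only when a review is recorded. A
  selection whose review never happens does not touch the posterior;
  incrementing N at selection time would penalise behaviors for missing
  review days rather than for non-completion.
- **Ad-hoc extras.** By default a behavior logged at review time without
  having been selected does not update its arm, because N counts *selections*.
  `UpdatePolicy(include_extras=True)` instead counts an extra as
  selected-and-completed, for deployments that read the counters as
  "opportunities observed".
- **Tie-breaking.** Equal sampled scores (a measure-zero event, but bit-exact
  reproducibility requires a rule) order lexicographically by arm id.
- **Randomness.** A user's stream is defined by a seed plus a draw counter;
  ranking call *i* uses `default_rng([seed, i])`. This makes ranking sequences
  bit-reproducible and makes serialized state (JSON: counters + seed +
  counter) lossless without persisting raw bit-generator state.
- **Catalog display.** The full catalog is always ranked; top-K truncation is
  presentation, left to callers.

## The event model

A study log is JSON Lines: a header with per-user metadata (timezone, bandit
seed, baseline covariates) followed by `set`, `review`, `mood`, and `weight`
events with ISO-8601 timestamps. Pairing matches each review to the most
recent prior set event of the same user with a gap strictly inside
(12 h, 36 h); pairing is one-to-one, the earlier review claims a contested
set, and everything unmatched is counted in a drop report rather than raised.
The daily outcome Y is the number of preselected behaviors performed plus the
number of extras. Mood is nine 0–100 visual-analog items scored into
depression, anxiety and positive-affect subscales as the mean of three
assigned items divided by 100; the item→subscale assignment is configuration
(default: items 1–3, 4–6, 7–9 respectively) since instruments vary, and
positive affect is never reverse-scored. Weight covariates at a review are
the change of the latest strictly-prior observation from the user's first
observation and from the immediately preceding observation; records lacking a
prior weight are left missing and excluded complete-case by the model fit (no
imputation). Use rate is 100 × distinct local calendar days with a review /
scheduled days (default 28, per-user configurable; calendar days follow the
user's header timezone, default UTC).

## The cohort simulator

`simulate_cohort` plays the whole daily loop so that every downstream rule is
exercised by data with the study's structure: 20 participants × 28 days by
default, a 10-item catalog, evening Thompson ranking and selection, a review
23.5 h later (inside the strict pairing window), morning mood and weight.
What it emulates and how, with defaults and the reasoning behind the free
choices:

- **Latent achievability.** Per-behavior completion probabilities p_k are
  drawn from Beta(2, 2) per user (mean 0.5, broad) unless fixed explicitly.
  No achievability distribution is reported for real cohorts; this choice is
  deliberately uninformative and is the single most consequential free
  parameter of the simulator.
- **Mood dynamics.** Each subscale follows a clamped AR(1) on [0, 1] —
  means 0.30 (depression), 0.30 (anxiety), 0.55 (positive affect),
  autocorrelation 0.6, innovation SD 0.10 — the minimal temporally-correlated
  model; item-level scatter around 100 × subscale uses SD 10 on the 0–100
  scale.
- **Mood→behavior coupling.** Completion of behavior k on day t is Bernoulli
  with logit(p) = logit(p_k) − 1.5 × depression_t. The logit link keeps
  probabilities valid; the magnitude is chosen to produce a clearly negative
  depression→behavior association at cohort scale without degenerate
  all-or-nothing days.
- **Selection attention.** The simulated user selects the item at display
  rank r with probability 0.65^(r−1) (always at least the top item),
  a geometric attention model giving ≈3 selections per evening.
- **Missingness.** Reviews are omitted independently with probability 0.05,
  which places simulated mean use rates in the 90–100% band that feasibility
  benchmarks for this kind of app target. Skipped reviews leave bandit
  counters untouched.
- **Weight.** Baseline ~ N(93.6, 15²) kg floored at 40, drift −0.02 kg/day,
  observation noise SD 0.3 kg. Linear-drift-plus-noise only; clinical realism
  of weight trajectories is out of scope.
- **Comorbidity.** Psychiatric comorbidity is Bernoulli(0.3) per participant,
  matching the rough prevalence such cohorts report.

What the simulator does *not* emulate: behavior-specific effects of anxiety
or positive affect, weight feedback on mood or behavior, weekly periodicity,
dropout (missingness is independent), user-created behaviors appearing
mid-study, and diet/activity questionnaire internals (their scores enter as
exogenous numbers). Passing tests on simulated cohorts therefore validates
the machinery — parsing, pairing, scoring, fitting — under the study's
design, not the clinical findings themselves.

`generate_lmm_dataset` is a second, separate generator that produces Y
*directly* from the two-level equations (defaults: γ00 = 4.45, γ10 = −1.88,
γ11 = 1.59; SD(ζ0) = 2.0, SD(ζ1) = 1.0, SD(ε) = 1.5; Depression ~ Beta(2, 5),
psychiatric comorbidity Bernoulli(0.3); 20 users × 22 observations, mirroring
the ~432-record scale of a 20 × 28 study after pairing losses). ζ0 and ζ1 are
drawn independently; the fit estimates their correlation as a free parameter.
Having both generators keeps the recovery test exact for the model being
fitted while the mechanistic generator stress-tests the full pipeline.

## The statistics

- **Wilcoxon signed rank.** Two-sided, zero differences dropped (reported as
  reduced n_effective), all-zero input degenerates to a flagged p = 1. The
  exact path computes the null distribution of W+ conditional on the observed
  midranks by subset-sum convolution on a doubled integer scale — identical
  to enumerating all 2^n sign assignments, which the tests do literally as an
  oracle — and is used for n ≤ 25 without ties (always under `mode="exact"`,
  where it also handles ties). Otherwise a normal approximation with
  continuity and tie corrections is used, cross-checked against scipy on
  tie-free data.
- **Mixed model.** statsmodels MixedLM, maximum likelihood (not REML) so AIC
  is comparable across fixed-effect structures; AIC = −2 logL + 2k with k
  counting fixed effects, free random-effect (co)variances, and the residual
  variance. Wald 95% CIs. Rows are pre-sorted on all model columns so the fit
  is invariant to input row order. Optimizers fall back lbfgs → powell → nm;
  a boundary (zero-variance) estimate is reported as a converged fit with a
  zero variance component, while optimizer failure or an inestimable
  structure (fewer than 2 participants with random effects requested) clears
  the convergence flag. Rank-deficient designs raise an error naming the
  collinear columns.
- **AIC selection.** Exhaustive enumeration over subsets of the candidate
  level-1 and level-2 sets, subsets of candidate cross-level interactions
  whose main effects are included, and candidate random-effect structures
  (a random depression slope requires the depression fixed effect). Ties
  break by fewer parameters, then lexicographically on the model formula.
  The default interaction candidate list contains only
  depression × psychiatric-comorbidity to keep the default search in the
  hundreds of fits; pass more pairs for a wider search.
- **Recovery harness.** Repeatedly generate → fit → collect bias, RMSE and
  95% CI coverage per fixed effect; non-converged replicates are excluded and
  counted. Noise-free recovery checks use a fixed-effects-only specification,
  because with all variance components at zero the mixed likelihood is
  degenerate while the fixed effects are exactly identified.

## Numerical notes

- Posterior checks compare (a + 1)/(N + 2) against trapezoid integration of
  θ^a(1 − θ)^(N−a) on a 100 001-point grid (worst error ~8 × 10⁻¹⁰ over all
  N ≤ 50), and sampling against numerically integrated CDFs — never against
  the same beta formulas the implementation uses.
- Problem sizes in the test and acceptance runs — 500 bandit replicates × 200
  rounds, 200 recovery replicates at 20 × 22, 10⁵ posterior draws — were
  chosen to put Monte-Carlo error well inside the asserted tolerances while
  keeping a full run in tens of seconds.
- Medians use the midpoint convention for even-length samples; SD of a
  single-participant sample is reported as undefined rather than zero.

## Known limitations

- The bandit treats arms as independent: it cannot share strength across
  similar behaviors, consider clinical benefit, or retire mastered items —
  the monotony metric exists precisely to make that last effect measurable.
- The pairing rule keeps at most one review per set event; deployments that
  allow editing a review would need an explicit amendment event type.
- MixedLM Wald CIs on variance components are not reported; only point
  estimates of the (co)variances are exposed.
- The simulator's free parameters (above) are calibration targets, not
  estimates; conclusions about real cohorts require real logs.
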