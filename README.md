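# emibandit

Thompson-sampling behavior recommendation for mobile-health behavior-change
studies — together with the event data model, feasibility metrics, synthetic
cohort simulator, and longitudinal mixed-model analysis needed to evaluate
such a recommender end to end.

## The problem

Ecological momentary interventions for obesity management ask a participant,
every evening, to pick a few small weight-loss behaviors ("walk 30 minutes",
"no late-night snack") to attempt the next day, and to review the next evening
which were actually done. Sustained engagement depends on suggesting behaviors
the person can actually achieve. This package implements the per-user
recommender that learns achievability online, and the analysis stack a
feasibility study of such an app needs.

## The model

Each behavior is an independent arm of a beta–Bernoulli bandit. For a given
user, arm *k* carries two counters: *N*, the times it was selected and
reviewed, and *a*, the times it was actually performed. Under a uniform
Beta(1, 1) prior the completion probability θ has posterior

    p(θ | a, N) ∝ θ^a (1 − θ)^(N−a)   i.e.   θ | a, N ~ Beta(a + 1, N − a + 1)

Each evening the app draws one θ per arm from its posterior and displays the
behaviors sorted by the sampled score, descending (Thompson sampling). Arms
with little data have wide posteriors and get shuffled upward at random
(exploration); well-observed, frequently completed arms dominate the top
(exploitation). Every participant has an independent model trained only on
their own reviews.

On the analysis side, daily behavior counts Y are modeled with a two-level
linear mixed-effects model,

    Level 1:  Y_ij  = Π_0i + Π_1i · Depression_ij + ε_ij
    Level 2:  Π_0i  = γ00 + ζ0_i
              Π_1i  = γ10 + γ11 · Psychiatry_i + ζ1_i

fit by maximum likelihood with structure chosen by AIC, plus exact/approximate
Wilcoxon signed-rank tests for pre/post comparisons and per-user app use rates
for feasibility.

## Worked example

Four weeks of one simulated user (`python examples/recommend_daily_behaviors.py`):

```
evening of day 28:
  walk-30min     sampled score 0.896  (N=22, a=21, posterior mean 0.92)
  no-late-snack  sampled score 0.765  (N= 8, a= 6, posterior mean 0.70)
  take-stairs    sampled score 0.715  (N=22, a=18, posterior mean 0.79)
  gym-session    sampled score 0.303  (N= 2, a= 0, posterior mean 0.25)
  cook-dinner    sampled score 0.193  (N= 2, a= 0, posterior mean 0.25)
```

The user's reliably completed behaviors (true completion probabilities 0.85
and 0.75) have risen to the top with tight posteriors; behaviors they rarely
manage have sunk, and the still-jittering sampled scores are what keeps a
little exploration alive.

The full pipeline on a synthetic cohort
(`python examples/simulate_and_analyze_cohort.py`) simulates 20 participants
for 28 days, summarises feasibility, and fits the mixed model:

```
use rate: median 92.9% (range 89.3%-100.0%), mean 94.5% (SD 3.8%); ...
analysis table: 529 paired records (outcome y = behaviors performed that day)
                              estimate     se  ci_low  ci_high      p
intercept                        1.690  0.123   1.450    1.931  0.000
depression                      -0.649  0.404  -1.442    0.143  0.108
...
```

The negative depression coefficient reflects the mechanism built into the
simulator: days with worse preceding depressive mood see fewer completed
behaviors. `examples/regret_and_monotony.py` shows the recommender's median
cumulative regret beating a uniform-random suggester by an order of magnitude,
and the week-over-week narrowing of the top-3 suggestion pool that long-term
users experience as monotony. `examples/pre_post_comparison.py` demonstrates
the exact Wilcoxon signed-rank path on paired start/end measurements.

A thin CLI wraps the same functions: `emibandit simulate | etl | feasibility |
analyze | recommend | update | recover` (see `emibandit --help`).

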