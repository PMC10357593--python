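# Methods

## The model

`ceatree` evaluates a two-strategy decision tree for one-year prevention of
adolescent depression via universal vitamin D supplementation. Each arm is a
two-level chance tree: a student is vitamin D **deficient or sufficient**
(probability depends on the arm), then **depressed or not** (probability
depends on vitamin D status). Leaves carry a one-year cost and a QALY
weight; the supplementation arm additionally carries a strategy-level
upfront cost — the per-student programme cost — incurred regardless of
outcome. The horizon is one year, so no discounting or state-transition
machinery exists anywhere in the engine.

Rollback computes, per strategy *s*,

    E[cost_s]   = upfront_s + Σ_paths P(path) · cost(leaf)
    E[effect_s] = Σ_paths P(path) · utility(leaf)

and the incremental comparison of intervention *i* against comparator *c* is

    Δcost = E[cost_i] − E[cost_c],  Δeffect = E[effect_i] − E[effect_c]
    ICER  = Δcost / Δeffect         (USD per QALY)
    NMB(λ) = λ·E[effect] − E[cost]  (λ = willingness to pay per QALY)

Dominance (Δcost < 0 and Δeffect > 0) means the intervention is preferred
at every λ ≥ 0. A dominant strategy's conventional ICER is negative;
published tables often print the magnitude |Δcost|/|Δeffect| instead, so
the engine carries both (`icer` and `paper_convention_icer`) rather than
endorsing one sign convention.

## Inputs and defaults

The bundled model (`src/ceatree/models/vitd_iran_2018.yaml`) holds the
Iranian high-school cohort inputs, all in 2018 USD and one-year QALY
weights:

| parameter | value | uncertainty | role |
|---|---|---|---|
| P(deficient), no intervention | 0.76 | fixed | probability |
| P(deficient), supplemented | 0.172 | fixed | probability |
| P(depressed \| deficient) | 0.314 | fixed | probability |
| P(depressed \| sufficient) | 0.16 | fixed | probability |
| utility, healthy | 0.760 | ±0.070, Beta | utility |
| utility, depressed | 0.545 | ±0.035, Beta | utility |
| depression management, 1 yr | 335.4 | ±35, Gamma | cost |
| supplement programme, per student | 0.604 | ±0.120, Gamma | cost |

The depressed-state utility 0.545 is the pooled (arithmetic mean) utility
of moderate (0.57) and severe (0.52) depression. The supplement cost is
the total of direct (0.354) and indirect (0.250) programme components.
The depression-management cost is treated as the one-year-horizon cost.

Two published inconsistencies are resolved in the model file itself:

- The post-supplementation status percentages (17.2% deficient, 87.2%
  sufficient) sum to 104.4%. The sufficiency branch is declared as the
  `complement` of its siblings (= 0.828), the normalization that
  reproduces the published base-case table; the raw pair is rejected by
  the validator as a normalization violation.
- The source's "exchange rate of 9.6" is read as the 2018 inflation rate;
  the effective 2018 exchange rate (≈ 42,003 Rials/USD) is implied by the
  printed pair 14,087,678 Rials ↔ 335.4 USD. The model stores final USD
  figures, so this ambiguity cannot touch results; `MoneyAdjustment`
  exposes the general base × inflation / exchange-rate transform.

## Uncertainty

Distribution parameters come from the stated mean ± SD by method of
moments: Gamma shape = m²/s², rate = m/s²; Beta α = m·k, β = (1−m)·k with
k = m(1−m)/s² − 1 (feasible only when s² < m(1−m)). The fitted analytic
moments reproduce the inputs to 1e-12 relative error (property-tested).

PSA draws each uncertain parameter once per iteration and shares the draw
across both arms (common random parameters): the utilities and the
depression cost are the same quantities in both strategies, and
independent per-arm sampling would overstate the variance of the
increments. Branch probabilities carry no stated uncertainty and are held
fixed. Defaults: 10,000 iterations (the source does not state its count;
10,000 is standard and makes the acceptability claim stable to < 0.005
across seeds), CEAC grid $0–5000/QALY in $50 steps always including the
decision thresholds $1032 and $2666, strategy-selection WTP $2666. A draw
counts as acceptable on strict inequality NMB > 0; ties are measure-zero
for continuous draws. CE-plane quadrant ties (a delta exactly zero) go to
the positive side (east/north).

## Synthetic cohorts

`ceatree.cohort` simulates individual students: supplement receipt ~
Bernoulli(adherence) in the programme arm, deficiency ~ Bernoulli(0.172 if
supplemented else 0.76), depression ~ Bernoulli(0.314 if deficient else
0.16), with base-case payoffs attached deterministically. Individual
outcomes vary (first-order uncertainty) but parameters do not: the
generator exists to validate the rollback expectations by an independent
route, while parameter (second-order) uncertainty lives in the PSA module.
Cohort means converge to the tree values at the binomial rate; tests
assert agreement within 3 standard errors at n = 10⁵.

What the generator does **not** emulate: correlation between deficiency
and other depression risk factors, seasonality of the 9-month dosing
schedule, continuous serum levels (the model consumes only the 30 ng/ml
dichotomy), or longitudinal follow-up. Passing tests therefore show the
engine's arithmetic is right under the model's assumptions, not that the
model is right about real students.

Adherence is a scenario knob only: 1.0 reproduces the idealized decision
model used for all headline results; 0.785 mirrors the observed national
programme uptake. Non-receivers behave like the comparator arm and are
not charged the supplement cost (whether non-adherent students incur the
cost is unstated in the source; charging only receivers is the
conservative reading and is flagged here).

## Numerical choices

- Branch probabilities must sum to 1 within 1e-9 (inputs are exact
  decimals; only accumulated float error is tolerated).
- |Δeffect| < 1e-12 QALY is treated as equivalence and the ICER left
  undefined, avoiding division blow-up on identical arms.
- `pool_utilities` interprets its inputs as the decimals their repr
  prints and averages in exact rational arithmetic with one final
  rounding, so the pooled mean of short decimals is exact (binary-float
  averaging of (0.57, 0.52) would land one ulp below 0.545).
- Golden comparisons against the published two-decimal table use ±0.02
  absolute: the table appears to truncate rather than round (rollback
  gives 92.9192 printed as "92.91", and 0.7199 printed as "0.71").
- Trees are generic (any nesting depth, ≥ 2 branches per chance node);
  rollback accepts array-valued parameters, which is how the PSA
  vectorizes 10,000 iterations into one pass.
- RNG: `numpy.random.default_rng(seed)`; parameters are sampled in sorted
  name order from a single generator, making runs bit-reproducible.

## Problem sizes

Deterministic results are instant. Default stochastic sizes — 10,000 PSA
iterations, 10⁵-student oracle cohorts — run in well under a minute on one
CPU and give Monte Carlo error comfortably below every tolerance used in
the tests (binomial SE ≈ 0.0014 on the depression rate at n = 10⁵; CEAC
acceptability spread ≤ 0.005 across 20 seeds at 10,000 iterations).

## Known limitations

- Exactly two strategies per comparison; no efficiency frontier for ≥ 3.
- No EVPI, no one-way/tornado deterministic sensitivity analysis.
- No Markov cycles or discounting (one-year horizon by design).
- The cost/inflation machinery takes an explicit factor; there is no
  inflation-series database.
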