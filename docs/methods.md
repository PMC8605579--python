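# Methods

## Model and assumptions

A center offers `m` examination sets over `n` resources, linked by the
binary incidence matrix `V` (every set uses at least one resource — a set
using none would have an unbounded booking limit and is rejected at
configuration time). Booking limits `N_j` are chosen per set; overage is
counted per resource against the ideal consumer level `K_i` and capped in
expectation by the search-space constraint `Σ_j V_ij N_j ≤ K_i + U_i`.

Bookings cancel late independently, each with its own probability `r_jk`.
Independence is a modelling assumption, not a fact about group bookings:
members of a group plausibly cancel together, which would fatten the tails
of the show-up distribution. The cluster model captures the *marginal*
rate difference of group bookings but not their correlation; this is the
main known gap between the model and the process it idealizes.

Demand is assumed saturated — every open slot is booked — which matches a
center whose slots are reserved months ahead. A stochastic-demand mode
(Poisson daily requests per set, truncated at the limit) exists for
robustness studies and is not used in any default.

## Show-up distributions

`X_j`, the number of non-cancelled bookings of set `j`, is Poisson-binomial.
`exact_pmf` computes it by the standard O(N²) dynamic-programming
convolution, which is mathematically identical to enumerating all `2^N`
cancellation patterns (the tests verify this equivalence up to N = 12, and
the closed-form binomial special case to 1e-12). The pmf is renormalized at
the end to absorb accumulated floating-point drift; entries are nonnegative
and sum to 1 within 1e-9 by contract.

`monte_carlo_pmf` implements the operational definition — draw one uniform
per booking per iteration in a fixed booking order, a booking shows iff its
uniform is at least `r_jk` — in batches (default 10,000) on a seeded
generator. "Convergence" is operationalized as: stop when the maximum
absolute change of any pmf entry between successive cumulative estimates
falls below `tolerance` (default 1e-4), or at `max_iterations` (default
1e6). Runs are bit-reproducible given the seed. The exact DP is the default
everywhere; the Monte-Carlo route is kept as an independent cross-check and
for the definition's sake.

## Overage costs

Marginal costs for overage units 1..Z0 (default Z0 = 10:
2,500 ×3, 5,000 ×3, 10,000 ×3, 20,000 NTD) must be positive and
nondecreasing, making the cumulative cost strictly increasing and convex in
the integer sense. Beyond Z0 the cumulative cost is extended by a
zero-intercept quadratic `y = a·z + b·z²` least-squares fitted to the ten
cumulative points; on the default table `a ≈ 18.80`, `b ≈ 682.73`, giving
82,817 NTD at z = 11 and 98,539 NTD at z = 12. (A published figure of
82,871 NTD at z = 11 is inconsistent with its own fitted curve — almost
certainly a digit transposition of 82,817 — and is documented here rather
than targeted.)

The table is authoritative for `z ≤ Z0` and the curve is used only for
`z > Z0`, even though the two disagree at the boundary (72,500 vs ≈68,461):
the curve is an extrapolation device, not a smoother, so the discontinuity
is deliberate. Extrapolated values are rounded to whole NTD. Cost
multipliers (sensitivity analysis) scale the marginal table and refit the
extrapolation, preserving the structure. One schedule is shared by all
resources by default, with per-resource overrides allowed.

## Expected net reward

The defining expectation weights `π(x)` over the joint support
`Π_j {0..N_j}`. Because the cost term depends on `x` only through the
per-resource loads, the package evaluates the mathematically identical
decomposition

```
E[π] = Σ_j P_j E[X_j] − Σ_i E[ f_i(L_i − K_i) ],   L_i = Σ_{j: V_ij=1} X_j,
```

with each load pmf obtained by convolving the independent per-set pmfs.
This is exact up to floating point and turns a product-space sum into a few
convolutions of short vectors, which is what makes complete search
affordable (the case-study overbooking space has 15,466 feasible
combinations; a search takes seconds). A brute-force joint-support
enumerator lives in the test suite as the independent oracle. Revenue terms
start at `x_j = 0`; zero-show terms contribute no revenue but their
probability mass must weight the cost term, so the full support is always
used.

The expected overage percentage attached to each evaluated combination is
the ratio of expectations `E[Σ_i overage_i] / E[Σ_j X_j]` (0 when no
consumer is expected) — a deterministic quantity suitable for Pareto
screening, as opposed to the simulated weekly ratio described below.

## Search

Enumeration of the feasible region is depth-first in lexicographic order
with running-load pruning; ties in the maximizer are broken toward the
lexicographically smallest combination, so results are order-invariant and
reproducible. The greedy search starts from the all-zero combination by
default (any feasible start is accepted, e.g. the center's original
limits), adds one unit to the set whose increment raises `E[π]` most (ties
to the lower set index), and stops when no feasible increment improves. It
can stall at a local optimum; when a complete-search result is supplied the
optimality gap is computed and reported rather than assumed zero.

Under the OC policy the hypothetical future bookings of a set are assigned
cluster rates in proportion to the season's within-cluster booking shares,
using largest-remainder apportionment over the model's cluster order (ties
by lower row index). Optimization is run once per season.

## Probability estimation

The staged logistic screen enters literature-suggested variables and
exploratory variables together, removes factors whose most significant
level has `p ≥ alpha` (default 0.05), then offers untested variables and
keeps the significant ones. Dummy coding uses the modal level as reference;
coefficients therefore measure risk relative to the most common group.
Factors can be force-included (the holiday flag hovers near the threshold
at realistic sizes). Perfect separation and non-convergence raise an
estimation error naming the variables involved.

Clustering cross-products the retained categorical factors, excluding any
factor whose minority level has fewer than `min_count` records (default
100 — chosen so that levels of a few dozen records, like last-minute
bookings, are excluded while levels of several hundred are kept). Empty
clusters fall back to the uniform rate. The booking-weighted mean of
cluster rates equals the uniform rate identically, a conservation property
the tests assert.

Continuous variables are factorized before regression and clustering: age
into [45, 70] versus outside (inclusive bounds), lead time at ≤ 7 days
(last-minute), months into winter {Nov, Dec, Jan}, summer {Aug, Sep} and
off-peak. The month grouping is configurable (`make_season_map`) and a
utility refits the model under alternative groupings, reporting residual
deviance and AIC; deviance is this package's criterion for "explains best",
a choice among reasonable alternatives.

Dates: the late-cancellation window and the last-minute boundary are both
inclusive 7-day differences; lead time is the plain day difference. A
booking with no cancellation record that is marked absent (`no_show`)
counts as a late cancellation. Rescheduling is treated as cancellation plus
re-booking: a reservation with N reschedule events becomes N+1 bookings,
the k-th cancelled on the k-th request date and the (k+1)-th booked that
same day; a missing request date is imputed as the calendar midpoint
(floored to a whole day) of the previous booking date and the new
examination date.

## Discrete-event evaluation

Each simulated day fills every set's limit, draws a cluster for each
accepted booking from the season's cluster mix, cancels it with the
cluster's rate, and books revenue and per-resource overage costs; days
aggregate into weeks (default 50 weeks of 5 operating days — the number of
operating days is an explicit parameter, and no weekly magnitude should be
read as reproducible across centers since it scales with both the unknown
prices and the day count). The true cancellation process is the cluster
model for *all* policies, including those whose limits were optimized under
the uniform rate; that asymmetry is the point of the comparison. Weekly
overage percentage is the week's total overage across resources divided by
consumers served (per-resource levels are retained in the output).
Pairwise policy differences use the Tukey HSD studentized-range procedure
on weekly net rewards.

Sensitivity analysis has two modes: `reoptimize` re-runs the search under
each scaled cost schedule (how the optimum reacts to costs known to be
higher), and `underestimate` keeps the multiplier-1 limits and re-evaluates
them under the scaled true costs (how a decision maker who underestimated
costs actually fares). A Pareto-efficient combination is one that no other
combination beats simultaneously in expected net reward (strictly higher)
and expected overage percentage (strictly lower); the frontier and the best
combination under an overage-percentage bound are reported from the
complete-search evaluation list.

## Synthetic data

The generator emulates, per seed and exactly by construction: the
12-cluster design (cluster sizes default to the published booking counts,
so season, group and age-interval margins are exact), cluster-level
late-cancellation rates (labels are Bernoulli draws at the cluster rate),
the aggregate set mix, and rare holiday (rate 0.008) and last-minute
(rate 47/8046) flags whose effects enter on the logit scale with
coefficients 0.5702 and 2.0522, so the regression screen can recover their
signs. Ages, examination months, group sizes and dates are sampled
consistently with the intended factor levels, so re-deriving features
reproduces each booking's cluster and re-derivation is idempotent.

What it does **not** emulate: within-group cancellation correlation,
consumer-level booking histories, day-of-week structure, true price
heterogeneity within a set, and the raw reschedule-event stream (a toy
split fixture exists for the cleansing rules). Passing tests on synthetic
data therefore demonstrate that the estimators and optimizers recover the
structure the generator encodes — not that the published revenue magnitudes
(which depend on unpublished per-set prices and the centers' operating
calendar) are reproduced.

## Numerical choices and degenerate inputs

- pmf validity tolerance 1e-9; exact-vs-binomial agreement asserted at
  1e-12; expectation conservation at 1e-9.
- Largest-remainder ties and greedy-increment ties break toward the lower
  index; complete-search ties toward the lexicographically smallest
  combination.
- Empty booking list: uniform-rate estimation raises; an empty slot vector
  yields a point mass at zero shows; a zero-served simulation week reports
  overage percentage 0 with a warning.
- Currency is stored in NTD as floats and rounded only where the cost
  schedule demands it; probabilities are decimals end-to-end, rendered as
  percentages only in presentation.
- `U = fraction * K` in configuration files is floored to an integer; the
  shipped default stores explicit `U` values (18, 18, 12, 2, 1) to avoid
  rounding ambiguity.

## Limitations

Booking-limit choice is daily and static — no intra-day slot assignment,
no dynamic acceptance, no multi-center coordination, and no modelling of
interventions that would reduce cancellation rates. The greedy search
carries no optimality guarantee. Cluster rates are plug-in empirical
proportions without shrinkage; with many sparse clusters a hierarchical
estimator would be preferable. The independence assumption across bookings
(notably within group bookings) is untested against real data.
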