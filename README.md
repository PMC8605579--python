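# overbook

Booking-limit optimization for physical-examination centers that sell
bundled examination **sets** drawing on shared, capacity-limited
**resources** (gastroenteroscope, MRI, DWI, ...), under late cancellations
and no-shows.

The structural difficulty this package addresses is that booking limits are
chosen *per set* while overage — consumers beyond a resource's ideal service
level — accrues *per resource*. A binary set-resource matrix `V`
(`V[i,j] = 1` iff set `j` uses resource `i`) couples the two sides, so the
usual single-resource overbooking results do not apply.

## The model

For booking limits `N = (N_1, ..., N_m)`, let `X_j ≤ N_j` be the number of
set-`j` bookings that are not cancelled late. With per-set prices `P_j`,
ideal consumer levels `K_i` and a convex overage cost `f_i(·)`, the net
reward of a realized show-up vector `x` is

```
π(x) = Σ_j x_j P_j − Σ_i f_i( Σ_j V_ij x_j − K_i ),     f_i(z) = 0 for z ≤ 0,
```

and the center chooses `N` to maximize `E[π]` subject to
`Σ_j V_ij N_j ≤ K_i + U_i` for every resource (`U_i` = maximum allowable
overage; `U_i = 0` forbids overbooking). Each booking `k` for set `j` has
its own late-cancellation probability `r_jk`, so `X_j` is Poisson-binomial;
the package computes its pmf exactly by dynamic programming (with a seeded
Monte-Carlo estimator as an alternative route) and evaluates `E[π]` exactly
by convolving the per-set pmfs into per-resource load distributions.

Probabilities `r_jk` come from historical bookings in three flavors:

* **uniform** — one rate `r = q1/q2` for everyone (policies NO and OU);
* **regression-screened factors** — staged logistic regression keeps the
  significant ones (age in [45, 70], examination season, group booking,
  last-minute booking, holiday examination);
* **cluster rates** — the retained factors are cross-producted into
  clusters and each booking inherits its cluster's empirical rate
  (policy OC).

Optimal limits are found by complete search of the feasible region, or by a
greedy unit-increment ascent with a reported optimality gap. Policies are
compared by discrete-event simulation of weekly net rewards (Tukey HSD for
pairwise differences), cost-multiplier sensitivity analysis, and a Pareto
frontier over expected net reward versus expected overage percentage.

The center's raw data are private, so a first-class synthetic generator
reproduces the published aggregates: the 12-cluster structure with its
booking counts and late-cancellation rates, rare holiday/last-minute flags
with logit-scale effects, and the set mix. Per-set prices are unpublished;
the shipped defaults are synthetic placeholders in the published
20,000–100,000 NTD range, and no reproduced quantity depends on them.

## Worked example

```python
import overbook as ob

case = ob.default_case_study_config()   # K=(36,36,24,4,2), U=K/2, cost table

ob.overage_cost(5, case.schedule)       # 17500.0  (3x2500 + 2x5000 NTD)
ob.overage_cost(12, case.schedule)      # 98539.0  (quadratic extrapolation)

ob.estimate_probability(                # 38-year-old, alone, August exam
    {"season": "summer", "group_booking": 0, "age_interval": 0},
    case.cluster_model,
)                                       # 0.0514  (cluster rate, not 0.0334)

space = case.search_space("OC")         # RHS (54, 54, 36, 6, 3)
policy = case.policy("OC", season="winter")
result = ob.complete_search(space, policy, case.config, case.schedule)
result.optimal_limits                   # (0, 36, 3, 3)
result.expected_net_reward              # 1,340,086 NTD per day

sim = ob.SimulationConfig(weeks=50, days_per_week=5, seed=1, season="winter")
ev = ob.simulate_weeks(result.optimal_limits, case.cluster_model, sim,
                       case.config, case.schedule, policy_label="OC")
ev.mean_weekly_net_reward               # 6,703,771 NTD
ob.overage_percentage(ev).mean()        # 0.434

frontier, best = ob.pareto_frontier(result.evaluations, max_overage_pct=0.07)
best["limits"], best["expected_net_reward"]   # (0, 24, 4, 2), 1,070,126
```

The optimal limits and reward magnitudes depend on the placeholder prices;
the search-space geometry, cost schedule and cluster rates do not.

A command-line interface mirrors the pipeline:

```sh
overbook synth --out data --seed 0
overbook prep --bookings data/bookings.csv --holidays data/holidays.txt --out prepared.csv
overbook estimate --bookings prepared.csv --out model.json
overbook optimize --policy OC --model model.json --season winter --out oc.json
overbook simulate --model model.json --limits 0,36,3,3 --season winter --out run.csv
```

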