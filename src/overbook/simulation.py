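"""Discrete-event evaluation of booking policies.

A policy's optimized limits are tested under the *true* cancellation
process: per day each set's limit is filled with bookings (the center's
slots are essentially always fully reserved), every accepted booking is
assigned a cluster drawn from the season's cluster mix, and cancels late
with its cluster's rate.  Daily revenue and per-resource overage costs
aggregate into weekly net rewards; policies are compared on those weekly
rewards with the Tukey honestly-significant-difference test.

Also here: cost-multiplier sensitivity analysis (re-optimize under scaled
costs, or keep the baseline limits while the true costs are scaled — the
cost-underestimation scenario) and Pareto-frontier reporting over the
(expected net reward, expected overage percentage) plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import CenterConfig, SearchSpace, is_feasible, overage_level
from .cost_model import OverageCostSchedule, _per_resource, overage_cost
from .estimation import ClusterModel
from .optimizer import OptimizationResult, PolicySpec, complete_search

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PolicyEvaluation",
    "simulate_weeks",
    "overage_percentage",
    "compare_policies",
    "sensitivity_analysis",
    "pareto_frontier",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation design: 50 weeks by default; operating days are a choice.

    ``demand_mode`` is ``saturated`` (every slot filled, the default) or
    ``stochastic``, in which daily requests per set are Poisson with rates
    ``arrival_rates`` and acceptance is capped at the booking limit.
    """

    weeks: int = 50
    days_per_week: int = 5
    seed: int = 0
    season: str | None = None
    demand_mode: str = "saturated"
    arrival_rates: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.weeks < 1 or self.days_per_week < 1:
            raise ValueError("weeks and days_per_week must be positive")
        if self.demand_mode not in ("saturated", "stochastic"):
            raise ValueError("demand_mode must be 'saturated' or 'stochastic'")
        if self.demand_mode == "stochastic" and self.arrival_rates is None:
            raise ValueError("stochastic demand needs arrival_rates")


@dataclass(frozen=True)
class PolicyEvaluation:
    """Weekly outcomes of one policy's limits under the true process."""

    policy_label: str
    limits: tuple[int, ...]
    weekly_net_rewards: np.ndarray
    weekly_revenue: np.ndarray
    weekly_overage_costs: np.ndarray
    weekly_consumers_served: np.ndarray
    weekly_overage_levels: np.ndarray  # weeks x resources
    weekly_shows_per_set: np.ndarray  # weeks x sets

    @property
    def mean_weekly_net_reward(self) -> float:
        return float(self.weekly_net_rewards.mean())


def _true_probability_table(
    model: ClusterModel | float, season: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """(cluster shares, cluster rates) of the true cancellation process."""
    if isinstance(model, (int, float)):
        return np.array([1.0]), np.array([float(model)])
    where = {"season": season} if season is not None else {}
    sub = model.conditional(where) if where else model.table
    counts = sub["bookings"].to_numpy(dtype=float)
    if counts.sum() <= 0:
        raise ValueError("no bookings in the selected season")
    return counts / counts.sum(), sub["rate"].to_numpy(dtype=float)


def simulate_weeks(
    limits: Sequence[int],
    probability_model: ClusterModel | float,
    sim_config: SimulationConfig,
    center_config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
    policy_label: str = "",
    space: SearchSpace | None = None,
) -> PolicyEvaluation:
    """Simulate weekly net rewards of a booking-limit combination.

    ``probability_model`` is the *true* process — a cluster model (with
    ``sim_config.season`` selecting the mix) or a single uniform rate.
    Reproducible bit-for-bit given the seed.
    """
    N = np.asarray(limits, dtype=int)
    if (N < 0).any() or len(N) != center_config.n_sets:
        raise ValueError("limits must be nonnegative, one per set")
    if space is not None and not is_feasible(N, space):
        raise ValueError("limits are not feasible in the given search space")
    shares, rates = _true_probability_table(probability_model, sim_config.season)
    scheds = _per_resource(schedules, center_config.n_resources)
    rng = np.random.default_rng(sim_config.seed)
    prices = center_config.prices
    W, D = sim_config.weeks, sim_config.days_per_week

    wk_revenue = np.zeros(W)
    wk_cost = np.zeros(W)
    wk_served = np.zeros(W, dtype=int)
    wk_over = np.zeros((W, center_config.n_resources), dtype=int)
    wk_shows = np.zeros((W, center_config.n_sets), dtype=int)
    for w in range(W):
        for _ in range(D):
            shows = np.zeros(center_config.n_sets, dtype=int)
            for j, nj in enumerate(N):
                if sim_config.demand_mode == "stochastic":
                    accepted = min(int(rng.poisson(sim_config.arrival_rates[j])), nj)
                else:
                    accepted = int(nj)
                if accepted == 0:
                    continue
                clusters = rng.choice(shares.size, size=accepted, p=shares)
                cancelled = rng.random(accepted) < rates[clusters]
                shows[j] = accepted - int(cancelled.sum())
            over = overage_level(shows, center_config)
            wk_shows[w] += shows
            wk_revenue[w] += float(shows @ prices)
            wk_cost[w] += float(
                sum(overage_cost(z, s) for z, s in zip(over, scheds))
            )
            wk_served[w] += int(shows.sum())
            wk_over[w] += over
    return PolicyEvaluation(
        policy_label=policy_label,
        limits=tuple(int(n) for n in N),
        weekly_net_rewards=wk_revenue - wk_cost,
        weekly_revenue=wk_revenue,
        weekly_overage_costs=wk_cost,
        weekly_consumers_served=wk_served,
        weekly_overage_levels=wk_over,
        weekly_shows_per_set=wk_shows,
    )


def overage_percentage(evaluation: PolicyEvaluation) -> np.ndarray:
    """Weekly overage level (summed over resources) over consumers served.

    Weeks with zero consumers served report 0 with a warning.
    """
    served = evaluation.weekly_consumers_served.astype(float)
    total_over = evaluation.weekly_overage_levels.sum(axis=1).astype(float)
    zero = served == 0
    if zero.any():
        logger.warning("%d week(s) served zero consumers; ratio set to 0", zero.sum())
    out = np.zeros_like(total_over)
    np.divide(total_over, served, out=out, where=~zero)
    return out


def compare_policies(evaluations: Sequence[PolicyEvaluation]) -> pd.DataFrame:
    """Tukey HSD on weekly net rewards; one row per policy pair.

    Returns mean differences with multiplicity-adjusted p-values.  Requires
    at least two policies with equally many simulated weeks.
    """
    if len(evaluations) < 2:
        raise ValueError("need at least two policies to compare")
    lengths = {len(e.weekly_net_rewards) for e in evaluations}
    if len(lengths) != 1:
        raise ValueError("policies must have equal numbers of simulated weeks")
    groups = [e.weekly_net_rewards for e in evaluations]
    labels = [e.policy_label or f"policy{i}" for i, e in enumerate(evaluations)]
    res = stats.tukey_hsd(*groups)
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            rows.append(
                dict(
                    policy_a=labels[a],
                    policy_b=labels[b],
                    mean_difference=float(groups[a].mean() - groups[b].mean()),
                    p_value=float(res.pvalue[a, b]),
                )
            )
    return pd.DataFrame(rows)


def sensitivity_analysis(
    multipliers: Sequence[float],
    mode: str,
    policies: Mapping[str, tuple[SearchSpace, PolicySpec]],
    config: CenterConfig,
    schedule: OverageCostSchedule,
) -> pd.DataFrame:
    """Optimal limits and expected net reward as overage costs scale.

    ``reoptimize`` re-runs the complete search for each scaled schedule (how
    limits and rewards react when costs are *known* to be higher).
    ``underestimate`` keeps the limits optimized at multiplier 1 and
    re-evaluates their expected net reward under the scaled true costs (how
    a decision maker who underestimated costs actually fares).
    """
    if len(multipliers) == 0:
        raise ValueError("need at least one cost multiplier")
    if any(m < 1 for m in multipliers):
        raise ValueError("cost multipliers must be >= 1")
    if mode not in ("reoptimize", "underestimate"):
        raise ValueError("mode must be 'reoptimize' or 'underestimate'")
    baseline: dict[str, OptimizationResult] = {
        label: complete_search(space, policy, config, schedule)
        for label, (space, policy) in policies.items()
    }
    rows = []
    for mult in multipliers:
        scaled = schedule.scaled(mult)
        for label, (space, policy) in policies.items():
            if mode == "reoptimize":
                res = complete_search(space, policy, config, scaled)
                limits, reward = res.optimal_limits, res.expected_net_reward
            else:
                limits = baseline[label].optimal_limits
                from .optimizer import expected_net_reward as _enr

                reward = _enr(limits, policy, config, scaled)
            rows.append(
                dict(
                    multiplier=float(mult),
                    policy=label,
                    limits=limits,
                    expected_net_reward=float(reward),
                )
            )
    return pd.DataFrame(rows)


def pareto_frontier(
    evaluations: pd.DataFrame,
    max_overage_pct: float | None = None,
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Non-dominated combinations in (net reward up, overage percentage down).

    A combination is dominated if some other has strictly higher expected
    net reward and strictly lower expected overage percentage.  When
    ``max_overage_pct`` is given, also returns the reward-maximizing row
    among combinations within the bound (None if none qualifies).

    ``evaluations`` needs columns ``limits``, ``expected_net_reward`` and
    ``overage_pct`` (the complete-search evaluation list works directly).
    """
    if len(evaluations) == 0:
        raise ValueError("empty evaluation list")
    df = evaluations.reset_index(drop=True)
    reward = df["expected_net_reward"].to_numpy(dtype=float)
    pct = df["overage_pct"].to_numpy(dtype=float)
    order = np.argsort(-reward, kind="stable")
    dominated = np.zeros(len(df), dtype=bool)
    best_pct = np.inf  # min pct among strictly higher rewards
    i = 0
    while i < len(order):
        # process reward ties as one block so ties never dominate each other
        block = [order[i]]
        while i + 1 < len(order) and reward[order[i + 1]] == reward[order[i]]:
            i += 1
            block.append(order[i])
        for idx in block:
            if pct[idx] > best_pct:
                dominated[idx] = True
        best_pct = min(best_pct, min(pct[idx] for idx in block))
        i += 1
    frontier = df[~dominated].sort_values(
        "expected_net_reward", ascending=False, kind="stable"
    )
    constrained = None
    if max_overage_pct is not None:
        within = df[pct <= max_overage_pct]
        if len(within):
            constrained = within.loc[within["expected_net_reward"].idxmax()]
    return frontier.reset_index(drop=True), constrained
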