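"""Expected-net-reward evaluation and booking-limit optimization.

The net reward of a realized show-up vector x is revenue minus overage cost,

    pi(x) = sum_j x_j P_j - sum_i f_i(sum_j V_ij x_j - K_i),

and a booking-limit combination N is scored by E[pi] with X_j the show-up
count among its N_j accepted bookings.  Because the cost term depends on x
only through the per-resource loads, the expectation decomposes exactly:

    E[pi] = sum_j P_j E[X_j] - sum_i E[f_i(L_i - K_i)],

where the load L_i = sum_{j: V_ij=1} X_j is a sum of independent show-up
counts, so its pmf is the convolution of the per-set Poisson-binomial pmfs.
This evaluation is exact up to floating point and fast enough for complete
search over the feasible region; a greedy unit-increment ascent is provided
for larger spaces (it may stop at a local optimum — compare against the
complete search to measure the gap).

Three booking policies are supported: NO (no overbooking, U_i = 0), OU
(overbooking, one uniform cancellation rate for every slot) and OC
(overbooking, cluster-specific rates apportioned to slots in proportion to
the season's cluster mix).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import CenterConfig, SearchSpace, enumerate_search_space, is_feasible
from .cost_model import OverageCostSchedule, total_overage_cost, _per_resource, overage_cost
from .estimation import ClusterModel
from .showup import exact_pmf

__all__ = [
    "PolicySpec",
    "OptimizationResult",
    "net_reward",
    "slot_probabilities",
    "expected_net_reward",
    "complete_search",
    "greedy_search",
]


@dataclass(frozen=True)
class PolicySpec:
    """A booking policy: NO, OU or OC.

    NO and OU assume one uniform late-cancellation rate for every slot; OC
    assigns cluster rates per season.  ``season`` selects the cluster mix for
    OC (optimal limits legitimately differ by season).
    """

    kind: str
    uniform_rate: float | None = None
    cluster_model: ClusterModel | None = None
    season: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("NO", "OU", "OC"):
            raise ValueError("policy kind must be one of NO, OU, OC")
        if self.kind in ("NO", "OU"):
            if self.uniform_rate is None or not 0 <= self.uniform_rate <= 1:
                raise ValueError(f"{self.kind} policy needs a uniform rate in [0, 1]")
        else:
            if self.cluster_model is None:
                raise ValueError("OC policy needs a cluster model")
            if self.season is None:
                raise ValueError("OC policy needs a season")


def _largest_remainder(shares: np.ndarray, n: int) -> np.ndarray:
    """Apportion n slots to categories in proportion to shares."""
    quotas = shares * n
    alloc = np.floor(quotas).astype(int)
    remainder = quotas - alloc
    short = n - alloc.sum()
    if short:
        order = np.argsort(-remainder, kind="stable")  # ties: lower index first
        alloc[order[:short]] += 1
    return alloc


def slot_probabilities(
    limits: Sequence[int], policy: PolicySpec
) -> list[np.ndarray]:
    """Per-set vectors of slot late-cancellation probabilities.

    NO/OU: every slot gets the uniform rate.  OC: for the policy's season,
    each set's N_j slots are split across the season's clusters in
    proportion to within-cluster booking shares (largest-remainder rounding,
    slots ordered by cluster), and each slot gets its cluster's rate.
    """
    N = np.asarray(limits, dtype=int)
    if (N < 0).any():
        raise ValueError("booking limits must be nonnegative")
    if policy.kind in ("NO", "OU"):
        return [np.full(nj, policy.uniform_rate) for nj in N]
    sub = policy.cluster_model.conditional({"season": policy.season})
    counts = sub["bookings"].to_numpy(dtype=float)
    rates = sub["rate"].to_numpy(dtype=float)
    if counts.sum() <= 0:
        raise ValueError(f"no bookings observed in season {policy.season!r}")
    shares = counts / counts.sum()
    out = []
    for nj in N:
        alloc = _largest_remainder(shares, int(nj))
        out.append(np.repeat(rates, alloc))
    return out


def net_reward(
    shows: Sequence[int],
    config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
) -> float:
    """Realized net reward pi(x) = revenue - total overage cost."""
    x = np.asarray(shows)
    return float(x @ config.prices) - total_overage_cost(x, config, schedules)


class _Evaluator:
    """Caches per-set pmfs and per-resource cost terms across evaluations."""

    def __init__(
        self,
        policy: PolicySpec,
        config: CenterConfig,
        schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
    ):
        self.policy = policy
        self.config = config
        self.schedules = _per_resource(schedules, config.n_resources)
        self._pmfs: dict[tuple[int, int], np.ndarray] = {}
        self._means: dict[tuple[int, int], float] = {}
        self._cost: dict[tuple[int, tuple[int, ...]], tuple[float, float]] = {}
        self._ftab: list[np.ndarray] = [np.zeros(1) for _ in self.schedules]

    def _f(self, i: int, size: int) -> np.ndarray:
        """f_i(z) tabulated on 0..size-1, grown lazily."""
        tab = self._ftab[i]
        if tab.size < size:
            tab = np.array(
                [overage_cost(z, self.schedules[i]) for z in range(size)]
            )
            self._ftab[i] = tab
        return tab

    def _set_pmf(self, j: int, nj: int) -> np.ndarray:
        key = (j, nj)
        if key not in self._pmfs:
            # slot probabilities depend only on N_j, not on which set
            probs = slot_probabilities([nj], self.policy)[0]
            pmf = exact_pmf(probs).probabilities
            self._pmfs[key] = pmf
            self._means[key] = float(np.arange(pmf.size) @ pmf)
        return self._pmfs[key]

    def evaluate(self, limits: Sequence[int]) -> tuple[float, float]:
        """(expected net reward, expected overage percentage) of ``limits``.

        The expected overage percentage is E[total overage] / E[consumers
        served] (ratio of expectations), 0 when no consumer is expected.
        """
        N = tuple(int(n) for n in limits)
        prices = self.config.prices
        revenue = 0.0
        expected_shows = 0.0
        for j, nj in enumerate(N):
            self._set_pmf(j, nj)
            mean = self._means[(j, nj)]
            revenue += prices[j] * mean
            expected_shows += mean
        cost = 0.0
        expected_overage = 0.0
        V = self.config.matrix.entries
        K = self.config.ideal_levels
        for i in range(self.config.n_resources):
            sets_i = tuple(np.flatnonzero(V[i] == 1))
            if not sets_i:  # resource used by no set: never any overage
                continue
            key = (i, tuple(N[j] for j in sets_i))
            if key not in self._cost:
                load = self._set_pmf(sets_i[0], N[sets_i[0]])
                for j in sets_i[1:]:
                    load = np.convolve(load, self._set_pmf(j, N[j]))
                z = np.arange(load.size) - K[i]
                over = np.maximum(z, 0)
                fz = self._f(i, int(over.max()) + 1)[over]
                self._cost[key] = (float(load @ fz), float(load @ over))
            ci, oi = self._cost[key]
            cost += ci
            expected_overage += oi
        pct = expected_overage / expected_shows if expected_shows > 0 else 0.0
        return revenue - cost, pct


@dataclass(frozen=True)
class OptimizationResult:
    optimal_limits: tuple[int, ...]
    expected_net_reward: float
    evaluations: pd.DataFrame  # columns: limits, expected_net_reward, overage_pct
    algorithm: str
    gap_to_complete: float | None = None


def expected_net_reward(
    limits: Sequence[int],
    policy: PolicySpec,
    config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
) -> float:
    """E[pi] of one booking-limit combination (exact, see module docstring)."""
    reward, _ = _Evaluator(policy, config, schedules).evaluate(limits)
    return reward


def complete_search(
    space: SearchSpace,
    policy: PolicySpec,
    config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
    max_combinations: int = 10_000_000,
) -> OptimizationResult:
    """Evaluate every feasible combination and return the maximizer.

    Ties are broken toward the lexicographically smallest combination (the
    enumeration order).  Raises if the space exceeds ``max_combinations`` —
    use :func:`greedy_search` then.
    """
    evaluator = _Evaluator(policy, config, schedules)
    best_N: tuple[int, ...] | None = None
    best = -np.inf
    rows = []
    for count, N in enumerate(enumerate_search_space(space), start=1):
        if count > max_combinations:
            raise RuntimeError(
                f"search space exceeds {max_combinations} combinations; "
                "use greedy_search or raise max_combinations"
            )
        reward, pct = evaluator.evaluate(N)
        rows.append((N, reward, pct))
        if reward > best:  # strict: first (lexicographically smallest) wins ties
            best, best_N = reward, N
    evaluations = pd.DataFrame(
        rows, columns=["limits", "expected_net_reward", "overage_pct"]
    )
    return OptimizationResult(
        optimal_limits=best_N,
        expected_net_reward=float(best),
        evaluations=evaluations,
        algorithm="complete",
    )


def greedy_search(
    space: SearchSpace,
    policy: PolicySpec,
    config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
    start: Sequence[int] | None = None,
    complete_result: OptimizationResult | None = None,
) -> OptimizationResult:
    """Unit-increment ascent from ``start`` (default the all-zero combination).

    Each iteration scores every feasible single-set increment and applies the
    best one; ties break toward the lower set index.  Stops when no increment
    improves the expected net reward or all increments leave the space.  The
    optimality gap is reported when a complete-search result is supplied.
    """
    m = space.matrix.n_sets
    N = np.zeros(m, dtype=int) if start is None else np.asarray(start, dtype=int)
    if not is_feasible(N, space):
        raise ValueError("greedy start is not feasible")
    evaluator = _Evaluator(policy, config, schedules)
    current, pct = evaluator.evaluate(N)
    rows = [(tuple(N), current, pct)]
    while True:
        best_j, best_reward, best_pct = None, current, pct
        for j in range(m):
            candidate = N.copy()
            candidate[j] += 1
            if not is_feasible(candidate, space):
                continue
            reward, cpct = evaluator.evaluate(candidate)
            if reward > best_reward:  # strict: ties keep the lower index
                best_j, best_reward, best_pct = j, reward, cpct
        if best_j is None:
            break
        N[best_j] += 1
        current, pct = best_reward, best_pct
        rows.append((tuple(N), current, pct))
    gap = None
    if complete_result is not None:
        gap = complete_result.expected_net_reward - current
    evaluations = pd.DataFrame(
        rows, columns=["limits", "expected_net_reward", "overage_pct"]
    )
    return OptimizationResult(
        optimal_limits=tuple(int(n) for n in N),
        expected_net_reward=float(current),
        evaluations=evaluations,
        algorithm="greedy",
        gap_to_complete=gap,
    )
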