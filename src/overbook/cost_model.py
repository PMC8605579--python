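"""Piecewise-convex overage cost with quadratic extrapolation.

The center elicits marginal overtime costs for the first Z0 units of overage
(a nondecreasing schedule, so the cumulative cost is convex in the integer
sense).  Beyond the elicited range a zero-intercept quadratic
``y = a*z + b*z**2``, least-squares fitted to the cumulative points, extends
the cost.  The table is authoritative for ``z <= Z0`` and the curve is used
only for ``z > Z0``; the two disagree slightly at the boundary and the
discontinuity is deliberate (the curve is an extrapolation device, not a
smoother).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import CenterConfig

__all__ = [
    "DEFAULT_MARGINAL_COSTS",
    "OverageCostSchedule",
    "fit_extrapolation",
    "overage_cost",
    "total_overage_cost",
]

#: Elicited marginal cost (NTD) of overage units 1..10 in the case study.
DEFAULT_MARGINAL_COSTS: tuple[float, ...] = (
    2500, 2500, 2500, 5000, 5000, 5000, 10000, 10000, 10000, 20000,
)


def fit_extrapolation(
    cumulative_points: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """OLS fit of ``y = a*z + b*z**2`` (zero intercept) to (z, cumulative cost).

    Returns ``(a, b)``.  At least two distinct positive abscissae are required.
    """
    pts = np.asarray(cumulative_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (z, cost) points")
    z, y = pts[:, 0], pts[:, 1]
    if (z <= 0).any() or np.unique(z).size < 2:
        raise ValueError("abscissae must be positive and not all identical")
    X = np.column_stack([z, z**2])
    coef, residuals, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("degenerate design: cannot identify both coefficients")
    return float(coef[0]), float(coef[1])


@dataclass(frozen=True)
class OverageCostSchedule:
    """Cumulative overage cost: tabulated to Z0, quadratic beyond.

    ``marginal_costs[u-1]`` is the cost of the u-th unit of overage; the list
    must be positive and nondecreasing so the cumulative cost is strictly
    increasing and convex.  ``extrapolation`` holds the quadratic coefficients
    (a, b); when omitted they are fitted to the cumulative points implied by
    the marginal table.
    """

    marginal_costs: tuple[float, ...] = DEFAULT_MARGINAL_COSTS
    extrapolation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        mc = np.asarray(self.marginal_costs, dtype=float)
        if mc.size == 0 or (mc <= 0).any():
            raise ValueError("marginal costs must be positive")
        if (np.diff(mc) < 0).any():
            raise ValueError("marginal costs must be nondecreasing (convexity)")
        object.__setattr__(self, "marginal_costs", tuple(float(c) for c in mc))
        if self.extrapolation is None:
            cum = np.cumsum(mc)
            z = np.arange(1, mc.size + 1)
            object.__setattr__(
                self, "extrapolation", fit_extrapolation(list(zip(z, cum)))
            )

    @property
    def elicited_range(self) -> int:
        """Z0: the largest overage level covered by the marginal table."""
        return len(self.marginal_costs)

    @property
    def cumulative_costs(self) -> np.ndarray:
        return np.cumsum(self.marginal_costs)

    def scaled(self, multiplier: float) -> "OverageCostSchedule":
        """Schedule with all costs scaled; the extrapolation is refitted."""
        if multiplier <= 0:
            raise ValueError("cost multiplier must be positive")
        return OverageCostSchedule(
            marginal_costs=tuple(multiplier * c for c in self.marginal_costs)
        )


def overage_cost(z: int, schedule: OverageCostSchedule) -> float:
    """Cumulative cost f(z): 0 for z <= 0, tabulated to Z0, quadratic beyond.

    Extrapolated values are rounded to the nearest whole currency unit.
    """
    z = int(z)
    if z <= 0:
        return 0.0
    if z <= schedule.elicited_range:
        return float(schedule.cumulative_costs[z - 1])
    a, b = schedule.extrapolation
    return float(round(a * z + b * z * z))


def total_overage_cost(
    shows: Sequence[int] | np.ndarray,
    config: CenterConfig,
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule],
) -> float:
    """Sum over resources of f_i(load_i - K_i) for the show-up vector."""
    sched = _per_resource(schedules, config.n_resources)
    z = config.matrix.loads(np.asarray(shows)) - config.ideal_levels
    return float(sum(overage_cost(zi, s) for zi, s in zip(z, sched)))


def _per_resource(
    schedules: OverageCostSchedule | Sequence[OverageCostSchedule], n: int
) -> list[OverageCostSchedule]:
    if isinstance(schedules, OverageCostSchedule):
        return [schedules] * n
    schedules = list(schedules)
    if len(schedules) != n:
        raise ValueError(f"expected {n} schedules, got {len(schedules)}")
    return schedules
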