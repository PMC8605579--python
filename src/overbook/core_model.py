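"""Domain types for sets, resources and the booking-limit search space.

A physical-examination center sells examination *sets* (bundled products)
that each consume one or more capacity-limited *resources* (gastroenteroscope,
MRI, ...).  Booking limits are chosen per set, but overage — consumers beyond
a resource's ideal level — accrues per resource.  The binary set-resource
matrix ``V`` (``V[i, j] = 1`` iff set ``j`` uses resource ``i``) couples the
two sides and defines the feasible region of booking-limit combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Resource",
    "ExaminationSet",
    "SetResourceMatrix",
    "CenterConfig",
    "SearchSpace",
    "overage_level",
    "is_feasible",
    "enumerate_search_space",
]


@dataclass(frozen=True)
class Resource:
    """A capacity-limited facility shared by several examination sets.

    Parameters
    ----------
    name
        Human-readable identifier, used in configuration files.
    ideal_consumer_level
        Maximum consumers served in regular time (K_i); show-ups beyond it
        are overage.
    max_allowable_overage
        Hard cap on overage (U_i).  Zero under a no-overbooking policy.
    """

    name: str
    ideal_consumer_level: int
    max_allowable_overage: int = 0

    def __post_init__(self) -> None:
        if self.ideal_consumer_level < 0:
            raise ValueError(f"resource {self.name!r}: ideal_consumer_level < 0")
        if self.max_allowable_overage < 0:
            raise ValueError(f"resource {self.name!r}: max_allowable_overage < 0")


@dataclass(frozen=True)
class ExaminationSet:
    """A bookable examination product with a price and an original limit."""

    name: str
    price: float
    original_booking_limit: int = 0

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError(f"set {self.name!r}: price must be positive")
        if self.original_booking_limit < 0:
            raise ValueError(f"set {self.name!r}: original_booking_limit < 0")


class SetResourceMatrix:
    """Binary n_resources x n_sets incidence matrix V.

    Every set must use at least one resource; otherwise its booking limit
    would be unconstrained and the search space infinite.
    """

    def __init__(self, entries: Sequence[Sequence[int]] | np.ndarray):
        V = np.asarray(entries, dtype=np.int64)
        if V.ndim != 2:
            raise ValueError("set-resource matrix must be 2-dimensional")
        if not np.isin(V, (0, 1)).all():
            raise ValueError("set-resource matrix entries must be 0 or 1")
        empty = np.flatnonzero(V.sum(axis=0) == 0)
        if empty.size:
            raise ValueError(
                f"set column(s) {empty.tolist()} use no resource; "
                "the search space would be unbounded"
            )
        self.entries = V

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SetResourceMatrix) and np.array_equal(
            self.entries, other.entries
        )

    def __repr__(self) -> str:
        return f"SetResourceMatrix({self.entries.tolist()!r})"

    @property
    def n_resources(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sets(self) -> int:
        return self.entries.shape[1]

    def loads(self, x: Sequence[int] | np.ndarray) -> np.ndarray:
        """Per-resource load V @ x for per-set counts ``x``."""
        x = np.asarray(x)
        if x.shape != (self.n_sets,):
            raise ValueError(
                f"expected {self.n_sets} per-set counts, got shape {x.shape}"
            )
        return self.entries @ x


@dataclass(frozen=True)
class CenterConfig:
    """The center: its sets, resources and set-resource relationship."""

    sets: tuple[ExaminationSet, ...]
    resources: tuple[Resource, ...]
    matrix: SetResourceMatrix

    def __post_init__(self) -> None:
        if self.matrix.n_resources != len(self.resources):
            raise ValueError("matrix rows do not match resource count")
        if self.matrix.n_sets != len(self.sets):
            raise ValueError("matrix columns do not match set count")

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def n_resources(self) -> int:
        return len(self.resources)

    @property
    def ideal_levels(self) -> np.ndarray:
        return np.array([r.ideal_consumer_level for r in self.resources])

    @property
    def prices(self) -> np.ndarray:
        return np.array([s.price for s in self.sets], dtype=float)

    def with_no_overbooking(self) -> "CenterConfig":
        """Copy with U_i = 0 for every resource (the NO policy's space)."""
        return CenterConfig(
            sets=self.sets,
            resources=tuple(
                Resource(r.name, r.ideal_consumer_level, 0) for r in self.resources
            ),
            matrix=self.matrix,
        )


@dataclass(frozen=True)
class SearchSpace:
    """Feasible region S = {N >= 0 integer : V @ N <= K + U componentwise}."""

    matrix: SetResourceMatrix
    capacities: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_config(cls, config: CenterConfig) -> "SearchSpace":
        caps = np.array(
            [r.ideal_consumer_level + r.max_allowable_overage for r in config.resources]
        )
        return cls(config.matrix, caps)

    def __post_init__(self) -> None:
        caps = np.asarray(self.capacities, dtype=np.int64)
        if caps.shape != (self.matrix.n_resources,):
            raise ValueError("capacities length does not match resource count")
        if (caps < 0).any():
            raise ValueError("capacities must be nonnegative")
        object.__setattr__(self, "capacities", caps)

    def per_set_bounds(self) -> np.ndarray:
        """Upper bound on each N_j: min capacity over the resources it uses."""
        V = self.matrix.entries
        bounds = np.empty(self.matrix.n_sets, dtype=np.int64)
        for j in range(self.matrix.n_sets):
            bounds[j] = self.capacities[V[:, j] == 1].min()
        return bounds


def overage_level(
    shows: Sequence[int] | np.ndarray, config: CenterConfig
) -> np.ndarray:
    """Per-resource overage max{sum_j V_ij x_j - K_i, 0} for show-ups ``shows``."""
    x = np.asarray(shows)
    if (x < 0).any():
        raise ValueError("show-up counts must be nonnegative")
    return np.maximum(config.matrix.loads(x) - config.ideal_levels, 0)


def is_feasible(limits: Sequence[int] | np.ndarray, space: SearchSpace) -> bool:
    """True iff ``limits`` lies in the search space (V @ N <= K + U)."""
    N = np.asarray(limits)
    if (N < 0).any():
        return False
    return bool((space.matrix.loads(N) <= space.capacities).all())


def enumerate_search_space(space: SearchSpace) -> Iterator[tuple[int, ...]]:
    """Yield every feasible booking-limit combination once, lexicographically.

    Depth-first over set indices with running resource loads, so infeasible
    branches are pruned without materializing the full integer box.
    """
    V = space.matrix.entries
    caps = space.capacities
    m = space.matrix.n_sets
    current = [0] * m

    def recurse(j: int, loads: np.ndarray) -> Iterator[tuple[int, ...]]:
        if j == m:
            yield tuple(current)
            return
        col = V[:, j]
        used = col == 1
        # remaining headroom on the resources this set touches
        slack = (caps - loads)[used]
        for nj in range(int(slack.min()) + 1):
            current[j] = nj
            yield from recurse(j + 1, loads + nj * col)
        current[j] = 0

    yield from recurse(0, np.zeros(space.matrix.n_resources, dtype=np.int64))
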