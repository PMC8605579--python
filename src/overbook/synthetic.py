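"""Synthetic booking data with the statistical structure of the case study.

The center's raw reservation data are private, so every stage of the
pipeline is exercised on generated bookings that emulate the published
aggregates: a 12-cluster structure (season x group-booking x age-interval)
with the printed per-cluster booking counts and late-cancellation rates,
rare holiday-examination and last-minute flags whose effects enter on the
logit scale, and the printed mix of the four aggregate examination sets.

Also here: the default case-study center — four aggregate sets over five
resources (basic check, breast check, gastroenteroscope, MRI, DWI), ideal
consumer levels K = (36, 36, 24, 4, 2), maximum allowable overage U = K/2,
and the elicited overage-cost schedule.  Set prices are synthetic
placeholders inside the published 20,000-100,000 NTD range (the real
per-set prices are unpublished); no reproduced quantity depends on them.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core_model import CenterConfig, ExaminationSet, Resource, SearchSpace, SetResourceMatrix
from .cost_model import DEFAULT_MARGINAL_COSTS, OverageCostSchedule
from .estimation import ClusterModel, UniformRateEstimate
from .optimizer import PolicySpec

__all__ = [
    "CLUSTER_TABLE",
    "SET_MIX_BOOKINGS",
    "DEFAULT_HOLIDAYS",
    "SyntheticPopulationSpec",
    "generate_bookings",
    "reference_cluster_model",
    "default_case_study_config",
    "CaseStudyDefaults",
]

# Published cluster structure: one row per cluster in table order
# (season block winter/summer/off-peak; within a block: group x age-interval).
CLUSTER_TABLE = pd.DataFrame(
    {
        "season": ["winter"] * 4 + ["summer"] * 4 + ["off-peak"] * 4,
        "group_booking": [1, 1, 0, 0] * 3,
        "age_interval": [1, 0, 1, 0] * 3,
        "bookings": [583, 247, 842, 433, 236, 111, 578, 311, 835, 420, 2319, 1131],
        "late_cancellations": [20, 15, 31, 22, 10, 4, 19, 16, 32, 19, 42, 39],
    }
)
CLUSTER_TABLE["rate"] = (
    CLUSTER_TABLE["late_cancellations"] / CLUSTER_TABLE["bookings"]
)

#: Bookings per aggregate set (basic+colonoscopy; breast variant; MRI; MRI+DWI).
SET_MIX_BOOKINGS = (3068, 3514, 648, 816)

SEASON_MONTHS = {
    "winter": (11, 12, 1),
    "summer": (8, 9),
    "off-peak": (2, 3, 4, 5, 6, 7, 10),
}

#: Synthetic national-holiday calendar for the simulated year, with at least
#: one holiday in each season group.
DEFAULT_HOLIDAYS: tuple[dt.date, ...] = (
    dt.date(2019, 1, 1),
    dt.date(2019, 2, 5),
    dt.date(2019, 2, 28),
    dt.date(2019, 4, 4),
    dt.date(2019, 4, 5),
    dt.date(2019, 5, 1),
    dt.date(2019, 6, 7),
    dt.date(2019, 8, 15),
    dt.date(2019, 9, 13),
    dt.date(2019, 10, 10),
    dt.date(2019, 11, 12),
    dt.date(2019, 12, 25),
)


@dataclass(frozen=True)
class SyntheticPopulationSpec:
    """Generative parameters; defaults are the published aggregates."""

    cluster_bookings: tuple[int, ...] = tuple(CLUSTER_TABLE["bookings"])
    cluster_rates: tuple[float, ...] = tuple(CLUSTER_TABLE["rate"])
    holiday_rate: float = 0.008
    last_minute_rate: float = 47 / 8046
    holiday_logit_effect: float = 0.5702
    last_minute_logit_effect: float = 2.0522
    female_share: float = 4171 / 8046
    set_mix: tuple[float, ...] = tuple(
        np.array(SET_MIX_BOOKINGS) / sum(SET_MIX_BOOKINGS)
    )
    prices: tuple[float, ...] = (25_000, 30_000, 60_000, 80_000)
    early_cancel_rate: float = 0.05
    year: int = 2019
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_bookings) != len(CLUSTER_TABLE):
            raise ValueError("one booking count per cluster is required")
        if any(n <= 0 for n in self.cluster_bookings):
            raise ValueError("cluster booking counts must be positive")
        if any(not 0 <= r <= 1 for r in self.cluster_rates):
            raise ValueError("cluster rates must lie in [0, 1]")
        if abs(sum(self.set_mix) - 1) > 1e-9:
            raise ValueError("set mix must sum to 1")

    def scaled(self, factor: float) -> "SyntheticPopulationSpec":
        """Spec with cluster sizes scaled by ``factor`` (minimum 1 each)."""
        sizes = tuple(max(1, round(n * factor)) for n in self.cluster_bookings)
        return replace(self, cluster_bookings=sizes)


def _logit(p: float) -> float:
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_bookings(spec: SyntheticPopulationSpec | None = None) -> pd.DataFrame:
    """Draw a booking table whose derived factors realize the cluster design.

    Ages are sampled inside/outside [45, 70], examination months inside the
    cluster's season group, and group sizes 1 vs 2-4, so re-deriving the
    analysis variables reproduces the intended cluster of every booking.
    Late cancellation is Bernoulli at the cluster rate shifted on the logit
    scale by the holiday and last-minute flags; booking and cancellation
    dates are generated consistently with the labels.  Reproducible per
    ``spec.seed``.
    """
    spec = spec or SyntheticPopulationSpec()
    rng = np.random.default_rng(spec.seed)
    holiday_by_season = {
        s: [h for h in DEFAULT_HOLIDAYS if h.month in months]
        for s, months in SEASON_MONTHS.items()
    }
    holiday_set = set(DEFAULT_HOLIDAYS)
    rows: list[dict] = []
    for c, (n, rate) in enumerate(zip(spec.cluster_bookings, spec.cluster_rates)):
        season = CLUSTER_TABLE.loc[c, "season"]
        group = int(CLUSTER_TABLE.loc[c, "group_booking"])
        in_interval = int(CLUSTER_TABLE.loc[c, "age_interval"])
        months = SEASON_MONTHS[season]
        for _ in range(n):
            if in_interval:
                age = int(rng.integers(45, 71))
            else:
                age = int(rng.integers(20, 45) if rng.random() < 0.7
                          else rng.integers(71, 86))
            group_size = int(rng.integers(2, 5)) if group else 1
            month = int(months[rng.integers(len(months))])
            day = int(rng.integers(1, 29))
            exam = dt.date(spec.year, month, day)
            is_holiday = rng.random() < spec.holiday_rate
            if is_holiday and holiday_by_season[season]:
                exam = holiday_by_season[season][
                    rng.integers(len(holiday_by_season[season]))
                ]
            else:
                while exam in holiday_set:  # keep unflagged bookings off holidays
                    exam += dt.timedelta(days=1 if exam.day < 28 else -1)
            is_holiday = exam in holiday_set
            last_minute = rng.random() < spec.last_minute_rate
            lead = int(rng.integers(0, 8)) if last_minute else int(rng.integers(14, 181))
            booked = exam - dt.timedelta(days=lead)
            p = float(
                _sigmoid(
                    _logit(rate)
                    + spec.holiday_logit_effect * is_holiday
                    + spec.last_minute_logit_effect * last_minute
                )
            ) if 0 < rate < 1 else rate
            cancel: dt.date | None = None
            if rng.random() < p:
                back = int(rng.integers(0, 8))
                cancel = max(exam - dt.timedelta(days=back), booked)
            elif lead >= 9 and rng.random() < spec.early_cancel_rate:
                back = int(rng.integers(8, min(lead, 60) + 1))
                cancel = exam - dt.timedelta(days=back)
            set_idx = int(rng.choice(len(spec.set_mix), p=spec.set_mix))
            rows.append(
                dict(
                    age=age,
                    gender="female" if rng.random() < spec.female_share else "male",
                    booking_date=booked,
                    booking_type=("online" if rng.random() < 0.6 else "in-person"),
                    examination_date=exam,
                    set_id=f"set{set_idx + 1}",
                    price=spec.prices[set_idx],
                    group_size=group_size,
                    cancellation_date=cancel,
                )
            )
    frame = pd.DataFrame(rows)
    for col in ("booking_date", "examination_date", "cancellation_date"):
        frame[col] = pd.to_datetime(frame[col])
    return frame


def reference_cluster_model() -> ClusterModel:
    """Cluster model holding the published per-cluster counts and rates."""
    factors = (
        ("season", ("off-peak", "summer", "winter")),
        ("group_booking", (0, 1)),
        ("age_interval", (0, 1)),
    )
    rows = []
    for season in factors[0][1]:
        for grp in factors[1][1]:
            for age in factors[2][1]:
                row = CLUSTER_TABLE[
                    (CLUSTER_TABLE["season"] == season)
                    & (CLUSTER_TABLE["group_booking"] == grp)
                    & (CLUSTER_TABLE["age_interval"] == age)
                ].iloc[0]
                rows.append(
                    dict(
                        season=season,
                        group_booking=grp,
                        age_interval=age,
                        bookings=int(row["bookings"]),
                        late_cancellations=int(row["late_cancellations"]),
                        rate=float(row["rate"]),
                    )
                )
    total_q = int(CLUSTER_TABLE["late_cancellations"].sum())
    total_n = int(CLUSTER_TABLE["bookings"].sum())
    return ClusterModel(
        factors=factors,
        table=pd.DataFrame(rows),
        fallback=UniformRateEstimate(total_q, total_n),
        excluded=("holiday_examination", "last_minute"),
    )


@dataclass(frozen=True)
class CaseStudyDefaults:
    """The default center: sets, resources, V, K, U, costs and rates."""

    config: CenterConfig
    schedule: OverageCostSchedule
    cluster_model: ClusterModel = field(repr=False, default=None)  # type: ignore
    uniform_rate: float = 0.0

    def search_space(self, policy_kind: str) -> SearchSpace:
        """Feasible region: U_i = 0 under NO, the configured U otherwise."""
        cfg = self.config.with_no_overbooking() if policy_kind == "NO" else self.config
        return SearchSpace.from_config(cfg)

    def policy(self, kind: str, season: str | None = None) -> PolicySpec:
        if kind in ("NO", "OU"):
            return PolicySpec(kind=kind, uniform_rate=self.uniform_rate)
        return PolicySpec(kind="OC", cluster_model=self.cluster_model, season=season)


def default_case_study_config() -> CaseStudyDefaults:
    """The case-study center with K = (36, 36, 24, 4, 2) and U = K/2.

    The set-resource matrix follows the published capacity constraints
    (N1+N2+N3+N4 <= 36, N2 <= 36, N1+N2 <= 24, N3+N4 <= 4, N4 <= 2); the
    integer halving K/2 is exact for every resource.  Prices and original
    booking limits are synthetic placeholders.
    """
    resources = (
        Resource("basic", 36, 18),
        Resource("breast", 36, 18),
        Resource("gastroenteroscope", 24, 12),
        Resource("mri", 4, 2),
        Resource("dwi", 2, 1),
    )
    sets = (
        ExaminationSet("set1", 25_000, 2),
        ExaminationSet("set2", 30_000, 22),
        ExaminationSet("set3", 60_000, 3),
        ExaminationSet("set4", 80_000, 2),
    )
    V = SetResourceMatrix(
        [
            [1, 1, 1, 1],  # basic: every set
            [0, 1, 0, 0],  # breast: set 2 only
            [1, 1, 0, 0],  # gastroenteroscope: sets 1-2
            [0, 0, 1, 1],  # MRI: sets 3-4
            [0, 0, 0, 1],  # DWI: set 4 only
        ]
    )
    model = reference_cluster_model()
    return CaseStudyDefaults(
        config=CenterConfig(sets=sets, resources=resources, matrix=V),
        schedule=OverageCostSchedule(DEFAULT_MARGINAL_COSTS),
        cluster_model=model,
        uniform_rate=model.fallback.rate,
    )
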