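"""Per-booking late-cancellation probability estimation.

Three estimators of increasing granularity:

1. the *uniform rate* r = q1/q2 (late cancellations over bookings), under
   which the show-up count is binomial;
2. a staged logistic regression of the late-cancellation flag that screens
   candidate factors for significance;
3. a *cluster model*: the retained categorical factors are cross-producted
   into clusters and each booking inherits its cluster's empirical late-
   cancellation rate r_jk.

Factors whose minority level is too rare are excluded from clustering (their
rates would be too noisy), and empty clusters fall back to the uniform rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "EstimationError",
    "UniformRateEstimate",
    "RegressionResult",
    "ClusterModel",
    "uniform_rate",
    "fit_late_cancellation_model",
    "build_clusters",
    "estimate_probability",
    "assign_probabilities",
    "compare_season_groupings",
]

LABEL = "late_cancellation"

#: Minimum minority-level count for a factor to enter clustering.
DEFAULT_MIN_COUNT = 100


class EstimationError(RuntimeError):
    """Raised when a probability model cannot be estimated."""


@dataclass(frozen=True)
class UniformRateEstimate:
    late_cancellations: int
    bookings: int

    def __post_init__(self) -> None:
        if not 0 <= self.late_cancellations <= self.bookings:
            raise ValueError("need 0 <= late cancellations <= bookings")

    @property
    def rate(self) -> float:
        return self.late_cancellations / self.bookings


def uniform_rate(records: pd.DataFrame) -> UniformRateEstimate:
    """Overall late-cancellation proportion q1/q2."""
    if len(records) == 0:
        raise EstimationError("cannot estimate a rate from zero bookings")
    return UniformRateEstimate(int(records[LABEL].sum()), len(records))


# ---------------------------------------------------------------------------
# staged logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    """Coefficient table and the factors retained by staged selection."""

    table: pd.DataFrame  # columns: variable, level, coef, std_err, z, p_value
    retained: tuple[str, ...]
    forced: tuple[str, ...]
    alpha: float


def _design(records: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Dummy-coded design matrix; the most frequent level is the reference."""
    cols = {}
    for var in variables:
        series = records[var]
        levels = series.value_counts().index.tolist()
        if len(levels) < 2:
            raise EstimationError(f"variable {var!r} has a single level")
        for level in levels[1:]:  # drop the modal level as reference
            cols[f"{var}[{level}]"] = (series == level).astype(float)
    return pd.DataFrame(cols, index=records.index)


def _fit(records: pd.DataFrame, variables: Sequence[str]):
    X = sm.add_constant(_design(records, variables))
    try:
        fit = sm.Logit(records[LABEL].astype(float), X).fit(disp=False, maxiter=200)
    except Exception as exc:  # separation, singular design, ...
        raise EstimationError(f"logistic fit failed for {list(variables)}: {exc}")
    if not fit.mle_retvals.get("converged", True):
        raise EstimationError(f"logistic fit did not converge for {list(variables)}")
    return fit


def _factor_pvalues(fit, variables: Sequence[str]) -> dict[str, float]:
    """Per-factor p-value: the smallest level p-value of that factor."""
    out = {}
    for var in variables:
        ps = [p for name, p in fit.pvalues.items() if name.startswith(f"{var}[")]
        out[var] = min(ps) if ps else 1.0
    return out


def fit_late_cancellation_model(
    records: pd.DataFrame,
    stage1_vars: Sequence[str],
    stage2_vars: Sequence[str] = (),
    stage3_vars: Sequence[str] = (),
    alpha: float = 0.05,
    force_include: Sequence[str] = (),
) -> RegressionResult:
    """Staged logistic screening of late-cancellation factors.

    Stage 1 (literature-suggested) and stage 2 (exploratory) variables enter
    together and insignificant ones are removed; stage 3 variables are then
    offered and kept only if significant.  A multi-level factor is judged by
    its most significant level.  ``force_include`` keeps a factor regardless
    of its p-value (flagged in the result).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    forced = tuple(force_include)
    offered = list(dict.fromkeys([*stage1_vars, *stage2_vars]))
    fit = _fit(records, offered)
    pvals = _factor_pvalues(fit, offered)
    retained = [v for v in offered if pvals[v] < alpha or v in forced]
    dropped = sorted(set(offered) - set(retained))
    if dropped:
        logger.info("stage 1+2 removed insignificant factor(s): %s", dropped)
    stage3 = [v for v in stage3_vars if v not in retained]
    if stage3:
        fit = _fit(records, [*retained, *stage3])
        pvals3 = _factor_pvalues(fit, stage3)
        retained += [v for v in stage3 if pvals3[v] < alpha or v in forced]
    if not retained:
        raise EstimationError("no factor survived significance screening")
    final = _fit(records, retained)
    rows = []
    for name in final.params.index:
        var, _, rest = name.partition("[")
        rows.append(
            dict(
                variable="constant" if name == "const" else var,
                level=rest.rstrip("]") if rest else "",
                coef=final.params[name],
                std_err=final.bse[name],
                z=final.tvalues[name],
                p_value=final.pvalues[name],
            )
        )
    return RegressionResult(
        table=pd.DataFrame(rows), retained=tuple(retained), forced=forced, alpha=alpha
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterModel:
    """Cross-product clusters over categorical factors, with empirical rates.

    ``table`` has one row per factor-level combination (including empty
    ones) with columns ``bookings``, ``late_cancellations`` and ``rate``;
    empty clusters carry the fallback uniform rate.
    """

    factors: tuple[tuple[str, tuple], ...]  # (name, ordered levels)
    table: pd.DataFrame
    fallback: UniformRateEstimate
    excluded: tuple[str, ...] = field(default=())

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.factors)

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def conditional(self, where: Mapping[str, object]) -> pd.DataFrame:
        """Sub-table of clusters matching the given factor levels."""
        mask = pd.Series(True, index=self.table.index)
        for name, level in where.items():
            if name not in self.factor_names:
                raise KeyError(f"{name!r} is not a clustering factor")
            mask &= self.table[name] == level
        return self.table[mask]

    def to_dict(self) -> dict:
        return {
            "factors": [[n, list(lv)] for n, lv in self.factors],
            "excluded": list(self.excluded),
            "fallback": {
                "late_cancellations": self.fallback.late_cancellations,
                "bookings": self.fallback.bookings,
            },
            "table": self.table.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ClusterModel":
        return cls(
            factors=tuple((n, tuple(lv)) for n, lv in payload["factors"]),
            table=pd.DataFrame(payload["table"]),
            fallback=UniformRateEstimate(**payload["fallback"]),
            excluded=tuple(payload.get("excluded", ())),
        )


def build_clusters(
    records: pd.DataFrame,
    factors: Sequence[str],
    min_count: int = DEFAULT_MIN_COUNT,
) -> ClusterModel:
    """Cluster bookings by the cross product of categorical factors.

    A factor whose minority level has fewer than ``min_count`` records is
    excluded — its clusters would be too small for stable rates.  If no
    factor survives, the model degenerates to the uniform rate (with a
    warning, not an error).
    """
    if min_count < 1:
        raise ValueError("min_count must be at least 1")
    fallback = uniform_rate(records)
    kept, excluded = [], []
    for name in factors:
        counts = records[name].value_counts()
        if len(counts) >= 2 and counts.min() >= min_count:
            kept.append(name)
        else:
            excluded.append(name)
    if excluded:
        logger.info("factor(s) excluded from clustering (rare level): %s", excluded)
    if not kept:
        logger.warning("no factor survived exclusion; using the uniform rate only")
    level_lists = [sorted(records[name].unique().tolist()) for name in kept]
    rows = []
    grouped = (
        records.groupby(kept, observed=False)[LABEL].agg(["count", "sum"])
        if kept
        else None
    )
    for combo in product(*level_lists) if kept else [()]:
        if kept:
            key = combo if len(combo) > 1 else combo[0]
            if grouped is not None and key in grouped.index:
                n, q = int(grouped.loc[key, "count"]), int(grouped.loc[key, "sum"])
            else:
                n, q = 0, 0
        else:
            n, q = fallback.bookings, fallback.late_cancellations
        rows.append(
            dict(
                zip(kept, combo),
                bookings=n,
                late_cancellations=q,
                rate=(q / n) if n else fallback.rate,
            )
        )
    return ClusterModel(
        factors=tuple((n, tuple(lv)) for n, lv in zip(kept, level_lists)),
        table=pd.DataFrame(rows),
        fallback=fallback,
        excluded=tuple(excluded),
    )


def estimate_probability(attributes: Mapping[str, object], model: ClusterModel) -> float:
    """Late-cancellation probability r_jk of a booking: its cluster's rate.

    An empty cluster falls back to the uniform rate; an unknown factor level
    is an input error.
    """
    where = {}
    for name, levels in model.factors:
        if name not in attributes:
            raise KeyError(f"booking attributes missing clustering factor {name!r}")
        level = attributes[name]
        if level not in levels:
            raise ValueError(f"unknown level {level!r} for factor {name!r}")
        where[name] = level
    sub = model.conditional(where)
    assert len(sub) == 1
    return float(sub["rate"].iloc[0])


def assign_probabilities(records: pd.DataFrame, model: ClusterModel) -> pd.DataFrame:
    """Copy of ``records`` with a column ``r`` of per-booking probabilities."""
    df = records.copy()
    if model.factors:
        keys = list(model.factor_names)
        merged = df.merge(
            model.table[keys + ["rate"]], on=keys, how="left", validate="many_to_one"
        )
        if merged["rate"].isna().any():
            raise ValueError("some bookings carry unknown factor levels")
        df["r"] = merged["rate"].to_numpy()
    else:
        df["r"] = model.fallback.rate
    return df


def compare_season_groupings(
    records: pd.DataFrame,
    groupings: Mapping[str, Mapping[int, str]],
    variables: Sequence[str],
) -> pd.DataFrame:
    """Refit the logistic model under alternative month-to-season maps.

    ``groupings`` maps a label to a month->season mapping; for each candidate
    the ``season`` column is recomputed from ``examination_date`` and the
    model refitted on ``variables``.  Model fit is reported as residual
    deviance (lower explains the data better) plus AIC; the choice of
    criterion is a package convention.
    """
    rows = []
    for label, season_map in groupings.items():
        df = records.copy()
        months = pd.to_datetime(df["examination_date"]).dt.month
        df["season"] = months.map(dict(season_map))
        fit = _fit(df, variables)
        rows.append(
            dict(grouping=label, deviance=-2 * fit.llf, aic=fit.aic, n=len(df))
        )
    return pd.DataFrame(rows).sort_values("deviance").reset_index(drop=True)
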