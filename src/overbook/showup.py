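"""Distribution of the show-up count under heterogeneous cancellation rates.

Each of the N accepted bookings for a set independently fails to show
("cancels late") with its own probability r_k, so the number of show-ups is
Poisson-binomial with success probabilities 1 - r_k.  The exact pmf is
computed by the standard O(N^2) dynamic-programming convolution; a seeded
Monte-Carlo estimator with batch-wise convergence is provided as well, since
sampling is how the distribution is defined operationally (draw a uniform R
per booking; the consumer shows iff R >= r_k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ShowUpPMF", "MonteCarloConfig", "exact_pmf", "monte_carlo_pmf"]


@dataclass(frozen=True)
class ShowUpPMF:
    """pmf of the show-up count over support 0..support_max."""

    probabilities: np.ndarray
    iterations_used: int | None = None  # set by the Monte-Carlo estimator

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("pmf must be a nonempty 1-d vector")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pmf entries must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def support_max(self) -> int:
        return self.probabilities.size - 1

    @property
    def mean(self) -> float:
        return float(np.arange(self.probabilities.size) @ self.probabilities)

    def tv_distance(self, other: "ShowUpPMF") -> float:
        """Total-variation distance; shorter support is zero-padded."""
        n = max(self.probabilities.size, other.probabilities.size)
        a = np.pad(self.probabilities, (0, n - self.probabilities.size))
        b = np.pad(other.probabilities, (0, n - other.probabilities.size))
        return float(0.5 * np.abs(a - b).sum())


@dataclass(frozen=True)
class MonteCarloConfig:
    batch_size: int = 10_000
    max_iterations: int = 1_000_000
    tolerance: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.max_iterations <= 0:
            raise ValueError("batch_size and max_iterations must be positive")
        if self.batch_size > self.max_iterations:
            raise ValueError("batch_size must not exceed max_iterations")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _validated(late_cancel_probs: Sequence[float]) -> np.ndarray:
    r = np.asarray(late_cancel_probs, dtype=float)
    if r.ndim != 1:
        raise ValueError("late-cancellation probabilities must be a vector")
    if r.size and ((r < 0) | (r > 1)).any():
        raise ValueError("late-cancellation probabilities must lie in [0, 1]")
    return r


def exact_pmf(late_cancel_probs: Sequence[float]) -> ShowUpPMF:
    """Exact Poisson-binomial pmf of the show-up count.

    Equivalent to enumerating all 2^N cancellation patterns, but computed by
    the DP recurrence that convolves one Bernoulli slot at a time.  An empty
    input yields a point mass at zero shows.
    """
    r = _validated(late_cancel_probs)
    show = 1.0 - r
    pmf = np.zeros(r.size + 1)
    pmf[0] = 1.0
    for k, p in enumerate(show):
        # after slot k: P(X=x) = p * P_prev(X=x-1) + (1-p) * P_prev(X=x)
        pmf[1 : k + 2] = p * pmf[: k + 1] + (1.0 - p) * pmf[1 : k + 2]
        pmf[0] *= 1.0 - p
    pmf /= pmf.sum()
    return ShowUpPMF(pmf)


def monte_carlo_pmf(
    late_cancel_probs: Sequence[float], config: MonteCarloConfig | None = None
) -> ShowUpPMF:
    """Monte-Carlo estimate of the show-up pmf, reproducible per seed.

    Iterations are drawn in batches; one uniform is consumed per booking per
    iteration in a fixed booking order.  Accumulation stops when the maximum
    absolute change of any pmf entry between successive cumulative estimates
    falls below ``tolerance``, or at ``max_iterations``.
    """
    config = config or MonteCarloConfig()
    r = _validated(late_cancel_probs)
    rng = np.random.default_rng(config.seed)
    n = r.size
    counts = np.zeros(n + 1, dtype=np.int64)
    total = 0
    previous = None
    while total < config.max_iterations:
        batch = min(config.batch_size, config.max_iterations - total)
        if n:
            draws = rng.random((batch, n))
            shows = (draws >= r).sum(axis=1)
        else:
            shows = np.zeros(batch, dtype=np.int64)
        counts += np.bincount(shows, minlength=n + 1)
        total += batch
        estimate = counts / total
        if previous is not None and np.abs(estimate - previous).max() < config.tolerance:
            break
        previous = estimate
    return ShowUpPMF(counts / total, iterations_used=total)
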