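"""Bootstrap upper bound on the size of clusters that may remain
undetected after an iteration.

The exact probability of capturing a given set of clusters is hard to
compute, so a simulation stands in: for every candidate cluster size k
we hypothesise the worst case — that the unclustered pool still hides
``floor(pool_size / k)`` additional clusters of size k on top of the
ones already discovered — and replay the last sampling round ``r``
times, detecting each hypothetical cluster with the exact
hypergeometric probability.  If the observed number of discovered
size-k clusters matches (is at least) the simulated number in at least
``(1 - epsilon) * r`` realizations, size k is marked *detected*: had
clusters of that size remained, the round would very likely have found
more of them.  The reported upper bound is the smallest k such that
every candidate size >= k is detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import IterationStats
from .prob import _log_p_miss_one_exact

__all__ = ["ConfidenceConfig", "DetectionReport", "detected_sizes"]


@dataclass(frozen=True)
class ConfidenceConfig:
    """r realizations, tolerance epsilon, candidate sizes, and the size
    scale (``"distinct"`` matches the sampling space of deduplicated
    records; ``"total"`` uses multiplicity-weighted sizes)."""

    r: int = 1000
    epsilon: float = 0.05
    size_grid: tuple[int, ...] = (2, 5, 10, 20, 50, 100)
    size_mode: str = "distinct"

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if not self.size_grid:
            raise ValueError("size_grid must be non-empty")
        if any(k < 2 for k in self.size_grid):
            raise ValueError("candidate sizes must be >= 2")
        if self.size_mode not in ("total", "distinct"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")


@dataclass(frozen=True)
class DetectionReport:
    """Sizes marked detected after an iteration, and the smallest size k
    with every candidate >= k detected (None when even the largest
    candidate size cannot be ruled out)."""

    detected: frozenset[int]
    upper_bound_size: int | None
    fractions: dict[int, float] = field(default_factory=dict, hash=False)


def _iteration_frame(stats: IterationStats, size_mode: str) -> tuple[int, int, tuple[int, ...]]:
    if size_mode == "distinct":
        return stats.pool_start, stats.n_sampled, stats.cluster_sizes_distinct
    return stats.pool_start_total, stats.n_sampled_total, stats.cluster_sizes


def detected_sizes(
    history: Sequence[IterationStats],
    pool_size: int,
    cfg: ConfidenceConfig = ConfidenceConfig(),
    seed: int = 0,
) -> DetectionReport:
    """Detection confidence after the most recent iteration.

    ``pool_size`` is the current unclustered count on the configured
    size scale.  Deterministic given ``seed``; enlarging ``epsilon``
    can only grow the detected set.
    """
    if not history:
        raise ValueError("history must contain at least one iteration")
    stats = history[-1]
    N, n, discovered = _iteration_frame(stats, cfg.size_mode)
    rng = np.random.default_rng(seed)
    detected: set[int] = set()
    fractions: dict[int, float] = {}
    grid = sorted(set(cfg.size_grid))
    for k in grid:
        observed = sum(1 for s in discovered if s == k)
        hypothesised = observed + pool_size // k
        if hypothesised == 0:
            fractions[k] = 1.0
            detected.add(k)
            continue
        if k > N or n < 2 or N < 2:
            p = 0.0
        else:
            p = float(
                np.clip(
                    1.0 - np.exp(_log_p_miss_one_exact(N, min(n, N), k)), 0.0, 1.0
                )
            )
        sim_counts = rng.binomial(hypothesised, p, size=cfg.r)
        frac = float(np.mean(observed >= sim_counts))
        fractions[k] = frac
        if frac >= 1.0 - cfg.epsilon:
            detected.add(k)
    upper: int | None = None
    for k in reversed(grid):
        if k in detected:
            upper = k
        else:
            break
    return DetectionReport(
        detected=frozenset(detected), upper_bound_size=upper, fractions=fractions
    )
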