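"""Detection probabilities under uniform subsampling, and a coin-flip
iteration simulator.

A cluster of size ``rho`` in a pool of ``N`` sequences is *detected* by
a uniform sample of ``n`` sequences iff the sample contains at least two
of its members (two sequences are needed for the cluster to form in the
subsample).  The number of members drawn is hypergeometric, so

* ``p_detect``   = P(X >= 2),            X ~ Hypergeom(N, rho, n)
* ``p_miss_one`` = P(X <= 1) exactly, or the exponential upper bound
  ``exp(-rho n / N) * (1 + (rho n / N) exp(rho / N))``.
* ``p_miss_many`` = probability that *each* of m disjoint clusters of
  sizes rho_1 <= ... <= rho_m contributes at most one sequence to the
  sample.  Exactly:

      sum_{i=0..m}  e_i(rho) * C(N - S, n - i) / C(N, n),

  where e_i is the i-th elementary symmetric polynomial of the sizes and
  S their sum; the e_i satisfy the recurrence
  ``B[i][j] = B[i-1][j-1]*rho_i + B[i-1][j]`` with ``B[0][0] = 1``.
  The bound is ``exp(-m rho_1 n / N) * (1 + (rho_1 n / N)
  exp(m rho_1 / N))**m``.

All combinatorials are evaluated in log space (log-gamma), so pool
sizes up to 10^7 and beyond are handled without overflow.

:func:`simulate_iterations` runs the sequence-free analogue of the
iterative clustering loop: each round every remaining non-singleton
cluster is detected with probability ``p_detect`` (a biased coin flip),
detected clusters are removed and the pool shrinks.  This reproduces the
qualitative behaviour of the full algorithm — large clusters go first,
and the entropy of the detected size distribution falls together with
the number of unclustered sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .metrics import size_entropy

__all__ = [
    "ProbabilityQuery",
    "p_detect",
    "p_miss_one",
    "p_miss_many",
    "elementary_symmetric",
    "SimulationRound",
    "simulate_iterations",
    "sample_cluster_sizes",
]


def _log_binom(n, k):
    """log C(n, k), vectorized; -inf outside the support."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    bad = (k < 0) | (k > n) | (n < 0)
    out = np.where(bad, -np.inf, out)
    return out


def _validate(N: int, n: int, rho: Sequence[int]) -> tuple[int, ...]:
    rho_t = tuple(int(r) for r in rho)
    if N < 1 or n < 1:
        raise ValueError(f"N and n must be positive (N={N}, n={n})")
    if n > N:
        raise ValueError(f"sample size n={n} exceeds pool size N={N}")
    if not rho_t:
        raise ValueError("at least one cluster size required")
    if any(r < 1 for r in rho_t):
        raise ValueError(f"cluster sizes must be positive: {rho_t}")
    if sum(rho_t) > N:
        raise ValueError(f"cluster sizes sum to {sum(rho_t)} > N={N}")
    return rho_t


@dataclass(frozen=True)
class ProbabilityQuery:
    """Pool size N, sample size n, and disjoint cluster sizes rho."""

    N: int
    n: int
    rho: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rho", _validate(self.N, self.n, self.rho))

    @property
    def m(self) -> int:
        return len(self.rho)


def _exact_feasible(N: int, n: int) -> bool:
    # integer binomials stay cheap while C(N, n) has < ~20k digits
    return n * math.log10(max(N, 2)) < 20_000


def p_detect(N: int, n: int, rho: int) -> float:
    """Probability that a single cluster of size ``rho`` is detected
    (>= 2 members sampled) by a uniform n-of-N sample."""
    (rho,) = _validate(N, n, [rho])
    imax = min(n, rho)
    if imax < 2:
        return 0.0
    if _exact_feasible(N, n):
        num = sum(
            math.comb(N - rho, n - i) * math.comb(rho, i)
            for i in range(2, imax + 1)
            if n - i >= 0
        )
        return float(Fraction(num, math.comb(N, n)))
    i = np.arange(2, imax + 1)
    log_terms = (
        _log_binom(N - rho, n - i) + _log_binom(rho, i) - _log_binom(N, n)
    )
    finite = log_terms[np.isfinite(log_terms)]
    if finite.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(finite))))


def _log_p_miss_one_exact(N, n, rho):
    """log P(X <= 1) for hypergeometric X, vectorized over rho."""
    rho = np.asarray(rho, dtype=float)
    log_cn = _log_binom(N, n)
    t1 = _log_binom(N - rho, n - 1) + np.log(rho) - log_cn
    t0 = _log_binom(N - rho, n) - log_cn
    return np.logaddexp(t0, t1)


def p_miss_one(N: int, n: int, rho: int, use_bound: bool = False) -> float:
    """Probability of missing one cluster of size ``rho``.

    Exact form: ``[C(N-rho, n-1)*rho + C(N-rho, n)] / C(N, n)``
    (complement of :func:`p_detect`).  With ``use_bound=True``, the
    exponential upper bound is returned instead.
    """
    (rho,) = _validate(N, n, [rho])
    if use_bound:
        x = rho * n / N
        return float(np.exp(-x) * (1.0 + x * np.exp(rho / N)))
    if _exact_feasible(N, n):
        num = math.comb(N - rho, n - 1) * rho + math.comb(N - rho, n)
        return float(Fraction(num, math.comb(N, n)))
    return float(min(1.0, np.exp(_log_p_miss_one_exact(N, n, rho))))


def elementary_symmetric(values: Sequence[int]) -> list[int]:
    """Elementary symmetric polynomials ``[e_0, e_1, ..., e_m]`` of the
    given values, by the recurrence ``B[i][j] = B[i-1][j-1]*v_i +
    B[i-1][j]`` with base ``B[0][0] = 1`` (exact integer arithmetic)."""
    e = [1]
    for v in values:
        e = [1] + [e[j] + v * e[j - 1] for j in range(1, len(e))] + [v * e[-1]]
    return e


def p_miss_many(
    N: int, n: int, rho: Sequence[int], use_bound: bool = False
) -> float:
    """Probability that each of ``m`` disjoint clusters of the given
    sizes contributes at most one sequence to the sample (all missed).

    Reduces to :func:`p_miss_one` for a single size.  With
    ``use_bound=True``, returns the exponential upper bound driven by the
    smallest size.
    """
    rho_t = _validate(N, n, rho)
    rho_sorted = tuple(sorted(rho_t))
    m = len(rho_sorted)
    if use_bound:
        rho1 = rho_sorted[0]
        x = rho1 * n / N
        return float(np.exp(-m * x) * (1.0 + x * np.exp(m * rho1 / N)) ** m)
    S = sum(rho_sorted)
    e = elementary_symmetric(rho_sorted)
    if _exact_feasible(N, n):
        num = sum(
            e[i] * math.comb(N - S, n - i) for i in range(m + 1) if n - i >= 0
        )
        return float(Fraction(num, math.comb(N, n)))
    i = np.arange(0, m + 1)
    log_terms = _log_binom(N - S, n - i) - _log_binom(N, n)
    with np.errstate(divide="ignore"):
        log_e = np.array([float(np.log(v)) if v > 0 else -np.inf for v in e])
    log_terms = log_terms + log_e
    finite = log_terms[np.isfinite(log_terms)]
    if finite.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(finite))))


# ---------------------------------------------------------------------------
# coin-flip simulator


@dataclass(frozen=True)
class SimulationRound:
    """Per-round bookkeeping of the coin-flip simulation."""

    round: int
    n_sampled: int
    detected_sizes: tuple[int, ...]
    entropy_bits: float
    largest_detected: int
    remaining_unclustered: int
    remaining_clusters: int


def sample_cluster_sizes(
    distribution: str,
    n_clusters: int,
    rng: np.random.Generator,
    **params,
) -> np.ndarray:
    """Draw non-singleton cluster sizes (>= 2) from a named distribution.

    ``geometric`` (param ``p``), ``uniform`` (``low``, ``high``,
    inclusive) or ``normal`` (``mu``, ``sigma``; truncated at 2 by
    resampling).
    """
    if distribution == "geometric":
        sizes = rng.geometric(params["p"], size=n_clusters) + 1
    elif distribution == "uniform":
        sizes = rng.integers(
            max(2, int(params["low"])), int(params["high"]) + 1, size=n_clusters
        )
    elif distribution == "normal":
        mu, sigma = params["mu"], params["sigma"]
        sizes = np.empty(n_clusters, dtype=np.int64)
        filled = 0
        while filled < n_clusters:
            draw = np.rint(rng.normal(mu, sigma, size=n_clusters)).astype(np.int64)
            draw = draw[draw >= 2]
            take = min(draw.size, n_clusters - filled)
            sizes[filled : filled + take] = draw[:take]
            filled += take
    else:
        raise ValueError(f"unknown size distribution {distribution!r}")
    return np.maximum(sizes, 2).astype(np.int64)


def simulate_iterations(
    sizes: Sequence[int],
    singleton_fraction: float = 0.20,
    alpha: float = 0.001,
    seed: int = 0,
    max_rounds: int = 100,
) -> list[SimulationRound]:
    """Sequence-free simulation of the iterative clustering loop.

    ``sizes`` are the non-singleton cluster sizes.  Singletons are added
    so that they make up ``singleton_fraction`` of the total pool; being
    undetectable (a sample can never contain two of their members), they
    only dilute the pool.  Each round draws ``n = max(2, round(alpha *
    N))`` and flips, for every remaining cluster, a biased coin with
    success probability ``p_detect(N, n, rho)``; detected clusters are
    removed and N decremented by their sizes.  Stops when no non-
    singleton cluster remains or after ``max_rounds``.
    """
    sizes_arr = np.asarray(list(sizes), dtype=np.int64)
    if sizes_arr.size and sizes_arr.min() < 1:
        raise ValueError("cluster sizes must be positive")
    if not 0.0 <= singleton_fraction < 1.0:
        raise ValueError("singleton_fraction must be in [0, 1)")
    mass = int(sizes_arr.sum())
    n_singletons = int(round(singleton_fraction * mass / (1.0 - singleton_fraction)))
    N = mass + n_singletons
    rng = np.random.default_rng(seed)
    remaining = sizes_arr.copy()
    rounds: list[SimulationRound] = []
    for rnd in range(1, max_rounds + 1):
        if remaining.size == 0 or N < 2:
            break
        n = max(2, int(round(alpha * N)))
        n = min(n, N)
        p = 1.0 - np.exp(_log_p_miss_one_exact(N, n, remaining))
        p = np.clip(p, 0.0, 1.0)
        hit = rng.random(remaining.size) < p
        detected = remaining[hit]
        detected_sizes = tuple(int(s) for s in np.sort(detected)[::-1])
        N -= int(detected.sum())
        remaining = remaining[~hit]
        rounds.append(
            SimulationRound(
                round=rnd,
                n_sampled=n,
                detected_sizes=detected_sizes,
                entropy_bits=size_entropy(detected_sizes),
                largest_detected=int(detected.max()) if detected.size else 0,
                remaining_unclustered=N,
                remaining_clusters=int(remaining.size),
            )
        )
        if remaining.size == 0:
            break
    return rounds
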