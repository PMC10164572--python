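"""The iterative sample-cluster-recruit loop.

Each iteration:

1. draw a uniform subsample of the unclustered pool (rate ``alpha``);
2. greedy-cluster the subsample at the similarity threshold;
3. keep only non-singleton subsample clusters (a cluster needs two
   sampled members to be *detected*); subsample singletons return to the
   pool — they may belong to clusters that will surface later;
4. use the kept representatives as baits to recruit the entire pool;
5. optionally *mode-shift*: move each cluster's representative to its
   highest-multiplicity member (the presumed error-free parent
   sequence) and repeat the baiting against the shifted
   representatives, letting sequences change cluster and dropping those
   that fall outside every radius back into the pool;
6. remove finally clustered sequences from the pool, record statistics;
7. optionally adapt ``alpha`` upward when the iteration clustered fewer
   sequences than the previous one.

The loop stops when no cluster at least as large as
``convergence_size`` has been found for ``convergence_window``
consecutive iterations, when the pool is exhausted, or at
``max_iterations``.  With ``adapt=False`` and ``mode_shift=False`` the
engine is the naive fixed-rate baseline.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .align import Cluster, SimilaritySpec, bait, greedy_cluster
from .metrics import size_entropy
from .records import Dataset, SequenceRecord

__all__ = [
    "EngineConfig",
    "IterationStats",
    "SamplingState",
    "RunResult",
    "sample_pool",
    "run_iteration",
    "mode_shift_cluster",
    "update_alpha",
    "has_converged",
    "run",
]


@dataclass(frozen=True)
class EngineConfig:
    """Engine parameters.

    alpha0 : initial sampling rate n/N.
    adapt : grow alpha when productivity drops (up to ``alpha_max``),
        by ``adapt_gamma`` times the relative drop in sequences
        clustered.
    mode_shift : re-centre clusters on their highest-multiplicity
        member and re-bait (``mode_shift_rounds`` times).
    min_cluster_report_size : smallest distinct size a cluster may have
        in the final report; smaller remnants dissolve back to the pool.
    convergence_window / convergence_size : stop once no cluster of at
        least ``convergence_size`` has appeared in this many consecutive
        iterations.
    size_mode : ``"total"`` (multiplicity-weighted, default) or
        ``"distinct"`` — the scale used for reported cluster sizes,
        entropy and convergence.
    weighted_sampling : sample records proportionally to multiplicity
        instead of uniformly over distinct records.
    """

    similarity: SimilaritySpec
    alpha0: float = 0.001
    adapt: bool = True
    adapt_gamma: float = 1.0
    alpha_max: float = 0.05
    mode_shift: bool = True
    mode_shift_rounds: int = 1
    max_iterations: int = 50
    min_cluster_report_size: int = 2
    convergence_window: int = 5
    convergence_size: int = 10
    size_mode: str = "total"
    weighted_sampling: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha0 <= self.alpha_max <= 1.0:
            raise ValueError(
                f"need 0 < alpha0 <= alpha_max <= 1, got "
                f"alpha0={self.alpha0}, alpha_max={self.alpha_max}"
            )
        if self.adapt_gamma <= 0 or self.adapt_gamma > 1:
            raise ValueError("adapt_gamma must be in (0, 1]")
        if self.size_mode not in ("total", "distinct"):
            raise ValueError(f"unknown size_mode {self.size_mode!r}")
        if self.mode_shift_rounds < 1:
            raise ValueError("mode_shift_rounds must be >= 1")


@dataclass(frozen=True)
class IterationStats:
    """Per-iteration record of the clustering progress."""

    iteration: int
    alpha_used: float
    n_sampled: int
    n_sampled_total: int
    clusters_found: int
    sequences_clustered: int
    sequences_clustered_distinct: int
    largest_cluster: int
    entropy_bits: float
    elapsed_s: float
    pool_start: int
    pool_start_total: int
    cluster_sizes: tuple[int, ...]
    cluster_sizes_distinct: tuple[int, ...]


@dataclass
class SamplingState:
    """Live state of a run: the unclustered pool, the current sampling
    rate and the iteration history."""

    pool: list[SequenceRecord]
    alpha: float
    rng_seed: int
    iteration: int = 0
    history: list[IterationStats] = field(default_factory=list)

    @property
    def pool_distinct(self) -> int:
        return len(self.pool)

    @property
    def pool_total(self) -> int:
        return sum(r.multiplicity for r in self.pool)


def _iteration_rng(state: SamplingState) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=state.rng_seed, spawn_key=(state.iteration,))
    )


def sample_pool(
    state: SamplingState, weighted: bool = False
) -> list[SequenceRecord]:
    """Draw ``max(2, round(alpha * N))`` distinct records uniformly
    without replacement (or multiplicity-weighted when ``weighted``),
    deterministically from the state's seed and iteration index."""
    N = len(state.pool)
    if N < 2:
        raise ValueError("pool has fewer than 2 records; nothing to sample")
    n = min(N, max(2, int(round(state.alpha * N))))
    rng = _iteration_rng(state)
    if weighted:
        mults = np.array([r.multiplicity for r in state.pool], dtype=float)
        idx = rng.choice(N, size=n, replace=False, p=mults / mults.sum())
    else:
        idx = rng.choice(N, size=n, replace=False)
    return [state.pool[i] for i in sorted(idx)]


def _mode_shift_rep(cluster: Cluster) -> SequenceRecord:
    """Highest-multiplicity member; ties broken by longer sequence, then
    lexicographically smaller bases (deterministic)."""
    return max(
        (r for r, _ in cluster.members),
        key=lambda r: (r.multiplicity, len(r.bases), _ReversedStr(r.bases)),
    )


class _ReversedStr(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def mode_shift_cluster(
    cluster: Cluster,
    pool: list[SequenceRecord],
    spec: SimilaritySpec,
    rounds: int = 1,
) -> tuple[Cluster, list[SequenceRecord]]:
    """Re-centre one cluster on its highest-multiplicity member.

    The membership is recomputed by baiting the union of the old members
    and ``pool`` against the new representative; old members now outside
    the radius are returned as *released* (they belong back in the
    unclustered pool).  Repeated ``rounds`` times; a cluster whose
    representative is already the mode is a fixed point.
    """
    if not cluster.members:
        raise ValueError("cannot mode-shift an empty cluster")
    current = cluster
    extra = list(pool)
    released_ids: set[str] = set()
    original_ids = cluster.member_ids()
    for _ in range(rounds):
        new_rep = _mode_shift_rep(current)
        candidates = [r for r, _ in current.members if r.id != new_rep.id]
        candidates += [
            r for r in extra
            if r.id != new_rep.id and r.id not in {c.id for c in candidates}
        ]
        [shifted], leftover = bait([new_rep], candidates, spec)
        current = shifted
        member_ids = current.member_ids()
        released_ids = (original_ids - member_ids)
        extra = [r for r in leftover if r.id not in original_ids]
    by_id = {r.id: r for r, _ in cluster.members}
    released = [by_id[i] for i in sorted(released_ids)]
    return current, released


def update_alpha(
    state: SamplingState,
    config: EngineConfig,
    prev_clustered: int,
    cur_clustered: int,
) -> float:
    """Adaptive sampling-rate update.

    When the current iteration clustered fewer sequences than the
    previous one, alpha grows by ``adapt_gamma`` times the relative
    drop, capped at ``alpha_max``; otherwise it is unchanged.
    """
    if cur_clustered >= prev_clustered:
        return state.alpha
    rel_drop = (prev_clustered - cur_clustered) / max(prev_clustered, 1)
    return min(config.alpha_max, state.alpha * (1.0 + config.adapt_gamma * rel_drop))


def has_converged(history: list[IterationStats], config: EngineConfig) -> bool:
    """True once no cluster of size >= ``convergence_size`` (on the
    configured size scale) has been found in the last
    ``convergence_window`` iterations, or at ``max_iterations``."""
    if len(history) >= config.max_iterations:
        return True
    if len(history) < config.convergence_window:
        return False
    recent = history[-config.convergence_window:]
    return all(
        all(s < config.convergence_size for s in st.cluster_sizes)
        for st in recent
    )


def run_iteration(
    state: SamplingState, config: EngineConfig
) -> tuple[list[Cluster], SamplingState]:
    """Execute one full iteration, mutating and returning ``state``.

    Returns the clusters finalised this iteration; the pool shrinks by
    exactly their distinct membership (sequence conservation).
    """
    t0 = time.perf_counter()
    spec = config.similarity
    pool_start = len(state.pool)
    pool_start_total = state.pool_total

    sample = sample_pool(state, weighted=config.weighted_sampling)
    sample_clusters = greedy_cluster(sample, spec)
    kept = [c for c in sample_clusters if c.distinct_size >= 2]

    final: list[Cluster] = []
    if kept:
        reps = [c.representative for c in kept]
        clusters, leftover = bait(reps, state.pool, spec)
        if config.mode_shift:
            for _ in range(config.mode_shift_rounds):
                shifted_reps = []
                seen_rep_ids: set[str] = set()
                for cl in clusters:
                    rep = _mode_shift_rep(cl)
                    if rep.id not in seen_rep_ids:
                        seen_rep_ids.add(rep.id)
                        shifted_reps.append(rep)
                # everything clustered this iteration plus the leftover
                # competes again against the shifted representatives
                candidates: list[SequenceRecord] = list(leftover)
                cand_ids = {r.id for r in leftover}
                for cl in clusters:
                    for r, _ in cl.members:
                        if r.id not in cand_ids:
                            cand_ids.add(r.id)
                            candidates.append(r)
                clusters, leftover = bait(shifted_reps, candidates, spec)
        # dissolve sub-minimum remnants back into the pool
        final = []
        for cl in clusters:
            if cl.distinct_size >= max(2, config.min_cluster_report_size):
                final.append(cl)
            else:
                for r, _ in cl.members:
                    leftover.append(r)
        clustered_ids = set()
        for cl in final:
            clustered_ids |= cl.member_ids()
        state.pool = [r for r in state.pool if r.id not in clustered_ids]
    sizes_total = tuple(sorted((c.total_size for c in final), reverse=True))
    sizes_distinct = tuple(sorted((c.distinct_size for c in final), reverse=True))
    sizes_mode = sizes_total if config.size_mode == "total" else sizes_distinct

    stats = IterationStats(
        iteration=state.iteration,
        alpha_used=state.alpha,
        n_sampled=len(sample),
        n_sampled_total=sum(r.multiplicity for r in sample),
        clusters_found=len(final),
        sequences_clustered=sum(sizes_total),
        sequences_clustered_distinct=sum(sizes_distinct),
        largest_cluster=max(sizes_mode, default=0),
        entropy_bits=size_entropy(sizes_mode),
        elapsed_s=time.perf_counter() - t0,
        pool_start=pool_start,
        pool_start_total=pool_start_total,
        cluster_sizes=sizes_mode,
        cluster_sizes_distinct=sizes_distinct,
    )
    state.history.append(stats)
    state.iteration += 1
    return final, state


@dataclass
class RunResult:
    """Outcome of a full run: the clusters, final state and history."""

    clusters: list[Cluster]
    state: SamplingState
    config: EngineConfig

    @property
    def history(self) -> list[IterationStats]:
        return self.state.history

    def cluster_sizes(self, mode: str | None = None) -> list[int]:
        mode = mode or self.config.size_mode
        return [c.size(mode) for c in self.clusters]


def run(dataset: Dataset, config: EngineConfig, seed: int = 0) -> RunResult:
    """Cluster a deduplicated dataset with the iterative engine."""
    state = SamplingState(
        pool=list(dataset), alpha=config.alpha0, rng_seed=seed
    )
    all_clusters: list[Cluster] = []
    while len(state.pool) >= 2 and not has_converged(state.history, config):
        new_clusters, state = run_iteration(state, config)
        all_clusters.extend(new_clusters)
        if config.adapt and len(state.history) >= 2:
            state.alpha = update_alpha(
                state,
                config,
                prev_clustered=state.history[-2].sequences_clustered,
                cur_clustered=state.history[-1].sequences_clustered,
            )
    return RunResult(clusters=all_clusters, state=state, config=config)
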