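"""The iterative sample-cluster-recruit engine."""

import numpy as np
import pytest

from iterotu.align import Cluster, SimilaritySpec, similarity
from iterotu.engine import (
    EngineConfig,
    SamplingState,
    has_converged,
    mode_shift_cluster,
    run,
    run_iteration,
    sample_pool,
    update_alpha,
)
from iterotu.records import Dataset, SequenceRecord
from iterotu.simulate import (
    CommunitySpec,
    generate_community,
    perturb_representative,
)


def _config(**kw):
    base = dict(
        similarity=SimilaritySpec(0.97),
        alpha0=0.05,
        max_iterations=25,
    )
    base.update(kw)
    base.setdefault("alpha_max", max(0.05, base["alpha0"]))
    return EngineConfig(**base)


def _state(records, alpha=0.05, seed=0):
    return SamplingState(pool=list(records), alpha=alpha, rng_seed=seed)


def _random_records(n, length=120, seed=0):
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), size=length)))
        for i in range(n)
    ]


class TestSamplePool:
    def test_floor_guard_of_two(self):
        st = _state(_random_records(1000), alpha=0.001)
        assert len(sample_pool(st)) == 2

    def test_sample_size_arithmetic(self):
        st = _state(_random_records(500), alpha=0.1)
        assert len(sample_pool(st)) == 50

    def test_deterministic_under_seed_and_iteration(self):
        st1 = _state(_random_records(200), alpha=0.1, seed=7)
        st2 = _state(_random_records(200), alpha=0.1, seed=7)
        assert [r.id for r in sample_pool(st1)] == [r.id for r in sample_pool(st2)]
        st1.iteration = 1
        assert [r.id for r in sample_pool(st1)] != [r.id for r in sample_pool(st2)]

    def test_tiny_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_pool(_state(_random_records(1)))


class TestUpdateAlpha:
    def test_unchanged_without_drop(self):
        st = _state([], alpha=0.001)
        assert update_alpha(st, _config(), 1000, 1000) == 0.001
        assert update_alpha(st, _config(), 1000, 1500) == 0.001

    def test_grows_by_relative_drop(self):
        st = _state([], alpha=0.001)
        cfg = _config(adapt_gamma=1.0, alpha_max=0.05, alpha0=0.001)
        assert update_alpha(st, cfg, 1000, 500) == pytest.approx(0.0015)

    def test_monotone_and_capped(self):
        cfg = _config(adapt_gamma=1.0, alpha_max=0.05, alpha0=0.001)
        st = _state([], alpha=0.001)
        rng = np.random.default_rng(0)
        alpha = st.alpha
        for _ in range(100):
            prev, cur = rng.integers(0, 1000, size=2)
            st.alpha = update_alpha(st, cfg, int(prev), int(cur))
            assert st.alpha >= alpha - 1e-15
            assert st.alpha <= cfg.alpha_max
            alpha = st.alpha


class TestConvergence:
    def _stats(self, sizes):
        from iterotu.engine import IterationStats

        return IterationStats(
            iteration=0, alpha_used=0.01, n_sampled=2, n_sampled_total=2,
            clusters_found=len(sizes), sequences_clustered=sum(sizes),
            sequences_clustered_distinct=sum(sizes), largest_cluster=max(sizes, default=0),
            entropy_bits=0.0, elapsed_s=0.0, pool_start=100, pool_start_total=100,
            cluster_sizes=tuple(sizes), cluster_sizes_distinct=tuple(sizes),
        )

    def test_quiet_window_converges(self):
        cfg = _config(convergence_window=3, convergence_size=10)
        history = [self._stats([50]), self._stats([]), self._stats([2]), self._stats([9])]
        assert has_converged(history, cfg)

    def test_large_cluster_in_window_blocks_convergence(self):
        cfg = _config(convergence_window=3, convergence_size=10)
        history = [self._stats([]), self._stats([50]), self._stats([])]
        assert not has_converged(history, cfg)

    def test_short_history_never_converged(self):
        cfg = _config(convergence_window=5)
        assert not has_converged([self._stats([])], cfg)


class TestModeShift:
    def _cluster(self, records, rep_idx=0):
        rep = records[rep_idx]
        members = [(r, similarity(r.bases, rep.bases)) for r in records]
        return Cluster(representative=rep, members=members)

    def test_mode_representative_is_fixed_point(self, spec097):
        seq = "ACGT" * 30
        rep = SequenceRecord("a", seq, multiplicity=10)
        other = SequenceRecord("b", seq[:-1] + "T", multiplicity=1)
        cl = self._cluster([rep, other])
        shifted, released = mode_shift_cluster(cl, [], spec097)
        assert shifted.representative.id == "a"
        assert not released
        assert shifted.member_ids() == cl.member_ids()

    def test_shifts_to_highest_multiplicity_member(self, spec097):
        seq = "ACGT" * 30
        peripheral = SequenceRecord("p", seq[:-2] + "TT", multiplicity=1)
        centroid = SequenceRecord("c", seq, multiplicity=10)
        cl = self._cluster([peripheral, centroid], rep_idx=0)
        shifted, _ = mode_shift_cluster(cl, [], spec097)
        assert shifted.representative.id == "c"

    def test_member_outside_new_radius_is_released(self):
        # chain: member m sits exactly at the radius of old rep o but
        # beyond the radius of the new high-multiplicity rep c
        spec = SimilaritySpec(0.97)
        L = 100
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list("ACGT"), size=L))

        def mutate(s, positions):
            out = list(s)
            for p in positions:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        old_rep = SequenceRecord("o", base, multiplicity=2)
        member = SequenceRecord("m", mutate(base, [0, 10, 20]), multiplicity=1)
        new_rep = SequenceRecord("c", mutate(base, [50, 60, 70]), multiplicity=10)
        assert similarity(member.bases, old_rep.bases) == pytest.approx(0.97)
        assert similarity(member.bases, new_rep.bases) < 0.97
        cl = self._cluster([old_rep, member, new_rep], rep_idx=0)
        shifted, released = mode_shift_cluster(cl, [], spec)
        assert shifted.representative.id == "c"
        assert [r.id for r in released] == ["m"]

    def test_perturbed_seed_recovers_planted_centroid(self, spec097):
        spec = CommunitySpec(
            n_clusters=1, distribution="uniform",
            dist_params={"low": 30, "high": 30}, singleton_fraction=0.0,
            seed=4,
        )
        ds, gt = generate_community(spec)
        cid = next(iter(gt.centroids))
        pert = perturb_representative(ds, gt, cid, seed=1, threshold=0.97)
        from iterotu.align import greedy_cluster

        clusters = greedy_cluster(list(pert.dataset), spec097)
        seed_cluster = clusters[0]
        assert seed_cluster.representative.id == pert.member_id
        shifted, _ = mode_shift_cluster(seed_cluster, [], spec097)
        assert shifted.representative.bases == gt.centroids[cid].bases


class TestRunIteration:
    def test_planted_cluster_detected_and_removed(self):
        spec = CommunitySpec(
            n_clusters=1, distribution="uniform",
            dist_params={"low": 200, "high": 200}, singleton_fraction=0.0,
            seed=8,
        )
        ds, gt = generate_community(spec)
        st = _state(list(ds), alpha=0.1, seed=5)
        clusters, st = run_iteration(st, _config(alpha0=0.1))
        assert len(clusters) == 1
        assert clusters[0].total_size == 200
        assert len(st.pool) == 0

    def test_all_singleton_pool_unchanged(self):
        records = _random_records(40, seed=3)
        st = _state(records, alpha=0.5)
        clusters, st = run_iteration(st, _config(alpha0=0.5))
        assert clusters == []
        assert len(st.pool) == 40

    def test_sequence_conservation_through_run(self, small_community):
        ds, _, _ = small_community
        cfg = _config(alpha0=0.05, max_iterations=15)
        res = run(ds, cfg, seed=2)
        clustered_d = sum(c.distinct_size for c in res.clusters)
        clustered_t = sum(c.total_size for c in res.clusters)
        assert clustered_d + len(res.state.pool) == len(ds)
        assert clustered_t + res.state.pool_total == ds.total_raw
        # per-iteration ledger agrees
        for a, b in zip(res.history, res.history[1:]):
            assert a.pool_start - a.sequences_clustered_distinct == b.pool_start

    def test_no_reported_cluster_below_two_distinct(self, small_community):
        ds, _, _ = small_community
        res = run(ds, _config(alpha0=0.05, max_iterations=15), seed=2)
        assert all(c.distinct_size >= 2 for c in res.clusters)

    def test_members_within_radius_of_final_representative(self, small_community):
        ds, _, _ = small_community
        cfg = _config(alpha0=0.05, max_iterations=15)
        res = run(ds, cfg, seed=2)
        for c in res.clusters:
            for r, s in c.members:
                assert similarity(r.bases, c.representative.bases) >= cfg.similarity.threshold

    def test_deterministic_given_seed(self, small_community):
        ds, _, _ = small_community
        cfg = _config(alpha0=0.05, max_iterations=10)
        r1 = run(ds, cfg, seed=9)
        r2 = run(ds, cfg, seed=9)
        key = lambda res: [
            (c.representative.id, sorted(r.id for r, _ in c.members))
            for c in res.clusters
        ]
        assert key(r1) == key(r2)
        assert [s.n_sampled for s in r1.history] == [s.n_sampled for s in r2.history]


class TestNaiveBaseline:
    def test_naive_flags_disable_adaptation_and_shifting(self, small_community):
        ds, _, _ = small_community
        cfg = _config(alpha0=0.02, adapt=False, mode_shift=False, max_iterations=10)
        res = run(ds, cfg, seed=3)
        assert all(s.alpha_used == 0.02 for s in res.history)

    def test_adaptive_mode_shift_clusters_at_least_naive(self, small_community):
        # cumulative recruitment under the full strategy is at least the
        # naive fixed-rate baseline for nearly all seeds
        ds, _, _ = small_community
        wins = 0
        for seed in range(6):
            full = run(ds, _config(alpha0=0.005, max_iterations=12,
                                   convergence_window=999), seed=seed)
            naive = run(ds, _config(alpha0=0.005, adapt=False, mode_shift=False,
                                    max_iterations=12, convergence_window=999),
                        seed=seed)
            c_full = sum(c.total_size for c in full.clusters)
            c_naive = sum(c.total_size for c in naive.clusters)
            wins += c_full >= c_naive
        assert wins >= 5
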