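"""Fixed-radius clustering kernel: similarity, greedy seeding, baiting.

The similarity between two sequences is::

    similarity = 1 - d / len(shorter)

where ``d`` is the minimum edit distance over semiglobal alignments that
are anchored at position 0 of both sequences, with gaps free at the *end*
of either sequence (the DP minimum over the last row and last column).
This is the convention used by radius-based OTU clustering tools: a
shorter amplicon that is a prefix of a longer one is a perfect match.

Two clustering operations are built on this measure:

* :func:`greedy_cluster` — CD-HIT-style greedy incremental clustering of
  a (sub)sample, processing sequences in decreasing length order; each
  sequence joins the first existing cluster whose representative it
  matches at or above the threshold, else seeds a new cluster.
* :func:`bait` — recruitment of a sequence pool to a *fixed* set of
  representatives; each pool sequence within the radius of at least one
  representative is assigned to the best-matching one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .records import SequenceRecord

__all__ = [
    "SimilaritySpec",
    "Cluster",
    "similarity",
    "semiglobal_distance",
    "greedy_cluster",
    "bait",
]


@dataclass(frozen=True)
class SimilaritySpec:
    """Cluster radius definition.

    threshold : fraction in (0, 1); a sequence belongs to a cluster iff
        its similarity to the representative is >= threshold.
    end_gap_policy : only ``"free_trailing"`` is defined — gaps are free
        at sequence ends and forbidden at beginnings.
    """

    threshold: float
    end_gap_policy: str = "free_trailing"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        if self.end_gap_policy != "free_trailing":
            raise ValueError(f"unknown end_gap_policy {self.end_gap_policy!r}")

    def max_distance(self, shorter_len: int) -> int:
        """Largest edit distance still within the radius for a pair whose
        shorter sequence has the given length."""
        return math.floor((1.0 - self.threshold) * shorter_len)


@dataclass
class Cluster:
    """A representative sequence plus its recruited members.

    ``members`` always includes the representative itself (similarity 1).
    ``distinct_size`` counts deduplicated records; ``total_size`` weights
    each member by its multiplicity (raw-read scale).
    """

    representative: SequenceRecord
    members: list[tuple[SequenceRecord, float]] = field(default_factory=list)

    @property
    def distinct_size(self) -> int:
        return len(self.members)

    @property
    def total_size(self) -> int:
        return sum(r.multiplicity for r, _ in self.members)

    def size(self, mode: str = "total") -> int:
        if mode == "total":
            return self.total_size
        if mode == "distinct":
            return self.distinct_size
        raise ValueError(f"unknown size mode {mode!r}")

    def member_ids(self) -> set[str]:
        return {r.id for r, _ in self.members}


def _dp_semiglobal(a: str, b: str) -> int:
    """Unit-cost semiglobal edit distance by full dynamic programming.

    Both sequences are anchored at position 0; the distance is the
    minimum over the last row and last column of the DP matrix, so
    trailing gaps on either sequence are free.  ``N`` mismatches every
    character, including another ``N``.
    """
    la, lb = len(a), len(b)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    b_is_n = bv == ord("N")
    prev = np.arange(lb + 1)
    best_last_col = prev[lb]
    for i in range(1, la + 1):
        ca = a[i - 1]
        if ca == "N":
            sub_cost = np.ones(lb, dtype=prev.dtype)
        else:
            sub_cost = ((bv != ord(ca)) | b_is_n).astype(prev.dtype)
        cur = np.empty(lb + 1, dtype=prev.dtype)
        cur[0] = i
        diag = prev[:-1] + sub_cost
        up = prev[1:] + 1
        np.minimum(diag, up, out=cur[1:])
        # left-dependency needs a sequential pass
        run = np.minimum.accumulate(cur - np.arange(lb + 1))
        cur = np.minimum(cur, run + np.arange(lb + 1))
        prev = cur
        if cur[lb] < best_last_col:
            best_last_col = cur[lb]
    return int(min(prev.min(), best_last_col))


def semiglobal_distance(a: str, b: str, k: int | None = None) -> int:
    """Semiglobal (free-trailing-gap) unit-cost edit distance.

    Uses edlib's prefix mode in both orientations, which realises the
    minimum over the DP last row and last column.  If ``k`` is given and
    the distance exceeds it, returns ``k + 1`` (a cheap band-limited
    rejection).  Sequences containing ``N`` take a full-DP path in which
    ``N`` matches nothing.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if "N" in a or "N" in b:
        d = _dp_semiglobal(a, b)
        return d if k is None or d <= k else k + 1
    kk = -1 if k is None else k
    r1 = edlib.align(a, b, mode="SHW", task="distance", k=kk)["editDistance"]
    r2 = edlib.align(b, a, mode="SHW", task="distance", k=kk)["editDistance"]
    if r1 == -1 and r2 == -1:
        return (k or 0) + 1
    cands = [d for d in (r1, r2) if d != -1]
    return min(cands)


def similarity(a: str, b: str, spec: SimilaritySpec | None = None) -> float:
    """Similarity ``1 - d/len(shorter)``, clamped at 0.

    ``spec`` is accepted for interface symmetry; the measure itself does
    not depend on the threshold.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    shorter = min(len(a), len(b))
    d = semiglobal_distance(a, b)
    return max(0.0, 1.0 - d / shorter)


def _similarity_if_within(a: str, b: str, spec: SimilaritySpec) -> float | None:
    """Similarity if >= spec.threshold, else None (band-limited)."""
    shorter = min(len(a), len(b))
    kmax = spec.max_distance(shorter)
    d = semiglobal_distance(a, b, k=kmax)
    if d > kmax:
        return None
    return 1.0 - d / shorter


def _greedy_order(records: list[SequenceRecord]) -> list[SequenceRecord]:
    # decreasing length, ties: decreasing multiplicity, then id
    return sorted(records, key=lambda r: (-len(r.bases), -r.multiplicity, r.id))


def greedy_cluster(
    sample: list[SequenceRecord], spec: SimilaritySpec
) -> list[Cluster]:
    """Greedy incremental fixed-radius clustering.

    Sequences are processed in decreasing length order (ties broken by
    decreasing multiplicity, then id).  Each sequence joins the *first*
    existing cluster whose representative it matches at >= threshold,
    else it seeds a new cluster.  Singleton clusters are returned too.
    """
    if not sample:
        raise ValueError("sample must be non-empty")
    clusters: list[Cluster] = []
    for rec in _greedy_order(list(sample)):
        placed = False
        for cl in clusters:
            s = _similarity_if_within(rec.bases, cl.representative.bases, spec)
            if s is not None:
                cl.members.append((rec, s))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec, members=[(rec, 1.0)]))
    return clusters


def bait(
    representatives: list[SequenceRecord],
    pool: list[SequenceRecord],
    spec: SimilaritySpec,
) -> tuple[list[Cluster], list[SequenceRecord]]:
    """Recruit pool sequences to fixed representatives ("baiting").

    Every pool sequence within the radius of at least one representative
    is assigned to exactly one cluster: the representative with the
    highest similarity, ties broken by larger representative
    multiplicity, then lexicographic representative id.  Unrecruited
    sequences are returned as the leftover pool.

    A representative that also appears in the pool is assigned to its own
    cluster (similarity 1 beats any tie).
    """
    if not representatives:
        raise ValueError("representative set must be non-empty")
    clusters = [Cluster(representative=r, members=[]) for r in representatives]
    rep_ids = {r.id: i for i, r in enumerate(representatives)}
    leftover: list[SequenceRecord] = []
    for rec in pool:
        if rec.id in rep_ids:
            ci = rep_ids[rec.id]
            clusters[ci].members.append((rec, 1.0))
            continue
        best: tuple[float, int, str, int] | None = None
        for ci, rep in enumerate(representatives):
            s = _similarity_if_within(rec.bases, rep.bases, spec)
            if s is None:
                continue
            key = (s, rep.multiplicity, _NegStr(rep.id), ci)
            if best is None or key > best:
                best = key
        if best is None:
            leftover.append(rec)
        else:
            clusters[best[3]].members.append((rec, best[0]))
    # representatives not present in the pool still anchor their clusters
    for cl in clusters:
        if cl.representative.id not in cl.member_ids():
            cl.members.insert(0, (cl.representative, 1.0))
    return clusters, leftover


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the
    lexicographically smallest id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
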