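"""Synthetic deduplicated amplicon communities with ground truth.

The generator emulates the statistical structure of a dereplicated 16S
amplicon data set: a set of well-separated cluster centroids, cluster
sizes (raw-read mass) drawn from a chosen distribution, a configurable
fraction of each cluster's mass present as exact centroid copies (so the
centroid carries the highest multiplicity), remaining members derived
from the centroid by a bounded number of substitutions and indels, and a
stated fraction of the data set made up of singleton sequences unrelated
to any cluster.

Because centroids are mutually separated by more than the clustering
radius, the planted partition is the unique clustering at the chosen
threshold and serves as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .align import semiglobal_distance, similarity
from .prob import sample_cluster_sizes
from .records import Dataset, SequenceRecord

__all__ = [
    "CommunitySpec",
    "GroundTruth",
    "PerturbResult",
    "generate_community",
    "perturb_representative",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_MAX_REJECT = 200


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a planted community.

    ``distribution``/``dist_params`` name the non-singleton cluster-size
    law (``geometric``: p; ``uniform``: low, high; ``normal``: mu,
    sigma — truncated at 2).  Sizes are raw-read mass: a fraction
    ``centroid_mult_boost`` of each cluster's mass is emitted as exact
    centroid copies (one record with that multiplicity), the remainder
    as distinct mutated members of multiplicity 1.  ``singleton_fraction``
    of the final data set's mass consists of unrelated singletons.
    """

    n_clusters: int = 50
    distribution: str = "uniform"
    dist_params: Mapping[str, float] = field(
        default_factory=lambda: {"low": 5, "high": 50}
    )
    singleton_fraction: float = 0.20
    seq_length: int = 250
    similarity_threshold: float = 0.97
    centroid_mult_boost: float = 0.4
    separation_margin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.singleton_fraction < 1.0:
            raise ValueError("singleton_fraction must be in [0, 1)")
        if not 0.0 < self.similarity_threshold < 1.0:
            raise ValueError("similarity_threshold must be in (0, 1)")
        if not 0.0 <= self.centroid_mult_boost <= 1.0:
            raise ValueError("centroid_mult_boost must be in [0, 1]")
        if self.similarity_threshold - self.separation_margin <= 0.5:
            raise ValueError("threshold minus margin must exceed 0.5")

    @property
    def max_edits(self) -> int:
        return int((1.0 - self.similarity_threshold) * self.seq_length)


@dataclass
class GroundTruth:
    """Planted partition: member id -> cluster id, and the centroid
    record of each cluster."""

    assignments: dict[str, str]
    centroids: dict[str, SequenceRecord]

    def members_of(self, cluster_id: str) -> list[str]:
        return [m for m, c in self.assignments.items() if c == cluster_id]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _separated_seq(
    rng: np.random.Generator,
    length: int,
    others: list[str],
    max_sim: float,
) -> str:
    """A random sequence whose similarity to every sequence in
    ``others`` is below ``max_sim``."""
    kmax = int((1.0 - max_sim) * length)
    for _ in range(_MAX_REJECT):
        cand = _random_seq(rng, length)
        if all(semiglobal_distance(cand, o, k=kmax) > kmax for o in others):
            return cand
    raise RuntimeError(
        "could not generate a separated sequence; use a longer sequence "
        "length or fewer clusters"
    )


def _mutate(
    rng: np.random.Generator,
    centroid: str,
    n_edits: int,
    indel_prob: float = 0.1,
) -> str:
    """Apply ``n_edits`` random edits (substitutions; with probability
    ``indel_prob`` each, a 1-bp insertion or deletion)."""
    seq = list(centroid)
    for _ in range(n_edits):
        pos = int(rng.integers(0, len(seq)))
        r = rng.random()
        if r < indel_prob / 2 and len(seq) > 2:
            del seq[pos]
        elif r < indel_prob:
            seq.insert(pos, chr(_BASES[int(rng.integers(0, 4))]))
        else:
            old = seq[pos]
            choices = [b for b in "ACGT" if b != old]
            seq[pos] = choices[int(rng.integers(0, 3))]
    return "".join(seq)


def generate_community(spec: CommunitySpec) -> tuple[Dataset, GroundTruth]:
    """Generate a deduplicated community and its ground truth.

    Deterministic under ``spec.seed``.  Every member lies within the
    similarity radius of its centroid; every centroid pair (and every
    singleton) is separated by more than ``threshold -
    separation_margin``, so baiting with the true centroids recovers the
    planted partition exactly.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.seq_length
    thr = spec.similarity_threshold
    sep = thr - spec.separation_margin

    sizes = sample_cluster_sizes(
        spec.distribution, spec.n_clusters, rng, **dict(spec.dist_params)
    )

    centroid_seqs: list[str] = []
    for _ in range(spec.n_clusters):
        centroid_seqs.append(_separated_seq(rng, L, centroid_seqs, sep))

    records: list[SequenceRecord] = []
    assignments: dict[str, str] = {}
    centroids: dict[str, SequenceRecord] = {}
    seen_bases: set[str] = set(centroid_seqs)

    for ci, (cseq, mass) in enumerate(zip(centroid_seqs, sizes)):
        cid = f"C{ci:04d}"
        mass = int(mass)
        n_copies = max(1, int(round(spec.centroid_mult_boost * mass)))
        n_members = mass - n_copies
        crec = SequenceRecord(id=cid, bases=cseq, multiplicity=n_copies)
        records.append(crec)
        centroids[cid] = crec
        assignments[cid] = cid
        for j in range(n_members):
            mid = f"{cid}_m{j:04d}"
            for _ in range(_MAX_REJECT):
                e = int(rng.integers(1, max(2, spec.max_edits + 1)))
                bases = _mutate(rng, cseq, e)
                if bases in seen_bases:
                    continue
                if similarity(bases, cseq) >= thr:
                    break
            else:
                raise RuntimeError(
                    f"could not place a member within radius of {cid}"
                )
            seen_bases.add(bases)
            records.append(SequenceRecord(id=mid, bases=bases, multiplicity=1))
            assignments[mid] = cid

    mass_total = int(sizes.sum())
    n_singletons = int(
        round(
            spec.singleton_fraction * mass_total / (1.0 - spec.singleton_fraction)
        )
    )
    for j in range(n_singletons):
        bases = _separated_seq(rng, L, centroid_seqs, sep)
        seen_bases.add(bases)
        records.append(
            SequenceRecord(id=f"S{j:05d}", bases=bases, multiplicity=1)
        )

    return Dataset(records=records), GroundTruth(
        assignments=assignments, centroids=centroids
    )


@dataclass(frozen=True)
class PerturbResult:
    """A community with one cluster member lengthened so that greedy
    longest-first clustering seeds on it instead of the centroid."""

    dataset: Dataset
    member_id: str
    suffix: str


def perturb_representative(
    ds: Dataset,
    gt: GroundTruth,
    cluster_id: str,
    seed: int = 0,
    n_extra: int = 3,
    threshold: float | None = None,
) -> PerturbResult:
    """Lengthen one non-centroid member of ``cluster_id`` by random
    trailing bases so it becomes the longest sequence in its cluster
    (hence the greedy seed), while remaining within the similarity
    radius of the planted centroid (trailing bases are largely absorbed
    by the free end gaps; when ``threshold`` is given, candidates whose
    perturbed similarity would fall below it are skipped).
    """
    if cluster_id not in gt.centroids:
        raise ValueError(f"unknown cluster {cluster_id!r}")
    rng = np.random.default_rng(seed)
    centroid = gt.centroids[cluster_id]
    member_ids = [m for m in gt.members_of(cluster_id) if m != centroid.id]
    if not member_ids:
        raise ValueError(f"cluster {cluster_id!r} has no non-centroid member")
    by_id = ds.by_id()
    max_len = max(len(by_id[m]) for m in gt.members_of(cluster_id))
    for mid in rng.permutation(member_ids):
        rec = by_id[mid]
        suffix = _random_seq(rng, max_len - len(rec) + n_extra)
        new_bases = rec.bases + suffix
        if threshold is not None and similarity(new_bases, centroid.bases) < threshold:
            continue
        new_rec = SequenceRecord(
            id=rec.id, bases=new_bases, multiplicity=rec.multiplicity
        )
        new_records = [new_rec if r.id == mid else r for r in ds]
        return PerturbResult(
            dataset=Dataset(records=new_records), member_id=str(mid), suffix=suffix
        )
    raise RuntimeError(
        f"no member of {cluster_id!r} can be lengthened without leaving "
        "the similarity radius"
    )
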