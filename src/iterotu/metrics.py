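"""Clustering diagnostics: the fragmentation curve and size entropy.

The fragmentation curve reports, for every cluster size x, the total
number of sequences contained in clusters of size >= x, with singleton
clusters excluded.  It plays the role cumulative length statistics play
for genome assemblies: when two clusterings of the same data are
compared, the one whose curve lies higher is less fragmented.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "FragmentationCurve",
    "fragmentation",
    "size_entropy",
    "compare_fragmentation",
    "DominanceReport",
]


@dataclass(frozen=True)
class FragmentationCurve:
    """Ordered points ``(x, F(x))`` with x descending and F
    non-decreasing as x decreases; singletons are excluded."""

    points: tuple[tuple[int, int], ...]

    def value_at(self, x: int) -> int:
        """F(x) = total sequences in clusters of size >= x, for any x
        (step semantics): the F of the smallest curve size >= x, or 0
        if every curve size is smaller."""
        return _curve_value(self, x)

    def __len__(self) -> int:
        return len(self.points)


def fragmentation(cluster_sizes: Iterable[int]) -> FragmentationCurve:
    """Fragmentation curve of a multiset of cluster sizes.

    Singletons (size 1) are dropped; for each distinct remaining size x,
    ``F(x)`` is the total number of sequences in clusters of size >= x.
    """
    sizes = [int(s) for s in cluster_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    sizes = [s for s in sizes if s >= 2]
    counts = Counter(sizes)
    points: list[tuple[int, int]] = []
    running = 0
    for x in sorted(counts, reverse=True):
        running += x * counts[x]
        points.append((x, running))
    return FragmentationCurve(points=tuple(points))


def _curve_value(curve: FragmentationCurve, x: int) -> int:
    """F(x) for arbitrary x under step semantics: the total sequences in
    clusters of size >= x, i.e. the F of the smallest curve size >= x
    (0 if every curve size is < x)."""
    best = 0
    for s, f in curve.points:  # descending x, increasing F
        if s >= x:
            best = f
        else:
            break
    return best


@dataclass(frozen=True)
class DominanceReport:
    """Pointwise comparison of two fragmentation curves over the union
    of their x values."""

    a_dominates: bool
    b_dominates: bool
    crossings: tuple[int, ...]

    @property
    def verdict(self) -> str:
        if self.a_dominates and self.b_dominates:
            return "equal"
        if self.a_dominates:
            return "a_less_fragmented"
        if self.b_dominates:
            return "b_less_fragmented"
        return "curves_cross"


def compare_fragmentation(
    a: FragmentationCurve, b: FragmentationCurve
) -> DominanceReport:
    """Compare two curves pointwise over the union of their x values.

    ``a_dominates`` means F_a(x) >= F_b(x) everywhere (the clustering
    behind ``a`` is no more fragmented than ``b``); ``crossings`` lists
    the x values where the sign of F_a - F_b differs from a neighbouring
    x value.
    """
    xs = sorted({x for x, _ in a.points} | {x for x, _ in b.points})
    diffs = [_curve_value(a, x) - _curve_value(b, x) for x in xs]
    a_dom = all(d >= 0 for d in diffs)
    b_dom = all(d <= 0 for d in diffs)
    crossings = []
    for i in range(1, len(xs)):
        if (diffs[i - 1] > 0 > diffs[i]) or (diffs[i - 1] < 0 < diffs[i]):
            crossings.append(xs[i])
    return DominanceReport(
        a_dominates=a_dom, b_dominates=b_dom, crossings=tuple(crossings)
    )


def size_entropy(sizes: Sequence[int]) -> float:
    """Shannon entropy (bits) of the empirical distribution of cluster
    sizes; 0 for empty input or a single distinct size."""
    sizes = list(sizes)
    if not sizes:
        return 0.0
    counts = Counter(sizes)
    total = len(sizes)
    return -sum(
        (c / total) * math.log2(c / total) for c in counts.values()
    ) if len(counts) > 1 else 0.0
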