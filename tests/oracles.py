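"""Independent reference implementations used only as test oracles.

Deliberately naive: plain-Python dynamic programming and exhaustive
enumeration, kept separate from the package's own code paths.
"""

from __future__ import annotations

import itertools
from collections import Counter


def dp_semiglobal_distance(a: str, b: str) -> int:
    """Unit-cost edit distance, both sequences anchored at position 0,
    trailing gaps free on either sequence: the minimum over the last row
    and last column of the full DP matrix.  N matches nothing."""
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            eq = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            D[i][j] = min(
                D[i - 1][j - 1] + (0 if eq else 1),
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
            )
    return min(min(D[la]), min(D[i][lb] for i in range(la + 1)))


def dp_similarity(a: str, b: str) -> float:
    return max(0.0, 1.0 - dp_semiglobal_distance(a, b) / min(len(a), len(b)))


def enumerate_miss_probability(N: int, n: int, clusters: list[list[int]]) -> float:
    """Fraction of all C(N, n) samples containing at most one element
    from each listed cluster (clusters given as disjoint element lists
    drawn from range(N))."""
    total = 0
    missed = 0
    cluster_sets = [set(c) for c in clusters]
    for sample in itertools.combinations(range(N), n):
        total += 1
        s = set(sample)
        if all(len(s & c) <= 1 for c in cluster_sets):
            missed += 1
    return missed / total


def enumerate_detect_probability(N: int, n: int, cluster: list[int]) -> float:
    """Fraction of all C(N, n) samples containing >= 2 elements of the
    cluster."""
    total = 0
    hit = 0
    c = set(cluster)
    for sample in itertools.combinations(range(N), n):
        total += 1
        if len(set(sample) & c) >= 2:
            hit += 1
    return hit / total


def brute_force_fragmentation(sizes: list[int]) -> dict[int, int]:
    """F(x) for each distinct non-singleton size x by a double loop."""
    keep = [s for s in sizes if s >= 2]
    return {
        x: sum(s for s in keep if s >= x) for x in sorted(set(keep), reverse=True)
    }


def elementary_symmetric_bruteforce(values: list[int]) -> list[int]:
    """e_i by summing products over all i-subsets."""
    m = len(values)
    out = []
    for i in range(m + 1):
        tot = 0
        for combo in itertools.combinations(values, i):
            p = 1
            for v in combo:
                p *= v
            tot += p
        out.append(tot)
    return out
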