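# Methods

## The similarity measure

Two sequences are compared by unit-cost edit distance (match 0,
mismatch/insertion/deletion 1) over semiglobal alignments: both
sequences are anchored at position 0, and gaps are free at the *end* of
either sequence but forbidden at the beginning. Operationally the
distance is the minimum over the last row and last column of the full
dynamic-programming matrix, and

    similarity(a, b) = 1 − d / min(|a|, |b|),

clamped at 0. This is the convention of radius-based OTU clustering: a
shorter amplicon that is a prefix of a longer one scores 1.0, while a
shifted (left-trimmed) copy pays for every leading offset. The measure
is symmetric, but note it is not a metric — the short-sequence
denominator breaks the triangle inequality, which is why a cluster
guarantees member–representative similarity, not member–member
similarity.

The production path computes the distance with edlib (prefix mode in
both orientations, whose minimum equals the last-row/last-column
minimum), with a distance cutoff of ⌊(1−θ)·|shorter|⌋ so that
non-matching pairs are rejected in a narrow band. Sequences containing
`N` take a NumPy full-DP path in which `N` matches nothing, including
another `N` — the conservative reading of an ambiguous base call. The
test suite checks the production path against an independent plain
full-DP implementation on 1000 random pairs.

## Greedy clustering and baiting

`greedy_cluster` follows the classical longest-first greedy paradigm:
sequences in decreasing length order (ties: higher multiplicity, then
id), each joining the first existing cluster whose representative it
matches at ≥ θ, else seeding a new cluster. `bait` is the recruitment
primitive: given *fixed* representatives, every pool sequence within
radius of at least one of them is assigned to the best-matching one
(ties: higher representative multiplicity, then lexicographically
smaller representative id). Greedy uses first-fit because its clusters
are created sequentially; baiting uses best-fit because all baits
compete simultaneously.

## The iterative engine

Per iteration: sample n = max(2, round(αN)) distinct records uniformly
without replacement (the floor of 2 keeps a two-member cluster
detectable at any α); greedy-cluster the subsample; return subsample
singletons to the pool (they may pair up in a later draw) and keep
non-singleton representatives; bait the entire pool with them. With
mode shifting enabled, each cluster's representative then moves to its
highest-multiplicity member (ties: longer sequence, then
lexicographically smaller bases — fully deterministic), and one global
re-bait pass reassigns everything clustered this iteration plus the
leftover pool against the shifted representatives. Sequences that fall
outside every radius return to the pool, as do the members of any
remnant cluster left with fewer than two distinct members. Clustered
records are removed from the pool; distinct and multiplicity-weighted
counts are conserved at every step and asserted in tests.

The re-bait after shifting is a single global pass: released members
compete for membership in *other* clusters within the same iteration
rather than waiting for a later round. Whether same-iteration rejoining
should be allowed is genuinely open; the global pass was chosen because
it converges to the same assignment the next iteration would produce,
one round earlier, and keeps the per-iteration output self-consistent
(every reported member is within radius of its final representative).
`mode_shift_rounds` > 1 repeats shift-and-rebait; the default is one
round.

Adaptive sampling: when the sequences clustered in the current
iteration drop below the previous iteration's count,

    α ← min(α_max, α · (1 + γ · (prev − cur) / max(prev, 1))),

else α is unchanged, so α is non-decreasing. Defaults γ = 1.0 and
α_max = 0.05 are this package's choice: γ = 1 passes the full relative
drop through, and the cap keeps the per-iteration subsample (and hence
the cost of the greedy pass) bounded at 5% of the pool.

Termination: after `convergence_window` (default 5) consecutive
iterations in which no cluster of size ≥ `convergence_size` (default
10, the size class used for reporting guarantees) was found, or at
`max_iterations`, or when fewer than two records remain.

Cluster "size" is multiplicity-weighted (`total`) by default, since
multiplicities represent real reads; every operation that depends on
size also accepts `distinct` (deduplicated records), and iteration
statistics record both.

## Detection probabilities

A cluster of size ρ is detected by a uniform n-of-N sample iff the
sample holds ≥ 2 of its members; the count is hypergeometric. The
single-cluster miss probability is computed from the closed form
[C(N−ρ, n−1)·ρ + C(N−ρ, n)] / C(N, n); the m-cluster joint miss uses
the elementary symmetric polynomials e_i of the sizes, generated by the
recurrence B[i][j] = B[i−1][j−1]·ρ_i + B[i−1][j] with base B[0][0] = 1.
(A printed version of this recurrence with a vanishing i = 0 base would
make the whole sum zero; the standard base is used here and validated
against exhaustive enumeration of all C(N, n) samples on small
instances.)

Numerics: binomial coefficients are evaluated with exact integer
arithmetic whenever C(N, n) stays below ~20 000 digits — this gives
correctly rounded probabilities and 1e−12 agreement with enumeration —
and otherwise in log space via log-gamma, which holds to ~1e−11 at
N ~ 10⁶–10⁷.

**The exponential bounds are asymptotic, not universal.** The closed
forms come with exponential approximations, e.g.
e^{−ρn/N}(1 + (ρn/N)e^{ρ/N}) for a single cluster. Exact rational
evaluation shows these are *not* upper bounds in the weak-detection
corner: at (N, n, ρ) = (50, 5, 2) the exact miss probability is
0.99184 against a claimed bound of 0.98916. The P(X = 1) term's exact
factor n/(N−ρ−n+1) always exceeds the bound's (n/N)e^{ρ/N}, and only
the slack in bounding P(X = 0) by e^{−ρn/N} — which grows with ρ —
can absorb the excess. Empirically the inequality holds on the tested
grid whenever ρn/N ≥ 0.25 and fails only for tiny clusters (ρ = 2, and
one ρ = 10 cell). The package reports both exact values and bounds;
the bounds should be treated as sharp approximations for the large
clusters they are meant to describe.

## The coin-flip simulator

`simulate_iterations` is the sequence-free analogue of the engine: a
list of non-singleton cluster sizes plus a singleton fraction (default
20% of total mass), and per round one biased coin per remaining
cluster with success probability p_detect(N, n, ρ). Detected clusters
leave the pool; singletons never can (a sample cannot contain two of
their members) and progressively dilute it — exactly the dynamics that
motivate adaptive sampling. Default study conditions are 500 clusters
with geometric sizes of mean 1000 (uniform(2, 2000) and
normal(1000, 300) variants), α = 0.1%, up to 100 rounds: at these
sizes ρn/N spans the whole detection regime, from near-certain for the
biggest clusters to negligible for pairs. The diagnostic reproduced in
tests is that the Shannon entropy (bits) of the detected-size
distribution falls together with the remaining unclustered count —
late rounds detect a homogeneous trickle of small clusters.

## Detection confidence

After an iteration with pool size N and sample size n, and for each
candidate size k: hypothesise the worst case, that the current pool of
P unclustered sequences hides ⌊P/k⌋ additional size-k clusters on top
of the `observed` discovered ones; draw r (default 1000) binomial
realizations of how many of those hypothetical clusters the round
would have discovered at probability p_detect(N, n, k); mark k
*detected* iff `observed` is ≥ the simulated count in at least
(1 − ε)·r realizations (ε default 0.05). The reported upper bound is
the smallest k such that every candidate ≥ k is detected, or open
(None) when even the largest candidate cannot be ruled out.

How to estimate the number of clusters still hiding in the pool is
genuinely underdetermined; the worst-case choice makes the procedure
conservative by construction: a size is only ruled out once the pool is
too depleted to plausibly hide such a cluster, and the coverage
property (the bound is ≥ the true largest undetected cluster size in
≥ 1 − ε of runs) holds a fortiori. The price is bluntness early in a
run, when the bound stays open. The size scale defaults to `distinct`
here (the sampling space of deduplicated records, which is what the
hypergeometric model describes); `total` is available for consistency
with the engine's reporting.

## Synthetic communities

The generator emulates a dereplicated amplicon data set: centroids are
uniform random sequences (default 250 bp) rejected until every pair is
below θ − margin (default margin 0.05) similarity; cluster sizes (raw
mass) come from a geometric, uniform or truncated-normal law with
minimum 2; a fraction of each cluster's mass (default 40%) is emitted
as exact centroid copies, i.e. one record carrying that multiplicity,
so the centroid is the multiplicity mode that mode shifting should
find; the rest are distinct members mutated by 1..⌊(1−θ)L⌋ edits, 10%
of which are 1-bp indels (amplicon errors are substitution-dominated;
the indels exercise the free-end-gap alignment path). Singletons —
fresh sequences separated from every centroid — are added to make up a
stated fraction (default 20%) of total mass. Everything is
deterministic under the community seed.

What this does *not* emulate: chimeras, quality-score structure, primer
artifacts, length variation beyond indels, and above all *ambiguous
density* — planted clusters are separated by construction, so the
planted partition is the unique clustering at θ. Passing recovery tests
therefore shows the machinery is correct, not that θ = 0.97 resolves
real communities; on real data clusters abut and overlap, and the
fragmentation diagnostic exists precisely because the greedy radius
paradigm then fragments them.

`perturb_representative` lengthens one non-centroid member by random
trailing bases until it is the longest sequence in its cluster, making
it the greedy seed while the free-end-gap policy keeps it within
radius of the centroid — the fixture used to demonstrate that mode
shifting undoes a bad seeding choice.

## Evaluation metrics

The fragmentation curve reports, for each cluster size x (singletons
excluded), F(x) = total sequences in clusters of size ≥ x. Between two
clusterings of the same data, the higher curve is the less fragmented
one; `compare_fragmentation` evaluates both curves over the union of
their x values under step semantics and reports dominance or the
crossing points. Per-iteration entropy is the Shannon entropy (base 2;
bits chosen as the conventional unit) of the empirical distribution of
cluster sizes discovered in that iteration.

## Problem sizes used in tests and the acceptance script

Planted communities of 12–50 clusters with raw masses 5–500 (a few
hundred to ~12 000 distinct records), thresholds 0.95–0.99, and
simulator pools of ~625 000 implicit sequences. These sizes were chosen
so the full suite exercises every code path — multi-iteration adaptive
runs, mode-shift reassignment, conservative confidence bounds — while
each scenario completes in seconds; the underlying algorithms have no
data-dependent branches that would behave differently at the
multi-million scale, apart from the documented switch from integer to
log-gamma arithmetic, which is itself tested on both sides.

## Known limitations

- A fixed similarity radius inflates richness estimates; mode shifting
  mitigates but does not remove this.
- The engine is single-threaded; per-cluster baiting is independent
  and could be parallelized.
- Sampling is uniform over distinct records by default
  (multiplicity-weighted sampling is available but not the default, as
  the deduplicated pool is the natural sampling space).
- The exponential bounds understate the miss probability for tiny
  clusters (see above); rely on the exact forms where they are cheap,
  which is everywhere the package operates.
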