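# Methods

## The data model

The package operates on *movement panels*: counts `n^h_ij` of users moving
from node `i` to node `j` during 8-hour slot `h` (diagonal entries count
users staying put), plus per-node user counts `n^h_i`. Three slots make a
calendar day; day `d` comprises slots `3d, 3d+1, 3d+2`, with slot 0
starting at 00:00 of day 0. Real panels of this kind are anonymized:
origin–destination counts below a threshold (10 by default) are suppressed
before release, and the observed users are a small, roughly uniform sample
(3–7 %) of the resident population.

## Transition matrices

A window's transition matrix pools the counts of all slots whose start
falls in the half-open interval `[24·t − ε, 24·t + δ)` hours and normalizes
each row:

    Π_ij(t) = Σ_h n^h_ij / Σ_j Σ_h n^h_ij .

Pooling before normalizing makes matrix construction additive in the
counts: the matrix of a union of disjoint windows is the matrix of the
pooled counts, not the average of the per-window matrices. Daily matrices
use `(ε, δ) = (0, 24)` h; weekly-rolled matrices use `(72, 96)` h, which
under the half-open convention covers exactly the 3 days before through the
3 days after day `t` and cancels day/night and weekday/weekend
seasonality. (The stated `δ = 96` h includes day `t` itself plus the 3
following days; the half-open interval realizes that reading exactly.)

Numerical choices:

- A node with no recorded movers in a window gets an absorbing self-loop
  `Π_ii = 1` rather than a NaN row; the event is logged. This preserves
  row-stochasticity and is the correct "nobody observed moving" limit.
- Boundary days of a weekly-rolled series use truncated windows by default
  (configurable to drop them instead).
- Censored links are exact zeros; no imputation is attempted.
- Matrices are stored dense: at `N ≈ 10²` nodes, self-loops alone make the
  arrays effectively dense.

## Perron–Frobenius quality assessment

The mean matrix `Π̄` generates a Markov jump process. When its
positive-entry digraph is strongly connected and aperiodic, the leading
eigenvalue is exactly 1 and the left eigenvector at 1, normalized to unit
sum, is the unique stationary density `ρ*`; any starting density converges
to it. Aperiodicity is not tested separately: a diagonally dominant
mobility matrix always carries positive self-loops, and a positive diagonal
entry in a strongly connected graph suffices. The solver extracts the
eigenvector via `scipy.linalg.eig` (left eigenvectors), takes real parts,
normalizes, and verifies the residual `‖ρ*Π̄ − ρ*‖_∞ ≤ 1e−10`; a power
iteration (`tolerance 1e−12`) provides an independent route used in tests
(agreement to `1e−8`).

The quality check compares `ρ*` against the census density. The aggregate
deviation is the root-mean-square of the per-node signed deviations; both
are exposed, since the aggregation behind a printed "standard deviation" is
ambiguous and the per-node vector is what identifies which nodes become
sources or sinks.

*Pruning sensitivity.* `prune_and_renormalize` zeroes entries below a
probability cutoff and renormalizes rows. Diagonal entries are exempt by
default (`prune_diagonal` overrides): pruning models the suppression of
*links*, and self-stay probabilities of order 0.9 sit four orders of
magnitude above realistic cutoffs, so the exemption is unobservable there
but keeps small-matrix experiments sensible. The sweep prunes at increasing
cutoffs, records strong connectivity, and computes `ρ*` and its deviation
while the stationary state exists; losing strong connectivity is a
*result* (the breaking point), not an error. Once a row loses all
off-diagonal mass the matrix acquires absorbing states and deviations can
only grow; on generated panels the deviation is monotonically
non-decreasing up to the breaking point.

## Temporal clustering

Daily matrices are compared by the Frobenius distance, which equals the
Euclidean distance between vectorized matrices; Ward linkage on the
vectorized series is therefore exactly Ward in the Frobenius geometry, and
the implementation uses `scipy.cluster.hierarchy.linkage(method="ward")`.
The tree is cut with `cut_tree`, which honors the requested cluster count
even when merge heights tie (an all-identical series still yields the
requested two clusters); scipy's linkage resolves tied merge costs by
lowest pair index, making the result deterministic. Labels are renumbered
by order of first appearance. The *confined* regime is identified as the
cluster with the lower mean `⟨P_out⟩`.

Per-regime summaries: the cluster mean matrix (entrywise mean,
row-renormalized only to guard float drift — means of stochastic matrices
are already stochastic), the representative matrix (the member closest to
the mean in Frobenius distance, earliest day on ties — always an actual
member, never the mean), and the current matrix `J_ij = Π̃_ij ρ_i` built
with the *census* density rather than `ρ*`: the census is the more accurate
statement of where people are, so the currents better approximate real
fluxes even though detailed balance then holds only approximately.

*Regime scoring uses the daily series.* The weekly-rolled window smears a
regime boundary across 6 days: a boundary day's window mixes the two
regimes at weights 1/7…6/7, and which cluster such a day joins depends on
Ward's merge path, not on the ground truth. Day-exact recovery is therefore
scored on the unsmoothed daily series (20/20 seeds exact at suppression
factor 0.3 in the test suite), while the weekly-rolled series remains the
default input for regime *discovery* and for representative matrices, where
seasonal cancellation matters more than boundary sharpness.

## Greedy modularity communities

Modularity is evaluated exactly as

    Q = (1/2m) Σ_ij [ W_ij − k_i k_j / 2m ] δ(c_i, c_j),
    m = (1/2) Σ_ij W_ij,   k_i = Σ_j W_ij ,

on symmetric weights with zero diagonal. The single-cluster partition gives
exactly `Q = 0`. The all-singleton partition retains only the diagonal null
terms, `Q = −Σ_i (k_i/2m)²`, which vanishes only in the sparse-graph limit
— the often-quoted "`Q = 0` for singletons" is that limit, not an identity
of the formula (the formula's own value is what the implementation and
tests assert).

Because modularity is defined for undirected graphs without self-loops,
directed current matrices are prepared by zeroing the diagonal and
symmetrizing `W = (X + Xᵗ)/2`. The optimizer is the classical greedy
agglomeration: start from singletons, repeatedly merge the community pair
with the largest modularity gain while a strictly positive gain exists,
ties broken on the lexicographically smallest pair of community ids (a
community is named by its smallest member index). Only positive gains are
accepted, so the final state is the peak of the greedy trajectory.
Zero-degree nodes never produce a positive gain and stay singletons;
disconnected components are never merged. The resolution parameter is
fixed at 1 (the formula has none). An exhaustive enumerator over all set
partitions (feasible to ~10 nodes) provides the exact optimum for scoring:
on planted two-block instances the greedy result attains it; on arbitrary
instances the greedy value is verified never to exceed it.

## Critical variable selection

*Effective distances.* Each directed link with `Π_ij > 0` has length
`d_ij = 1 − ln Π_ij ≥ 1` (probabilities ≤ 1 guarantee positive lengths, so
Dijkstra is well-posed); `D_ij` is the shortest directed path length. The
all-pairs matrix `Δ` is assembled by an ordered rule, first match wins:
0 on the diagonal; `d_ij` if the direct link exists; `d_ji` if only the
reverse link exists; `D_ij` if a forward path exists; `D_ji` if only a
reverse path exists; otherwise a finite cap equal to 100× the largest
well-defined entry. Note the direct-link case precedes the path case, so a
direct link supplies its own length even when a shorter indirect route
exists; the shortest-path matrix `D` is exposed separately
(`effective_path_lengths`) for analyses that want all-routes distances
everywhere. The cap participates in symmetrization
`Δ^S = (Δ + Δᵗ)/2` and in the mean-normalization `Δ^S ← Δ^S / mean(Δ^S)`
like any other entry; after normalization the mean over all `N²` entries
is exactly 1 and downstream clustering is invariant to the cap scale.

*Resolution and relevance.* For cluster sizes `k_s` (base-N logarithms
throughout, so both quantities live on a 0–1 scale):

    H[s] = −Σ_s (k_s/N) log_N (k_s/N)          (resolution)
    H[k] = −Σ_k (k·m_k/N) log_N (k·m_k/N)      (relevance)

with `m_k` the number of clusters of size `k`. Resolution is 0 at one
cluster and 1 at all singletons; relevance vanishes at both limits and —
notably — at any partition whose sizes are all equal (`k·m_k/N = 1`), so it
rewards size-heterogeneous, informative partitions.

*Optimal partition.* Agglomerative clustering on `Δ^S` uses average
linkage: Ward requires coordinate geometry that a capped, mean-normalized
distance matrix does not possess (complete and single linkage are exposed
as options). One partition per `K = 1…N` is produced by cutting the tree
(`cut_tree` per K, exact counts under ties); the returned partition
maximizes relevance, smallest K on ties (the coarsest equally informative
description).

## The synthetic generator

The generator is a fixture emulating the *structure* of anonymized
mobility panels, not a fitted model of any real panel. Defaults and their
rationale:

- **Populations**: log-uniform over 1e5–2e6 unless given explicitly —
  province-scale units spanning about an order of magnitude with a heavy
  upper tail.
- **Sampling fractions**: per-node uniform in (0.03, 0.07), the observed
  visibility band of location-sharing panels.
- **Geometry and flows**: nodes uniform in the unit square; off-diagonal
  expected flux follows a gravity law `pop_i·pop_j / dist^γ` (γ = 2
  default), row-normalized to an off-diagonal mass of `1 − diagonal_floor`
  (floor 0.9), so the latent diagonal sits exactly at the floor in the
  unsuppressed regime and above it otherwise.
- **Seasonality**: multiplicative suppression of off-diagonal mass — night
  slot ×(1 − 0.5), weekend days ×(1 − 0.2). Factors only ever reduce
  mobility, so the realized diagonal never drops below the floor in
  expectation.
- **Lockdowns**: half-open day intervals multiplying off-diagonal mass by
  `lockdown_offdiag_factor` (0.3 in regime-recovery fixtures).
- **Counts**: independent Poisson draws around `f_i · pop_i · P^h_ij`, the
  simplest integer law consistent with aggregating independent movers;
  `n^h_i` is the origin-row total, keeping panel internals consistent.
- **Planted blocks**: optional; nodes are assigned to the nearest of
  `n_blocks` random centers, so blocks are spatially contiguous and the
  gravity distance decay reinforces rather than fights them, and each block
  is repaired to hold at least 2 nodes — a 1-node block carries no
  intra-block link and is not a community in any detectable sense.
  Intra-block gravity is multiplied by `block_strength`.

`GroundTruth` records the latent slot matrices; their time average is the
exact expectation of the empirical mean transition matrix (row totals are
slot-independent), which is what the parameter-recovery test checks at
`n_days = 200` (max-norm < 1e−3).

What the generator does **not** emulate: real geography and its elongated,
chain-like adjacency; tile-level (sub-node) structure; user-base drift;
correlated (non-Poisson) burstiness; partial or regionally staggered
lockdowns. Passing tests therefore certify the pipeline's behavior under
gravity-like, homogeneously sampled mobility — not the idiosyncrasies of
any particular country's panel.

## Fixture scales

Test fixtures use 6–20 nodes and 7–30 days (200 days for the convergence
test, 106 objects where the partition arithmetic itself is the point);
these sizes keep the full suite under a minute while leaving every
statistic (Poisson counts per link, cluster separations) far from its noise
floor.

## Known limitations

- The relevance maximum is often shallow: on statistically generated
  panels the relevance curve is nearly flat within ~0.03 of its peak, and
  the location of the argmax wanders with sampling noise even when
  confinement demonstrably fragments the graph (more strongly connected
  components, more isolated nodes). The confined-vs-unconfined cluster-count
  comparison is therefore tested on a constructed two-scale mobility
  hierarchy — sub-blocks within super-blocks plus remote weakly-attached
  nodes, with suppression pushing intermediate links below a
  censoring-equivalent probability cutoff — and asserted on the mean
  optimal K across tie-break seeds. Single instances can deviate.
- Greedy modularity is a heuristic with the usual resolution limit: very
  small communities attached to large ones can be absorbed even when
  planted.
- The stationary-density check presumes the sampled users move like the
  whole population; a biased sample with perfect mixing would pass it.
- Effective distances follow the printed ordered case rule (direct link
  before shortest path); analyses wanting all-routes distances for linked
  pairs should use `effective_path_lengths` directly.
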