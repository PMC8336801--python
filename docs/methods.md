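# Methods

## Model and procedure

The algorithm is agglomerative clustering driven by exact linear
assignment. The state after any iteration is a partition of the n input
rows into k clusters, each with a representative. One iteration:

1. **Inter-cluster distances.** Build the symmetric, zero-diagonal k×k
   matrix C. In `centroid` mode (default for coordinate input) C[j,l] is
   the metric distance between representatives; in `single` / `average` /
   `complete` mode it is the corresponding linkage function of the raw
   member-to-member distances, so no centroid is ever needed (general
   metric spaces, distance-matrix input).
2. **Penalty.** η = Σ_{j<l} C[j,l] / (k(k−1)) — half the average pairwise
   distance between representatives. η is exactly the average of the
   centroid self-cohesions γ(c_j,c_j) divided by 2(k−1); `values.self_cohesion`
   and `core.compute_eta` agree to 1e-12 and the test suite asserts it.
3. **Assignment.** Minimize O(σ) = Σ_j [C[j,σ(j)] + η·1(σ(j)=j)] over all
   permutations — a linear assignment problem with η (or, in
   `cluster_utility` mode, the cluster's own tour value u(S_j) when
   |S_j| > 1) on the diagonal.
4. **Merge.** Each cycle of the optimal permutation becomes one new
   cluster (the union of the member sets on the orbit); representatives
   are recomputed from the union's raw member points, not averaged from
   the previous centroids, so the `mean` representative of a merged
   cluster is the exact k-means centroid of its points.

The loop starts from n singletons and stops when the optimal permutation is
the identity (staying alone is cheaper for every cluster) or k = 1. k is
non-increasing and every non-identity permutation removes at least one
cluster, so at most n iterations run; `max_iterations` (default 0 =
unbounded) exists only as a debugging cap and flags the result as
non-converged when hit.

**Assumptions.** The method only needs a metric d; it does not assume
cluster shapes or a probabilistic model. The identity-vs-merge trade-off is
scale-equivariant (η and C scale together). Per-iteration optimality is
exact; no claim is made that the final partition globally minimizes any
functional over all partitions.

## The assignment solver

`assignment.solve_assignment` is a Jonker–Volgenant shortest-augmenting-path
solver with dual potentials, O(k³), exact for arbitrary finite real costs.
Its optimality is tested against exhaustive enumeration (k ≤ 7, 200 random
matrices per size) and against `scipy.optimize.linear_sum_assignment` on
larger random matrices; scipy is used only as a cross-check, never in the
computation path.

**Tie-breaking.** Among cost-minimizing permutations the contract is the
lexicographically smallest mapping. A perturbation of the cost matrix
cannot deliver this: any additive term of the form ε·(i·k + j) contributes
a permutation-independent constant to every assignment (Σ_i i·k is fixed
and Σ_i σ(i) = k(k+1)/2 for every σ), and weights strong enough to impose
true lexicographic priority across k rows underflow double precision for
moderate k. Instead, for k ≤ 12 the solver fixes σ(1), σ(2), … in turn to
the smallest column that still admits an optimal completion, each check
being a LAP solve on the reduced matrix (tolerance 1e-9·(1 + max|M|)). For
k > 12 the solver's deterministic output is returned directly; with
continuous distance data, exact ties between distinct permutations have
measure zero, and runs remain bit-reproducible either way. The one place
ties matter in practice — exactly coincident representatives, where η = 0
and identity and merge both cost zero — resolves toward the identity, so
coincident singletons are *not* force-merged.

## Tour utility and cohesion

`values.tour_value` computes u(S) exactly by Held–Karp dynamic programming
(O(2^m m²)) for m ≤ 12 members and raises beyond that unless the explicitly
flagged nearest-neighbour + 2-opt heuristic is requested (the heuristic is
an upper bound and is what `cluster_utility` penalty mode uses for clusters
larger than 12). For m = 2 the pair distance is counted once: the
transposition formally traverses the edge twice, but the pair value and the
centroid value coincide at d(x₁,x₂) under the single-count reading, which
also matches the square example (u = 4a, not 8a). For m ≥ 3 every cycle
traverses each tour edge exactly once, so no such question arises.

`values.point_cohesion` / `set_cohesion` implement the binding-force
measure γ on the full point set, including the closed form of γ(S) in terms
of the block sums d(S,S′), d(S′,S′), d(S,S) (ordered double sums); the
complement identity γ(S′) = γ(S) is asserted on random instances.
`self_cohesion` gives the centroid-level γ(c_j,c_j) =
(2/k)Σ_l d(c_j,c_l) − (1/k²)ΣΣ d; the companion `relative_distance` helper
exposes RD(c_i‖c_j) = d(c_i,c_j) − mean_l d(c_i,c_l), from which the
self-cohesion follows by averaging.

`core.single_cycle_stop_check` asks whether the current k is final by
comparing η with the cheapest permutation containing a single non-trivial
cycle, fixed points priced at η. Because O(σ) is additive over cycles, this
is equivalent to the identity being the strict assignment optimum. A
literal "full k-cycles only, no fixed-point term" enumeration would *not*
certify stopping (a cheap partial merge can hide behind an expensive full
tour — e.g. centroids at 0, 0.01, 10); the implemented reading is the one
consistent with the algorithm's actual stopping rule. Enumeration is
guarded to k ≤ 9.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `metric` | `euclidean` | point distance; `sqeuclidean` for k-means-style comparisons, `arc_length` (radians) on the unit sphere |
| `representative_method` | `mean` | `extrinsic_sphere` = renormalized mean; `medoid` = member minimizing summed distance, ties to lowest index |
| `cluster_distance_mode` | `centroid` (points) / `average` (distance input) | how C is built |
| `penalty_mode` | `eta` | `cluster_utility` prices non-singletons at their own tour value |
| `standardize` | off | per-column centring/scaling; useful for mixed-unit tables, meaningless on the sphere |
| `max_iterations` | 0 (unbounded) | debugging cap only |

Plain (unsquared) Euclidean distance is the default because the
identity-vs-merge geometry of the objective is stated on distances; with
squared distances η changes scale quadratically and the stopping behaviour
differs. Under the plain-distance default the simulation endpoints below
are reproduced, so the choice was kept.

Numerical guards: arc-length inner products are clamped to [−1,1];
unit-sphere rows are renormalized when within 1e-6 of unit norm and
rejected beyond; distance matrices must be symmetric (1e-12 internal,
1e-9 for CSV input, where tiny negatives are clipped); the extrinsic mean
raises on a numerically zero mean vector (antipodal degeneracy) rather
than guessing a direction.

## Synthetic designs

The generators define the study conditions used by the tests and the
acceptance script.

* **Planar blobs.** Five fixed centres (0,0), (1,3), (3,3), (3,1),
  (0,1.5); isotropic Gaussian noise. Even design: 90 points per centre,
  sd 0.3 (the closest centres, C1 and C5, are 1.5 apart — separated but
  not trivially). Unbalanced design: sizes 180/80/110/60/20 with the noise
  given as a per-coordinate *variance* σ², so sd = √σ²; the noise sweep
  runs 50 seeded replicates per variance and reports the modal final
  cluster count.
* **Sphere.** Two projected-normal groups (sizes 50 and 40): Gaussian
  perturbations (sd 0.2) of two unit mean directions 90° apart,
  renormalized to the sphere; zero-norm draws are resampled. The sd and
  the 90° separation were chosen so the two caps are visually distinct but
  adjacent; individual runs end at 2 clusters in roughly 7 of 10 seeds
  (else 3), so replicate-level statements use the modal count over seeds.

One root seed drives everything; replicate experiments spawn independent
child streams via `numpy.random.SeedSequence`.

What the generators emulate — compact isotropic groups, unequal sizes,
controlled overlap, directional data — is what the endpoint claims are
about. They do not emulate anisotropic or non-convex clusters, heavy-tailed
noise, outliers, or mixed data types, so passing tests say nothing about
behaviour there beyond the structural guarantees (termination, partition
validity, per-iteration optimality), which hold for any metric input.

## Problem sizes and runtime

Defaults keep every check desk-scale: the full loop on 450 points runs in
about 0.15 s (the first iteration's 450×450 assignment dominates), a
50-replicate noise sweep in a few seconds, and the complete test suite in
well under a minute. Exact-enumeration oracles are restricted to the sizes
where enumeration is exact and fast (k ≤ 7 assignments, m ≤ 8 tours,
k ≤ 9 stop checks).

## Known limitations

* The final partition is per-iteration optimal, not globally optimal; the
  loop only merges and cannot revisit an early merge.
* Exact tour values stop at 12 members; the heuristic beyond that is an
  unflagged upper bound inside `cluster_utility` penalties.
* Lexicographic tie-breaking is certified only for k ≤ 12 (see above).
* Intrinsic (geodesic) Fréchet means on the sphere and Riemannian
  shape-space distances are out of scope; the distance-matrix mode plus
  medoid representatives are the supported route for general metric data.
* Whether to standardize mixed-unit tables is left to the user (`standardize`
  flag); no automatic preprocessing is applied.
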