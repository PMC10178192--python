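# Methods

## Model and constraint semantics

`careassign` solves a triple-criteria binary assignment program over elderly
people *I* and helpers *J*. Each helper is typed (`caregiver` / `robot`);
the type partition is roster data, not a decision. The objective is the
weighted sum λ₁·f₁ + λ₂·f₂ − λ₃·f₃ of the three criteria sums
f₁ = Σ c·x (efficiency, maximized), f₂ = Σ a·x (robot utilization,
maximized) and f₃ = Σ b·x (caregiver stress, minimized), subject to each
elderly person being served at most once and each helper serving at most
one elderly person. Coefficients live in [0, 1] (configurable upper bound
per instance) so the criteria are commensurable under convex weights;
utilization is structurally zero on caregiver columns and stress on robot
columns.

Two feasibility semantics are exposed by `check_feasibility`:

* **REPAIRED** (default, used by all solvers): the partial-matching
  constraints above.
* **STRICT**: the literal equality-constraint formulation of this model
  family, in which per-helper balance equations Σᵢ x₍ᵢⱼ₎ = zⱼ and
  Σᵢ x₍ᵢⱼ₎ = uⱼ + zⱼ are imposed simultaneously. Subtracting them forces
  every robot-use indicator uⱼ to zero, i.e. no robot could ever be
  assigned — inconsistent with the mixed outcomes the model is meant to
  produce. STRICT mode is a checker only: it flags every robot pair
  (`STRICT_ROBOT_EXCLUSION`) to document the inconsistency. STRICT
  feasibility implies REPAIRED feasibility.

Coverage is not forced: y-type service indicators are chosen by
optimization. Full coverage emerges on the reference scenarios from
positive composite weights plus the coverage-preferring tie-break (below).
The weighted-sum parametrization is classically stated with strictly
decreasing weights λ₁ > λ₂ > λ₃; the reference experiments use pure and
50/50 weights, so any simplex point is accepted and a log notice records
non-conforming orderings.

## Scalarized solver

By linearity the scalarized score of an assignment is the sum of its pairs'
composite weights w₍ᵢⱼ₎ = λ₁c₍ᵢⱼ₎ + λ₂a₍ᵢⱼ₎ − λ₃b₍ᵢⱼ₎. Entries within 1e-9 of zero are snapped to exactly
zero; this single tolerance governs weight-sum validation, tie detection
and frontier deduplication. Pairs with negative snapped weight are never
forced (skipping contributes zero); pairs with zero weight are still worth
serving because of the tie-break.

Ties are broken deterministically, in order: (1) maximize the number of
elderly served, (2) maximize f₁ (efficiency), (3) lexicographically
smallest pair list by (elderly index, helper index). The solver realises
this contract exactly on instances up to 12 elderly × 14 helpers by
encoding (score, coverage, efficiency, pair-rank bonus) into a single
arbitrary-precision integer per pair, in mixed radix: float64 coefficients
are dyadic rationals, so scores convert to integers without rounding, and a
per-pair bonus of 2^(R−1−rank) makes every matching's total unique and
orders equal-score matchings by lexicographic pair list. Maximum-weight
matching over these integers is computed by successive augmentation along
maximum-gain alternating paths (multi-source Bellman–Ford relaxation);
uniqueness of totals makes the algorithm fully deterministic, and greedy
maximum-gain augmentation yields the maximum-weight matching of every
cardinality, so stopping at non-positive gain is exact. The brute-force
oracle ranks all partial matchings by the same integer encoding but finds
the maximum by exhaustive enumeration (guard: 6 × 8), so the two must agree
bit-for-bit — this dual route is asserted on hundreds of random instances.

Above the exact guard (e.g. the 100 × 200 reference instance) the solver
reduces to scipy's rectangular `linear_sum_assignment` on the matrix
[w + β + γ·c | 0], where the zero block holds one skip column per elderly
person, β = 2⁻²⁰ is the serving bonus and γ = 2⁻⁴⁰ the efficiency bonus.
Both bonuses sit far above float64 resolution for objective sums of a few
hundred terms; the serving bonus can displace score optimality only when an
alternative differs by less than ~1e-4 in total score, which realises the
coverage tie-break on the calibrated scenarios (where ties are exact, e.g.
all-robot pairs under pure stress weights). Exact tie-break fidelity at
scale is best-effort; all accuracy-critical checks run on the exact path.

## Frontier operations

* `weight_sweep` solves the scalarized program on the simplex grid
  (k₁/r, k₂/r, k₃/r), deduplicates objective vectors (1e-9 component-wise,
  first producer kept) and returns the non-dominated subset — supported
  points with their generating weights.
* `full_frontier` enumerates all partial matchings of a small instance
  (guard 6 × 8) into a running non-dominated archive, then flags each point
  supported if a resolution-10 sweep reproduces its objective vector.
  Points the sweep never produces are unsupported candidates. Dominance
  comparisons are exact; equal-within-tolerance vectors are one point with
  the first-enumerated assignment as representative.
* `epsilon_constraint_solve` maximizes one criterion under bounds on the
  others — lower bounds for the maximized criteria, an upper bound for
  stress, since a literal upper bound on a maximized criterion can never
  cut toward unsupported points. It is an exact depth-first branch-and-
  bound over pair inclusion (guard 10 × 12) with an admissible bound: the
  sum over remaining elderly of each one's best single-pair contribution
  ignoring helper contention. Contradictory bounds return INFEASIBLE
  status, not an exception. Worst-case node counts grow quickly with
  instance size; the guard keeps the search tractable.
* `pareto_filter` is the quadratic non-dominated filter (order-preserving,
  exact-duplicate collapsing); it is cross-checked in the tests against an
  independently written double-loop oracle.

## Synthetic scenario generator

No coefficient data accompany the reference experiment, so the generator
emulates its published structure: 100 elderly people and a pool of 100
caregivers plus 100 robots (the pool reading consistent with pure-criterion
scenarios assigning a single helper type to all 100 elderly). Each elderly
person draws a latent robot-affinity indicator ρ ~ Bernoulli(0.5) —
"robot-suited" people are served well by robots and are the most stressful
for human caregivers. Pair coefficients are uniform on (type, affinity)-
specific ranges:

| coefficient | ρ = 1 (robot-suited) | ρ = 0 |
|---|---|---|
| caregiver efficiency | U(0.70, 0.90) | U(0.70, 0.90) |
| caregiver stress | U(0.50, 0.70) | U(0.10, 0.30) |
| robot efficiency | U(0.55, 0.65) | U(0.15, 0.25) |
| robot utilization | U(0.85, 0.95) | U(0.45, 0.55) |

An affinity-free profile cannot make the pure-criterion optima unanimous
while the mixed criteria split evenly; the two-population structure is the
minimal mechanism that does. A pointwise argmax analysis at the range
extremes verifies the calibration: under (0.5, 0.5, 0) a robot pair scores
0.70–0.80 for ρ = 1 (caregivers ≤ 0.45) and ≤ 0.40 for ρ = 0 (caregivers
≥ 0.35 with 100 draws to choose from), so the robot share tracks the
binomial affinity count — within [35 %, 65 %] per seed with high
probability and 50 % in expectation. Uniform distributions are used for
transparency; the profile schema permits alternative ranges but not
alternative families. Generation is deterministic given the seed with a
fixed draw order (affinity, caregiver efficiency, caregiver stress, robot
efficiency, robot utilization).

The replication harness solves the six reference weight scenarios —
(1, 0, 0), (0, 1, 0), (0, 0, 1), (½, ½, 0), (½, 0, ½), (0, ½, ½) — and
records coverage, helper-type shares and objective values. The
utilization+stress scenario's reference outcome is an even split, but under
the model's own semantics caregiver pairs contribute ≤ 0 and robot pairs
≥ 0 to that scalarization while robots are plentiful, so the optimum is
provably all-robots; the harness flags this as a documented discrepancy
(`matches_reported = False` with an explanatory note) rather than asserting
or forcing agreement.

What the generator does not emulate: real coefficient estimation (how one
would measure efficiency or stress), heterogeneous caregiver capacity,
temporal dynamics of stress, and correlations between criteria beyond the
affinity mechanism. Passing replication therefore shows the optimization
machinery reproduces the reference outcome *structure* under the stated
calibration, not that the calibration reflects any real care population.

## Numerical choices and limitations

* Single absolute tolerance 1e-9 for weight-sum validation, zero-snapping
  of composite weights and frontier deduplication; dominance itself is
  exact.
* Deterministic file formats: CSV rows sorted by identifier, floats written
  with shortest round-trip representation and read back with round-trip
  parsing, so write→read is the identity and identical seeds give
  byte-identical outputs. The elderly set is recovered from the dense pairs
  table, so an instance with elderly people but no helpers does not
  round-trip.
* Problem sizes: the replication experiment runs at the full 100 × 200
  reference size (a solve takes milliseconds on the scipy path); exactness
  cross-checks run at enumeration scale (≤ 4 × 6 against the brute-force
  oracle, ≤ 6 × 8 for full frontiers), where exhaustive enumeration is the
  independent referee.
* Fractional assignments, helpers serving several elderly people,
  time-indexed scheduling and stochastic coefficients within a solve are
  out of scope.
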