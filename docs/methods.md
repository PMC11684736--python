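# Methods

## Problem and model

A host molecule *cages* a guest when the guest admits a collision-free
placement from which no continuous rigid motion reaches infinity. Both
molecules are hard-sphere models: unions of balls at the file coordinates
with per-element van der Waals radii (packaged Bondi-style defaults: H 1.20,
C 1.70, N 1.55, O 1.52, F 1.47, P 1.80, S 1.80, Cl 1.75, Br 1.85, I 1.98 Å;
any table can be supplied). No protonation, bond perception or energetics —
the model is purely the printed coordinates, and caging is decided by shape
alone. Molecular flexibility is handled implicitly upstream, by screening
conformational ensembles supplied as one file per conformation.

The guest's configuration space is SE(3): translation t of its reference
point (the centroid of its sphere centers) plus rotation q about that
point. The free space F is the set of placements with positive clearance,
`min_clearance = min_{i,j} (|c_i − x_j| − r_i − r_j)`. Caging ⇔ F has a
bounded connected component.

## Conservative discretization

Verification must never claim caging falsely, so the discretization
over-approximates F:

* **Translation grid.** Cubic cells of edge h covering the host's center
  bounding box inflated on every side by
  ρ_guest + max r_host + max r_guest + 2h. The inflation guarantees the
  outermost cell layer is collision-free at every orientation (clearance
  ≥ h even at cell corners), so it is a correct exterior seed.
* **Orientation samples.** A deterministic quasi-uniform set of unit
  quaternions (antipodal pairs identified): greedy farthest-point selection
  from a fixed pseudo-random pool, identity first. Because the pool and
  seeds are fixed and the greedy sequence is a prefix chain, doubling the
  sample count never increases the covering radius, and verdicts are
  reproducible across machines. The covering radius θ_cov is estimated as
  1.2 × the worst probe-to-nearest-sample geodesic over 100,000 fixed-seed
  probes (the 1.2 safety factor absorbs estimation error; the estimate is
  validated by independent sampling in the tests).
* **Labeling.** Within one cell at one orientation sample, no guest sphere
  center moves farther than m = (√3/2)h + 2ρ sin(θ_cov/2) from its
  cell-center position (half cell diagonal plus the exact rotation chord at
  the guest circumradius ρ; the chord is used rather than the looser ρθ).
  A cell is `BLOCKED_CERTAIN` iff the deepest overlap at the cell-center
  placement is ≥ m — then the deepest pair cannot separate anywhere in the
  cell's coverage region. All other cells are `FREE_POSSIBLE`. Consequently
  every strictly-free placement lands in a `FREE_POSSIBLE` cell (measured
  as exactly 100% over random placements in the acceptance run).
* **Reachability.** Escape-reachable cells are flood-filled from every
  boundary-layer cell at every orientation, moving through 26-connected
  translation neighbors at fixed orientation and orientation-adjacent
  samples at fixed cell. Orientation adjacency links samples within
  2.5 × θ_cov — deliberately over-connected: two samples can be co-nearest
  to one orientation only within 2 × θ_cov, and extra edges can only weaken
  caging claims, never break soundness. The fill is implemented as
  per-orientation 26-connected component labeling linked across orientation
  edges (checked against a plain breadth-first search in the tests).
* **Witness.** The first `FREE_POSSIBLE` cell (deterministic index order)
  outside the reachable set whose center placement has clearance
  > τ_w = 1e-6 Å (a float-noise guard) proves caging: any true escape path
  from it would traverse `FREE_POSSIBLE` cells reachable from the exterior
  seeds. No witness ⇒ `NOT_PROVEN`, which is *not* a disproof.

Spherically symmetric guests (circumradius 0, e.g. ball probes) are
verified with a single orientation sample; every rotation of such a guest
gives the identical sphere placement and the rotation margin term is zero,
so the reduction is exact, not an approximation.

### Resolution, refinement, defaults

Defaults: h = 0.5 Å, 60 orientations, up to 2 refinement levels (h halved
and the orientation count doubled per level, stopping early once caging is
proven) — sized for single-pair verification of ≤100-atom molecules at a
desk. Screening-scale runs use coarser settings (the acceptance script uses
h = 0.6–0.7 Å, 4–8 orientations, ≤1 refinement level on 30–60-sphere
geometries); coarsening can only lose proofs, never fabricate them. A
`fixed` orientation mode (identity only) exists for triage and unit tests;
it is conservative only under a fixed-orientation assumption and is never
the screening default.

### NOT_PROVEN diagnostics

`escape_not_excluded` vs `no_interior_free_cell` ("the guest does not
fit") are separated by a cavity probe: strictly-free cell-center placements
whose reference point lies within the ball around the host centroid of
radius min_i(|c_i − centroid| − r_i). This realises the cannot-fit outcome
for cavity-bearing hosts; it is a reporting aid with no bearing on the
one-sided guarantee, and may mislabel exotic hosts whose centroid falls
inside an atom.

## Robustness classification

Radii of *both* molecules are shifted jointly by each offset in
{−Δr, 0, +Δr} and verification repeated: strong = proven caged at every
offset, not = at none, weak = mixed. Three offsets (rather than ±Δr alone)
are the minimal sweep that separates the two weak mechanisms — escape after
deflation, no-fit after inflation. Δr defaults to 0.3 Å; there is no
principled way to auto-tune it, so it is a required, logged parameter and
Δr = 0 (single non-robust verification, class strong/not only) is flagged
in the metadata. Inflating both molecules by Δr shifts any fit/passage
threshold by 2Δr, which is why weak bands appear within ±2Δr of a size
threshold. Strong/weak caging says nothing about binding affinity.

## Screening

All host × guest pairs are classified independently (embarrassingly
parallel, partitioned by pair index), so the matrix is identical for any
worker count; per-pair failures and optional per-pair timeouts become
"error" cells instead of aborting the screen. Matrices round-trip through
CSV/TSV (hosts in rows, guests in columns) and JSON (with per-offset
verdicts and full parameter metadata); ensemble summaries tally class
counts and fractions per label along either axis.

## Synthetic fixtures and oracles

All testing is anchored on analytic geometries with certified ground
truth — no external structures:

* **Shell cages**: n_s spheres of radius r_s on a Fibonacci covering of a
  sphere of radius R, optionally with a polar aperture. Cavity clearance is
  exactly R − r_s. The **passage oracle** bounds escapability along dense
  straight exit rays (Fibonacci directions plus the six axes, so
  axis-aligned openings are probed exactly): the maximum over rays of the
  minimum over spheres of (ray distance − r_s) is the largest ball that
  slides out straight — a lower-bound certificate of escapability, and a
  construction target for sealed cages (the packaged sealed shell, R = 4,
  r_s = 1, n_s = 100, has bound −0.015 Å: not even a point exits straight).
* **Escape oracle**: exhaustive flood fill over a fine configuration grid
  accepting only strictly-free placements. `escape_found` returns a
  concrete path that is independently re-validated step by step (every
  placement strictly free, bounded steps, endpoint outside the inflated
  box); `no_escape_at_resolution` is not a proof. The randomized soundness
  suite feeds oracle-certified escapable cases (apertured shells with
  guests sized below the passage bound, balls and dumbbells) to the
  verifier and requires zero caging proofs.
* **Jittered ensembles** (Gaussian coordinate noise, σ = 0.1 Å default,
  fixed seed) emulate the *shape* of an MD conformational ensemble — many
  near-identical conformations straddling a classification threshold — not
  its physics. The screening host family randomizes shell radius, sphere
  radius and apertures so a ball-guest series produces all three classes.

What passing these tests shows: the implementation honours the one-sided
guarantee, the over-approximation property, the classification semantics
and determinism on geometries where ground truth is certifiable. What they
do not show: predictive accuracy on real crystal structures or MD
ensembles, which depends on radii choices, protonation and conformational
sampling outside the scope of a geometric verifier.

## Numerical choices

Geometric comparisons default to 1e-9 Å; quaternions must be unit within
1e-9; the witness clearance guard is 1e-6 Å. Clearance/penetration queries
group host spheres by radius and take per-group nearest-neighbour minima —
exact, not approximate, and verified against all-pairs scans. Penetration
is computed as an independent maximum (the deepest-overlap pair need not be
the smallest-gap pair). Cell labeling uses closed-ball queries, so a
penetration exactly equal to the margin counts as blocked (the conservative
direction). Ties in witness search are broken by deterministic C-order
index scanning. Degenerate inputs rejected with named-atom errors:
non-positive radii, radius underflow under −Δr, colliding oracle starts,
apertures that remove every shell sphere.

## Known limitations

* `NOT_PROVEN` is not a disproof of caging; completeness would require a
  complementary under-approximation that is out of scope.
* Orientation covering radii shrink slowly (∝ n^(−1/3)), so guests with
  large circumradius need many samples before the rotation margin stops
  dominating; the exact spherical-guest reduction sidesteps this only for
  ball-like probes.
* The cavity-probe diagnostic assumes the host centroid sits in the cavity.
* Flexibility is ensemble-based only; no conformer generation is provided.
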