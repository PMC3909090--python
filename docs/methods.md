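# Methods

## Overview

`hopdock` samples rigid-body decoy configurations of a protein dimer with a
basin-hopping search over SE(3). The search space is discretized by pairs of
*active surface triangles* — triples of sparse molecular-surface points that
are geometrically complementary across the two units and evolutionarily
conserved — and each aligned pose is refined against a three-term
physics score (Lennard-Jones + Coulomb + 12-10 hydrogen bonding) before a
Metropolis rule decides whether it joins the trajectory of minima.

One unit (the *base*) stays fixed; every pose is a proper rigid motion
`x -> R x + t` of the *moving* unit. Internal energies are constant because
both units are rigid, so only inter-unit atom pairs are ever scored.

## Surface representation

The molecular surface is approximated by a probe-accessible point cloud:
candidate points are sampled on each atom's van der Waals sphere
(golden-spiral directions, default density 1.0 point/Å²) and kept when a
water-sized probe (radius 1.4 Å) placed tangent at the point clears every
atom. The cloud is reduced to sparse *critical points* by greedy
farthest-point selection at 1.5 Å spacing.

Sampling directions are generated in a covariant frame built from the
unit's principal axes (with deterministic sign fixes), which makes the whole
surface pipeline *exactly* equivariant under rigid motion of the input —
a rotated unit yields rotated points with identical labels, not merely
statistically similar ones.

### Shape labels (cap / pit / belt)

Each critical point is labeled convex (`cap`), concave (`pit`) or
saddle-like/flat (`belt`). Classifying discrete, sub-nanometer molecular
surfaces is the numerically delicate step: the vdW surface undulates at the
atomic scale, and that bumpiness masks pocket-scale curvature. Two design
choices address this:

1. Shape analysis runs on the *probe-center* (solvent-accessible) surface,
   where rolling the probe smooths crevices narrower than the probe.
2. The label comes from a combined concavity score
   `s = (burial − 0.33) + 0.8 · κ`, where

   * `κ` is a mean-curvature estimate: a quadratic patch is least-squares
     fit to neighboring probe centers (3.0 Å neighborhood) in the tangent
     frame; the trace of its quadratic form is positive on concave patches,
     negative on convex ones, invariant to the in-plane axes, and the fit's
     linear terms absorb normal-estimation error;
   * `burial` is a ray-cast fraction: of 96 covariant directions, the
     fraction whose ray penetrates at least 1.0 Å through some atom within
     6.0 Å. A flat face measures ≈ 0.33 (the score's zero point), cavities
     more, tips less.

   Labels: `pit` for `s ≥ +0.10`, `cap` for `s ≤ −0.10`, else `belt`.

During development each proxy alone proved too noisy on discrete
atom-cluster surfaces (confusable with the ±0.1–0.2 noise floor); the sum
separates pockets, flat faces and knobs cleanly. The weight and thresholds
were fixed against analytic references — a sphere (κ = −1/R exactly), a flat
slab, and a spherical cavity — before being applied to the benchmark suite.

## Conservation gating

Per-residue conservation scores in [0, 1] are supplied externally (the
package reads a `chain / resSeq / score` table; producing such scores by
evolutionary-trace analysis is out of scope). A critical point inherits the
score of the residue of its nearest atom and is *active* when the score
strictly exceeds `conserve_th` (default 0.5). On a known complex the module
also reports the interface-conservation contrast: with critical points of
the two units in contact at ≤ 5 Å, `R_interface` is the conserved fraction
of interfacial points pooled over both units, `R_rest = 1 − R_interface`
(the literal complement; an alternative mode measures the conserved fraction
of non-interfacial points instead), and the headline number is
`(R_rest − R_interface) · 100` — negative when the interface is the more
conserved side.

## Active triangles and complementarity

Triples of critical points form triangles with all sides in [2.0, 5.0] Å —
longer than an atomic radius so the vertices sit on different atoms, short
enough to stay local — and a minimum internal angle of 15° against
degeneracy. A triangle is active when its lexicographically-first vertex is
active. Uniqueness keeps the set below the number of critical points: points
are scanned in lexicographic order, each active point contributes at most
one triangle (its first valid pair of lex-later partners), and a 1.0 Å
center-of-mass hash grid rejects triangles whose cell is already claimed.

Two triangles from opposite units are *complementary* when some vertex
correspondence matches all three side lengths within 1.0 Å and pairs
compatible shapes at every vertex: convex caps must meet concave pits, and
belts act as wildcards (configurable). When several correspondences are
valid, the docking transform uses the one whose alignment makes the matched
vertex normals most anti-parallel — surfaces facing each other — with a
deterministic tie-break. This facing rule resolves the two chiralities of a
side-length match and roughly doubles the fraction of clash-free alignments.

## Rigid transforms

A triangle defines an orthonormal reference frame (origin at its first
vertex, x along v2−v1, z along the plane normal, y completing a right-handed
set). The pose aligning moving-unit triangle `tr_B` onto base triangle
`tr_A` is the composition of `tr_A`'s frame with the inverse of `tr_B`'s —
for congruent triangles it superimposes the vertices exactly (residuals at
machine precision; an acceptance test drives 1000 random triangle/motion
pairs through this identity). The frame convention cancels because it is
applied identically on both units.

Transforms are also viewed in an axis-angle parameterization `<t, u, θ>`
for the minimization moves: the translation is resampled uniformly in a
`δt`-ball (radius law `r ∝ U^{1/3}`), the axis `u` is tilted by an angle
uniform in [0, δφ] about a uniformly random perpendicular direction, and θ
moves uniformly within ±δθ. Tilting (rather than spinning about `u`, which
would fold into θ and be redundant) is the adopted reading of the
axis-perturbation convention.

## Interaction energy

For a pose, over inter-unit atom pairs within a 12 Å neighbor cutoff:

* 12-6 Lennard-Jones: `ε_ij [(r_ij/d)^12 − 2 (r_ij/d)^6]` with `r_ij` the
  sum of vdW radii and `ε_ij` the geometric mean of well depths — minimum
  exactly `−ε_ij` at `d = r_ij`;
* Coulomb: `k q_i q_j / (e d²)` with dielectric `e = 1` (vacuum) and
  `k = 332.06 kcal·Å/(mol·e²)` as a configurable conversion constant (only
  energy differences and rankings matter to the search);
* 12-10 hydrogen bond: `5 (r0/d)^12 − 6 (r0/d)^10` with `r0 = 2.9 Å`
  (minimum exactly −1 there), summed over donor–acceptor pairs, one atom on
  each unit in either orientation, within 5 Å.

Atom parameters come from a reduced per-name / per-element table (backbone
names plus common polar side-chain atoms; element fallbacks). Donors are
identified heuristically when hydrogens are absent (N atoms and
hydroxyl/thiol oxygens; carbonyl/carboxyl oxygens as acceptors); an
`explicit_h` mode instead requires a hydrogen within 1.2 Å.

Numerics: pair distances are floored at 1e-6 Å; small systems use a fully
vectorized all-pairs path with precomputed pair matrices, large ones a
KD-tree at the same cutoff. Truncating the r⁻⁶ tail at 12 Å without
shifting biases absolute totals by ~1–2% on 150-atom units (measured
against the no-cutoff sum); rankings, which are what the search consumes,
are unaffected in practice.

## The basin-hopping loop

Defaults (the production conditions): `conserve_th = 0.5`, effective
temperature `T0 = −2/ln 0.39 ≈ 2.124 kcal/mol`, perturbation neighborhood
`d = 5 Å`, minimization steps `δt = 1.5 Å`, `δφ = 10°`, `δθ = 30°`, at most
`m = 100` proposals with a `k = 20` consecutive-failure cutoff.

* **Start**: a uniformly sampled complementary pair, aligned and minimized.
* **Perturb**: resample the generating pair inside a `d`-neighborhood (by
  triangle center-of-mass distance) of the current pair until complementary;
  `d = ∞` degenerates to memory-free random restart. If no clash-free
  complementary pair appears within 500 attempts the neighborhood doubles
  (up to three times) before falling back to global sampling — small
  neighborhoods can genuinely be empty.
* **Minimize**: greedy descent with the `<t, u, θ>` moves; a proposal is
  kept only if the energy strictly decreases. Poses with any inter-unit
  atom pair closer than 1.0 Å are rejected before scoring (steric
  pre-filter, configurable) — the LJ term already penalizes clashes, the
  filter only avoids astronomically large numbers.
* **Metropolis**: the minimized pose replaces the current minimum always if
  its energy is no higher, else with probability `exp(−ΔE/T_e)`. A rejected
  minimum leaves the state unchanged (standard basin-hopping convention).
  One guard augments the plain rule: when the current minimum is much deeper
  than everything the perturbation can reach (on the benchmark this happens
  after the planted basin is found, where rival minima sit 20+ kcal/mol
  higher and the acceptance probability collapses to ~1e-5), the trajectory
  would stagnate indefinitely. After `stall_limit` (default 50) consecutive
  rejections the next minimized pose is accepted unconditionally — the
  *occasional jumping* variant of basin hopping — and such steps are flagged
  in the step records so the Metropolis bookkeeping remains auditable.
  The two shipped temperature presets are defined by the acceptance
  probability they give a 2 kcal/mol increase: `T0 ↔ 0.39` (default) and
  `T1 = −2/ln 0.16 ≈ 1.091 ↔ 0.16`. The probabilities-to-presets mapping
  follows the convention that the *higher* temperature is the default and
  accepts more readily.

Every attempt is logged — the perturbation jump `l` (lRMSD between
consecutive perturbed poses), the minimization displacement `i` (lRMSD from
perturbed to minimized pose), ΔE, and the uniform Metropolis draw for uphill
moves — so a run is exactly replayable from its seed and the acceptance
bookkeeping is auditable after the fact.

## Ensemble analysis

lRMSD between two configurations is the root-mean-square deviation over all
heavy atoms of the dimer after optimal superposition (closed-form Kabsch
rotation with the determinant correction that excludes reflections; a
CA-only mode exists). The default superposes the whole dimer rather than
fixing the base unit; both conventions are common and the base-fixed one is
available through the coordinate helpers.

`Ω_p` retains the `⌈p/100·n⌉` lowest-total-energy configurations (ties by
trajectory index), so the minimum lRMSD over `Ω_p` is non-increasing in `p`
by construction; the report tabulates it for p = 10…100 along with the
medians and 0–5 / 5–10 Å band fractions of the logged `l` and `i`
distributions.

## The synthetic benchmark

`make_knob_pocket_pair` builds a complementary dimer with a *planted* native
pose so every stage is testable without external data:

* unit A: ~150 carbon-like pseudo-atoms (radius 1.7 Å, well depth
  0.1 kcal/mol, zero charge) on a jittered 2.4 Å lattice ball, with a
  spherical cavity (default radius 7.0 Å, center sunk 2.0 Å below the hull)
  plus a smaller side-lobe cavity carved out and *lined* with atoms placed
  on the carving spheres at 1.8 Å spacing;
* unit B: a congruent ball carrying a knob (radius = cavity radius − 3.3 Å
  contact gap) and a lobe finger that fill the cavity.

Design notes, each load-bearing:

* **Lining.** A raw carved lattice leaves a wall too ragged to carry a
  well-defined concavity; lining the cavity and shelling the knob on their
  defining spheres gives the interface the analytic geometry the shape
  classifier and the complementarity matcher are supposed to detect. The
  1.8 Å lining spacing keeps the probe from dimpling through gaps.
* **Side lobe.** A purely axisymmetric knob-in-pocket leaves a free
  azimuthal rotation with near-identical energy, so "the" planted pose
  would be ill-defined. The lobe breaks the symmetry both sterically and
  energetically.
* **Pocket scale and seating.** The pocket is deep and wide enough that the
  knob-pocket contact buries more near-optimal pairs than any rival docking
  mode — in particular the moving ball hugging the crater rim, which on
  shallower prototypes out-scored the planted pose and made recovery
  ill-posed. At generation time the docked complex is assembled first, the
  contact is verified (minimum inter-unit distance in [2.5, 4.5] Å), and the
  pose is seated at the bottom of its own energy basin by a line search
  along the pocket axis. The planted transform is then a seeded random
  rigid motion mapping unit B's own frame into the dock.
* **Conservation.** Pocket/knob residues score in (0.65, 0.95); 80% of the
  remaining residues score below 0.5 with a 20% minority of spurious
  conservation, emulating the enrichment of conserved residues on real
  interfaces. Optional extras plant a ±0.3 e charge ring and donor/acceptor
  caps across the contact to exercise the electrostatic and hydrogen-bond
  terms in isolation (off by default).

What the benchmark does *not* emulate: real side-chain chemistry and
packing, backbone connectivity, solvation, flexibility, the statistics of
real conservation scores, or realistic decoy degeneracy on large smooth
interfaces. Passing the recovery tests shows the machinery — surface,
gating, triangles, alignment, scoring, search — composes correctly and can
find a planted optimum; it does not by itself demonstrate accuracy on real
complexes.

## Problem sizes used in validation

The acceptance suite runs ten independent 500-decoy searches on the
~150-atom benchmark (production parameters) for the recovery and
energy-reduction checks, one 300-decoy unrestricted (`d = ∞`) run for the
jump-statistics ordering, 10⁵ Metropolis trials per temperature, 1000
alignment identities, and brute-force energy / lRMSD oracles on 10 poses /
100 instances. The acceptance script scales the searches to four 400-decoy
runs; ensembles of 10⁴ decoys on real-scale units are reachable through the
CLI but are not part of the test suite.

## Known limitations

* The cap/pit/belt classifier is calibrated for pocket-scale features
  (≥ ~3 Å); shallow grooves read as belts. Its thresholds assume vdW-scale
  atoms; coarse-grained beads would need re-calibration.
* The reduced parameter table is not a force field: charges are
  representative, not residue-topology-resolved, and hydrogens are handled
  heuristically.
* Energy totals depend on the cutoff convention (no shifting/switching);
  only rankings should be consumed.
* The search assumes rigid bodies throughout; no refinement stage is
  included.
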