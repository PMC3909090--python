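"""Synthetic complementary dimer systems with a planted native pose.

The generator builds two rigid pseudo-atomic units whose surfaces are
geometrically complementary by construction:

* unit A carries a pocket: a quasi-spherical cluster of carbon-like
  pseudo-atoms with a spherical cavity (plus a smaller side-lobe cavity)
  carved out of its surface;
* unit B carries a matching knob: a congruent cluster with a protrusion
  that fills the cavity, including the side lobe.

The side lobe breaks the azimuthal symmetry of a plain knob-in-pocket: a
purely axisymmetric interface would leave a rotational degree of freedom
that no real protein interface has, making the planted pose ill-defined.

The complex is assembled in docked coordinates first (so the contact
geometry can be verified directly), then unit B is expressed in its own
frame via a seeded random rigid motion; that motion is the planted
*native transform*.  Per-residue conservation maps are enriched on the
pocket/knob residues, mimicking an evolutionarily conserved interface.

Pseudo-atoms use a single carbon-like type (radius 1.7 A, well depth
0.1 kcal/mol, zero charge).  Optional extras plant a ring of opposite
charges around the contact (``charged_ring``) and donor/acceptor caps on
the knob tip and pocket floor (``hbond_caps``) so the electrostatic and
hydrogen-bond terms can be exercised in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .conservation import ConservationMap, write_conservation_scores
from .rigid_geometry import RigidTransform
from .structure_io import Atom, Unit, write_decoy, write_unit

__all__ = [
    "SyntheticSystem",
    "make_knob_pocket_pair",
    "make_random_scores",
    "write_system",
]

ATOM_RADIUS = 1.7  # Angstrom, carbon-like
WELL_DEPTH = 0.1  # kcal/mol
LATTICE_SPACING = 2.4  # Angstrom between pseudo-atom centers
JITTER = 0.12  # Angstrom, positional noise on the lattice
CONTACT_GAP = 3.3  # Angstrom, target wall-to-knob atom-center separation
RESIDUE_SIZE = 4  # pseudo-atoms per pseudo-residue
LINING_SPACING = 1.8  # Angstrom between lining/shell atoms: tight enough that a
                      # probe cannot dimple through the gaps of a curved feature


@dataclass
class SyntheticSystem:
    """A generated complementary dimer with its planted pose and scores."""

    unit_a: Unit  # pocket-bearing, base
    unit_b: Unit  # knob-bearing, moving (own frame)
    native_transform: RigidTransform
    scores_a: ConservationMap
    scores_b: ConservationMap
    seed: int
    metadata: dict = field(default_factory=dict)


def _fibonacci_directions(n: int) -> np.ndarray:
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _spherical_cluster(center: np.ndarray, radius: float, rng: np.random.Generator) -> np.ndarray:
    """A smooth ball of atoms: a surface shell on the defining sphere plus an
    interior fill, so the protrusion has the analytic spherical geometry."""
    n_shell = max(8, int(4.0 * np.pi * radius**2 / LINING_SPACING**2))
    shell = center + radius * _fibonacci_directions(n_shell)
    shell = shell + rng.normal(scale=0.05, size=shell.shape)
    parts = [shell, center[None, :]]
    if radius > 1.9 + LATTICE_SPACING / 2:
        inner_r = radius - LATTICE_SPACING
        n_inner = max(4, int(4.0 * np.pi * inner_r**2 / LINING_SPACING**2))
        parts.append(center + inner_r * _fibonacci_directions(n_inner))
    return np.vstack(parts)


def _lattice_ball(center: np.ndarray, n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """The n_atoms jittered cubic-lattice points nearest to ``center``."""
    reach = LATTICE_SPACING * (3.0 * n_atoms / (4.0 * np.pi)) ** (1.0 / 3.0) + 3 * LATTICE_SPACING
    k = int(np.ceil(reach / LATTICE_SPACING))
    ax = np.arange(-k, k + 1) * LATTICE_SPACING
    grid = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3) + center
    grid = grid + rng.normal(scale=JITTER, size=grid.shape)
    dist = np.linalg.norm(grid - center, axis=1)
    order = np.argsort(dist, kind="stable")
    return grid[order[:n_atoms]]


def _make_unit(coords: np.ndarray, chain: str, label: str) -> Unit:
    """Pseudo-atom unit with carbon-like parameters and 4-atom residues.

    Atoms are ordered lexicographically so consecutive residue runs are
    spatially coherent columns of the lattice.
    """
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    coords = coords[order]
    atoms = []
    for i, pos in enumerate(coords):
        atoms.append(
            Atom(
                serial=i + 1,
                name=f"C{i % RESIDUE_SIZE + 1}",  # unique within each residue
                element="C",
                residue_id=(chain, i // RESIDUE_SIZE + 1, ""),
                position=pos,
                res_name="UNK",
                charge=0.0,
                vdw_radius=ATOM_RADIUS,
                well_depth=WELL_DEPTH,
                hb_role="none",
            )
        )
    return Unit(atoms=atoms, chain_ids=frozenset({chain}), label=label)


def make_knob_pocket_pair(
    n_atoms_per_unit: int = 150,
    pocket_radius: float = 7.0,
    seed: int = 0,
    charged_ring: bool = False,
    hbond_caps: bool = False,
) -> SyntheticSystem:
    """Generate a pocket unit, a knob unit, and their planted docked pose.

    ``pocket_radius`` is the radius of the main cavity carved out of unit A;
    the knob fills it to a wall clearance of about ``CONTACT_GAP``.  At the
    planted pose the minimum inter-unit atom distance is verified to lie in
    [2.5, 4.5] A (contact without clash).  Deterministic given ``seed``.
    """
    if n_atoms_per_unit < 50:
        raise ValueError("n_atoms_per_unit must be at least 50")
    r_knob = pocket_radius - CONTACT_GAP
    if r_knob < 1.5:
        raise ValueError(
            f"pocket_radius {pocket_radius} too small for the contact gap: "
            "no room for a knob"
        )
    rng = np.random.default_rng(seed)

    # --- unit A: ball with a pear-shaped cavity -------------------------
    # Carve the cavity out of the lattice ball, then *line* it with atoms
    # placed on the carving spheres themselves: the cavity wall then has the
    # analytic spherical geometry the knob is built to match (a raw carved
    # lattice leaves a wall too ragged to carry a well-defined concavity).
    ball_a = _lattice_ball(np.zeros(3), n_atoms_per_unit, rng)
    radius_a = float(np.linalg.norm(ball_a, axis=1).max())
    # sink the cavity center below the hull so the bowl wraps past a
    # hemisphere: a deep, wide pocket has an unambiguous concavity, locks
    # the knob sterically, and gives the planted contact more buried area
    # than any rival docking mode (e.g. the moving ball hugging the crater
    # rim), so the planted pose is the energy optimum by construction
    pocket_center = np.array([0.0, 0.0, radius_a - 2.0])
    lobe_radius = 1.8
    lobe_center = pocket_center + np.array([r_knob + 0.7, 0.0, 0.0])
    lobe_carve = lobe_radius + CONTACT_GAP
    in_cavity = (np.linalg.norm(ball_a - pocket_center, axis=1) < pocket_radius) | (
        np.linalg.norm(ball_a - lobe_center, axis=1) < lobe_carve
    )
    coords_a = ball_a[~in_cavity]
    if len(coords_a) < 20:
        raise ValueError("pocket_radius incompatible with cluster size: pocket ate the unit")
    lining = []
    for center, radius, other_c, other_r in (
        (pocket_center, pocket_radius, lobe_center, lobe_carve),
        (lobe_center, lobe_carve, pocket_center, pocket_radius),
    ):
        shell = center + radius * _fibonacci_directions(
            max(12, int(4.0 * np.pi * radius**2 / LINING_SPACING**2))
        )
        shell = shell + rng.normal(scale=0.05, size=shell.shape)
        keep = (np.linalg.norm(shell, axis=1) <= radius_a - 0.8) & (
            np.linalg.norm(shell - other_c, axis=1) >= other_r
        )
        lining.append(shell[keep])
    lining = np.vstack(lining)
    # drop backing atoms overlapping the lining
    if len(lining):
        close = cdist(coords_a, lining).min(axis=1) < 1.6
        coords_a = np.vstack([coords_a[~close], lining])

    # --- unit B (docked frame): ball + smooth knob + lobe finger --------
    radius_b_est = LATTICE_SPACING * (3.0 * n_atoms_per_unit / (4.0 * np.pi)) ** (1.0 / 3.0)
    merge = 1.5  # knob ball sinks this deep into B's ball, keeping them contiguous
    center_b = pocket_center + np.array([0.0, 0.0, r_knob + radius_b_est - merge])
    ball_b = _lattice_ball(center_b, n_atoms_per_unit, rng)
    knob = _spherical_cluster(pocket_center, r_knob, rng)
    lobe = _spherical_cluster(lobe_center, lobe_radius, rng)
    coords_b = np.vstack([ball_b, knob, lobe])
    # drop accidental duplicates / near-overlaps from merged regions
    d_self = cdist(coords_b, coords_b)
    np.fill_diagonal(d_self, np.inf)
    drop = np.zeros(len(coords_b), dtype=bool)
    for i in range(len(coords_b)):
        if not drop[i]:
            drop |= (d_self[i] < 1.2) & (np.arange(len(coords_b)) > i)
    coords_b = coords_b[~drop]

    # --- contact adjustment ---------------------------------------------
    # shift B along the pocket axis until the planted pose is in contact
    # without clashing: minimum inter-unit distance in [2.5, 4.5] A
    z_hat = np.array([0.0, 0.0, 1.0])
    for _ in range(200):
        dmin = cdist(coords_a, coords_b).min()
        if dmin < 2.5:
            coords_b = coords_b + 0.1 * z_hat
        elif dmin > 4.5:
            coords_b = coords_b - 0.1 * z_hat
        else:
            break
    dmin = float(cdist(coords_a, coords_b).min())
    if not (2.5 <= dmin <= 4.5):
        raise ValueError(f"could not seat knob in pocket (min distance {dmin:.2f} A)")

    # seat the planted pose at the bottom of its own energy basin: line
    # search along the pocket axis with the pair potential of the pseudo-atoms
    def _lj_energy(xb):
        d = cdist(coords_a, xb)
        d = d[d <= 12.0]
        sr6 = (2.0 * ATOM_RADIUS / d) ** 6
        return float(np.sum(WELL_DEPTH * (sr6 * sr6 - 2.0 * sr6)))

    best_dz, best_e = 0.0, _lj_energy(coords_b)
    for dz in np.arange(-1.0, 1.001, 0.05):
        shifted = coords_b + dz * z_hat
        if cdist(coords_a, shifted).min() < 2.5:
            continue
        e = _lj_energy(shifted)
        if e < best_e:
            best_dz, best_e = float(dz), e
    coords_b = coords_b + best_dz * z_hat
    dmin = float(cdist(coords_a, coords_b).min())

    # --- express B in its own frame via the planted transform -----------
    rot = Rotation.random(random_state=np.random.RandomState(seed + 1)).as_matrix()
    anchor = coords_b.mean(axis=0)
    # local coordinates satisfy: world = rot @ local + anchor
    local_b = (coords_b - anchor) @ rot
    native = RigidTransform(rot, anchor)

    unit_a = _make_unit(coords_a, "A", "base")
    unit_b = _make_unit(local_b, "B", "moving")

    # sanity: the planted pose must reproduce the docked contact
    world_b = native.apply(unit_b.coords)
    dmin_check = float(cdist(unit_a.coords, world_b).min())
    if not (2.5 <= dmin_check <= 4.5):
        raise AssertionError("planted transform lost the docked contact")

    # --- optional charge ring and hydrogen-bond caps --------------------
    if charged_ring:
        _plant_charge_ring(unit_a, unit_b, native, pocket_center, pocket_radius)
    if hbond_caps:
        _plant_hbond_caps(unit_a, unit_b, native, pocket_center, r_knob)

    # --- conservation maps enriched on the interface --------------------
    iface_a = _interface_residues(unit_a, None, pocket_center, pocket_radius, lobe_center,
                                  lobe_radius + CONTACT_GAP)
    iface_b = _interface_residues(unit_b, native, pocket_center, r_knob + 1.6, lobe_center,
                                  lobe_radius + 1.6)
    scores_a = _enriched_scores(unit_a, iface_a, rng)
    scores_b = _enriched_scores(unit_b, iface_b, rng)

    return SyntheticSystem(
        unit_a=unit_a,
        unit_b=unit_b,
        native_transform=native,
        scores_a=scores_a,
        scores_b=scores_b,
        seed=seed,
        metadata={
            "n_atoms_a": len(unit_a),
            "n_atoms_b": len(unit_b),
            "pocket_center": pocket_center,
            "pocket_radius": pocket_radius,
            "knob_radius": r_knob,
            "lobe_center": lobe_center,
            "lobe_radius": lobe_radius,
            "min_contact_distance": dmin_check,
            "interface_residues_a": iface_a,
            "interface_residues_b": iface_b,
        },
    )


def _interface_residues(unit, native, c1, r1, c2, r2):
    """Residues with any atom inside either contact sphere (+1.5 A shell)."""
    coords = unit.coords if native is None else native.apply(unit.coords)
    near = (np.linalg.norm(coords - c1, axis=1) <= r1 + 1.5) | (
        np.linalg.norm(coords - c2, axis=1) <= r2 + 1.5
    )
    return sorted({unit.atoms[i].residue_id[:2] for i in np.nonzero(near)[0]})


def _enriched_scores(unit, interface_residues, rng) -> ConservationMap:
    """Interface residues conserved (> 0.5); >= 80% of the rest below 0.5."""
    iface = set(interface_residues)
    scores = {}
    for res in unit.residue_ids:
        key = res[:2]
        if key in scores:
            continue
        if key in iface:
            scores[key] = float(rng.uniform(0.65, 0.95))
        elif rng.random() < 0.2:  # a minority of spuriously conserved residues
            scores[key] = float(rng.uniform(0.55, 0.75))
        else:
            scores[key] = float(rng.uniform(0.05, 0.45))
    return ConservationMap(scores)


def _plant_charge_ring(unit_a, unit_b, native, pocket_center, pocket_radius):
    """Opposite partial charges on the pocket rim (A) and knob base (B)."""
    da = np.linalg.norm(unit_a.coords - pocket_center, axis=1)
    rim = np.argsort(np.abs(da - (pocket_radius + 0.8)))[:12]
    for i in rim:
        unit_a.atoms[i].charge = -0.3
    world_b = native.apply(unit_b.coords)
    db = np.linalg.norm(world_b - pocket_center, axis=1)
    base = np.argsort(db)[:12]
    for i in base:
        unit_b.atoms[i].charge = +0.3


def _plant_hbond_caps(unit_a, unit_b, native, pocket_center, r_knob):
    """Donor caps on the knob tip (B), acceptor caps on the pocket floor (A)."""
    floor_dir = pocket_center / np.linalg.norm(pocket_center)
    world_b = native.apply(unit_b.coords)
    tip = np.argsort(world_b @ floor_dir)[:6]  # B atoms deepest into the cavity
    for i in tip:
        unit_b.atoms[i].hb_role = "donor"
        unit_b.atoms[i].element = "N"
        unit_b.atoms[i].name = f"N{i % RESIDUE_SIZE + 1}"
    # acceptors: the cavity-wall atoms facing the planted donors
    donor_centroid = world_b[tip].mean(axis=0)
    floor = np.argsort(np.linalg.norm(unit_a.coords - donor_centroid, axis=1))[:6]
    for i in floor:
        unit_a.atoms[i].hb_role = "acceptor"
        unit_a.atoms[i].element = "O"
        unit_a.atoms[i].name = f"O{i % RESIDUE_SIZE + 1}"


def make_random_scores(unit: Unit, frac_conserved: float, seed: int = 0) -> ConservationMap:
    """Uniformly placed conservation: exactly round(frac * n_residues)
    residues score above 0.5, the rest at or below."""
    if not (0.0 <= frac_conserved <= 1.0):
        raise ValueError("frac_conserved must be in [0, 1]")
    rng = np.random.default_rng(seed)
    residues = sorted({r[:2] for r in unit.residue_ids})
    n_cons = round(frac_conserved * len(residues))
    order = rng.permutation(len(residues))
    scores = {}
    for rank, idx in enumerate(order):
        if rank < n_cons:
            scores[residues[idx]] = float(rng.uniform(0.55, 0.95))
        else:
            scores[residues[idx]] = float(rng.uniform(0.05, 0.5))
    return ConservationMap(scores)


def write_system(system: SyntheticSystem, outdir: str | Path) -> dict[str, Path]:
    """Write unitA.pdb, unitB.pdb, native.pdb and the two score tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "unit_a": outdir / "unitA.pdb",
        "unit_b": outdir / "unitB.pdb",
        "native": outdir / "native.pdb",
        "scores_a": outdir / "scores_a.tsv",
        "scores_b": outdir / "scores_b.tsv",
    }
    write_unit(system.unit_a, paths["unit_a"])
    write_unit(system.unit_b, paths["unit_b"])
    write_decoy(system.unit_a, system.unit_b, system.native_transform, paths["native"])
    write_conservation_scores(system.scores_a, paths["scores_a"])
    write_conservation_scores(system.scores_b, paths["scores_b"])
    return paths
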