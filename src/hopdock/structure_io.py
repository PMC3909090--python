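"""PDB input/output and per-atom physics parameters for rigid docking units.

A *unit* is one rigid monomer: an ordered list of heavy atoms read from the
ATOM records of selected chains of a PDB file.  Before scoring, each atom is
assigned a partial charge, a van der Waals radius, a well depth and a
hydrogen-bond role (donor / acceptor / none) from a reduced per-element /
per-atom-name parameter table.  The table deliberately covers only what the
pairwise interaction energy consumes (charges, radii, well depths, H-bond
roles); it is not a force field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from Bio.PDB import PDBParser

from .rigid_geometry import RigidTransform

__all__ = [
    "Atom",
    "Unit",
    "ParameterTable",
    "read_pdb",
    "assign_parameters",
    "write_decoy",
    "write_unit",
]

ResidueId = tuple[str, int, str]  # (chain id, residue number, insertion code)


@dataclass
class Atom:
    """One heavy atom of a rigid unit."""

    serial: int
    name: str
    element: str
    residue_id: ResidueId
    position: np.ndarray  # (3,) Angstrom
    res_name: str = "UNK"
    charge: float | None = None  # elementary charges
    vdw_radius: float | None = None  # Angstrom
    well_depth: float | None = None  # kcal/mol
    hb_role: str = "none"  # none | donor | acceptor

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if self.well_depth is not None and self.well_depth < 0:
            raise ValueError(f"atom {self.serial}: well_depth must be non-negative")
        if self.hb_role not in ("none", "donor", "acceptor"):
            raise ValueError(f"atom {self.serial}: bad hb_role {self.hb_role!r}")


@dataclass
class Unit:
    """A rigid monomer: ordered atoms plus bookkeeping."""

    atoms: list[Atom]
    chain_ids: frozenset[str]
    label: str = "base"  # "base" | "moving"
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers in unit")
        if len(self.atoms) < 4:
            raise ValueError("a unit needs at least 4 atoms")
        X = np.stack([a.position for a in self.atoms])
        # non-collinearity: rank of centered coordinates must exceed 1
        if np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-6) < 2:
            raise ValueError("unit atoms are collinear")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array (cached; geometry never mutates in place)."""
        if self._coords is None or len(self._coords) != len(self.atoms):
            self._coords = np.stack([a.position for a in self.atoms])
        return self._coords

    @property
    def residue_ids(self) -> list[ResidueId]:
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def parameterized(self) -> bool:
        return all(
            a.charge is not None and a.vdw_radius is not None and a.well_depth is not None
            for a in self.atoms
        )


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

# Reduced CHARMM-like defaults: (charge e, vdw radius A, well depth kcal/mol, hb role).
# Names cover the protein backbone and common polar side-chain atoms; anything
# else falls back to its element entry.
_DEFAULT_NAME_ENTRIES: dict[str, tuple[float, float, float, str]] = {
    "N": (-0.47, 1.85, 0.20, "donor"),
    "CA": (0.07, 2.275, 0.02, "none"),
    "C": (0.51, 2.00, 0.11, "none"),
    "O": (-0.51, 1.70, 0.12, "acceptor"),
    "OXT": (-0.67, 1.70, 0.12, "acceptor"),
    # hydroxyl / thiol side chains: polar H bearers -> donors
    "OG": (-0.66, 1.77, 0.15, "donor"),
    "OG1": (-0.66, 1.77, 0.15, "donor"),
    "OH": (-0.54, 1.77, 0.15, "donor"),
    "SG": (-0.23, 1.98, 0.45, "donor"),
    # carboxylate / amide side-chain oxygens -> acceptors
    "OD1": (-0.55, 1.70, 0.12, "acceptor"),
    "OD2": (-0.55, 1.70, 0.12, "acceptor"),
    "OE1": (-0.55, 1.70, 0.12, "acceptor"),
    "OE2": (-0.55, 1.70, 0.12, "acceptor"),
    # side-chain nitrogens -> donors
    "ND1": (-0.36, 1.85, 0.20, "donor"),
    "ND2": (-0.62, 1.85, 0.20, "donor"),
    "NE": (-0.70, 1.85, 0.20, "donor"),
    "NE1": (-0.61, 1.85, 0.20, "donor"),
    "NE2": (-0.62, 1.85, 0.20, "donor"),
    "NH1": (-0.80, 1.85, 0.20, "donor"),
    "NH2": (-0.80, 1.85, 0.20, "donor"),
    "NZ": (-0.30, 1.85, 0.20, "donor"),
    "SD": (-0.09, 1.98, 0.45, "none"),
}

_DEFAULT_ELEMENT_ENTRIES: dict[str, tuple[float, float, float, str]] = {
    "C": (0.00, 2.00, 0.10, "none"),
    "N": (-0.30, 1.85, 0.20, "donor"),
    "O": (-0.40, 1.70, 0.12, "acceptor"),
    "S": (-0.09, 1.98, 0.45, "none"),
    "H": (0.10, 1.00, 0.046, "none"),
    "P": (1.00, 2.15, 0.585, "none"),
}


@dataclass
class ParameterTable:
    """Per-atom physics parameters with an element-level fallback.

    ``dielectric`` is the dimensionless constant *e* of the Coulomb term
    (vacuum value 1 by default) and ``r0_hbond`` the idealized hydrogen-bond
    distance in Angstrom (2.9 by default).  ``donor_mode`` selects how donors
    are identified when hydrogens are absent: ``"heuristic"`` (N atoms and
    hydroxyl/thiol oxygens are donors) or ``"explicit_h"`` (an N/O atom is a
    donor only if a hydrogen lies within ``h_bond_length`` of it in the file).
    """

    name_entries: dict[str, tuple[float, float, float, str]] = field(
        default_factory=lambda: dict(_DEFAULT_NAME_ENTRIES)
    )
    element_entries: dict[str, tuple[float, float, float, str]] = field(
        default_factory=lambda: dict(_DEFAULT_ELEMENT_ENTRIES)
    )
    dielectric: float = 1.0
    r0_hbond: float = 2.9
    donor_mode: str = "heuristic"
    h_bond_length: float = 1.2

    def lookup(self, element: str, name: str) -> tuple[float, float, float, str]:
        entry = self.name_entries.get(name.upper())
        if entry is not None:
            return entry
        entry = self.element_entries.get(element.upper())
        if entry is None:
            raise KeyError(
                f"no parameters for atom name {name!r} (element {element!r}) "
                "and no element fallback"
            )
        return entry

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterTable":
        """Load a user override table; unspecified entries keep their defaults."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        table = cls()
        for key, section in (("names", table.name_entries), ("elements", table.element_entries)):
            for name, entry in (data.get(key) or {}).items():
                section[str(name).upper()] = (
                    float(entry["charge"]),
                    float(entry["vdw_radius"]),
                    float(entry["well_depth"]),
                    str(entry.get("hb_role", "none")),
                )
        for scalar in ("dielectric", "r0_hbond", "donor_mode", "h_bond_length"):
            if scalar in data:
                setattr(table, scalar, data[scalar])
        return table


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_pdb(path: str | Path, chains: list[str] | str, label: str = "base") -> Unit:
    """Read the ATOM records of the requested chains into a :class:`Unit`.

    HETATM records and waters are excluded.  Disordered atoms are resolved to
    the highest-occupancy alternate location (ties: the first encountered).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    if isinstance(chains, str):
        chains = [c.strip() for c in chains.split(",") if c.strip()]
    if not chains:
        raise ValueError("no chains requested")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # biopython warns on nonstandard records
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    model = next(structure.get_models())

    present = {ch.id for ch in model}
    missing = [c for c in chains if c not in present]
    if missing:
        raise ValueError(f"chain not found in {path.name}: {', '.join(missing)}")

    atoms: list[Atom] = []
    for chain_id in chains:
        chain = model[chain_id]
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag != " " or residue.resname.strip() in _WATER_NAMES:
                continue
            for atom in residue:
                if atom.is_disordered():
                    alts = atom.disordered_get_list()
                    occ = [a.get_occupancy() or 0.0 for a in alts]
                    atom = alts[int(np.argmax(occ))]  # ties: first (argmax rule)
                element = (atom.element or atom.get_name()[:1]).strip().upper()
                atoms.append(
                    Atom(
                        serial=atom.get_serial_number(),
                        name=atom.get_name().strip(),
                        element=element,
                        residue_id=(chain_id, int(resseq), icode.strip()),
                        position=np.asarray(atom.get_coord(), dtype=float),
                        res_name=residue.resname.strip(),
                    )
                )
        if not any(a.residue_id[0] == chain_id for a in atoms):
            raise ValueError(f"chain {chain_id} of {path.name} has no ATOM records")

    return Unit(atoms=atoms, chain_ids=frozenset(chains), label=label)


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------


def assign_parameters(unit: Unit, table: ParameterTable | None = None) -> Unit:
    """Return a copy of ``unit`` with charges, radii, well depths and H-bond roles.

    Coordinates are untouched (same arrays, bitwise).  With
    ``donor_mode="explicit_h"`` the donor flag from the table is kept only for
    N/O atoms that have a hydrogen within ``table.h_bond_length``.
    """
    table = table or ParameterTable()
    new_atoms: list[Atom] = []
    unknown: list[str] = []
    h_positions = None
    if table.donor_mode == "explicit_h":
        h_positions = np.array(
            [a.position for a in unit.atoms if a.element == "H"], dtype=float
        ).reshape(-1, 3)
    for atom in unit.atoms:
        try:
            charge, radius, depth, role = table.lookup(atom.element, atom.name)
        except KeyError:
            unknown.append(f"{atom.serial} {atom.name} ({atom.element})")
            continue
        if role == "donor" and h_positions is not None:
            has_h = len(h_positions) > 0 and (
                np.linalg.norm(h_positions - atom.position, axis=1).min()
                <= table.h_bond_length
            )
            if not has_h:
                role = "none" if atom.element == "N" else "acceptor"
        new_atoms.append(
            replace(atom, charge=charge, vdw_radius=radius, well_depth=depth, hb_role=role)
        )
    if unknown:
        raise ValueError("atoms without parameters: " + "; ".join(unknown))
    return Unit(atoms=new_atoms, chain_ids=unit.chain_ids, label=unit.label)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def _format_atom_line(atom: Atom, serial: int, position: np.ndarray) -> str:
    name = atom.name
    # PDB column rule: 1-character elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    chain, resseq, icode = atom.residue_id
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {atom.res_name:<3.3s} {chain[:1]}"
        f"{resseq:4d}{(icode or ' '):1.1s}   "
        f"{position[0]:8.3f}{position[1]:8.3f}{position[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}\n"
    )


def write_unit(unit: Unit, path: str | Path, transform: RigidTransform | None = None) -> None:
    """Write a unit as PDB ATOM records, optionally after a rigid motion."""
    coords = unit.coords if transform is None else transform.apply(unit.coords)
    lines = []
    last_chain = None
    serial = 0
    for atom, pos in zip(unit.atoms, coords):
        chain = atom.residue_id[0]
        if last_chain is not None and chain != last_chain:
            lines.append("TER\n")
        last_chain = chain
        serial += 1
        lines.append(_format_atom_line(atom, serial, pos))
    lines.append("TER\nEND\n")
    Path(path).write_text("".join(lines))


def write_decoy(base: Unit, moving: Unit, transform: RigidTransform, path: str | Path) -> None:
    """Write a docked pose: base atoms unchanged, moving atoms transformed.

    Chain identifiers of both units are preserved; serial numbers are
    renumbered consecutively.
    """
    shared = base.chain_ids & moving.chain_ids
    if shared:
        warnings.warn(f"base and moving unit share chain ids: {sorted(shared)}")
    moved = transform.apply(moving.coords)
    lines = []
    serial = 0
    last_chain = None
    for unit, coords in ((base, base.coords), (moving, moved)):
        for atom, pos in zip(unit.atoms, coords):
            chain = atom.residue_id[0]
            if last_chain is not None and chain != last_chain:
                lines.append("TER\n")
            last_chain = chain
            serial += 1
            lines.append(_format_atom_line(atom, serial, pos))
    lines.append("TER\nEND\n")
    Path(path).write_text("".join(lines))
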