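"""Pairwise interaction energy of a docked pose.

The score is the sum of three terms over *inter-unit* atom pairs:

* a 12-6 Lennard-Jones term  eps_ij [ (r_ij/d)^12 - 2 (r_ij/d)^6 ],
  with r_ij the sum of the two vdW radii and eps_ij the geometric mean of
  the two well depths (its minimum is exactly -eps_ij at d = r_ij);
* a Coulomb term  k q_i q_j / (e d^2), with e the dielectric constant
  (vacuum value 1) and k = 332.06 kcal A / (mol e^2) the unit conversion
  (configurable; only energy differences matter to the search);
* a 12-10 hydrogen-bond term  5 (r0/d)^12 - 6 (r0/d)^10 over donor-acceptor
  pairs (one atom on each unit, either orientation), with r0 = 2.9 A the
  idealized hydrogen-bond distance (its minimum is exactly -1 at d = r0).

Intra-unit pairs are never scored: the units are rigid, so their internal
energy is constant along the search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .rigid_geometry import RigidTransform
from .structure_io import ParameterTable, Unit

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyBreakdown",
    "vdw_pair",
    "electrostatic_pair",
    "hbond_pair",
    "interaction_energy",
    "EnergyModel",
]

#: kcal * Angstrom / (mol * e^2); Coulomb's law in kcal/mol for charges in
#: elementary charges and distances in Angstrom.
COULOMB_CONSTANT = 332.06

#: default neighbor cutoff (Angstrom) for pair enumeration
DEFAULT_PAIR_CUTOFF = 12.0

#: donor-acceptor pairs farther than this never count as hydrogen bonds
DEFAULT_HBOND_CUTOFF = 5.0

_BRUTE_FORCE_LIMIT = 400_000  # N*M above which the KD-tree pair path is used


@dataclass(frozen=True)
class EnergyBreakdown:
    """Interaction energy split by term; ``total`` is their exact sum."""

    e_vdw: float
    e_elec: float
    e_hbond: float

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_elec + self.e_hbond

    def __repr__(self) -> str:  # compact, for logs
        return (
            f"EnergyBreakdown(vdw={self.e_vdw:.3f}, elec={self.e_elec:.3f}, "
            f"hbond={self.e_hbond:.3f}, total={self.total:.3f})"
        )


def vdw_pair(epsilon: float, r_sum: float, d: float) -> float:
    """12-6 Lennard-Jones energy of one pair; minimum -epsilon at d = r_sum."""
    if d <= 0:
        raise ValueError("pair distance must be positive")
    sr6 = (r_sum / d) ** 6
    return epsilon * (sr6 * sr6 - 2.0 * sr6)


def electrostatic_pair(
    qi: float,
    qj: float,
    dielectric: float,
    d: float,
    conversion: float = COULOMB_CONSTANT,
) -> float:
    """Coulomb energy of one pair, q_i q_j / (e d^2) times the conversion constant."""
    if d <= 0:
        raise ValueError("pair distance must be positive")
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    return conversion * qi * qj / (dielectric * d * d)


def hbond_pair(r0: float, d: float) -> float:
    """12-10 hydrogen-bond energy of one pair; minimum -1 at d = r0."""
    if d <= 0:
        raise ValueError("pair distance must be positive")
    sr = r0 / d
    sr10 = sr**10
    return 5.0 * sr10 * sr * sr - 6.0 * sr10


class EnergyModel:
    """Precomputed scorer for repeated pose evaluations of one unit pair.

    Extracts the per-atom parameter arrays once; :meth:`evaluate` then scores
    an arbitrary pose of the moving unit.  Pair enumeration uses a dense
    distance matrix for small systems and a KD-tree for large ones.
    """

    def __init__(
        self,
        base: Unit,
        moving: Unit,
        params: ParameterTable | None = None,
        pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
        hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
        conversion: float = COULOMB_CONSTANT,
    ) -> None:
        for unit in (base, moving):
            if not unit.parameterized():
                raise ValueError(
                    f"{unit.label} unit has unparameterized atoms: run assign_parameters first"
                )
        self.params = params or ParameterTable()
        self.pair_cutoff = float(pair_cutoff)
        self.hbond_cutoff = float(hbond_cutoff)
        self.conversion = float(conversion)

        self.xb = base.coords.astype(float)
        self.xm_local = moving.coords.astype(float)
        self.qb = np.array([a.charge for a in base.atoms])
        self.qm = np.array([a.charge for a in moving.atoms])
        self.rb = np.array([a.vdw_radius for a in base.atoms])
        self.rm = np.array([a.vdw_radius for a in moving.atoms])
        eb = np.sqrt(np.array([a.well_depth for a in base.atoms]))
        em = np.sqrt(np.array([a.well_depth for a in moving.atoms]))
        self.eps_sqrt_b, self.eps_sqrt_m = eb, em
        roles_b = np.array([a.hb_role for a in base.atoms])
        roles_m = np.array([a.hb_role for a in moving.atoms])
        self.donor_b = roles_b == "donor"
        self.acceptor_b = roles_b == "acceptor"
        self.donor_m = roles_m == "donor"
        self.acceptor_m = roles_m == "acceptor"
        self._dense = self.xb.shape[0] * self.xm_local.shape[0] <= _BRUTE_FORCE_LIMIT
        self._tree_b = None if self._dense else cKDTree(self.xb)
        if self._dense:
            # precomputed pair matrices for the vectorized dense path
            self._r_sum2 = (self.rb[:, None] + self.rm[None, :]) ** 2
            self._eps = np.outer(eb, em)
            self._qq = (
                self.conversion
                * np.outer(self.qb, self.qm)
                / self.params.dielectric
            )
            self._hb = (self.donor_b[:, None] & self.acceptor_m[None, :]) | (
                self.acceptor_b[:, None] & self.donor_m[None, :]
            )
            self._has_hb = bool(self._hb.any())
            self._has_q = bool(np.any(self.qb != 0) and np.any(self.qm != 0))

    # -- internals ---------------------------------------------------------
    def _pairs(self, xm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Indices (i into base, j into moving) and distances of pairs in cutoff."""
        if self._dense:
            D = cdist(self.xb, xm)
            if np.isfinite(self.pair_cutoff):
                ii, jj = np.nonzero(D <= self.pair_cutoff)
            else:
                ii, jj = np.nonzero(np.ones_like(D, dtype=bool))
            return ii, jj, D[ii, jj]
        cutoff = self.pair_cutoff
        if not np.isfinite(cutoff):
            D = cdist(self.xb, xm)
            ii, jj = np.nonzero(np.ones_like(D, dtype=bool))
            return ii, jj, D[ii, jj]
        tree_m = cKDTree(xm)
        coo = self._tree_b.sparse_distance_matrix(tree_m, cutoff, output_type="coo_matrix")
        return coo.row, coo.col, coo.data

    def evaluate(self, transform: RigidTransform) -> tuple[EnergyBreakdown, float]:
        """Score a pose; returns (breakdown, minimum inter-unit distance)."""
        xm = transform.apply(self.xm_local)
        if self._dense:
            return self._evaluate_dense(xm)
        ii, jj, d = self._pairs(xm)
        if len(ii) == 0:
            min_dist = self._min_distance(xm)
            return EnergyBreakdown(0.0, 0.0, 0.0), min_dist
        d = np.maximum(d, 1e-6)  # guard exact overlap against division by zero
        r_sum = self.rb[ii] + self.rm[jj]
        eps = self.eps_sqrt_b[ii] * self.eps_sqrt_m[jj]
        sr6 = (r_sum / d) ** 6
        e_vdw = float(np.sum(eps * (sr6 * sr6 - 2.0 * sr6)))
        e_elec = float(
            np.sum(self.conversion * self.qb[ii] * self.qm[jj] / (self.params.dielectric * d * d))
        )
        hb = (self.donor_b[ii] & self.acceptor_m[jj]) | (self.acceptor_b[ii] & self.donor_m[jj])
        hb &= d <= self.hbond_cutoff
        if np.any(hb):
            sr = self.params.r0_hbond / d[hb]
            sr10 = sr**10
            e_hbond = float(np.sum(5.0 * sr10 * sr * sr - 6.0 * sr10))
        else:
            e_hbond = 0.0
        return EnergyBreakdown(e_vdw, e_elec, e_hbond), float(d.min())

    def _evaluate_dense(self, xm: np.ndarray) -> tuple[EnergyBreakdown, float]:
        """Vectorized all-pairs path using the precomputed matrices."""
        d2 = cdist(self.xb, xm, "sqeuclidean")
        min_dist = float(np.sqrt(d2.min()))
        np.maximum(d2, 1e-12, out=d2)  # guard exact overlap
        inv_d2 = 1.0 / d2
        if np.isfinite(self.pair_cutoff):
            inv_d2 *= d2 <= self.pair_cutoff**2  # zeroed pairs contribute nothing
        x = self._r_sum2 * inv_d2
        sr6 = x * x
        sr6 *= x
        e_vdw = float(np.sum(self._eps * (sr6 * sr6 - 2.0 * sr6)))
        e_elec = float(np.sum(self._qq * inv_d2)) if self._has_q else 0.0
        if self._has_hb:
            inv_hb = inv_d2 * (self._hb & (d2 <= self.hbond_cutoff**2))
            sr2 = self.params.r0_hbond**2 * inv_hb
            sr4 = sr2 * sr2
            sr10 = sr4 * sr4 * sr2
            e_hbond = float(np.sum(5.0 * sr10 * sr2 - 6.0 * sr10))
        else:
            e_hbond = 0.0
        return EnergyBreakdown(e_vdw, e_elec, e_hbond), min_dist

    def _min_distance(self, xm: np.ndarray) -> float:
        if self._dense:
            return float(cdist(self.xb, xm).min())
        dist, _ = self._tree_b.query(xm, k=1)
        return float(dist.min())

    def min_distance(self, transform: RigidTransform) -> float:
        """Minimum inter-unit atom distance at a pose (steric pre-filter)."""
        return self._min_distance(transform.apply(self.xm_local))


def interaction_energy(
    base: Unit,
    moving: Unit,
    transform: RigidTransform,
    params: ParameterTable | None = None,
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    conversion: float = COULOMB_CONSTANT,
) -> EnergyBreakdown:
    """Score one docked pose (see module docstring for the three terms).

    ``pair_cutoff`` may be ``numpy.inf`` to enumerate all inter-unit pairs.
    For repeated evaluations of the same unit pair build an
    :class:`EnergyModel` once instead.
    """
    model = EnergyModel(
        base,
        moving,
        params=params,
        pair_cutoff=pair_cutoff,
        hbond_cutoff=hbond_cutoff,
        conversion=conversion,
    )
    breakdown, _ = model.evaluate(transform)
    return breakdown
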