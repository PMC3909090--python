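"""Ensemble scoring: least RMSD to a native complex, energy reduction, jump stats.

lRMSD between two configurations of the same dimer is the root-mean-square
atomic deviation minimized over all proper rigid motions of one onto the
other (optimal superposition; reflections excluded).  An ensemble is reduced
by energy by retaining the p% lowest-total-energy configurations (Omega_p);
the minimum lRMSD over Omega_p is non-increasing in p by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Unit

__all__ = [
    "lrmsd",
    "optimal_superposition",
    "reduce_by_energy",
    "ensemble_report",
    "EnsembleReport",
    "dimer_coords",
    "match_native",
]

NEAR_NATIVE_CUTOFF = 5.0  # Angstrom; 2-5 A is the conventional near-native band


def optimal_superposition(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ||X - (Y R^T + t)||.

    Closed-form Kabsch solution with the determinant correction that
    excludes reflections.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    H = (Y - cy).T @ (X - cx)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cx - R @ cy
    return R, t


def lrmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Least RMSD between corresponding point sets after optimal superposition."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"coordinate shapes differ: {X.shape} vs {Y.shape}")
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need matching (N, 3) arrays with N >= 3")
    R, t = optimal_superposition(X, Y)
    diff = X - (Y @ R.T + t)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def dimer_coords(base: Unit, moving: Unit, transform, ca_only: bool = False) -> np.ndarray:
    """Full-dimer coordinates of a pose: base atoms then transformed moving atoms."""
    xb, xm = base.coords, transform.apply(moving.coords)
    if ca_only:
        mb = np.array([a.name == "CA" for a in base.atoms])
        mm = np.array([a.name == "CA" for a in moving.atoms])
        xb, xm = xb[mb], xm[mm]
    return np.vstack([xb, xm])


def match_native(native_base: Unit, native_moving: Unit, base: Unit, moving: Unit) -> np.ndarray:
    """Native dimer coordinates reordered to the decoy atom order.

    Atoms are matched by (chain, resSeq, iCode, name); a decoy atom missing
    from the native complex is an error.
    """
    coords = []
    for native, unit in ((native_base, base), (native_moving, moving)):
        index = {(a.residue_id, a.name): a.position for a in native.atoms}
        for a in unit.atoms:
            key = (a.residue_id, a.name)
            if key not in index:
                raise ValueError(f"atom {key} not found in native complex")
            coords.append(index[key])
    return np.stack(coords)


def reduce_by_energy(configurations: list, p: float) -> list:
    """The Omega_p subset: ceil(p/100 * n) lowest-total-energy configurations.

    Ties break by trajectory index.  Returned in ascending energy order.
    """
    if not configurations:
        raise ValueError("empty ensemble")
    if not (0 < p <= 100):
        raise ValueError("p must be in (0, 100]")
    n_keep = math.ceil(p / 100.0 * len(configurations))
    ranked = sorted(configurations, key=lambda c: (c.energy.total, c.index))
    return ranked[:n_keep]


@dataclass
class EnsembleReport:
    """Summary statistics of a decoy ensemble against a native complex."""

    lowest_lrmsd: float
    pct_within_cutoff: float  # % of decoys with lRMSD < near-native cutoff
    omega_curve: dict[int, float]  # p% -> lowest lRMSD within Omega_p
    l_median: float  # median perturbation jump (l_m), Angstrom
    i_median: float  # median minimization displacement (i_m), Angstrom
    l_pct_0_5: float
    l_pct_5_10: float
    i_pct_0_5: float
    i_pct_5_10: float
    lrmsds: np.ndarray = field(repr=False)  # per accepted decoy, ensemble order

    def to_rows(self) -> list[dict]:
        rows = [
            {"statistic": "lowest_lrmsd", "value": self.lowest_lrmsd},
            {"statistic": "pct_within_cutoff", "value": self.pct_within_cutoff},
            {"statistic": "l_median", "value": self.l_median},
            {"statistic": "i_median", "value": self.i_median},
            {"statistic": "l_pct_0_5", "value": self.l_pct_0_5},
            {"statistic": "l_pct_5_10", "value": self.l_pct_5_10},
            {"statistic": "i_pct_0_5", "value": self.i_pct_0_5},
            {"statistic": "i_pct_5_10", "value": self.i_pct_5_10},
        ]
        for p, v in self.omega_curve.items():
            rows.append({"statistic": f"omega_{p}_lowest_lrmsd", "value": v})
        return rows


def _band_pct(values: np.ndarray, lo: float, hi: float) -> float:
    if len(values) == 0:
        return float("nan")
    return float(100.0 * np.mean((values >= lo) & (values < hi)))


def ensemble_report(
    ensemble,
    base: Unit,
    moving: Unit,
    native_coords: np.ndarray,
    near_native_cutoff: float = NEAR_NATIVE_CUTOFF,
    ca_only: bool = False,
) -> EnsembleReport:
    """Score every accepted decoy against the native dimer and summarize.

    ``native_coords`` must be the full-dimer coordinates in decoy atom order
    (see :func:`match_native`, or :func:`dimer_coords` with the planted
    transform for synthetic systems).
    """
    configs = ensemble.configurations
    if not configs:
        raise ValueError("empty ensemble")
    native = np.asarray(native_coords, dtype=float)
    probe = dimer_coords(base, moving, configs[0].transform, ca_only=ca_only)
    if native.shape != probe.shape:
        raise ValueError(
            f"native/decoy atom mismatch: {native.shape} vs {probe.shape}"
        )
    vals = np.array(
        [
            lrmsd(native, dimer_coords(base, moving, c.transform, ca_only=ca_only))
            for c in configs
        ]
    )

    omega: dict[int, float] = {}
    ranked = sorted(range(len(configs)), key=lambda i: (configs[i].energy.total, configs[i].index))
    for p in range(10, 101, 10):
        n_keep = math.ceil(p / 100.0 * len(configs))
        omega[p] = float(vals[ranked[:n_keep]].min())

    l_vals = np.array([r.perturb_jump for r in ensemble.records if r.perturb_jump is not None])
    i_vals = np.array(
        [r.minimization_displacement for r in ensemble.records
         if r.minimization_displacement is not None]
    )
    return EnsembleReport(
        lowest_lrmsd=float(vals.min()),
        pct_within_cutoff=float(100.0 * np.mean(vals < near_native_cutoff)),
        omega_curve=omega,
        l_median=float(np.median(l_vals)) if len(l_vals) else float("nan"),
        i_median=float(np.median(i_vals)) if len(i_vals) else float("nan"),
        l_pct_0_5=_band_pct(l_vals, 0.0, 5.0),
        l_pct_5_10=_band_pct(l_vals, 5.0, 10.0),
        i_pct_0_5=_band_pct(i_vals, 0.0, 5.0),
        i_pct_5_10=_band_pct(i_vals, 5.0, 10.0),
        lrmsds=vals,
    )
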