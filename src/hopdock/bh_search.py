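"""The basin-hopping docking loop.

Starting from a pose that aligns a uniformly-sampled complementary triangle
pair, the search repeats three moves until the requested number of minima is
accepted:

1. *Perturb*: resample the generating triangle pair inside a d-neighborhood
   (by triangle center-of-mass distance) of the current pair, until the new
   pair is geometrically complementary; align it to get the perturbed pose.
2. *Minimize*: greedy descent in continuous SE(3) - propose a nearby
   transform in the <t, u, theta> parameterization and keep it only if the
   interaction energy strictly decreases; stop after m total proposals or k
   consecutive failures.
3. *Metropolis*: accept the minimized pose over the previous accepted
   minimum always if its energy is lower, else with probability
   exp(-dE / T_e).  A rejected minimum leaves the current state unchanged
   (standard basin-hopping convention).

Every attempt is logged: the perturbation jump l (lRMSD between consecutive
perturbed poses), the minimization displacement i (lRMSD between perturbed
and minimized pose), the energy change and the Metropolis draw, so the run
is exactly replayable from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import dimer_coords, lrmsd
from .energy import (
    COULOMB_CONSTANT,
    DEFAULT_HBOND_CUTOFF,
    DEFAULT_PAIR_CUTOFF,
    EnergyBreakdown,
    EnergyModel,
)
from .rigid_geometry import RigidTransform, perturb_transform
from .structure_io import ParameterTable, Unit
from .surface import SurfacePoint
from .triangles import (
    DEFAULT_SIDE_TOL,
    Triangle,
    build_active_triangles,
    complementary,
    neighbors_within,
    pair_alignment,
    sample_complementary_pair,
)

__all__ = [
    "T0",
    "T1",
    "BHParams",
    "Configuration",
    "StepRecord",
    "Ensemble",
    "metropolis_accept",
    "minimize",
    "perturb",
    "run_hopdock",
]

#: Effective temperatures (kcal/mol) defined by the acceptance probability
#: they give an energy increase of 2 kcal/mol: T0 accepts with p = 0.39
#: (the medium temperature, the production default), T1 with p = 0.16.
T0 = -2.0 / math.log(0.39)
T1 = -2.0 / math.log(0.16)


@dataclass
class BHParams:
    """Tunable parameters of the basin-hopping search (defaults = production)."""

    conserve_th: float = 0.5  # conservation gate for active points
    temperature: float = T0  # Metropolis effective temperature, kcal/mol
    d: float = 5.0  # perturbation neighborhood radius, Angstrom (inf = restart)
    delta_t: float = 1.5  # minimization translation step, Angstrom
    delta_phi: float = 10.0  # axis tilt step, degrees
    delta_theta: float = 30.0  # angle step, degrees
    m: int = 100  # max proposals per minimization
    k: int = 20  # consecutive-failure cutoff
    n_decoys: int = 10_000  # accepted minima to collect
    side_tol: float = DEFAULT_SIDE_TOL  # triangle side-match tolerance, Angstrom
    belt_wildcard: bool = True
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF  # energy neighbor cutoff, Angstrom
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF
    conversion: float = COULOMB_CONSTANT
    steric_filter: bool = True  # reject poses with atoms closer than steric_min_dist
    steric_min_dist: float = 1.0  # Angstrom
    max_pair_attempts: int = 500  # per perturbation, before widening d
    stall_limit: int = 50  # consecutive rejections before a forced acceptance
    seed: int | None = None

    def __post_init__(self) -> None:
        positive = {
            "temperature": self.temperature,
            "d": self.d,
            "n_decoys": self.n_decoys,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        for name, v in (("delta_t", self.delta_t), ("delta_phi", self.delta_phi),
                        ("delta_theta", self.delta_theta), ("m", self.m), ("k", self.k)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.k > self.m:
            raise ValueError("k (failure cutoff) must not exceed m (max proposals)")


@dataclass
class Configuration:
    """A docked pose: transform, generating triangle pair, energy, index."""

    transform: RigidTransform
    gen_pair: tuple[Triangle, Triangle] | None
    energy: EnergyBreakdown
    index: int = -1  # position in the accepted trajectory

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy.total):
            raise ValueError("configuration energy must be finite")


@dataclass
class StepRecord:
    """Bookkeeping for one basin-hopping attempt."""

    attempt: int
    perturb_jump: float | None  # l: lRMSD between consecutive perturbed poses
    minimization_displacement: float | None  # i: lRMSD perturbed -> minimized
    energy_before: float
    energy_after: float
    delta_e: float
    metropolis_draw: float | None  # uniform draw when delta_e > 0, else None
    accepted: bool
    d_used: float  # perturbation neighborhood actually used (after widening)
    forced: bool = False  # stagnation escape: accepted without a Metropolis draw


@dataclass
class Ensemble:
    """Accepted minima plus the per-attempt records of the run."""

    configurations: list[Configuration]
    records: list[StepRecord]
    params: BHParams

    def __len__(self) -> int:
        return len(self.configurations)

    def to_dataframe(self) -> pd.DataFrame:
        """Compact decoy table: quaternion, translation, energy breakdown."""
        rows = []
        for c in self.configurations:
            qw, qx, qy, qz = c.transform.quat
            tx, ty, tz = c.transform.translation
            rows.append(
                {
                    "index": c.index,
                    "qw": qw, "qx": qx, "qy": qy, "qz": qz,
                    "tx": tx, "ty": ty, "tz": tz,
                    "e_vdw": c.energy.e_vdw,
                    "e_elec": c.energy.e_elec,
                    "e_hbond": c.energy.e_hbond,
                    "total": c.energy.total,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.9g")

    def records_to_dataframe(self) -> pd.DataFrame:
        """One row per basin-hopping attempt: dE, acceptance, jump l, displacement i."""
        return pd.DataFrame(
            {
                "step": r.attempt,
                "delta_e": r.delta_e,
                "accepted": int(r.accepted),
                "forced": int(r.forced),
                "l": r.perturb_jump,
                "i": r.minimization_displacement,
                "d_used": r.d_used,
            }
            for r in self.records
        )

    def records_to_tsv(self, path) -> None:
        self.records_to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @staticmethod
    def configurations_from_tsv(path) -> list[Configuration]:
        """Reload decoys written by :meth:`to_tsv` (records are not persisted)."""
        df = pd.read_csv(path, sep="\t")
        configs = []
        for row in df.itertuples():
            T = RigidTransform.from_quat(
                (row.qw, row.qx, row.qy, row.qz), (row.tx, row.ty, row.tz)
            )
            configs.append(
                Configuration(
                    transform=T,
                    gen_pair=None,
                    energy=EnergyBreakdown(row.e_vdw, row.e_elec, row.e_hbond),
                    index=int(row.index),
                )
            )
        return configs


def metropolis_accept(
    e_new: float, e_old: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Accept a move: always if energy does not increase, else with
    probability exp(-(e_new - e_old) / temperature)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta = e_new - e_old
    if delta <= 0:
        return True
    return rng.random() < math.exp(-delta / temperature)


def minimize(
    start: Configuration,
    params: BHParams,
    rng: np.random.Generator,
    model: EnergyModel,
) -> Configuration:
    """Greedy continuous descent from a perturbed pose.

    At most ``params.m`` proposals; stop early after ``params.k`` consecutive
    failures to lower the energy.  The returned energy never exceeds the
    start energy, and the generating triangle pair is inherited.
    """
    current_T = start.transform
    current_E = start.energy
    fails = 0
    for _ in range(params.m):
        cand_T = perturb_transform(
            current_T, params.delta_t, params.delta_phi, params.delta_theta, rng
        )
        cand_E, min_dist = model.evaluate(cand_T)
        clash = params.steric_filter and min_dist < params.steric_min_dist
        if not clash and cand_E.total < current_E.total:
            current_T, current_E = cand_T, cand_E
            fails = 0
        else:
            fails += 1
            if fails >= params.k > 0:
                break
    return Configuration(
        transform=current_T, gen_pair=start.gen_pair, energy=current_E, index=start.index
    )


def _aligned_configuration(
    tr_a: Triangle,
    tr_b: Triangle,
    params: BHParams,
    model: EnergyModel,
) -> Configuration | None:
    """Align a pair and score it; None if the pose fails the steric filter."""
    T = pair_alignment(tr_a, tr_b, params.side_tol, params.belt_wildcard)
    breakdown, min_dist = model.evaluate(T)
    if params.steric_filter and min_dist < params.steric_min_dist:
        return None
    return Configuration(transform=T, gen_pair=(tr_a, tr_b), energy=breakdown)


def perturb(
    current: Configuration,
    triangles_a: list[Triangle],
    triangles_b: list[Triangle],
    d: float,
    rng: np.random.Generator,
    params: BHParams,
    model: EnergyModel,
) -> tuple[Configuration, float]:
    """Resample the generating pair in a d-neighborhood of the current pair.

    Returns the perturbed (aligned, scored) configuration and the
    neighborhood radius actually used.  If no complementary, clash-free pair
    is found within ``params.max_pair_attempts``, the neighborhood is doubled
    (up to three times) and finally sampling falls back to the global pool.
    """
    if current.gen_pair is None:
        raise ValueError("current configuration carries no generating pair")
    tr_a, tr_b = current.gen_pair
    d_used = d
    for _widening in range(4):
        cand_a = neighbors_within(triangles_a, tr_a, d_used)
        cand_b = neighbors_within(triangles_b, tr_b, d_used)
        if cand_a and cand_b:
            for _ in range(params.max_pair_attempts):
                na = cand_a[int(rng.integers(len(cand_a)))]
                nb = cand_b[int(rng.integers(len(cand_b)))]
                if not complementary(na, nb, params.side_tol, params.belt_wildcard):
                    continue
                cfg = _aligned_configuration(na, nb, params, model)
                if cfg is not None:
                    return cfg, d_used
        d_used = d_used * 2.0 if np.isfinite(d_used) else d_used
        if not np.isfinite(d_used):
            break
    # global fallback
    for _ in range(params.max_pair_attempts * 4):
        na, nb = sample_complementary_pair(
            triangles_a, triangles_b, rng, params.side_tol, params.belt_wildcard
        )
        cfg = _aligned_configuration(na, nb, params, model)
        if cfg is not None:
            return cfg, float("inf")
    raise RuntimeError("perturbation failed: no clash-free complementary pair found")


def run_hopdock(
    base: Unit,
    moving: Unit,
    points_a: list[SurfacePoint],
    points_b: list[SurfacePoint],
    params: BHParams,
    rng: np.random.Generator | int | None = None,
    triangles_a: list[Triangle] | None = None,
    triangles_b: list[Triangle] | None = None,
) -> Ensemble:
    """Run the basin-hopping search and collect ``params.n_decoys`` minima.

    ``points_a`` / ``points_b`` must already be conservation-annotated.
    Pre-built triangle lists may be passed to amortize setup across runs.
    The run is fully reproducible given the RNG seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    if triangles_a is None:
        triangles_a = build_active_triangles(points_a)
    if triangles_b is None:
        triangles_b = build_active_triangles(points_b)
    if not triangles_a or not triangles_b:
        raise ValueError("no active triangles on one of the units")

    model = EnergyModel(
        base,
        moving,
        pair_cutoff=params.pair_cutoff,
        hbond_cutoff=params.hbond_cutoff,
        conversion=params.conversion,
    )

    # C1: global uniform complementary pair, minimized, accepted unconditionally
    first = None
    for _ in range(params.max_pair_attempts * 4):
        ta, tb = sample_complementary_pair(
            triangles_a, triangles_b, rng, params.side_tol, params.belt_wildcard
        )
        first = _aligned_configuration(ta, tb, params, model)
        if first is not None:
            break
    if first is None:
        raise RuntimeError("could not find a clash-free starting pair")
    current = minimize(first, params, rng, model)
    current.index = 0

    configurations = [current]
    records: list[StepRecord] = []
    prev_perturbed_coords = None
    max_attempts = max(200, 100 * params.n_decoys)
    attempt = 0
    consecutive_rejections = 0
    while len(configurations) < params.n_decoys:
        attempt += 1
        if attempt > max_attempts:
            raise RuntimeError(
                f"basin hopping stalled: {len(configurations)} accepted in {attempt} attempts"
            )
        perturbed, d_used = perturb(
            current, triangles_a, triangles_b, params.d, rng, params, model
        )
        perturbed_coords = dimer_coords(base, moving, perturbed.transform)
        jump = (
            lrmsd(prev_perturbed_coords, perturbed_coords)
            if prev_perturbed_coords is not None
            else None
        )
        prev_perturbed_coords = perturbed_coords

        minimized = minimize(perturbed, params, rng, model)
        displacement = lrmsd(
            perturbed_coords, dimer_coords(base, moving, minimized.transform)
        )

        delta = minimized.energy.total - current.energy.total
        forced = False
        if delta <= 0:
            accepted, draw = True, None
        elif consecutive_rejections >= params.stall_limit:
            # stagnation escape (occasional jumping): a very deep minimum can
            # reject every Metropolis candidate indefinitely; accept one
            # unconditionally so the trajectory keeps moving
            accepted, draw, forced = True, None, True
        else:
            draw = rng.random()
            accepted = draw < math.exp(-delta / params.temperature)
        records.append(
            StepRecord(
                attempt=attempt,
                perturb_jump=jump,
                minimization_displacement=displacement,
                energy_before=current.energy.total,
                energy_after=minimized.energy.total,
                delta_e=delta,
                metropolis_draw=draw,
                accepted=accepted,
                d_used=d_used,
                forced=forced,
            )
        )
        if accepted:
            consecutive_rejections = 0
            minimized.index = len(configurations)
            configurations.append(minimized)
            current = minimized
        else:
            consecutive_rejections += 1
    return Ensemble(configurations=configurations, records=records, params=params)
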