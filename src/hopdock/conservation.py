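"""Per-residue evolutionary conservation: annotation, gating, interface statistic.

Conservation scores (trace scores in [0, 1], produced externally by an
evolutionary-trace analysis) are attached to surface critical points via the
residue of the nearest atom.  A point whose score strictly exceeds the
threshold ``conserve_th`` is *active*; only active points seed docking
triangles.  The module also computes the interface-conservation contrast
used to justify the gating: on a known complex, the fraction of conserved
critical points on the interface versus elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .rigid_geometry import RigidTransform
from .surface import SurfacePoint

__all__ = [
    "ConservationMap",
    "ConservationSummary",
    "read_conservation_scores",
    "write_conservation_scores",
    "annotate_critical_points",
    "interface_conservation",
    "conservation_summary_table",
]

DEFAULT_CONSERVE_TH = 0.5
DEFAULT_CONTACT_CUTOFF = 5.0  # Angstrom, critical points in contact


@dataclass
class ConservationMap:
    """Map (chain, resSeq) -> trace score in [0, 1].

    Insertion codes are not part of the key: the score table interface
    carries only chain and residue number columns.
    """

    scores: dict[tuple[str, int], float]

    def __post_init__(self) -> None:
        for key, s in self.scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"conservation score out of [0, 1] for {key}: {s}")

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, residue_id, default: float | None = None) -> float | None:
        chain, resseq = residue_id[0], residue_id[1]
        return self.scores.get((chain, int(resseq)), default)


def read_conservation_scores(path: str | Path) -> ConservationMap:
    """Read a TSV with columns chain, resSeq, score."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    required = {"chain", "resSeq", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"conservation TSV must have columns {sorted(required)}")
    if df[["chain", "resSeq", "score"]].isna().any().any():
        raise ValueError("malformed conservation TSV: missing values")
    if df.duplicated(subset=["chain", "resSeq"]).any():
        dupes = df[df.duplicated(subset=["chain", "resSeq"])]
        raise ValueError(f"duplicate residues in conservation TSV: {dupes.to_dict('records')}")
    scores = {
        (str(row.chain), int(row.resSeq)): float(row.score) for row in df.itertuples()
    }
    return ConservationMap(scores)


def write_conservation_scores(cmap: ConservationMap, path: str | Path) -> None:
    rows = [
        {"chain": chain, "resSeq": resseq, "score": score}
        for (chain, resseq), score in cmap.scores.items()
    ]
    pd.DataFrame(rows, columns=["chain", "resSeq", "score"]).to_csv(
        path, sep="\t", index=False
    )


def annotate_critical_points(
    points: list[SurfacePoint],
    cmap: ConservationMap,
    conserve_th: float = DEFAULT_CONSERVE_TH,
) -> list[SurfacePoint]:
    """Attach scores and active flags in place (and return the list).

    A point is active iff its score strictly exceeds ``conserve_th``.
    Residues missing from the map score 0 (with a warning).
    """
    missing = set()
    for p in points:
        score = cmap.get(p.nearest_residue)
        if score is None:
            missing.add(p.nearest_residue[:2])
            score = 0.0
        p.conservation = score
        p.active = score > conserve_th
    if missing:
        warnings.warn(
            f"{len(missing)} residues missing from conservation map; scored 0.0"
        )
    return points


@dataclass(frozen=True)
class ConservationSummary:
    """Interface-conservation contrast on a known complex.

    ``r_interface`` is the fraction of interfacial critical points (pooled
    over both units) that are conserved; ``r_rest`` is literally
    ``1 - r_interface``; ``diff_percent`` is ``(r_rest - r_interface) * 100``
    (negative when the interface is more conserved than not).  Per-unit
    interface fractions are reported alongside.
    """

    r_interface: float
    r_rest: float
    diff_percent: float
    r_interface_a: float
    r_interface_b: float
    n_interfacial: int


def interface_conservation(
    points_a: list[SurfacePoint],
    points_b: list[SurfacePoint],
    native_pose: RigidTransform,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    conserve_th: float = DEFAULT_CONSERVE_TH,
    rest_mode: str = "literal",
) -> ConservationSummary:
    """Conservation contrast between interface and rest of the surface.

    A critical point of unit A is interfacial iff some critical point of B
    (placed by the native pose) lies within ``contact_cutoff``, and vice
    versa.  ``rest_mode="literal"`` defines r_rest = 1 - r_interface;
    ``rest_mode="surface"`` instead measures the conserved fraction over the
    non-interfacial points.
    """
    if rest_mode not in ("literal", "surface"):
        raise ValueError("rest_mode must be 'literal' or 'surface'")
    xa = np.stack([p.position for p in points_a])
    xb = native_pose.apply(np.stack([p.position for p in points_b]))
    tree_a, tree_b = cKDTree(xa), cKDTree(xb)
    d_a, _ = tree_b.query(xa, k=1)
    d_b, _ = tree_a.query(xb, k=1)
    iface_a = d_a <= contact_cutoff
    iface_b = d_b <= contact_cutoff
    if not (iface_a.any() or iface_b.any()):
        raise ValueError("units not in contact: no interfacial critical points")

    cons_a = np.array([(p.conservation or 0.0) > conserve_th for p in points_a])
    cons_b = np.array([(p.conservation or 0.0) > conserve_th for p in points_b])

    n_iface = int(iface_a.sum() + iface_b.sum())
    n_cons_iface = int(cons_a[iface_a].sum() + cons_b[iface_b].sum())
    r_interface = n_cons_iface / n_iface
    if rest_mode == "literal":
        r_rest = 1.0 - r_interface
    else:
        n_rest = int((~iface_a).sum() + (~iface_b).sum())
        n_cons_rest = int(cons_a[~iface_a].sum() + cons_b[~iface_b].sum())
        r_rest = n_cons_rest / n_rest if n_rest else 0.0

    def _unit_ratio(iface, cons):
        n = int(iface.sum())
        return float(cons[iface].sum() / n) if n else float("nan")

    return ConservationSummary(
        r_interface=r_interface,
        r_rest=r_rest,
        diff_percent=(r_rest - r_interface) * 100.0,
        r_interface_a=_unit_ratio(iface_a, cons_a),
        r_interface_b=_unit_ratio(iface_b, cons_b),
        n_interfacial=n_iface,
    )


def conservation_summary_table(
    points_a: list[SurfacePoint],
    points_b: list[SurfacePoint],
    native_pose: RigidTransform,
    thresholds=(0.25, 0.5, 0.75),
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> pd.DataFrame:
    """Interface-conservation contrast across thresholds (one row per threshold)."""
    rows = []
    for th in thresholds:
        s = interface_conservation(
            points_a, points_b, native_pose, contact_cutoff, conserve_th=th
        )
        rows.append({"threshold": th, "diff_percent": s.diff_percent})
    return pd.DataFrame(rows)
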