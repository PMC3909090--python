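"""Active surface triangles: the discrete search space for docking alignments.

Triples of critical points form triangles subject to side-length bounds
(2.0 - 5.0 Angstrom by default: larger than an atomic radius, small enough
to stay local) and a non-collinearity angle bound.  A triangle is *active*
when its lexicographically-first vertex is an active (conserved) critical
point.  Two uniqueness rules keep the set small - no two triangles share
their first vertex, and no two share a quantized center-of-mass cell - so a
unit with n critical points yields fewer than n active triangles.

Geometric complementarity between a base-unit triangle and a moving-unit
triangle requires a vertex correspondence under which all three side lengths
match within a tolerance and the vertex shapes are compatible (cap pairs
with pit; belt is a wildcard by default).  The correspondence whose
alignment best opposes the matched surface normals (surfaces facing each
other) is the one used to build the docking transform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .rigid_geometry import RigidTransform, alignment_transform
from .surface import SurfacePoint

__all__ = [
    "Triangle",
    "build_active_triangles",
    "complementary",
    "matching_correspondences",
    "pair_alignment",
    "sample_complementary_pair",
    "neighbors_within",
    "triangles_to_tsv",
]

DEFAULT_D_MIN = 2.0  # Angstrom, minimum triangle side
DEFAULT_D_MAX = 5.0  # Angstrom, maximum triangle side
DEFAULT_ANGLE_MIN = 15.0  # degrees, minimum internal angle
DEFAULT_COM_RESOLUTION = 1.0  # Angstrom, center-of-mass hash cell
DEFAULT_SIDE_TOL = 1.0  # Angstrom, complementarity side match
DEFAULT_MAX_ATTEMPTS = 10_000


@dataclass(frozen=True, eq=False)
class Triangle:
    """Three critical points in lexicographic order.

    Geometric views (positions, center of mass, side matrix) are computed
    once at construction; the vertices never move.
    """

    vertices: tuple[SurfacePoint, SurfacePoint, SurfacePoint]
    indices: tuple[int, int, int]  # into the source critical-point list
    active: bool

    def __post_init__(self) -> None:
        pos = np.stack([v.position for v in self.vertices])
        object.__setattr__(self, "_positions", pos)
        object.__setattr__(self, "_com", pos.mean(axis=0))
        object.__setattr__(
            self, "_dmat", np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        )

    @property
    def vertex_positions(self) -> np.ndarray:
        return self._positions

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.stack([v.normal for v in self.vertices])

    @property
    def com(self) -> np.ndarray:
        return self._com

    @property
    def distance_matrix(self) -> np.ndarray:
        return self._dmat

    @property
    def sides(self) -> np.ndarray:
        """Side lengths (|v1 v2|, |v1 v3|, |v2 v3|)."""
        return self._dmat[[0, 0, 1], [1, 2, 2]]

    @property
    def shapes(self) -> tuple[str, str, str]:
        return tuple(v.shape for v in self.vertices)

    def permuted(self, perm: tuple[int, int, int]) -> "Triangle":
        """The same triangle with vertices reordered (for alignment only)."""
        return Triangle(
            vertices=tuple(self.vertices[i] for i in perm),
            indices=tuple(self.indices[i] for i in perm),
            active=self.active,
        )


def _min_internal_angle(p: np.ndarray) -> float:
    """Minimum internal angle of a triangle, degrees."""
    angles = []
    for i in range(3):
        a = p[(i + 1) % 3] - p[i]
        b = p[(i + 2) % 3] - p[i]
        cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return float(min(angles))


def triple_is_valid(
    p1: np.ndarray,
    p2: np.ndarray,
    p3: np.ndarray,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    angle_min: float = DEFAULT_ANGLE_MIN,
) -> bool:
    """Side-length and angle constraints on a vertex triple."""
    pts = np.stack([p1, p2, p3])
    for i, j in ((0, 1), (0, 2), (1, 2)):
        d = np.linalg.norm(pts[i] - pts[j])
        if d < d_min or d > d_max:
            return False
    return _min_internal_angle(pts) >= angle_min


def build_active_triangles(
    points: list[SurfacePoint],
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    angle_min: float = DEFAULT_ANGLE_MIN,
    com_resolution: float = DEFAULT_COM_RESOLUTION,
) -> list[Triangle]:
    """Enumerate unique active triangles over annotated critical points.

    Points are scanned in lexicographic order of position.  For each active
    point p1, candidate pairs (p2, p3) of lexicographically-later points are
    scanned in index order; the first pair that satisfies the side/angle
    constraints and whose center of mass claims a free hash cell yields p1's
    (single) triangle.  Zero active points yields an empty list.
    """
    if not points:
        return []
    order = sorted(range(len(points)), key=lambda i: tuple(points[i].position))
    pos = np.stack([points[i].position for i in order])
    tree = cKDTree(pos)
    claimed_cells: set[tuple[int, int, int]] = set()
    out: list[Triangle] = []

    for a in range(len(order)):
        if not points[order[a]].active:
            continue
        # candidates strictly later in lexicographic order, within d_max
        cand = sorted(j for j in tree.query_ball_point(pos[a], d_max) if j > a)
        placed = False
        for bi in range(len(cand)):
            if placed:
                break
            for ci in range(bi + 1, len(cand)):
                b, c = cand[bi], cand[ci]
                if not triple_is_valid(pos[a], pos[b], pos[c], d_min, d_max, angle_min):
                    continue
                com = (pos[a] + pos[b] + pos[c]) / 3.0
                cell = tuple(np.floor(com / com_resolution).astype(int))
                if cell in claimed_cells:
                    continue
                claimed_cells.add(cell)
                out.append(
                    Triangle(
                        vertices=(points[order[a]], points[order[b]], points[order[c]]),
                        indices=(order[a], order[b], order[c]),
                        active=True,
                    )
                )
                placed = True
                break
    return out


def _shapes_compatible(sa: str, sb: str, belt_wildcard: bool) -> bool:
    if belt_wildcard and ("belt" in (sa, sb)):
        return True
    return {sa, sb} == {"cap", "pit"}


def matching_correspondences(
    tr_a: Triangle,
    tr_b: Triangle,
    side_tol: float = DEFAULT_SIDE_TOL,
    belt_wildcard: bool = True,
) -> list[tuple[int, int, int]]:
    """Vertex permutations of tr_b that match tr_a geometrically.

    A permutation is valid when every matched side length agrees within
    ``side_tol`` and every matched vertex pair has complementary shapes.
    """
    da = tr_a.distance_matrix
    db = tr_b.distance_matrix
    sa, sb = tr_a.shapes, tr_b.shapes
    valid = []
    for perm in itertools.permutations(range(3)):
        if not all(_shapes_compatible(sa[i], sb[perm[i]], belt_wildcard) for i in range(3)):
            continue
        ok = all(
            abs(da[i, j] - db[perm[i], perm[j]]) <= side_tol
            for i, j in ((0, 1), (0, 2), (1, 2))
        )
        if ok:
            valid.append(perm)
    return valid


def complementary(
    tr_a: Triangle,
    tr_b: Triangle,
    side_tol: float = DEFAULT_SIDE_TOL,
    belt_wildcard: bool = True,
) -> bool:
    """True iff some vertex correspondence matches sides and shapes."""
    return bool(matching_correspondences(tr_a, tr_b, side_tol, belt_wildcard))


def pair_alignment(
    tr_a: Triangle,
    tr_b: Triangle,
    side_tol: float = DEFAULT_SIDE_TOL,
    belt_wildcard: bool = True,
) -> RigidTransform:
    """Docking transform for a complementary pair.

    Among the valid correspondences, the one whose alignment makes the
    matched vertex normals most anti-parallel (surfaces facing each other)
    is chosen; ties break on permutation order, deterministically.
    """
    perms = matching_correspondences(tr_a, tr_b, side_tol, belt_wildcard)
    if not perms:
        raise ValueError("triangles are not complementary")
    best = None
    best_score = np.inf
    na = tr_a.vertex_normals
    for perm in perms:
        trb = tr_b.permuted(perm)
        T = alignment_transform(tr_a, trb)
        nb = trb.vertex_normals @ T.rotation.T
        score = float(np.sum(na * nb))  # most negative = best facing
        if score < best_score - 1e-12:
            best_score = score
            best = T
    return best


def sample_complementary_pair(
    triangles_a: list[Triangle],
    triangles_b: list[Triangle],
    rng: np.random.Generator,
    side_tol: float = DEFAULT_SIDE_TOL,
    belt_wildcard: bool = True,
    max_attempts: int = DEFAULT_MAX_ATTEMPTS,
) -> tuple[Triangle, Triangle]:
    """Uniformly sample a geometrically-complementary triangle pair.

    Rejection sampling over uniform index pairs: conditional on acceptance
    the sampled pair is uniform over all complementary pairs.
    """
    if not triangles_a or not triangles_b:
        raise ValueError("no complementary pair: empty triangle list")
    for _ in range(max_attempts):
        ta = triangles_a[int(rng.integers(len(triangles_a)))]
        tb = triangles_b[int(rng.integers(len(triangles_b)))]
        if complementary(ta, tb, side_tol, belt_wildcard):
            return ta, tb
    raise ValueError(f"no complementary pair found in {max_attempts} attempts")


def neighbors_within(
    triangles: list[Triangle], center: Triangle, d: float
) -> list[Triangle]:
    """Triangles whose center of mass lies within d of the center triangle's.

    ``d = inf`` returns the full list (the memory-free restart case).
    """
    if d < 0:
        raise ValueError("neighborhood distance must be non-negative")
    if np.isinf(d):
        return list(triangles)
    coms = np.stack([t.com for t in triangles])
    keep = np.linalg.norm(coms - center.com, axis=1) <= d
    return [t for t, k in zip(triangles, keep) if k]


def triangles_to_tsv(triangles: list[Triangle], path) -> None:
    """Export triangles: vertex indices, center of mass, sides, shapes, active."""
    with open(path, "w") as fh:
        fh.write("i1\ti2\ti3\tcom_x\tcom_y\tcom_z\ts12\ts13\ts23\t"
                 "shape1\tshape2\tshape3\tactive\n")
        for t in triangles:
            com, sides, shapes = t.com, t.sides, t.shapes
            fh.write(
                f"{t.indices[0]}\t{t.indices[1]}\t{t.indices[2]}\t"
                f"{com[0]:.4f}\t{com[1]:.4f}\t{com[2]:.4f}\t"
                f"{sides[0]:.4f}\t{sides[1]:.4f}\t{sides[2]:.4f}\t"
                f"{shapes[0]}\t{shapes[1]}\t{shapes[2]}\t{int(t.active)}\n"
            )
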