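"""Rigid-body transforms in SE(3): triangle reference frames, alignment, perturbation.

A docked pose of the moving unit is a proper rigid motion ``x -> R x + t``.
Poses are built by superimposing a triangle of surface points on the moving
unit onto a matching triangle on the base unit: each triangle defines an
orthonormal reference frame, and the alignment transform is the composition
of one frame with the inverse of the other.  During local minimization the
pose is perturbed directly in an axis-angle parameterization ``<t, u, theta>``
(quaternions internally), not through triangles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "triangle_frame",
    "alignment_transform",
    "apply_transform",
    "perturb_transform",
    "random_transform",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation``.

    ``rotation`` is a 3x3 orthonormal matrix with det +1 (validated on
    construction); ``translation`` is in Angstrom.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (|R^T R - I| = {err:.2e})")
        if err > _ORTHO_TOL:
            # re-orthonormalize tiny drift from composed operations
            u, _, vt = np.linalg.svd(R)
            R = u @ vt
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (det = -1): reflections not allowed")
        R = np.ascontiguousarray(R)
        t = np.ascontiguousarray(t)
        R.flags.writeable = False
        t.flags.writeable = False
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_quat(cls, quat_wxyz, translation) -> "RigidTransform":
        """Build from a scalar-first unit quaternion (w, x, y, z)."""
        w, x, y, z = np.asarray(quat_wxyz, dtype=float)
        rot = Rotation.from_quat([x, y, z, w])  # scipy is scalar-last
        return cls(rot.as_matrix(), translation)

    @classmethod
    def from_axis_angle(cls, translation, axis, angle_rad: float) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            if abs(angle_rad) > 1e-12:
                raise ValueError("zero axis with non-zero angle")
            return cls(np.eye(3), translation)
        rot = Rotation.from_rotvec(axis / n * angle_rad)
        return cls(rot.as_matrix(), translation)

    # -- views -------------------------------------------------------------
    @property
    def quat(self) -> np.ndarray:
        """Unit quaternion (w, x, y, z), canonicalized to w >= 0."""
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q

    @property
    def axis_angle(self) -> tuple[np.ndarray, np.ndarray, float]:
        """The ``<t, u, theta>`` view: translation, unit axis, angle in radians."""
        u, theta = _axis_angle_of(self.rotation)
        return self.translation.copy(), u, theta

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of positions."""
        X = np.asarray(positions, dtype=float)
        return X @ self.rotation.T + self.translation

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )


def triangle_frame(triangle) -> RigidTransform:
    """Orthonormal reference frame of a surface triangle.

    Origin at the first vertex, x-axis along v2 - v1, z-axis along
    (v2 - v1) x (v3 - v1), y-axis completing a right-handed frame.  The
    returned transform maps frame coordinates into world coordinates.
    """
    v1, v2, v3 = (np.asarray(v, dtype=float) for v in _triangle_vertices(triangle))
    e1 = v2 - v1
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise ValueError("degenerate triangle: coincident vertices")
    x = e1 / n1
    zraw = np.cross(e1, v3 - v1)
    nz = np.linalg.norm(zraw)
    if nz < 1e-12:
        raise ValueError("degenerate triangle: collinear vertices")
    z = zraw / nz
    y = np.cross(z, x)
    R = np.column_stack([x, y, z])
    return RigidTransform(R, v1)


def _triangle_vertices(triangle):
    """Accept a Triangle object (``vertex_positions``) or a (3, 3) array."""
    pos = getattr(triangle, "vertex_positions", None)
    if pos is not None:
        return np.asarray(pos, dtype=float)
    arr = np.asarray(triangle, dtype=float)
    if arr.shape != (3, 3):
        raise ValueError("triangle must be a Triangle or a (3, 3) array")
    return arr


def alignment_transform(tr_a, tr_b) -> RigidTransform:
    """Rigid motion that superimposes triangle ``tr_b`` onto ``tr_a``.

    The transform composes the base triangle's frame with the inverse of the
    moving triangle's frame; applied to the moving unit it carries the
    vertices of ``tr_b`` onto the corresponding vertices of ``tr_a`` (exactly
    for congruent triangles, in the least-distorting frame sense otherwise).
    """
    return triangle_frame(tr_a).compose(triangle_frame(tr_b).inverse())


def apply_transform(transform: RigidTransform, positions: np.ndarray) -> np.ndarray:
    return transform.apply(positions)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product of two 3-vectors without numpy's axis machinery."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _unchecked_transform(rotation: np.ndarray, translation: np.ndarray) -> RigidTransform:
    """Internal fast constructor for rotations known to be orthonormal.

    Skips validation; used in the sampling inner loops where the rotation is
    built by Rodrigues' formula from a unit axis.
    """
    obj = object.__new__(RigidTransform)
    object.__setattr__(obj, "rotation", rotation)
    object.__setattr__(obj, "translation", translation)
    return obj


def _rotation_from_axis_angle(u: np.ndarray, theta: float) -> np.ndarray:
    """Rodrigues' formula for a unit axis."""
    c, s = np.cos(theta), np.sin(theta)
    K = np.array([[0.0, -u[2], u[1]], [u[2], 0.0, -u[0]], [-u[1], u[0], 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def _axis_angle_of(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Unit axis and angle of a rotation matrix (scipy fallback near pi)."""
    cos_theta = (np.trace(R) - 1.0) / 2.0
    cos_theta = min(1.0, max(-1.0, cos_theta))
    theta = float(np.arccos(cos_theta))
    if theta < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    if theta > np.pi - 1e-3:  # axis from off-diagonals is ill-conditioned here
        rv = Rotation.from_matrix(R).as_rotvec()
        theta = float(np.linalg.norm(rv))
        return rv / theta, theta
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return axis / (2.0 * np.sin(theta)), theta


def _perpendicular_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A uniformly random unit vector perpendicular to unit vector ``u``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p1 = _cross3(u, helper)
    p1 /= np.linalg.norm(p1)
    p2 = _cross3(u, p1)
    psi = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(psi) * p1 + np.sin(psi) * p2


def random_transform(rng: np.random.Generator, max_translation: float = 10.0) -> RigidTransform:
    """A uniformly random rotation with a translation in a ball (testing aid)."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    t = v * max_translation * rng.uniform() ** (1.0 / 3.0)
    return RigidTransform(R, t)


def perturb_transform(
    transform: RigidTransform,
    delta_t: float,
    delta_phi_deg: float,
    delta_theta_deg: float,
    rng: np.random.Generator,
) -> RigidTransform:
    """Sample a nearby transform in the ``<t, u, theta>`` parameterization.

    The translation moves uniformly within a ball of radius ``delta_t``; the
    rotation axis ``u`` is tilted by an angle sampled uniformly in
    [0, delta_phi] about a uniformly random direction perpendicular to it;
    the rotation angle moves uniformly within ``+- delta_theta``.  Angles are
    given in degrees.  The tilt convention (rather than a spin about ``u``,
    which would fold into theta) is documented in the methods note.
    """
    if delta_t < 0 or delta_phi_deg < 0 or delta_theta_deg < 0:
        raise ValueError("perturbation radii must be non-negative")
    t = transform.translation
    u, theta = _axis_angle_of(transform.rotation)

    if delta_t > 0:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        t = t + v * delta_t * rng.uniform() ** (1.0 / 3.0)

    if delta_phi_deg > 0:
        tilt = np.deg2rad(rng.uniform(0.0, delta_phi_deg))
        axis_perp = _perpendicular_unit(u, rng)
        # rotate u about a perpendicular axis: Rodrigues with k.u = 0
        u = np.cos(tilt) * u + np.sin(tilt) * _cross3(axis_perp, u)
        u /= np.linalg.norm(u)

    if delta_theta_deg > 0:
        theta = theta + np.deg2rad(rng.uniform(-delta_theta_deg, delta_theta_deg))

    return _unchecked_transform(_rotation_from_axis_angle(u, theta), np.asarray(t, float))
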