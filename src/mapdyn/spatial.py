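"""Spatial (6-D) vector algebra for rigid multi-body kinematics and dynamics.

Conventions used throughout the package
---------------------------------------

* 6-vectors stack the **linear block first, then the angular block**:
  a twist is ``(v, w)`` with ``v`` the velocity of the body point at the
  frame origin and ``w`` the angular velocity; a wrench is ``(f, m)``.
* A rotation matrix ``R = A_R_B`` maps coordinates expressed in frame B to
  coordinates expressed in frame A.
* A :class:`SpatialTransform` ``T = (R, o)`` carries the pose of frame B in
  frame A: ``R = A_R_B`` and ``o = A_o_B`` (origin of B expressed in A).
* Gravity defaults to ``[0, 0, -9.81] m/s^2`` in the inertial frame.

The motion adjoint of ``T`` maps twists in B-coordinates to A-coordinates::

    X  = [[R, S(o) R],
          [0,      R]]

and the force adjoint is its inverse-transpose (power invariance
``(X* f) . (X v) = f . v``)::

    X* = [[R,      0],
          [S(o) R, R]]

``S(.)`` is the skew (cross-product) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRAVITY = np.array([0.0, 0.0, -9.81])

_ORTHO_TOL = 1e-10


def skew(x) -> np.ndarray:
    """Skew-symmetric matrix S(x) with S(x) @ y == cross(x, y)."""
    x0, x1, x2 = np.asarray(x, dtype=float)
    return np.array([[0.0, -x2, x1],
                     [x2, 0.0, -x0],
                     [-x1, x0, 0.0]])


def check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> np.ndarray:
    """Validate that ``R`` is a proper rotation (orthonormal, det +1)."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=max(tol, 1e-9)):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=max(tol, 1e-9)):
        raise ValueError("rotation matrix determinant is not +1")
    return R


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix exp(S(axis) * angle) for a unit axis (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if not np.isclose(n, 1.0, atol=1e-8):
        raise ValueError("axis must be a unit vector")
    K = skew(a)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


@dataclass(frozen=True)
class SpatialTransform:
    """Pose of a child frame B in a parent frame A: ``(A_R_B, A_o_B)``."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        object.__setattr__(self, "rotation",
                           np.array(self.rotation, dtype=float))
        object.__setattr__(self, "origin",
                           np.asarray(self.origin, dtype=float).reshape(3))
        check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "SpatialTransform") -> "SpatialTransform":
        """T_AC = T_AB.compose(T_BC)."""
        return SpatialTransform(
            self.rotation @ other.rotation,
            self.origin + self.rotation @ other.origin,
        )

    def inverse(self) -> "SpatialTransform":
        return SpatialTransform(self.rotation.T,
                                -self.rotation.T @ self.origin)

    def apply(self, point) -> np.ndarray:
        """Map a point expressed in the child frame to the parent frame."""
        return self.rotation @ np.asarray(point, dtype=float) + self.origin


def motion_adjoint(T: SpatialTransform) -> np.ndarray:
    """6x6 adjoint mapping twists from child to parent coordinates.

    Full form ``[[R, S(o)R], [0, R]]``.  Used for all twist, acceleration
    and Jacobian frame changes between link frames (which have distinct
    origins).  See :func:`rotation_adjoint` for the origin-free form.
    """
    R, o = T.rotation, T.origin
    X = np.zeros((6, 6))
    X[:3, :3] = R
    X[:3, 3:] = skew(o) @ R
    X[3:, 3:] = R
    return X


def force_adjoint(T: SpatialTransform) -> np.ndarray:
    """6x6 adjoint mapping wrenches from child to parent coordinates.

    Dual of :func:`motion_adjoint` under power invariance:
    ``force_adjoint(T) == inv(motion_adjoint(T)).T``.
    """
    R, o = T.rotation, T.origin
    X = np.zeros((6, 6))
    X[:3, :3] = R
    X[3:, :3] = skew(o) @ R
    X[3:, 3:] = R
    return X


def rotation_adjoint(R: np.ndarray) -> np.ndarray:
    """Orientation-only 6x6 adjoint blockdiag(R, R).

    This is the pure re-orientation map used when two frames share an
    origin — e.g. when expressing a proper sensor acceleration, whose
    linear part is a classical (origin-bound) acceleration, in another
    orientation.
    """
    X = np.zeros((6, 6))
    X[:3, :3] = R
    X[3:, 3:] = R
    return X


def crm(v: np.ndarray) -> np.ndarray:
    """Motion cross-product matrix: crm(v) @ u == v x u for twists.

    With v = (vl, w): ``[[S(w), S(vl)], [0, S(w)]]``.
    """
    v = np.asarray(v, dtype=float)
    M = np.zeros((6, 6))
    M[:3, :3] = skew(v[3:])
    M[:3, 3:] = skew(v[:3])
    M[3:, 3:] = skew(v[3:])
    return M


def crf(v: np.ndarray) -> np.ndarray:
    """Force (dual) cross-product matrix: crf(v) = -crm(v).T.

    ``crf(v) @ f`` is the rate of change a wrench picks up when its frame
    of expression moves with twist v.
    """
    v = np.asarray(v, dtype=float)
    M = np.zeros((6, 6))
    M[:3, :3] = skew(v[3:])
    M[3:, :3] = skew(v[:3])
    M[3:, 3:] = skew(v[3:])
    return M


@dataclass(frozen=True)
class SpatialInertia:
    """Spatial inertia of a rigid link expressed at the link frame.

    Parameters
    ----------
    mass : float
        Link mass [kg], strictly positive.
    first_moment : (3,) array
        ``m * c`` with ``c`` the centre of mass in the link frame [kg m].
    inertia : (3, 3) array
        Rotational inertia about the **link-frame origin** [kg m^2]
        (not about the COM), symmetric positive definite.
    """

    mass: float
    first_moment: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "first_moment",
                           np.asarray(self.first_moment, dtype=float).reshape(3))
        object.__setattr__(self, "inertia",
                           np.asarray(self.inertia, dtype=float))
        if not self.mass > 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-10):
            raise ValueError("rotational inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.matrix()) <= 0):
            raise ValueError("spatial inertia matrix is not positive definite")

    @classmethod
    def from_com(cls, mass: float, com, inertia_at_com) -> "SpatialInertia":
        """Build from COM-referenced inertia via the parallel-axis theorem."""
        c = np.asarray(com, dtype=float)
        Sc = skew(c)
        I_origin = np.asarray(inertia_at_com, dtype=float) - mass * (Sc @ Sc)
        return cls(mass, mass * c, I_origin)

    @property
    def com(self) -> np.ndarray:
        return self.first_moment / self.mass

    def inertia_at_com(self) -> np.ndarray:
        Sc = skew(self.com)
        return self.inertia + self.mass * (Sc @ Sc)

    def matrix(self) -> np.ndarray:
        """Assembled 6x6 spatial inertia in (linear, angular) ordering::

            [[ m 1,   -S(h)],
             [ S(h),  I_o ]]     with h = m c.
        """
        Sh = skew(self.first_moment)
        M = np.zeros((6, 6))
        M[:3, :3] = self.mass * np.eye(3)
        M[:3, 3:] = -Sh
        M[3:, :3] = Sh
        M[3:, 3:] = self.inertia
        return M

    def transform(self, T: SpatialTransform) -> "SpatialInertia":
        """Express this inertia in the parent frame of ``T``.

        If the inertia is given in frame B and ``T = (A_R_B, A_o_B)``, the
        result is the same physical inertia expressed at frame A:
        ``M_A = X* M_B X^{-1}``.
        """
        Xs = force_adjoint(T)
        Xi = motion_adjoint(T.inverse())
        MA = Xs @ self.matrix() @ Xi
        MA = 0.5 * (MA + MA.T)
        m = MA[0, 0]
        Sh = MA[3:, :3]
        h = np.array([Sh[2, 1], Sh[0, 2], Sh[1, 0]])
        return SpatialInertia(m, h, MA[3:, 3:])
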