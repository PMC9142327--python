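"""Finite helical (screw) axis decomposition of a rigid transform.

By Chasles' theorem every proper rigid displacement ``x -> A x + o`` is a
rotation by an angle theta about a unique line (the finite helical axis)
combined with a translation ``t`` along that line.  For serial dental scans
this gives a compact, clinically readable summary of a tooth's interval
motion: the axis line (direction ``h`` through point ``q``), the rotation
angle about it, and the screw translation along it.

The axis is found from the displacement field p(n) = (A - K) n + o.  For
points on the axis the displacement is parallel to the axis and therefore
unchanged by the rotation, p = A^T p, which rearranges to the rank-2 linear
system

    (A + A^T - 2K) n + (K - A^T) o = 0.

Its solution set is exactly the axis line; the same points minimise the
displacement norm ||p(n)||.  Two strategies are provided for picking a
representative solution: the coordinate-free minimum-norm solution (the
axis point closest to the origin) and a fix-one-coordinate variant that
zeroes the coordinate with the largest axis component and solves the
remaining 2x2 system.

The rotation angle is available two ways that must agree: the trace
identity on ``A``, and a projection construction that rotates an off-axis
probe point ``d0`` to ``d1 = A d0 + o``, strips the screw translation
(``d2 = d1 - t h``), and measures the angle subtended at the common foot of
the perpendiculars from ``d0`` and ``d2`` to the axis.

Small rotations leave the axis *position* poorly determined (the linear
system approaches rank 1), so results below ``UNRELIABLE_THETA_DEG`` are
flagged, and below the degeneracy threshold the motion is reported as a
pure translation instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (DegenerateRotationError, IllConditionedPointError,
                     InconsistentAxisError)
from .geometry import RigidTransform, rotation_angle

#: Default angle (degrees) below which a motion is treated as a pure
#: translation (axis position undefined).
DEGENERACY_THRESHOLD_DEG = 0.1

#: Angle (degrees) below which the axis position, while computable, is
#: flagged as unreliable (highly noise-sensitive for small rotations).
UNRELIABLE_THETA_DEG = 0.5

#: Angle above which the skew-symmetric part of A is too small to orient
#: the axis and the symmetric part is used instead.
_NEAR_PI_DEG = 179.99

_AXIS_POINT_STRATEGIES = ("minimum_norm", "fix_coordinate")


@dataclass
class HelicalAxis:
    """Screw decomposition of a rigid transform.

    Attributes
    ----------
    h : unit axis direction (right-hand rule for the rotation sense);
        for a degenerate pure translation, the translation direction;
        the zero vector for a (near-)identity motion.
    q : a point on the axis in mm; NaN when degenerate.
    theta : rotation angle about ``h`` in degrees, in [0, 180].
    t : signed screw translation along ``h`` in mm.
    degenerate : True when theta is below the degeneracy threshold and the
        axis position is undefined.
    unreliable : True when theta is small enough (< 0.5 deg) that the axis
        position is highly sensitive to measurement error.
    """

    h: np.ndarray
    q: np.ndarray
    theta: float
    t: float
    degenerate: bool = False
    unreliable: bool = False

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64).reshape(3)
        self.q = np.asarray(self.q, dtype=np.float64).reshape(3)

    def to_transform(self) -> RigidTransform:
        """Reconstruct the rigid transform this axis describes."""
        if self.degenerate:
            return RigidTransform(np.eye(3), self.t * self.h)
        return RigidTransform.from_axis_angle(self.h, self.theta, self.q, self.t)


# ---------------------------------------------------------------------------
# Axis direction
# ---------------------------------------------------------------------------

def axis_direction(A: np.ndarray,
                   degeneracy_threshold_deg: float = DEGENERACY_THRESHOLD_DEG
                   ) -> np.ndarray:
    """Unit rotation axis ``h`` of ``A`` (the eigenvector with A h = h).

    The sign follows the right-hand rule, read off the skew-symmetric part
    of ``A``.  Near 180 degrees the skew part vanishes and the axis is taken
    from the dominant eigenvector of the symmetric part (A + K)/2, with the
    sign fixed so the first non-zero component is positive.
    """
    A = np.asarray(A, dtype=np.float64)
    theta = rotation_angle(A)
    if theta < degeneracy_threshold_deg:
        raise DegenerateRotationError(
            f"rotation angle {theta:.4g} deg below threshold "
            f"{degeneracy_threshold_deg:g} deg; axis undefined")
    if theta > _NEAR_PI_DEG:
        # skew part ~ 0: h is the eigenvector of (A + K)/2 with eigenvalue 1
        w, V = np.linalg.eigh((A + np.eye(3)) / 2.0)
        h = V[:, np.argmax(w)]
        nz = np.nonzero(np.abs(h) > 1e-12)[0]
        if nz.size and h[nz[0]] < 0:
            h = -h
    else:
        h = np.array([A[2, 1] - A[1, 2],
                      A[0, 2] - A[2, 0],
                      A[1, 0] - A[0, 1]])
        h = h / (2.0 * np.sin(np.deg2rad(theta)))
    return h / np.linalg.norm(h)


# ---------------------------------------------------------------------------
# Axis point
# ---------------------------------------------------------------------------

def _axis_system(t: RigidTransform) -> tuple:
    """Coefficients (M, b) of the on-axis condition M n = b."""
    K = np.eye(3)
    M = t.A + t.A.T - 2.0 * K
    b = -(K - t.A.T) @ t.o
    return M, b


def axis_point(t: RigidTransform, strategy: str = "minimum_norm",
               degeneracy_threshold_deg: float = DEGENERACY_THRESHOLD_DEG
               ) -> np.ndarray:
    """A point on the helical axis of ``t``.

    strategy="minimum_norm"
        Minimum-norm least-squares solution of the rank-2 axis system:
        the axis point closest to the origin.  Well conditioned for any
        axis orientation.
    strategy="fix_coordinate"
        Zero the coordinate with the largest |h| component and solve the
        remaining 2x2 system.  (Fixing a coordinate nearly perpendicular
        to the axis would be singular, hence the largest-|h| choice.)

    Both strategies return points on the same line; they differ by a vector
    parallel to the axis direction.
    """
    if strategy not in _AXIS_POINT_STRATEGIES:
        raise ValueError(f"unknown axis-point strategy {strategy!r}; "
                         f"choose from {_AXIS_POINT_STRATEGIES}")
    theta = rotation_angle(t.A)
    if theta < degeneracy_threshold_deg:
        raise DegenerateRotationError(
            f"rotation angle {theta:.4g} deg below threshold "
            f"{degeneracy_threshold_deg:g} deg; axis position undefined")
    M, b = _axis_system(t)
    if strategy == "minimum_norm":
        # The system is rank 2 by construction (its null space is the axis
        # direction); truncate the SVD to rank 2 explicitly, because the
        # numerically-tiny third singular value would otherwise leak an
        # arbitrary component along the axis into the solution.
        U, s, Vt = np.linalg.svd(M)
        return Vt[:2].T @ ((U[:, :2].T @ b) / s[:2])
    h = axis_direction(t.A, degeneracy_threshold_deg)
    i = int(np.argmax(np.abs(h)))
    keep = [j for j in range(3) if j != i]
    n2, *_ = np.linalg.lstsq(M[:, keep], b, rcond=None)
    n = np.zeros(3)
    n[keep] = n2
    return n


# ---------------------------------------------------------------------------
# Screw translation and angle via projection
# ---------------------------------------------------------------------------

def screw_translation(t: RigidTransform, h: Sequence[float],
                      q: Sequence[float] | None = None,
                      parallel_tol: float = 1e-6) -> float:
    """Signed translation along the axis ``h``: the displacement of an
    on-axis point projected onto ``h``.

    If ``q`` is omitted the minimum-norm axis point is computed.  Raises if
    ``h`` is not actually the rotation axis of ``t`` (the on-axis
    displacement must be parallel to ``h``).
    """
    h = np.asarray(h, dtype=np.float64).reshape(3)
    h = h / np.linalg.norm(h)
    if np.linalg.norm(t.A @ h - h) > parallel_tol:
        raise InconsistentAxisError(
            "direction is not invariant under the rotation (A h != h)")
    qv = axis_point(t) if q is None else np.asarray(q, dtype=np.float64).reshape(3)
    p = (t.A - np.eye(3)) @ qv + t.o
    t_screw = float(p @ h)
    perp = p - t_screw * h
    if np.linalg.norm(perp) > parallel_tol * max(1.0, np.linalg.norm(p)):
        raise InconsistentAxisError(
            f"displacement of the axis point is not parallel to h "
            f"(perpendicular residual {np.linalg.norm(perp):.3e} mm)")
    return t_screw


def project_onto_axis(d: Sequence[float], q: Sequence[float],
                      h: Sequence[float]) -> np.ndarray:
    """Foot of the perpendicular from ``d`` onto the line through ``q``
    with direction ``h``:  q' = q + ((d - q).h / h.h) h."""
    d = np.asarray(d, dtype=np.float64).reshape(3)
    q = np.asarray(q, dtype=np.float64).reshape(3)
    h = np.asarray(h, dtype=np.float64).reshape(3)
    hh = float(h @ h)
    if hh == 0.0:
        raise ValueError("axis direction h must be non-zero")
    return q + ((d - q) @ h / hh) * h


def rotation_angle_about_axis(t: RigidTransform, axis: HelicalAxis,
                              d0: Sequence[float],
                              min_offaxis_mm: float = 1e-6) -> float:
    """Rotation angle (degrees) measured geometrically at the axis.

    The probe point d0 is carried to d1 = A d0 + o, the screw translation
    is removed (d2 = d1 - t h), and the angle between the perpendicular
    offsets of d0 and d2 from the axis is returned.  Agrees with the trace
    formula for any valid off-axis probe.
    """
    d0 = np.asarray(d0, dtype=np.float64).reshape(3)
    foot0 = project_onto_axis(d0, axis.q, axis.h)
    u = d0 - foot0
    if np.linalg.norm(u) <= min_offaxis_mm:
        raise IllConditionedPointError(
            f"probe point is within {min_offaxis_mm:g} mm of the axis")
    d1 = t.A @ d0 + t.o
    d2 = d1 - axis.t * axis.h
    foot2 = project_onto_axis(d2, axis.q, axis.h)
    v = d2 - foot2
    cross = np.linalg.norm(np.cross(u, v))
    dot = float(u @ v)
    return float(np.rad2deg(np.arctan2(cross, dot)))


# ---------------------------------------------------------------------------
# Full decomposition
# ---------------------------------------------------------------------------

def helical_axis_from_transform(
        t: RigidTransform,
        degeneracy_threshold_deg: float = DEGENERACY_THRESHOLD_DEG,
        axis_point_strategy: str = "minimum_norm") -> HelicalAxis:
    """Decompose a rigid transform into its finite helical axis.

    Never raises on degeneracy: a motion whose rotation angle falls below
    the threshold is encoded as a pure translation (h along o, t = |o|,
    axis point NaN); a near-identity motion as a degenerate identity.
    """
    theta = rotation_angle(t.A)
    if theta < degeneracy_threshold_deg:
        norm_o = float(np.linalg.norm(t.o))
        if norm_o > 0.0:
            return HelicalAxis(h=t.o / norm_o, q=np.full(3, np.nan),
                               theta=theta, t=norm_o,
                               degenerate=True, unreliable=True)
        return HelicalAxis(h=np.zeros(3), q=np.full(3, np.nan),
                           theta=theta, t=0.0,
                           degenerate=True, unreliable=True)
    h = axis_direction(t.A, degeneracy_threshold_deg)
    q = axis_point(t, axis_point_strategy, degeneracy_threshold_deg)
    t_screw = screw_translation(t, h, q)
    return HelicalAxis(h=h, q=q, theta=theta, t=t_screw,
                       degenerate=False,
                       unreliable=theta < UNRELIABLE_THETA_DEG)


# ---------------------------------------------------------------------------
# Small geometric utility shared by tests, pipeline and acceptance script
# ---------------------------------------------------------------------------

def distance_to_line(points: np.ndarray, q: Sequence[float],
                     h: Sequence[float]) -> np.ndarray:
    """Perpendicular distance of each point to the line (q, h)."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    q = np.asarray(q, dtype=np.float64).reshape(3)
    h = np.asarray(h, dtype=np.float64).reshape(3)
    h = h / np.linalg.norm(h)
    rel = pts - q
    return np.linalg.norm(rel - np.outer(rel @ h, h), axis=1)
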