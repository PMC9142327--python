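"""Rigid-motion algebra on 3D point clouds.

A rigid tooth displacement between two serial scans is modelled as

    m = A n + o

with ``A`` a proper orthogonal 3x3 rotation matrix and ``o`` a translation
vector in millimetres.  The displacement field of the motion is

    p(n) = (A - K) n + o

where ``K`` is the 3x3 identity.  Everything downstream (registration,
helical-axis decomposition) is built on these two maps, so this module
enforces the rotation-matrix invariants strictly: orthonormality and
det(A) = +1 to within ``ORTHOGONALITY_TOL``.

Angles cross the public API in degrees; radians are used internally.
All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidTransformError

#: Tolerance on |A^T A - K| and |det(A) - 1| for accepting a rotation matrix.
ORTHOGONALITY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PointCloud:
    """An ordered set of 3D points in mm with optional per-point labels.

    Parameters
    ----------
    points
        Array-like of shape (n, 3); coerced to float64.
    labels
        Optional per-point structure identifiers (e.g. tooth names); must
        have the same length as ``points``.
    frame_id
        Free-text tag naming the coordinate frame the points live in.
    """

    points: np.ndarray
    labels: Optional[np.ndarray] = None
    frame_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must have shape (n, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        if self.labels is not None:
            lab = np.asarray(self.labels)
            if lab.shape[0] != pts.shape[0]:
                raise ValueError(
                    f"labels length {lab.shape[0]} != point count {pts.shape[0]}"
                )
            self.labels = lab

    def __len__(self) -> int:
        return self.points.shape[0]

    def subset(self, mask: np.ndarray, frame_id: Optional[str] = None) -> "PointCloud":
        """Return the sub-cloud selected by a boolean or index mask."""
        labels = self.labels[mask] if self.labels is not None else None
        return PointCloud(self.points[mask], labels,
                          self.frame_id if frame_id is None else frame_id)

    def select(self, label: str) -> "PointCloud":
        """Return the sub-cloud of points carrying ``label``."""
        if self.labels is None:
            raise ValueError("cloud has no labels")
        return self.subset(self.labels == label)

    def label_names(self) -> list:
        if self.labels is None:
            return []
        seen: dict = {}
        for l in self.labels:
            seen.setdefault(l, None)
        return list(seen)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> A x + o``.

    ``A`` must be orthogonal with det +1 (a rotation, never a reflection);
    construction rejects anything else.  Pass ``reproject=True`` via
    :meth:`from_matrix` to snap a slightly drifted matrix back onto SO(3).
    """

    A: np.ndarray
    o: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=np.float64)
        o = np.asarray(self.o, dtype=np.float64).reshape(3)
        _check_rotation(A)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "o", o)

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, A: np.ndarray, o: np.ndarray,
                    reproject: bool = False) -> "RigidTransform":
        """Build a transform, optionally re-projecting ``A`` onto SO(3).

        Re-projection (nearest rotation in Frobenius norm, via SVD) is
        opt-in: silently repairing a bad matrix would hide upstream bugs.
        """
        A = np.asarray(A, dtype=np.float64)
        if reproject:
            U, _, Vt = np.linalg.svd(A)
            D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
            A = U @ D @ Vt
        return cls(A, o)

    @classmethod
    def from_axis_angle(cls, axis: Sequence[float], theta_deg: float,
                        point: Sequence[float] = (0.0, 0.0, 0.0),
                        translation_along_axis: float = 0.0) -> "RigidTransform":
        """Screw motion: rotate ``theta_deg`` about the line through ``point``
        with direction ``axis``, then translate ``translation_along_axis``
        millimetres along the (unit-normalised) axis."""
        h = np.asarray(axis, dtype=np.float64)
        nrm = np.linalg.norm(h)
        if nrm == 0:
            raise ValueError("axis direction must be non-zero")
        h = h / nrm
        q = np.asarray(point, dtype=np.float64).reshape(3)
        A = rotation_from_axis_angle(h, theta_deg)
        o = q - A @ q + translation_along_axis * h
        return cls(A, o)

    # -- conveniences -------------------------------------------------------

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Apply the transform to a point or an (n, 3) array of points."""
        x = np.asarray(x, dtype=np.float64)
        return x @ self.A.T + self.o

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (np.allclose(self.A, np.eye(3), atol=tol)
                and np.allclose(self.o, 0.0, atol=tol))


@dataclass
class DisplacementField:
    """Per-point displacement vectors p_i = (A - K) n_i + o, index-aligned
    with the source cloud."""

    vectors: np.ndarray
    source: Optional[PointCloud] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vectors must have shape (n, 3), got {v.shape}")
        if self.source is not None and len(self.source) != v.shape[0]:
            raise ValueError("field length differs from source cloud length")
        self.vectors = v

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


# ---------------------------------------------------------------------------
# Rotation helpers
# ---------------------------------------------------------------------------

def _check_rotation(A: np.ndarray, tol: float = ORTHOGONALITY_TOL) -> None:
    if A.shape != (3, 3):
        raise InvalidTransformError(f"rotation matrix must be 3x3, got {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InvalidTransformError("rotation matrix contains non-finite entries")
    err = np.abs(A.T @ A - np.eye(3)).max()
    if err > tol:
        raise InvalidTransformError(
            f"matrix is not orthogonal: |A^T A - K| = {err:.3e} > {tol:g}")
    det = np.linalg.det(A)
    if abs(det - 1.0) > tol:
        raise InvalidTransformError(
            f"matrix is not a proper rotation: det(A) = {det:.12f} (reflection?)")


def rotation_from_axis_angle(axis: Sequence[float], theta_deg: float) -> np.ndarray:
    """Rodrigues' formula: the rotation matrix for ``theta_deg`` degrees
    about the unit vector ``axis`` (right-hand rule)."""
    h = np.asarray(axis, dtype=np.float64)
    nrm = np.linalg.norm(h)
    if nrm == 0:
        raise ValueError("axis direction must be non-zero")
    h = h / nrm
    th = np.deg2rad(theta_deg)
    Kx = np.array([[0.0, -h[2], h[1]],
                   [h[2], 0.0, -h[0]],
                   [-h[1], h[0], 0.0]])
    return np.eye(3) + np.sin(th) * Kx + (1.0 - np.cos(th)) * (Kx @ Kx)


def rotation_angle(A: np.ndarray) -> float:
    """Unsigned rotation angle of ``A`` in degrees, in [0, 180].

    Uses the trace identity theta = arccos((tr A - 1) / 2); the argument is
    clamped to [-1, 1] to absorb floating-point drift near 0 and 180 deg.
    """
    A = np.asarray(A, dtype=np.float64)
    _check_rotation(A)
    c = np.clip((np.trace(A) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.rad2deg(np.arccos(c)))


# ---------------------------------------------------------------------------
# Operations on transforms and clouds
# ---------------------------------------------------------------------------

def apply_transform(t: RigidTransform, cloud: PointCloud,
                    frame_id: Optional[str] = None) -> PointCloud:
    """Map every point n of ``cloud`` to A n + o, preserving labels and order."""
    pts = cloud.points @ t.A.T + t.o
    fid = frame_id if frame_id is not None else (cloud.frame_id + "*"
                                                if cloud.frame_id else "")
    labels = None if cloud.labels is None else cloud.labels.copy()
    return PointCloud(pts, labels, fid)


def displacement_field(t: RigidTransform, cloud: PointCloud) -> DisplacementField:
    """Displacement vectors p_i = (A - K) n_i + o for every point of ``cloud``."""
    vec = cloud.points @ (t.A - np.eye(3)).T + t.o
    return DisplacementField(vec, cloud)


def compose(t2: RigidTransform, t1: RigidTransform) -> RigidTransform:
    """The transform equal to applying ``t1`` first, then ``t2``."""
    return RigidTransform(t2.A @ t1.A, t2.A @ t1.o + t2.o)


def invert(t: RigidTransform) -> RigidTransform:
    """The inverse motion: A^-1 = A^T, o^-1 = -A^T o."""
    return RigidTransform(t.A.T, -(t.A.T @ t.o))
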