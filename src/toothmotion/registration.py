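"""Rigid registration of serial scan point clouds.

Serial dental casts are digitised in arbitrary poses, so each timepoint
must first be brought into a common coordinate frame before any per-tooth
motion can be measured.  Registration here is classical point-to-point:

* :func:`kabsch_fit` — least-squares optimal proper rotation + translation
  for *corresponded* point sets, via SVD of the cross-covariance, with the
  reflection case handled by a sign flip of the smallest singular
  direction so det(A) = +1 always.
* :func:`icp_register` — iterative closest point for *uncorresponded*
  clouds: alternate exact nearest-neighbour correspondence (via a k-d
  tree) with a Kabsch fit on the kept pairs until the mean fitting error
  stops improving.  Optional distance trimming gives robustness to partial
  overlap.
* :func:`mean_fitting_error` — the registration-quality statistic: the
  mean Euclidean distance from each point of one cloud to its nearest
  neighbour in the other.  Asymmetric (source -> target) by default; a
  symmetric average is available.
* :func:`normalize_series` — registers every timepoint onto the first via
  a designated stable reference structure (clinically: the maxillary first
  molars), so that per-tooth transforms are expressed in one frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError
from .geometry import PointCloud, RigidTransform, apply_transform, compose

logger = logging.getLogger("toothmotion.registration")

#: Relative singular-value threshold below which a source configuration is
#: considered collinear/coincident.
_RANK_TOL = 1e-9


@dataclass
class RegistrationResult:
    """Outcome of an ICP registration.

    ``per_iteration_error`` records the trimmed-mean nearest-neighbour
    distance at each correspondence step (the ICP objective), which is
    non-increasing under a fixed correspondence/trim policy.
    ``mean_fitting_error`` is the final untrimmed mean nearest-neighbour
    distance of the registered source to the target.
    """

    transform: RigidTransform
    mean_fitting_error: float
    iterations: int
    converged: bool
    per_iteration_error: List[float] = field(default_factory=list)


def _as_points(cloud) -> np.ndarray:
    if isinstance(cloud, PointCloud):
        return cloud.points
    return np.asarray(cloud, dtype=np.float64)


# ---------------------------------------------------------------------------
# Corresponded fit
# ---------------------------------------------------------------------------

def kabsch_fit(source, target) -> RigidTransform:
    """Least-squares rigid fit of corresponded point sets.

    Returns the proper rigid transform (A, o) minimising
    sum_i ||A s_i + o - t_i||^2 over rotations with det(A) = +1.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, mismatched counts, or a rank-deficient
        (collinear or coincident) source configuration.
    """
    S = _as_points(source)
    T = _as_points(target)
    if S.shape != T.shape:
        raise DegenerateGeometryError(
            f"corresponded clouds must match in size: {S.shape} vs {T.shape}")
    n = S.shape[0]
    if n < 3:
        raise DegenerateGeometryError(
            f"need at least 3 corresponded points, got {n}")
    cs = S.mean(axis=0)
    ct = T.mean(axis=0)
    P = S - cs
    Q = T - ct
    sv = np.linalg.svd(P, compute_uv=False)
    if sv[1] <= _RANK_TOL * max(sv[0], 1.0):
        kind = "coincident" if sv[0] <= _RANK_TOL else "collinear"
        raise DegenerateGeometryError(
            f"source points are {kind}: rotation about the degenerate "
            f"direction is unconstrained (singular values {sv})")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    A = Vt.T @ D @ U.T
    o = ct - A @ cs
    return RigidTransform(A, o)


# ---------------------------------------------------------------------------
# Fitting-error metric
# ---------------------------------------------------------------------------

def mean_fitting_error(a, b, symmetric: bool = False) -> float:
    """Mean nearest-neighbour distance (mm) from cloud ``a`` to cloud ``b``.

    Asymmetric by definition (every point of ``a`` to its closest point of
    ``b``); ``symmetric=True`` averages the two directions.
    """
    A = _as_points(a)
    B = _as_points(b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise DegenerateGeometryError("mean fitting error of an empty cloud")
    d_ab = cKDTree(B).query(A)[0].mean()
    if not symmetric:
        return float(d_ab)
    d_ba = cKDTree(A).query(B)[0].mean()
    return float((d_ab + d_ba) / 2.0)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

def icp_register(source, target, max_iter: int = 100, tol: float = 1e-6,
                 trim_fraction: float = 0.0,
                 initial: Optional[RigidTransform] = None) -> RegistrationResult:
    """Point-to-point ICP of ``source`` onto ``target``.

    Alternates exact nearest-neighbour correspondence (ties broken by
    lowest target index) with a Kabsch fit on the kept pairs.  With
    ``trim_fraction`` > 0 the farthest pairs are dropped each iteration
    (robustness to partial overlap).  Iteration stops when the objective
    improves by less than ``tol`` mm or after ``max_iter`` iterations;
    non-convergence is reported via ``converged=False``, never raised.

    Initialisation is the identity (serial casts are assumed coarsely
    pre-oriented) unless ``initial`` is given.
    """
    S = _as_points(source)
    T = _as_points(target)
    if S.shape[0] < 10 or T.shape[0] < 10:
        raise DegenerateGeometryError(
            f"ICP needs at least 10 points per cloud, got "
            f"{S.shape[0]} and {T.shape[0]}")
    if not (0.0 <= trim_fraction < 0.5):
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")

    tree = cKDTree(T)
    current = RigidTransform.identity() if initial is None else initial
    n_keep = S.shape[0] - int(np.floor(trim_fraction * S.shape[0]))
    errors: List[float] = []
    converged = False
    iterations = 0

    for iterations in range(1, max_iter + 1):
        moved = S @ current.A.T + current.o
        dist, idx = tree.query(moved)
        if n_keep < S.shape[0]:
            keep = np.argsort(dist, kind="stable")[:n_keep]
        else:
            keep = slice(None)
        err = float(dist[keep].mean()) if n_keep < S.shape[0] else float(dist.mean())
        errors.append(err)
        if len(errors) >= 2 and errors[-2] - errors[-1] < tol:
            converged = True
            break
        if err == 0.0:
            converged = True
            break
        delta = kabsch_fit(moved[keep], T[idx[keep]])
        current = compose(delta, current)

    moved = S @ current.A.T + current.o
    final_err = float(tree.query(moved)[0].mean())
    if not converged:
        logger.warning("ICP did not converge in %d iterations (last "
                       "improvement %.3g mm)", max_iter,
                       errors[-2] - errors[-1] if len(errors) > 1 else np.nan)
    return RegistrationResult(transform=current,
                              mean_fitting_error=final_err,
                              iterations=iterations,
                              converged=converged,
                              per_iteration_error=errors)


# ---------------------------------------------------------------------------
# Series normalization
# ---------------------------------------------------------------------------

def normalize_series(scans: Sequence[PointCloud], reference_label: str,
                     max_iter: int = 100, tol: float = 1e-6,
                     trim_fraction: float = 0.0
                     ) -> List[Tuple[PointCloud, RigidTransform]]:
    """Register every scan onto the first via the stable reference structure.

    For each scan after the first, the sub-cloud carrying
    ``reference_label`` is ICP-registered onto the first scan's reference
    sub-cloud and the resulting transform is applied to the whole scan.
    Returns (normalized scan, normalizing transform) pairs; the first scan
    is returned unchanged with the identity.
    """
    if len(scans) == 0:
        raise ValueError("empty scan series")
    refs = []
    for i, scan in enumerate(scans):
        if scan.labels is None or not np.any(scan.labels == reference_label):
            raise DegenerateGeometryError(
                f"scan {i} has no points labelled {reference_label!r}")
        refs.append(scan.select(reference_label))

    out: List[Tuple[PointCloud, RigidTransform]] = [
        (scans[0], RigidTransform.identity())]
    for i in range(1, len(scans)):
        res = icp_register(refs[i], refs[0], max_iter=max_iter, tol=tol,
                           trim_fraction=trim_fraction)
        logger.info("normalize scan %d: mean fitting error %.4g mm after "
                    "%d ICP iterations (converged=%s)", i,
                    res.mean_fitting_error, res.iterations, res.converged)
        out.append((apply_transform(res.transform, scans[i],
                                    frame_id=scans[0].frame_id),
                    res.transform))
    return out
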