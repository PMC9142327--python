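"""Measurement-accuracy check: plane fit to a scanned calibration plate.

A flat calibration plate is scanned and a best-fit plane is computed; the
largest absolute deviation of the measured points from that plane bounds
the measurement accuracy of the scanning system.

Two fitting conventions are provided.  The default is orthogonal (total)
least squares — minimise the *geometric* point-to-plane distances, which
is what the deviation metric measures — computed from the smallest
principal direction of the centred cloud.  The coordinate-regression
variant (ordinary least squares of z on x, y) is exposed for comparison;
it minimises vertical residuals and is never better than the orthogonal
fit in RMS geometric deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .geometry import PointCloud

_PLANE_METHODS = ("orthogonal", "z_regression")


@dataclass
class PlaneFitResult:
    """Best-fit plane {x : normal . x = offset} plus deviation statistics.

    ``max_abs_deviation`` is the calibration accuracy statistic: the
    largest absolute signed distance of any point from the fitted plane.
    """

    normal: np.ndarray
    offset: float
    max_abs_deviation: float
    rms_deviation: float
    deviations: np.ndarray
    method: str = "orthogonal"


def _fix_sign(n: np.ndarray) -> np.ndarray:
    """Sign convention: positive z-component, else first non-zero positive."""
    if n[2] != 0.0:
        return n if n[2] > 0 else -n
    nz = np.nonzero(n)[0]
    if nz.size and n[nz[0]] < 0:
        return -n
    return n


def fit_plane(cloud, method: str = "orthogonal") -> PlaneFitResult:
    """Fit a plane to a point cloud and report deviation statistics.

    Parameters
    ----------
    cloud
        PointCloud or (n, 3) array, n >= 3, not all collinear.
    method
        "orthogonal" (total least squares, default) or "z_regression"
        (ordinary least squares of z on x and y).
    """
    pts = cloud.points if isinstance(cloud, PointCloud) else \
        np.asarray(cloud, dtype=np.float64)
    if pts.shape[0] < 3:
        raise DegenerateGeometryError(
            f"plane fit needs at least 3 points, got {pts.shape[0]}")
    c = pts.mean(axis=0)
    centered = pts - c
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            "points are collinear or coincident; plane is undetermined")

    if method == "orthogonal":
        # normal = direction of least variance of the centred cloud
        _, _, Vt = np.linalg.svd(centered, full_matrices=False)
        n = _fix_sign(Vt[2])
    elif method == "z_regression":
        X = np.column_stack([pts[:, 0], pts[:, 1], np.ones(pts.shape[0])])
        try:
            beta, *_ = np.linalg.lstsq(X, pts[:, 2], rcond=None)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DegenerateGeometryError(str(exc)) from exc
        a, b, _ = beta
        n = _fix_sign(np.array([-a, -b, 1.0]) / np.sqrt(a * a + b * b + 1.0))
    else:
        raise ValueError(f"unknown plane-fit method {method!r}; "
                         f"choose from {_PLANE_METHODS}")

    # geometric signed deviations from the plane through the deviation-mean
    # (for the regression fit the plane is re-anchored so the mean signed
    # geometric deviation is zero, making RMS comparisons fair)
    offset = float(n @ c) if method == "orthogonal" else float((pts @ n).mean())
    dev = pts @ n - offset
    return PlaneFitResult(normal=n, offset=offset,
                          max_abs_deviation=float(np.abs(dev).max()),
                          rms_deviation=float(np.sqrt(np.mean(dev ** 2))),
                          deviations=dev, method=method)
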