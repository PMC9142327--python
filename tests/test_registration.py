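"""Kabsch fit, ICP, mean fitting error, series normalization."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from toothmotion import (DegenerateGeometryError, PointCloud, RigidTransform,
                         ScrewMotionSpec, add_scanner_noise, apply_transform,
                         generate_crown, icp_register, kabsch_fit,
                         mean_fitting_error, normalize_series,
                         rotation_angle, rotation_from_axis_angle)
from conftest import random_cloud, random_rigid


def _fib_sphere(n):
    """Quasi-uniform directions on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def brute_force_rigid_residual(S, T, grid_deg=2.0):
    """Independent oracle: exhaustive axis-angle grid search (about
    ``grid_deg`` spacing) with local refinement, using scipy rotations.

    Returns the smallest sum of squared residuals found."""
    cs, ct = S.mean(0), T.mean(0)
    P, Q = S - cs, T - ct
    H = P.T @ Q
    const = (P ** 2).sum() + (Q ** 2).sum()

    n_dirs = int(np.ceil(4 * 180 ** 2 / (np.pi * grid_deg ** 2)))
    dirs = _fib_sphere(n_dirs)
    angles = np.deg2rad(np.arange(0.0, 180.0 + grid_deg, grid_deg))
    # residual(R) = const - 2 tr(R H); evaluate on the whole grid
    best = (np.inf, None)
    for ang in angles:
        R = Rotation.from_rotvec(dirs * ang).as_matrix()
        res = const - 2 * np.einsum("nij,ji->n", R, H)
        k = int(np.argmin(res))
        if res[k] < best[0]:
            best = (float(res[k]), dirs[k] * ang)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return const - 2 * float(np.trace(R @ H))

    out = minimize(objective, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 2000})
    return min(best[0], float(out.fun))


def _sum_sq_residual(t: RigidTransform, S, T):
    return float(((S @ t.A.T + t.o - T) ** 2).sum())


# ---------------------------------------------------------------------------
# kabsch_fit
# ---------------------------------------------------------------------------

class TestKabschFit:
    def test_identical_clouds_give_identity(self, rng):
        cloud = random_cloud(rng, n=12)
        t = kabsch_fit(cloud, cloud)
        assert t.is_identity(tol=1e-10)

    def test_pure_translation_recovered(self, rng):
        src = random_cloud(rng, n=8)
        tgt = PointCloud(src.points + np.array([1.0, 2.0, 3.0]))
        t = kabsch_fit(src, tgt)
        np.testing.assert_allclose(t.A, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t.o, [1, 2, 3], atol=1e-10)

    def test_noisy_screw_recovery_and_grid_oracle(self, rng):
        spec = ScrewMotionSpec((0.3, -0.5, 0.81), (2.0, 1.0, -3.0), 4.0, 0.2)
        truth = spec.to_transform()
        S = rng.uniform(-10, 10, (10, 3))
        T = truth(S) + rng.normal(0, 0.01, (10, 3))
        fit = kabsch_fit(S, T)
        assert rotation_angle(fit.A @ truth.A.T) < 0.5
        assert np.linalg.norm(fit.o - truth.o) < 0.1
        assert _sum_sq_residual(fit, S, T) <= \
            brute_force_rigid_residual(S, T) + 1e-9

    def test_global_optimality_vs_grid_oracle(self, rng):
        for _ in range(5):
            S = rng.uniform(-5, 5, (rng.integers(4, 13), 3))
            T = random_rigid(rng, max_angle_deg=90)(S) \
                + rng.normal(0, 0.3, S.shape)
            fit = kabsch_fit(S, T)
            assert _sum_sq_residual(fit, S, T) <= \
                brute_force_rigid_residual(S, T, grid_deg=4.0) + 1e-9

    def test_rotation_equivariance(self, rng):
        S = rng.uniform(-5, 5, (15, 3))
        T = random_rigid(rng)(S) + rng.normal(0, 0.05, S.shape)
        fit = kabsch_fit(S, T)
        Q = rotation_from_axis_angle((0.2, 0.9, -0.3), 57.0)
        fit_rot = kabsch_fit(S @ Q.T, T @ Q.T)
        np.testing.assert_allclose(fit_rot.A, Q @ fit.A @ Q.T, atol=1e-9)
        np.testing.assert_allclose(fit_rot.o, Q @ fit.o, atol=1e-9)

    def test_reflection_never_returned(self, rng):
        # a degenerate correspondence that tempts det = -1
        S = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                      [0.5, 0.5, 1.0]])
        T = S.copy()
        T[:, 2] *= -1  # mirrored target
        fit = kabsch_fit(S, T)
        assert np.linalg.det(fit.A) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad,match", [
        (np.zeros((2, 3)), "at least 3"),
        (np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3.0]]), "collinear"),
        (np.zeros((5, 3)), "coincident"),
    ])
    def test_degenerate_sources_rejected(self, bad, match):
        with pytest.raises(DegenerateGeometryError, match=match):
            kabsch_fit(bad, bad + 1.0)


# ---------------------------------------------------------------------------
# mean_fitting_error
# ---------------------------------------------------------------------------

class TestMeanFittingError:
    def test_identical_clouds_zero(self, rng):
        c = random_cloud(rng, n=50)
        assert mean_fitting_error(c, c) == 0.0

    def test_dense_plane_offset(self):
        xs = np.arange(0, 1.0, 0.01)
        grid = np.array([[x, y, 0.0] for x in xs for y in xs])
        a = PointCloud(grid)
        b = PointCloud(grid + np.array([0, 0, 0.05]))
        err = mean_fitting_error(a, b)
        assert err == pytest.approx(0.05, rel=0.02)
        # oracle: exhaustive pairwise distances on a subsample
        sub = a.points[::37]
        d = np.linalg.norm(sub[:, None, :] - b.points[None, :, :],
                           axis=2).min(axis=1)
        assert d.mean() == pytest.approx(0.05, rel=0.02)

    def test_asymmetric_by_default_symmetric_on_request(self, rng):
        a = PointCloud(rng.uniform(0, 1, (30, 3)))
        b = PointCloud(np.vstack([a.points, rng.uniform(5, 6, (30, 3))]))
        ab = mean_fitting_error(a, b)
        ba = mean_fitting_error(b, a)
        assert ab == pytest.approx(0.0, abs=1e-12)
        assert ba > 1.0
        assert mean_fitting_error(a, b, symmetric=True) == \
            pytest.approx((ab + ba) / 2)

    def test_triangle_style_bound(self, rng):
        for _ in range(10):
            a, b, c = (rng.uniform(-3, 3, (25, 3)) for _ in range(3))
            hausdorff_bc = max(
                np.linalg.norm(b[:, None] - c[None], axis=2).min(1).max(),
                np.linalg.norm(c[:, None] - b[None], axis=2).min(1).max())
            assert mean_fitting_error(a, c) <= \
                mean_fitting_error(a, b) + hausdorff_bc + 1e-12

    def test_empty_cloud_rejected(self, rng):
        with pytest.raises(DegenerateGeometryError):
            mean_fitting_error(np.zeros((0, 3)), random_cloud(rng))


# ---------------------------------------------------------------------------
# icp_register
# ---------------------------------------------------------------------------

class TestIcpRegister:
    def test_identical_clouds_converge_immediately(self, rng):
        c = random_cloud(rng, n=50)
        res = icp_register(c, c)
        assert res.converged and res.iterations <= 2
        assert res.mean_fitting_error == 0.0
        assert res.transform.is_identity(tol=1e-12)

    def test_noise_free_screw_recovered(self):
        crown = generate_crown(n_points=1000, seed=5)
        spec = ScrewMotionSpec((0.1, 0.7, 0.7), (1.0, 2.0, 0.0), 2.0, 0.2)
        target = PointCloud(spec.to_transform()(crown.points))
        res = icp_register(crown, target, trim_fraction=0.0)
        assert res.converged
        moved = res.transform(crown.points)
        assert np.abs(moved - target.points).max() < 1e-6
        assert res.mean_fitting_error < 1e-6

    def test_per_iteration_error_non_increasing(self):
        crown = generate_crown(n_points=800, seed=6)
        t = RigidTransform.from_axis_angle((0, 1, 0), 4.0,
                                           point=(3, 0, 0),
                                           translation_along_axis=1.0)
        res = icp_register(crown, PointCloud(t(crown.points)))
        errs = np.asarray(res.per_iteration_error)
        assert np.all(np.diff(errs[1:]) <= 1e-12)

    def test_noise_floor_matches_monte_carlo_band(self):
        """With sigma = 0.02 mm target noise, the converged fitting error
        sits in a band around the pure noise floor (Monte-Carlo oracle)."""
        crown = generate_crown(n_points=1000, seed=7)
        spec = ScrewMotionSpec((0, 0, 1), (2.0, 0.0, 0.0), 2.0, 0.2)
        truth = spec.to_transform()
        rng = np.random.default_rng(99)
        moved = truth(crown.points)
        target = PointCloud(moved + rng.normal(0, 0.02, moved.shape))
        res = icp_register(crown, target)
        # oracle: mean NN distance of a clean cloud to noisy copies of itself
        floors = []
        for _ in range(50):
            noisy = crown.points + rng.normal(0, 0.02, crown.points.shape)
            from scipy.spatial import cKDTree
            floors.append(cKDTree(noisy).query(crown.points)[0].mean())
        floor = float(np.mean(floors))
        assert 0.8 * floor <= res.mean_fitting_error <= 1.3 * floor

    def test_trim_fraction_validated(self, rng):
        c = random_cloud(rng, n=20)
        with pytest.raises(ValueError):
            icp_register(c, c, trim_fraction=0.7)

    def test_tiny_clouds_rejected(self, rng):
        c = random_cloud(rng, n=5)
        with pytest.raises(DegenerateGeometryError):
            icp_register(c, c)

    def test_non_convergence_flagged_not_raised(self):
        crown = generate_crown(n_points=300, seed=8)
        t = RigidTransform.from_axis_angle((1, 0, 0), 4.0)
        res = icp_register(crown, PointCloud(t(crown.points)),
                           max_iter=2, tol=1e-12)
        assert not res.converged


# ---------------------------------------------------------------------------
# normalize_series
# ---------------------------------------------------------------------------

def _two_block_scan(seed, frame="T0"):
    ref = generate_crown((-15.0, 0.0, 0.0), (5, 5, 5), 400, seed=seed)
    tooth = generate_crown((10.0, 5.0, 0.0), (4, 3, 5), 400, seed=seed + 1)
    pts = np.vstack([ref.points, tooth.points])
    labels = np.array(["molars"] * 400 + ["incisor"] * 400)
    return PointCloud(pts, labels, frame)


class TestNormalizeSeries:
    def test_coincident_series_returns_identities(self):
        scans = [_two_block_scan(1, f"T{i}") for i in range(3)]
        out = normalize_series(scans, "molars")
        for scan, t in out:
            assert t.is_identity(tol=1e-9)

    def test_whole_scan_motion_removed_tooth_motion_kept(self):
        base = _two_block_scan(2)
        tooth_motion = RigidTransform.from_axis_angle(
            (0, 0, 1), 3.0, point=(10, 5, 0), translation_along_axis=0.2)
        moved = base.points.copy()
        mask = base.labels == "incisor"
        moved[mask] = tooth_motion(moved[mask])
        scan1 = PointCloud(moved, base.labels.copy(), "T1")
        # whole-scan placement perturbation on scan 1
        pose = RigidTransform.from_axis_angle((1, 2, 0.5), 4.0,
                                              point=(0, 0, 0))
        pose = RigidTransform(pose.A, pose.o + np.array([3.0, -2.0, 1.0]))
        scan1 = apply_transform(pose, scan1)
        out = normalize_series([base, scan1], "molars")
        norm1 = out[1][0]
        # reference coincides again
        assert mean_fitting_error(norm1.select("molars"),
                                  base.select("molars")) < 1e-6
        # the moved tooth retains exactly its simulated relative motion
        np.testing.assert_allclose(
            norm1.select("incisor").points,
            tooth_motion(base.select("incisor").points), atol=1e-6)

    def test_missing_reference_label_identifies_scan(self):
        good = _two_block_scan(3)
        bad = PointCloud(good.points.copy(),
                         np.array(["incisor"] * len(good)), "T1")
        with pytest.raises(DegenerateGeometryError, match="scan 1"):
            normalize_series([good, bad], "molars")
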