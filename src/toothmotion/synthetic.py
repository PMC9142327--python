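"""Synthetic serial-scan generator: the ground truth for every other stage.

No deposited scan data exists for this kind of study, so the simulator
produces what the measurement chain would see: crown-like point clouds
(superellipsoid surfaces at the millimetre scale of tooth crowns) arranged
into a labelled arch, displaced between timepoints by small prescribed
screw motions (the recovery targets), placed in an arbitrary global pose
per timepoint (casts are positioned randomly in the scanner), and
corrupted by anisotropic scanner noise.

The scanner's axis resolutions are quantisation steps, not Gaussian
widths; the default noise model is Gaussian with sigma = step / sqrt(12)
per axis (variance-matching a uniform quantiser, steps 0.01 / 0.1 / 0.01
mm).  A pure-quantisation mode is available via :func:`quantize_cloud`.

All randomness flows from a single seed, fanned out to per-operation
child generators by stable hashing of (seed, operation, label, timepoint),
so regeneration is bit-identical and independent of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import PointCloud, RigidTransform, apply_transform

#: Scanner axis quantisation steps in mm (x, y, z).
SCANNER_STEPS_MM = (0.01, 0.1, 0.01)

#: Gaussian-equivalent noise sigmas: step / sqrt(12).
DEFAULT_NOISE_SIGMA = tuple(s / np.sqrt(12.0) for s in SCANNER_STEPS_MM)

#: Superellipsoid shape exponent: 1 is an ellipsoid, ->0 a box; 0.8 gives
#: the box-rounded look of a tooth crown.
CROWN_EXPONENT = 0.8

#: Default crown half-axes in mm (bucco-lingual, mesio-distal, occluso-apical).
DEFAULT_CROWN_SIZE = (4.0, 3.0, 5.0)

#: Default global cast-placement perturbation bounds: uniform rotation angle
#: in [0, 5] degrees and translation magnitude in [0, 5] mm.
POSE_PERTURBATION_MAX_DEG = 5.0
POSE_PERTURBATION_MAX_MM = 5.0


def child_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child generator for (seed, *tokens).

    Tokens are hashed with CRC-32 so the stream depends only on the seed
    and the identifying strings, never on call order.
    """
    entropy = [int(seed)] + [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Ground-truth screw motions
# ---------------------------------------------------------------------------

@dataclass
class ScrewMotionSpec:
    """Ground-truth screw motion applied to one structure over one interval.

    theta in degrees (>= 0), t in mm (signed, along h), q in mm.
    """

    h: np.ndarray
    q: np.ndarray
    theta: float
    t: float
    label: str = ""
    interval: Tuple[int, int] = (0, 1)

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=np.float64).reshape(3)
        nrm = np.linalg.norm(h)
        if nrm == 0:
            raise ValueError("screw axis direction must be non-zero")
        self.h = h / nrm
        self.q = np.asarray(self.q, dtype=np.float64).reshape(3)
        if self.theta < 0:
            raise ValueError("theta must be non-negative")

    def to_transform(self) -> RigidTransform:
        return RigidTransform.from_axis_angle(self.h, self.theta, self.q, self.t)


def random_screw(rng: np.random.Generator, label: str = "",
                 interval: Tuple[int, int] = (0, 1),
                 theta_range: Tuple[float, float] = (0.5, 5.0),
                 t_range: Tuple[float, float] = (0.05, 0.5),
                 axis_radius_mm: float = 20.0,
                 center: Sequence[float] = (0.0, 0.0, 0.0)) -> ScrewMotionSpec:
    """Draw a random screw motion at dental scale: rotation 0.5-5 degrees,
    translation 0.05-0.5 mm, axis passing within ``axis_radius_mm`` of
    ``center``."""
    h = rng.standard_normal(3)
    h /= np.linalg.norm(h)
    # uniform point in the ball of radius axis_radius_mm around center
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    r = axis_radius_mm * rng.random() ** (1.0 / 3.0)
    q = np.asarray(center, dtype=np.float64) + r * u
    theta = rng.uniform(*theta_range)
    t = rng.uniform(*t_range) * rng.choice([-1.0, 1.0])
    return ScrewMotionSpec(h=h, q=q, theta=theta, t=t,
                           label=label, interval=interval)


def apply_screw(cloud: PointCloud, spec: ScrewMotionSpec) -> PointCloud:
    """Displace a cloud by the screw motion: Rodrigues rotation about the
    line (q, h) plus t mm translation along h."""
    return apply_transform(spec.to_transform(), cloud,
                           frame_id=cloud.frame_id)


# ---------------------------------------------------------------------------
# Crown surfaces
# ---------------------------------------------------------------------------

def generate_crown(center: Sequence[float] = (0.0, 0.0, 0.0),
                   size: Sequence[float] = DEFAULT_CROWN_SIZE,
                   n_points: int = 800, seed: int = 0,
                   exponent: float = CROWN_EXPONENT) -> PointCloud:
    """Sample a crown-like superellipsoid surface.

    The surface is the level set sum_i |x_i / a_i|^(2/eps) = 1 with
    half-axes ``size`` and shape exponent ``eps``; points are generated by
    casting seeded random directions from the centre and scaling each onto
    the surface (quasi-uniform for these mildly aspherical shapes).
    """
    size = np.asarray(size, dtype=np.float64)
    if np.any(size <= 0):
        raise ValueError(f"crown half-axes must be positive, got {size}")
    if n_points < 50:
        raise ValueError(f"n_points must be >= 50, got {n_points}")
    rng = child_rng(seed, "crown", tuple(np.round(center, 9)))
    u = rng.standard_normal((n_points, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    g = np.sum(np.abs(u / size) ** (2.0 / exponent), axis=1)
    r = g ** (-exponent / 2.0)
    pts = np.asarray(center, dtype=np.float64) + r[:, None] * u
    return PointCloud(pts, frame_id="crown")


def superellipsoid_implicit(points: np.ndarray, center: Sequence[float],
                            size: Sequence[float],
                            exponent: float = CROWN_EXPONENT) -> np.ndarray:
    """Implicit function sum_i |x_i/a_i|^(2/eps) - 1 (zero on the surface)."""
    rel = (np.atleast_2d(points) - np.asarray(center, dtype=np.float64))
    return np.sum(np.abs(rel / np.asarray(size, dtype=np.float64))
                  ** (2.0 / exponent), axis=1) - 1.0


# ---------------------------------------------------------------------------
# Scanner noise
# ---------------------------------------------------------------------------

def add_scanner_noise(cloud: PointCloud,
                      sigma_xyz: Sequence[float] = DEFAULT_NOISE_SIGMA,
                      seed: int = 0) -> PointCloud:
    """Add independent zero-mean Gaussian noise per axis (mm)."""
    sigma = np.asarray(sigma_xyz, dtype=np.float64)
    if np.any(sigma < 0):
        raise ValueError("noise sigmas must be non-negative")
    rng = child_rng(seed, "noise")
    noisy = cloud.points + rng.standard_normal(cloud.points.shape) * sigma
    labels = None if cloud.labels is None else cloud.labels.copy()
    return PointCloud(noisy, labels, cloud.frame_id)


def quantize_cloud(cloud: PointCloud,
                   steps_xyz: Sequence[float] = SCANNER_STEPS_MM) -> PointCloud:
    """Pure-quantisation scanner model: round each axis to its resolution step."""
    steps = np.asarray(steps_xyz, dtype=np.float64)
    pts = cloud.points.copy()
    for i, s in enumerate(steps):
        if s > 0:
            pts[:, i] = np.round(pts[:, i] / s) * s
    labels = None if cloud.labels is None else cloud.labels.copy()
    return PointCloud(pts, labels, cloud.frame_id)


# ---------------------------------------------------------------------------
# Arch layout and serial series
# ---------------------------------------------------------------------------

@dataclass
class ArchLayout:
    """Which structures make up the simulated arch.

    ``structures`` maps a label to a list of (center, half-axes, n_points)
    crown blocks; a structure may consist of several blocks (e.g. a molar
    pair sharing one reference label).
    """

    structures: Dict[str, List[Tuple[Tuple[float, float, float],
                                     Tuple[float, float, float], int]]]
    reference_label: str

    def labels(self) -> List[str]:
        return list(self.structures)


def default_arch() -> ArchLayout:
    """A minimal maxillary-like arch: three anterior teeth plus a stable
    posterior reference (bilateral molar blocks, as when a transpalatal
    bar splints the first molars)."""
    crown = DEFAULT_CROWN_SIZE
    molar = (5.0, 4.5, 5.0)
    return ArchLayout(
        structures={
            "incisor_central": [((0.0, 22.0, 0.0), crown, 700)],
            "incisor_lateral": [((8.0, 20.0, 0.0), crown, 700)],
            "canine": [((15.0, 15.0, 0.0), crown, 700)],
            "molars": [((22.0, 0.0, 0.0), molar, 500),
                       ((-22.0, 0.0, 0.0), molar, 500)],
        },
        reference_label="molars",
    )


@dataclass
class SyntheticSeries:
    """A simulated serial-scan study with its complete ground truth."""

    scans: List[PointCloud]
    specs: List[ScrewMotionSpec]
    noise_sigma: Tuple[float, float, float]
    seed: int
    layout: Optional[ArchLayout] = None
    global_poses: List[RigidTransform] = field(default_factory=list)
    anatomy: List[PointCloud] = field(default_factory=list, repr=False)


def _base_arch_cloud(layout: ArchLayout, seed: int) -> PointCloud:
    points, labels = [], []
    for label, blocks in layout.structures.items():
        for bi, (center, size, n_points) in enumerate(blocks):
            crown = generate_crown(center, size, n_points,
                                   seed=child_rng(seed, "arch", label, bi)
                                   .integers(2 ** 31))
            points.append(crown.points)
            labels.extend([label] * len(crown))
    return PointCloud(np.vstack(points), np.asarray(labels), frame_id="T0")


def _random_pose(rng: np.random.Generator,
                 max_deg: float, max_mm: float) -> RigidTransform:
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_deg)
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    o = rng.uniform(0.0, max_mm) * u
    from .geometry import rotation_from_axis_angle
    return RigidTransform(rotation_from_axis_angle(axis, angle), o)


def generate_series(layout: Optional[ArchLayout] = None,
                    specs: Sequence[ScrewMotionSpec] = (),
                    n_timepoints: int = 5,
                    noise: Sequence[float] = DEFAULT_NOISE_SIGMA,
                    seed: int = 0,
                    global_perturbation: bool = True,
                    perturb_max_deg: float = POSE_PERTURBATION_MAX_DEG,
                    perturb_max_mm: float = POSE_PERTURBATION_MAX_MM
                    ) -> SyntheticSeries:
    """Simulate a serial-scan study.

    Timepoint 0 is the base arch.  Each later timepoint applies that
    interval's per-tooth screw motions (in the anatomical frame, i.e.
    motions accumulate), keeps the reference structure fixed, then — for
    scans after the first — applies a random whole-scan pose perturbation
    emulating arbitrary cast placement, and finally adds scanner noise.

    The ground-truth screw specs are expressed in the anatomical frame of
    timepoint 0, which is also the frame the analysis recovers after
    normalisation on the reference structure.
    """
    if n_timepoints < 2:
        raise ValueError(f"need at least 2 timepoints, got {n_timepoints}")
    if layout is None:
        layout = default_arch()
    known = set(layout.structures)
    for s in specs:
        if s.label not in known:
            raise ValueError(f"screw spec references unknown structure "
                             f"{s.label!r} (known: {sorted(known)})")
        if s.label == layout.reference_label:
            raise ValueError(f"reference structure {s.label!r} must stay fixed")
        i, j = s.interval
        if not (0 <= i < j < n_timepoints) or j != i + 1:
            raise ValueError(f"spec interval {s.interval} is not a consecutive "
                             f"pair within 0..{n_timepoints - 1}")

    base = _base_arch_cloud(layout, seed)
    anatomy = [base]
    for k in range(1, n_timepoints):
        prev = anatomy[-1]
        pts = prev.points.copy()
        for s in specs:
            if s.interval == (k - 1, k):
                mask = prev.labels == s.label
                t = s.to_transform()
                pts[mask] = pts[mask] @ t.A.T + t.o
        anatomy.append(PointCloud(pts, prev.labels.copy(), frame_id=f"T{k}"))

    noise = tuple(float(v) for v in np.asarray(noise, dtype=np.float64))
    scans: List[PointCloud] = []
    poses: List[RigidTransform] = []
    for k, cloud in enumerate(anatomy):
        if global_perturbation and k > 0:
            pose = _random_pose(child_rng(seed, "pose", k),
                                perturb_max_deg, perturb_max_mm)
        else:
            pose = RigidTransform.identity()
        poses.append(pose)
        placed = apply_transform(pose, cloud, frame_id=f"T{k}/scanner")
        if any(v > 0 for v in noise):
            placed = add_scanner_noise(
                placed, noise, seed=child_rng(seed, "scan-noise", k)
                .integers(2 ** 31))
        scans.append(placed)

    return SyntheticSeries(scans=scans, specs=list(specs), noise_sigma=noise,
                           seed=seed, layout=layout, global_poses=poses,
                           anatomy=anatomy)
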