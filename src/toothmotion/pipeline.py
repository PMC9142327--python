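"""Analysis configuration, the end-to-end pipeline, and motion reports.

The workflow mirrors how serial casts are analysed clinically:

1. normalise all timepoints into a common frame by registering each scan's
   stable reference structure (e.g. the first molars) onto the first scan;
2. for each tooth and each consecutive timepoint interval, ICP-register
   the tooth's points at Ti onto Ti+1 in the normalised frame, yielding a
   rigid transform per (tooth, interval);
3. decompose each transform into its finite helical axis and report the
   rotation angle, screw translation, axis line and registration quality
   as one row per (tooth, interval).

Reports print angles to 2 decimals and lengths to 3: digits beyond that
are below the scanner's resolution and would be noise.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigError, ToothMotionError
from .geometry import PointCloud
from .helical import helical_axis_from_transform, DEGENERACY_THRESHOLD_DEG
from .io import read_point_cloud
from .registration import icp_register, normalize_series

logger = logging.getLogger("toothmotion.pipeline")

REPORT_COLUMNS = ["tooth", "interval", "theta_deg", "t_mm",
                  "hx", "hy", "hz", "qx", "qy", "qz",
                  "mean_fitting_error_mm", "degenerate", "unreliable"]


@dataclass
class IcpSettings:
    max_iter: int = 100
    tol: float = 1e-6
    trim_fraction: float = 0.0


@dataclass
class AnalysisConfig:
    """Configuration of one serial-scan analysis (JSON-mirrorable)."""

    timepoint_files: List[Tuple[str, str]]  # (timepoint name, path)
    reference_label: str
    tooth_labels: List[str]
    icp: IcpSettings = field(default_factory=IcpSettings)
    degeneracy_threshold: float = DEGENERACY_THRESHOLD_DEG
    axis_point_strategy: str = "minimum_norm"
    seed: int = 0
    report_path: Optional[str] = None
    intervals: Optional[List[Tuple[int, int]]] = None  # None -> consecutive

    def __post_init__(self) -> None:
        if len(self.timepoint_files) < 2:
            raise ConfigError("need at least 2 timepoints")
        if self.reference_label in self.tooth_labels:
            raise ConfigError(
                f"reference label {self.reference_label!r} cannot also be an "
                f"analysed tooth")
        if self.axis_point_strategy not in ("minimum_norm", "fix_coordinate"):
            raise ConfigError(
                f"unknown axis_point_strategy {self.axis_point_strategy!r}")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            doc = json.load(fh)
        icp = IcpSettings(**doc.pop("icp", {}))
        tpf = [tuple(item) for item in doc.pop("timepoint_files")]
        intervals = doc.pop("intervals", None)
        if intervals is not None:
            intervals = [tuple(iv) for iv in intervals]
        return cls(timepoint_files=tpf, icp=icp, intervals=intervals, **doc)

    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


@dataclass
class MotionReportRow:
    """One tooth's motion over one interval: the tabular form of an
    axis-overlay figure."""

    tooth: str
    interval: str
    theta_deg: float
    t_mm: float
    h: Tuple[float, float, float]
    q: Tuple[float, float, float]
    mean_fitting_error_mm: float
    degenerate: bool
    unreliable: bool

    def as_record(self) -> dict:
        def _len3(v):  # undefined axis point (degenerate motion) -> null
            return round(float(v), 3) if np.isfinite(v) else None
        return {
            "tooth": self.tooth,
            "interval": self.interval,
            "theta_deg": round(self.theta_deg, 2),
            "t_mm": round(self.t_mm, 3),
            "hx": round(self.h[0], 6), "hy": round(self.h[1], 6),
            "hz": round(self.h[2], 6),
            "qx": _len3(self.q[0]), "qy": _len3(self.q[1]),
            "qz": _len3(self.q[2]),
            "mean_fitting_error_mm": round(self.mean_fitting_error_mm, 3),
            "degenerate": self.degenerate,
            "unreliable": self.unreliable,
        }


def write_motion_report(rows: Sequence[MotionReportRow], path,
                        fmt: Optional[str] = None) -> None:
    """Write rows as CSV (fixed column order) or JSON (array of objects)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "csv"
    fmt = fmt.lower()
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_COLUMNS)
            writer.writeheader()
            for row in rows:
                writer.writerow(row.as_record())
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump([row.as_record() for row in rows], fh, indent=2)
    else:
        raise ValueError(f"unsupported report format {fmt!r} (csv or json)")


def read_motion_report(path) -> List[dict]:
    """Read back a CSV or JSON motion report as a list of records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)
    with open(path, newline="") as fh:
        out = []
        for rec in csv.DictReader(fh):
            for k in ("theta_deg", "t_mm", "hx", "hy", "hz",
                      "qx", "qy", "qz", "mean_fitting_error_mm"):
                rec[k] = float(rec[k]) if rec[k] not in ("", None) else None
            for k in ("degenerate", "unreliable"):
                rec[k] = rec[k] == "True"
            out.append(rec)
        return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: AnalysisConfig,
                 scans: Optional[Sequence[PointCloud]] = None,
                 return_details: bool = False):
    """Run the full serial-scan analysis.

    ``scans`` may be supplied in-memory (same order as
    ``config.timepoint_files``); otherwise the configured files are read.
    Returns the list of MotionReportRow, ordered by interval then by the
    configured tooth order; with ``return_details=True`` also returns the
    normalizing transforms per timepoint.
    """
    names = [name for name, _ in config.timepoint_files]
    if scans is None:
        scans = [read_point_cloud(path) for _, path in config.timepoint_files]
    if len(scans) != len(names):
        raise ConfigError(f"{len(scans)} scans for {len(names)} timepoints")

    try:
        normalized = normalize_series(
            scans, config.reference_label,
            max_iter=config.icp.max_iter, tol=config.icp.tol,
            trim_fraction=config.icp.trim_fraction)
    except ToothMotionError as exc:
        raise type(exc)(f"series normalization failed: {exc}") from exc

    norm_scans = [cloud for cloud, _ in normalized]
    norm_transforms = [t for _, t in normalized]

    intervals = config.intervals or [(i, i + 1) for i in range(len(names) - 1)]
    rows: List[MotionReportRow] = []
    for i, j in intervals:
        for tooth in config.tooth_labels:
            try:
                sub_i = norm_scans[i].select(tooth)
                sub_j = norm_scans[j].select(tooth)
                if len(sub_i) == 0 or len(sub_j) == 0:
                    raise ConfigError(f"no points labelled {tooth!r}")
                res = icp_register(sub_i, sub_j,
                                   max_iter=config.icp.max_iter,
                                   tol=config.icp.tol,
                                   trim_fraction=config.icp.trim_fraction)
                axis = helical_axis_from_transform(
                    res.transform,
                    degeneracy_threshold_deg=config.degeneracy_threshold,
                    axis_point_strategy=config.axis_point_strategy)
            except ToothMotionError as exc:
                raise type(exc)(
                    f"interval {names[i]}->{names[j]}, tooth {tooth!r}: "
                    f"{exc}") from exc
            logger.info("%s %s->%s: theta=%.2f deg t=%.3f mm err=%.4g mm",
                        tooth, names[i], names[j], axis.theta, axis.t,
                        res.mean_fitting_error)
            rows.append(MotionReportRow(
                tooth=tooth, interval=f"{names[i]}->{names[j]}",
                theta_deg=axis.theta, t_mm=axis.t,
                h=tuple(axis.h), q=tuple(axis.q),
                mean_fitting_error_mm=res.mean_fitting_error,
                degenerate=axis.degenerate, unreliable=axis.unreliable))

    if return_details:
        return rows, norm_transforms
    return rows
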