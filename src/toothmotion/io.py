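"""Point-cloud file I/O: PLY (ascii / binary little-endian), OBJ, XYZ.

Coordinates are always millimetres.  Structure labels travel with the
points where the format allows:

* XYZ — plain text ``x y z [label]`` per line.
* PLY — per-vertex ``uchar label`` property holding an integer code, with
  the code->name map stored as ``comment label <code> <name>`` header
  lines.  Reading goes through trimesh (which handles both ascii and
  binary and tolerates extra properties); the label map is recovered from
  the header, which is ascii in either mode.
* OBJ — ``v`` records only; faces are ignored, labels unsupported.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

from .errors import PointCloudFormatError
from .geometry import PointCloud

logger = logging.getLogger("toothmotion.io")

_FORMATS = ("ply", "obj", "xyz")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in _FORMATS:
        raise PointCloudFormatError(
            f"unsupported point-cloud format {fmt!r} for {path} "
            f"(supported: {_FORMATS})")
    return fmt


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_point_cloud(path, fmt: Optional[str] = None) -> PointCloud:
    """Read a point cloud from PLY, OBJ or XYZ.

    Labels are recovered from an XYZ label column or a PLY ``label``
    vertex property; OBJ carries no labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "obj":
        return _read_obj(path)
    return _read_ply(path)


def _read_xyz(path: Path) -> PointCloud:
    points, labels = [], []
    any_label = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise PointCloudFormatError(
                    f"{path}:{lineno}: expected 'x y z [label]', got "
                    f"{len(parts)} fields")
            try:
                points.append([float(v) for v in parts[:3]])
            except ValueError as exc:
                raise PointCloudFormatError(
                    f"{path}:{lineno}: non-numeric coordinate ({exc})") from exc
            if len(parts) == 4:
                labels.append(parts[3])
                any_label = True
            else:
                labels.append("")
    if not points:
        raise PointCloudFormatError(f"{path}: no points")
    return PointCloud(np.asarray(points),
                      np.asarray(labels) if any_label else None,
                      frame_id=path.stem)


def _read_obj(path: Path) -> PointCloud:
    try:
        loaded = trimesh.load(str(path), file_type="obj", process=False)
    except Exception as exc:
        raise PointCloudFormatError(f"{path}: OBJ parse failed: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    if verts.size == 0:
        raise PointCloudFormatError(f"{path}: no vertices")
    return PointCloud(verts, frame_id=path.stem)


def _ply_header_label_map(path: Path) -> dict:
    """Parse ``comment label <code> <name>`` lines from a PLY header
    (ascii in both storage modes)."""
    mapping = {}
    with open(path, "rb") as fh:
        for raw in fh:
            try:
                line = raw.decode("ascii", errors="replace").strip()
            except Exception:  # pragma: no cover
                break
            if line == "end_header":
                break
            parts = line.split()
            if len(parts) == 4 and parts[0] == "comment" and parts[1] == "label":
                mapping[int(parts[2])] = parts[3]
    return mapping


def _read_ply(path: Path) -> PointCloud:
    try:
        loaded = trimesh.load(str(path), file_type="ply", process=False)
    except Exception as exc:
        raise PointCloudFormatError(f"{path}: PLY parse failed: {exc}") from exc
    verts = np.asarray(loaded.vertices, dtype=np.float64)
    if verts.size == 0:
        raise PointCloudFormatError(f"{path}: no vertices")
    labels = None
    raw = loaded.metadata.get("_ply_raw", {}).get("vertex", {})
    data = raw.get("data", {})
    # trimesh exposes ascii vertices as a dict of arrays and binary
    # vertices as one structured array
    if isinstance(data, np.ndarray) and data.dtype.names:
        fields = list(data.dtype.names)
        get = lambda k: np.asarray(data[k]).reshape(-1)  # noqa: E731
    elif isinstance(data, dict):
        fields = list(data)
        get = lambda k: np.asarray(data[k]).reshape(-1)  # noqa: E731
    else:
        fields, get = [], None
    if "label" in fields:
        codes = get("label")
        name_map = _ply_header_label_map(path)
        labels = np.asarray([name_map.get(int(c), str(int(c))) for c in codes])
    extra = [k for k in fields if k not in ("x", "y", "z", "label")]
    if extra:
        logger.warning("%s: ignoring unsupported PLY vertex properties %s",
                       path, extra)
    return PointCloud(verts, labels, frame_id=path.stem)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_point_cloud(cloud: PointCloud, path, fmt: Optional[str] = None,
                      binary: bool = True) -> None:
    """Write a point cloud to PLY (binary little-endian by default, or
    ascii), OBJ (vertices, labels dropped) or XYZ text."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "obj":
        _write_obj(cloud, path)
    else:
        _write_ply(cloud, path, binary=binary)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(cloud.points):
            line = f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
            if cloud.labels is not None:
                line += f" {cloud.labels[i]}"
            fh.write(line + "\n")


def _write_obj(cloud: PointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        for p in cloud.points:
            fh.write(f"v {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")


def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    has_labels = cloud.labels is not None
    if has_labels:
        names = sorted(set(str(l) for l in cloud.labels))
        if len(names) > 255:
            raise PointCloudFormatError(
                f"PLY label property supports at most 255 distinct labels, "
                f"got {len(names)}")
        code_of = {name: i for i, name in enumerate(names)}
        codes = np.asarray([code_of[str(l)] for l in cloud.labels],
                           dtype=np.uint8)

    header = ["ply",
              "format binary_little_endian 1.0" if binary
              else "format ascii 1.0"]
    if has_labels:
        header += [f"comment label {i} {name}" for i, name in enumerate(names)]
    header += [f"element vertex {len(cloud)}",
               "property double x", "property double y", "property double z"]
    if has_labels:
        header.append("property uchar label")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            if has_labels:
                rec = np.empty(len(cloud), dtype=np.dtype(
                    [("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                     ("label", "u1")]))
                rec["x"], rec["y"], rec["z"] = cloud.points.T
                rec["label"] = codes
            else:
                rec = np.ascontiguousarray(cloud.points, dtype="<f8")
            fh.write(rec.tobytes())
        else:
            lines = []
            for i, p in enumerate(cloud.points):
                line = f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}"
                if has_labels:
                    line += f" {codes[i]}"
                lines.append(line)
            fh.write(("\n".join(lines) + "\n").encode("ascii"))
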