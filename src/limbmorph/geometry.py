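"""Core geometric data types and file I/O.

Everything is expressed in millimetres. Meshes are triangle soups with
shared vertex indexing (0-based); anatomy (muscle paths + bony landmarks)
is serialised as a small JSON schema, point clouds as XYZ text or PLY.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh

__all__ = [
    "TriMesh",
    "PointCloud",
    "LandmarkSet",
    "MusclePath",
    "MuscleModel",
    "ROLES",
    "read_mesh",
    "write_mesh",
    "read_anatomy",
    "write_anatomy",
    "read_point_cloud",
    "write_point_cloud",
    "sample_surface_points",
    "extract_end_regions",
]

ROLES = ("origin", "insertion", "via")

_MESH_FORMATS = ("ply", "stl", "obj")


def _as_finite_array(values, shape_tail: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != shape_tail:
        raise ValueError(f"{name} must be an (N, {shape_tail}) array, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains NaN/Inf coordinates")
    return arr


@dataclass(frozen=True)
class TriMesh:
    """Triangulated surface: ``vertices`` (V, 3) mm and ``triangles`` (T, 3) indices."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        v = _as_finite_array(self.vertices, 3, "vertices")
        t = np.asarray(self.triangles, dtype=np.int64)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError(f"triangles must be (T, 3), got {t.shape}")
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            raise ValueError("triangle indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of axis-aligned [min; max] corners."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def triangle_areas(self) -> np.ndarray:
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same topology, new vertex positions."""
        return TriMesh(vertices, self.triangles)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.triangles.copy(), process=False
        )


@dataclass(frozen=True)
class PointCloud:
    """Unordered 3D points (mm), optionally with per-point provenance labels."""

    points: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        p = _as_finite_array(self.points, 3, "points")
        object.__setattr__(self, "points", p)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(p):
                raise ValueError("labels must align one-to-one with points")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)


class LandmarkSet(dict):
    """Mapping landmark name -> 3D point (mm); names unique, points finite."""

    def __init__(self, items: Mapping[str, Sequence[float]] | None = None):
        super().__init__()
        if items:
            for name, point in items.items():
                self[name] = point

    def __setitem__(self, name: str, point):
        p = np.asarray(point, dtype=np.float64).reshape(3)
        if not np.isfinite(p).all():
            raise ValueError(f"landmark {name!r} has non-finite coordinates")
        super().__setitem__(str(name), p)

    def as_array(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = list(names) if names is not None else list(self)
        return np.array([self[n] for n in names], dtype=np.float64)

    def common_names(self, other: "LandmarkSet") -> list[str]:
        return [n for n in self if n in other]


@dataclass(frozen=True)
class MusclePath:
    """One muscle (or ligament) polyline with per-point anatomical roles.

    The first point must be the origin, the last the insertion; any points
    between are via (routing) points.
    """

    name: str
    points: np.ndarray
    roles: tuple[str, ...]

    def __post_init__(self):
        p = _as_finite_array(self.points, 3, f"path {self.name!r} points")
        roles = tuple(self.roles)
        if len(p) < 2:
            raise ValueError(f"path {self.name!r} needs >= 2 points")
        if len(roles) != len(p):
            raise ValueError(f"path {self.name!r}: roles must align with points")
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"path {self.name!r}: unknown role {r!r}")
        if roles[0] != "origin" or roles[-1] != "insertion":
            raise ValueError(
                f"path {self.name!r}: endpoints must be origin ... insertion"
            )
        if any(r != "via" for r in roles[1:-1]):
            raise ValueError(f"path {self.name!r}: interior points must be via")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "roles", roles)

    @property
    def n_points(self) -> int:
        return len(self.points)


_SEGMENTS = ("pelvis", "thigh", "shank", "foot", "patella")


@dataclass(frozen=True)
class MuscleModel:
    """All scalable anatomy of one body segment: muscle paths + landmarks."""

    paths: tuple[MusclePath, ...]
    landmarks: LandmarkSet
    segment: str = "thigh"

    def __post_init__(self):
        object.__setattr__(self, "paths", tuple(self.paths))
        if self.segment not in _SEGMENTS:
            raise ValueError(f"unknown segment {self.segment!r}; expected one of {_SEGMENTS}")

    def all_points(self) -> np.ndarray:
        """Every anatomy point (muscle path points then landmarks), (N, 3)."""
        blocks = [p.points for p in self.paths]
        if self.landmarks:
            blocks.append(self.landmarks.as_array())
        if not blocks:
            return np.empty((0, 3))
        return np.vstack(blocks)

    def muscle_points(self) -> np.ndarray:
        if not self.paths:
            return np.empty((0, 3))
        return np.vstack([p.points for p in self.paths])

    def oi_points(self) -> np.ndarray:
        """Origin/insertion points only (attachment sites)."""
        pts = [p.points[[0, -1]] for p in self.paths]
        return np.vstack(pts) if pts else np.empty((0, 3))

    def with_points(self, points: np.ndarray) -> "MuscleModel":
        """Rebuild the model from transformed anatomy points (same layout as all_points)."""
        points = np.asarray(points, dtype=np.float64)
        if len(points) != len(self.all_points()):
            raise ValueError("point count mismatch")
        paths, i = [], 0
        for p in self.paths:
            paths.append(MusclePath(p.name, points[i : i + p.n_points], p.roles))
            i += p.n_points
        lm = LandmarkSet({n: points[i + k] for k, n in enumerate(self.landmarks)})
        return MuscleModel(tuple(paths), lm, self.segment)


# ---------------------------------------------------------------------------
# Mesh I/O


def _detect_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_MESH_FORMATS}")
    return fmt


def read_mesh(path, format: str | None = None) -> TriMesh:
    """Read a PLY/STL/OBJ triangle mesh.

    STL carries no shared vertex indexing, so exact duplicate coordinates
    are merged on load.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    loaded = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if len(faces) == 0:
        raise ValueError(f"{path}: mesh has no triangles")
    if fmt == "stl":
        vertices, inverse = np.unique(vertices, axis=0, return_inverse=True)
        faces = inverse[faces]
    return TriMesh(vertices, faces)


def _write_ply_double(mesh: TriMesh, path: Path, binary: bool = True) -> None:
    # Native writer: trimesh exports PLY vertices as float32, which breaks
    # double-precision round-trips.
    n_v, n_t = mesh.n_vertices, mesh.n_triangles
    fmt_line = "binary_little_endian" if binary else "ascii"
    header = (
        f"ply\nformat {fmt_line} 1.0\n"
        f"element vertex {n_v}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {n_t}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(mesh.vertices.astype("<f8").tobytes())
            tri = mesh.triangles.astype("<i4")
            packed = bytearray()
            for row in tri:
                packed += struct.pack("<B3i", 3, *row)
            fh.write(bytes(packed))
        else:
            for v in mesh.vertices:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n".encode("ascii"))
            for t in mesh.triangles:
                fh.write(f"3 {t[0]} {t[1]} {t[2]}\n".encode("ascii"))


def write_mesh(mesh: TriMesh, path, format: str | None = None, binary: bool = True) -> None:
    """Write a mesh; PLY preserves vertex coordinates at double precision."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if mesh.n_triangles == 0:
        raise ValueError("refusing to write a mesh with no triangles")
    if fmt == "ply":
        _write_ply_double(mesh, path, binary=binary)
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)


# ---------------------------------------------------------------------------
# Anatomy JSON
#
# Schema: {"segment": str,
#          "landmarks": {name: [x, y, z]},
#          "paths": [{"name": str, "points": [[x,y,z], ...],
#                     "roles": ["origin", "via", ..., "insertion"]}]}


def read_anatomy(path) -> MuscleModel:
    with open(path) as fh:
        data = json.load(fh)
    try:
        segment = data["segment"]
        landmarks = LandmarkSet(data["landmarks"])
        paths = tuple(
            MusclePath(p["name"], np.asarray(p["points"], dtype=np.float64), tuple(p["roles"]))
            for p in data["paths"]
        )
    except KeyError as exc:
        raise ValueError(f"anatomy file {path}: missing key {exc}") from exc
    if len({p["name"] for p in data["paths"]}) != len(data["paths"]):
        raise ValueError(f"anatomy file {path}: duplicate path names")
    return MuscleModel(paths, landmarks, segment)


def write_anatomy(model: MuscleModel, path) -> None:
    """Write anatomy JSON; output is byte-deterministic for identical input."""
    data = {
        "segment": model.segment,
        "landmarks": {n: [float(x) for x in model.landmarks[n]] for n in sorted(model.landmarks)},
        "paths": [
            {
                "name": p.name,
                "points": [[float(x) for x in row] for row in p.points],
                "roles": list(p.roles),
            }
            for p in model.paths
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Point clouds


def read_point_cloud(path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        loaded = trimesh.load(str(path), process=False)
        return PointCloud(np.asarray(loaded.vertices, dtype=np.float64))
    pts = np.loadtxt(path, dtype=np.float64, ndmin=2)
    return PointCloud(pts)


def write_point_cloud(cloud: PointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        trimesh.PointCloud(cloud.points).export(str(path))
    else:
        np.savetxt(path, cloud.points, fmt="%.17g")


# ---------------------------------------------------------------------------
# Surface sampling


def sample_surface_points(mesh: TriMesh, n: int, seed: int | None = None) -> PointCloud:
    """Draw ``n`` points area-uniformly from the surface (seed-deterministic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mesh.area() <= 0:
        raise ValueError("mesh has zero surface area")
    points, _ = trimesh.sample.sample_surface(mesh.to_trimesh(), n, seed=seed)
    return PointCloud(np.asarray(points, dtype=np.float64))


def principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant principal axis of the point covariance, deterministically signed."""
    points = np.asarray(points, dtype=np.float64)
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    # deterministic sign: largest-|component| entry is positive
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def extract_end_regions(data, fraction: float = 0.2, axis: np.ndarray | None = None) -> PointCloud:
    """Keep only points in the proximal and distal ``fraction`` of the axial extent.

    Emulates reconstruction from partial imaging that covers only the joint
    regions of a long bone. The longitudinal axis defaults to the dominant
    principal axis of the points.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    points = data.points if isinstance(data, PointCloud) else np.asarray(
        getattr(data, "vertices", data), dtype=np.float64
    )
    if len(points) == 0:
        raise ValueError("empty input")
    ax = principal_axis(points) if axis is None else np.asarray(axis, float) / np.linalg.norm(axis)
    coord = points @ ax
    lo, hi = coord.min(), coord.max()
    if hi == lo:
        return PointCloud(points)
    s = (coord - lo) / (hi - lo)
    keep = (s <= fraction) | (s >= 1.0 - fraction)
    return PointCloud(points[keep])
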