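"""Mesh and landmark file I/O.

OBJ is the primary interchange format and is parsed in-package so that
malformed files yield line-numbered :class:`~morphodist.errors.MeshFormatError`
rather than crashes; texture/normal references in face records are ignored
and on-disk 1-based indices are converted to 0-based. PLY (ascii + binary,
with 8-bit RGB vertex colors) and STL (ascii + binary) go through trimesh
with vertex order preserved; STL vertices are welded on exact coordinate
match, since facet soup formats triplicate them.

Landmark files are plain text, one landmark per line:
``label, x, y, z`` (comma- or whitespace-separated). Pairing between two
files is by line order.
"""
from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import LandmarkError, MeshFormatError, MeshIOError
from .mesh import LandmarkSet, PointCloud, TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "read_mesh",
    "write_mesh",
    "mesh_to_cloud",
    "read_landmarks",
    "write_landmarks",
]

_FORMATS = ("obj", "ply", "stl")


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format {fmt!r} (supported: {_FORMATS})")
    return fmt


def _parse_obj(text: str, name: str) -> TriangleMesh:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        tag = parts[0]
        if tag == "v":
            if len(parts) < 4:
                raise MeshFormatError(f"{name}:{lineno}: vertex record needs 3 coordinates")
            try:
                vertices.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"{name}:{lineno}: non-numeric vertex coordinate") from exc
        elif tag == "f":
            if len(parts) < 4:
                raise MeshFormatError(f"{name}:{lineno}: face record needs >=3 indices")
            idx = []
            for p in parts[1:]:
                head = p.split("/")[0]  # drop texture/normal refs
                try:
                    i = int(head)
                except ValueError as exc:
                    raise MeshFormatError(f"{name}:{lineno}: non-integer face index {p!r}") from exc
                if i < 0:  # OBJ negative = relative to current vertex count
                    i = len(vertices) + 1 + i
                if not (1 <= i <= len(vertices)):
                    raise MeshFormatError(
                        f"{name}:{lineno}: face index {p!r} outside valid range "
                        f"1..{len(vertices)}"
                    )
                idx.append(i - 1)
            # polygon faces fan-triangulated from the first corner
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
        # vt/vn/usemtl/o/g/s/mtllib records carry no geometry we keep
    if not vertices:
        raise MeshFormatError(f"{name}: no vertices found (empty or non-OBJ file)")
    return TriangleMesh(np.array(vertices), np.array(faces).reshape(-1, 3))


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a triangle mesh from OBJ, PLY or STL (format inferred from extension).

    Vertex order is preserved for OBJ and PLY; STL reads weld exactly
    coincident vertices (facet formats store each corner per-triangle).
    """
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"mesh file not found: {path}")
    if fmt == "obj":
        try:
            text = path.read_text()
        except OSError as exc:
            raise MeshIOError(f"cannot read {path}: {exc}") from exc
        return _parse_obj(text, path.name)
    try:
        tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except OSError as exc:
        raise MeshIOError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # trimesh raises a zoo of parse errors
        raise MeshFormatError(f"{path.name}: failed to parse as {fmt}: {exc}") from exc
    if tm.vertices is None or len(tm.vertices) == 0:
        raise MeshFormatError(f"{path.name}: empty mesh")
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64).reshape(-1, 3)
    colors = None
    if fmt == "ply" and tm.visual is not None and tm.visual.kind == "vertex":
        vc = np.asarray(tm.visual.vertex_colors)
        if len(vc) == len(vertices):
            colors = vc[:, :3].astype(np.uint8)
    if fmt == "stl":
        vertices, faces, n_before = _weld_exact(vertices, faces)
        if n_before != len(vertices):
            logger.info(
                "STL read: welded %d duplicate vertices (%d -> %d)",
                n_before - len(vertices), n_before, len(vertices),
            )
    return TriangleMesh(vertices, faces, colors=colors)


def _weld_exact(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly coincident vertices, keeping first-occurrence order."""
    n_before = len(vertices)
    uniq, first, inverse = np.unique(
        vertices, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)  # restore file order of first occurrences
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    return uniq[order], rank[inverse][faces], n_before


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh to OBJ, PLY or STL.

    OBJ uses 9 significant digits and 1-based indices. Per-vertex colors are
    written only for PLY (8-bit RGB); other formats log a warning and write
    geometry only.
    """
    fmt = _infer_format(path, fmt)
    path = Path(path)
    if fmt == "obj":
        if mesh.colors is not None:
            logger.warning("OBJ cannot store vertex colors; writing geometry only")
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        return
    kwargs = {}
    if mesh.colors is not None:
        if fmt == "ply":
            kwargs["vertex_colors"] = mesh.colors
        else:
            logger.warning("%s cannot store vertex colors; writing geometry only", fmt.upper())
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False, **kwargs)
    try:
        tm.export(str(path), file_type=fmt)
    except OSError as exc:
        raise MeshIOError(f"cannot write {path}: {exc}") from exc


def mesh_to_cloud(mesh: TriangleMesh) -> PointCloud:
    """The mesh's vertices as a point cloud, order and count preserved.

    This is the cloud a comparison operates on: point density follows scan
    resolution, and trimming a mesh shrinks the cloud accordingly.
    """
    return PointCloud(mesh.vertices.copy())


def read_landmarks(path, epsilon: float = 1e-8) -> LandmarkSet:
    """Read an ordered landmark set from a plain-text file.

    Each line: ``label, x, y, z`` or ``label x y z``; a line of three bare
    numbers is accepted and auto-labelled. At least 3 landmarks required.
    """
    path = Path(path)
    if not path.is_file():
        raise MeshIOError(f"landmark file not found: {path}")
    labels: list[str] = []
    pts: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) == 3:
            label, coords = f"lm{len(pts)}", parts
        elif len(parts) >= 4:
            label, coords = parts[0], parts[-3:]
        else:
            raise LandmarkError(f"{path.name}:{lineno}: expected 'label x y z'")
        try:
            pts.append([float(c) for c in coords])
        except ValueError as exc:
            raise LandmarkError(
                f"{path.name}:{lineno}: non-numeric coordinate in {line!r}"
            ) from exc
        labels.append(label)
    if len(pts) < 3:
        raise LandmarkError(
            f"{path.name}: at least 3 landmarks required, found {len(pts)}"
        )
    return LandmarkSet(np.array(pts), labels, epsilon=epsilon)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write a landmark set as ``label, x, y, z`` lines (row order preserved)."""
    with open(path, "w") as fh:
        for label, p in zip(landmarks.labels, landmarks.points):
            fh.write(f"{label}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
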