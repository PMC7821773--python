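"""Core geometric containers: triangle meshes, point clouds, landmark sets.

Coordinates are in model units (typically millimetres for CT-derived
surfaces) and stored at full double precision. Face indices are 0-based
internally regardless of on-disk convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import LandmarkError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["TriangleMesh", "PointCloud", "LandmarkSet"]


def _as_coords(arr, name: str) -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim != 2 or out.shape[1] != 3:
        raise ValidationError(f"{name} must be an (n, 3) array, got shape {out.shape}")
    if not np.isfinite(out).all():
        raise ValidationError(f"{name} contains non-finite coordinates")
    return out


@dataclass
class TriangleMesh:
    """A triangulated surface: vertices, faces, optional per-vertex attributes.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in model units.
    faces : (m, 3) int array
        Vertex-index triples, 0-based. Faces referencing a vertex twice
        (degenerate) are dropped with a logged count; out-of-range indices
        are an error.
    scalar : (n,) float array, optional
        Per-vertex scalar field (e.g. a distance field).
    colors : (n, 3) uint8 array, optional
        Per-vertex RGB colors.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar: np.ndarray | None = None
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = _as_coords(self.vertices, "vertices")
        faces = np.asarray(self.faces)
        if faces.size == 0:
            faces = np.zeros((0, 3), dtype=np.int64)
        faces = faces.astype(np.int64, copy=False)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValidationError(f"faces must be an (m, 3) array, got shape {faces.shape}")
        n = len(self.vertices)
        if faces.size and (faces.min() < 0 or faces.max() >= n):
            bad = int(np.flatnonzero((faces < 0).any(axis=1) | (faces >= n).any(axis=1))[0])
            raise ValidationError(
                f"face {bad} references vertex outside [0, {n}): {faces[bad].tolist()}"
            )
        degen = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        if degen.any():
            logger.warning("dropping %d degenerate face(s)", int(degen.sum()))
            faces = faces[~degen]
        self.faces = faces
        for attr in ("scalar", "colors"):
            val = getattr(self, attr)
            if val is None:
                continue
            val = np.asarray(val)
            if len(val) != n:
                raise ValidationError(
                    f"{attr} has {len(val)} entries for {n} vertices"
                )
            setattr(self, attr, val)
        if self.colors is not None:
            self.colors = np.clip(np.asarray(self.colors), 0, 255).astype(np.uint8)
            if self.colors.ndim != 2 or self.colors.shape[1] != 3:
                raise ValidationError("colors must be an (n, 3) RGB array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates as an (m, 3, 3) array."""
        return self.vertices[self.faces]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (k, 2) index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        """V - E + F of the connectivity (2 for a closed sphere-topology shell)."""
        return self.n_vertices - len(self.edges()) + self.n_faces

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals (zero vector for stranded vertices)."""
        tri = self.triangles()
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        nz = norm[:, 0] > 0
        vn[nz] /= norm[nz]
        return vn

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.scalar is None else np.array(self.scalar),
            None if self.colors is None else np.array(self.colors),
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity and attributes with replaced coordinates."""
        out = self.copy()
        out.vertices = _as_coords(vertices, "vertices")
        if len(out.vertices) != self.n_vertices:
            raise ValidationError("replacement vertices must keep the vertex count")
        return out


@dataclass
class PointCloud:
    """An unordered set of 3D points (model units)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = _as_coords(self.points, "points")

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "PointCloud":
        return PointCloud(self.points.copy())


@dataclass
class LandmarkSet:
    """An ordered set of >=3 homologous landmarks; pairing is by position.

    Labels are documentation only (e.g. ``"flexor_tubercle"``); two sets
    picked on homologous regions of different specimens are paired row by
    row, mirroring the order in which an operator places points.
    """

    points: np.ndarray
    labels: list[str] = field(default_factory=list)
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        self.points = _as_coords(self.points, "landmarks")
        n = len(self.points)
        if n < 3:
            raise LandmarkError(f"at least 3 landmarks required, got {n}")
        if not self.labels:
            self.labels = [f"lm{i}" for i in range(n)]
        if len(self.labels) != n:
            raise LandmarkError(f"{len(self.labels)} labels for {n} landmarks")
        d = np.linalg.norm(self.points[:, None] - self.points[None, :], axis=-1)
        d[np.diag_indices(n)] = np.inf
        if (d < self.epsilon).any():
            i, j = np.unravel_index(int(np.argmin(d)), d.shape)
            raise LandmarkError(
                f"landmarks {i} ({self.labels[i]!r}) and {j} ({self.labels[j]!r}) "
                f"coincide within epsilon={self.epsilon}"
            )

    def __len__(self) -> int:
        return len(self.points)
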