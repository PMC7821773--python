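"""Mesh editing prior to comparison: trimming artefacts, matching resolution.

Fractured surfaces, preparation damage and excavation artefacts are removed
by vertex masks (programmatic stand-ins for interactive lasso selection),
and higher-resolution scans are decimated down to the polygon count of the
lower-resolution partner. Upsampling is refused: interpolated detail would
misrepresent the scan.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mesh import TriangleMesh

logger = logging.getLogger(__name__)

__all__ = [
    "trim",
    "select_by_sphere",
    "select_by_plane",
    "decimate",
    "match_resolution",
    "DecimationReport",
]


def _check_mask(mesh: TriangleMesh, mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool).reshape(-1)
    if len(m) != mesh.n_vertices:
        raise ValidationError(
            f"mask length {len(m)} != vertex count {mesh.n_vertices}"
        )
    return m


def trim(mesh: TriangleMesh, keep_mask) -> TriangleMesh:
    """Delete vertices where the mask is False, keeping faces whose three
    corners all survive.

    Surviving vertices keep their coordinates and relative order (compact
    re-indexing); the result may be an open shell. Raises if nothing
    survives.
    """
    m = _check_mask(mesh, keep_mask)
    if not m.any():
        raise ValidationError("trim would remove every vertex")
    new_index = np.full(mesh.n_vertices, -1, dtype=np.int64)
    new_index[m] = np.arange(int(m.sum()))
    face_keep = m[mesh.faces].all(axis=1)
    faces = new_index[mesh.faces[face_keep]]
    return TriangleMesh(
        mesh.vertices[m],
        faces,
        None if mesh.scalar is None else np.asarray(mesh.scalar)[m],
        None if mesh.colors is None else np.asarray(mesh.colors)[m],
    )


def select_by_sphere(
    mesh: TriangleMesh, center, radius: float, mode: str = "keep-outside"
) -> np.ndarray:
    """Boolean keep-mask selecting vertices by distance to a sphere center.

    ``keep-outside`` (default) flags for removal everything inside — the
    typical way to cut out a roughly spherical excavation artefact. Points
    exactly on the boundary count as inside.
    """
    if not radius > 0:
        raise ValidationError("radius must be positive")
    if mode not in ("keep-inside", "keep-outside"):
        raise ValidationError(f"mode must be keep-inside|keep-outside, got {mode!r}")
    d = np.linalg.norm(mesh.vertices - np.asarray(center, dtype=float), axis=1)
    inside = d <= radius
    return inside if mode == "keep-inside" else ~inside


def select_by_plane(mesh: TriangleMesh, point, normal) -> np.ndarray:
    """Keep-mask for vertices on the non-normal side of a plane
    (signed distance <= 0); used for planar cuts of fractured regions."""
    n = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(n)
    if nn == 0:
        raise ValidationError("plane normal must be nonzero")
    signed = (mesh.vertices - np.asarray(point, dtype=float)) @ (n / nn)
    return signed <= 0


@dataclass
class DecimationReport:
    """Bookkeeping for a decimation run."""

    input_vertices: int
    output_vertices: int
    collapses: int
    fidelity_bound: float  # max distance of any removed vertex to the new surface
    skipped: bool = False


def _face_quadric(a, b, c):
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm == 0:
        return np.zeros((4, 4))
    n = n / norm
    p = np.append(n, -n @ a)  # plane [nx, ny, nz, d]
    return np.outer(p, p)


def decimate(
    mesh: TriangleMesh,
    target_vertex_count: int,
    return_report: bool = False,
):
    """Reduce vertex count by iterative quadric-error edge collapse.

    Each collapse merges one edge into the position minimising the summed
    plane-distance quadric of both endpoints, so the cheapest (flattest)
    regions simplify first. Collapses that would flip a face normal are
    rejected. One collapse removes exactly one vertex, so the output lands
    on the target exactly unless the mesh runs out of valid edges first.
    The report carries a fidelity bound: the maximum distance from any
    removed vertex position to the decimated surface.
    """
    from .distance_field import c2m  # local import; distance_field imports mesh only

    nv = mesh.n_vertices
    if target_vertex_count == nv:
        logger.info("decimate: target equals current vertex count; skipped")
        out = mesh.copy()
        rep = DecimationReport(nv, nv, 0, 0.0, skipped=True)
        return (out, rep) if return_report else out
    if not (3 <= target_vertex_count < nv):
        raise ValidationError(
            f"target_vertex_count must be in [3, {nv}), got {target_vertex_count}"
        )

    V = mesh.vertices.copy()
    alive = np.ones(nv, dtype=bool)
    Q = np.zeros((nv, 4, 4))
    faces = {i: tuple(f) for i, f in enumerate(mesh.faces.tolist())}
    vertex_faces: list[set] = [set() for _ in range(nv)]
    for fi, (a, b, c) in faces.items():
        K = _face_quadric(V[a], V[b], V[c])
        for v in (a, b, c):
            Q[v] += K
            vertex_faces[v].add(fi)
    neighbors: list[set] = [set() for _ in range(nv)]
    for a, b, c in faces.values():
        neighbors[a] |= {b, c}
        neighbors[b] |= {a, c}
        neighbors[c] |= {a, b}

    version = np.zeros(nv, dtype=np.int64)

    def edge_cost(u, v):
        Quv = Q[u] + Q[v]
        A = Quv[:3, :3]
        bvec = -Quv[:3, 3]
        try:
            pos = np.linalg.solve(A, bvec)
            if not np.isfinite(pos).all():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            pos = 0.5 * (V[u] + V[v])
        h = np.append(pos, 1.0)
        return float(h @ Quv @ h), pos

    heap: list = []
    push_count = 0

    def push_edge(u, v):
        nonlocal push_count
        a, b = (u, v) if u < v else (v, u)
        cost, pos = edge_cost(a, b)
        # tuple order (cost, a, b) gives deterministic lowest-index tie-breaking;
        # the counter guarantees ties never reach the position array
        push_count += 1
        heapq.heappush(
            heap, (cost, a, b, int(version[a]), int(version[b]), push_count, pos)
        )

    seen = set()
    for a, b, c in faces.values():
        for u, v in ((a, b), (b, c), (a, c)):
            key = (u, v) if u < v else (v, u)
            if key not in seen:
                seen.add(key)
                push_edge(u, v)
    del seen

    def collapse_ok(u, v, pos):
        """Reject collapses that flip the normal of a surviving face."""
        for fi in vertex_faces[u] | vertex_faces[v]:
            f = faces.get(fi)
            if f is None or (u in f and v in f):
                continue  # face dies in the collapse
            pts_old = [V[w] for w in f]
            pts_new = [pos if w in (u, v) else V[w] for w in f]
            n_old = np.cross(pts_old[1] - pts_old[0], pts_old[2] - pts_old[0])
            n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
            if n_old @ n_new <= 0:
                return False
        return True

    removed_positions = []
    n_alive = nv
    collapses = 0
    while n_alive > target_vertex_count and heap:
        cost, u, v, vu, vv, _, pos = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or version[u] != vu or version[v] != vv:
            continue
        if v not in neighbors[u]:
            continue
        if not collapse_ok(u, v, pos):
            continue
        # collapse u into v at the optimal position
        removed_positions.append(V[u].copy())
        V[v] = pos
        Q[v] = Q[u] + Q[v]
        alive[u] = False
        n_alive -= 1
        collapses += 1
        dead_faces = [fi for fi in vertex_faces[u] if fi in vertex_faces[v]]
        for fi in dead_faces:
            f = faces.pop(fi, None)
            if f is None:
                continue
            for w in f:
                vertex_faces[w].discard(fi)
        for fi in list(vertex_faces[u]):
            f = faces.get(fi)
            if f is None:
                vertex_faces[u].discard(fi)
                continue
            newf = tuple(v if w == u else w for w in f)
            if len(set(newf)) < 3:
                faces.pop(fi)
                for w in f:
                    vertex_faces[w].discard(fi)
                continue
            faces[fi] = newf
            vertex_faces[u].discard(fi)
            vertex_faces[v].add(fi)
        for w in neighbors[u]:
            neighbors[w].discard(u)
            if w != v:
                neighbors[w].add(v)
                neighbors[v].add(w)
        neighbors[v].discard(v)
        neighbors[u] = set()
        # only edges incident to v change cost (its position and quadric moved)
        version[v] += 1
        for w in neighbors[v]:
            push_edge(v, w)

    if n_alive > target_vertex_count:
        logger.warning(
            "decimate: ran out of valid collapses at %d vertices (target %d)",
            n_alive, target_vertex_count,
        )

    new_index = np.full(nv, -1, dtype=np.int64)
    new_index[alive] = np.arange(int(alive.sum()))
    out_faces = np.array(
        [[new_index[w] for w in f] for f in faces.values()], dtype=np.int64
    ).reshape(-1, 3)
    out = TriangleMesh(V[alive], out_faces)

    fidelity = 0.0
    if removed_positions and out.n_faces > 0:
        from .mesh import PointCloud

        dfield = c2m(PointCloud(np.array(removed_positions)), out)
        fidelity = float(dfield.distances.max())
    rep = DecimationReport(nv, out.n_vertices, collapses, fidelity)
    logger.info(
        "decimate: %d -> %d vertices (%d collapses, fidelity bound %.4g)",
        nv, out.n_vertices, collapses, fidelity,
    )
    return (out, rep) if return_report else out


def match_resolution(high: TriangleMesh, low: TriangleMesh) -> TriangleMesh:
    """Decimate the higher-resolution mesh to the vertex count of the lower.

    Refuses to upsample: if ``high`` does not have more vertices than
    ``low``, an error is raised rather than subdividing, because invented
    surface detail degrades the comparison.
    """
    if high.n_vertices <= low.n_vertices:
        raise ValidationError(
            f"match_resolution: 'high' has {high.n_vertices} vertices, not more than "
            f"'low' ({low.n_vertices}); upsampling is not supported"
        )
    return decimate(high, low.n_vertices)
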