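"""Synthetic fragmentary specimens with known ground truth.

Real comparisons pair a fragmentary target ungual against more complete
reference unguals; scan data cannot ship with a library, so this module
generates stand-ins: a curved, tapered claw-like shell with lateral blood
grooves and a bulbous ventral flexor tubercle, which can then be degraded
the way real fossils are — distal end missing, a roughly spherical
excavation artefact punched out, surface noise — and displaced by a known
similarity transform so registration accuracy is checkable exactly.

Everything is deterministic for a fixed seed; differing seeds change the
noise realisation but never the topology.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .mesh import LandmarkSet, TriangleMesh
from .mesh_edit import trim
from .registration import SimilarityTransform

__all__ = [
    "ClawParams",
    "DegradationSpec",
    "DegradationReport",
    "make_claw",
    "degrade",
    "plant_transform",
    "make_landmark_pair",
    "axial_fraction",
    "default_landmark_indices",
]


@dataclass
class ClawParams:
    """Shape parameters of the synthetic ungual (model units ~ mm).

    The claw axis is a circular arc of the given ``length`` sweeping
    ``curvature`` radians; cross-section rings shrink distally as
    ``(1-u)**taper_exponent`` of the arc-length fraction ``u``. Grooves
    indent both lateral sides along the mid-section; the tubercle inflates
    the ventral surface near the proximal end.
    """

    length: float = 30.0
    curvature: float = 1.6
    proximal_radius: float = 6.0
    taper_exponent: float = 1.5
    groove_depth: float = 0.15
    tubercle_bulge: float = 0.25
    n_rings: int = 24
    n_theta: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.proximal_radius <= 0:
            raise ValidationError("length and proximal_radius must be positive")
        if self.curvature <= 0:
            raise ValidationError("curvature must be positive")
        if self.n_rings < 8 or self.n_theta < 8:
            raise ValidationError("resolutions must be >= 8")
        if not (0 <= self.groove_depth < 1 and 0 <= self.tubercle_bulge < 1):
            raise ValidationError("groove/tubercle fractions must be in [0, 1)")


@dataclass
class DegradationSpec:
    """How to break the specimen.

    Defaults emulate a heavily fragmentary target: the whole distal third
    gone, a small spherical excavation artefact near the proximal
    extremity, and mild scanner noise along vertex normals.
    """

    distal_fraction_removed: float = 0.35
    hole_center: float | None = 0.1  # axial fraction; None = no hole
    hole_radius: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.distal_fraction_removed < 1:
            raise ValidationError("distal_fraction_removed must be in [0, 1)")
        if self.hole_center is not None and not 0 <= self.hole_center < 1:
            raise ValidationError("hole_center must be in [0, 1)")
        if self.hole_radius < 0 or self.noise_sd < 0:
            raise ValidationError("hole_radius and noise_sd must be >= 0")


@dataclass
class DegradationReport:
    removed_distal: int
    removed_hole: int
    kept: int


def _arc_frames(params: ClawParams, u: np.ndarray):
    """Axis points, in-plane normals and lateral binormals at arc fractions u."""
    R = params.length / params.curvature
    phi = u * params.curvature
    axis = np.stack([R * np.sin(phi), np.zeros_like(phi), R * (1 - np.cos(phi))], axis=-1)
    normal = np.stack([-np.sin(phi), np.zeros_like(phi), np.cos(phi)], axis=-1)
    binormal = np.broadcast_to(np.array([0.0, 1.0, 0.0]), normal.shape)
    return axis, normal, binormal


def _ring_radius(params: ClawParams, u: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Cross-section radius with taper, lateral grooves and ventral tubercle."""
    base = params.proximal_radius * (1.0 - u) ** params.taper_exponent
    # grooves: indentations at theta = +-pi/2 (the two lateral sides),
    # active over the mid-section of the arc
    groove = np.exp(-((theta - np.pi / 2) ** 2) / (2 * 0.35**2)) + np.exp(
        -((theta - 3 * np.pi / 2) ** 2) / (2 * 0.35**2)
    )
    axial_window = np.exp(-((u - 0.5) ** 2) / (2 * 0.25**2))
    mod = 1.0 - params.groove_depth * groove * axial_window
    # tubercle: ventral (theta = pi) bulge near the proximal end
    tub = np.exp(-((theta - np.pi) ** 2) / (2 * 0.7**2)) * np.exp(
        -((u - 0.15) ** 2) / (2 * 0.12**2)
    )
    mod = mod * (1.0 + params.tubercle_bulge * tub)
    return base * mod


def make_claw(params: ClawParams | None = None) -> TriangleMesh:
    """Generate a closed, manifold claw-like shell (sphere topology).

    Vertex layout: proximal pole, then ``n_rings`` rings of ``n_theta``
    vertices ordered proximal to distal, then the distal tip pole; the
    construction is fully deterministic for fixed parameters.
    """
    p = params or ClawParams()
    K, n = p.n_rings, p.n_theta
    u = (np.arange(K) + 1.0) / (K + 1.0)  # rings strictly between the poles
    theta = np.arange(n) * (2 * np.pi / n)
    uu, tt = np.meshgrid(u, theta, indexing="ij")
    axis, normal, binormal = _arc_frames(p, uu)
    r = _ring_radius(p, uu, tt)
    ring_pts = axis + r[..., None] * (
        np.cos(tt)[..., None] * normal + np.sin(tt)[..., None] * binormal
    )
    pole_prox, _, _ = _arc_frames(p, np.array([0.0]))
    pole_tip, _, _ = _arc_frames(p, np.array([1.0]))
    vertices = np.vstack([pole_prox, ring_pts.reshape(-1, 3), pole_tip])

    def rid(k: int, j: int) -> int:
        return 1 + k * n + (j % n)

    faces: list[list[int]] = []
    for j in range(n):  # proximal cap fan
        faces.append([0, rid(0, j + 1), rid(0, j)])
    for k in range(K - 1):  # side quads, split into two triangles
        for j in range(n):
            a, b = rid(k, j), rid(k, j + 1)
            c, d = rid(k + 1, j), rid(k + 1, j + 1)
            faces.append([a, b, d])
            faces.append([a, d, c])
    tip = len(vertices) - 1
    for j in range(n):  # distal tip fan
        faces.append([rid(K - 1, j), rid(K - 1, j + 1), tip])
    return TriangleMesh(vertices, np.array(faces))


def axial_fraction(mesh: TriangleMesh, params: ClawParams | None = None) -> np.ndarray:
    """Arc-length fraction u in [0, 1] of each vertex along the claw axis.

    With known generator parameters the exact arc geometry is inverted;
    otherwise the first principal axis of the vertex cloud is used as a
    proxy (adequate for gently curved shapes).
    """
    V = mesh.vertices
    if params is not None:
        R = params.length / params.curvature
        phi = np.arctan2(V[:, 0], R - V[:, 2])
        return np.clip(phi / params.curvature, 0.0, 1.0)
    c = V - V.mean(axis=0)
    _, _, Vt = np.linalg.svd(c, full_matrices=False)
    proj = c @ Vt[0]
    lo, hi = proj.min(), proj.max()
    if hi - lo <= 0:
        raise ValidationError("cannot orient a degenerate vertex cloud")
    return (proj - lo) / (hi - lo)


def degrade(
    mesh: TriangleMesh,
    spec: DegradationSpec | None = None,
    params: ClawParams | None = None,
) -> tuple[TriangleMesh, DegradationReport]:
    """Produce a fragmentary version of a specimen mesh.

    Removes all vertices distal of the cut plane and inside the excavation
    ball (faces reindexed, boundary left open), then perturbs survivors
    along their vertex normals with Gaussian noise of the given sd. Passing
    the generator ``params`` makes the cut exactly perpendicular to the arc
    axis; otherwise a principal-axis proxy is used.
    """
    s = spec or DegradationSpec()
    u = axial_fraction(mesh, params)
    keep = np.ones(mesh.n_vertices, dtype=bool)
    distal_mask = u > 1.0 - s.distal_fraction_removed if s.distal_fraction_removed > 0 else np.zeros_like(keep)
    keep &= ~distal_mask
    removed_hole = 0
    if s.hole_center is not None and s.hole_radius > 0:
        # center the excavation ball on the ventral surface vertex nearest
        # the requested axial fraction
        normals = mesh.vertex_normals()
        ventral = normals[:, 2] < 0 if params is not None else np.ones_like(keep)
        cand = np.where(keep & ventral)[0]
        if cand.size == 0:
            cand = np.where(keep)[0]
        center_idx = cand[np.argmin(np.abs(u[cand] - s.hole_center))]
        d = np.linalg.norm(mesh.vertices - mesh.vertices[center_idx], axis=1)
        hole_mask = keep & (d <= s.hole_radius)
        removed_hole = int(hole_mask.sum())
        keep &= ~hole_mask
    if int(keep.sum()) < 3:
        raise ValidationError("degradation would remove (almost) every vertex")
    out = trim(mesh, keep)
    if s.noise_sd > 0:
        rng = np.random.default_rng(s.seed)
        normals = out.vertex_normals()
        out = out.with_vertices(
            out.vertices + s.noise_sd * rng.standard_normal(out.n_vertices)[:, None] * normals
        )
    report = DegradationReport(
        removed_distal=int(distal_mask.sum()),
        removed_hole=removed_hole,
        kept=out.n_vertices,
    )
    return out, report


def plant_transform(
    mesh: TriangleMesh,
    scale: float = 1.0,
    rotation=(0.0, 0.0, 0.0),
    translation=(0.0, 0.0, 0.0),
) -> tuple[TriangleMesh, SimilarityTransform]:
    """Apply a known similarity transform x -> s R x + t to a mesh.

    Returns the displaced mesh together with the ground-truth *inverse*
    transform — i.e. exactly what a registration run should recover to map
    the displaced mesh back onto the original.
    """
    if not scale > 0:
        raise ValidationError("scale must be positive")
    R = Rotation.from_euler("xyz", rotation).as_matrix()
    forward = SimilarityTransform(scale, R, np.asarray(translation, dtype=float))
    moved = mesh.with_vertices(forward.apply(mesh.vertices))
    return moved, forward.inverse()


def make_landmark_pair(
    mesh_a: TriangleMesh, mesh_b: TriangleMesh, indices
) -> tuple[LandmarkSet, LandmarkSet]:
    """Homologous landmark sets sampled at the same template vertex indices
    of two meshes derived from a common template."""
    idx = np.asarray(indices, dtype=int)
    if idx.size < 3:
        raise ValidationError("at least 3 landmark indices required")
    for name, m in (("first", mesh_a), ("second", mesh_b)):
        if (idx < 0).any() or (idx >= m.n_vertices).any():
            raise ValidationError(f"landmark index out of range for the {name} mesh")
    labels = [f"lm{i}" for i in idx]
    return (
        LandmarkSet(mesh_a.vertices[idx], list(labels)),
        LandmarkSet(mesh_b.vertices[idx], list(labels)),
    )


def default_landmark_indices(params: ClawParams | None = None, count: int = 4) -> np.ndarray:
    """Well-spread, non-collinear vertex indices on a generated claw:
    proximal pole plus points on rings at staggered angular positions."""
    p = params or ClawParams()
    K, n = p.n_rings, p.n_theta
    picks = [0]
    for i in range(1, count):
        k = (i * K) // count
        j = (i * n) // count
        picks.append(1 + k * n + (j % n))
    return np.array(picks)
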