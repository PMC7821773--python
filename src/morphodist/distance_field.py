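"""Absolute distance fields between a compared cloud and a reference.

Two modes mirror common mesh-comparison practice: cloud-to-cloud (C2C),
the Euclidean distance from each compared point to its nearest reference
vertex, and cloud-to-mesh (C2M), the exact distance to the nearest point
anywhere on the reference surface (face interior, edge or vertex). All
distances are unsigned; the field's maximum is the directed Hausdorff
distance from the compared cloud to the reference. Fields are summarised
by mean (MD), standard deviation (SD), and range — low MD and SD indicate
high shape fidelity between specimens.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .mesh import PointCloud, TriangleMesh
from .mesh_io import mesh_to_cloud
from .registration import (
    ICPResult,
    SimilarityTransform,
    apply_transform,
    icp_align,
    landmark_similarity,
)

__all__ = [
    "DistanceField",
    "FieldSummary",
    "ComparisonResult",
    "c2c",
    "c2m",
    "summarize",
    "histogram",
    "heatmap_colors",
    "compare",
]


@dataclass
class DistanceField:
    """Per-point unsigned distances of a compared cloud against a reference."""

    distances: np.ndarray
    mode: str  # "C2C" | "C2M"
    compared_id: str = "compared"
    reference_id: str = "reference"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64).reshape(-1)
        if self.distances.size == 0:
            raise ValidationError("distance field is empty")
        if not np.isfinite(self.distances).all() or (self.distances < 0).any():
            raise ValidationError("distances must be finite and non-negative")
        if self.mode not in ("C2C", "C2M"):
            raise ValidationError(f"mode must be C2C|C2M, got {self.mode!r}")

    @property
    def n(self) -> int:
        return len(self.distances)


@dataclass
class FieldSummary:
    """Standard statistics of a distance field (SD uses the sample, n-1 form)."""

    mean: float
    sd: float
    min: float
    max: float
    n: int
    sd_is_sample: bool = True

    @property
    def directed_hausdorff(self) -> float:
        """Maximum of the field = directed Hausdorff distance to the reference."""
        return self.max

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "n": self.n,
            "directed_hausdorff": self.max,
        }


def c2c(compared: PointCloud, reference: PointCloud) -> DistanceField:
    """Cloud-to-cloud: exact nearest-reference-vertex distance per point."""
    cp = compared.points if isinstance(compared, PointCloud) else np.asarray(compared, float)
    rp = reference.points if isinstance(reference, PointCloud) else np.asarray(reference, float)
    if len(cp) == 0 or len(rp) == 0:
        raise ValidationError("c2c requires nonempty clouds")
    d, _ = cKDTree(rp).query(cp)
    return DistanceField(d, mode="C2C")


def _point_triangle_sq(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Squared distance from points to paired triangles (all (k, 3) arrays).

    Closest-point classification by barycentric region: face interior,
    the three edges, or the three vertices.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex A region
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    # vertex B region
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    # vertex C region
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    w = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = a[m] + w[m, None] * ab[m]
    done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = a[m] + w[m, None] * ac[m]
    done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    closest[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    # face interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    closest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]

    diff = p - closest
    return np.einsum("ij,ij->i", diff, diff)


def c2m(
    compared: PointCloud, reference: TriangleMesh, chunk_size: int = 128
) -> DistanceField:
    """Cloud-to-mesh: exact minimum distance from each point to any triangle.

    Evaluates every point against every reference triangle in vectorised
    chunks — exact by construction, with no spatial-index approximation.
    """
    pts = compared.points if isinstance(compared, PointCloud) else np.asarray(compared, float)
    if len(pts) == 0:
        raise ValidationError("c2m requires a nonempty cloud")
    if reference.n_faces == 0:
        raise ValidationError("c2m reference mesh has no faces")
    tri = reference.triangles()  # (m, 3, 3)
    m = len(tri)
    out = np.empty(len(pts))
    for start in range(0, len(pts), chunk_size):
        chunk = pts[start : start + chunk_size]
        k = len(chunk)
        P = np.repeat(chunk, m, axis=0)
        A = np.tile(tri[:, 0], (k, 1))
        B = np.tile(tri[:, 1], (k, 1))
        C = np.tile(tri[:, 2], (k, 1))
        sq = _point_triangle_sq(P, A, B, C).reshape(k, m)
        out[start : start + k] = np.sqrt(sq.min(axis=1))
    return DistanceField(out, mode="C2M")


def summarize(field: DistanceField) -> FieldSummary:
    """Mean, sample SD, min, max and count of a distance field."""
    d = field.distances
    sd = float(d.std(ddof=1)) if field.n > 1 else 0.0
    return FieldSummary(
        mean=float(d.mean()), sd=sd, min=float(d.min()), max=float(d.max()), n=field.n
    )


def histogram(field: DistanceField, bin_count: int = 256):
    """Equal-width histogram of the field over [0, max]; counts sum to n,
    with the rightmost bin closed. Returns (edges, counts)."""
    if bin_count < 1:
        raise ValidationError("bin_count must be >= 1")
    top = float(field.distances.max())
    if top <= 0:
        top = 1.0  # all-zero field: everything lands in the first bin
    counts, edges = np.histogram(field.distances, bins=bin_count, range=(0.0, top))
    return edges, counts


# cold (blue) -> green -> yellow -> warm (red), the conventional deviation map
_HEAT_ANCHORS = np.array(
    [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 0.0]]
)


def heatmap_colors(
    field: DistanceField, saturation_max: float | None = None
) -> np.ndarray:
    """Map distances to RGB heat-map colors (uint8, one row per point).

    Zero maps to the cold (blue) end; ``saturation_max`` (default: field
    maximum) and anything beyond maps to the warm (red) end; the mapping is
    piecewise-linear and monotone in between. Attach the result to the
    compared mesh's ``colors`` for PLY export.
    """
    if saturation_max is None:
        saturation_max = float(field.distances.max())
    if saturation_max <= 0:
        saturation_max = 1.0
    t = np.clip(field.distances / saturation_max, 0.0, 1.0)
    pos = t * (len(_HEAT_ANCHORS) - 1)
    i = np.minimum(pos.astype(int), len(_HEAT_ANCHORS) - 2)
    frac = (pos - i)[:, None]
    rgb = _HEAT_ANCHORS[i] * (1 - frac) + _HEAT_ANCHORS[i + 1] * frac
    return np.round(rgb * 255).astype(np.uint8)


@dataclass
class ComparisonResult:
    """Everything a pairwise comparison produces."""

    field: DistanceField
    summary: FieldSummary
    mode: str
    icp_used: bool
    transform: SimilarityTransform
    icp_result: ICPResult | None = None
    pre_icp_summary: FieldSummary | None = None


def compare(
    target: TriangleMesh,
    reference: TriangleMesh,
    mode: str = "C2M",
    icp: bool = True,
    landmarks: tuple | None = None,
    max_iterations: int = 20,
    with_scale: bool = True,
) -> ComparisonResult:
    """Full pairwise comparison: optional landmark first registration,
    optional ICP second registration, then a C2M or C2C distance field.

    ``landmarks`` is a ``(target_landmarks, reference_landmarks)`` pair used
    for the initial similarity fit; without it the meshes are assumed
    pre-aligned (identity initialisation). With ``icp=True`` the summary
    before the fine alignment is also recorded, so the effect of the second
    registration is visible.
    """
    mode = mode.upper()
    if mode not in ("C2M", "C2C"):
        raise ValidationError(f"mode must be C2M or C2C, got {mode!r}")
    if mode == "C2M" and reference.n_faces == 0:
        raise ValidationError("C2M comparison needs a reference with faces")

    if landmarks is not None:
        lm_t, lm_r = landmarks
        T = landmark_similarity(lm_t, lm_r, with_scale=with_scale)
    else:
        T = SimilarityTransform.identity()

    def field_for(transform: SimilarityTransform) -> DistanceField:
        moved = apply_transform(target, transform)
        cloud = mesh_to_cloud(moved)
        if mode == "C2C":
            return c2c(cloud, mesh_to_cloud(reference))
        return c2m(cloud, reference)

    pre_summary = None
    icp_result = None
    if icp:
        pre_summary = summarize(field_for(T))
        icp_result = icp_align(
            mesh_to_cloud(target),
            mesh_to_cloud(reference),
            max_iterations=max_iterations,
            with_scale=with_scale,
            initial=T,
        )
        T = icp_result.transform
    field = field_for(T)
    return ComparisonResult(
        field=field,
        summary=summarize(field),
        mode=mode,
        icp_used=icp,
        transform=T,
        icp_result=icp_result,
        pre_icp_summary=pre_summary,
    )
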