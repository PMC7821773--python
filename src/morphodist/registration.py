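"""Two-stage registration of a target cloud to a reference.

First registration: a closed-form least-squares similarity transform
(scale + rotation + translation, reflection excluded) fitted to >=3 pairs
of homologous landmarks picked on both specimens. Second registration:
point-to-point iterative closest point (ICP) with per-iteration scale
re-estimation, minimising the root-mean-square distance between each
target point and its nearest reference vertex. The RMS trace is recorded
every iteration; under full correspondence retention it is provably
non-increasing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryError, NumericalError, ValidationError
from .mesh import LandmarkSet, PointCloud, TriangleMesh

__all__ = [
    "SimilarityTransform",
    "ICPResult",
    "SweepResult",
    "landmark_similarity",
    "icp_align",
    "iteration_sweep",
    "apply_transform",
]


@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t with R proper orthonormal and scale > 0."""

    scale: float = 1.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.scale = float(self.scale)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not self.scale > 0:
            raise ValidationError(f"scale must be positive, got {self.scale}")
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthonormal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValidationError("rotation determinant is not +1 (reflection?)")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return self.scale * pts @ self.rotation.T + self.translation

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ inner: apply ``inner`` first, then ``self``."""
        return SimilarityTransform(
            self.scale * inner.scale,
            self.rotation @ inner.rotation,
            self.scale * self.rotation @ inner.translation + self.translation,
        )

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            1.0 / self.scale, Rinv, -Rinv @ self.translation / self.scale
        )

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(d["scale"], np.array(d["rotation"]), np.array(d["translation"]))


@dataclass
class ICPResult:
    """Outcome of an ICP run: cumulative transform and convergence trace."""

    transform: SimilarityTransform
    rms_history: np.ndarray
    iterations_run: int
    converged: bool
    n_correspondences: int

    def __post_init__(self) -> None:
        self.rms_history = np.asarray(self.rms_history, dtype=np.float64)
        if self.rms_history.size == 0:
            raise ValidationError("rms_history must be nonempty")

    @property
    def final_rms(self) -> float:
        return float(self.rms_history[-1])


@dataclass
class SweepResult:
    """Final RMS as a function of ICP iteration budget."""

    budgets: np.ndarray
    rms: np.ndarray
    plateau_budget: int | None

    def as_rows(self) -> list[tuple[int, float]]:
        return [(int(b), float(r)) for b, r in zip(self.budgets, self.rms)]


def _coords(obj) -> np.ndarray:
    if isinstance(obj, TriangleMesh):
        return obj.vertices
    if isinstance(obj, (PointCloud, LandmarkSet)):
        return obj.points
    return np.asarray(obj, dtype=np.float64)


def _umeyama(x: np.ndarray, y: np.ndarray, with_scale: bool) -> SimilarityTransform:
    """Closed-form least-squares similarity x -> y via cross-covariance SVD."""
    n = len(x)
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    cov = yc.T @ xc / n
    U, D, Vt = np.linalg.svd(cov)
    S = np.ones(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2] = -1.0  # force a proper rotation, never a reflection
    R = U @ np.diag(S) @ Vt
    if with_scale:
        var_x = (xc**2).sum() / n
        if var_x <= 0:
            raise DegenerateGeometryError("source points are all coincident")
        s = float((D * S).sum() / var_x)
        if not s > 0:
            raise DegenerateGeometryError("estimated scale is non-positive")
    else:
        s = 1.0
    t = my - s * R @ mx
    return SimilarityTransform(s, R, t)


def _check_not_collinear(pts: np.ndarray, what: str) -> None:
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[0] <= 0 or sv[1] < 1e-9 * sv[0]:
        raise DegenerateGeometryError(f"{what} landmarks are collinear or coincident")


def landmark_similarity(
    source: LandmarkSet | np.ndarray,
    destination: LandmarkSet | np.ndarray,
    with_scale: bool = True,
) -> SimilarityTransform:
    """Least-squares similarity (or rigid) transform mapping source landmarks
    onto destination landmarks, paired by row order.

    Minimises sum ||s R x_i + t - y_i||^2 in closed form; with
    ``with_scale=False`` the scale is fixed at exactly 1.
    """
    x, y = _coords(source), _coords(destination)
    if len(x) != len(y):
        raise ValidationError(f"landmark counts differ: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValidationError(f"at least 3 landmark pairs required, got {len(x)}")
    _check_not_collinear(x, "source")
    _check_not_collinear(y, "destination")
    return _umeyama(x, y, with_scale)


def icp_align(
    source: PointCloud | TriangleMesh | np.ndarray,
    reference: PointCloud | TriangleMesh | np.ndarray,
    max_iterations: int = 20,
    with_scale: bool = True,
    rel_rms_tolerance: float = 1e-8,
    initial: SimilarityTransform | None = None,
    keep_fraction: float = 1.0,
) -> ICPResult:
    """Point-to-point ICP of a source cloud onto reference vertices.

    Each iteration (1) pairs every source point with its nearest reference
    vertex (KD-tree, ties to the lowest index), (2) solves the closed-form
    similarity update minimising the mean squared pair distance, and
    (3) re-applies the composed transform, until the relative RMS change
    drops below ``rel_rms_tolerance`` or the iteration budget (default 20)
    is spent. ``keep_fraction`` < 1 retains only the closest fraction of
    pairs in the update (outlier trimming; default keeps all).
    """
    src = _coords(source)
    ref = _coords(reference)
    if len(src) == 0:
        raise ValidationError("source cloud is empty")
    if len(ref) < 3:
        raise ValidationError("reference needs at least 3 points")
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must be in (0, 1]")
    if max_iterations < 1:
        raise ValidationError("max_iterations must be >= 1")
    tree = cKDTree(ref)
    T = initial if initial is not None else SimilarityTransform.identity()
    history: list[float] = []
    converged = False
    n_keep = max(3, int(round(keep_fraction * len(src))))
    iterations = 0
    for _ in range(max_iterations):
        iterations += 1
        cur = T.apply(src)
        d, idx = tree.query(cur)
        if n_keep < len(src):
            sel = np.argsort(d, kind="stable")[:n_keep]
        else:
            sel = slice(None)
        update = _umeyama(cur[sel], ref[idx[sel]], with_scale)
        T = update.compose(T)
        moved = T.apply(src)
        rms = float(np.sqrt(np.mean(np.sum((moved[sel] - ref[idx[sel]]) ** 2, axis=1))))
        if not np.isfinite(rms):
            raise NumericalError("ICP produced a non-finite RMS (degenerate collapse)")
        history.append(rms)
        if len(history) >= 2:
            prev = history[-2]
            # relative above 1 model unit, absolute below (machine-noise floor)
            if abs(prev - rms) <= rel_rms_tolerance * max(prev, 1.0):
                converged = True
                break
    return ICPResult(
        transform=T,
        rms_history=np.array(history),
        iterations_run=iterations,
        converged=converged,
        n_correspondences=n_keep if n_keep < len(src) else len(src),
    )


def iteration_sweep(
    source,
    reference,
    counts=tuple(range(5, 101, 5)),
    with_scale: bool = True,
    rel_rms_tolerance: float = 1e-8,
    initial: SimilarityTransform | None = None,
) -> SweepResult:
    """Final ICP RMS for a range of iteration budgets (default 5..100 step 5).

    Each budget is an independent run from the same initial transform; the
    plateau is the first budget after which the final RMS changes by less
    than ``rel_rms_tolerance`` relative to the previous budget.
    """
    budgets = np.asarray(list(counts), dtype=int)
    if budgets.size == 0 or (budgets < 1).any():
        raise ValidationError("iteration budgets must be positive integers")
    rms = np.empty(len(budgets))
    for i, b in enumerate(budgets):
        # convergence tolerance disabled so each run uses its full budget
        res = icp_align(
            source,
            reference,
            max_iterations=int(b),
            with_scale=with_scale,
            rel_rms_tolerance=0.0,
            initial=initial,
        )
        rms[i] = res.final_rms
    plateau = None
    for i in range(1, len(budgets)):
        # tolerance acts relatively above 1 model unit and absolutely below,
        # so machine-noise jitter around a converged RMS still counts as flat
        if abs(rms[i - 1] - rms[i]) <= rel_rms_tolerance * max(rms[i - 1], 1.0):
            plateau = int(budgets[i])
            break
    return SweepResult(budgets=budgets, rms=rms, plateau_budget=plateau)


def apply_transform(obj, transform: SimilarityTransform):
    """Apply a similarity transform to a mesh, cloud, landmark set or array.

    Connectivity, labels and per-vertex attributes are untouched; only
    coordinates move. Returns the same type as the input.
    """
    if isinstance(obj, TriangleMesh):
        return obj.with_vertices(transform.apply(obj.vertices))
    if isinstance(obj, PointCloud):
        return PointCloud(transform.apply(obj.points))
    if isinstance(obj, LandmarkSet):
        return LandmarkSet(
            transform.apply(obj.points), list(obj.labels), epsilon=obj.epsilon
        )
    return transform.apply(np.asarray(obj, dtype=np.float64))
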