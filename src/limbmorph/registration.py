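"""Rigid alignment and dense correspondence.

Landmark-based alignment is the closed-form least-squares (Kabsch/Umeyama
without scale) solution; surface-based refinement is iterative closest
point (ICP) against the target mesh. Dense correspondence re-expresses a
target surface with a template's topology by FFD-regularised projection,
which is what makes PCA across training surfaces meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .ffd import fit_ffd, apply_ffd
from .geometry import LandmarkSet, PointCloud, TriMesh
from .proximity import MeshProximity

__all__ = [
    "RigidTransform",
    "rigid_from_landmarks",
    "rigid_from_points",
    "icp_rigid",
    "establish_correspondence",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform x -> R x + t (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_json(self) -> str:
        m = np.hstack([self.rotation, self.translation[:, None]])
        return json.dumps({"matrix": m.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        m = np.asarray(json.loads(text)["matrix"], dtype=np.float64).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


def rigid_from_points(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform between corresponded points."""
    src = np.asarray(source, dtype=np.float64)
    tgt = np.asarray(target, dtype=np.float64)
    if src.shape != tgt.shape or len(src) < 3:
        raise ValueError("need >= 3 corresponded point pairs of equal shape")
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, S, Vt = np.linalg.svd(H)
    # rank-deficient (collinear) configurations leave the rotation unconstrained
    if S[1] <= 1e-12 * max(S[0], 1e-300):
        raise ValueError("point configuration is collinear (rank-deficient)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, ct - R @ cs)


def rigid_from_landmarks(source: LandmarkSet, target: LandmarkSet) -> RigidTransform:
    """Rigid transform minimising Σ ||R s + t - d||² over common landmark names."""
    names = source.common_names(target)
    if len(names) < 3:
        raise ValueError(f"need >= 3 common landmarks, found {len(names)}")
    return rigid_from_points(source.as_array(names), target.as_array(names))


def icp_rigid(
    source: PointCloud,
    target: TriMesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> RigidTransform:
    """Surface-based rigid refinement by iterative closest point.

    Alternates closest-point-on-surface correspondence with the closed-form
    rigid update; the mean residual is monotone non-increasing. The final
    per-iteration mean residuals are attached as ``residuals`` (mm).
    """
    if len(source) == 0:
        raise ValueError("empty source cloud")
    prox = MeshProximity(target)
    T = RigidTransform.identity() if init is None else init
    residuals: list[float] = []
    pts = source.points
    for _ in range(max_iter):
        moved = T.apply(pts)
        foot, dist, _ = prox.query(moved)
        res = float(np.sqrt(np.mean(dist**2)))
        if not np.isfinite(res):
            raise ValueError("non-finite ICP residual")
        if residuals and abs(residuals[-1] - res) < tol:
            residuals.append(res)
            break
        residuals.append(res)
        T = rigid_from_points(pts, foot)
    T = RigidTransform(T.rotation, T.translation)
    object.__setattr__(T, "residuals", tuple(residuals))
    return T


def establish_correspondence(
    template: TriMesh,
    target: TriMesh,
    lattice_spacing: float = 20.0,
    levels: int = 2,
    iterations_per_level: int = 3,
    bending_weight: float = 1e-3,
) -> TriMesh:
    """Re-express ``target`` with the template's topology.

    Template vertices are iteratively projected onto the target surface and
    the motion is regularised by a coarse-to-fine B-spline FFD (spacing
    halved per level), so vertex i of the output corresponds anatomically to
    template vertex i while lying on the target surface. Both meshes must be
    rigidly pre-aligned.
    """
    prox = MeshProximity(target)
    verts = template.vertices
    _, d0, _ = prox.query(verts)
    diag = np.linalg.norm(template.bounds()[1] - template.bounds()[0])
    if np.median(d0) > diag / 2:
        raise ValueError("surfaces do not overlap (median projection distance too large)")
    current = verts.copy()
    spacings = [lattice_spacing * 2 ** (levels - 1 - k) for k in range(levels)]
    for spacing in spacings:
        for _ in range(iterations_per_level):
            foot, _, _ = prox.query(current)
            lattice = fit_ffd(verts, foot, spacing=spacing, bending_weight=bending_weight)
            current = apply_ffd(lattice, verts)
    # final snap onto the target surface
    foot, _, _ = prox.query(current)
    return TriMesh(foot, template.triangles.copy())
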