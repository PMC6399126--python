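"""Reconstruct a full bone surface by fitting the SSM to a sparse point cloud.

Given a (possibly partial) cloud of surface points, the fit alternates:

1. correspond every cloud point to its closest point on the currently
   synthesised surface (expressed barycentrically, so the corresponded
   model point is linear in the mode weights);
2. solve the regularised linear least-squares problem

       min_b  Σ_j ||p_j - y_j(b)||²  +  α Σ_i b_i²/λ_i

   whose penalty is the squared Mahalanobis norm of the weights;
3. optionally re-align the cloud rigidly to the current surface.

Weights are clamped to ±3σ (|b_i| <= 3 sqrt(λ_i)) so that partial clouds
cannot drive the model to implausible shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .geometry import PointCloud, TriMesh
from .proximity import MeshProximity
from .registration import RigidTransform, rigid_from_points
from .shape_model import ShapeModel, synthesize

__all__ = ["FitResult", "fit_to_point_cloud"]


@dataclass(frozen=True)
class FitResult:
    """Outcome of an SSM fit: mode weights, synthesised surface and diagnostics."""

    weights: np.ndarray
    surface: TriMesh
    rigid: RigidTransform
    residual_rmse: float
    iterations: int
    objectives: tuple[float, ...] = field(default=())


def _barycentric_matrix(mesh: TriMesh, prox: MeshProximity, points: np.ndarray) -> sp.csr_matrix:
    """Sparse (n_pts, V) matrix B with B @ vertices = closest surface points."""
    foot, _, tri_idx = prox.query(points)
    tri = mesh.triangles[tri_idx]
    a = mesh.vertices[tri[:, 0]]
    b = mesh.vertices[tri[:, 1]]
    c = mesh.vertices[tri[:, 2]]
    v0, v1, v2 = b - a, c - a, foot - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom > 0, (d11 * d20 - d01 * d21) / denom, 1 / 3)
        w = np.where(denom > 0, (d00 * d21 - d01 * d20) / denom, 1 / 3)
    u = 1.0 - v - w
    n = len(points)
    rows = np.repeat(np.arange(n), 3)
    cols = tri.ravel()
    vals = np.column_stack([u, v, w]).ravel()
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, mesh.n_vertices))


def fit_to_point_cloud(
    model: ShapeModel,
    cloud: PointCloud,
    n_modes: int | None = None,
    alpha: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    init: RigidTransform | None = None,
    rigid_realign: bool = False,
    sigma_clamp: float = 3.0,
    bootstrap: bool = True,
) -> FitResult:
    """Fit mode weights (and optionally a rigid pose) to a point cloud.

    Parameters
    ----------
    n_modes : number of leading PMVs used (default: all available).
    alpha : fixed Mahalanobis penalty weight. By default the weight starts
        at 0.1 * (mean squared cloud-to-surface distance) / n_modes and is
        re-evaluated from the current misfit each iteration, never
        increasing: strong regularisation while the pose/shape is far off,
        vanishing bias as the fit converges.
    rigid_realign : interleave a rigid re-alignment of the cloud with the
        weight updates (useful when the cloud is only coarsely registered).
    bootstrap : start from a correspondence computed after normalising the
        cloud to the mean shape's bounding box, so gross size differences
        are captured in the first solve instead of creeping in over many
        closest-point rounds.
    """
    if len(cloud) == 0:
        raise ValueError("empty point cloud")
    M = model.n_modes
    n_modes = M if n_modes is None else int(n_modes)
    if not 1 <= n_modes <= M:
        raise ValueError(f"n_modes must be in [1, {M}]")
    lam = model.eigenvalues[:n_modes]
    modes = model.modes[:, :n_modes]
    mode_fields = modes.reshape(model.mean.n_vertices, 3, n_modes)

    rigid = RigidTransform.identity() if init is None else init
    pts = rigid.apply(cloud.points)
    adaptive = alpha is None
    alpha_cur = np.inf if adaptive else float(alpha)

    b = np.zeros(n_modes)
    clamp = sigma_clamp * np.sqrt(lam)
    objectives: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        surface = synthesize(model, b)
        prox = MeshProximity(surface)
        if rigid_realign:
            foot, _, _ = prox.query(pts, exact=False)
            rigid_step = rigid_from_points(pts, foot)
            rigid = rigid_step.compose(rigid)
            pts = rigid_step.apply(pts)

        # correspondence: cloud points -> closest point on the current surface
        if it == 1 and bootstrap and not b.any():
            # normalise per-axis extents so length/width mismatch does not
            # trap the ends; correspondences still live on the current surface
            mb = surface.bounds()
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            scale = np.where(hi - lo > 1e-9, (mb[1] - mb[0]) / np.maximum(hi - lo, 1e-9), 1.0)
            probe = (pts - (lo + hi) / 2) * scale + (mb[0] + mb[1]) / 2
        else:
            probe = pts
        _, dist, _ = prox.query(pts, exact=False)
        B = _barycentric_matrix(surface, prox, probe)
        base = B @ model.mean.vertices  # (n, 3)
        Ablocks = [B @ mode_fields[:, d, :] for d in range(3)]
        Amat = np.vstack(Ablocks)
        rhs = np.concatenate([pts[:, d] - base[:, d] for d in range(3)])

        if adaptive:
            alpha_cur = min(alpha_cur, 0.1 * float(np.mean(dist**2)) / n_modes)

        H = Amat.T @ Amat + alpha_cur * np.diag(1.0 / lam)
        b_new = np.linalg.solve(H, Amat.T @ rhs)
        b_new = np.clip(b_new, -clamp, clamp)

        resid = rhs - Amat @ b_new
        obj = float(resid @ resid + alpha_cur * np.sum(b_new**2 / lam))
        if not np.isfinite(obj):
            raise ValueError("divergent (non-finite) fit residual")
        objectives.append(obj)
        delta = float(np.max(np.abs(b_new - b) / np.sqrt(lam)))
        b = b_new
        if delta < tol:
            break

    surface = synthesize(model, b)
    prox = MeshProximity(surface)
    _, dist, _ = prox.query(pts)
    rmse = float(np.sqrt(np.mean(dist**2)))
    return FitResult(b, surface, rigid, rmse, it, tuple(objectives))
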