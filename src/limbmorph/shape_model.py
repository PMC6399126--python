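"""Statistical shape model (point distribution model) of corresponded surfaces.

The model is the classic Cootes-style SSM: training surfaces in dense
correspondence are rigidly aligned to their evolving mean (generalised
Procrustes, no scaling — size stays in the modes), then the principal modes
of variation (PMVs) of the stacked vertex coordinates are extracted by PCA.
Because the number of training shapes n is far smaller than the number of
coordinates 3V, the eigen-decomposition uses the n x n Gram matrix.

A shape is synthesised as  mean + Σ_i b_i · PMV_i ; the Mahalanobis norm
sqrt(Σ b_i²/λ_i) measures how plausible a weight vector is relative to the
training population.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import TriMesh
from .registration import rigid_from_points

__all__ = [
    "ShapeModel",
    "build_ssm",
    "synthesize",
    "compactness",
    "mahalanobis_norm",
    "mirror_mesh",
    "save_ssm",
    "load_ssm",
]


@dataclass(frozen=True)
class ShapeModel:
    """mean shape, orthonormal mode matrix (3V, M), eigenvalues λ (mm², descending)."""

    mean: TriMesh
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_training: int

    def __post_init__(self):
        modes = np.asarray(self.modes, dtype=np.float64)
        ev = np.asarray(self.eigenvalues, dtype=np.float64)
        if modes.ndim != 2 or modes.shape[0] != 3 * self.mean.n_vertices:
            raise ValueError("modes must be (3V, M)")
        if modes.shape[1] != len(ev):
            raise ValueError("one eigenvalue per mode required")
        if (ev < 0).any() or (np.diff(ev) > 1e-12 * max(ev[0] if len(ev) else 0, 1)).any():
            raise ValueError("eigenvalues must be non-negative and sorted descending")
        object.__setattr__(self, "modes", modes)
        object.__setattr__(self, "eigenvalues", ev)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def project(self, mesh: TriMesh) -> np.ndarray:
        """Mode weights of a corresponded (and aligned) shape."""
        if mesh.n_vertices != self.mean.n_vertices:
            raise ValueError("vertex count mismatch")
        dev = (mesh.vertices - self.mean.vertices).ravel()
        return self.modes.T @ dev


def mirror_mesh(mesh: TriMesh, axis: int = 0) -> TriMesh:
    """Mirror across the plane normal to ``axis`` (default x, i.e. left/right),
    flipping triangle winding so outward normals are preserved."""
    v = mesh.vertices.copy()
    v[:, axis] *= -1
    t = mesh.triangles[:, [0, 2, 1]].copy()
    return TriMesh(v, t)


def _procrustes_align(stacks: np.ndarray, tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Generalised rigid (no-scale) alignment of (n, V, 3) shapes to their mean."""
    shapes = stacks.copy()
    mean = shapes.mean(axis=0)
    for _ in range(max_iter):
        for i in range(len(shapes)):
            T = rigid_from_points(shapes[i], mean)
            shapes[i] = T.apply(shapes[i])
        new_mean = shapes.mean(axis=0)
        move = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if move < tol:
            break
    return shapes


def build_ssm(training: list[TriMesh], align: bool = True, mode_tol: float = 1e-10) -> ShapeModel:
    """Build an SSM from corresponded training meshes.

    align=True runs generalised rigid alignment first (the normal case);
    set it to False for populations that are already pose-normalised, e.g.
    synthetic shapes generated about a common frame. Modes with
    λ_i <= mode_tol · λ_1 are dropped.
    """
    if len(training) < 2:
        raise ValueError("need >= 2 training shapes")
    ref = training[0]
    for m in training[1:]:
        if m.n_vertices != ref.n_vertices or not np.array_equal(m.triangles, ref.triangles):
            raise ValueError("training meshes must share identical topology")
    stacks = np.stack([m.vertices for m in training])
    if align:
        stacks = _procrustes_align(stacks)
    mean_v = stacks.mean(axis=0)
    X = (stacks - mean_v).reshape(len(training), -1)  # (n, 3V)
    n = len(training)
    G = (X @ X.T) / (n - 1)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    lam1 = evals[0] if evals[0] > 0 else 1.0
    keep = evals > mode_tol * lam1
    keep[min(n - 1, len(keep)) :] = False  # at most n-1 meaningful modes
    evals, evecs = evals[keep], evecs[:, keep]
    modes = X.T @ evecs  # (3V, M), columns ∝ eigenvectors of covariance
    norms = np.linalg.norm(modes, axis=0)
    modes /= norms
    return ShapeModel(TriMesh(mean_v, ref.triangles.copy()), modes, evals, n)


def synthesize(model: ShapeModel, weights: np.ndarray) -> TriMesh:
    """mean + Σ_i weights_i · PMV_i, reshaped to a surface."""
    w = np.asarray(weights, dtype=np.float64).ravel()
    if len(w) > model.n_modes:
        raise ValueError(f"got {len(w)} weights for a {model.n_modes}-mode model")
    if not np.isfinite(w).all():
        raise ValueError("non-finite weights")
    dev = model.modes[:, : len(w)] @ w
    verts = model.mean.vertices + dev.reshape(-1, 3)
    return TriMesh(verts, model.mean.triangles.copy())


def compactness(model: ShapeModel, k: int) -> float:
    """Cumulative fraction of total shape variance captured by the first k modes."""
    if not 0 <= k <= model.n_modes:
        raise ValueError(f"k must be in [0, {model.n_modes}]")
    total = model.eigenvalues.sum()
    if total == 0:
        return 1.0 if k == model.n_modes else 0.0
    return float(model.eigenvalues[:k].sum() / total)


def mahalanobis_norm(model: ShapeModel, weights: np.ndarray) -> float:
    """sqrt(Σ b_i² / λ_i): the shape-plausibility norm used in reconstruction."""
    w = np.asarray(weights, dtype=np.float64).ravel()
    if len(w) > model.n_modes:
        raise ValueError("weight vector longer than the number of modes")
    lam = model.eigenvalues[: len(w)]
    if (lam <= 0).any():
        raise ValueError("zero eigenvalue among referenced modes")
    return float(np.sqrt(np.sum(w**2 / lam)))


def save_ssm(model: ShapeModel, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mean_vertices", data=model.mean.vertices)
        fh.create_dataset("triangles", data=model.mean.triangles)
        fh.create_dataset("modes", data=model.modes)
        fh.create_dataset("eigenvalues", data=model.eigenvalues)
        fh.attrs["n_training"] = model.n_training


def load_ssm(path) -> ShapeModel:
    with h5py.File(path, "r") as fh:
        return ShapeModel(
            TriMesh(fh["mean_vertices"][...], fh["triangles"][...]),
            fh["modes"][...],
            fh["eigenvalues"][...],
            int(fh.attrs["n_training"]),
        )
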