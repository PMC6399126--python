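"""Cubic B-spline free-form deformation (FFD).

A regular lattice of control points carries 3D *displacement* coefficients;
a point is moved by the tensor-product cubic B-spline blend of its 4x4x4
neighbouring control displacements. Zero coefficients therefore give the
identity map, and cubic B-splines reproduce affine fields exactly inside
the lattice (linear precision).

The lattice is fitted to corresponded point pairs by linear least squares
with a discrete bending-energy (second-difference) regulariser, the
standard formulation for landmark-driven B-spline registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import factorized

__all__ = ["FFDLattice", "fit_ffd", "apply_ffd", "save_ffd", "load_ffd"]


def bspline_basis(s: np.ndarray) -> np.ndarray:
    """The four uniform cubic B-spline basis values at local offset s in [0, 1).

    Returns shape (len(s), 4); rows sum to exactly 1 (partition of unity).
    """
    s = np.asarray(s, dtype=np.float64)
    s2 = s * s
    s3 = s2 * s
    b0 = (1 - s) ** 3 / 6.0
    b1 = (3 * s3 - 6 * s2 + 4) / 6.0
    b2 = (-3 * s3 + 3 * s2 + 3 * s + 1) / 6.0
    b3 = s3 / 6.0
    return np.stack([b0, b1, b2, b3], axis=-1)


@dataclass
class FFDLattice:
    """Regular control-point grid of B-spline displacement coefficients.

    origin : position of control point (0,0,0), mm
    spacing : node spacing per axis, mm (the study default is 20 mm)
    grid_shape : control-point counts per axis
    coefficients : (nx, ny, nz, 3) displacement vectors, mm
    """

    origin: np.ndarray
    spacing: np.ndarray
    grid_shape: tuple[int, int, int]
    coefficients: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be positive")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("need at least 4 control points per axis (cubic support)")
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64).reshape(
            *self.grid_shape, 3
        )

    @property
    def n_controls(self) -> int:
        return int(np.prod(self.grid_shape))

    @classmethod
    def for_domain(cls, lo, hi, spacing) -> "FFDLattice":
        """Zero lattice whose valid support covers [lo, hi] with a full 4^3
        basis neighbourhood (one node below, two above the box per axis)."""
        lo = np.asarray(lo, dtype=np.float64)
        hi = np.asarray(hi, dtype=np.float64)
        spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
        origin = lo - spacing
        n = np.ceil((hi - origin) / spacing - 1e-9).astype(int) + 3
        n = np.maximum(n, 4)
        return cls(origin, spacing, tuple(n), np.zeros((*n, 3)))

    def _local(self, points: np.ndarray):
        """Cell index (base control = cell-1) and fractional offset per point."""
        u = (points - self.origin) / self.spacing
        n = np.array(self.grid_shape)
        lo_ok = u >= 1.0 - 1e-9
        hi_ok = u <= (n - 2) + 1e-9
        bad = ~(lo_ok & hi_ok).all(axis=1)
        if bad.any():
            idx = np.flatnonzero(bad)
            raise ValueError(
                f"{len(idx)} point(s) outside the FFD lattice support "
                f"(first offending index {idx[0]})"
            )
        cell = np.clip(np.floor(u).astype(int), 1, n - 3)
        return cell, u - cell

    def weights(self, points: np.ndarray):
        """Sparse basis rows: (flat control indices (N, 64), weights (N, 64))."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        cell, s = self._local(points)
        bx = bspline_basis(s[:, 0])
        by = bspline_basis(s[:, 1])
        bz = bspline_basis(s[:, 2])
        w = (bx[:, :, None, None] * by[:, None, :, None] * bz[:, None, None, :]).reshape(-1, 64)
        offs = np.arange(-1, 3)
        gx = cell[:, 0, None] + offs
        gy = cell[:, 1, None] + offs
        gz = cell[:, 2, None] + offs
        nx, ny, nz = self.grid_shape
        flat = (
            (gx[:, :, None, None] * ny + gy[:, None, :, None]) * nz + gz[:, None, None, :]
        ).reshape(-1, 64)
        return flat, w

    def design_matrix(self, points: np.ndarray) -> sp.csr_matrix:
        flat, w = self.weights(points)
        n = len(w)
        rows = np.repeat(np.arange(n), 64)
        return sp.csr_matrix((w.ravel(), (rows, flat.ravel())), shape=(n, self.n_controls))


def apply_ffd(lattice: FFDLattice, points: np.ndarray) -> np.ndarray:
    """Displace points by the lattice's B-spline field. Points must lie
    inside the lattice support (no extrapolation)."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    flat, w = lattice.weights(points)
    coef = lattice.coefficients.reshape(-1, 3)
    disp = np.einsum("nk,nkd->nd", w, coef[flat])
    return points + disp


def _bending_operator(grid_shape) -> sp.csr_matrix:
    """Sum over axes of squared second differences of lattice coefficients."""
    eyes = [sp.identity(n, format="csr") for n in grid_shape]
    K = None
    for ax, n in enumerate(grid_shape):
        if n < 3:
            continue
        data = np.tile([1.0, -2.0, 1.0], (n - 2, 1))
        D = sp.diags(
            [data[:, 0], data[:, 1], data[:, 2]], [0, 1, 2], shape=(n - 2, n)
        ).tocsr()
        mats = [eyes[0], eyes[1], eyes[2]]
        mats[ax] = D
        Dfull = sp.kron(sp.kron(mats[0], mats[1]), mats[2]).tocsr()
        term = (Dfull.T @ Dfull).tocsr()
        K = term if K is None else K + term
    return K


def fit_ffd(
    source_points: np.ndarray,
    target_points: np.ndarray,
    spacing: float | np.ndarray = 20.0,
    bending_weight: float = 1e-3,
    support_points: np.ndarray | None = None,
) -> FFDLattice:
    """Least-squares fit of control displacements mapping source -> target.

    ``support_points`` extends the lattice domain beyond the source points
    (e.g. muscle path and landmark positions that must be transformable
    later); the lattice covers the union bounding box padded by one cell.
    Residual fit RMSE is stored on the returned lattice as ``residual_rmse``.
    """
    src = np.atleast_2d(np.asarray(source_points, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target_points, dtype=np.float64))
    if src.shape != tgt.shape:
        raise ValueError("source and target point lists must have equal shape")
    if len(src) == 0:
        raise ValueError("need at least one point pair")
    domain = src if support_points is None else np.vstack([src, np.atleast_2d(support_points)])
    lattice = FFDLattice.for_domain(domain.min(axis=0), domain.max(axis=0), spacing)

    W = lattice.design_matrix(src)
    disp = tgt - src
    A = (W.T @ W).tocsc()
    if bending_weight > 0:
        A = (A + bending_weight * _bending_operator(lattice.grid_shape)).tocsc()
    else:
        # keep unconstrained controls solvable with a vanishing ridge
        A = (A + 1e-12 * sp.identity(lattice.n_controls)).tocsc()
    solve = factorized(A)
    rhs = W.T @ disp
    coef = np.column_stack([solve(rhs[:, d]) for d in range(3)])
    lattice.coefficients = coef.reshape(*lattice.grid_shape, 3)
    fitted = apply_ffd(lattice, src)
    lattice.residual_rmse = float(np.sqrt(np.mean(np.sum((fitted - tgt) ** 2, axis=1))))
    return lattice


def save_ffd(lattice: FFDLattice, target, group: str = "ffd") -> None:
    """Persist a lattice into an HDF5 file (or open h5py Group)."""
    own = isinstance(target, (str, bytes)) or hasattr(target, "__fspath__")
    fh = h5py.File(target, "a") if own else target
    try:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("origin", data=lattice.origin)
        g.create_dataset("spacing", data=lattice.spacing)
        g.create_dataset("grid_shape", data=np.array(lattice.grid_shape))
        g.create_dataset("coefficients", data=lattice.coefficients)
    finally:
        if own:
            fh.close()


def load_ffd(target, group: str = "ffd") -> FFDLattice:
    own = isinstance(target, (str, bytes)) or hasattr(target, "__fspath__")
    fh = h5py.File(target, "r") if own else target
    try:
        g = fh[group]
        return FFDLattice(
            g["origin"][...],
            g["spacing"][...],
            tuple(int(x) for x in g["grid_shape"][...]),
            g["coefficients"][...],
        )
    finally:
        if own:
            fh.close()
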