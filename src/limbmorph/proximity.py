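"""Exact closest-point queries against a triangle mesh.

Candidate triangles come from a k-d tree over triangle centroids; the true
nearest triangle's centroid lies within (upper bound + max circumradius) of
the query point, so a ball query with that radius makes the search exact.
Ties are broken toward the lowest triangle index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriMesh

__all__ = ["MeshProximity", "closest_point_on_mesh"]


def _point_triangle_closest(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest points on triangles (a, b, c) to points p, all (N, 3). Vectorised
    version of the standard region-classification algorithm."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1 / 3)
        w = np.where(denom != 0, vc / denom, 1 / 3)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class MeshProximity:
    """Reusable closest-point structure for one mesh."""

    def __init__(self, mesh: TriMesh):
        if mesh.n_triangles == 0:
            raise ValueError("mesh has no triangles")
        self.mesh = mesh
        tri = mesh.triangles
        self._corners = tuple(mesh.vertices[tri[:, k]] for k in range(3))
        a, b, c = self._corners
        self._centroids = (a + b + c) / 3.0
        self._max_reach = float(
            np.max(
                np.maximum.reduce(
                    [
                        np.linalg.norm(a - self._centroids, axis=1),
                        np.linalg.norm(b - self._centroids, axis=1),
                        np.linalg.norm(c - self._centroids, axis=1),
                    ]
                )
            )
        )
        self._tree = cKDTree(self._centroids)

    def _exact_over(self, points, cand_idx):
        """Min distance over candidate triangle indices per point (object arrays ok)."""
        a, b, c = self._corners
        best_d = np.full(len(points), np.inf)
        best_q = np.zeros((len(points), 3))
        best_t = np.zeros(len(points), dtype=np.int64)
        for i, (p, idx) in enumerate(zip(points, cand_idx)):
            idx = np.sort(np.asarray(idx, dtype=np.int64))
            pp = np.broadcast_to(p, (len(idx), 3))
            q = _point_triangle_closest(pp, a[idx], b[idx], c[idx])
            d = np.linalg.norm(q - pp, axis=1)
            j = int(np.argmin(d))  # first minimum -> lowest triangle index
            best_d[i], best_q[i], best_t[i] = d[j], q[j], idx[j]
        return best_q, best_d, best_t

    def query(self, points: np.ndarray, exact: bool = True):
        """Return (closest_points, distances, triangle_indices) for each query point.

        With ``exact=False`` only the k nearest candidate triangles are
        checked — a fast approximation used inside iterative fits, where a
        rare slightly-suboptimal correspondence is harmless.
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        k = min(8, len(self._centroids))
        _, nearest = self._tree.query(points, k=k)
        nearest = np.atleast_2d(nearest)
        q0, d0, t0 = self._exact_over(points, list(nearest))
        if not exact:
            return q0, d0, t0
        # exactness: true nearest centroid is within d_upper + max_reach
        radii = d0 + self._max_reach + 1e-12
        balls = self._tree.query_ball_point(points, radii)
        need = np.array([len(bi) > k for bi in balls])
        if need.any():
            qq, dd, tt = self._exact_over(points[need], [balls[i] for i in np.flatnonzero(need)])
            better = dd <= d0[need]
            ids = np.flatnonzero(need)[better]
            q0[ids], d0[ids], t0[ids] = qq[better], dd[better], tt[better]
        return q0, d0, t0


def closest_point_on_mesh(mesh: TriMesh, points: np.ndarray):
    """One-shot convenience wrapper around :class:`MeshProximity`."""
    return MeshProximity(mesh).query(points)
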