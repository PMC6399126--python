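"""Accuracy metrics and the statistical comparison of scaling methods.

Scaled models are compared to their manually-digitised counterparts by
root-mean-square error (point-to-surface for bones, corresponding-point for
muscle paths and landmarks). Methods are compared across subjects with a
one-way repeated-measures ANOVA (subject as block; the paired design is
implied by the paired post-hoc t-tests) followed, where significant at
α = 0.05, by pairwise paired t-tests with Holm step-down correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import TriMesh
from .proximity import MeshProximity

__all__ = [
    "EvaluationReport",
    "surface_rmse",
    "corresponding_point_rmse",
    "per_point_variability",
    "holm_adjust",
    "compare_methods",
]

ALPHA = 0.05


def surface_rmse(a: TriMesh, b: TriMesh, symmetric: bool = False) -> float:
    """RMS of closest-point distances from a's vertices to b's surface (mm).

    ``symmetric`` pools distances from both directions before taking the RMS.
    """
    if a.n_triangles == 0 or b.n_triangles == 0:
        raise ValueError("empty mesh")
    _, d_ab, _ = MeshProximity(b).query(a.vertices)
    if not symmetric:
        return float(np.sqrt(np.mean(d_ab**2)))
    _, d_ba, _ = MeshProximity(a).query(b.vertices)
    pooled = np.concatenate([d_ab, d_ba])
    return float(np.sqrt(np.mean(pooled**2)))


def corresponding_point_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of pairwise distances between corresponded point lists (mm)."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.shape != b.shape or len(a) == 0:
        raise ValueError("point lists must be nonempty and of equal shape")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def per_point_variability(point_sets: list[np.ndarray]) -> dict[str, np.ndarray]:
    """Per-point spread of corresponded point lists across subjects.

    Returns, for every corresponded point: ``sd`` — the sample SD (n−1) of
    distances to the per-point mean position; ``axis_sd`` — per-axis sample
    SDs, the semi-axes of the variability ellipsoid as plotted in
    method-comparison figures; and ``mean`` — the mean position.
    """
    if len(point_sets) < 2:
        raise ValueError("need >= 2 point sets")
    arr = np.stack([np.atleast_2d(np.asarray(p, dtype=np.float64)) for p in point_sets])
    mean = arr.mean(axis=0)  # (P, 3)
    dists = np.linalg.norm(arr - mean, axis=2)  # (n, P)
    sd = np.sqrt((dists**2).sum(axis=0) / (len(arr) - 1))
    axis_sd = arr.std(axis=0, ddof=1)  # (P, 3)
    return {"mean": mean, "sd": sd, "axis_sd": axis_sd}


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending; adjusted_(i) = max_{j<=i} min((m−j+1)·p_(j), 1).
    """
    p = np.asarray(pvalues, dtype=np.float64).ravel()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj = np.maximum.accumulate(adj)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class EvaluationReport:
    """Method comparison for one error metric across subjects."""

    table: pd.DataFrame  # subjects x methods, mm
    means: pd.Series
    sds: pd.Series
    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame | None = None  # columns: method_a, method_b, t, p, p_holm

    def significant_pairs(self, alpha: float = ALPHA) -> list[tuple[str, str]]:
        if self.pairwise is None:
            return []
        sig = self.pairwise[self.pairwise["p_holm"] < alpha]
        return list(zip(sig["method_a"], sig["method_b"]))


def _rm_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (methods within subjects)."""
    y = table.to_numpy(dtype=np.float64)
    n, k = y.shape
    grand = y.mean()
    ss_methods = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_error = ss_total - ss_methods - ss_subjects
    df_m, df_e = k - 1, (n - 1) * (k - 1)
    ms_error = ss_error / df_e
    if ms_error <= 0:
        # degenerate: no within-subject variation beyond the method effect
        return (np.inf, 0.0) if ss_methods > 0 else (0.0, 1.0)
    F = (ss_methods / df_m) / ms_error
    p = float(stats.f.sf(F, df_m, df_e))
    return float(F), p


def compare_methods(per_subject_errors: pd.DataFrame | dict) -> EvaluationReport:
    """Compare scaling methods on a complete subjects × methods error table.

    Runs the repeated-measures ANOVA; when significant at α = 0.05, all
    pairwise paired t-tests are run and Holm-adjusted.
    """
    table = pd.DataFrame(per_subject_errors)
    if table.shape[1] < 2:
        raise ValueError("need >= 2 methods")
    if table.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    if table.isna().any().any():
        raise ValueError("error table has missing cells")
    F, p = _rm_anova(table)
    pairwise = None
    if p < ALPHA:
        methods = list(table.columns)
        rows = []
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a, b = methods[i], methods[j]
                diff = table[a] - table[b]
                if np.allclose(diff.std(ddof=1), 0):
                    t, praw = (0.0, 1.0) if np.allclose(diff, 0) else (np.inf, 0.0)
                else:
                    t, praw = stats.ttest_rel(table[a], table[b])
                rows.append({"method_a": a, "method_b": b, "t": float(t), "p": float(praw)})
        pairwise = pd.DataFrame(rows)
        pairwise["p_holm"] = holm_adjust(pairwise["p"].to_numpy())
    return EvaluationReport(
        table=table,
        means=table.mean(axis=0),
        sds=table.std(axis=0, ddof=1),
        anova_F=F,
        anova_p=p,
        pairwise=pairwise,
    )
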