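"""End-to-end pipeline: population -> SSM -> reconstruction -> scaling -> stats.

This is the programmatic core behind the ``demo`` CLI subcommand. On a
synthetic population it mirrors the full study design:

* build an SSM from the corresponded bone surfaces;
* reconstruct a held-out-style subject from a sparse 1000-point cloud
  (full and joint-regions-only variants);
* morph a reference subject's muscle model onto every other subject with
  the three scaling methods — two-parameter linear, affine least-squares,
  and non-linear B-spline FFD — and score each against the subject's own
  ("digitised") anatomy;
* compare the methods with repeated-measures ANOVA + Holm-corrected paired
  t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, compare_methods, corresponding_point_rmse, surface_rmse
from .ffd import apply_ffd, fit_ffd
from .geometry import extract_end_regions, sample_surface_points
from .reconstruction import FitResult, fit_to_point_cloud
from .scaling import affine_fit, apply_affine, linear_scale_points, segment_params_from_landmarks
from .shape_model import ShapeModel, build_ssm, compactness
from .synthetic import SyntheticSpec, SyntheticSubject, generate_population

METHODS = ("linear", "affine", "ffd")

__all__ = ["DemoResult", "run_demo", "morph_reference_to_subject"]


@dataclass
class DemoResult:
    model: ShapeModel
    surface_table: pd.DataFrame
    muscle_table: pd.DataFrame
    oi_table: pd.DataFrame
    landmark_table: pd.DataFrame
    reports: dict[str, EvaluationReport]
    recon_full: FitResult
    recon_partial_rmse: float
    recon_full_truth_rmse: float
    seed: int

    def summary(self) -> dict:
        out = {
            "n_subjects": int(len(self.surface_table) + 1),
            "ssm_n_modes": int(self.model.n_modes),
            "ssm_compactness_4": compactness(self.model, min(4, self.model.n_modes)),
            "reconstruction_rmse_full_mm": self.recon_full_truth_rmse,
            "reconstruction_rmse_end_regions_mm": self.recon_partial_rmse,
        }
        for metric, report in self.reports.items():
            for m in METHODS:
                out[f"{metric}_rmse_mm_{m}"] = float(report.means[m])
                out[f"{metric}_rmse_sd_mm_{m}"] = float(report.sds[m])
            out[f"{metric}_anova_p"] = report.anova_p
            if report.pairwise is not None:
                for _, row in report.pairwise.iterrows():
                    key = f"{metric}_p_holm_{row['method_a']}_vs_{row['method_b']}"
                    out[key] = float(row["p_holm"])
        return out


def morph_reference_to_subject(
    reference: SyntheticSubject,
    subject: SyntheticSubject,
    method: str,
    ffd_spacing: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Morph the reference anatomy (muscle paths + landmarks) and surface
    vertices onto a subject with one scaling method.

    Returns (anatomy_points, surface_vertices) in the subject's space.
    """
    ref_pts = reference.muscles.all_points()
    ref_verts = reference.mesh.vertices
    if method == "linear":
        src = segment_params_from_landmarks(reference.landmarks, "thigh")
        tgt = segment_params_from_landmarks(subject.landmarks, "thigh")
        return (
            linear_scale_points(ref_pts, src, tgt),
            linear_scale_points(ref_verts, src, tgt),
        )
    if method == "affine":
        # surfaces here share topology (as SSM reconstructions do), so the
        # least-squares affine map is fitted on dense vertex correspondences
        T = affine_fit(reference.mesh, subject.mesh, index_correspondence=True)
        return apply_affine(T, ref_pts), apply_affine(T, ref_verts)
    if method == "ffd":
        # reconstructed surfaces share the reference topology, so the FFD is
        # fitted on exact vertex correspondences
        lattice = fit_ffd(
            ref_verts,
            subject.mesh.vertices,
            spacing=ffd_spacing,
            support_points=ref_pts,
        )
        return apply_ffd(lattice, ref_pts), apply_ffd(lattice, ref_verts)
    raise ValueError(f"unknown method {method!r}")


def run_demo(
    seed: int = 0,
    n_subjects: int = 12,
    spec: SyntheticSpec | None = None,
    n_cloud_points: int = 1000,
    recon_modes: int | None = None,
    ffd_spacing: float = 20.0,
) -> DemoResult:
    """Run the full method-comparison study on a synthetic population."""
    if spec is None:
        spec = SyntheticSpec(n_subjects=n_subjects, seed=seed)
    subjects = generate_population(spec)
    if len(subjects) < 4:
        raise ValueError("need >= 4 subjects for a meaningful comparison")
    meshes = [s.mesh for s in subjects]
    model = build_ssm(meshes, align=False)

    # --- sparse reconstruction of the last subject -------------------------
    target = subjects[-1]
    cloud = sample_surface_points(target.mesh, n_cloud_points, seed=seed)
    fit_full = fit_to_point_cloud(model, cloud, n_modes=recon_modes)
    recon_full_truth = surface_rmse(fit_full.surface, target.mesh)
    partial = extract_end_regions(cloud, fraction=0.2)
    fit_part = fit_to_point_cloud(model, partial, n_modes=recon_modes)
    recon_part_truth = surface_rmse(fit_part.surface, target.mesh)

    # --- scaling comparison: reference -> every other subject --------------
    reference = subjects[0]
    others = subjects[1:]
    tables = {k: {m: [] for m in METHODS} for k in ("surface", "muscle_paths", "muscle_oi", "landmarks")}
    n_path_pts = len(reference.muscles.muscle_points())
    oi_idx = _oi_indices(reference)
    for subj in others:
        truth_anat = subj.muscles.all_points()
        for m in METHODS:
            anat, verts = morph_reference_to_subject(reference, subj, m, ffd_spacing)
            morphed_mesh = reference.mesh.with_vertices(verts)
            tables["surface"][m].append(surface_rmse(morphed_mesh, subj.mesh))
            tables["muscle_paths"][m].append(
                corresponding_point_rmse(anat[:n_path_pts], truth_anat[:n_path_pts])
            )
            tables["muscle_oi"][m].append(
                corresponding_point_rmse(anat[oi_idx], truth_anat[oi_idx])
            )
            tables["landmarks"][m].append(
                corresponding_point_rmse(anat[n_path_pts:], truth_anat[n_path_pts:])
            )
    frames = {k: pd.DataFrame(v) for k, v in tables.items()}
    reports = {k: compare_methods(df) for k, df in frames.items()}
    return DemoResult(
        model=model,
        surface_table=frames["surface"],
        muscle_table=frames["muscle_paths"],
        oi_table=frames["muscle_oi"],
        landmark_table=frames["landmarks"],
        reports=reports,
        recon_full=fit_full,
        recon_partial_rmse=recon_part_truth,
        recon_full_truth_rmse=recon_full_truth,
        seed=seed,
    )


def _oi_indices(subject: SyntheticSubject) -> np.ndarray:
    """Indices of origin/insertion points within the muscle-point block."""
    idx, i = [], 0
    for p in subject.muscles.paths:
        idx.extend([i, i + p.n_points - 1])
        i += p.n_points
    return np.asarray(idx, dtype=np.int64)
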