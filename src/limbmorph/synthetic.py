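"""Synthetic populations of bone-like meshes with exact ground truth.

No clinical surfaces ship with the package, so every pipeline stage is
exercised on a parametric "long bone": a tube swept along a bowed axis with
flared end bulbs (condyle-like), elliptical cross-sections and capped ends.
All subjects of a population share one parametric (t, θ) grid, so their
meshes are in exact index-wise correspondence and the image of *any*
parametric anatomy point under a subject-to-subject shape change is known
in closed form — the oracle for correspondence, FFD and scaling tests.

Anatomy mirrors a femur-like thigh segment: landmarks HJC (hip joint
centre, proximal pole), RLFE/RMFE (lateral/medial distal epicondyles) and
fabricated pelvis landmarks RASIS/LASIS whose separation tracks overall
subject width only imperfectly — pelvis width is exactly the kind of crude
transverse surrogate the two-parameter linear scaling law relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import LandmarkSet, MuscleModel, MusclePath, TriMesh

__all__ = [
    "BoneParams",
    "SyntheticSpec",
    "SyntheticSubject",
    "bone_mesh",
    "surface_point",
    "generate_population",
    "ground_truth_deformation",
    "add_noise",
]


@dataclass(frozen=True)
class BoneParams:
    """Shape parameters of one parametric long bone (mm, except curvature 1/mm
    and the dimensionless ellipse ratio)."""

    length: float = 400.0
    shaft_radius: float = 16.0
    proximal_bulb_radius: float = 26.0
    distal_bulb_radius: float = 31.0
    bow_curvature: float = 5e-4
    ellipse_ratio: float = 1.0
    pelvis_width: float = 230.0


def _radius_profile(p: BoneParams, t: np.ndarray) -> np.ndarray:
    """Shaft radius with smooth condyle bulbs at both ends (support 25%)."""
    t = np.asarray(t, dtype=np.float64)

    def bump(s):
        s = np.clip(s, 0.0, 1.0)
        return np.cos(0.5 * np.pi * s) ** 2

    r = np.full_like(t, p.shaft_radius)
    r = r + (p.distal_bulb_radius - p.shaft_radius) * bump(t / 0.25)
    r = r + (p.proximal_bulb_radius - p.shaft_radius) * bump((1 - t) / 0.25)
    return r


def _centerline(p: BoneParams, t: np.ndarray) -> np.ndarray:
    """Bone axis: longitudinal along +y (distal end at y=0), parabolic bow in x
    with mid-shaft sagitta κL²/8."""
    t = np.asarray(t, dtype=np.float64)
    y = p.length * t
    x = p.bow_curvature * p.length**2 / 2.0 * t * (1.0 - t)
    return np.stack([x, y, np.zeros_like(t)], axis=-1)


def surface_point(p: BoneParams, t, theta, offset=0.0) -> np.ndarray:
    """Closed-form parametric map (t, θ, radial offset) -> world point.

    t in [0, 1] runs distal -> proximal, θ is the circumferential angle
    (θ=0 on the lateral +x side), offset is measured radially outward from
    the surface (0 = on the surface). This map is the exact ground truth
    for how any anatomical site moves between two parameter sets.
    """
    t = np.asarray(t, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    offset = np.asarray(offset, dtype=np.float64)
    c = _centerline(p, t)
    r = _radius_profile(p, t) + offset
    x = r * p.ellipse_ratio * np.cos(theta)
    z = r * np.sin(theta)
    return c + np.stack([x, np.zeros_like(x), z], axis=-1)


def bone_mesh(p: BoneParams, n_axial: int = 40, n_circ: int = 24) -> TriMesh:
    """Watertight swept-tube mesh on the shared (t, θ) grid plus two pole caps."""
    if n_axial < 8 or n_circ < 8:
        raise ValueError("resolution must be >= 8 x 8")
    t = np.linspace(0.0, 1.0, n_axial)
    theta = np.arange(n_circ) * (2 * np.pi / n_circ)
    tt, th = np.meshgrid(t, theta, indexing="ij")
    ring_verts = surface_point(p, tt.ravel(), th.ravel())
    pole_d = _centerline(p, np.array([0.0]))[0]
    pole_p = _centerline(p, np.array([1.0]))[0]
    verts = np.vstack([ring_verts, pole_d, pole_p])

    def vid(i, j):
        return i * n_circ + (j % n_circ)

    tris = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j), vid(i + 1, j + 1)
            tris.append([a, d, b])
            tris.append([a, c, d])
    id_d, id_p = n_axial * n_circ, n_axial * n_circ + 1
    for j in range(n_circ):
        tris.append([vid(0, j), vid(0, j + 1), id_d])
        tris.append([vid(n_axial - 1, j + 1), vid(n_axial - 1, j), id_p])
    return TriMesh(verts, np.asarray(tris, dtype=np.int64))


# ---------------------------------------------------------------------------
# Population specification and anatomy sites


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic population.

    Ranges are uniform sampling intervals chosen so that inter-subject
    surface RMSE before scaling falls in the 5-20 mm regime typical of
    adult lower-limb bones; the pelvis-width noise makes the linear law's
    transverse surrogate imperfect, as it is in vivo.
    """

    n_subjects: int = 12
    seed: int = 0
    length_range: tuple[float, float] = (340.0, 470.0)
    shaft_radius_range: tuple[float, float] = (13.0, 19.0)
    proximal_bulb_range: tuple[float, float] = (21.0, 31.0)
    distal_bulb_range: tuple[float, float] = (25.0, 37.0)
    bow_curvature_range: tuple[float, float] = (0.0, 1.0e-3)
    ellipse_ratio_range: tuple[float, float] = (0.85, 1.15)
    pelvis_width_noise: float = 0.06
    n_axial: int = 40
    n_circ: int = 24
    n_muscle_paths: int = 10
    noise_sd: float = 0.0

    def __post_init__(self):
        for name in (
            "length_range",
            "shaft_radius_range",
            "proximal_bulb_range",
            "distal_bulb_range",
            "ellipse_ratio_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range {name}={getattr(self, name)}")
        lo, hi = self.bow_curvature_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid bow_curvature_range")
        if self.n_axial < 8 or self.n_circ < 8:
            raise ValueError("resolution must be >= 8 x 8")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SurfaceSite:
    """Anatomy point pinned to the parametric surface frame.

    ``on_axis`` sites sit on the bone's centerline (used for joint centres).
    """

    t: float
    theta: float
    offset: float = 0.0
    on_axis: bool = False

    def locate(self, p: BoneParams) -> np.ndarray:
        if self.on_axis:
            return _centerline(p, np.asarray(self.t))[()]
        return surface_point(p, self.t, self.theta, self.offset)


@dataclass(frozen=True)
class AnatomySites:
    """Parametric definitions of every anatomy point, shared by a population."""

    landmark_sites: dict[str, SurfaceSite]
    path_sites: tuple[tuple[str, tuple[SurfaceSite, ...]], ...]

    def bone_landmarks(self, p: BoneParams) -> LandmarkSet:
        """Landmarks digitised on (or at) the bone itself."""
        return LandmarkSet({n: s.locate(p) for n, s in self.landmark_sites.items()})

    def landmarks(self, p: BoneParams) -> LandmarkSet:
        """Bone landmarks plus the fabricated pelvis landmarks (RASIS/LASIS)
        that feed the linear scaling law's pelvis-width surrogate; the pelvis
        pair is off-bone and is not part of the morphed thigh anatomy."""
        lm = self.bone_landmarks(p)
        half = p.pelvis_width / 2.0
        y = p.length * 1.1
        lm["RASIS"] = np.array([half, y, 0.0])
        lm["LASIS"] = np.array([-half, y, 0.0])
        return lm

    def muscle_model(self, p: BoneParams) -> MuscleModel:
        paths = []
        for name, sites in self.path_sites:
            pts = np.vstack([s.locate(p) for s in sites])
            roles = ("origin",) + ("via",) * (len(sites) - 2) + ("insertion",)
            paths.append(MusclePath(name, pts, roles))
        return MuscleModel(tuple(paths), self.bone_landmarks(p), "thigh")

    def all_points(self, p: BoneParams) -> np.ndarray:
        return self.muscle_model(p).all_points()


def _default_sites(spec: SyntheticSpec, rng: np.random.Generator) -> AnatomySites:
    landmark_sites = {
        "HJC": SurfaceSite(1.0, 0.0, 0.0, on_axis=True),  # proximal pole centre
        "RLFE": SurfaceSite(0.04, 0.0, 0.0),
        "RMFE": SurfaceSite(0.04, np.pi, 0.0),
        "MSH": SurfaceSite(0.5, 0.5 * np.pi, 0.0),
    }
    paths = []
    for k in range(spec.n_muscle_paths):
        theta0 = 2 * np.pi * k / spec.n_muscle_paths + rng.uniform(-0.2, 0.2)
        twist = rng.uniform(-0.5 * np.pi, 0.5 * np.pi)
        n_via = int(rng.integers(2, 6))
        t_vals = np.concatenate(
            [[rng.uniform(0.85, 0.96)], np.sort(rng.uniform(0.2, 0.8, n_via))[::-1], [rng.uniform(0.04, 0.15)]]
        )
        offs = rng.uniform(1.0, 4.0, len(t_vals))
        sites = tuple(
            SurfaceSite(float(tv), float(theta0 + twist * (1 - i / (len(t_vals) - 1))), float(o))
            for i, (tv, o) in enumerate(zip(t_vals, offs))
        )
        paths.append((f"muscle_{k:02d}", sites))
    return AnatomySites(landmark_sites, tuple(paths))


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic subject: surface, anatomy, and the generating parameters."""

    mesh: TriMesh
    landmarks: LandmarkSet
    muscles: MuscleModel
    params: BoneParams
    sites: AnatomySites
    resolution: tuple[int, int]


def _draw_params(spec: SyntheticSpec, rng: np.random.Generator) -> BoneParams:
    u = lambda r: float(rng.uniform(*r))
    shaft = u(spec.shaft_radius_range)
    width_factor = shaft / np.mean(spec.shaft_radius_range)
    noise = 1.0 + rng.uniform(-spec.pelvis_width_noise, spec.pelvis_width_noise)
    return BoneParams(
        length=u(spec.length_range),
        shaft_radius=shaft,
        proximal_bulb_radius=u(spec.proximal_bulb_range),
        distal_bulb_radius=u(spec.distal_bulb_range),
        bow_curvature=u(spec.bow_curvature_range),
        ellipse_ratio=u(spec.ellipse_ratio_range),
        pelvis_width=230.0 * width_factor * noise,
    )


def generate_population(spec: SyntheticSpec) -> list[SyntheticSubject]:
    """Deterministically generate a population of corresponded subjects."""
    rng = np.random.default_rng(spec.seed)
    sites = _default_sites(spec, rng)
    subjects = []
    for _ in range(spec.n_subjects):
        p = _draw_params(spec, rng)
        mesh = bone_mesh(p, spec.n_axial, spec.n_circ)
        if spec.noise_sd > 0:
            seed = int(rng.integers(0, 2**31 - 1))
            mesh = mesh.with_vertices(add_noise(mesh.vertices, spec.noise_sd, seed))
        subjects.append(
            SyntheticSubject(
                mesh=mesh,
                landmarks=sites.landmarks(p),
                muscles=sites.muscle_model(p),
                params=p,
                sites=sites,
                resolution=(spec.n_axial, spec.n_circ),
            )
        )
    return subjects


def ground_truth_deformation(
    subject_a: SyntheticSubject, subject_b: SyntheticSubject
) -> tuple[np.ndarray, np.ndarray]:
    """Exact corresponded point pairs under the parametric shape change a -> b.

    Returns (points_a, points_b): index-wise mesh vertices followed by the
    exact images of every muscle-path point and landmark.
    """
    if subject_a.resolution != subject_b.resolution or subject_a.sites is not subject_b.sites:
        if not np.array_equal(subject_a.mesh.triangles, subject_b.mesh.triangles):
            raise ValueError("subjects are not from the same parametric family")
    pa = [subject_a.mesh.vertices, subject_a.muscles.all_points()]
    pb = [subject_b.mesh.vertices, subject_b.muscles.all_points()]
    return np.vstack(pa), np.vstack(pb)


def add_noise(points: np.ndarray, sd: float, seed: int | None = None) -> np.ndarray:
    """Isotropic Gaussian perturbation emulating digitisation error."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    points = np.asarray(points, dtype=np.float64)
    if sd == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    return points + rng.normal(0.0, sd, points.shape)
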