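"""Comparator scaling methods: the two-parameter linear law and the affine fit.

The linear law scales each body segment with exactly two factors derived
from bony landmarks — a longitudinal factor (segment length ratio) and a
transverse factor (pelvis width ratio; the patella swaps the two) — the
convention used by landmark-based musculoskeletal scaling tools. The affine
fit is a 12-parameter least-squares map between complete bone surfaces and
serves as the lower bound on what any linear scaling law can achieve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import LandmarkSet, TriMesh
from .proximity import MeshProximity
from .registration import RigidTransform

__all__ = [
    "SegmentScaleParams",
    "AffineTransform",
    "segment_params_from_landmarks",
    "linear_scale_points",
    "affine_fit",
    "apply_affine",
]


@dataclass(frozen=True)
class SegmentScaleParams:
    """Per-segment scaling dimensions: longitudinal ``length`` and transverse
    ``width`` (mm), both positive."""

    segment: str
    length: float
    width: float

    def __post_init__(self):
        if self.length <= 0 or self.width <= 0:
            raise ValueError("length and width must be positive")


@dataclass(frozen=True)
class AffineTransform:
    """General linear map x -> L x + t with non-singular L."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.linear, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(L)) < 1e-12:
            raise ValueError("linear part is singular")
        object.__setattr__(self, "linear", L)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "AffineTransform":
        Linv = np.linalg.inv(self.linear)
        return AffineTransform(Linv, -Linv @ self.translation)


def _midpoint(lm: LandmarkSet, a: str, b: str) -> np.ndarray:
    return (lm[a] + lm[b]) / 2.0


def _require(lm: LandmarkSet, names: list[str], segment: str) -> None:
    missing = [n for n in names if n not in lm]
    if missing:
        raise ValueError(f"segment {segment!r}: missing landmarks {missing}")


def _pelvis_width(lm: LandmarkSet) -> float:
    _require(lm, ["RASIS", "LASIS"], "pelvis")
    return float(np.linalg.norm(lm["RASIS"] - lm["LASIS"]))


def _thigh_length(lm: LandmarkSet, side: str) -> float:
    names = ["HJC", f"{side}LFE", f"{side}MFE"]
    _require(lm, names, "thigh")
    return float(np.linalg.norm(lm["HJC"] - _midpoint(lm, names[1], names[2])))


def _shank_length(lm: LandmarkSet, side: str) -> float:
    names = [f"{side}LFE", f"{side}MFE", f"{side}MM", f"{side}LM"]
    _require(lm, names, "shank")
    knee = _midpoint(lm, names[0], names[1])
    ankle = _midpoint(lm, names[2], names[3])
    return float(np.linalg.norm(knee - ankle))


def _foot_length(lm: LandmarkSet, side: str) -> float:
    names = [f"{side}MM", f"{side}LM", f"{side}FM2"]
    _require(lm, names, "foot")
    ankle = _midpoint(lm, names[0], names[1])
    return float(np.linalg.norm(ankle - lm[names[2]]))


def segment_params_from_landmarks(
    landmarks: LandmarkSet, segment: str, side: str = "R"
) -> SegmentScaleParams:
    """Derive the linear-law dimensions of a segment from bony landmarks.

    Pelvis width: |RASIS - LASIS|. Thigh length: hip joint centre (HJC
    landmark) to femoral epicondyle midpoint. Shank length: epicondyle
    midpoint to malleoli midpoint. Foot length: malleoli midpoint to the
    distal end of the second metatarsal. Segment pairing: pelvis/thigh/
    shank/foot take their own length with pelvis width as the transverse
    factor; the patella swaps the two (pelvis width as length, thigh length
    as width).
    """
    if segment == "pelvis":
        return SegmentScaleParams(segment, _thigh_length(landmarks, side), _pelvis_width(landmarks))
    if segment == "thigh":
        return SegmentScaleParams(segment, _thigh_length(landmarks, side), _pelvis_width(landmarks))
    if segment == "shank":
        return SegmentScaleParams(segment, _shank_length(landmarks, side), _pelvis_width(landmarks))
    if segment == "foot":
        return SegmentScaleParams(segment, _foot_length(landmarks, side), _pelvis_width(landmarks))
    if segment == "patella":
        return SegmentScaleParams(segment, _pelvis_width(landmarks), _thigh_length(landmarks, side))
    raise ValueError(f"unknown segment {segment!r}")


def linear_scale_points(
    points: np.ndarray,
    source: SegmentScaleParams,
    target: SegmentScaleParams,
    frame: RigidTransform | None = None,
) -> np.ndarray:
    """Two-parameter linear scaling of points expressed in (or mapped into)
    the segment's anatomical frame.

    The frame's second (y) axis is the longitudinal superior-inferior axis
    (ISB convention): it is scaled by target.length/source.length, while
    both transverse axes are scaled by target.width/source.width. The frame
    maps anatomical to world coordinates; points are scaled about the frame
    origin and mapped back.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    frame = RigidTransform.identity() if frame is None else frame
    s = np.array(
        [
            target.width / source.width,
            target.length / source.length,
            target.width / source.width,
        ]
    )
    local = frame.inverse().apply(points)
    return frame.apply(local * s)


def apply_affine(transform: AffineTransform, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    return points @ transform.linear.T + transform.translation


def affine_fit(
    source: TriMesh,
    target: TriMesh,
    max_iter: int = 50,
    tol: float = 1e-6,
    index_correspondence: bool = False,
) -> AffineTransform:
    """Least-squares affine map bringing the source surface onto the target.

    Default behaviour alternates closest-point correspondence (transformed
    source vertices onto the target surface) with the closed-form affine
    update; the RMS residual is monotone non-increasing. With
    ``index_correspondence`` the meshes must share topology and the closed
    form is solved once on vertex pairs.
    """
    src = source.vertices
    centred = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(centred).max())) < 3:
        raise ValueError("source vertices are rank-deficient (coplanar/collinear)")

    def solve(pairs_src: np.ndarray, pairs_tgt: np.ndarray) -> AffineTransform:
        X = np.hstack([pairs_src, np.ones((len(pairs_src), 1))])
        coef, *_ = np.linalg.lstsq(X, pairs_tgt, rcond=None)
        return AffineTransform(coef[:3].T, coef[3])

    if index_correspondence:
        if target.n_vertices != source.n_vertices:
            raise ValueError("index correspondence requires equal vertex counts")
        return solve(src, target.vertices)

    prox = MeshProximity(target)
    T = AffineTransform.identity()
    prev = np.inf
    for _ in range(max_iter):
        moved = apply_affine(T, src)
        foot, dist, _ = prox.query(moved)
        res = float(np.sqrt(np.mean(dist**2)))
        if prev - res < tol:
            break
        prev = res
        T = solve(src, foot)
    return T
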