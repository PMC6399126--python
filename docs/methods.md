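# Methods

`limbmorph` implements non-linear scaling of lower-limb musculoskeletal
geometry: bone surfaces are modelled with a statistical shape model (SSM),
reconstructed from sparse point clouds, and the mapping between a
reference bone and a subject's bone — expressed as a cubic B-spline
free-form deformation (FFD) — carries the reference's muscle paths and
bony landmarks onto the subject. Two comparator methods frame the
evaluation: a two-parameter linear scaling law driven by bony landmarks,
and an affine least-squares surface fit, the lower bound on what any
linear law can achieve. All quantities are in millimetres.

## Statistical shape model

Training surfaces must be in dense correspondence (identical topology,
vertex *i* anatomically equivalent across shapes). `build_ssm` optionally
runs generalised rigid alignment — each shape is aligned to the evolving
mean with the closed-form Kabsch solution, iterated until the mean moves
by less than 1e-6 mm — and then extracts principal modes of variation
(PMVs) by PCA of the stacked vertex coordinates. No scaling is used in
the alignment, so overall size remains in the modes (typically PMV 1).
Because the number of shapes *n* is far below the number of coordinates
3V, the eigen-decomposition uses the n×n Gram matrix; eigenvalues use the
(n−1) sample convention, and modes with λ_i ≤ 1e-10·λ_1 are dropped.

For populations generated about a common frame (e.g. this package's
synthetic bones) alignment can be disabled (`align=False`). This matters
when validating PCA against planted displacement fields: optimal rigid
alignment of non-rigidly perturbed shapes mixes an O(‖d‖²) rotation into
the modes — correct behaviour, but it breaks exact recovery of planted
variances.

A shape is synthesised as mean + Σ b_i·PMV_i. The plausibility of a
weight vector is its Mahalanobis norm sqrt(Σ b_i²/λ_i); compactness(k) is
the cumulative eigenvalue fraction of the first k modes.

## Reconstruction from sparse point clouds

`fit_to_point_cloud` fits mode weights to a (possibly partial) cloud of
surface points by alternating:

1. correspondence — each cloud point is matched to its closest point on
   the current synthesised surface, expressed barycentrically so the
   matched point is linear in the weights;
2. a regularised linear solve of
   min_b Σ‖p_j − y_j(b)‖² + α Σ b_i²/λ_i, followed by clamping each
   weight to |b_i| ≤ 3·sqrt(λ_i) so partial clouds cannot push the model
   to implausible shapes;
3. optional rigid re-alignment of the cloud (off by default; clouds are
   assumed pre-registered).

Two numerical choices matter:

* **Correspondence bootstrap.** Plain closest-point correspondence from
  the mean shape converges very slowly when the target differs grossly
  in length: points beyond the bone end all project onto the end cap and
  the fit creeps a few millimetres per iteration. The first iteration
  therefore normalises the cloud to the mean shape's per-axis bounding
  box before projecting, which captures the gross length/width change in
  a single solve. Subsequent iterations use plain closest-point, whose
  standard monotone-objective guarantee then applies.
* **Decaying regularisation.** The penalty weight starts at
  α = 0.1·(mean squared cloud-to-surface distance)/M and is re-evaluated
  from the current misfit each iteration, never increasing. A fixed α of
  that magnitude permanently biases small-variance modes by more than
  0.1·σ even on noiseless clouds; letting α track the shrinking misfit
  keeps strong regularisation early (when correspondence is unreliable)
  and removes the asymptotic bias. Because α is non-increasing, the
  recorded objective sequence is still monotone non-increasing. A fixed
  α can be supplied explicitly.

Convergence is declared when the largest weight change is below
1e-4·sqrt(λ_i); the default iteration cap is 100.

## Free-form deformation

The FFD is the classic displacement-parameterised tensor-product cubic
B-spline lattice: a regular control grid (default node spacing 20 mm,
per axis) carries 3D displacement coefficients, and a point is moved by
the 4×4×4 blend of its neighbouring controls. Zero coefficients give the
identity exactly; cubic B-splines have linear precision, so affine fields
are reproduced to machine accuracy; the basis partitions unity to 1e-12.

`fit_ffd` solves for the coefficients by linear least squares over
corresponded point pairs with a discrete bending-energy regulariser
(squared second differences of the coefficient grid, default weight
1e-3). The bending term vanishes on affine coefficient fields, so it does
not bias linear trends. The lattice covers the union bounding box of the
source points and any `support_points` (muscle paths and landmarks that
must be transformable later), padded by one cell below and two above per
axis so every interior point has a full 4³ basis neighbourhood. Points
outside the support are a hard error — no extrapolation — with the
offending index reported.

`establish_correspondence` re-expresses a target surface with a
template's topology: template vertices are repeatedly projected onto the
target and the motion is regularised by a coarse-to-fine FFD (spacing
halved per level, 2 levels, 3 projection rounds per level). This is
reliable for smooth deformations of moderate amplitude; pure closest-point
projection cannot recover large tangential motion (e.g. a 15% length
change), for which landmark- or feature-driven initialisation would be
needed. Surfaces whose median projection distance exceeds half the
bounding-box diagonal are rejected as non-overlapping.

## Scaling comparators

**Two-parameter linear law.** Segment dimensions come from bony
landmarks: pelvis width = |RASIS − LASIS|; thigh length = hip joint
centre to the femoral-epicondyle midpoint; shank length = epicondyle
midpoint to the malleoli midpoint; foot length = malleoli midpoint to the
distal second metatarsal. Pelvis, thigh, shank and foot scale their own
length along the longitudinal axis and pelvis width across both
transverse axes; the patella swaps the two sources (pelvis width as
length, thigh length as width) with the same axis convention — the
anatomical axis assignment for the patella is not standardised, which is
why it is called out here. The longitudinal axis is the second (y) axis
of the segment's anatomical frame (ISB superior–inferior convention);
points are mapped into that frame, scaled about its origin, and mapped
back. The hip joint centre is an input landmark; no regression-based
estimation is provided.

**Affine fit.** A 12-parameter map fitted by least squares. With meshes
in dense correspondence (the normal case here: reconstructed surfaces
share the mean's topology) the closed form is solved once on vertex
pairs. Without correspondence an ICP-style alternation (closest point,
then closed-form update) is available; note that closest-point
correspondence lets surfaces slide tangentially, so the
dense-correspondence path is strongly preferred whenever topology allows.

## Evaluation and statistics

Bone accuracy is the RMS of closest-point distances from the scaled
surface's vertices to the target surface (directional by default; a
symmetric variant pools both directions). Muscle-path, attachment
(origin/insertion) and landmark accuracy are corresponding-point RMSE.
Per-point variability across subjects reports the sample SD (n−1) of
distances to the per-point mean and per-axis SDs (variability ellipsoid
semi-axes).

Methods are compared with a one-way repeated-measures ANOVA (subject as
block — the paired post-hoc design implies the within-subject ANOVA),
implemented in closed form so the degenerate all-identical table returns
F = 0, p = 1 rather than NaN. When the ANOVA is significant at α = 0.05,
all pairwise paired t-tests are run and Holm step-down adjusted.

## Closest-point queries

`trimesh` supplies mesh I/O and area-uniform seeded surface sampling, but
its proximity queries require an rtree index, so closest-point-on-mesh is
implemented directly: a k-d tree over triangle centroids proposes
candidates, exact point–triangle distances (the standard region
classification) select the best, and a ball query of radius
(upper bound + maximum centroid-to-corner reach) guarantees exactness.
Iterative fits use the candidate-only approximation, which is what makes
them fast; final metrics always use the exact query. Ties resolve to the
lowest triangle index.

## Synthetic populations

The generator emulates a femur-like thigh segment at desk scale: a tube
swept along a bowed axis (parabolic bow, mid-shaft sagitta κL²/8) with
smooth condyle-like end bulbs, elliptical cross-sections and capped ends,
on a shared (t, θ) parametric grid — so all subjects of a population are
in exact index-wise correspondence and the image of any parametric
anatomy point under a subject-to-subject shape change is known in closed
form. Default ranges (uniform draws): length 340–470 mm, shaft radius
13–19 mm, proximal/distal bulb radii 21–31/25–37 mm, bow curvature
0–1e-3 mm⁻¹, ellipse aspect 0.85–1.15 — sized so unscaled inter-subject
surface RMSE falls in the 5–20 mm regime of adult lower-limb bones.
Muscle anatomy is 10 paths with 2–5 via points each, offset 1–4 mm from
the surface; landmarks are HJC (on-axis proximal pole), lateral/medial
distal epicondyles, a mid-shaft point, and fabricated pelvis landmarks
RASIS/LASIS whose separation tracks subject width only up to a ±6%
noise factor.

Two generator choices are deliberate modelling decisions, not accidents:

* **Anisotropic cross-sections.** With circular cross-sections an affine
  map has no degrees of freedom beyond the two-parameter law (plus
  shear), and the affine-vs-linear comparison degenerates. Varying the
  ellipse aspect ratio restores the regime in which each additional
  degree of freedom measurably helps: linear worst, affine intermediate,
  FFD best.
* **Imperfect pelvis-width surrogate.** In vivo, pelvis width is a crude
  proxy for a bone's transverse dimensions; the ±6% noise reproduces
  that, which is precisely why the linear law trails the surface-driven
  methods.

What the synthetic family does **not** emulate: real femoral anatomy
(anteversion, condyle asymmetry, trochanters), segmentation and
digitisation noise (available separately via `add_noise` but off by
default), soft-tissue constraints on muscle paths, and inter-subject
variability of muscle topology. Passing results therefore demonstrate the
correctness and relative behaviour of the algorithms, not clinical
accuracy on MR/CT-derived surfaces.

## Problem sizes

The end-to-end demo uses 12 subjects at 40×24 surface resolution
(962 vertices), 1000-point clouds for reconstruction, and 20 mm FFD
spacing; unit tests use coarser 24×12 populations. These sizes keep the
full pipeline to well under a minute on one core while leaving every
statistical comparison overwhelmingly significant.

## Known limitations

* `establish_correspondence` assumes rigid pre-alignment and moderate
  smooth deformation; it is not a substitute for feature-driven
  registration across grossly different bones.
* The SSM fit's bounding-box bootstrap assumes the cloud covers both
  ends of the bone (true for full clouds and for proximal+distal
  end-region clouds alike).
* The ±3σ weight clamp is enforced per mode, so the total Mahalanobis
  norm is bounded by 3·sqrt(M) rather than 3.
* Mirroring (for pooling left/right bones) is provided as a utility
  (`mirror_mesh`); pooling itself is left to the caller.
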