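import json

import numpy as np
import pytest

from limbmorph.geometry import (
    LandmarkSet,
    MuscleModel,
    MusclePath,
    PointCloud,
    TriMesh,
    extract_end_regions,
    read_anatomy,
    read_mesh,
    read_point_cloud,
    sample_surface_points,
    write_anatomy,
    write_mesh,
    write_point_cloud,
)
from limbmorph.proximity import closest_point_on_mesh

ASCII_PLY_CUBE = """ply
format ascii 1.0
element vertex 8
property float x
property float y
property float z
element face 12
property list uchar int vertex_indices
end_header
0 0 0
0 0 1
0 1 0
0 1 1
1 0 0
1 0 1
1 1 0
1 1 1
3 0 1 3
3 0 3 2
3 4 6 7
3 4 7 5
3 0 4 5
3 0 5 1
3 2 3 7
3 2 7 6
3 0 2 6
3 0 6 4
3 1 5 7
3 1 7 3
"""


def test_read_ascii_ply_cube(tmp_path):
    path = tmp_path / "cube.ply"
    path.write_text(ASCII_PLY_CUBE)
    mesh = read_mesh(path)
    assert mesh.n_vertices == 8
    assert mesh.n_triangles == 12


def test_ply_round_trip_is_double_lossless(tmp_path, cube_mesh):
    rng = np.random.default_rng(0)
    verts = cube_mesh.vertices + rng.uniform(-1e-7, 1e-7, (8, 3)) + 1 / 3
    mesh = TriMesh(verts, cube_mesh.triangles)
    for binary in (True, False):
        path = tmp_path / f"m_{binary}.ply"
        write_mesh(mesh, path, binary=binary)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.vertices, mesh.vertices)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)


@pytest.mark.parametrize("fmt", ["stl", "obj"])
def test_cross_format_round_trip_preserves_counts(tmp_path, cube_mesh, fmt):
    p1 = tmp_path / f"m.{fmt}"
    write_mesh(cube_mesh, p1)
    back = read_mesh(p1)
    assert back.n_triangles == cube_mesh.n_triangles
    # STL duplicates vertices per facet; exact-coordinate merge restores them
    assert back.n_vertices == cube_mesh.n_vertices
    p2 = tmp_path / "m2.ply"
    write_mesh(back, p2)
    assert read_mesh(p2).n_triangles == cube_mesh.n_triangles


def test_nan_coordinates_rejected(tmp_path):
    bad = ASCII_PLY_CUBE.replace("0 0 0", "nan 0 0", 1)
    path = tmp_path / "bad.ply"
    path.write_text(bad)
    with pytest.raises(ValueError, match="NaN|finite"):
        read_mesh(path)


def test_write_mesh_rejects_empty_triangles(tmp_path):
    mesh = TriMesh(np.zeros((3, 3)), np.empty((0, 3), dtype=int))
    with pytest.raises(ValueError):
        write_mesh(mesh, tmp_path / "x.ply")


def test_trimesh_invariants():
    with pytest.raises(ValueError):
        TriMesh(np.zeros((3, 3)), [[0, 1, 5]])  # index out of range
    with pytest.raises(ValueError):
        TriMesh([[0, 0, np.nan]], np.empty((0, 3), dtype=int))


# ---------------------------------------------------------------------------
# anatomy JSON


def _toy_model() -> MuscleModel:
    path = MusclePath(
        "vastus_toy",
        np.array([[0.0, 10.0, 0.0], [1.0, 5.0, 0.5], [0.0, 0.0, 0.0]]),
        ("origin", "via", "insertion"),
    )
    lm = LandmarkSet({"RLFE": [3.0, 0.0, 0.0], "RMFE": [-3.0, 0.0, 0.0]})
    return MuscleModel((path,), lm, "thigh")


def test_anatomy_round_trip(tmp_path):
    model = _toy_model()
    p = tmp_path / "anatomy.json"
    write_anatomy(model, p)
    back = read_anatomy(p)
    assert back.segment == model.segment
    assert len(back.paths) == 1
    np.testing.assert_array_equal(back.paths[0].points, model.paths[0].points)
    assert back.paths[0].roles == model.paths[0].roles
    for name in model.landmarks:
        np.testing.assert_array_equal(back.landmarks[name], model.landmarks[name])


def test_anatomy_write_is_deterministic(tmp_path):
    model = _toy_model()
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    write_anatomy(model, p1)
    write_anatomy(model, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_anatomy_empty_paths_ok(tmp_path):
    model = MuscleModel((), LandmarkSet({"HJC": [0, 0, 0]}), "thigh")
    p = tmp_path / "a.json"
    write_anatomy(model, p)
    assert read_anatomy(p).paths == ()


def test_anatomy_unknown_role_rejected(tmp_path):
    data = {
        "segment": "thigh",
        "landmarks": {},
        "paths": [
            {
                "name": "m",
                "points": [[0, 0, 0], [1, 1, 1]],
                "roles": ["origin", "middle"],
            }
        ],
    }
    p = tmp_path / "a.json"
    p.write_text(json.dumps(data))
    with pytest.raises(ValueError, match="role|insertion"):
        read_anatomy(p)


def test_muscle_path_role_invariants():
    with pytest.raises(ValueError):
        MusclePath("m", np.zeros((1, 3)), ("origin",))
    with pytest.raises(ValueError):
        MusclePath("m", np.zeros((2, 3)), ("via", "insertion"))


# ---------------------------------------------------------------------------
# point clouds and sampling


def test_point_cloud_io(tmp_path):
    cloud = PointCloud(np.random.default_rng(1).normal(size=(20, 3)))
    for name in ("c.xyz", "c.ply"):
        p = tmp_path / name
        write_point_cloud(cloud, p)
        back = read_point_cloud(p)
        assert np.abs(back.points - cloud.points).max() < 1e-6


def test_sample_surface_points_on_surface(small_population):
    mesh = small_population[0].mesh
    cloud = sample_surface_points(mesh, 1000, seed=3)
    assert len(cloud) == 1000
    _, dist, _ = closest_point_on_mesh(mesh, cloud.points)
    assert dist.max() < 1e-9


def test_sample_surface_points_deterministic(cube_mesh):
    a = sample_surface_points(cube_mesh, 50, seed=9)
    b = sample_surface_points(cube_mesh, 50, seed=9)
    np.testing.assert_array_equal(a.points, b.points)


def test_sample_surface_area_weighting():
    # two triangles with area ratio 9:1
    v = np.array([[0, 0, 0], [9, 0, 0], [0, 2, 0], [9, 2, 0], [10, 0, 0]], dtype=float)
    t = np.array([[0, 1, 2], [1, 4, 3]])
    mesh = TriMesh(v, t)
    areas = mesh.triangle_areas()
    frac_large = areas.max() / areas.sum()
    cloud = sample_surface_points(mesh, 10000, seed=0)
    # classify samples by nearest triangle id (points lie exactly on one)
    _, _, tid = closest_point_on_mesh(mesh, cloud.points)
    observed = np.mean(tid == int(np.argmax(areas)))
    se = np.sqrt(frac_large * (1 - frac_large) / 10000)
    assert abs(observed - frac_large) < 3 * se


def test_sample_surface_uniformity_chi_squared(cube_mesh):
    from scipy import stats

    n = 12000
    cloud = sample_surface_points(cube_mesh, n, seed=4)
    _, _, tid = closest_point_on_mesh(cube_mesh, cloud.points)
    counts = np.bincount(tid, minlength=12)
    expected = n * cube_mesh.triangle_areas() / cube_mesh.area()
    chi2 = ((counts - expected) ** 2 / expected).sum()
    p = stats.chi2.sf(chi2, df=11)
    assert p > 0.01


def test_extract_end_regions_definition():
    rng = np.random.default_rng(2)
    theta = rng.uniform(0, 2 * np.pi, 5000)
    z = rng.uniform(0, 100, 5000)
    pts = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta), z])
    kept = extract_end_regions(PointCloud(pts), 0.2, axis=[0, 0, 1.0])
    s = (kept.points[:, 2] - 0) / 100
    assert np.all((s <= 0.2 + 1e-9) | (s >= 0.8 - 1e-9))
    frac = len(kept) / 5000
    se = np.sqrt(0.4 * 0.6 / 5000)
    assert abs(frac - 0.4) < 3 * se


def test_extract_end_regions_uses_principal_axis():
    rng = np.random.default_rng(3)
    z = rng.uniform(0, 100, 2000)
    pts = np.column_stack([rng.normal(0, 2, 2000), rng.normal(0, 2, 2000), z])
    kept = extract_end_regions(PointCloud(pts), 0.25)
    s = (kept.points[:, 2] - pts[:, 2].min()) / np.ptp(pts[:, 2])
    assert np.mean((s <= 0.27) | (s >= 0.73)) > 0.99


def test_extract_end_regions_bounds():
    pts = PointCloud(np.random.default_rng(0).normal(size=(100, 3)))
    assert len(extract_end_regions(pts, 0.5)) == 100
    with pytest.raises(ValueError):
        extract_end_regions(pts, 0.0)
    with pytest.raises(ValueError):
        extract_end_regions(PointCloud(np.empty((0, 3))), 0.2)


def test_closest_point_matches_brute_force(cube_mesh):
    from limbmorph.proximity import MeshProximity, _point_triangle_closest

    rng = np.random.default_rng(5)
    pts = rng.uniform(-1.5, 2.5, (200, 3))
    q, d, tid = MeshProximity(cube_mesh).query(pts)
    # naive loop over every triangle
    a, b, c = (cube_mesh.vertices[cube_mesh.triangles[:, k]] for k in range(3))
    for i, p in enumerate(pts):
        pp = np.broadcast_to(p, (len(a), 3))
        qq = _point_triangle_closest(pp, a, b, c)
        dd = np.linalg.norm(qq - pp, axis=1)
        assert abs(d[i] - dd.min()) < 1e-12
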