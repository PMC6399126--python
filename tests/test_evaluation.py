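import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from limbmorph.evaluation import (
    compare_methods,
    corresponding_point_rmse,
    holm_adjust,
    per_point_variability,
    surface_rmse,
)
from limbmorph.geometry import TriMesh


def _plane(z: float = 0.0, n: int = 4) -> TriMesh:
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    v = np.column_stack([xs.ravel(), ys.ravel(), np.full(n * n, z)])
    tris = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            tris.append([a, a + 1, a + n])
            tris.append([a + 1, a + n + 1, a + n])
    return TriMesh(v, np.array(tris))


def test_surface_rmse_zero_on_self(cube_mesh):
    assert surface_rmse(cube_mesh, cube_mesh) == 0.0


def test_surface_rmse_constant_offset_plane():
    a = _plane(0.0)
    b = _plane(1.0)
    assert surface_rmse(a, b) == pytest.approx(1.0)
    assert surface_rmse(a, b, symmetric=True) == pytest.approx(1.0)


def test_surface_rmse_directional_vs_symmetric_on_subpatch():
    patch = _plane(0.0, n=3)  # strict subregion of the big plane
    whole = TriMesh(_plane(0.0, 8).vertices, _plane(0.0, 8).triangles)
    d = surface_rmse(patch, whole)
    s = surface_rmse(patch, whole, symmetric=True)
    assert d == pytest.approx(0.0, abs=1e-12)
    assert s > d  # far vertices of the big plane have nowhere close to go


def test_surface_rmse_rigid_invariance(cube_mesh):
    from limbmorph.registration import RigidTransform

    th = 0.7
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    T = RigidTransform(R, np.array([5.0, 6.0, -2.0]))
    other = cube_mesh.with_vertices(cube_mesh.vertices * 1.1)
    before = surface_rmse(cube_mesh, other)
    after = surface_rmse(
        cube_mesh.with_vertices(T.apply(cube_mesh.vertices)),
        other.with_vertices(T.apply(other.vertices)),
    )
    assert after == pytest.approx(before, abs=1e-9)


def test_corresponding_point_rmse_pythagorean():
    a = np.array([[0.0, 0, 0]])
    b = np.array([[3.0, 4, 0]])
    assert corresponding_point_rmse(a, b) == 5.0
    assert corresponding_point_rmse(a, a) == 0.0
    with pytest.raises(ValueError):
        corresponding_point_rmse(a, np.zeros((2, 3)))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(1, 40))
def test_corresponding_point_rmse_matches_naive_loop(seed, n):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=(n, 3)), rng.normal(size=(n, 3))
    naive = np.sqrt(sum(np.sum((pa - pb) ** 2) for pa, pb in zip(a, b)) / n)
    assert abs(corresponding_point_rmse(a, b) - naive) < 1e-12


def test_per_point_variability_identical_sets():
    sets = [np.ones((5, 3))] * 4
    out = per_point_variability(sets)
    assert np.all(out["sd"] == 0)
    assert np.all(out["axis_sd"] == 0)


def test_per_point_variability_two_point_hand_case():
    d = 3.0
    sets = [np.array([[d, 0, 0]]), np.array([[-d, 0, 0]])]
    out = per_point_variability(sets)
    assert out["axis_sd"][0, 0] == pytest.approx(d * np.sqrt(2))
    assert out["sd"][0] == pytest.approx(d * np.sqrt(2))


def test_per_point_variability_isotropic_gaussian_ci():
    from scipy import stats

    rng = np.random.default_rng(6)
    n, sigma = 200, 2.0
    sets = [rng.normal(0, sigma, (10, 3)) for _ in range(n)]
    out = per_point_variability(sets)
    # chi-squared CI for a sample SD at n-1 dof
    lo = sigma * np.sqrt(stats.chi2.ppf(0.025, n - 1) / (n - 1))
    hi = sigma * np.sqrt(stats.chi2.ppf(0.975, n - 1) / (n - 1))
    inside = (out["axis_sd"] >= lo) & (out["axis_sd"] <= hi)
    assert inside.mean() > 0.8  # 30 SDs, 95% CI each


def test_holm_single_and_hand_case():
    np.testing.assert_allclose(holm_adjust([0.03]), [0.03])
    np.testing.assert_allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])


def test_holm_ties():
    np.testing.assert_allclose(holm_adjust([0.02, 0.02, 0.02]), [0.06, 0.06, 0.06])
    np.testing.assert_allclose(holm_adjust([0.5, 0.5]), [1.0, 1.0])


def test_holm_matches_reference_implementation_exhaustively():
    """Every permutation of a 4-element p-vector agrees with statsmodels."""
    from statsmodels.stats.multitest import multipletests

    base = [0.001, 0.02, 0.04, 0.2]
    for perm in itertools.permutations(base):
        ours = holm_adjust(list(perm))
        _, ref, _, _ = multipletests(list(perm), method="holm")
        np.testing.assert_allclose(ours, ref, atol=1e-12)


def test_holm_rejects_out_of_range():
    with pytest.raises(ValueError):
        holm_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        holm_adjust([-0.1])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
def test_holm_properties(ps):
    adj = holm_adjust(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(ps, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_compare_methods_identical_columns():
    table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
    rep = compare_methods(table)
    assert rep.anova_F == 0.0
    assert rep.anova_p == 1.0
    assert rep.pairwise is None


def test_compare_methods_detects_constant_shift():
    rng = np.random.default_rng(8)
    a = 5 + rng.normal(0, 0.3, 9)
    table = pd.DataFrame({"A": a, "B": a + 2.0 + rng.normal(0, 0.1, 9)})
    rep = compare_methods(table)
    assert rep.anova_p < 0.05
    assert rep.pairwise is not None
    assert float(rep.pairwise["p_holm"].iloc[0]) < 0.05
    assert ("A", "B") in rep.significant_pairs()


def test_paired_t_matches_closed_form_toy_table():
    table = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [2.1, 3.0, 4.2]})
    rep = compare_methods(table)
    d = table["A"] - table["B"]
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
    assert rep.pairwise is not None
    assert float(rep.pairwise["t"].iloc[0]) == pytest.approx(t_hand)


def test_rm_anova_matches_statsmodels():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(9)
    table = pd.DataFrame(
        {m: rng.normal(i, 1.0, 10) for i, m in enumerate(["L", "A", "N"])}
    )
    rep = compare_methods(table)
    long = table.reset_index().melt(id_vars="index", var_name="method", value_name="err")
    res = AnovaRM(long, "err", "index", within=["method"]).fit()
    assert rep.anova_F == pytest.approx(float(res.anova_table["F Value"].iloc[0]))
    assert rep.anova_p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]))


def test_compare_methods_input_validation():
    with pytest.raises(ValueError):
        compare_methods(pd.DataFrame({"a": [1.0, 2, 3]}))
    with pytest.raises(ValueError):
        compare_methods(pd.DataFrame({"a": [1.0, 2], "b": [1.0, 2]}))
    with pytest.raises(ValueError):
        compare_methods(pd.DataFrame({"a": [1.0, 2, np.nan], "b": [1.0, 2, 3]}))
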