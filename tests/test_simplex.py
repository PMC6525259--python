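"""Corner identification: planted geometry, tau sweep, Smart Corners."""

import numpy as np
import pytest

import linsimplex as ls
from linsimplex import dimension, simplex


def _triangle_cloud(n_interior=500, seed=0, drop_near_vertices=False):
    """Known triangle in 2-D: vertices + uniformly drawn interior points."""
    rng = np.random.default_rng(seed)
    verts = np.array([[0.0, 0.0], [1.0, 0.1], [0.4, 0.9]])
    bary = rng.dirichlet(np.ones(3), size=n_interior)
    pts = bary @ verts
    if drop_near_vertices:
        # no point with a dominant barycentric coordinate: the analogue of
        # removing signature genes
        pts = pts[bary.max(axis=1) < 0.85]
    else:
        pts = np.vstack([verts, pts])
    return verts, pts.T  # corners (3,2), points (2,N)


def _max_vertex_error(found, verts):
    matched = simplex.match_corners(verts, found)
    edge = np.mean(
        [np.linalg.norm(verts[i] - verts[j]) for i in range(3) for j in range(i + 1, 3)]
    )
    return np.linalg.norm(matched - verts, axis=1).max() / edge


class TestFindCorners:
    def test_planted_triangle_exact_with_enclosure(self):
        # with the vertices present in the data, the minimum-volume fit at
        # the containment end of the tau grid plus facet-wise enclosure
        # recovers them to numerical precision
        verts, pts = _triangle_cloud()
        corners = simplex.find_corners(pts, 3, tau=1.0, seed=0)
        enclosed = simplex.expand_to_enclose(corners, pts)
        assert _max_vertex_error(enclosed, verts) < 1e-6

    def test_vca_picks_data_points(self):
        verts, pts = _triangle_cloud()
        corners = simplex.find_corners(pts, 3, method="vca")
        # every corner is a member of the input cloud
        for c in corners:
            dists = np.linalg.norm(pts - c[:, None], axis=0)
            assert dists.min() < 1e-12
        assert _max_vertex_error(corners, verts) < 1e-6  # vertices are in the data

    def test_truncated_cloud_sisal_beats_vca(self):
        """Without near-vertex points the extreme-point picker cannot reach
        the vertices while the minimum-volume fit still extrapolates them."""
        verts, pts = _triangle_cloud(n_interior=4000, seed=1, drop_near_vertices=True)
        sol_err = {}
        for method in ("sisal", "vca"):
            corners = simplex.find_corners(pts, 3, tau=0.25, method=method, seed=0)
            if method == "sisal":
                corners = simplex.expand_to_enclose(corners, pts)
            sol_err[method] = _max_vertex_error(corners, verts)
        assert sol_err["sisal"] < 0.02
        assert sol_err["vca"] > sol_err["sisal"]

    def test_k2_segment_endpoints(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-1.0, 3.0, size=(1, 200))
        pts[0, 0], pts[0, 1] = -1.0, 3.0
        corners = simplex.find_corners(pts, 2, tau=0.5, seed=0)
        corners = simplex.expand_to_enclose(corners, pts)
        got = sorted(corners.ravel())
        assert got[0] == pytest.approx(-1.0, abs=1e-6)
        assert got[1] == pytest.approx(3.0, abs=1e-6)

    def test_input_validation(self):
        pts = np.zeros((2, 10))
        with pytest.raises(ValueError):
            simplex.find_corners(pts, 1)
        with pytest.raises(ValueError):
            simplex.find_corners(pts, 4)  # dims disagree
        with pytest.raises(ValueError):
            simplex.find_corners(np.zeros((2, 2)), 3)  # too few points

    def test_gene_order_invariance(self, rng):
        verts, pts = _triangle_cloud(300, seed=5)
        a = simplex.find_corners(pts, 3, tau=0.25, seed=1)
        perm = rng.permutation(pts.shape[1])
        b = simplex.find_corners(pts[:, perm], 3, tau=0.25, seed=1)
        np.testing.assert_allclose(
            simplex.match_corners(a, b), a, atol=1e-6
        )


class TestDefaultGrid:
    def test_grid_is_21_powers_of_two(self):
        grid = simplex.default_tau_grid()
        assert len(grid) == 21
        np.testing.assert_allclose(grid[0], 2.0**-20)
        np.testing.assert_allclose(grid[-1], 1.0)
        np.testing.assert_allclose(np.diff(np.log2(grid)), 1.0)


@pytest.fixture(scope="module")
def fitted_projection(small_mixture_module):
    expr, truth = small_mixture_module
    norm = ls.row_normalize(expr)
    return expr, truth, norm, dimension.project(norm, 3)


@pytest.fixture(scope="session")
def small_mixture_module():
    return ls.simulate_dataset(n_genes=1_500, m_samples=24, k_types=3,
                               noise_sd=0.0, seed=11)


class TestSweepTau:
    def test_noiseless_recovery_and_table(self, fitted_projection):
        expr, truth, norm, proj = fitted_projection
        sol = simplex.sweep_tau(proj, norm, seed=0)
        relerr = sol.reconstruction_error / np.linalg.norm(norm.values, "fro")
        assert relerr < 1e-6
        assert len(sol.tau_table) == 21
        Ht = truth.H / truth.H.sum(axis=1, keepdims=True)
        # corner accuracy is limited by how closely the most type-specific
        # genes approach the facets (~1e-3 at 1,500 genes)
        np.testing.assert_allclose(
            simplex.match_corners(Ht, sol.corners_sample_space), Ht, atol=5e-3
        )

    def test_deterministic_given_seed(self, fitted_projection):
        _, _, norm, proj = fitted_projection
        grid = np.exp2(np.arange(-6, 1, dtype=float))
        a = simplex.sweep_tau(proj, norm, tau_grid=grid, seed=3)
        b = simplex.sweep_tau(proj, norm, tau_grid=grid, seed=3)
        np.testing.assert_array_equal(
            a.tau_table["reconstruction_error"],
            b.tau_table["reconstruction_error"],
        )
        np.testing.assert_array_equal(a.corners_projected, b.corners_projected)

    def test_empty_grid_rejected(self, fitted_projection):
        _, _, norm, proj = fitted_projection
        with pytest.raises(ValueError):
            simplex.sweep_tau(proj, norm, tau_grid=np.array([]))


class TestSmartCorners:
    def test_budget_one_reduces_to_single_tau(self, fitted_projection):
        _, _, norm, proj = fitted_projection
        grid = np.exp2(np.arange(-4, 1, dtype=float))
        single = simplex.sweep_tau(proj, norm, tau_grid=grid, seed=0)
        smart = simplex.smart_corners(
            proj, norm, tau_grid=grid, max_combinations=1, seed=0
        )
        np.testing.assert_array_equal(
            smart.corners_projected, single.corners_projected
        )

    def test_never_worse_than_single_tau(self, fitted_projection):
        _, _, norm, proj = fitted_projection
        grid = np.exp2(np.arange(-4, 1, dtype=float))
        single = simplex.sweep_tau(proj, norm, tau_grid=grid, seed=0)
        smart = simplex.smart_corners(
            proj, norm, tau_grid=grid, max_combinations=27, seed=0
        )
        assert smart.reconstruction_error <= single.reconstruction_error + 1e-12


class TestBackprojectCorners:
    def test_true_corner_round_trip(self, fitted_projection):
        _, truth, _, proj = fitted_projection
        Ht = truth.H / truth.H.sum(axis=1, keepdims=True)
        projected = (proj.basis @ Ht.T).T
        back = simplex.backproject_corners(projected, proj)
        np.testing.assert_allclose(back, Ht, atol=1e-6)

    def test_gene_point_reproduced(self, fitted_projection):
        _, _, norm, proj = fitted_projection
        coords = proj.projected[:, 7]
        back = simplex.backproject_corners(coords[None, :], proj)
        np.testing.assert_allclose(back[0], norm.values[7], atol=1e-8)

    def test_tiny_negative_clipped_silently(self, fitted_projection):
        _, truth, _, proj = fitted_projection
        Ht = truth.H / truth.H.sum(axis=1, keepdims=True)
        projected = (proj.basis @ Ht.T).T
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("error")  # no warning expected for -1e-9 dust
            back = simplex.backproject_corners(projected + 1e-12, proj)
        np.testing.assert_allclose(back.sum(axis=1), 1.0, atol=1e-12)


class TestCornerGenes:
    def test_gene_at_corner_ranked_first(self):
        pts = np.array([[0.0, 0.5, 1.0], [0.0, 0.5, 0.0]])
        corners = np.array([[0.0, 0.0], [1.0, 0.0]])
        lists = simplex.corner_genes(pts, corners, ["a", "b", "c"], g_top=2)
        assert lists[0]["gene"].iloc[0] == "a"
        assert lists[0]["distance"].iloc[0] == 0.0
        assert lists[1]["gene"].iloc[0] == "c"

    def test_g_top_bounds(self):
        pts = np.zeros((1, 3))
        with pytest.raises(ValueError):
            simplex.corner_genes(pts, np.zeros((2, 1)), g_top=10)

    def test_planted_type_purity(self, fitted_projection):
        expr, truth, norm, proj = fitted_projection
        sol = simplex.sweep_tau(proj, norm, seed=0, g_top=50)
        Wn = truth.W + 1.0
        Wn = Wn / Wn.sum(axis=1, keepdims=True)
        gid = {g: i for i, g in enumerate(expr.gene_ids)}
        for tab in sol.corner_gene_lists:
            types = {int(np.argmax(Wn[gid[g]])) for g in tab["gene"]}
            assert len(types) == 1
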