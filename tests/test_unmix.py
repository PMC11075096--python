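"""K-means endmember discovery, cluster ranking and NNLS abundances."""

import numpy as np
import pytest

from hsdfm import (
    ReflectanceCube,
    WavelengthGrid,
    abundance_composite,
    abundance_to_maps,
    generate_cube,
    kmeans_endmembers,
    nnls_abundances,
    normalize_cube,
    rank_clusters,
    spectral_angle,
    stack_cubes,
)
from hsdfm.datacube import ConfigurationError
from hsdfm.unmix import AbundanceMatrix, PixelMatrix

from conftest import three_stripe_spec


def toy_matrix(X):
    X = np.asarray(X, dtype=float)
    g = WavelengthGrid(np.arange(500.0, 500.0 + 10.0 * X.shape[1], 10.0))
    return PixelMatrix(X=X, shapes=[(X.shape[0], 1)], grid=g)


class TestStackCubes:
    def test_single_cube_shape(self, grid):
        cube = ReflectanceCube(np.random.default_rng(0).random((2, 2, grid.n_bands)), grid)
        pm = stack_cubes([cube])
        assert pm.X.shape == (4, grid.n_bands)

    def test_two_cubes_row_count(self, grid):
        rng = np.random.default_rng(1)
        a = ReflectanceCube(rng.random((2, 3, grid.n_bands)), grid)
        b = ReflectanceCube(rng.random((4, 4, grid.n_bands)), grid)
        pm = stack_cubes([a, b])
        assert pm.X.shape[0] == 6 + 16

    def test_unstack_round_trip(self, grid):
        rng = np.random.default_rng(2)
        a = ReflectanceCube(rng.random((3, 5, grid.n_bands)), grid)
        b = ReflectanceCube(rng.random((2, 2, grid.n_bands)), grid)
        pm = stack_cubes([a, b])
        col = pm.X[:, 7]
        rasters = pm.unstack(col)
        assert np.array_equal(rasters[0], a.values[:, :, 7])
        assert np.array_equal(rasters[1], b.values[:, :, 7])


class TestKMeans:
    def test_two_separated_clouds_exact(self):
        X = np.vstack([np.tile([1.0, 0.0], (20, 1)), np.tile([0.0, 1.0], (20, 1))])
        cr = kmeans_endmembers(toy_matrix(X), k=2, restarts=3, seed=0)
        cents = sorted(map(tuple, cr.centroids))
        assert cents == [(0.0, 1.0), (1.0, 0.0)]
        assert cr.objective == 0.0

    def test_best_restart_objective(self):
        rng = np.random.default_rng(3)
        X = rng.random((60, 4))
        cr = kmeans_endmembers(toy_matrix(X), k=4, restarts=8, seed=1)
        assert cr.objective == pytest.approx(min(cr.restart_objectives))
        assert all(cr.objective <= o + 1e-12 for o in cr.restart_objectives)

    def test_objective_matches_direct_recomputation(self):
        rng = np.random.default_rng(4)
        X = rng.random((80, 5))
        cr = kmeans_endmembers(toy_matrix(X), k=3, restarts=5, seed=2)
        direct = sum(
            np.sum((X[cr.assignment == i] - cr.centroids[i]) ** 2)
            for i in range(cr.k)
        )
        assert cr.objective == pytest.approx(direct, rel=1e-9)
        # centroids are the means of their members
        for i in range(cr.k):
            assert np.allclose(cr.centroids[i], X[cr.assignment == i].mean(axis=0))

    def test_recovers_planted_templates(self, templates, template_map):
        scene = generate_cube(three_stripe_spec(shape=(24, 24)), templates)
        cube = normalize_cube(scene.sample, scene.dark, scene.reference)
        pm = stack_cubes([cube])
        cr = kmeans_endmembers(pm, k=3, restarts=5, seed=0)
        for c in cr.centroids:
            best = min(
                spectral_angle(c, template_map[lbl].spectrum)
                for lbl in ("blood", "ICT1", "fat")
            )
            assert best < 1e-9

    def test_k_exceeding_distinct_rows_raises(self):
        X = np.tile([1.0, 2.0], (10, 1))
        with pytest.raises(ConfigurationError):
            kmeans_endmembers(toy_matrix(X), k=2, restarts=1, seed=0)

    def test_seeded_rerun_identical(self):
        rng = np.random.default_rng(5)
        X = rng.random((50, 6))
        a = kmeans_endmembers(toy_matrix(X), k=3, restarts=4, seed=9)
        b = kmeans_endmembers(toy_matrix(X), k=3, restarts=4, seed=9)
        assert a.centroids.tobytes() == b.centroids.tobytes()
        assert np.array_equal(a.assignment, b.assignment)

    def test_agrees_with_sklearn_on_easy_problem(self):
        """Independent cross-check: same optimum as sklearn's K-means."""
        sklearn = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(6)
        centers = np.array([[0.0, 0.0, 0.0], [5.0, 5.0, 5.0], [0.0, 5.0, 0.0]])
        X = np.vstack([c + 0.05 * rng.standard_normal((30, 3)) for c in centers])
        ours = kmeans_endmembers(toy_matrix(X), k=3, restarts=5, seed=0)
        theirs = sklearn.KMeans(n_clusters=3, n_init=5, random_state=0).fit(X)
        assert ours.objective == pytest.approx(theirs.inertia_, rel=1e-9)


class TestRankClusters:
    def test_single_cluster_degenerate(self):
        X = np.random.default_rng(7).random((10, 3))
        cr = kmeans_endmembers(toy_matrix(X), k=1, restarts=1, seed=0)
        ranking = rank_clusters(cr, toy_matrix(X))
        assert ranking.degenerate
        assert np.allclose(ranking.shares, 0.0)

    def test_symmetric_clusters_share_equally(self):
        X = np.vstack([np.tile([1.0, 0.0], (15, 1)), np.tile([-1.0, 0.0], (15, 1))])
        cr = kmeans_endmembers(toy_matrix(X), k=2, restarts=3, seed=0)
        ranking = rank_clusters(cr, toy_matrix(X))
        assert np.allclose(ranking.shares, [0.5, 0.5])

    def test_shares_match_direct_recomputation(self):
        rng = np.random.default_rng(8)
        X = rng.random((40, 4))
        cr = kmeans_endmembers(toy_matrix(X), k=3, restarts=4, seed=1)
        ranking = rank_clusters(cr, toy_matrix(X))
        xbar = X.mean(axis=0)
        scores = np.array([
            (cr.assignment == i).sum() * np.sum((cr.centroids[i] - xbar) ** 2)
            for i in range(3)
        ])
        assert np.allclose(ranking.shares, scores / scores.sum())
        assert list(ranking.order) == list(np.argsort(-ranking.shares, kind="stable"))


class TestNNLS:
    def test_orthonormal_columns_identity(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        ab = nnls_abundances(np.array([[0.3, 0.7]]), U)
        assert np.allclose(ab.M, [[0.3, 0.7]])

    def test_single_endmember_closed_form(self):
        U = np.array([[1.0], [1.0]])
        ab = nnls_abundances(np.array([[1.0, 2.0]]), U)
        assert ab.M[0, 0] == pytest.approx(1.5)

    def test_active_constraint_kkt_case(self):
        # unconstrained solution (-1, 1) is infeasible; NNLS gives (0, 0.5)
        U = np.array([[1.0, 1.0], [0.0, 1.0]])
        ab = nnls_abundances(np.array([[0.0, 1.0]]), U)
        assert np.allclose(ab.M, [[0.0, 0.5]], atol=1e-12)

    def test_residual_no_worse_than_zero_vector(self):
        rng = np.random.default_rng(9)
        X = rng.random((30, 6))
        U = rng.random((6, 3))
        ab = nnls_abundances(X, U)
        for j in range(30):
            res = np.linalg.norm(U @ ab.M[j] - X[j])
            assert res <= np.linalg.norm(X[j]) + 1e-12

    def test_pure_pixel_identifiability(self):
        rng = np.random.default_rng(10)
        U = rng.uniform(0.5, 2.0, size=(8, 3))
        ab = nnls_abundances(U.T.copy(), U)   # pixels are the endmembers themselves
        assert np.allclose(ab.M, np.eye(3), atol=1e-9)

    def test_rank_deficient_warns(self):
        U = np.array([[1.0, 2.0], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="rank deficient"):
            nnls_abundances(np.array([[1.0, 1.0]]), U)

    def test_nonnegativity_enforced(self):
        with pytest.raises(ConfigurationError):
            AbundanceMatrix(M=np.array([[-0.1]]), U=np.array([[1.0]]))


class TestAbundanceMaps:
    def test_reshape_round_trip_and_composite(self):
        rng = np.random.default_rng(11)
        X = rng.random((12, 4))
        pm = toy_matrix(X)
        pm.shapes = [(3, 4)]
        U = rng.uniform(0.5, 1.5, size=(4, 3))
        ab = nnls_abundances(pm, U)
        maps = abundance_to_maps(ab, pm)
        assert len(maps) == 3
        assert maps[0][0].shape == (3, 4)
        assert np.allclose(maps[1][0].ravel(), ab.M[:, 1])
        rgb = abundance_composite(ab, pm, [2, 0, 1])
        assert rgb.shape == (3, 4, 3)
        assert rgb.max() <= 1.0 + 1e-12

    def test_pure_and_mixed_pixels_in_composite(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # 3 bands, 2 endmembers
        X = np.array([
            U[:, 0],                        # pure endmember 0
            U[:, 1],                        # pure endmember 1
            0.5 * U[:, 0] + 0.5 * U[:, 1],  # balanced mixture
        ])
        pm = PixelMatrix(X=X, shapes=[(1, 3)],
                         grid=WavelengthGrid(np.array([500.0, 510.0, 520.0])))
        ab = nnls_abundances(pm, U)
        assert np.allclose(ab.M[0], [1.0, 0.0], atol=1e-10)
        assert np.allclose(ab.M[2], [0.5, 0.5], atol=1e-10)
        rgb = abundance_composite(ab, pm, [0, 1])
        assert rgb[0, 0, 0] == pytest.approx(1.0)    # pure pixel: full red channel
        assert rgb[0, 0, 1] == pytest.approx(0.0)
        assert rgb[0, 2, 0] == pytest.approx(rgb[0, 2, 1])  # mixed: equal channels
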