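"""Resolution functions, spectral bounds, scaling, and classical MDS."""

import numpy as np
import pytest
import scipy.sparse as sp

import treeshape as ts
from treeshape.nni import DistanceMatrix
from treeshape.resolution import SpectralBounds


def tiny_dist(D) -> DistanceMatrix:
    return DistanceMatrix(space=None, distances=np.asarray(D, dtype=np.int16))


class TestResolutionD:
    def test_two_point_hand_value(self):
        # D = [[0,1],[1,0]], x = (1/sqrt2, -1/sqrt2):
        # -1/2 * sum d_ij^2 x_i x_j = -1/2 * 2 * 1 * (-1/2) = 1/2
        x = np.array([1.0, -1.0]) / np.sqrt(2.0)
        assert ts.resolution_D(x, tiny_dist([[0, 1], [1, 0]])) == pytest.approx(0.5)

    def test_equals_xd_quadratic_form(self, cache, rng):
        # Eq-1 form equals x^t X_D x for centered unit x
        dm = cache.dist(9)
        n = dm.distances.shape[0]
        H = np.eye(n) - 1.0 / n
        XD = -0.5 * (H @ dm.squared @ H)
        for _ in range(5):
            x = rng.standard_normal(n)
            x -= x.mean()
            x /= np.linalg.norm(x)
            assert ts.resolution_D(x, dm) == pytest.approx(
                float(x @ XD @ x), abs=1e-10)

    def test_naive_pair_loop_oracle(self, cache, classical_names):
        # -1/2 sum_ij d_ij^2 x_i x_j summed explicitly over all pairs
        for l in (6, 8):
            dm = cache.dist(l)
            D = dm.distances.astype(float)
            for name in classical_names:
                x = cache.vector(l, name).centered_unit
                naive = -0.5 * sum(
                    D[i, j] ** 2 * x[i] * x[j]
                    for i in range(len(x)) for j in range(len(x)))
                assert ts.resolution_D(x, dm) == pytest.approx(naive, abs=1e-10)

    def test_dimension_mismatch(self, cache):
        with pytest.raises(ValueError):
            ts.resolution_D(np.zeros(3), cache.dist(7))


class TestResolutionL:
    def test_naive_edge_loop_oracle(self, cache, classical_names):
        for l in (6, 8):
            g = cache.graph(l)
            L = cache.lap(l)
            edges = g.edge_list()
            for name in classical_names:
                x = cache.vector(l, name).centered_unit
                naive = sum((x[i] - x[j]) ** 2 for i, j in edges)
                assert ts.resolution_L(x, L) == pytest.approx(naive, abs=1e-10)

    def test_dimension_mismatch(self, cache):
        with pytest.raises(ValueError):
            ts.resolution_L(np.zeros(3), cache.lap(7))


class TestBounds:
    def test_path3_laplacian(self):
        adj = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        L = ts.laplacian(ts.CayleyGraph(space=None, adjacency=adj))
        b = ts.bounds_laplacian(L)
        assert b.lower == pytest.approx(1.0, abs=1e-9)
        assert b.upper == pytest.approx(3.0, abs=1e-9)

    def test_two_point_distance(self):
        b = ts.bounds_distance(tiny_dist([[0, 1], [1, 0]]))
        assert b.lower == pytest.approx(0.5, abs=1e-9)
        assert b.upper == pytest.approx(0.5, abs=1e-9)

    def test_fiedler_positive(self, cache):
        for l in range(4, 13):
            assert cache.bounds_l(l).lower > 0

    def test_sparse_path_matches_dense(self, cache):
        # force the iterative path on a graph small enough to also solve densely
        import treeshape.resolution as res
        L = cache.lap(11)
        dense = ts.bounds_laplacian(L)
        old = res._DENSE_LIMIT
        res._DENSE_LIMIT = 10
        try:
            sparse_b = ts.bounds_laplacian(L)
            dm = cache.dist(11)
            sparse_d = ts.bounds_distance(dm)
        finally:
            res._DENSE_LIMIT = old
        dense_d = ts.bounds_distance(cache.dist(11))
        assert sparse_b.lower == pytest.approx(dense.lower, rel=1e-7)
        assert sparse_b.upper == pytest.approx(dense.upper, rel=1e-7)
        assert sparse_d.lower == pytest.approx(dense_d.lower, rel=1e-6)
        assert sparse_d.upper == pytest.approx(dense_d.upper, rel=1e-6)

    def test_disconnected_laplacian_rejected(self):
        adj = sp.csr_matrix(np.array([[0, 1, 0, 0], [1, 0, 0, 0],
                                      [0, 0, 0, 1], [0, 0, 1, 0]]))
        L = ts.laplacian(ts.CayleyGraph(space=None, adjacency=adj))
        with pytest.raises(ValueError, match="disconnected"):
            ts.bounds_laplacian(L)


class TestScaledResolution:
    def test_rayleigh_bracketing(self, cache, classical_names):
        for l in (7, 9, 10):
            bd, bl = cache.bounds_d(l), cache.bounds_l(l)
            for name in classical_names:
                vec = cache.vector(l, name)
                rd = ts.resolution_report(vec, cache.dist(l), "distance", bd)
                rl = ts.resolution_report(vec, cache.lap(l), "laplacian", bl)
                for rep in (rd, rl):
                    assert rep.lower - 1e-9 <= rep.raw <= rep.upper + 1e-9
                    assert 0.0 - 1e-9 <= rep.scaled <= 1.0 + 1e-9

    def test_extreme_eigenvectors_hit_bounds(self, cache):
        L = cache.lap(8)
        vals, vecs = np.linalg.eigh(L.toarray())
        fiedler, top = vecs[:, 1], vecs[:, -1]
        b = cache.bounds_l(8)
        assert ts.scaled_resolution(ts.resolution_L(fiedler, L), b) == \
            pytest.approx(0.0, abs=1e-9)
        assert ts.scaled_resolution(ts.resolution_L(top, L), b) == \
            pytest.approx(1.0, abs=1e-9)

    def test_sign_invariance(self, cache):
        vec = cache.vector(9, "sackin")
        neg = ts.StatVector("neg", vec.space, -vec.values)
        for function, operand, b in (
            ("distance", cache.dist(9), cache.bounds_d(9)),
            ("laplacian", cache.lap(9), cache.bounds_l(9)),
        ):
            r1 = ts.resolution_report(vec, operand, function, b)
            r2 = ts.resolution_report(neg, operand, function, b)
            assert r1.scaled == pytest.approx(r2.scaled, abs=1e-12)

    def test_affine_invariance(self, cache):
        vec = cache.vector(9, "colless")
        aff = ts.StatVector("aff", vec.space, 7.5 * vec.values - 2.0)
        r1 = ts.resolution_report(vec, cache.lap(9), "laplacian", cache.bounds_l(9))
        r2 = ts.resolution_report(aff, cache.lap(9), "laplacian", cache.bounds_l(9))
        assert r1.scaled == pytest.approx(r2.scaled, abs=1e-12)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ts.scaled_resolution(0.3, SpectralBounds("L", 1.0, 1.0))


class TestMDS:
    def test_two_points(self):
        pts = ts.mds_embed(tiny_dist([[0, 4], [4, 0]]), dims=1)
        assert sorted(pts[:, 0]) == pytest.approx([-2.0, 2.0])

    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        pts = ts.mds_embed(D, dims=2)
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(pts[i] - pts[j]) == pytest.approx(
                    1.0, abs=1e-9)

    def test_strain_decreases_with_dims(self, cache):
        dm = cache.dist(9)
        D2 = dm.squared

        def strain(dims):
            pts = ts.mds_embed(dm, dims=dims)
            G = pts @ pts.T
            n = G.shape[0]
            H = np.eye(n) - 1.0 / n
            XD = -0.5 * (H @ D2 @ H)
            return np.linalg.norm(XD - G)

        s1, s2, s3 = strain(1), strain(2), strain(3)
        assert s1 >= s2 >= s3

    def test_rank_deficient_padding(self):
        pts = ts.mds_embed(tiny_dist([[0, 3], [3, 0]]), dims=3)
        assert pts.shape == (2, 3)
        np.testing.assert_allclose(pts[:, 1:], 0.0)
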