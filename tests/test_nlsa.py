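import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trsfx.core import MillerIndexSet
from trsfx.nlsa import (
    EmbeddingConfig,
    delay_embed,
    diagonal_average,
    diffusion_basis,
    embedded_distances,
    markov_matrix,
    nlsa_run,
    project,
    reconstruct_embedded,
    svd_modes,
)
from trsfx.preprocess import DenseSeries


def _dense(values, timestamps=None):
    """Wrap a raw (D, N) array as a DenseSeries with trivial constants."""
    values = np.asarray(values, dtype=float)
    D, N = values.shape
    iset = MillerIndexSet(
        np.column_stack([np.arange(1, D + 1), np.zeros(D, int), np.zeros(D, int)]),
        np.linspace(0.1, 0.5, D),
    )
    return DenseSeries(
        values=values,
        mask=np.ones((D, N), dtype=bool),
        mean=np.zeros(D),
        std=np.ones(D),
        timestamps=np.arange(N, dtype=float) if timestamps is None else timestamps,
        index_set=iset,
    )


class TestDelayEmbed:
    def test_hand_checkable_columns(self):
        X = delay_embed(np.array([[1.0, 2.0, 3.0, 4.0]]), c=2)
        assert X.shape == (2, 3)
        expected = np.array([[2.0, 3.0, 4.0], [1.0, 2.0, 3.0]])
        assert np.array_equal(X.dense(), expected)

    def test_c_one_is_identity(self, rng):
        vals = rng.random((4, 6))
        X = delay_embed(vals, c=1)
        assert np.array_equal(X.dense(), vals)

    def test_hankel_structure(self, rng):
        vals = rng.random((3, 10))
        X = delay_embed(vals, c=4)
        for t in range(1, X.n):
            assert np.array_equal(X.dense()[3:6, t], X.dense()[0:3, t - 1])

    def test_columns_match_blocks(self, rng):
        vals = rng.random((3, 9))
        X = delay_embed(vals, c=3)
        dense = X.dense()
        for j in range(X.n):
            assert np.array_equal(X.column(j), dense[:, j])

    def test_c_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            delay_embed(rng.random((2, 5)), c=5)


class TestEmbeddedDistances:
    def test_duplicate_columns_zero_distance(self):
        vals = np.tile(np.array([[1.0], [2.0]]), (1, 6))
        X = delay_embed(vals, c=2)
        g = embedded_distances(X, knn=2)
        assert np.all(g.d2 == 0.0)
        assert len(g.row) > 0  # zero-distance edges must survive

    def test_c_one_equals_plain_distances(self, rng):
        vals = rng.random((5, 12))
        X = delay_embed(vals, c=1)
        g = embedded_distances(X, knn=11)
        d2 = g.to_dense_d2()
        diff = vals[:, :, None] - vals[:, None, :]
        expected = (diff**2).sum(axis=0)
        assert np.allclose(d2, expected, atol=1e-10)

    def test_sliding_window_matches_brute_force(self, rng):
        # brute-force oracle: concatenate supervectors and take Euclidean
        D, c, n = 7, 5, 50
        vals = rng.standard_normal((D, n + c - 1))
        X = delay_embed(vals, c=c)
        g = embedded_distances(X, knn=n - 1)
        got = g.to_dense_d2()
        sup = np.stack([X.column(j) for j in range(n)], axis=1)
        diff = sup[:, :, None] - sup[:, None, :]
        expected = (diff**2).sum(axis=0)
        scale = np.maximum(expected, 1.0)
        assert np.max(np.abs(got - expected) / scale) < 1e-10

    def test_knn_bounds(self, rng):
        X = delay_embed(rng.random((2, 8)), c=2)
        with pytest.raises(ValueError):
            embedded_distances(X, knn=0)
        with pytest.raises(ValueError):
            embedded_distances(X, knn=7)

    def test_graph_symmetric(self, rng):
        X = delay_embed(rng.random((3, 30)), c=4)
        g = embedded_distances(X, knn=5)
        pairs = set(zip(g.row.tolist(), g.col.tolist()))
        assert all((j, i) in pairs for i, j in pairs)


class TestDiffusionBasis:
    def _graph(self, rng, n=60, D=4):
        vals = rng.standard_normal((D, n))
        X = delay_embed(vals, c=1)
        return embedded_distances(X, knn=10)

    def test_markov_rows_sum_to_one(self, rng):
        g = self._graph(rng)
        P, mu = markov_matrix(g, epsilon=0.5)
        rows = np.asarray(P.sum(axis=1)).ravel()
        assert np.allclose(rows, 1.0, atol=1e-12)

    def test_mu_is_stationary(self, rng):
        g = self._graph(rng)
        P, mu = markov_matrix(g, epsilon=0.5)
        assert mu.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(mu @ P.toarray(), mu, atol=1e-12)

    def test_leading_eigenpair_trivial(self, rng):
        basis = diffusion_basis(self._graph(rng), n_basis=6)
        assert basis.eigenvalues[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(basis.phi[:, 0], basis.phi[0, 0], atol=1e-9)
        assert basis.phi[0, 0] > 0

    def test_mu_orthonormality(self, rng):
        basis = diffusion_basis(self._graph(rng), n_basis=8)
        gram = basis.phi.T @ (basis.mu[:, None] * basis.phi)
        assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_eigenvalues_non_increasing(self, rng):
        basis = diffusion_basis(self._graph(rng), n_basis=8)
        assert np.all(np.diff(basis.eigenvalues) <= 1e-12)

    def test_two_clusters_split_by_first_eigenfunction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.05, (3, 25))
        b = rng.normal(5.0, 0.05, (3, 25))
        vals = np.concatenate([a, b], axis=1)
        X = delay_embed(vals, c=1)
        g = embedded_distances(X, knn=30)
        basis = diffusion_basis(g, n_basis=3)
        signs = np.sign(basis.phi[:, 1])
        assert len(set(signs[:25])) == 1
        assert len(set(signs[25:])) == 1
        assert signs[0] != signs[25]

    def test_disconnected_graph_rejected(self):
        # two clusters, knn=1 with a gap so the union graph splits
        vals = np.array([[0.0, 0.01, 10.0, 10.01]])
        X = delay_embed(vals, c=1)
        g = embedded_distances(X, knn=1)
        with pytest.raises(ValueError, match="knn"):
            diffusion_basis(g, n_basis=2)

    def test_basis_too_large_rejected(self, rng):
        g = self._graph(rng, n=20)
        with pytest.raises(ValueError):
            diffusion_basis(g, n_basis=21)


class TestProject:
    def test_constant_basis_gives_weighted_mean(self, rng):
        vals = rng.random((3, 10))
        X = delay_embed(vals, c=2)
        n = X.n
        mu = rng.random(n)
        mu /= mu.sum()
        phi = np.ones((n, 1))
        from trsfx.nlsa import ManifoldBasis

        basis = ManifoldBasis(phi=phi, mu=mu, eigenvalues=np.array([1.0]), epsilon=1.0)
        A = project(X, basis)
        expected = X.dense() @ mu
        assert np.allclose(A[:, 0], expected, atol=1e-12)

    def test_matches_dense_triple_product(self, rng):
        vals = rng.standard_normal((4, 15))
        X = delay_embed(vals, c=3)
        n = X.n
        mu = rng.random(n)
        mu /= mu.sum()
        phi = rng.standard_normal((n, 5))
        from trsfx.nlsa import ManifoldBasis

        basis = ManifoldBasis(phi=phi, mu=mu, eigenvalues=np.ones(5), epsilon=1.0)
        A = project(X, basis)
        expected = X.dense() @ np.diag(mu) @ phi
        assert np.max(np.abs(A - expected)) < 1e-10

    def test_shape_mismatch_rejected(self, rng):
        vals = rng.random((2, 8))
        X = delay_embed(vals, c=2)
        from trsfx.nlsa import ManifoldBasis

        basis = ManifoldBasis(
            phi=np.ones((3, 1)), mu=np.full(3, 1 / 3), eigenvalues=np.ones(1), epsilon=1.0
        )
        with pytest.raises(ValueError):
            project(X, basis)


class TestSvdModes:
    def test_rank_one_recovery(self, rng):
        u = rng.standard_normal(12)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(4)
        v /= np.linalg.norm(v)
        A = 3.5 * np.outer(u, v)
        modes = svd_modes(A)
        assert modes.s[0] == pytest.approx(3.5, abs=1e-10)
        assert np.allclose(np.abs(modes.u[:, 0]), np.abs(u), atol=1e-10)

    def test_frobenius_identity(self, rng):
        A = rng.standard_normal((20, 6))
        modes = svd_modes(A)
        assert (modes.s**2).sum() == pytest.approx((A**2).sum(), rel=1e-8)

    def test_diagonal_matrix(self):
        A = np.diag([3.0, -7.0, 1.0])
        modes = svd_modes(A)
        assert np.allclose(modes.s, [7.0, 3.0, 1.0])

    def test_sign_convention_deterministic(self, rng):
        A = rng.standard_normal((10, 4))
        m1, m2 = svd_modes(A), svd_modes(A.copy())
        assert np.array_equal(m1.u, m2.u)
        for k in range(m1.u.shape[1]):
            assert m1.u[np.argmax(np.abs(m1.u[:, k])), k] > 0

    def test_reconstructs_input(self, rng):
        A = rng.standard_normal((9, 5))
        m = svd_modes(A)
        assert np.allclose(m.u @ np.diag(m.s) @ m.v.T, A, atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svd_modes(np.array([[1.0, np.nan]]))


class TestReconstructAndAverage:
    def _full_setup(self, rng, D=3, N=14, c=4):
        vals = rng.standard_normal((D, N))
        X = delay_embed(vals, c=c)
        n = X.n
        g = embedded_distances(X, knn=n - 1)
        basis = diffusion_basis(g, n_basis=n)
        A = project(X, basis)
        modes = svd_modes(A)
        return vals, X, basis, modes

    def test_full_basis_identity(self, rng):
        # K = n, M = K: diag(mu) Phi Phi^T = I, so X~ = X exactly
        vals, X, basis, modes = self._full_setup(rng)
        x_emb = reconstruct_embedded(modes, basis, n_modes=basis.n_basis, c=X.c)
        assert np.max(np.abs(x_emb.dense() - X.dense())) < 1e-6

    def test_zero_modes_give_zero(self, rng):
        vals, X, basis, modes = self._full_setup(rng)
        x_emb = reconstruct_embedded(modes, basis, n_modes=0, c=X.c)
        assert np.all(x_emb.dense() == 0.0)

    def test_frobenius_monotone_in_modes(self, rng):
        vals, X, basis, modes = self._full_setup(rng)
        norms = [
            np.linalg.norm(reconstruct_embedded(modes, basis, m, X.c).dense())
            for m in range(basis.n_basis + 1)
        ]
        assert np.all(np.diff(norms) >= -1e-9)

    def test_too_many_modes_rejected(self, rng):
        vals, X, basis, modes = self._full_setup(rng)
        with pytest.raises(ValueError):
            reconstruct_embedded(modes, basis, n_modes=basis.n_basis + 1, c=X.c)

    def test_diagonal_average_inverts_hankel(self, rng):
        # exact Hankel input round-trips to the original series
        vals = rng.standard_normal((3, 11))
        X = delay_embed(vals, c=4)
        out = diagonal_average(X.dense(), c=4)
        assert np.allclose(out, vals, atol=1e-12)

    def test_diagonal_average_c1_identity(self, rng):
        vals = rng.standard_normal((4, 6))
        assert np.array_equal(diagonal_average(vals, c=1), vals)

    def test_diagonal_average_brute_force(self, rng):
        # D=3 rows per block, c=2 blocks, n=4 columns -> N=5 time points;
        # oracle enumerates (block, column) pairs per original time.
        arr = rng.standard_normal((6, 4))
        got = diagonal_average(arr, c=2)
        D, c, n = 3, 2, 4
        N = n + c - 1
        expected = np.zeros((D, N))
        for t in range(N):
            terms = []
            for i in range(c):
                j = t - (c - 1) + i
                if 0 <= j < n:
                    terms.append(arr[i * D : (i + 1) * D, j])
            expected[:, t] = np.mean(terms, axis=0)
        assert np.allclose(got, expected, atol=1e-12)


class TestNlsaRun:
    def test_static_series_recovered(self):
        # constant manifold: reconstruction equals the input exactly-ish
        vals = np.tile(np.array([[1.0], [2.0], [-0.5]]), (1, 30))
        vals = vals + 0.0
        dense = _dense(vals)
        rec = nlsa_run(dense, EmbeddingConfig(c=4, n_modes=1, n_basis=4, knn=8))
        assert np.max(np.abs(rec.intensities - vals)) < 1e-6

    def test_full_basis_run_identity(self, rng):
        vals = rng.standard_normal((5, 16))
        dense = _dense(vals)
        c = 3
        n = 16 - c + 1  # D*c = 15 >= n so the thin SVD keeps all n modes
        rec = nlsa_run(dense, EmbeddingConfig(c=c, n_modes=n, n_basis=n, knn=n - 1))
        assert np.max(np.abs(rec.standardized - vals)) < 1e-6

    def test_rank_two_dynamics_variance_capture(self):
        # one mixing coordinate -> signal lives in a 2-d linear span;
        # leading-2-mode reconstruction captures >= 99% of the variance
        rng = np.random.default_rng(8)
        D, N = 40, 400
        base = rng.standard_normal(D)
        delta = rng.standard_normal(D)
        alpha = 0.5 * (1 + np.tanh(np.linspace(-3, 3, N)))
        vals = np.outer(base, np.ones(N)) + np.outer(delta, alpha)
        dense = _dense(vals)
        rec = nlsa_run(dense, EmbeddingConfig(c=20, n_modes=2, n_basis=8, knn=50))
        resid = np.linalg.norm(rec.standardized - vals) ** 2
        total = np.linalg.norm(vals) ** 2
        assert 1.0 - resid / total >= 0.99

    def test_row_permutation_equivariance(self, rng):
        vals = rng.standard_normal((6, 25))
        perm = rng.permutation(6)
        cfg = EmbeddingConfig(c=3, n_modes=2, n_basis=6, knn=10)
        rec1 = nlsa_run(_dense(vals), cfg)
        rec2 = nlsa_run(_dense(vals[perm]), cfg)
        assert np.allclose(rec2.standardized, rec1.standardized[perm], atol=1e-8)

    def test_large_scale_configs_accepted(self):
        # shape-only checks for production-scale c/M combinations
        EmbeddingConfig(c=2048, n_modes=5)
        EmbeddingConfig(c=8192, n_modes=10)
        with pytest.raises(ValueError):
            EmbeddingConfig(c=0, n_modes=5)
        with pytest.raises(ValueError):
            EmbeddingConfig(c=16, n_modes=7, n_basis=6)

    def test_c_not_below_series_length_rejected(self, rng):
        dense = _dense(rng.random((3, 10)))
        with pytest.raises(ValueError):
            nlsa_run(dense, EmbeddingConfig(c=10, n_modes=1))

    def test_deterministic_under_seed(self, rng):
        vals = rng.standard_normal((5, 40))
        cfg = EmbeddingConfig(c=5, n_modes=3, n_basis=8, knn=12, seed=7)
        r1 = nlsa_run(_dense(vals), cfg)
        r2 = nlsa_run(_dense(vals.copy()), cfg)
        assert np.array_equal(r1.intensities, r2.intensities)
        assert np.array_equal(r1.singular_values, r2.singular_values)


@given(st.integers(0, 10_000), st.integers(2, 5), st.integers(6, 12))
@settings(max_examples=20, deadline=None)
def test_hankel_round_trip_property(seed, c, N):
    rng = np.random.default_rng(seed)
    vals = rng.standard_normal((3, N))
    X = delay_embed(vals, c=min(c, N - 1))
    out = diagonal_average(X.dense(), c=min(c, N - 1))
    assert np.allclose(out, vals, atol=1e-12)
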