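"""Geometry statistics: spectra, Procrustes, subspaces, remapping vectors."""

import numpy as np
import pytest

from ringremap.geometry import (Manifold, nullspace_rotation_control,
                                pairwise_remap_angles, pca_variance_spectrum,
                                position_subspace, preprocess_manifold,
                                procrustes_misalignment, random_rotation,
                                remap_vector_analysis, remapping_dimension,
                                subspace_cosine)


def _ring(P=50, N=12, radius=1.0, rng=None, noise=0.0):
    """A planted circular manifold embedded in the first two coordinates."""
    theta = np.linspace(0, 2 * np.pi, P, endpoint=False)
    X = np.zeros((P, N))
    X[:, 0] = radius * np.cos(theta)
    X[:, 1] = radius * np.sin(theta)
    if noise and rng is not None:
        X += rng.normal(scale=noise, size=(P, N))
    return X


class TestVarianceSpectrum:
    def test_planar_data_needs_two_components(self, rng):
        X = _ring(N=10)
        spec = pca_variance_spectrum(X)
        assert spec[1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(spec) >= -1e-12)
        assert spec[-1] == pytest.approx(1.0)

    def test_isotropic_noise_is_flat(self, rng):
        X = rng.normal(size=(4000, 20))
        spec = pca_variance_spectrum(X)
        per_comp = np.diff(np.r_[0.0, spec])
        assert np.allclose(per_comp, 1 / 20, atol=0.01)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            pca_variance_spectrum(np.ones((1, 5)))


class TestProcrustes:
    def test_identical_manifolds_score_zero(self, rng):
        X = _ring(rng=rng, noise=0.3)
        res = procrustes_misalignment(X, X.copy(), n_null=100, seed=0)
        assert res.observed_rmse == pytest.approx(res.optimal_rmse, abs=1e-12)
        assert res.score == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_has_identical_shape(self, rng):
        # a rotated copy has the same shape (optimal RMSE 0) but is no
        # longer aligned as embedded: it scores like a null draw
        X = _ring(rng=rng, noise=0.3)
        R = random_rotation(X.shape[1], rng)
        res = procrustes_misalignment(X, X @ R, n_null=300, seed=1)
        assert res.optimal_rmse == pytest.approx(0.0, abs=1e-9)
        assert res.score == pytest.approx(
            res.observed_rmse / np.percentile(res.null_rmse, 25), rel=1e-6)
        assert 0.5 < res.score < 1.5

    def test_independent_manifolds_score_near_one(self, rng):
        scores = []
        for s in range(5):
            A = rng.normal(size=(40, 15))
            B = rng.normal(size=(40, 15))
            scores.append(procrustes_misalignment(A, B, n_null=300,
                                                  seed=s).score)
        assert np.mean(scores) == pytest.approx(1.0, abs=0.3)

    def test_common_rotation_invariance(self, rng):
        A = _ring(rng=rng, noise=0.2)
        B = _ring(radius=1.3, rng=rng, noise=0.2)
        R = random_rotation(A.shape[1], rng)
        r1 = procrustes_misalignment(A, B, n_null=200, seed=2)
        r2 = procrustes_misalignment(A @ R, B @ R, n_null=200, seed=2)
        assert r1.score == pytest.approx(r2.score, abs=0.05)

    def test_rotation_matrices_are_proper(self, rng):
        for n in (3, 8, 20):
            R = random_rotation(n, rng)
            assert np.allclose(R @ R.T, np.eye(n), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0)

    def test_degenerate_manifold_rejected(self):
        with pytest.raises(ValueError):
            preprocess_manifold(np.ones((10, 4)))

    def test_preprocessing_invariants(self, rng):
        m = preprocess_manifold(rng.normal(size=(20, 6)))
        assert np.allclose(m.points.mean(axis=0), 0.0, atol=1e-12)
        assert np.linalg.norm(m.points) == pytest.approx(1.0)


class TestPositionSubspace:
    def test_recovers_planted_plane(self):
        basis = position_subspace(_ring(N=8))
        # spans exactly the first two coordinates
        assert np.allclose(np.abs(basis[:2, :]) @ np.ones(2) > 0.0, True)
        assert np.allclose(basis[2:, :], 0.0, atol=1e-10)

    def test_orthonormal(self, rng):
        basis = position_subspace(rng.normal(size=(30, 10)))
        assert np.allclose(basis.T @ basis, np.eye(2), atol=1e-10)

    def test_rank_deficient_raises(self):
        X = np.outer(np.arange(10.0), np.ones(5))
        with pytest.raises(ValueError):
            position_subspace(X)

    def test_projection_preserves_ring_order(self, session_2state):
        # bins projected into the position plane stay angularly ordered
        curves = session_2state["curves"].curves
        basis = position_subspace(curves)
        proj = (curves[0] - curves[0].mean(axis=0)) @ basis
        ang = np.unwrap(np.arctan2(proj[:, 1], proj[:, 0]))
        diffs = np.diff(ang)
        # consistent winding direction for nearly all bin steps
        assert (np.sign(diffs) == np.sign(np.median(diffs))).mean() > 0.9


class TestRemappingDimension:
    def test_pure_translation(self, rng):
        X = _ring(rng=rng, noise=0.1)
        v = rng.normal(size=X.shape[1])
        d = remapping_dimension(X, X + v)
        assert np.allclose(d, v / np.linalg.norm(v), atol=1e-12)

    def test_antisymmetry(self, rng):
        A = rng.normal(size=(20, 6))
        B = rng.normal(size=(20, 6))
        assert np.allclose(remapping_dimension(A, B),
                           -remapping_dimension(B, A))

    def test_identical_maps_raise(self):
        X = _ring()
        with pytest.raises(ValueError):
            remapping_dimension(X, X)


class TestRemapVectors:
    def test_pure_translation_structure(self, rng):
        X = _ring(rng=rng, noise=0.2)
        v = rng.normal(size=X.shape[1])
        W = rng.normal(size=(2, X.shape[1]))
        rv = remap_vector_analysis(X, X + v, W)
        assert np.allclose(rv.v, v)
        assert np.allclose(rv.normalized_residuals, 0.0, atol=1e-9)
        # xi matrix is exactly rank 1 and its first axis is v
        assert rv.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.allclose(rv.xi[0] / np.linalg.norm(rv.xi[0]),
                           v / np.linalg.norm(v))
        d = remapping_dimension(X, X + v)
        assert abs(d @ (v / np.linalg.norm(v))) == pytest.approx(1.0)

    def test_linearity_identity_exact(self, rng):
        A = rng.normal(size=(30, 10))
        B = rng.normal(size=(30, 10))
        W = rng.normal(size=(2, 10))
        rv = remap_vector_analysis(A, B, W)
        direct = np.linalg.norm(B @ W.T - A @ W.T, axis=1)
        assert np.allclose(rv.readout_residuals, direct, atol=1e-12)

    def test_mean_centering_exact(self, rng):
        rv = remap_vector_analysis(rng.normal(size=(20, 5)),
                                   rng.normal(size=(20, 5)),
                                   rng.normal(size=(2, 5)))
        assert np.allclose((rv.xi - rv.v).mean(axis=0), 0.0, atol=1e-12)


class TestNullspaceRotation:
    def test_readout_preserved_exactly(self, rng):
        X = rng.normal(size=(40, 12))
        W = rng.normal(size=(2, 12))
        Xr = nullspace_rotation_control(X, W, seed=3)
        assert np.abs(Xr @ W.T - X @ W.T).max() < 1e-9
        # and the manifold itself genuinely moved
        assert np.abs(Xr - X).max() > 0.1

    def test_full_rank_W_required(self, rng):
        X = rng.normal(size=(10, 3))
        W = np.eye(3)
        with pytest.raises(ValueError):
            nullspace_rotation_control(X, W, seed=0)


class TestSubspaceCosine:
    def test_contained_and_orthogonal(self):
        basis = np.eye(6)[:, :2]
        assert subspace_cosine(np.array([1.0, 2, 0, 0, 0, 0]), basis) == \
            pytest.approx(1.0)
        assert subspace_cosine(np.array([0, 0, 1.0, 0, 0, 0]), basis) == \
            pytest.approx(0.0)

    def test_random_vector_expectation(self, rng):
        # E[cos^2] = k/N for a random direction vs a k-dim subspace
        N, k = 64, 2
        basis = np.linalg.qr(rng.normal(size=(N, k)))[0]
        cs = [subspace_cosine(rng.normal(size=N), basis)
              for _ in range(2000)]
        assert np.mean(np.square(cs)) == pytest.approx(k / N, rel=0.15)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            subspace_cosine(np.zeros(4), np.eye(4)[:, :1])


class TestPairwiseRemapAngles:
    def _maps_with_centroids(self, centroids, rng):
        ring = _ring(P=30, N=centroids.shape[1], radius=0.1, rng=rng,
                     noise=0.01)
        return np.stack([ring + c for c in centroids])

    def test_equilateral_triangle_gives_sixty_degrees(self, rng):
        # three centroids at the vertices of an equilateral triangle
        c = np.zeros((3, 8))
        c[0, :2] = [1.0, 0.0]
        c[1, :2] = [-0.5, np.sqrt(3) / 2]
        c[2, :2] = [-0.5, -np.sqrt(3) / 2]
        angles = pairwise_remap_angles(self._maps_with_centroids(5 * c, rng))
        for val in angles.values():
            assert val == pytest.approx(60.0, abs=2.0)

    def test_identical_and_orthogonal_dimensions(self, rng):
        # four collinear centroids -> parallel remap dimensions (0 degrees)
        c = np.zeros((3, 8))
        c[0, 0], c[1, 0], c[2, 0] = 0.0, 5.0, 10.0
        angles = pairwise_remap_angles(self._maps_with_centroids(c, rng))
        assert angles[((0, 1), (0, 2))] == pytest.approx(0.0, abs=2.0)
        # right-angle configuration -> 90 degrees
        c2 = np.zeros((3, 8))
        c2[1, 0] = 5.0
        c2[2, 1] = 5.0
        angles2 = pairwise_remap_angles(self._maps_with_centroids(c2, rng))
        assert angles2[((0, 1), (0, 2))] == pytest.approx(90.0, abs=2.0)

    def test_needs_three_maps(self, rng):
        with pytest.raises(ValueError):
            pairwise_remap_angles(rng.normal(size=(2, 10, 5)))
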