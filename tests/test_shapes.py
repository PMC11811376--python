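import numpy as np
import pytest
from scipy.optimize import minimize

from hasm import LandmarkSet, to_shape_vector
from hasm.shapes import (
    DegenerateShapeError,
    ShapeModel,
    SimilarityTransform,
    constrain_shape,
    fit_similarity,
    generalized_procrustes,
    tangent_project,
)


def _fixed_points(seed=5):
    return np.random.default_rng(seed).normal(size=(22, 2)) * 30 + 100


class TestFitSimilarity:
    def test_identity_and_translation(self):
        pts = _fixed_points()
        t = fit_similarity(pts, pts)
        assert t.scale == pytest.approx(1.0) and t.rotation == pytest.approx(0.0)
        assert np.allclose(t.translation, 0)
        t = fit_similarity(pts, pts + [5, -2])
        assert t.scale == pytest.approx(1.0) and t.rotation == pytest.approx(0.0)
        assert np.allclose(t.translation, [5, -2])

    def test_construct_then_recover(self):
        """Recovers s=2, theta=30 deg, t=(3,7) within 1e-8, and matches a
        direct numerical least-squares solution."""
        pts = _fixed_points()
        truth = SimilarityTransform(2.0, np.deg2rad(30), np.array([3.0, 7.0]))
        dst = truth.apply(pts)
        est = fit_similarity(pts, dst)
        assert est.scale == pytest.approx(2.0, abs=1e-8)
        assert est.rotation == pytest.approx(np.deg2rad(30), abs=1e-8)
        assert np.allclose(est.translation, [3, 7], atol=1e-8)

        # independent oracle: numeric minimization of the same objective
        noisy = dst + np.random.default_rng(0).normal(size=dst.shape)

        def objective(params):
            s, th, tx, ty = params
            tr = SimilarityTransform(abs(s) + 1e-12, th, np.array([tx, ty]))
            return np.sum((tr.apply(pts) - noisy) ** 2)

        est = fit_similarity(pts, noisy)
        num = minimize(objective, [1.5, 0.4, 0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert objective([est.scale, est.rotation, *est.translation]) <= num.fun + 1e-6

    def test_weighted_fit_ignores_zero_weight_outlier(self):
        pts = _fixed_points()
        dst = pts + [1, 2]
        dst[0] += [500, -300]  # outlier
        w = np.ones(22)
        w[0] = 0.0
        t = fit_similarity(pts, dst, weights=w)
        assert t.scale == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(t.translation, [1, 2], atol=1e-10)

    def test_degenerate_source(self):
        with pytest.raises(DegenerateShapeError):
            fit_similarity(np.ones((22, 2)), _fixed_points())

    def test_inverse_roundtrip(self):
        t = SimilarityTransform(0.7, 1.1, np.array([4.0, -9.0]))
        pts = _fixed_points()
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)


class TestGeneralizedProcrustes:
    def test_identical_shapes(self):
        """Identical inputs give a mean that is the shared shape centered and
        unit-normalized (up to the canonical orientation) with zero aligned
        spread."""
        from hasm.landmarks import vector_to_points

        pts = _fixed_points()
        res = generalized_procrustes([pts] * 4)
        mean_pts = vector_to_points(res.mean)
        assert np.allclose(mean_pts.mean(axis=0), 0, atol=1e-12)
        assert np.linalg.norm(res.mean) == pytest.approx(1.0, abs=1e-12)
        # mean is similarity-equivalent to the input with zero residual
        t = fit_similarity(pts, mean_pts)
        assert np.abs(t.apply(pts) - mean_pts).max() < 1e-10
        assert np.ptp(res.aligned, axis=0).max() < 1e-10

    def test_similarity_related_shapes_align_exactly(self):
        pts = _fixed_points()
        other = SimilarityTransform(1.7, 0.5, np.array([40.0, -10.0])).apply(pts)
        res = generalized_procrustes([pts, other])
        assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-8

    def test_mean_invariant_to_input_order(self, train_shapes):
        shapes = train_shapes[:40]
        res = generalized_procrustes(shapes)
        perm = list(np.random.default_rng(3).permutation(len(shapes)))
        res_p = generalized_procrustes([shapes[i] for i in perm])
        assert np.allclose(res.mean, res_p.mean, atol=1e-6)

    def test_mean_invariant_to_pretransform(self, train_shapes):
        shapes = [s.points for s in train_shapes[:20]]
        res = generalized_procrustes(shapes)
        shapes[0] = SimilarityTransform(2.2, 0.9, np.array([5.0, 5.0])).apply(shapes[0])
        res_t = generalized_procrustes(shapes)
        assert np.allclose(res.mean, res_t.mean, atol=1e-6)


class TestShapeModel:
    def test_single_mode_dominates(self, train_shapes):
        """Shapes varying along one direction put >=99.9% variance on mode 1."""
        base = generalized_procrustes(train_shapes[:10]).mean
        u = np.random.default_rng(8).normal(size=44)
        u -= (u @ base) * base  # keep variation off the radial direction
        u /= np.linalg.norm(u)
        shapes = [base + c * u for c in np.linspace(-0.05, 0.05, 9)]
        model = ShapeModel.fit(shapes)
        assert model.eigenvalues[0] / model.eigenvalues.sum() >= 0.999

    def test_orthonormal_modes_and_nonneg_spectrum(self, shape_model):
        P = shape_model.eigenvectors
        assert np.allclose(P.T @ P, np.eye(shape_model.n_modes), atol=1e-10)
        assert np.all(shape_model.eigenvalues >= 0)
        assert np.all(np.diff(shape_model.eigenvalues) <= 1e-12)

    def test_full_rank_reconstruction(self, train_shapes, shape_model):
        """The complete basis reproduces tangent-projected aligned shapes."""
        gpa = generalized_procrustes(train_shapes)
        projected = tangent_project(gpa.aligned, gpa.mean)
        P = shape_model.eigenvectors
        for y in projected[:10]:
            recon = shape_model.mean + P @ (P.T @ (y - shape_model.mean))
            assert np.linalg.norm(recon - y) < 1e-8

    def test_eigenvalues_sum_to_total_variance(self, train_shapes, shape_model):
        gpa = generalized_procrustes(train_shapes)
        projected = tangent_project(gpa.aligned, gpa.mean)
        dev = projected - gpa.mean
        total = np.sum(dev**2) / (len(train_shapes) - 1)
        assert shape_model.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_json_roundtrip(self, shape_model, tmp_path):
        path = tmp_path / "model.json"
        shape_model.to_json(path)
        loaded = ShapeModel.from_json(path)
        assert np.array_equal(loaded.mean, shape_model.mean)
        assert np.array_equal(loaded.eigenvectors, shape_model.eigenvectors)
        assert np.array_equal(loaded.eigenvalues, shape_model.eigenvalues)
        assert loaded.n_train == shape_model.n_train


class TestConstrainShape:
    def test_mean_shape_is_fixed_point(self, shape_model):
        t = SimilarityTransform(250.0, 0.3, np.array([130.0, 160.0]))
        Y = t.apply(shape_model.mean)
        res = constrain_shape(Y, shape_model, n_P=10)
        assert np.linalg.norm(res.b) < 1e-8
        assert np.allclose(res.X, Y, atol=1e-8)

    def test_recovers_constructed_coefficients(self, shape_model):
        """A shape built from coefficients inside the clamp box is recovered."""
        n_P = 8
        rng = np.random.default_rng(21)
        b0 = 1.5 * np.sqrt(shape_model.eigenvalues[:n_P]) * rng.uniform(-1, 1, n_P)
        x = shape_model.synthesize(b0)
        t = SimilarityTransform(300.0, -0.2, np.array([100.0, 150.0]))
        Y = t.apply(x)
        res = constrain_shape(Y, shape_model, n_P=n_P, clamp_k=3.0)
        assert np.allclose(res.b, b0, atol=1e-6)
        assert np.allclose(res.X, Y, atol=1e-6)

    def test_reduces_single_landmark_corruption(self, shape_model, clean_truth):
        Y_clean = to_shape_vector(clean_truth)
        corrupted = clean_truth.points.copy()
        corrupted[7] += [25.0, -18.0]
        Y = to_shape_vector(clean_truth.with_points(corrupted))
        res = constrain_shape(Y, shape_model, n_P=20)
        assert np.linalg.norm(res.X - Y_clean) < np.linalg.norm(Y - Y_clean)

    def test_idempotent(self, shape_model, clean_truth):
        corrupted = clean_truth.points.copy()
        corrupted[3] += [15.0, 10.0]
        Y = to_shape_vector(clean_truth.with_points(corrupted))
        tol = 1e-6
        res1 = constrain_shape(Y, shape_model, n_P=20, tol=tol)
        res2 = constrain_shape(res1.X, shape_model, n_P=20, tol=tol)
        assert np.linalg.norm(res2.X - res1.X) < 10 * tol * np.linalg.norm(res1.X)

    def test_equivariant_to_similarity_transforms(self, shape_model, clean_truth):
        corrupted = clean_truth.points.copy()
        corrupted[12] += [-20.0, 12.0]
        Y = to_shape_vector(clean_truth.with_points(corrupted))
        t = SimilarityTransform(1.4, 0.25, np.array([30.0, -20.0]))
        X_direct = constrain_shape(t.apply(Y), shape_model, n_P=20).X
        X_mapped = t.apply(constrain_shape(Y, shape_model, n_P=20).X)
        assert np.allclose(X_direct, X_mapped, atol=1e-4)

    def test_clamping_limits_coefficients(self, shape_model, clean_truth):
        corrupted = clean_truth.points.copy()
        corrupted[0] += [300.0, 300.0]  # extreme outlier
        Y = to_shape_vector(clean_truth.with_points(corrupted))
        res = constrain_shape(Y, shape_model, n_P=20, clamp_k=3.0)
        limits = 3.0 * np.sqrt(shape_model.eigenvalues[:20])
        assert np.all(np.abs(res.b) <= limits + 1e-12)

    def test_rejects_bad_mode_count(self, shape_model):
        Y = shape_model.mean * 100
        with pytest.raises(ValueError):
            constrain_shape(Y, shape_model, n_P=shape_model.n_modes + 1)
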