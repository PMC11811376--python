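import dataclasses

import numpy as np
import pytest

from hasm import (
    HASMConfig,
    HeatmapASM,
    HeatmapNoiseParams,
    correct,
    detect_initial,
    simulate_heatmaps,
    snap_postprocess,
    update_landmarks,
)
from hasm.heatmaps import HeatmapChannel, HeatmapStack
from hasm.metrics import allowable_error
from hasm.model import DEFAULT_GRID, allowable_error_detected, grid_search


def _ramp_stack(truth, a=2.0):
    """Stacks whose channels are linear ramps with x-gradient ``a`` after
    per-channel max-normalization."""
    channels = []
    n = 32
    for k in range(22):
        x = np.arange(n)[None, :].astype(float)
        resp = np.broadcast_to(a * x, (n, n)).copy()
        resp /= resp.max()  # unit max; normalized gradient = a/max
        channels.append(
            HeatmapChannel(
                response=resp,
                origin_offset=(truth.points[k, 0] - 16, truth.points[k, 1] - 16),
                scale=1.0,
                landmark_index=k + 1,
            )
        )
    return HeatmapStack(channels=channels)


class TestUpdateLandmarks:
    def test_zero_mu_is_identity(self, clean_stack, clean_truth):
        out = update_landmarks(clean_truth, clean_stack, mu=0.0)
        assert np.array_equal(out.points, clean_truth.points)

    def test_no_displacement_at_gaussian_peak(self, clean_stack, clean_truth):
        """The gradient vanishes at the peak, so landmarks at the true
        positions essentially do not move."""
        out = update_landmarks(clean_truth, clean_stack, mu=0.02)
        assert np.linalg.norm(out.points - clean_truth.points, axis=1).max() < 1e-6

    def test_linear_ramp_displacement_formula(self, clean_truth):
        """Normalized ramp with slope 1/31 along x: step = mu * m_h * (1, 0)."""
        stack = _ramp_stack(clean_truth)
        mu = 0.02
        out = update_landmarks(clean_truth, stack, mu=mu, normalize=True)
        d = out.points - clean_truth.points
        expected = mu * (1.0 / 31.0)
        assert np.allclose(d[:, 0], expected, atol=1e-12)
        assert np.allclose(d[:, 1], 0, atol=1e-12)

    def test_out_of_channel_landmark_unmoved(self, clean_stack, clean_truth):
        pts = clean_truth.points.copy()
        pts[2] += [500.0, 500.0]  # far outside its 128x128 window
        moved = clean_truth.with_points(pts)
        out = update_landmarks(moved, clean_stack, mu=0.05)
        assert np.array_equal(out.points[2], pts[2])


class TestCorrect:
    def test_zero_iterations_returns_initial_detection(self, clean_stack, shape_model):
        cfg = HASMConfig(max_iterations=0)
        res = correct(clean_stack, shape_model, cfg)
        det = detect_initial(clean_stack)
        assert np.array_equal(res.landmarks.points, det.points)
        assert res.iterations_run == 0 and res.trace.size == 0

    def test_inert_configuration_fixes_initial_detection(self, clean_stack, shape_model):
        """mu = 0 with all modes and no clamping leaves the argmax detection
        essentially unchanged and stops after two iterations."""
        cfg = HASMConfig(n_P=shape_model.n_modes, mu=0.0, clamp_k=None)
        res = correct(clean_stack, shape_model, cfg)
        det = detect_initial(clean_stack)
        assert np.linalg.norm(res.landmarks.points - det.points, axis=1).max() < 0.5
        assert res.iterations_run <= 2 and res.converged_early

    def test_deterministic(self, clean_stack, shape_model):
        r1 = correct(clean_stack, shape_model)
        r2 = correct(clean_stack, shape_model)
        assert np.array_equal(r1.landmarks.points, r2.landmarks.points)
        assert np.array_equal(r1.trace, r2.trace)

    def test_all_outputs_finite_on_sparse_stack(self, shape_model, clean_truth):
        """Zero-gradient regions must not propagate NaNs."""
        channels = []
        for k in range(22):
            resp = np.zeros((32, 32))
            if k % 3 == 0:
                resp[16, 16] = 1.0  # two thirds of channels are all-zero
            channels.append(
                HeatmapChannel(
                    response=resp,
                    origin_offset=(clean_truth.points[k, 0] - 16, clean_truth.points[k, 1] - 16),
                    scale=1.0,
                    landmark_index=k + 1,
                )
            )
        res = correct(HeatmapStack(channels=channels), shape_model)
        assert np.all(np.isfinite(res.landmarks.points))

    def test_equivariant_to_channel_offset_translation(self, clean_stack, shape_model):
        delta = np.array([17.0, -6.0])
        shifted = HeatmapStack(
            channels=[
                dataclasses.replace(
                    ch, origin_offset=(ch.origin_offset[0] + delta[0], ch.origin_offset[1] + delta[1])
                )
                for ch in clean_stack.channels
            ],
            image_id=clean_stack.image_id,
        )
        res = correct(clean_stack, shape_model)
        res_shifted = correct(shifted, shape_model)
        assert np.allclose(res_shifted.landmarks.points, res.landmarks.points + delta, atol=1e-9)

    def test_rejects_excess_modes(self, clean_stack, shape_model):
        with pytest.raises(ValueError):
            correct(clean_stack, shape_model, HASMConfig(n_P=shape_model.n_modes + 1))

    def test_subspace_configuration_is_a_fixed_point(self, shape_model):
        """Clean Gaussians rendered at a configuration synthesized inside the
        model subspace: the corrected landmarks stay within 0.5 px of the
        argmax detection after the full 30-iteration loop."""
        from hasm.landmarks import from_shape_vector
        from hasm.shapes import SimilarityTransform

        rng = np.random.default_rng(55)
        b = np.sqrt(shape_model.eigenvalues[:20]) * rng.uniform(-1.5, 1.5, 20)
        pose = SimilarityTransform(290.0, 0.05, np.array([128.0, 160.0]))
        truth = from_shape_vector(pose.apply(shape_model.synthesize(b)))
        stack = simulate_heatmaps(truth, HeatmapNoiseParams(), rng)
        res = correct(stack, shape_model)
        det = detect_initial(stack)
        assert np.linalg.norm(res.landmarks.points - det.points, axis=1).max() < 0.5

    def test_generic_clean_stack_stays_near_detection(self, clean_stack, shape_model):
        """A configuration off the 20-mode subspace moves only by the small
        subspace-projection residual."""
        res = correct(clean_stack, shape_model)
        det = detect_initial(clean_stack)
        assert np.linalg.norm(res.landmarks.points - det.points, axis=1).max() < 3.0

    def test_results_summary_mentions_config(self, clean_stack, shape_model):
        res = HeatmapASM(clean_stack, shape_model).fit()
        text = res.summary()
        assert "n_P = 20" in text and "mu = 0.02" in text


class TestSnapPostprocess:
    def test_allowable_error_delegation(self, clean_truth):
        assert allowable_error_detected(clean_truth) == allowable_error(clean_truth)

    def test_gamma_zero_is_noop(self, clean_stack, clean_truth):
        out, snapped = snap_postprocess(clean_truth, clean_stack, gamma=0.0)
        assert np.array_equal(out.points, clean_truth.points)
        assert not snapped.any()

    def test_snaps_within_criterion(self, clean_stack, clean_truth):
        e_a = allowable_error(clean_truth)
        pts = clean_truth.points.copy()
        argmax0 = clean_stack.channel(1).argmax_image()
        pts[0] = argmax0 + np.array([0.5 * e_a, 0.0]) * 0.99
        out, snapped = snap_postprocess(clean_truth.with_points(pts), clean_stack, gamma=1.0)
        assert snapped[0]
        assert np.array_equal(out.points[0], argmax0)

    def test_snapped_sets_nested_in_gamma(self, clean_stack, shape_model):
        res = correct(clean_stack, shape_model)
        previous = None
        for gamma in (0.01, 0.03, 0.05, 0.07, 0.1):
            _, snapped = snap_postprocess(res.landmarks, clean_stack, gamma)
            if previous is not None:
                assert np.all(snapped >= previous)  # superset of the smaller gamma
            previous = snapped


class TestGridSearch:
    def test_single_candidate(self, clean_stack, clean_truth, shape_model):
        assert grid_search([(5, 0.01)], [(clean_stack, clean_truth)], shape_model) == (5, 0.01)

    def test_inert_candidate_loses_on_correctable_corruption(
        self, shape_model, clean_truth
    ):
        rng = np.random.default_rng(33)
        shifted = clean_truth.points[9] + [20.0, 0.0]
        stack = simulate_heatmaps(
            clean_truth, HeatmapNoiseParams(), rng, peak_overrides={10: shifted}
        )
        inert = (shape_model.n_modes, 0.0)
        active = (20, 0.02)
        base = HASMConfig(clamp_k=None)
        winner = grid_search([inert, active], [(stack, clean_truth)], shape_model, base)
        assert winner == active

    def test_default_grid_contains_selected_operating_point(self):
        assert (20, 0.02) in DEFAULT_GRID
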