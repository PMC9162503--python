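"""Virtual-pinhole views, extended depth of field and stereo rendering."""

import numpy as np
import pytest
from scipy import fft as spfft
from scipy import ndimage

from multifocus import (
    BlurModel,
    MultifocusStack,
    StereoPair,
    ViewpointRequest,
    disparity_px,
    extended_dof,
    generate_bead_scene,
    render_stereo,
    simulate_stack,
    stereo_pair,
    sweep_viewpoints,
    synthesize_viewpoint,
)
from multifocus.separation import LayerSpectra


def spectra_from_layers(layers, currents, R0):
    """Exact layer spectra (no inversion), for shift-theorem oracles."""
    return LayerSpectra(
        F=spfft.fft2(np.asarray(layers, dtype=float), axes=(1, 2)),
        currents_mA=np.asarray(currents, dtype=float),
        R0=R0,
    )


class TestViewpointRequest:
    @pytest.mark.parametrize("bx, by", [(1.2, 0.0), (0.0, -1.01), (2.0, 2.0)])
    def test_outside_pupil_rejected(self, bx, by):
        with pytest.raises(ValueError, match="pupil"):
            ViewpointRequest(bx, by)

    def test_boundary_allowed(self):
        ViewpointRequest(1.0, -1.0)


class TestDisparity:
    def test_zero_beta(self, blur):
        assert disparity_px(0.0, 265.0, blur) == 0.0

    def test_linear_in_current(self, blur):
        assert disparity_px(0.3, 200.0, blur) == pytest.approx(
            2 * disparity_px(0.3, 100.0, blur)
        )

    def test_arithmetic_example(self):
        assert disparity_px(0.25, 10.0, BlurModel(R0=12.7)) == pytest.approx(31.75)


class TestSynthesizeViewpoint:
    def test_zero_beta_recovers_all_in_focus_sum(self, symmetric_scene, blur):
        spec = spectra_from_layers(
            symmetric_scene.layers, symmetric_scene.currents_mA, blur.R0
        )
        out = synthesize_viewpoint(spec, ViewpointRequest(0.0, 0.0))
        assert np.allclose(out, symmetric_scene.composite(), atol=1e-9)

    def test_single_layer_integer_shift_matches_roll(self, symmetric_scene):
        # shift theorem: one layer at j=25 mA, R0=1 px/mA, beta=0.2 -> 5 px
        layer = symmetric_scene.layers[:1]
        spec = spectra_from_layers(layer, [25.0], R0=1.0)
        out = synthesize_viewpoint(spec, ViewpointRequest(0.2, 0.0))
        assert np.max(np.abs(out - np.roll(layer[0], 5, axis=1))) < 1e-9
        out_y = synthesize_viewpoint(spec, ViewpointRequest(0.0, 0.2))
        assert np.max(np.abs(out_y - np.roll(layer[0], 5, axis=0))) < 1e-9

    def test_opposite_betas_shift_oppositely(self, symmetric_scene):
        layer = symmetric_scene.layers[:1]
        spec = spectra_from_layers(layer, [25.0], R0=1.0)
        plus = synthesize_viewpoint(spec, ViewpointRequest(0.2, 0.0))
        minus = synthesize_viewpoint(spec, ViewpointRequest(-0.2, 0.0))
        assert np.max(np.abs(np.roll(plus, -10, axis=1) - minus)) < 1e-9

    def test_zero_spectra(self, blur):
        spec = spectra_from_layers(np.zeros((2, 16, 16)), [50.0, 0.0], blur.R0)
        assert np.array_equal(
            synthesize_viewpoint(spec, ViewpointRequest(0.4, -0.3)), np.zeros((16, 16))
        )

    def test_viewpoint_energy_invariant(self, spectra):
        # the DC bin carries no phase ramp, so total intensity is identical
        # across all synthesized viewpoints
        e0 = synthesize_viewpoint(spectra, ViewpointRequest(0.0, 0.0)).sum()
        for bx, by in [(0.5, 0.0), (-0.5, 0.25), (1.0, -1.0)]:
            e = synthesize_viewpoint(spectra, ViewpointRequest(bx, by)).sum()
            assert abs(e - e0) / abs(e0) < 1e-6


class TestExtendedDof:
    def test_single_slice_returns_slice(self, blur, symmetric_scene):
        img = symmetric_scene.composite()
        stack = MultifocusStack(img[None], [50.0], registered=True)
        assert np.allclose(extended_dof(stack, blur), img, atol=1e-9 * img.max())

    def test_energy_equals_mean_slice_energy(self, sim_stack, blur):
        edof = extended_dof(sim_stack, blur)
        assert edof.sum() == pytest.approx(sim_stack.slice_energies().mean(), rel=1e-6)

    def test_all_rings_simultaneously_sharp(self, symmetric_scene, blur, sim_stack):
        # per-ring high-pass sharpness of the reconstruction stays within 10%
        # of ground truth, whereas every input slice leaves at least one ring
        # below half of its true sharpness
        def ring_sharpness(img, layer):
            hp = img - ndimage.uniform_filter(img, 5)
            mask = ndimage.binary_dilation(layer > 0, iterations=3)
            return np.sqrt((hp[mask] ** 2).sum())

        edof = extended_dof(sim_stack, blur)
        truth = symmetric_scene.composite()
        ratios_edof = []
        for k in range(3):
            ref = ring_sharpness(truth, symmetric_scene.layers[k])
            ratios_edof.append(ring_sharpness(edof, symmetric_scene.layers[k]) / ref)
        assert all(abs(r - 1) < 0.10 for r in ratios_edof)
        for sl in sim_stack.slices:
            ratios = [
                ring_sharpness(sl, symmetric_scene.layers[k])
                / ring_sharpness(truth, symmetric_scene.layers[k])
                for k in range(3)
            ]
            assert min(ratios) < 0.5


class TestStereo:
    def test_zero_baseline_duplicates_edof(self, sim_stack, blur):
        pair = stereo_pair(sim_stack, blur, baseline_fraction=0.0)
        assert np.array_equal(pair.left, pair.right)
        assert np.allclose(pair.left, extended_dof(sim_stack, blur), atol=1e-9)

    def test_baseline_beyond_pupil_rejected(self, sim_stack, blur):
        with pytest.raises(ValueError, match="B <= 2R"):
            stereo_pair(sim_stack, blur, baseline_fraction=2.3)
        with pytest.raises(ValueError, match="B <= 2R"):
            StereoPair(np.zeros((4, 4)), np.zeros((4, 4)), baseline_fraction=-0.1)

    def test_negating_baseline_swaps_views(self, sim_stack, blur):
        pair = stereo_pair(sim_stack, blur, 0.5, pad=0)
        # views at -beta are exactly the mirrored assignment
        from multifocus.viewpoint import ViewpointRequest, synthesize_viewpoint
        from multifocus import solve_layer_spectra

        spec = solve_layer_spectra(sim_stack, blur)
        swapped_left = synthesize_viewpoint(spec, ViewpointRequest(-0.25, 0.0))
        assert np.allclose(pair.right, swapped_left, atol=1e-12)

    def test_cross_correlation_disparity_by_layer(self, blur):
        # phantom with layers at 50 and 0 mA, baseline B=R/2 (beta=±0.25):
        # the far layer is displaced 2·0.25·R0·50 px between views, the
        # in-focus-at-zero layer not at all
        scene = generate_bead_scene(
            n_layers=2,
            currents_mA=(50.0, 0.0),
            ring_radii_px=(40.0, 90.0),
            angular_jitter_rad=0.0,
            seed=0,
        )
        stack = simulate_stack(scene, blur)
        pair = stereo_pair(stack, blur, baseline_fraction=0.5, pad=0)
        expected = 2 * 0.25 * blur.R0 * 50.0
        for k, d_true in [(0, expected), (1, 0.0)]:
            mask = ndimage.binary_dilation(scene.layers[k] > 0, iterations=8)
            a, b = pair.left * mask, pair.right * mask
            corr = spfft.ifft2(spfft.fft2(a) * np.conj(spfft.fft2(b))).real
            shift = np.unravel_index(np.argmax(corr), corr.shape)[1]
            if shift > corr.shape[1] // 2:
                shift -= corr.shape[1]
            assert shift == pytest.approx(d_true, abs=0.5)


class TestRenderStereo:
    @pytest.fixture()
    def pair(self, rng):
        return StereoPair(rng.random((8, 10)), rng.random((8, 10)), 0.5)

    def test_cross_eye_layout(self, pair):
        out = render_stereo(pair, "cross_eye")
        assert out.shape == (8, 20)
        assert np.array_equal(out[:, 10:], pair.left)
        assert np.array_equal(out[:, :10], pair.right)

    def test_parallel_is_flipped_order(self, pair):
        cross = render_stereo(pair, "cross_eye")
        par = render_stereo(pair, "parallel")
        assert np.array_equal(cross[:, :10], par[:, 10:])
        assert np.array_equal(cross[:, 10:], par[:, :10])

    def test_gutter_width(self, pair):
        assert render_stereo(pair, "cross_eye", gutter=4).shape == (8, 24)

    def test_anaglyph_identical_views_are_gray(self, pair):
        same = StereoPair(pair.left, pair.left.copy(), 0.0)
        out = render_stereo(same, "anaglyph")
        assert out.shape == (8, 10, 3)
        assert np.allclose(out[..., 0], out[..., 1])
        assert np.allclose(out[..., 1], out[..., 2])

    def test_unknown_mode(self, pair):
        with pytest.raises(ValueError, match="mode"):
            render_stereo(pair, "holographic")


class TestSweep:
    def test_single_point_grid_is_edof(self, sim_stack, blur):
        frames = sweep_viewpoints(sim_stack, blur, [(0.0, 0.0)], pad=0)
        assert len(frames) == 1
        assert np.allclose(frames[0], extended_dof(sim_stack, blur), atol=1e-9)

    def test_grid_expansion_serpentine(self, sim_stack, blur):
        bxs = np.linspace(-0.2, 0.2, 5)
        bys = np.linspace(-0.2, 0.2, 5)
        frames = sweep_viewpoints(sim_stack, blur, (bxs, bys), pad=0)
        assert len(frames) == 25
        # row 1 traverses bx in reverse: its last frame equals the (bx=-0.2,
        # by=bys[1]) viewpoint, i.e. frame 9 and frame 10 share bx
        explicit = sweep_viewpoints(
            sim_stack, blur, [(-0.2, bys[1]), (0.2, bys[1])], pad=0
        )
        assert np.allclose(frames[9], explicit[0], atol=1e-12)
        assert np.allclose(frames[5], explicit[1], atol=1e-12)
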