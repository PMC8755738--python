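"""PSF fitting, separation bank, upsampling, and centroid detection."""

import numpy as np
import pytest
from skimage.feature import match_template

from ulmkit import (AcquisitionParams, IQStack, PSFModel, SeparationBank,
                    SceneConfig, VesselSpec, default_bank, fit_psf, localize_frame,
                    make_bank, make_scene, separation_filter, simulate_iq,
                    upsample_frame)
from ulmkit.localization import CorrelationLocalizer


def gaussian_patch(shape, z0, x0, sz, sx, pitch, amp=1.0):
    zc = (np.arange(shape[0]) + 0.5) * pitch
    xc = (np.arange(shape[1]) + 0.5) * pitch
    return amp * np.exp(-((zc[:, None] - z0) ** 2) / (2 * sz ** 2)
                        - ((xc[None, :] - x0) ** 2) / (2 * sx ** 2))


class TestFitPSF:
    def test_recovers_known_sigmas(self):
        patch = gaussian_patch((21, 21), 520.0, 510.0, 60.0, 100.0, 49.28)
        psf = fit_psf(patch, (49.28, 49.28))
        assert psf.sigma_axial == pytest.approx(60.0, rel=0.01)
        assert psf.sigma_lateral == pytest.approx(100.0, rel=0.01)

    def test_zero_patch_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_psf(np.zeros((11, 11)), (49.28, 49.28))

    def test_noise_robustness_over_seeded_repeats(self):
        clean = gaussian_patch((21, 21), 520.0, 510.0, 60.0, 100.0, 49.28)
        sig_ax, sig_lat = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            psf = fit_psf(clean + 0.05 * rng.standard_normal(clean.shape),
                          (49.28, 49.28))
            sig_ax.append(psf.sigma_axial)
            sig_lat.append(psf.sigma_lateral)
        assert np.mean(sig_ax) == pytest.approx(60.0, rel=0.05)
        assert np.mean(sig_lat) == pytest.approx(100.0, rel=0.05)

    def test_non_bubble_patch_rejected(self):
        # four isolated impulses: any single Gaussian leaves > 50% of the energy
        patch = np.zeros((15, 15))
        patch[2, 2] = patch[2, 12] = patch[12, 2] = patch[12, 12] = 1.0
        with pytest.raises(ValueError):
            fit_psf(patch, (49.28, 49.28))


class TestSeparationFilter:
    def test_identity_bank_reproduces_input(self, params):
        stack = _bubble_stack(params)
        [out] = separation_filter(stack, make_bank(stack.data.shape, params, "none"))
        err = np.linalg.norm(out.data - stack.data) / np.linalg.norm(stack.data)
        assert err < 1e-6

    def test_partition_of_unity_enforced(self, params):
        shape = (4, 4, 8)
        bad = [np.full(shape, 0.6), np.full(shape, 0.6)]
        with pytest.raises(ValueError, match="partition of unity"):
            SeparationBank(transfer=bad)

    def test_subsets_sum_to_input(self, params):
        stack = _bubble_stack(params)
        subsets = separation_filter(stack, default_bank(stack.data.shape, params))
        total = sum(s.data.astype(np.complex128) for s in subsets)
        err = np.linalg.norm(total - stack.data) / np.linalg.norm(stack.data)
        assert err < 1e-6

    def test_direction_split_isolates_opposite_flows(self, params):
        # two axial vessels with opposite flow signs, no clutter
        cfg = SceneConfig(grid_shape=(48, 32), vessels=[
            VesselSpec(kind="straight", start=(150.0, 400.0), end=(2200.0, 400.0),
                       radius=10.0, peak_speed=10.0, flow_sign=1, bubble_rate=10.0),
            VesselSpec(kind="straight", start=(150.0, 1100.0), end=(2200.0, 1100.0),
                       radius=10.0, peak_speed=10.0, flow_sign=-1, bubble_rate=10.0)],
            tissue_amplitude=0, noise_floor=0)
        scene = make_scene(cfg, params)
        stack, _ = simulate_iq(scene, params, n_frames=64, seed=2)
        subsets = separation_filter(stack, make_bank(stack.data.shape, params,
                                                     "direction"))
        # vessel columns: flow away (+) near x=400 µm, toward (-) near x=1100 µm
        px = params.native_pixel[1]
        away = slice(int(250 / px), int(560 / px))
        toward = slice(int(950 / px), int(1260 / px))
        energies = np.array([[np.sum(np.abs(s.data[:, away, :]) ** 2),
                              np.sum(np.abs(s.data[:, toward, :]) ** 2)]
                             for s in subsets])
        # each subset concentrates >= 90% of its energy in one vessel's column
        # and the two subsets pick different vessels
        frac = energies / energies.sum(axis=0, keepdims=True)
        assert frac[0].max() >= 0.9 and frac[1].max() >= 0.9
        assert np.argmax(frac[0]) != np.argmax(frac[1])


class TestUpsample:
    def test_factor_one_is_identity(self):
        rng = np.random.default_rng(3)
        f = rng.random((12, 14))
        np.testing.assert_array_equal(upsample_frame(f, 1), f)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            upsample_frame(np.ones((8, 8)), 2.5)

    def test_bilinear_ramp_reproduced_exactly(self):
        z, x = np.meshgrid(np.arange(16), np.arange(12), indexing="ij")
        ramp = 2.0 * z + 3.0 * x + 1.0
        up = upsample_frame(ramp, 4)
        zq = (np.arange(64) + 0.5) / 4 - 0.5
        xq = (np.arange(48) + 0.5) / 4 - 0.5
        expected = 2.0 * zq[:, None] + 3.0 * xq[None, :] + 1.0
        # interior only: cubic splines reproduce polynomials exactly away from
        # the extrapolated half-pixel border
        np.testing.assert_allclose(up[2:-2, 2:-2], expected[2:-2, 2:-2], atol=1e-9)

    def test_gaussian_peak_position_within_half_pixel(self):
        pitch, factor = 49.28, 10
        true_z, true_x = 812.3, 1133.7
        frame = gaussian_patch((32, 32), true_z, true_x, 60.0, 100.0, pitch)
        up = upsample_frame(frame, factor)
        # oracle: dense spline evaluation = the same grid; compare to truth
        iz, ix = np.unravel_index(np.argmax(up), up.shape)
        sp = pitch / factor
        assert abs((iz + 0.5) * sp - true_z) <= sp
        assert abs((ix + 0.5) * sp - true_x) <= sp


class TestLocalizeFrame:
    PITCH = 4.928

    def _psf(self):
        return PSFModel(sigma_axial=60.0, sigma_lateral=100.0)

    def test_single_bubble_detected_within_one_pixel(self):
        true_z, true_x = 801.2, 910.7
        frame = gaussian_patch((320, 320), true_z, true_x, 60.0, 100.0, self.PITCH)
        fl = localize_frame(frame, self._psf(), 0.5, self.PITCH)
        assert len(fl.corr) == 1
        err = np.hypot(*(fl.positions[0] - (true_z, true_x)))
        assert err < self.PITCH

    def test_pure_noise_high_threshold_no_detections(self):
        rng = np.random.default_rng(4)
        fl = localize_frame(rng.random((200, 200)), self._psf(), 0.99, self.PITCH)
        assert len(fl.corr) == 0

    def test_two_bubbles_resolved_at_three_sigma_merged_at_half(self):
        sep3 = 3 * 100.0
        frame = (gaussian_patch((320, 320), 800.0, 700.0, 60.0, 100.0, self.PITCH)
                 + gaussian_patch((320, 320), 800.0, 700.0 + sep3, 60.0, 100.0,
                                  self.PITCH))
        fl = localize_frame(frame, self._psf(), 0.5, self.PITCH)
        assert len(fl.corr) == 2
        frame2 = (gaussian_patch((320, 320), 800.0, 700.0, 60.0, 100.0, self.PITCH)
                  + gaussian_patch((320, 320), 800.0, 750.0, 60.0, 100.0, self.PITCH))
        fl2 = localize_frame(frame2, self._psf(), 0.5, self.PITCH)
        assert len(fl2.corr) == 1

    def test_matches_skimage_match_template(self):
        rng = np.random.default_rng(5)
        frame = rng.random((160, 180))
        psf = self._psf()
        loc = CorrelationLocalizer(psf, frame.shape, self.PITCH, 0.5)
        ours = loc.correlate(frame)
        ref = match_template(frame, psf.template(self.PITCH), pad_input=True)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_raising_threshold_never_increases_detections(self):
        rng = np.random.default_rng(6)
        frame = gaussian_patch((240, 240), 500.0, 500.0, 60.0, 100.0, self.PITCH)
        frame = frame + 0.2 * rng.random(frame.shape)
        counts = [len(localize_frame(frame, self._psf(), thr, self.PITCH).corr)
                  for thr in (0.2, 0.4, 0.6, 0.8)]
        assert all(a >= b for a, b in zip(counts[:-1], counts[1:]))

    def test_empty_frame_yields_empty_list(self):
        fl = localize_frame(np.zeros((160, 160)), self._psf(), 0.5, self.PITCH)
        assert len(fl.corr) == 0


def _bubble_stack(params):
    cfg = SceneConfig(grid_shape=(16, 16), vessels=[
        VesselSpec(kind="straight", start=(400.0, 100.0), end=(400.0, 680.0),
                   radius=10.0, peak_speed=5.0, bubble_rate=10.0)],
        tissue_amplitude=1.0, noise_floor=0.01)
    scene = make_scene(cfg, params)
    stack, _ = simulate_iq(scene, params, n_frames=32, seed=1)
    return stack
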