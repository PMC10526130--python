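"""B1 correction, signal→concentration inversion, subtraction images and
bolus-arrival detection, validated against phantom ground truth."""

import numpy as np
import pytest

import dcevasc as dv
from dcevasc.preprocessing import spgr_signal


class TestB1Correct:
    def test_identical_coils_identity(self, noiseless_phantom):
        ph = noiseless_phantom
        out = dv.b1_correct(ph.dce, ph.body_coil, ph.body_coil)
        assert np.allclose(out.data, ph.dce.data)

    def test_known_bias_field_removed(self, noiseless_phantom):
        """body/breast ratio restores the unbiased series to ~machine
        precision on a noiseless phantom."""
        ph = noiseless_phantom
        out = dv.b1_correct(ph.dce, ph.breast_coil, ph.body_coil)
        unbiased = ph.dce.data / ph.bias_field[..., None]
        assert np.max(np.abs(out.data - unbiased)) < 1e-6 * unbiased.max()

    def test_flipped_direction_squares_the_bias(self, noiseless_phantom):
        ph = noiseless_phantom
        out = dv.b1_correct(ph.dce, ph.breast_coil, ph.body_coil,
                            direction="breast_over_body")
        expected = ph.dce.data * ph.bias_field[..., None]
        assert np.allclose(out.data, expected)

    def test_grid_mismatch_rejected(self, noiseless_phantom):
        ph = noiseless_phantom
        small = dv.VolumeImage(np.ones((4, 4, 2)), role="body_coil_T1w")
        with pytest.raises(ValueError, match="grid"):
            dv.b1_correct(ph.dce, ph.breast_coil, small)

    def test_zero_denominator_masked_and_reported(self, noiseless_phantom):
        ph = noiseless_phantom
        breast = dv.VolumeImage(ph.breast_coil.data.copy(),
                                ph.breast_coil.voxel_spacing,
                                "breast_coil_T1w")
        breast.data[0, 0, 0] = 0.0
        out = dv.b1_correct(ph.dce, breast, ph.body_coil)
        assert out.meta["b1_zero_denominator"] == 1
        assert np.all(out.data[0, 0, 0, :] == 0.0)


class TestSignalToConcentration:
    def test_pre_injection_concentration_is_zero(self, recovered_concentration):
        pre = recovered_concentration.data[..., :5]
        assert np.max(np.abs(pre)) < 1e-9

    def test_phantom_concentration_recovered(self, noiseless_phantom,
                                             recovered_concentration):
        """Noiseless phantom: full B1+SPGR inversion recovers the true
        concentration within 1% at every frame."""
        truth = noiseless_phantom.conc_truth.data
        scale = truth.max()
        assert np.max(np.abs(recovered_concentration.data - truth)) < 0.01 * scale

    def test_blood_and_tissue_t10(self, noiseless_phantom):
        """Blood voxels must be converted with T10=1200 ms: converting the
        LV with the tissue T10 misreads the curve."""
        ph = noiseless_phantom
        corrected = dv.b1_correct(ph.dce, ph.breast_coil, ph.body_coil)
        lv = ph.lv_mask.data
        right = dv.signal_to_concentration(corrected, ph.spec.conversion, 1200.0)
        wrong = dv.signal_to_concentration(corrected, ph.spec.conversion, 900.0)
        truth = ph.aif.cp
        err_right = np.abs(right.data[lv] - truth).max()
        err_wrong = np.abs(wrong.data[lv] - truth).max()
        assert err_right < 1e-6
        assert err_wrong > 0.1

    def test_relative_enhancement_mode(self, noiseless_phantom):
        ph = noiseless_phantom
        settings = dv.ConversionSettings(mode="relative_enhancement")
        out = dv.signal_to_concentration(ph.dce, settings)
        s0 = ph.dce.data[..., :5].mean(axis=3)
        assert np.allclose(out.data, (ph.dce.data - s0[..., None])
                           / s0[..., None])

    def test_unphysical_ratio_clamped_and_counted(self, noiseless_phantom):
        ph = noiseless_phantom
        data = ph.dce.data.copy()
        data[0, 0, 0, 10] = -50.0  # impossible signal
        series = ph.dce.with_data(data)
        out = dv.signal_to_concentration(series, ph.spec.conversion)
        assert out.meta["n_clamped"] >= 1
        assert np.all(np.isfinite(out.data))

    def test_missing_baseline_rejected(self, frame_times):
        series = dv.DCESeries(np.ones((4, 4, 2, 4)), frame_times[:4])
        with pytest.raises(ValueError, match="baseline"):
            dv.signal_to_concentration(series, n_pre_frames=5)

    def test_spgr_forward_inverse_consistency(self):
        """Inverting the forward SPGR signal returns the input C(t)."""
        c = np.linspace(0, 5, 11)
        t10, r1, tr, fa = 900.0, 5.0, 5.46, 12.0
        t1 = 1000.0 / (1000.0 / t10 + r1 * c)
        sig = spgr_signal(t1, 1000.0, tr, fa)
        series = dv.DCESeries(
            np.broadcast_to(sig, (2, 2, 1, 11)).copy() * 0
            + sig[None, None, None, :],
            np.arange(11) * 13.0)
        # baseline = first frames where c=0: emulate by prepending zeros
        data = np.concatenate([np.full((2, 2, 1, 5), sig[0]),
                               series.data], axis=3)
        full = dv.DCESeries(data, np.arange(16) * 13.0)
        out = dv.signal_to_concentration(full, dv.ConversionSettings(),
                                         t10, n_pre_frames=5)
        assert np.allclose(out.data[0, 0, 0, 5:], c, atol=1e-9)


class TestSubtractionImage:
    def test_constant_series_gives_zero(self, frame_times):
        series = dv.DCESeries(np.full((4, 4, 2, len(frame_times)), 7.0),
                              frame_times)
        sub = dv.subtraction_image(series, injection_time=65.0)
        assert np.all(sub.data == 0.0)

    def test_nearest_frame_selection(self, frame_times):
        """13 s grid, injection at 65 s: the 238 s post-injection frame is
        round((65+238)/13) = frame 23."""
        series = dv.DCESeries(np.zeros((2, 2, 1, len(frame_times))),
                              frame_times)
        sub = dv.subtraction_image(series, post_time=238.0, injection_time=65.0)
        assert sub.meta["post_frame_index"] == round((65 + 238) / 13)

    def test_phantom_enhancement_recovered(self, noiseless_phantom):
        ph = noiseless_phantom
        sub = dv.subtraction_image(ph.conc_truth, injection_time=65.0)
        idx = sub.meta["post_frame_index"]
        expected = ph.conc_truth.data[..., idx]
        assert np.allclose(sub.data, expected)

    def test_linearity(self, noiseless_phantom):
        ph = noiseless_phantom
        sub1 = dv.subtraction_image(ph.dce, injection_time=65.0)
        sub3 = dv.subtraction_image(ph.dce.with_data(3.0 * ph.dce.data),
                                    injection_time=65.0)
        assert np.allclose(sub3.data, 3.0 * sub1.data)

    def test_short_series_rejected(self):
        times = np.arange(0, 200, 13.0)
        series = dv.DCESeries(np.zeros((2, 2, 1, len(times))), times)
        with pytest.raises(ValueError, match="required"):
            dv.subtraction_image(series, injection_time=65.0)


class TestDetectOnset:
    def test_flat_curve_no_onset(self, frame_times):
        assert dv.detect_onset(np.zeros_like(frame_times), frame_times) \
            == dv.NO_ONSET

    def test_step_at_frame8(self, frame_times):
        curve = np.zeros_like(frame_times)
        curve[8:] = 5.0
        assert dv.detect_onset(curve, frame_times) == frame_times[8]

    def test_noisy_phantom_onset_within_one_frame(self, frame_times,
                                                  default_aif):
        """SNR-20 noise on an enhancement curve shifts the detected onset
        by at most one frame from the bolus arrival."""
        ct = dv.forward_etm(default_aif, 0.13, 0.55, 0.094, frame_times)
        rng = np.random.default_rng(1)
        errors = []
        for _ in range(50):
            noisy = ct + rng.normal(0, ct.max() / 20, ct.shape)
            onset = dv.detect_onset(noisy, frame_times, k=3.0)
            errors.append(abs(onset - 65.0))
        assert np.median(errors) <= 13.0

    def test_too_few_baseline_frames_rejected(self, frame_times):
        with pytest.raises(ValueError):
            dv.detect_onset(np.zeros_like(frame_times), frame_times,
                            baseline_frames=2)
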