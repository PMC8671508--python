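"""Reconstruction: NEX averaging, zero-pad display interpolation, EPI ghost
and distortion correction, ADC pipeline."""

import copy

import numpy as np
import pytest

from ulfmri.acquisition import dwi_epi, kspace_of_volume, simulate_epi_dwi, t2w_fse, \
    simulate_scan
from ulfmri.contrast import dwi_signal
from ulfmri.recon import (KSpaceVolume, adc_pipeline, average_nex,
                          distortion_correct, epi_ghost_correct,
                          estimate_ghost_phase, recon_cartesian, recon_dwi_scan)


class TestAverageNex:
    def test_single_average_is_identity_placement(self, shielded_record32):
        ksp = average_nex(shielded_record32)
        for line, (i1, i2, _) in zip(shielded_record32.acq_rx,
                                     shielded_record32.acq_coords):
            np.testing.assert_array_equal(ksp.data[:, i1, i2], line)

    def test_identical_repeats_average_to_themselves(self, phantom32):
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=2, char_count=1,
                           elliptic=False)
        rec = simulate_scan(phantom32, protocol, None, seed=0)  # noise-free
        ksp = average_nex(rec)
        np.testing.assert_allclose(ksp.data[:, rec.acq_coords[0][0],
                                            rec.acq_coords[0][1]],
                                   rec.acq_rx[0], rtol=1e-12)

    def test_noise_shrinks_with_sqrt_averages(self, phantom32):
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=8, char_count=1,
                           elliptic=False, receiver_noise_sigma=0.1)
        rec = simulate_scan(phantom32, protocol, None, seed=2)
        clean = simulate_scan(phantom32,
                              t2w_fse(matrix=(32, 32, 1), etl=8, nex=1,
                                      char_count=1, elliptic=False), None, seed=2)
        truth = average_nex(clean).data
        err = average_nex(rec).data - truth
        assert np.std(err[:, rec.mask]) == pytest.approx(0.1 / np.sqrt(8), rel=0.1)

    def test_missing_repeat_lists_coordinates(self, record32):
        rec = copy.copy(record32)
        rec.acq_rx = rec.acq_rx[:-1]
        rec.acq_coords = rec.acq_coords[:-1]
        with pytest.raises(ValueError, match="missing NEX repeats"):
            average_nex(rec)


class TestReconCartesian:
    def test_dc_delta_gives_constant_magnitude(self):
        k = np.zeros((8, 8, 1), complex)
        k[4, 4, 0] = 1.0
        img = recon_cartesian(k, (1, 1, 1))
        assert np.allclose(img.data, img.data.flat[0])

    def test_round_trip_exact_without_padding(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(16, 12, 4))
        img = recon_cartesian(kspace_of_volume(vol), (1, 1, 1))
        np.testing.assert_allclose(img.data, np.abs(vol), atol=1e-12)

    def test_display_resolution_from_pad_factors(self):
        """2 x 2 x 10 mm acquisition voxels with pad (2,2,2) display at
        1 x 1 x 5 mm."""
        k = KSpaceVolume(np.zeros((4, 4, 2), complex), np.ones((4, 2), bool),
                         voxel_size=(2.0, 2.0, 10.0))
        img = recon_cartesian(k, (2, 2, 2))
        assert img.voxel_size == (1.0, 1.0, 5.0)
        assert img.data.shape == (8, 8, 4)

    def test_zero_padding_preserves_original_sample_values(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(size=(8, 8, 1)) + 1j * rng.normal(size=(8, 8, 1))
        base = recon_cartesian(kspace_of_volume(vol), (1, 1, 1)).data
        padded = recon_cartesian(kspace_of_volume(vol), (2, 2, 1)).data
        np.testing.assert_allclose(padded[::2, ::2, :], base, atol=1e-10)

    def test_non_integer_pad_rejected(self):
        with pytest.raises(ValueError, match="integers"):
            recon_cartesian(np.zeros((4, 4, 1), complex), (1.5, 1, 1))


def _compact_phantom(field=None):
    """Object confined to the central quarter of the FOV so a half-FOV
    ghost replica lands on empty background."""
    from ulfmri.phantom import Phantom, default_tissues

    labels = np.zeros((32, 32, 1), np.int16)
    labels[10:22, 12:20, 0] = 2          # GM block
    return Phantom(labels, default_tissues(), (4.0, 4.0, 10.0), field_map=field)


def _ghosted_scan(phi0=0.3, phi1=0.05, field=None):
    p = _compact_phantom(field)
    prot = dwi_epi(matrix=(32, 32, 1), nex=1, b=0.0, ghost_phi0=phi0,
                   ghost_phi1=phi1)
    return p, simulate_epi_dwi(p, prot, None, seed=0)


def _ghost_ratio(img):
    """Mean intensity in the half-FOV-shifted replica region over the main
    object region."""
    n = img.shape[1]
    main = img[:, n // 4: 3 * n // 4]
    ghost = np.roll(img, n // 2, axis=1)[:, n // 4: 3 * n // 4]
    obj = main > 0.2 * main.max()
    return float(np.mean(ghost[obj]) / np.mean(main[obj]))


class TestEpiGhostCorrection:
    def test_zero_offset_leaves_kspace_unchanged(self):
        _, scan = _ghosted_scan(0.0, 0.0)
        k = scan.kspace["b0"][0]
        np.testing.assert_allclose(epi_ghost_correct(k, scan.reference["b0"]),
                                   k, atol=1e-10)

    def test_slope_estimated_within_one_percent(self):
        _, scan = _ghosted_scan(0.3, 0.05)
        phi0, phi1 = estimate_ghost_phase(scan.reference["b0"])
        assert phi1 == pytest.approx(0.05, rel=0.01)
        assert phi0 == pytest.approx(0.3, abs=0.01)

    def test_ghost_suppressed_below_five_percent(self):
        """Injected odd/even phase: >20% ghost before, <5% after."""
        _, scan = _ghosted_scan(0.6, 0.12)
        k = scan.kspace["b0"][0]
        img_bad = np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k))))
        kc = epi_ghost_correct(k, scan.reference["b0"])
        img_ok = np.abs(np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kc))))
        assert _ghost_ratio(img_bad) > 0.20
        assert _ghost_ratio(img_ok) < 0.05

    def test_correction_idempotent(self):
        """Correcting the reference scan itself (odd line treated like data)
        leaves no residual odd/even phase, so a second pass is a no-op."""
        _, scan = _ghosted_scan(0.4, 0.08)
        ref = scan.reference["b0"]
        k1 = epi_ghost_correct(scan.kspace["b0"][0], ref)
        # apply the same correction to the reference's odd line
        corr_ref = ref.copy()
        corr_ref[1] = epi_ghost_correct(ref[1][:, None].repeat(2, 1), ref)[:, 1]
        r0, r1 = estimate_ghost_phase(corr_ref)
        assert abs(r1) < 1e-6 and abs(r0) < 1e-4
        np.testing.assert_allclose(epi_ghost_correct(k1, corr_ref), k1, atol=1e-8)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            epi_ghost_correct(np.zeros((8, 8), complex), None)


class TestDistortionCorrection:
    def test_zero_field_map_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        np.testing.assert_allclose(
            distortion_correct(img, np.zeros((16, 16)), 30.0), img, atol=1e-12)

    def test_uniform_offset_rigidly_undone(self):
        """Uniform off-resonance f displaces by f/bw pixels; correction
        recovers the original up to edge voxels."""
        img = np.zeros((16, 16))
        img[4:12, 4:12] = 1.0
        bw = 30.0
        f = 60.0                       # displaces by -2 pixels
        displaced = np.roll(img, -2, axis=1)
        fixed = distortion_correct(displaced, np.full((16, 16), f), bw)
        np.testing.assert_allclose(fixed[:, 2:-2], img[:, 2:-2], atol=1e-9)

    def test_simulated_distortion_edges_within_half_pixel(self):
        """End-to-end: off-resonance during the EPI train shifts the object;
        correction brings phantom edges back within 0.5 pixel."""
        field = np.full((32, 32, 1), 50.0)   # Hz: ~2.4 pixel displacement
        p, scan = _ghosted_scan(0.0, 0.0, field=field)
        imgs_raw = recon_dwi_scan(scan, ghost_correct=False)
        imgs_fix = recon_dwi_scan(scan, ghost_correct=False, dist_correct=True,
                                  field_map=field[:, :, 0])
        clean = recon_dwi_scan(simulate_epi_dwi(
            _compact_phantom(), dwi_epi(matrix=(32, 32, 1), nex=1, b=0.0),
            None, seed=0), ghost_correct=False)
        shift_px = 50.0 / scan.protocol.pe_bandwidth_per_pixel

        def com(img):
            """Object position along PE: thresholded intensity center of
            mass (threshold kills Gibbs-ringing tails)."""
            w = np.where(img[16] > 0.2 * img[16].max(), img[16], 0.0)
            return float(np.sum(np.arange(len(w)) * w) / np.sum(w))

        assert abs(com(imgs_raw["b0"]) - com(clean["b0"])) == pytest.approx(
            shift_px, abs=0.5)
        assert abs(com(imgs_fix["b0"]) - com(clean["b0"])) <= 0.5


class TestAdcPipeline:
    def test_isotropic_phantom_combined_equals_directional(self):
        b0 = np.full((8, 8), 2.0)
        b1 = dwi_signal(b0, 1.0e-3, 500.0)
        iso, adc = adc_pipeline(b0, (b1, b1, b1), 500.0)
        np.testing.assert_allclose(iso, b1, rtol=1e-12)
        np.testing.assert_allclose(adc, 1.0e-3, rtol=1e-12)

    def test_csf_attenuation_strongest(self):
        """CSF at b = 500 and ADC 3.0e-3: b1/b0 ~ exp(-1.5) ~ 0.223."""
        assert dwi_signal(1.0, 3.0e-3, 500.0) == pytest.approx(np.exp(-1.5),
                                                               rel=1e-12)
        for adc in (0.7e-3, 0.8e-3, 1.1e-3):
            assert dwi_signal(1.0, adc, 500.0) > dwi_signal(1.0, 3.0e-3, 500.0)

    def test_background_masked_out(self):
        b0 = np.zeros((8, 8))
        b0[2:6, 2:6] = 1.0
        b1 = dwi_signal(b0, 0.8e-3, 500.0)
        _, adc = adc_pipeline(b0, (b1, b1, b1), 500.0)
        assert np.all(adc[b0 == 0] == 0.0)
        np.testing.assert_allclose(adc[b0 > 0], 0.8e-3, rtol=1e-9)
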