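"""Dual-window acquisition simulation: masks, DFT content, twins, EPI."""

import numpy as np
import pytest

from ulfmri.acquisition import (ProtocolConfig, dwi_epi, elliptic_mask,
                                kspace_of_volume, signal_volume, simulate_epi_dwi,
                                simulate_scan, t2w_fse, t2w_smoke)
from ulfmri.contrast import SequenceKind
from ulfmri.phantom import make_phantom

from conftest import small_world


class TestEllipticMask:
    def test_single_point_grid_is_dc_only(self):
        m = elliptic_mask(1, 1)
        assert m.shape == (1, 1) and m[0, 0]

    def test_nine_by_nine_matches_lattice_enumeration(self):
        """Brute-force oracle: integer points inside the circle of radius 4."""
        m = elliptic_mask(9, 9)
        count = 0
        for k1 in range(-4, 5):
            for k2 in range(-4, 5):
                if (k1 / 4) ** 2 + (k2 / 4) ** 2 <= 1:
                    count += 1
        assert count == 49
        assert int(m.sum()) == count

    def test_large_grid_fraction_near_pi_over_four(self):
        m = elliptic_mask(128, 32)
        frac = m.sum() / m.size
        assert 0.76 <= frac <= 0.80

    def test_dc_always_included(self):
        for n1, n2 in [(2, 2), (3, 5), (64, 1)]:
            assert elliptic_mask(n1, n2)[n1 // 2, n2 // 2]


class TestProtocolConfig:
    def test_characterization_overhead_must_fit_in_tr(self):
        """The EMI characterization acquisition is genuine time overhead."""
        with pytest.raises(ValueError, match="characterization"):
            ProtocolConfig(SequenceKind.FSE3D, tr=20.0, te=10.0,
                           matrix=(64, 64, 1), etl=8, char_count=16)

    def test_paper_protocol_presets(self):
        t2 = t2w_fse()
        assert (t2.tr, t2.te, t2.etl, t2.nex) == (1500.0, 202.0, 21, 2)
        assert t2.matrix == (128, 126, 32)
        dwi = dwi_epi()
        assert (dwi.tr, dwi.te, dwi.nex) == (2800.0, 102.0, 52)
        assert dwi.diffusion.b == 500.0


class TestSimulateScan:
    def test_noiseless_shielded_lines_are_dft_rows(self, phantom32):
        """With no EMI and no noise, characterization windows are exactly 0
        and each FE line equals its k-space column to machine precision."""
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=4,
                           elliptic=False)
        rec = simulate_scan(phantom32, protocol, None, seed=0)
        assert np.all(rec.char_rx == 0)
        ksp = kspace_of_volume(signal_volume(phantom32, protocol))
        for line, (i1, i2, _) in zip(rec.acq_rx, rec.acq_coords):
            np.testing.assert_allclose(line, ksp[:, i1, i2], atol=1e-12)

    def test_parseval_energy_identity(self, phantom32):
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=1,
                           elliptic=False)
        vol = signal_volume(phantom32, protocol)
        ksp = kspace_of_volume(vol)
        assert np.sum(np.abs(ksp) ** 2) == pytest.approx(np.sum(vol**2), rel=1e-12)

    def test_determinism(self, phantom32):
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=2,
                           elliptic=False, receiver_noise_sigma=0.01)
        w = small_world()
        a = simulate_scan(phantom32, protocol, w, seed=3)
        b = simulate_scan(phantom32, protocol, w, seed=3)
        np.testing.assert_array_equal(a.acq_rx, b.acq_rx)
        np.testing.assert_array_equal(a.char_sens, b.char_sens)

    def test_twin_differs_only_by_replayed_emi(self, record32):
        """Contaminated minus shielded receive equals the noise-free coupled
        EMI replay; sensing data are shared (coils never see MRI signal)."""
        twin = record32.shielded_twin()
        np.testing.assert_array_equal(record32.acq_sens, twin.acq_sens)
        diff = record32.acq_rx - twin.acq_rx
        np.testing.assert_allclose(diff, record32.emi_replay(), rtol=1e-10)

    def test_shot_accounting_and_scan_time(self, record32):
        p = record32.protocol
        assert record32.meta["shots"] * p.etl >= record32.meta["n_masked_pe"]
        assert record32.meta["scan_time_s"] == pytest.approx(
            record32.meta["shots"] * p.nex * p.tr * 1e-3)

    def test_phantom_protocol_mismatch_rejected(self, phantom32):
        with pytest.raises(ValueError, match="does not match"):
            simulate_scan(phantom32, t2w_smoke(), None, seed=0)


class TestEpiDwi:
    def test_clean_epi_equals_ideal_dft(self):
        """Zero ghost offset and no field map: EPI k-space after bookkeeping
        equals the plain DFT of the diffusion-weighted slice."""
        p = make_phantom((32, 32, 1))
        prot = dwi_epi(matrix=(32, 32, 1), nex=1, b=0.0)
        scan = simulate_epi_dwi(p, prot, None, seed=0)
        vol = signal_volume(p, prot)
        np.testing.assert_allclose(scan.kspace["b0"][0],
                                   kspace_of_volume(vol)[:, :, 0], atol=1e-12)

    def test_b1_attenuation_follows_adc(self):
        """Per-tissue ratio of b1 to b0 image matches exp(-b * ADC)."""
        p = make_phantom((32, 32, 1))
        prot = dwi_epi(matrix=(32, 32, 1), nex=1)
        scan = simulate_epi_dwi(p, prot, None, seed=0)
        from ulfmri.recon import recon_dwi_scan

        imgs = recon_dwi_scan(scan, ghost_correct=False)
        names = [t.name for t in p.tissues]
        for tissue in ("WM", "GM"):
            m = (p.labels[:, :, 0] == names.index(tissue))
            # erode against edge ringing by keeping interior voxels only
            ratio = np.median(imgs["b1x"][m] / imgs["b0"][m])
            adc = p.tissues[names.index(tissue)].adc
            assert ratio == pytest.approx(np.exp(-500.0 * adc), rel=0.02)

    def test_nex_averaging_shrinks_noise(self):
        """Monte-Carlo check of the 1/sqrt(NEX) law at NEX = 52 for b0."""
        p = make_phantom((16, 16, 1))
        prot = dwi_epi(matrix=(16, 16, 1), nex=52, receiver_noise_sigma=0.1,
                       char_count=1, b=0.0)
        scan = simulate_epi_dwi(p, prot, None, seed=1)
        truth = _true_kspace(p, prot)
        sd_single = np.std(scan.kspace["b0"][0] - truth)
        sd_mean = np.std(scan.kspace["b0"].mean(axis=0) - truth)
        assert sd_single == pytest.approx(0.1, rel=0.1)
        assert sd_mean == pytest.approx(sd_single / np.sqrt(52), rel=0.15)

    def test_missing_field_map_with_distortion(self):
        p = make_phantom((16, 16, 1))
        prot = dwi_epi(matrix=(16, 16, 1), nex=1)
        scan = simulate_epi_dwi(p, prot, None, seed=0)
        from ulfmri.recon import recon_dwi_scan

        with pytest.raises(ValueError, match="field map"):
            recon_dwi_scan(scan, dist_correct=True)


def _true_kspace(p, prot):
    vol = signal_volume(p, prot)
    return kspace_of_volume(vol)[:, :, 0]
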