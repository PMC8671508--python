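"""Canceller contracts: training-set assembly, CNN training behaviour,
per-scan discipline, and the linear least-squares baseline."""

import numpy as np
import pytest

from ulfmri.acquisition import t2w_fse, simulate_scan
from ulfmri.canceller import (LinearCanceller, TrainConfig,
                              apply_linear, assemble_training, build_cnn,
                              cancel, fit_linear, predict_emi, predict_linear,
                              train_cnn)
from conftest import small_world


def _zeroed_model(record, epochs=1):
    """A trained model with the last layer nulled: predicts exactly 0."""
    cfg = TrainConfig(epochs=epochs, seed=0)
    model = train_cnn(assemble_training(record, cfg), cfg)
    last = model.net.layers[-1]
    last.W[:] = 0.0
    last.b[:] = 0.0
    return model


class TestAssembleTraining:
    def test_split_fractions_and_partition(self, record32):
        """85/15 split: disjoint index sets covering all windows."""
        ts = assemble_training(record32)
        n = record32.n_char_windows
        assert len(ts.train_idx) == int(np.floor(0.85 * n))
        assert len(ts.train_idx) + len(ts.val_idx) == n
        assert set(ts.train_idx).isdisjoint(ts.val_idx)
        assert set(ts.train_idx) | set(ts.val_idx) == set(range(n))

    def test_hundred_windows_split_85_15(self, record32):
        import copy

        rec = copy.copy(record32)
        n_x = record32.char_rx.shape[1]
        rec.char_rx = np.resize(record32.char_rx, (100, n_x))
        rec.char_sens = np.resize(record32.char_sens, (100, 10, n_x))
        ts = assemble_training(rec)
        assert len(ts.train_idx) == 85 and len(ts.val_idx) == 15

    def test_examples_come_from_characterization_windows_only(self, record32):
        """Inputs/targets are exactly the characterization data (no MRI
        acquisition window leaks into training)."""
        ts = assemble_training(record32)
        k = 5
        np.testing.assert_allclose(
            ts.x[k] * ts.x_scale,
            np.stack([record32.char_sens[k].real.T,
                      record32.char_sens[k].imag.T], axis=-1), rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(
            ts.y[k] * ts.y_scale,
            np.stack([record32.char_rx[k].real, record32.char_rx[k].imag], axis=-1),
            rtol=1e-5, atol=1e-7)

    def test_too_few_windows_advises_more(self, record32):
        import copy

        rec = copy.copy(record32)
        rec.char_rx = record32.char_rx[:8]
        rec.char_sens = record32.char_sens[:8]
        with pytest.raises(ValueError, match="characterization windows"):
            assemble_training(rec)


class TestCnnTraining:
    def test_architecture_matches_specification(self):
        """Five conv layers (11,9,5,1,7 kernels; 128,64,32,32,2 channels),
        batch norm + ReLU on all but the last."""
        net = build_cnn(seed=0)
        convs = [l for l in net.layers if hasattr(l, "W")
                 and getattr(l, "kh", None) is not None]
        assert [(l.kh, l.kw) for l in convs] == [(11, 11), (9, 9), (5, 5),
                                                 (1, 1), (7, 7)]
        assert [l.c_out for l in convs] == [128, 64, 32, 32, 2]
        assert len(net.layers) == 4 * 3 + 1  # conv+bn+relu x4, conv only x1

    def test_zero_data_trains_to_zero(self, shielded_record32):
        """All-zero inputs and targets (noise-free shielded scan has empty
        characterization windows): validation loss and predictions ~ 0."""
        import copy

        rec = copy.copy(shielded_record32)
        rec.char_rx = np.zeros_like(rec.char_rx)
        rec.char_sens = np.zeros_like(rec.char_sens)
        cfg = TrainConfig(epochs=1, seed=0)
        model = train_cnn(assemble_training(rec, cfg), cfg)
        assert model.history["val_loss"][-1] < 1e-6
        pred = predict_emi(model, rec.char_sens[0])
        assert np.max(np.abs(pred)) < 1e-6

    def test_validation_loss_decreases_on_emi_data(self, record32):
        cfg = TrainConfig(epochs=4, seed=1)
        model = train_cnn(assemble_training(record32, cfg), cfg)
        hist = model.history["val_loss"]
        assert len(hist) == cfg.epochs + 1        # epoch 0 entry + per epoch
        assert hist[-1] < hist[0]
        assert len(model.history["train_loss"]) == cfg.epochs

    def test_training_deterministic_given_seed(self, record32):
        cfg = TrainConfig(epochs=1, seed=3)
        a = train_cnn(assemble_training(record32, cfg), cfg)
        b = train_cnn(assemble_training(record32, cfg), cfg)
        assert a.history == b.history

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_reported_with_epoch_and_lr(self, record32):
        cfg = TrainConfig(epochs=2, seed=0, lr=1e12)
        with pytest.raises(FloatingPointError, match="lr"):
            train_cnn(assemble_training(record32, cfg), cfg)


class TestPredictAndCancel:
    def test_zero_model_cancel_is_identity(self, record32):
        model = _zeroed_model(record32)
        cleaned = cancel(record32, model)
        np.testing.assert_array_equal(cleaned.acq_rx, record32.acq_rx)
        np.testing.assert_array_equal(cleaned.acq_sens, record32.acq_sens)

    def test_shape_mismatch_rejected(self, record32):
        model = _zeroed_model(record32)
        with pytest.raises(ValueError, match="sensing shape"):
            predict_emi(model, np.zeros((5, 64), complex))

    def test_per_scan_training_contract(self, record32, phantom32):
        """A model refuses to cancel a record it was not trained on."""
        model = _zeroed_model(record32)
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=10,
                           elliptic=False, receiver_noise_sigma=0.005)
        other = simulate_scan(phantom32, protocol, small_world(seed=99), seed=42)
        with pytest.raises(ValueError, match="per-scan"):
            cancel(other, model)
        assert cancel(other, model, allow_foreign=True) is not None


class TestLinearCanceller:
    def test_scalar_coupling_recovered_exactly(self, record32):
        """receive = 2 x (coil 1), one tap, no noise: coefficient 2 and
        machine-precision residual."""
        import copy

        rec = copy.copy(record32)
        rec.char_rx = 2.0 * record32.char_sens[:, 0, :]
        lc = fit_linear(rec, taps=1)
        assert lc.coeffs[0, 0] == pytest.approx(2.0, rel=1e-10)
        assert np.max(np.abs(lc.coeffs[1:])) < 1e-8
        assert lc.residual_mse < 1e-20

    def test_four_tap_ground_truth_recovered(self, record32):
        """Constructed system with known 4-tap FIR solution."""
        import copy

        rng = np.random.default_rng(8)
        truth = LinearCanceller(coeffs=(rng.normal(size=(10, 4))
                                        + 1j * rng.normal(size=(10, 4))))
        rec = copy.copy(record32)
        rec.char_rx = predict_linear(truth, record32.char_sens)
        lc = fit_linear(rec, taps=4, drop_edge=False)
        np.testing.assert_allclose(lc.coeffs, truth.coeffs, rtol=1e-6)

    def test_rank_deficient_without_regularization(self, record32):
        import copy

        rec = copy.copy(record32)
        sens = record32.char_sens.copy()
        sens[:, 1:, :] = sens[:, :1, :]          # all coils identical
        rec.char_sens = sens
        rec.char_rx = sens[:, 0, :]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_linear(rec, taps=2)
        assert fit_linear(rec, taps=2, reg=1e-6) is not None

    def test_residual_floor_grows_with_sensor_noise(self, phantom32):
        """Monte-Carlo sweep: more sensor noise, higher fit residual."""
        protocol = t2w_fse(matrix=(32, 32, 1), etl=8, nex=1, char_count=10,
                           elliptic=False)
        resid = []
        for sigma in (0.001, 0.01, 0.1):
            w = small_world(seed=3, sensor_noise_sigma=sigma, receive_gain=1.0)
            rec = simulate_scan(phantom32, protocol, w, seed=5)
            resid.append(fit_linear(rec, taps=3, reg=1e-12).residual_mse)
        assert resid[0] < resid[1] < resid[2]

    def test_apply_mirrors_cancel(self, record32):
        """Away from the first taps-1 samples (whose lags reach before the
        window), the linear prediction removes nearly all EMI."""
        lc = fit_linear(record32, taps=3, reg=1e-12)
        cleaned = apply_linear(lc, record32)
        resid = (cleaned.acq_rx - record32.acq_rx_shielded)[:, 2:]
        before = (record32.acq_rx - record32.acq_rx_shielded)[:, 2:]
        assert np.mean(np.abs(resid) ** 2) < 0.01 * np.mean(np.abs(before) ** 2)
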