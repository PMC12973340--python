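"""VAE engine: architecture, loss, gradients, training contract, inference."""

import numpy as np
import pytest

from connvae.preprocess import ModelVector
from connvae.vae import (
    TrainedVAE,
    VAEConfig,
    VAETrainingError,
    build_vae,
    fine_tune,
    forward,
    loss_and_grads,
    reconstruct_subject,
    reconstruction_quality,
    train_vae,
    vae_loss,
)

TINY = VAEConfig(encoder_widths=(16, 8), decoder_widths=(8, 16), latent_dim=3,
                 batch_size=4, seed=3)


class TestArchitecture:
    def test_layer_widths_mirror_input(self):
        model = build_vae(VAEConfig(seed=0), 43_890)
        assert model.params["enc0_W"].shape == (43_890, 512)
        assert model.params["dec3_W"].shape == (512, 43_890)
        assert model.params["mu_W"].shape == (128, 8)
        assert model.params["logvar_W"].shape == (128, 8)

    def test_latent_heads_emit_means_and_logvars(self):
        model = build_vae(TINY, 20)
        x = np.zeros((2, 20))
        _, mu, logvar, *_ = forward(model, x)
        assert mu.shape == (2, 3)
        assert logvar.shape == (2, 3)

    def test_same_seed_identical_initialization(self):
        a = build_vae(TINY, 20)
        b = build_vae(TINY, 20)
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestLoss:
    def test_matched_gaussian_kl_is_zero(self):
        x = np.ones((2, 5))
        total, recon, kl = vae_loss(x, x, np.zeros((2, 3)), np.zeros((2, 3)), 0.1)
        assert kl == 0.0
        assert recon == 0.0
        assert total == 0.0

    def test_unit_mean_one_dimension_kl_half(self):
        x = np.zeros((1, 5))
        _, _, kl = vae_loss(x, x, np.ones((1, 1)), np.zeros((1, 1)), 1.0)
        assert kl == pytest.approx(0.5)

    def test_beta_norm_zero_reduces_to_autoencoder(self):
        rng = np.random.default_rng(0)
        x, xhat = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        mu, lv = rng.normal(size=(2, 3)), rng.normal(size=(2, 3))
        total, recon, _ = vae_loss(x, xhat, mu, lv, 0.0)
        assert total == recon

    def test_beta_norm_scales_with_input_length(self):
        cfg = VAEConfig()
        assert cfg.beta_norm(43_890) == pytest.approx(8 / 43_890)
        assert cfg.beta_norm(100) == pytest.approx(0.08)

    def test_non_finite_loss_aborts(self):
        x = np.zeros((1, 2))
        with pytest.raises(VAETrainingError):
            vae_loss(x, x + np.inf, np.zeros((1, 1)), np.zeros((1, 1)), 1.0)


def test_backprop_matches_finite_differences():
    """Analytic gradients agree with central finite differences on every
    parameter of a tiny network, with a fixed reparameterization draw."""
    rng = np.random.default_rng(9)
    model = build_vae(TINY, 10)
    x = rng.normal(size=(4, 10))
    eps = rng.normal(size=(4, 3))
    (_, _, _), grads = loss_and_grads(model, x, eps)
    h = 1e-6
    for name in ("enc0_W", "enc1_b", "mu_W", "logvar_b", "dec0_W", "dec2_b"):
        p = model.params[name]
        flat_idx = [0, p.size // 2, p.size - 1]
        for idx in flat_idx:
            orig = p.flat[idx]
            p.flat[idx] = orig + h
            up = loss_and_grads(model, x, eps)[0][0]
            p.flat[idx] = orig - h
            down = loss_and_grads(model, x, eps)[0][0]
            p.flat[idx] = orig
            numeric = (up - down) / (2 * h)
            assert grads[name].flat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-9)


class TestTrainingContract:
    def _data(self, n=12, d=10, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=d)
        return base + 0.1 * rng.normal(size=(n, d)), base + 0.1 * rng.normal(size=(4, d))

    def test_validation_loss_decreases_on_learnable_data(self):
        train, val = self._data()
        cfg = VAEConfig(**{**TINY.__dict__, "max_epochs": 60, "patience": 100})
        model = train_vae(train, val, cfg)
        assert model.history[-1]["val_total"] < model.history[0]["val_total"]

    def test_zero_learning_rate_stops_at_patience(self):
        train, val = self._data()
        cfg = VAEConfig(**{**TINY.__dict__, "max_epochs": 100, "patience": 5,
                           "learning_rate": 0.0})
        model = train_vae(train, val, cfg)
        assert len(model.history) <= 6

    def test_same_seed_identical_history(self):
        train, val = self._data()
        cfg = VAEConfig(**{**TINY.__dict__, "max_epochs": 10})
        h1 = train_vae(train, val, cfg).history
        h2 = train_vae(train, val, cfg).history
        assert h1 == h2

    def test_empty_split_rejected(self):
        with pytest.raises(VAETrainingError):
            train_vae(np.zeros((0, 4)), np.zeros((2, 4)), TINY)


class TestFineTune:
    def _model(self):
        train, val = np.zeros((6, 10)) + 0.1, np.zeros((2, 10)) + 0.1
        cfg = VAEConfig(**{**TINY.__dict__, "max_epochs": 5})
        return train_vae(train, val, cfg), train, val

    def test_zero_epochs_keeps_weights(self):
        model, train, val = self._model()
        tuned = fine_tune(model, train, val, {"max_epochs": 0})
        assert tuned.provenance == "fine_tuned"
        assert all(np.array_equal(tuned.params[k], model.params[k])
                   for k in model.params)

    def test_adaptation_never_hurts_validation(self):
        model, _, _ = self._model()
        rng = np.random.default_rng(4)
        shifted_train = rng.normal(0.5, 0.05, (6, 10))
        shifted_val = rng.normal(0.5, 0.05, (3, 10))
        from connvae.vae import _eval_loss
        before = _eval_loss(model, shifted_val)[0]
        tuned = fine_tune(model, shifted_train, shifted_val, {"max_epochs": 30})
        after = _eval_loss(tuned, shifted_val)[0]
        assert after <= before

    def test_double_fine_tune_rejected(self):
        model, train, val = self._model()
        tuned = fine_tune(model, train, val, {"max_epochs": 0})
        with pytest.raises(VAETrainingError, match="healthy-trained"):
            fine_tune(tuned, train, val)

    def test_empty_patient_split_rejected(self):
        model, train, _ = self._model()
        with pytest.raises(VAETrainingError, match="empty"):
            fine_tune(model, train, np.zeros((0, 10)))


class TestReconstruction:
    def test_output_ranges_and_determinism(self):
        p = 6
        model = build_vae(TINY, p * (p - 1))
        rng = np.random.default_rng(1)
        vec = ModelVector("s", rng.normal(size=p * (p - 1)), p)
        fc1, sc1 = reconstruct_subject(model, vec)
        fc2, sc2 = reconstruct_subject(model, vec)
        assert np.array_equal(fc1.values, fc2.values)  # inference never samples
        assert np.abs(fc1.values).max() < 1.0
        assert sc1.values.min() >= 0.0
        assert np.array_equal(sc1.values, sc2.values)

    def test_vector_length_mismatch_rejected(self):
        model = build_vae(TINY, 30)
        vec = ModelVector("s", np.zeros(12), 4)
        with pytest.raises(VAETrainingError):
            reconstruct_subject(model, vec)


class TestReconstructionQuality:
    def _sym(self, rng, p=8):
        m = rng.normal(size=(p, p))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_identity_and_sign_flip(self):
        m = self._sym(np.random.default_rng(2))
        assert reconstruction_quality(m, m) == (0.0, pytest.approx(1.0))
        assert reconstruction_quality(m, -m)[1] == pytest.approx(-1.0)

    def test_matches_brute_force_rank_correlation(self):
        rng = np.random.default_rng(3)
        a, b = self._sym(rng), self._sym(rng)
        iu = np.triu_indices(8, k=1)
        ra = np.argsort(np.argsort(a[iu])).astype(float)
        rb = np.argsort(np.argsort(b[iu])).astype(float)
        oracle = float(np.corrcoef(ra, rb)[0, 1])  # Pearson on ranks, no ties
        assert reconstruction_quality(a, b)[1] == pytest.approx(oracle, abs=1e-12)

    def test_constant_matrix_sentinel(self):
        m = np.zeros((4, 4))
        mse, rho = reconstruction_quality(m, m)
        assert mse == 0.0 and np.isnan(rho)
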