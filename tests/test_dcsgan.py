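from dataclasses import replace

import numpy as np
import pytest

from diabsgan import (
    DCSGANConfig,
    adversarial_value,
    classifier_loss,
    combined_objective,
    generate_samples,
    predict,
    train_dcsgan,
)
from diabsgan.dcsgan import EPS


def _log_loss_oracle(probs, labels):
    """Independent categorical log-loss: explicit one-hot double sum."""
    n, k = probs.shape
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    return -np.sum(onehot * np.log(np.clip(probs, EPS, 1.0))) / n


class TestClassifierLoss:
    def test_perfect_classifier_zero_loss(self):
        assert classifier_loss(np.array([[1.0, 0.0]]), np.array([0])) == 0.0

    def test_uniform_binary_is_ln2(self):
        loss = classifier_loss(np.array([[0.5, 0.5]]), np.array([0]))
        assert loss == pytest.approx(np.log(2), abs=1e-10)

    def test_mean_invariance_under_duplication(self):
        p = np.array([[0.7, 0.3]])
        one = classifier_loss(p, np.array([1]))
        many = classifier_loss(np.repeat(p, 10, axis=0), np.ones(10, dtype=int))
        assert many == pytest.approx(one)

    def test_zero_probability_clamped_finite(self):
        loss = classifier_loss(np.array([[0.0, 1.0]]), np.array([0]))
        assert np.isfinite(loss) and loss == pytest.approx(-np.log(EPS))

    def test_matches_independent_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = rng.uniform(size=(15, 4))
            probs = raw / raw.sum(axis=1, keepdims=True)
            labels = rng.integers(0, 4, size=15)
            assert classifier_loss(probs, labels) == pytest.approx(
                _log_loss_oracle(probs, labels), abs=1e-10
            )


class TestAdversarialValue:
    def test_half_half_is_two_ln_half(self):
        v = adversarial_value(np.full(4, 0.5), np.full(4, 0.5))
        assert v == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_perfect_discriminator_approaches_zero_from_below(self):
        v = adversarial_value(np.full(3, 1 - 1e-9), np.full(3, 1e-9))
        assert -1e-8 < v < 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        dr, df = rng.uniform(0.1, 0.9, 10), rng.uniform(0.1, 0.9, 10)
        assert adversarial_value(dr, df) == pytest.approx(
            adversarial_value(rng.permutation(dr), rng.permutation(df))
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adversarial_value(np.array([1.0]), np.array([0.5]))


class TestCombinedObjective:
    def test_lambda_zero_reduces_to_plain_gan(self):
        rng = np.random.default_rng(2)
        dr, df = rng.uniform(0.1, 0.9, 8), rng.uniform(0.1, 0.9, 8)
        raw = rng.uniform(size=(8, 3))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 3, size=8)
        v, _ = combined_objective(dr, df, probs, labels, lambda_c=0.0)
        assert v == pytest.approx(adversarial_value(dr, df), abs=1e-12)

    def test_linear_in_lambda(self):
        rng = np.random.default_rng(3)
        dr, df = rng.uniform(0.1, 0.9, 5), rng.uniform(0.1, 0.9, 5)
        raw = rng.uniform(size=(5, 2))
        probs = raw / raw.sum(axis=1, keepdims=True)
        labels = rng.integers(0, 2, size=5)
        base = adversarial_value(dr, df)
        v1, lc = combined_objective(dr, df, probs, labels, 1.0)
        v2, _ = combined_objective(dr, df, probs, labels, 2.0)
        assert v2 - base == pytest.approx(2 * (v1 - base), rel=1e-12)
        assert lc == pytest.approx(classifier_loss(probs, labels))


class TestTraining:
    def test_zero_epochs_gives_initialized_model(self, gaussian_fixture, tiny_gan_config):
        cfg = replace(tiny_gan_config, epochs=0)
        model = train_dcsgan(gaussian_fixture, cfg)
        assert model.history == []
        _, probs = predict(model, gaussian_fixture.features[:5])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_seeded_training_bit_reproducible(self, gaussian_fixture, tiny_gan_config):
        m1 = train_dcsgan(gaussian_fixture, tiny_gan_config)
        m2 = train_dcsgan(gaussian_fixture, tiny_gan_config)
        assert m1.history == m2.history  # bit-identical floats
        for a, b in zip(m1.generator.flat_params, m2.generator.flat_params):
            np.testing.assert_array_equal(a, b)

    def test_unlabeled_dataset_rejected(self, gaussian_fixture, tiny_gan_config):
        ds = gaussian_fixture.copy()
        ds.labels = None
        with pytest.raises(ValueError, match="label"):
            train_dcsgan(ds, tiny_gan_config)

    def test_discriminator_step_increases_value_on_fixed_batch(self, gaussian_fixture):
        """Small-step gradient sanity: one D update must not decrease V."""
        from diabsgan.dcsgan import _Adam, _Discriminator, _Generator

        cfg = DCSGANConfig(latent_dim=8, gen_hidden=(16,), disc_hidden=(16,),
                           batch_size=64, seed=1, learning_rate=1e-5)
        rng = np.random.default_rng(0)
        x = gaussian_fixture.features[:64]
        x = (x - x.mean(0)) / x.std(0)
        y = gaussian_fixture.labels[:64]
        gen = _Generator(rng, cfg, x.shape[1])
        disc = _Discriminator(rng, cfg, x.shape[1])
        z = rng.standard_normal((64, cfg.latent_dim))
        x_fake, _ = gen.forward(z)

        def value():
            d_real, probs, _ = disc.forward(x)
            d_fake, _, _ = disc.forward(x_fake)
            dr = np.clip(d_real, 1e-12, 1 - 1e-12)
            df = np.clip(d_fake, 1e-12, 1 - 1e-12)
            # V to be *maximized* by D: adv value minus lambda*CE
            return adversarial_value(dr, df) - cfg.lambda_c * classifier_loss(probs, y)

        before = value()
        d_real, probs, cache_r = disc.forward(x)
        d_fake, _, cache_f = disc.forward(x_fake)
        onehot = np.zeros_like(probs)
        onehot[np.arange(64), y] = 1.0
        g_real, _ = disc.backward((d_real - 1) / 64, cfg.lambda_c * (probs - onehot) / 64, cache_r)
        g_fake, _ = disc.backward(d_fake / 64, None, cache_f)
        opt = _Adam(disc.flat_params, cfg.learning_rate)
        opt.step([a + b for a, b in zip(g_real, g_fake)])
        assert value() >= before

    def test_separable_gaussians_high_holdout_accuracy(self, gaussian_fixture):
        """Two clusters 8σ apart: the classification head must nail held-out data."""
        n = gaussian_fixture.n_samples
        train, test = gaussian_fixture.subset(np.arange(480)), gaussian_fixture.subset(
            np.arange(480, n)
        )
        model = train_dcsgan(train, DCSGANConfig(epochs=100, seed=7))
        y_pred, probs = predict(model, test.features)
        assert np.mean(y_pred == test.labels) >= 0.95
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert len(model.history) == 100


class TestPredictAndGenerate:
    @pytest.fixture(scope="class")
    def trained(self, gaussian_fixture):
        # default architecture, trained to convergence on the fixture
        return train_dcsgan(gaussian_fixture, DCSGANConfig(seed=11))

    def test_probability_rows_sum_to_one(self, trained, gaussian_fixture):
        _, probs = predict(trained, gaussian_fixture.features)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_row_identical_prediction(self, trained, gaussian_fixture):
        row = gaussian_fixture.features[:1]
        labels, probs = predict(trained, np.vstack([row, row]))
        assert labels[0] == labels[1]
        np.testing.assert_array_equal(probs[0], probs[1])

    def test_dimension_mismatch_raises(self, trained):
        with pytest.raises(ValueError, match="features"):
            predict(trained, np.zeros((3, 5)))

    def test_generated_shape_and_determinism(self, trained):
        g1 = generate_samples(trained, 5, seed=3)
        g2 = generate_samples(trained, 5, seed=3)
        assert g1.shape == (5, 8)
        np.testing.assert_array_equal(g1, g2)
        with pytest.raises(ValueError):
            generate_samples(trained, 0, seed=3)

    def test_generated_means_near_real_means(self, trained, gaussian_fixture):
        """Loose distribution-matching check at convergence."""
        gen = generate_samples(trained, 2000, seed=9)
        real = gaussian_fixture.features
        diff = np.abs(gen.mean(0) - real.mean(0)) / real.std(0)
        assert diff.max() < 0.5

    def test_save_load_round_trip(self, trained, tmp_path, gaussian_fixture):
        from diabsgan import TrainedDCSGAN

        path = tmp_path / "model.npz"
        trained.save(path)
        back = TrainedDCSGAN.load(path)
        _, p1 = predict(trained, gaussian_fixture.features[:10])
        _, p2 = predict(back, gaussian_fixture.features[:10])
        np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        DCSGANConfig(gen_hidden=(0,))
    with pytest.raises(ValueError):
        DCSGANConfig(lambda_c=-1)
    with pytest.raises(ValueError):
        DCSGANConfig(n_classes=1)
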