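"""SIRT: IS divergence, autoencoder training, residual transform, batching."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegrobust as er


class TestISDivergence:
    def test_zero_iff_equal(self, rng):
        x = rng.gamma(2.0, 1.0, 50)
        assert er.is_divergence(x, x) == pytest.approx(0.0, abs=1e-12)
        assert er.is_divergence(x, x * 1.01) > 0

    def test_reference_value(self):
        # D([2] || [1]) = 2 - ln 2 - 1 = 1 - ln 2
        assert er.is_divergence([2.0], [1.0]) == pytest.approx(
            1 - np.log(2), rel=1e-12)

    def test_matches_brute_force_sum(self, rng):
        x = rng.gamma(2.0, 1.0, 30)
        xhat = rng.gamma(2.0, 1.0, 30) + 0.1
        expected = sum(a / b - np.log(a / b) - 1 for a, b in zip(x, xhat))
        assert er.is_divergence(x, xhat) == pytest.approx(expected, rel=1e-10)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(1e-3, 1e3), st.integers(0, 2 ** 31 - 1))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 1.0, 10)
        xhat = rng.gamma(2.0, 1.0, 10) + 0.1
        assert er.is_divergence(c * x, c * xhat) == pytest.approx(
            er.is_divergence(x, xhat), rel=1e-9)

    def test_nonpositive_reconstruction_rejected(self):
        with pytest.raises(ValueError):
            er.is_divergence([1.0], [0.0])


@pytest.fixture(scope="module")
def factorizable():
    """Data that is exactly a non-negative rank-3 product H0 @ W0."""
    rng = np.random.default_rng(1)
    H0 = rng.gamma(2.0, 1.0, (600, 3))
    W0 = rng.gamma(2.0, 1.0, (3, 30))
    return H0 @ W0


@pytest.fixture(scope="module")
def fitted(factorizable):
    cfg = er.SIRTConfig(latent_dim=5, dropout_p=0.0, epochs=60,
                        encoder_weight_decay=0.0, seed=0,
                        age_propensity_batching=False)
    return cfg, er.train_sirt(factorizable, config=cfg)


@pytest.fixture(scope="module")
def transform_model():
    rng = np.random.default_rng(3)
    X = rng.gamma(2.0, 1.0, (200, 20))
    cfg = er.SIRTConfig(latent_dim=4, dropout_p=0.1, epochs=8, seed=0,
                        age_propensity_batching=False)
    return er.train_sirt(X, config=cfg), X


class TestTraining:
    def test_exact_factorization_reached(self, factorizable, fitted):
        """Known exact non-negative factorization achieves IS divergence 0;
        the trainer gets below 0.05 per coordinate."""
        _, model = fitted
        xhat = model.reconstruct(factorizable)
        r = factorizable / xhat
        assert float(np.mean(r - np.log(r) - 1)) < 0.05

    def test_training_is_seed_deterministic(self, factorizable, fitted):
        cfg, model = fitted
        again = er.train_sirt(factorizable, config=cfg)
        assert model.training_log == again.training_log
        np.testing.assert_array_equal(model.params["V"], again.params["V"])

    def test_best_epoch_is_argmin_and_improves_on_first(self, fitted):
        _, model = fitted
        log = model.training_log
        assert model.best_epoch == int(np.argmin(log))
        assert log[model.best_epoch] <= log[0]

    def test_decoder_components_nonnegative(self, fitted):
        _, model = fitted
        assert np.all(model.decoder_components >= 0)
        assert np.all(model.encode(np.ones((2, 30))) >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            er.train_sirt(np.zeros((0, 4)))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            er.train_sirt(-np.ones((10, 4)))

    def test_checkpoint_roundtrip(self, factorizable, fitted, tmp_path):
        _, model = fitted
        path = tmp_path / "sirt.npz"
        model.save(path)
        loaded = er.SIRTModel.load(path)
        np.testing.assert_allclose(loaded.reconstruct(factorizable[:7]),
                                   model.reconstruct(factorizable[:7]))
        assert loaded.best_epoch == model.best_epoch


class TestTransform:
    def test_reconstruction_identity(self, transform_model):
        """x_tilde * x_hat = x elementwise (the multiplicative residual
        definition)."""
        m, X = transform_model
        xt = er.sirt_transform(m, X[:11])
        np.testing.assert_allclose(xt * m.reconstruct(X[:11]), X[:11],
                                   rtol=1e-12)

    def test_hand_computed_ratio(self):
        """x = [2, 8] against a reconstruction of [4, 4] gives [0.5, 2]."""
        x = np.array([2.0, 8.0])
        xhat = np.array([4.0, 4.0])
        np.testing.assert_allclose(x / xhat, [0.5, 2.0])

    def test_output_nonnegative_and_shape_preserving(self, transform_model):
        m, X = transform_model
        xt = er.sirt_transform(m, X)
        assert xt.shape == X.shape
        assert np.all(xt >= 0)
        one = er.sirt_transform(m, X[0])
        assert one.shape == (X.shape[1],)

    def test_dimension_mismatch_rejected(self, transform_model):
        m, _ = transform_model
        with pytest.raises(ValueError):
            er.sirt_transform(m, np.ones(7))

    def test_wellfit_residuals_concentrate_near_one(self):
        rng = np.random.default_rng(4)
        H0 = rng.gamma(2.0, 1.0, (400, 2))
        W0 = rng.gamma(2.0, 1.0, (2, 15))
        X = H0 @ W0
        cfg = er.SIRTConfig(latent_dim=4, dropout_p=0.0, epochs=50, seed=0,
                            encoder_weight_decay=0.0,
                            age_propensity_batching=False)
        m = er.train_sirt(X, config=cfg)
        xt = er.sirt_transform(m, X)
        assert abs(np.median(xt) - 1.0) < 0.25


class TestNuisanceRemoval:
    def test_between_subject_variance_share_drops(self):
        """On features = (subject gain) x (pattern + noise), SIRT residuals
        carry a much smaller between-subject variance share than the raw
        features."""
        rng = np.random.default_rng(2)
        n_subj, per, p = 30, 20, 40
        base = rng.gamma(3.0, 1.0, p)
        rows, sid = [], []
        for s in range(n_subj):
            g = np.exp(0.5 * rng.standard_normal())
            for _ in range(per):
                rows.append(g * base * rng.gamma(20.0, 1 / 20.0, p))
                sid.append(s)
        X = np.asarray(rows)
        sid = np.asarray(sid)
        cfg = er.SIRTConfig(latent_dim=5, dropout_p=0.3, epochs=20, seed=0,
                            age_propensity_batching=False)
        m = er.train_sirt(X, config=cfg)
        Xt = er.sirt_transform(m, X)

        def between_share(M):
            lm = np.log(M + 1e-12)
            grand = lm.mean(axis=0)
            tot = ((lm - grand) ** 2).sum()
            btw = sum(len(lm[sid == s])
                      * ((lm[sid == s].mean(axis=0) - grand) ** 2).sum()
                      for s in np.unique(sid))
            return btw / tot

        raw, resid = between_share(X), between_share(Xt)
        assert resid < 0.5 * raw


class TestAgePropensityBatches:
    def test_two_bin_closed_form_independence(self):
        """Two age bins with 9:1 and 1:9 class ratios: sampled (bin x class)
        cell frequencies match the independence product within 2% over 1e5
        draws."""
        ages = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[np.ones(45), np.zeros(5), np.ones(5), np.zeros(45)]
        batches = er.age_propensity_batches(ages, y, batch_size=1000, seed=0,
                                            n_batches=100, n_bins=2)
        idx = np.concatenate(batches)
        for b in (0, 1):
            for cls in (0, 1):
                freq = np.mean((ages[idx] == b) & (y[idx] == cls))
                assert abs(freq - 0.25) < 0.02  # 0.5 (bin) x 0.5 (class)

    def test_age_independent_of_class_gives_uniform_weights(self, rng):
        ages = rng.uniform(40, 90, 400)
        y = rng.integers(0, 2, 400)
        w = er.age_propensity_weights(ages, y, n_bins=4)
        for cls in (0, 1):
            wc = w[y == cls]
            assert wc.std() / wc.mean() < 0.35

    def test_same_seed_identical_batches(self):
        ages = np.linspace(40, 90, 60)
        y = np.tile([0, 1], 30)
        b1 = er.age_propensity_batches(ages, y, 16, seed=5)
        b2 = er.age_propensity_batches(ages, y, 16, seed=5)
        for a, b in zip(b1, b2):
            np.testing.assert_array_equal(a, b)

    def test_single_class_bin_warns_and_falls_back(self):
        ages = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.ones(10), np.zeros(5), np.ones(5)]
        with pytest.warns(UserWarning, match="single class"):
            w = er.age_propensity_weights(ages, y, n_bins=2)
        np.testing.assert_allclose(w[:10], w[0])  # fallback bin is uniform

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            er.age_propensity_weights(np.arange(10.0), np.ones(10))
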