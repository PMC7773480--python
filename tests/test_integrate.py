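"""Integration model: losses, gradients, training behavior."""

import numpy as np
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import scmatch
from scmatch._nn import Adam, sigmoid
from scmatch.datasets import ExpressionDataset
from scmatch.divergence import divergence_score
from scmatch.integrate import (
    SCIM,
    Discriminator,
    IntegrationConfig,
    TechnologyModel,
    _disc_step,
    discriminator_loss,
    encode,
    gaussian_kl,
    scim_objective,
    train_vae,
    vae_loss,
)

LN2 = np.log(2.0)


def _toy_model(n_features=5, latent=3, seed=0, **cfg_kw):
    cfg = IntegrationConfig(
        latent_dim=latent, hidden_units=(6, 6), disc_hidden=(4, 4), seed=seed, **cfg_kw
    )
    rng = np.random.default_rng(seed)
    model = TechnologyModel(n_features, cfg, rng)
    model.feature_mean_ = np.zeros(n_features)
    model.feature_std_ = np.ones(n_features)
    return cfg, rng, model


class TestGaussianLosses:
    def test_kl_zero_when_posterior_is_prior(self):
        assert gaussian_kl(np.zeros((4, 3)), np.zeros((4, 3))) == 0.0

    def test_kl_closed_form_unit_mean(self):
        # KL(N(1,1) || N(0,1)) = 0.5(mu^2 + sigma^2 - 1 - ln sigma^2) = 0.5
        assert gaussian_kl(np.ones((1, 1)), np.zeros((1, 1))) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(1, 4))
        logvar = rng.normal(scale=0.5, size=(1, 4))
        closed = gaussian_kl(mu, logvar)
        n = 10_000
        z = mu + np.exp(0.5 * logvar) * rng.normal(size=(n, 4))
        log_q = -0.5 * np.sum((z - mu) ** 2 / np.exp(logvar) + logvar, axis=1)
        log_p = -0.5 * np.sum(z**2, axis=1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(n)
        assert abs(samples.mean() - closed) < 3 * se

    def test_vae_loss_beta_zero_is_pure_reconstruction(self):
        _, rng, model = _toy_model()
        x = rng.normal(size=(6, 5))
        out = vae_loss(x, model, beta=0.0)
        assert out["total"] == pytest.approx(out["nll"])
        assert out["kl"] >= 0.0


class TestDiscriminator:
    def test_uninformative_discriminator_loss_is_ln2(self):
        cfg, rng, _ = _toy_model()
        disc = Discriminator(cfg, ["x", "y"], rng)
        last = disc.net.layers[-1]
        last.W[...] = 0.0
        last.b[...] = 0.0  # logits identically 0 -> p = 0.5 everywhere
        zs, zt = rng.normal(size=(8, 3)), rng.normal(size=(9, 3))
        assert discriminator_loss(disc, zs, zt) == pytest.approx(LN2)

    def test_best_loss_on_identical_distributions_is_ln2(self):
        cfg = IntegrationConfig(latent_dim=2)
        rng = np.random.default_rng(0)
        disc = Discriminator(cfg, [], rng)
        opt = Adam([disc.net], lr=2e-3)
        zs, zt = rng.normal(size=(2000, 2)), rng.normal(size=(2000, 2))
        oh = disc.one_hot(None, 2000)
        for _ in range(300):
            loss = _disc_step(disc, zs, oh, zt, oh, opt)
        assert abs(loss - LN2) < 0.05

    def test_separable_codes_drive_loss_down(self):
        cfg = IntegrationConfig(latent_dim=2)
        rng = np.random.default_rng(1)
        disc = Discriminator(cfg, [], rng)
        opt = Adam([disc.net], lr=2e-3)
        zs = rng.normal(size=(500, 2)) + 4.0
        zt = rng.normal(size=(500, 2)) - 4.0
        oh = disc.one_hot(None, 500)
        first = _disc_step(disc, zs, oh, zt, oh, opt)
        for _ in range(400):
            last = _disc_step(disc, zs, oh, zt, oh, opt)
        assert last < 0.1 < first

    def test_spectral_norm_bounds_effective_weights(self):
        cfg = IntegrationConfig(latent_dim=2)
        rng = np.random.default_rng(2)
        disc = Discriminator(cfg, [], rng)
        opt = Adam([disc.net], lr=5e-3)
        zs, zt = rng.normal(size=(256, 2)), rng.normal(size=(256, 2)) + 1.0
        oh = disc.one_hot(None, 256)
        for _ in range(200):
            _disc_step(disc, zs, oh, zt, oh, opt)
        for layer in disc.net.layers:
            sigma = np.linalg.svd(layer.effective_weight(), compute_uv=False)[0]
            assert sigma <= 1.05

    def test_dimension_mismatch_rejected(self):
        cfg, rng, _ = _toy_model()
        disc = Discriminator(cfg, [], rng)
        with pytest.raises(ValueError):
            disc.logits(rng.normal(size=(4, 7)), disc.one_hot(None, 4))


class TestScimObjective:
    def test_beta_zero_reduces_to_reconstruction(self):
        cfg, rng, model = _toy_model()
        disc = Discriminator(cfg, ["a"], rng)
        x = rng.normal(size=(4, 5))
        out = scim_objective(x, None, model, disc, beta=0.0)
        assert out["total"] == pytest.approx(out["nll"])

    def test_source_codes_receive_no_gradient(self):
        # z_s enters only as the fixed reference distribution: the objective
        # is numerically independent of it
        cfg, rng, model = _toy_model()
        disc = Discriminator(cfg, ["a"], rng)
        x = rng.normal(size=(4, 5))
        a = scim_objective(x, rng.normal(size=(4, 3)), model, disc, beta=2.0)
        b = scim_objective(x, rng.normal(size=(4, 3)) * 100, model, disc, beta=2.0)
        assert a == b

    def test_backprop_matches_finite_differences(self):
        cfg, rng, model = _toy_model()
        disc = Discriminator(cfg, ["a", "b"], rng)
        x = rng.normal(size=(4, 5))
        labels = np.array(["a", "b", None, "a"], dtype=object)
        beta = 0.7

        def loss():
            return scim_objective(x, None, model, disc, beta, labels_t=labels)["total"]

        # one backward pass along the posterior-mean path
        B = x.shape[0]
        model.encoder.zero_grad()
        model.decoder.zero_grad()
        mu, _ = model.encode_posterior(x, train=True)
        x_hat = model.decode(mu, train=True)
        dz = model.decoder.backward((x_hat - x) / B)
        h = np.hstack([mu, disc.one_hot(labels, B)])
        logits = disc.net.forward(h, train=True)[:, 0]
        dh = disc.net.backward(beta * (-sigmoid(-logits) / B)[:, None])
        dz = dz + dh[:, : model.latent_dim]
        model.encoder.backward(np.hstack([dz, np.zeros_like(dz)]))

        checks = [
            (model.decoder.layers[1], 2, 1),
            (model.decoder.layers[0], 0, 3),
            (model.encoder.layers[0], 1, 2),
        ]
        eps = 1e-6
        for layer, i, j in checks:
            orig = layer.W[i, j]
            layer.W[i, j] = orig + eps
            up = loss()
            layer.W[i, j] = orig - eps
            down = loss()
            layer.W[i, j] = orig
            fd = (up - down) / (2 * eps)
            assert layer.gW[i, j] == pytest.approx(fd, rel=1e-4)


class TestTrainVae:
    def test_degenerate_single_cell_collapses(self):
        counts = np.tile([3, 0, 7, 1], (60, 1))
        ds = ExpressionDataset(counts=counts, technology="t")
        cfg = IntegrationConfig(
            latent_dim=2, hidden_units=(8,), vae_epochs=300, seed=0, batch_size=16,
            lr_autoencoder=2e-3,
        )
        model, codes = train_vae(ds, cfg)
        # identical inputs -> identical codes, near-exact reconstruction
        assert np.allclose(codes.codes, codes.codes[0], atol=1e-8)
        x = model.transform(ds.counts)
        mu, _ = model.encode_posterior(x)
        assert np.abs(model.decode(mu) - x).max() < 0.05

    def test_latent_codes_recover_branch_structure(self, small_pair):
        cfg = IntegrationConfig(vae_epochs=64, seed=1)
        _, codes = train_vae(small_pair[0], cfg)
        assert codes.codes.shape == (small_pair[0].n_cells, 8)
        km = KMeans(n_clusters=5, n_init=10, random_state=0).fit(codes.codes)
        assert adjusted_rand_score(small_pair[0].branch, km.labels_) > 0.5


class TestEncode:
    def test_deterministic_and_row_equivariant(self, small_pair):
        ds = small_pair[0]
        cfg = IntegrationConfig(vae_epochs=4, seed=2)
        model, _ = train_vae(ds, cfg)
        c1 = encode(ds, model).codes
        c2 = encode(ds, model).codes
        np.testing.assert_array_equal(c1, c2)
        perm = np.random.default_rng(0).permutation(ds.n_cells)
        shuffled = ExpressionDataset(counts=ds.counts[perm], technology="t")
        np.testing.assert_allclose(encode(shuffled, model).codes, c1[perm])

    def test_feature_mismatch_rejected(self, small_pair):
        cfg = IntegrationConfig(vae_epochs=2, seed=3)
        model, _ = train_vae(small_pair[0], cfg)
        bad = ExpressionDataset(counts=np.zeros((5, 3)), technology="t")
        with pytest.raises(ValueError):
            encode(bad, model)


class TestTrainScim:
    def test_duplicated_technology_divergence_decreases(self, tree):
        cells = scmatch.sample_cells(tree, 3000, seed=3)
        prog = scmatch.simulate_programs(tree, 64, seed=4)
        a = scmatch.sample_counts(prog, cells, seed=5, technology="a")
        b = ExpressionDataset(
            counts=a.counts.copy(),
            technology="b",
            branch=a.branch.copy(),
            pseudotime=a.pseudotime.copy(),
        )
        cfg = IntegrationConfig(vae_epochs=64, scim_epochs=64, seed=0)
        res = SCIM([a, b], 0, cfg).fit()
        d0 = divergence_score(res.codes(0), res.initial_codes["b"], k=5).value
        d1 = divergence_score(res.codes(0), res.codes(1), k=5).value
        assert d1 < d0

    def test_training_is_reproducible(self, small_pair):
        cfg = IntegrationConfig(vae_epochs=3, scim_epochs=3, seed=7)
        r1 = SCIM(small_pair, 0, cfg).fit()
        r2 = SCIM(small_pair, 0, cfg).fit()
        np.testing.assert_array_equal(r1.codes(1).codes, r2.codes(1).codes)
        np.testing.assert_array_equal(r1.codes(0).codes, r2.codes(0).codes)

    def test_history_and_summary(self, small_pair):
        cfg = IntegrationConfig(vae_epochs=2, scim_epochs=2, seed=0)
        res = SCIM(small_pair, 0, cfg).fit()
        assert set(res.history.columns) >= {"epoch", "nll", "adv", "disc", "divergence"}
        assert len(res.history) == 2
        text = res.summary()
        assert "tech1" in text and "latent dim" in text

    def test_input_validation(self, small_pair):
        with pytest.raises(ValueError):
            SCIM(small_pair[:1])
        with pytest.raises(ValueError):
            SCIM(small_pair, source_index=5)
        with pytest.raises(ValueError):
            IntegrationConfig(label_fraction=1.5)
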