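import math

import numpy as np
import pytest

from cnvprior.vae import (
    ArchitectureSpec,
    TrainConfig,
    VAEParams,
    _elbo_grads,
    _flatten,
    _flatten_grads,
    elbo_loss,
    init_params,
    kl_divergence,
    load_checkpoint,
    plan_architecture,
    save_checkpoint,
    train_vae,
)


class TestPlanArchitecture:
    @pytest.mark.parametrize(
        "input_dim,hidden,latent",
        [
            (65536, (256, 16, 4), 2),
            (100, (10, 4, 2), 2),
            (4, (2,), 2),
            (527, (23, 5, 3), 2),
        ],
    )
    def test_square_root_rule(self, input_dim, hidden, latent):
        arch = plan_architecture(input_dim)
        assert arch.hidden_sizes == hidden
        assert arch.latent_dim == latent

    def test_too_small_input_is_fatal(self):
        with pytest.raises(ValueError):
            plan_architecture(3)

    def test_sizes_strictly_decreasing(self):
        for n in range(4, 3000, 37):
            arch = plan_architecture(n)
            chain = (n, *arch.hidden_sizes)
            assert all(a > b for a, b in zip(chain, chain[1:]))
            assert len(arch.hidden_sizes) <= 3
            assert arch.latent_dim >= 2


class TestKLDivergence:
    def test_prior_equals_posterior_is_zero(self):
        assert kl_divergence(np.zeros(3), np.zeros(3)) == 0.0

    def test_unit_mean_closed_form(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_non_negative_on_random_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            mu = rng.normal(0, 3, size=4)
            lv = rng.normal(0, 2, size=4)
            assert kl_divergence(mu, lv) >= 0.0

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0, 1, size=3)
        lv = rng.normal(0, 0.5, size=3)
        sig = np.exp(0.5 * lv)
        n = 100_000
        z = mu + sig * rng.standard_normal((n, 3))
        log_q = -0.5 * (((z - mu) / sig) ** 2 + np.log(2 * np.pi) + lv).sum(axis=1)
        log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        draws = log_q - log_p
        se = draws.std(ddof=1) / math.sqrt(n)
        assert kl_divergence(mu, lv) == pytest.approx(draws.mean(), abs=3 * se)

    def test_non_finite_input_is_fatal(self):
        with pytest.raises(ValueError):
            kl_divergence(np.array([np.nan]), np.array([0.0]))


def tiny_params():
    """Fixed-weight network: 4 inputs, one hidden pair, 2 latent dims."""
    arch = ArchitectureSpec(input_dim=4, hidden_sizes=(2,), latent_dim=2, dropout_rate=0.0)
    return VAEParams(
        arch=arch,
        enc_W=[np.array([[0.1, -0.2], [0.3, 0.4], [-0.5, 0.6], [0.7, -0.8]])],
        enc_b=[np.array([0.05, -0.05])],
        W_mu=np.array([[0.2, -0.1], [0.4, 0.3]]),
        b_mu=np.array([0.01, -0.02]),
        W_lv=np.array([[-0.3, 0.2], [0.1, -0.4]]),
        b_lv=np.array([-0.1, 0.1]),
        dec_W=[np.array([[0.5, -0.6], [0.7, 0.8]]), np.array([[0.2, -0.3, 0.4, -0.5], [0.6, 0.7, -0.8, 0.9]])],
        dec_b=[np.array([0.0, 0.1]), np.array([0.02, -0.02, 0.03, -0.03])],
    )


class TestElboLoss:
    def test_hand_computed_forward_pass(self):
        params = tiny_params()
        x = np.array([0.9, 0.1, 0.5, 0.7])
        # independent arithmetic, written out step by step
        h_pre = x @ params.enc_W[0] + params.enc_b[0]
        h = np.maximum(h_pre, 0.0)
        mu = h @ params.W_mu + params.b_mu
        lv = h @ params.W_lv + params.b_lv
        z = mu  # deterministic mode
        d1 = np.maximum(z @ params.dec_W[0] + params.dec_b[0], 0.0)
        xhat = 1.0 / (1.0 + np.exp(-(d1 @ params.dec_W[1] + params.dec_b[1])))
        recon_exp = float(np.sum((xhat - x) ** 2))
        kl_exp = float(0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv))
        total, recon, kl = elbo_loss(x[None, :], params)
        assert recon == pytest.approx(recon_exp, rel=1e-12)
        assert kl == pytest.approx(kl_exp, rel=1e-12)
        assert total == pytest.approx(recon_exp + kl_exp, rel=1e-12)

    def test_perfect_autoencoder_with_standard_posterior_is_zero(self):
        # zero encoder -> mu = 0, logvar = 0 -> KL 0; zero decoder with zero
        # output bias reconstructs the constant 0.5 input exactly
        arch = ArchitectureSpec(input_dim=4, hidden_sizes=(2,), latent_dim=2, dropout_rate=0.0)
        z4, z2 = np.zeros((4, 2)), np.zeros(2)
        params = VAEParams(
            arch=arch,
            enc_W=[z4],
            enc_b=[z2],
            W_mu=np.zeros((2, 2)),
            b_mu=z2,
            W_lv=np.zeros((2, 2)),
            b_lv=z2,
            dec_W=[np.zeros((2, 2)), np.zeros((2, 4))],
            dec_b=[z2, np.zeros(4)],
        )
        total, recon, kl = elbo_loss(np.full((3, 4), 0.5), params)
        assert total == recon == kl == 0.0

    def test_shape_mismatch_is_fatal(self):
        with pytest.raises(ValueError):
            elbo_loss(np.zeros((2, 5)), tiny_params())


class TestGradients:
    def test_analytic_matches_central_finite_differences(self):
        params = tiny_params()
        rng = np.random.default_rng(3)
        X = rng.random((5, 4))
        eps = rng.standard_normal((5, 2))

        def loss_of(p):
            _, _, mu, lv = _forward(p, X)
            return _loss(p, X, eps)

        def _loss(p, X, eps):
            from cnvprior.vae import decode, encode, kl_divergence

            _, _, mu, lv = encode(p, X)
            z = mu + np.exp(0.5 * lv) * eps
            _, _, xhat = decode(p, z)
            recon = float(np.mean(np.sum((xhat - X) ** 2, axis=1)))
            return recon + kl_divergence(mu, lv)

        def _forward(p, X):
            from cnvprior.vae import encode

            return encode(p, X)

        loss0, grads = _elbo_grads(params, X, eps, None, "mse")
        assert loss0 == pytest.approx(_loss(params, X, eps), rel=1e-12)
        flat_p = _flatten(params)
        flat_g = _flatten_grads(grads)
        h = 1e-6
        rng2 = np.random.default_rng(7)
        for arr, g in zip(flat_p, flat_g):
            # probe a few random coordinates of every array
            for _ in range(min(4, arr.size)):
                idx = tuple(rng2.integers(0, s) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + h
                lp = _loss(params, X, eps)
                arr[idx] = orig - h
                lm = _loss(params, X, eps)
                arr[idx] = orig
                num = (lp - lm) / (2 * h)
                assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestTrainVae:
    def make_data(self, n=200, p=64, seed=7):
        rng = np.random.default_rng(seed)
        latent = rng.random((n, 3))
        W = rng.random((3, p))
        X = np.clip(latent @ W / 3 + 0.05 * rng.random((n, p)), 0, 1)
        return X

    def test_validation_loss_improves(self):
        X = self.make_data()
        cfg = TrainConfig(seed=7, max_epochs=60, early_stop_patience=60)
        _, trace = train_vae(X, cfg)
        assert trace["val"][-1] < trace["val"][0]

    def test_identical_seeds_give_bit_identical_traces(self):
        X = self.make_data()
        cfg = TrainConfig(seed=11, max_epochs=10)
        _, t1 = train_vae(X, cfg)
        _, t2 = train_vae(X, cfg)
        assert t1["train"] == t2["train"] and t1["val"] == t2["val"]

    def test_constant_data_reconstruction_vanishes(self):
        # analytic optimum: the decoder output bias encodes the constant row
        # exactly, so the reconstruction term goes to ~0 while the KL term
        # stays bounded near the free-bits floor
        row = np.linspace(0.1, 0.9, 16)
        X = np.tile(row, (50, 1))
        cfg = TrainConfig(
            seed=0, max_epochs=2000, early_stop_patience=2000,
            kl_warmup_epochs=0, batch_size=16,
        )
        params, _ = train_vae(X, cfg, arch=plan_architecture(16, dropout_rate=0.0))
        _, recon, kl = elbo_loss(X, params)
        assert recon < 0.05
        assert kl < 1.0

    def test_divergence_aborts_with_diagnostic(self):
        X = self.make_data(n=20, p=16)
        cfg = TrainConfig(seed=0, max_epochs=50, learning_rate=1e6)
        with pytest.raises(FloatingPointError):
            train_vae(X, cfg)

    def test_too_few_samples_is_fatal(self):
        with pytest.raises(ValueError):
            train_vae(np.zeros((1, 8)), TrainConfig())


def test_checkpoint_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    arch = plan_architecture(32)
    params = init_params(arch, rng)
    cfg = TrainConfig(seed=5, max_epochs=17)
    head = {"head_w": rng.normal(size=arch.latent_dim), "head_b": np.array([0.3])}
    path = tmp_path / "m.ckpt"
    save_checkpoint(path, params, config=cfg, head=head)
    params2, cfg2, head2 = load_checkpoint(path)
    assert cfg2 == cfg
    assert params2.arch == arch
    for a, b in zip(_flatten(params), _flatten(params2)):
        assert np.array_equal(a, b)
    assert np.array_equal(head2["head_w"], head["head_w"])
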