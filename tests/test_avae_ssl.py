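"""Stochastic encoders, running priors, KL penalties, generation audit."""

import math

import numpy as np
import pytest

from painfuse import avae_ssl, ddcae
from painfuse._autodiff import Tensor
from painfuse.avae_ssl import (
    AdaptiveVAESystem, LatentPosterior, RunningPrior, SSLConfig,
    categorical_kl, gaussian_kl,
)
from painfuse.preprocess import SegmentDataset


def tiny_cfg(**over):
    base = dict(modalities=("EDA", "ECG"), m=32, eta=4, n_classes=2,
                alphas=(0.2, 0.2), alpha_psi=0.4, lr=3e-3, batch_size=6,
                attention=False, dropout=0.0, seed=1)
    base.update(over)
    return ddcae.ModelConfig(**base)


def tiny_ssl(**over):
    base = dict(beta1=1.0, beta2=1.0, beta3=1.0, ema_decay=0.98,
                pretrain_epochs=2, finetune_epochs=2, seed=3)
    base.update(over)
    return SSLConfig(**base)


class TestStochasticEncoder:
    def test_encoder_output_width_is_twice_eta(self):
        model = AdaptiveVAESystem(tiny_cfg(eta=256, m=1152), tiny_ssl())
        assert model.encoders["EDA"].dense.W.shape[1] == 512

    def test_zero_variance_head_gives_softplus_zero_sd(self):
        model = AdaptiveVAESystem(tiny_cfg(), tiny_ssl())
        enc = model.encoders["EDA"]
        enc.dense.W.data[...] = 0.0
        enc.dense.b.data[...] = 0.0
        post, _ = model.encode_stochastic(np.zeros((1, 32)), "EDA")
        np.testing.assert_allclose(post.sd, np.log(2.0), rtol=1e-12)

    def test_deterministic_path_returns_mean(self):
        model = AdaptiveVAESystem(tiny_cfg(), tiny_ssl())
        x = np.random.default_rng(0).random((3, 32))
        post, (_, _, h) = model.encode_stochastic(x, "EDA", sample=False)
        np.testing.assert_array_equal(h.data, post.mean)

    def test_reparameterized_sampling_moments(self):
        # fixed posterior, many draws: CLT bounds on empirical mean/sd
        rng = np.random.default_rng(42)
        mean, sd = 1.5, 0.4
        n = 10_000
        draws = mean + sd * rng.standard_normal(n)
        assert abs(draws.mean() - mean) < 3 * sd / math.sqrt(n)
        assert abs(draws.std() - sd) < 3 * sd / math.sqrt(2 * n)

    def test_posterior_requires_positive_sd(self):
        with pytest.raises(ValueError, match="positive"):
            LatentPosterior(np.zeros(3), np.array([0.1, 0.0, 0.2]))


class TestGaussianKL:
    def test_identical_distributions_zero(self):
        post = LatentPosterior(np.array([0.3, -1.0]), np.array([0.5, 2.0]))
        prior = RunningPrior("gaussian", mean=post.mean.copy(),
                             sd=post.sd.copy())
        assert gaussian_kl(post, prior) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        post = LatentPosterior(np.array([0.0]), np.array([1.0]))
        prior = RunningPrior("gaussian", mean=np.array([1.0]),
                             sd=np.array([1.0]))
        assert gaussian_kl(post, prior) == pytest.approx(0.5)

    def test_nonnegative_over_random_draws(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            post = LatentPosterior(rng.normal(size=3),
                                   rng.uniform(0.1, 3.0, 3))
            prior = RunningPrior("gaussian", mean=rng.normal(size=3),
                                 sd=rng.uniform(0.1, 3.0, 3))
            assert gaussian_kl(post, prior) >= -1e-12

    def test_nonpositive_prior_sd_rejected(self):
        post = LatentPosterior(np.zeros(1), np.ones(1))
        prior = RunningPrior("gaussian", mean=np.zeros(1),
                             sd=np.array([-1.0]))
        with pytest.raises(ValueError):
            gaussian_kl(post, prior)

    def test_tensor_path_matches_closed_form(self):
        rng = np.random.default_rng(4)
        mean = rng.normal(size=(5, 3))
        sd = rng.uniform(0.2, 2.0, (5, 3))
        prior = RunningPrior("gaussian", mean=rng.normal(size=3),
                             sd=rng.uniform(0.2, 2.0, 3))
        t = avae_ssl._kl_gauss_t(Tensor(mean), Tensor(sd), prior)
        ref = gaussian_kl(LatentPosterior(mean, sd), prior)
        assert float(t.data) == pytest.approx(ref, rel=1e-10)


class TestRunningPrior:
    def test_fixed_point(self):
        p = RunningPrior.categorical(4, tau=10.0)
        before = p.probs.copy()
        p.update(before.copy())
        np.testing.assert_allclose(p.probs, before, rtol=1e-12)

    def test_geometric_trajectory_closed_form(self):
        tau = 7.0
        target = np.array([0.7, 0.2, 0.1])
        p = RunningPrior.categorical(3, tau=tau)
        q0 = p.probs.copy()
        for _ in range(10):
            p.update(target)
        expect = target + (1 - 1 / tau) ** 10 * (q0 - target)
        np.testing.assert_allclose(p.probs, expect, rtol=1e-10)

    def test_tau_one_jumps_to_observation(self):
        p = RunningPrior.gaussian(2, tau=1.0)
        p.update((np.array([5.0, -5.0]), np.array([0.2, 0.3])))
        np.testing.assert_allclose(p.mean, [5.0, -5.0])
        np.testing.assert_allclose(p.sd, [0.2, 0.3])

    def test_ema_decay_tau_relation(self):
        assert tiny_ssl(ema_decay=0.9995).tau == pytest.approx(2000.0)


class TestVariationalObjective:
    def test_perfect_reconstruction_matched_prior_hits_floor(self):
        x = np.random.default_rng(0).random((4, 8))
        post = LatentPosterior(np.zeros((4, 3)), np.ones((4, 3)))
        prior = RunningPrior("gaussian", mean=np.zeros(3), sd=np.ones(3))
        assert avae_ssl.avae_loss(x, x.copy(), post, prior, beta1=0.5) == \
            pytest.approx(0.0, abs=1e-12)

    def test_kl_contribution_decreases_with_beta(self):
        x = np.zeros((1, 4))
        post = LatentPosterior(np.ones((1, 3)), np.ones((1, 3)))
        prior = RunningPrior("gaussian", mean=np.zeros(3), sd=np.ones(3))
        vals = [avae_ssl.avae_loss(x, x, post, prior, beta1=b)
                for b in (0.5, 1.0, 2.0)]
        assert vals[0] > vals[1] > vals[2] > 0

    def test_scalar_oracle_one_dimensional(self):
        x = np.array([[1.0, -1.0]])
        rec = np.array([[0.5, 0.0]])
        post = LatentPosterior(np.array([[0.3]]), np.array([[0.8]]))
        prior = RunningPrior("gaussian", mean=np.array([0.1]),
                             sd=np.array([1.2]))
        nll = 0.5 * ((1.0 - 0.5) ** 2 + (-1.0 - 0.0) ** 2)
        kl = (math.log(1.2 / 0.8)
              + (0.8**2 + (0.3 - 0.1) ** 2) / (2 * 1.2**2) - 0.5)
        expect = nll + (1 / 0.01) * kl
        got = avae_ssl.avae_loss(x, rec, post, prior, beta1=0.01)
        assert got == pytest.approx(expect, rel=1e-12)

    def test_info_constrained_loss_zero_penalty_at_marginal(self):
        q = np.array([0.3, 0.7])
        py = np.array([0.5, 0.5])
        got = avae_ssl.info_constrained_loss(0.42, q, q, py, py,
                                             beta2=0.001, beta3=0.001)
        assert got == pytest.approx(0.42, abs=1e-9)

    def test_info_constrained_loss_beta_limit(self):
        w = np.array([0.9, 0.1])
        pw = np.array([0.5, 0.5])
        big = avae_ssl.info_constrained_loss(1.0, w, pw, None, None,
                                             beta2=1e12, beta3=1e12)
        assert big == pytest.approx(1.0, abs=1e-9)

    def test_invalid_betas_rejected(self):
        with pytest.raises(ValueError):
            avae_ssl.avae_loss(np.zeros((1, 2)), np.zeros((1, 2)),
                               LatentPosterior(np.zeros((1, 1)),
                                               np.ones((1, 1))),
                               RunningPrior("gaussian", mean=np.zeros(1),
                                            sd=np.ones(1)), beta1=0.0)
        with pytest.raises(ValueError):
            avae_ssl.info_constrained_loss(0.0, np.ones(2) / 2,
                                           np.ones(2) / 2, None, None,
                                           beta2=-1.0, beta3=1.0)


class TestInformationPenalties:
    def test_categorical_kl_closed_form(self):
        p = np.array([0.9, 0.1])
        q = np.array([0.5, 0.5])
        expect = 0.9 * np.log(1.8) + 0.1 * np.log(0.2)
        assert categorical_kl(p, q) == pytest.approx(expect, rel=1e-9)
        t = avae_ssl._kl_cat_t(Tensor(p.reshape(1, 2)), q)
        assert float(t.data) == pytest.approx(expect, rel=1e-6)

    def test_output_equal_to_marginal_zero_penalty(self):
        q = np.array([0.25, 0.75])
        assert categorical_kl(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_large_beta_recovers_unpenalized_task_loss(self, toy_dataset):
        cfg = tiny_cfg()
        big = AdaptiveVAESystem(cfg, tiny_ssl(beta1=1e12, beta2=1e12,
                                              beta3=1e12))
        small = AdaptiveVAESystem(cfg, tiny_ssl())
        y = big.encode_targets(toy_dataset.y)
        small.encode_targets(toy_dataset.y)
        Xb = {m: x[:6] for m, x in toy_dataset.X.items()}
        lb, _ = big._batch_loss(Xb, y[:6], corrupt=False)
        ls, _ = small._batch_loss(Xb, y[:6], corrupt=False)
        # the penalized objective dominates the beta -> inf limit
        assert float(ls.data) > float(lb.data)

    def test_beta_monotonicity_of_kl_contribution(self, toy_dataset):
        cfg = tiny_cfg()
        losses = []
        for b in (0.5, 1.0, 2.0):
            model = AdaptiveVAESystem(cfg, tiny_ssl(beta1=b))
            y = model.encode_targets(toy_dataset.y)
            loss, _ = model._batch_loss(
                {m: x[:6] for m, x in toy_dataset.X.items()}, y[:6],
                corrupt=False)
            losses.append(float(loss.data))
        assert losses[0] >= losses[1] >= losses[2]


class TestGenerationAndFineTuning:
    def make_trained(self, toy_dataset, **ssl_over):
        model = AdaptiveVAESystem(tiny_cfg(), tiny_ssl(**ssl_over))
        model.fit(toy_dataset, epochs=2)
        return model

    def test_generated_shapes_and_labels(self, toy_dataset):
        model = self.make_trained(toy_dataset)
        gen = model.generate(7)
        assert all(x.shape == (7, 32) for x in gen.X.values())
        assert set(np.unique(gen.y)) <= {0, 4}
        assert np.all(gen.provenance == "generated")

    def test_generation_deterministic_given_rng(self, toy_dataset):
        model = self.make_trained(toy_dataset)
        a = model.generate(3, rng=np.random.default_rng(5))
        b = model.generate(3, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.X["EDA"], b.X["EDA"])

    def test_point_collapsed_prior_decodes_prior_mean(self, toy_dataset):
        model = self.make_trained(toy_dataset)
        for mod in model.cfg.modalities:
            model.priors[mod].sd[...] = 1e-300
        gen = model.generate(2)
        for mod in model.cfg.modalities:
            mean = Tensor(np.repeat(model.priors[mod].mean[None], 2, axis=0))
            expect = model.decoders[mod](mean).data
            np.testing.assert_allclose(gen.X[mod], expect, atol=1e-8)

    def test_untrained_model_cannot_generate(self, toy_dataset):
        model = AdaptiveVAESystem(tiny_cfg(), tiny_ssl())
        with pytest.raises(RuntimeError, match="trained"):
            model.generate(3)

    def test_fine_tune_rejects_real_data(self, toy_dataset):
        model = self.make_trained(toy_dataset)
        with pytest.raises(ValueError, match="self-generated"):
            model.fine_tune(toy_dataset)

    def test_pseudo_label_ties_resolve_to_lowest_class(self):
        probs = np.array([[0.5, 0.5], [0.9, 0.1], [0.1, 0.9]])
        assert probs.argmax(axis=1).tolist() == [0, 0, 1]

    def test_generation_count_rule(self):
        # ceil(0.25 x 3,440) = 860 pseudo-labeled samples
        assert math.ceil(0.25 * 3440) == 860

    def test_fixed_prior_stays_standard_normal(self, toy_dataset):
        model = self.make_trained(toy_dataset, fixed_prior=True)
        for mod in model.cfg.modalities:
            np.testing.assert_array_equal(model.priors[mod].mean, 0.0)
            np.testing.assert_array_equal(model.priors[mod].sd, 1.0)

    def test_adaptive_prior_moves(self, toy_dataset):
        model = self.make_trained(toy_dataset)
        moved = any(
            np.abs(model.priors[mod].mean).max() > 0
            for mod in model.cfg.modalities
        )
        assert moved


class TestSSLRunInterface:
    def test_fold_metrics_and_provenance_audit(self, toy_dataset):
        cfg = tiny_cfg()
        ssl = tiny_ssl(gen_fraction=0.5)
        results = avae_ssl.ssl_run(toy_dataset, cfg, ssl, folds=["sA"])
        assert len(results) == 1
        assert results[0].test_subject == "sA"
        assert 0.0 <= results[0].metrics["accuracy"] <= 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tiny_ssl(beta1=0.0)
        with pytest.raises(ValueError):
            tiny_ssl(ema_decay=1.5)
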