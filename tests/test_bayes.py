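"""Variational machinery: prior density, sampling, ELBO, credible intervals."""

import numpy as np
import pytest

from icurisk.autodiff import Tensor
from icurisk.bayes import (ScaleMixturePrior, VariationalPosterior, elbo_loss,
                           fit_bbb, log_prior, odds_ratios)
from icurisk.data import StayRecord, pad_batch
from icurisk.nn import Module
from icurisk.training import TrainConfig


class ToyLogistic(Module):
    """Minimal network: logit = static . w (for conjugate-style toy checks)."""

    def __init__(self, n_features: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = Tensor.param(np.zeros((n_features, 1)))

    def logits(self, batch, rng=None, training=False):
        return (Tensor(batch["static"]) @ self.w)[:, 0]

    @property
    def final(self):  # odds_ratios looks up the final-layer weight
        class _F:
            pass
        f = _F()
        f.W = self.w
        return f


def _toy_stays(n, beta, rng, n_features=None):
    n_features = len(beta) if n_features is None else n_features
    X = rng.normal(size=(n, n_features))
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(n) < p).astype(int)
    return [StayRecord(patient_id=i, stay_id=i, static=X[i],
                       codes_dxproc=np.empty(0, dtype=int),
                       elapsed_dxproc=np.empty(0),
                       codes_medvit=np.empty(0, dtype=int),
                       elapsed_medvit=np.empty(0), label=int(y[i]))
            for i in range(n)]


class TestPrior:
    def test_symmetric_in_w(self, rng):
        w = rng.normal(size=20)
        assert log_prior(w) == pytest.approx(log_prior(-w))

    def test_value_at_zero_matches_direct_evaluation(self):
        # log(0.5 * N(0;0,1) + 0.5 * N(0;0,e^-12)): the narrow component's
        # density at 0 is e^6 / sqrt(2 pi), dominating the mixture
        expected = np.log(0.5 / np.sqrt(2 * np.pi) * (1.0 + np.exp(6.0)))
        assert log_prior(np.zeros(1)) == pytest.approx(expected, abs=1e-12)

    def test_pi_one_reduces_to_single_gaussian(self):
        prior = ScaleMixturePrior(pi=1.0 - 1e-15, sigma1=2.0)
        w = np.array([0.3, -1.2])
        expected = np.sum(-0.5 * np.log(2 * np.pi * 4.0) - w**2 / 8.0)
        assert prior.log_prob(w) == pytest.approx(expected, abs=1e-9)

    def test_graph_value_matches_numpy_path(self, rng):
        prior = ScaleMixturePrior()
        w = rng.normal(size=(3, 2))
        assert float(prior.log_prob_graph(Tensor(w)).data) == \
            pytest.approx(prior.log_prob(w), abs=1e-10)


class TestSampling:
    def _posterior(self):
        net = ToyLogistic(3)
        post = VariationalPosterior(net)
        return post

    def test_zero_sigma_returns_mean(self):
        post = self._posterior()
        post.mus[0].data[:] = 1.5
        post.rhos[0].data[:] = -40.0  # softplus ~ 0
        draw = post.sample_weights(seed=0)[0]
        np.testing.assert_allclose(draw, np.full((3, 1), 1.5), atol=1e-12)

    def test_same_seed_same_draw(self):
        post = self._posterior()
        a = post.sample_weights(seed=5)[0]
        b = post.sample_weights(seed=5)[0]
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_obeys_clt(self):
        post = self._posterior()
        post.mus[0].data[:] = 0.7
        post.rhos[0].data[:] = 0.0  # sigma = log 2
        sigma = np.log(2.0)
        rng = np.random.default_rng(1)
        draws = np.array([post.sample_weights(rng)[0][0, 0] for _ in range(100_000)])
        assert draws.mean() == pytest.approx(0.7, abs=4 * sigma / np.sqrt(100_000))


class TestElbo:
    def test_doubling_batches_halves_complexity_term(self, rng):
        stays = _toy_stays(8, np.array([0.5]), rng)
        batch = pad_batch(stays)
        net = ToyLogistic(1)
        post = VariationalPosterior(net)
        post.rhos[0].data[:] = -40.0  # near-deterministic: same draw each call
        l1 = elbo_loss(batch, post, n_batches=1, seed=0)
        l2 = elbo_loss(batch, post, n_batches=2, seed=0)
        kl1 = l1 - _nll(net, post, batch)
        kl2 = l2 - _nll(net, post, batch)
        assert kl1 == pytest.approx(2 * kl2, rel=1e-9)

    def test_hand_computed_single_weight_model(self):
        # one weight w = mu + sigma * eps with mu = 0, sigma ~ 0, and one
        # observation x = 1, y = 1: NLL = log(1 + e^{-w}) ~ log 2;
        # the loss is log q(w) - log p(w) + NLL with the same eps draw
        stays = _toy_stays(1, np.array([0.0]), np.random.default_rng(0))
        stays[0].static = np.array([1.0])
        stays[0].label = 1
        batch = pad_batch(stays)
        net = ToyLogistic(1)
        post = VariationalPosterior(net)
        rho = -20.0
        post.rhos[0].data[:] = rho
        sigma = np.logaddexp(0.0, rho)
        eps = float(np.random.default_rng(3).standard_normal((1, 1))[0, 0])
        w = sigma * eps
        logq = -np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * eps**2
        expected = (logq - log_prior(np.array([w]))) / 1 + np.logaddexp(0.0, -w)
        assert elbo_loss(batch, post, n_batches=1, seed=3) == \
            pytest.approx(expected, rel=1e-9)

    def test_divergence_raises(self, rng):
        stays = _toy_stays(16, np.array([0.5]), rng)
        net = ToyLogistic(1)
        net.w.data[:] = np.nan
        with pytest.raises(RuntimeError):
            fit_bbb(stays, network=net, max_epochs=2,
                    config=TrainConfig(epochs=1, seed=0))


class TestFitBbb:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_toy_logistic_coefficients(self, seed):
        rng = np.random.default_rng(100 + seed)
        beta = np.array([1.0, -0.8])
        stays = _toy_stays(2500, beta, rng)
        net = ToyLogistic(2, seed=seed)
        post, history = fit_bbb(stays, network=net, seed=seed, max_epochs=60,
                                config=TrainConfig(epochs=1, learning_rate=0.02,
                                                   seed=seed,
                                                   class_weighting=False))
        mu = post.mus[0].data[:, 0]
        np.testing.assert_allclose(mu, beta, atol=0.3)

    def test_patience_stop_and_history_length(self, rng):
        stays = _toy_stays(60, np.array([0.3]), rng)
        net = ToyLogistic(1)
        post, history = fit_bbb(stays, network=net, seed=0, patience=10,
                                max_epochs=200,
                                config=TrainConfig(epochs=1, learning_rate=0.05,
                                                   seed=0, class_weighting=False))
        assert len(history) >= 11  # at least patience + 1 epochs when stopped

    def test_seed_reproducibility(self, rng):
        stays = _toy_stays(80, np.array([0.5]), rng)
        mus = []
        for _ in range(2):
            net = ToyLogistic(1)
            post, _ = fit_bbb(stays, network=net, seed=4, max_epochs=10,
                              config=TrainConfig(epochs=1, seed=4,
                                                 class_weighting=False))
            mus.append(post.mus[0].data.copy())
        np.testing.assert_allclose(mus[0], mus[1], atol=1e-6)


class TestOddsRatios:
    def _post(self, mu, rho):
        net = ToyLogistic(1)
        post = VariationalPosterior(net)
        post.mus[0].data[:] = mu
        post.rhos[0].data[:] = rho
        return post

    def test_degenerate_posterior_gives_unit_or(self):
        df = odds_ratios(self._post(0.0, -40.0), ["x"], n_samples=500, seed=0)
        assert df.or_mean[0] == pytest.approx(1.0)
        assert df.ci_lower[0] == pytest.approx(1.0)
        assert df.ci_upper[0] == pytest.approx(1.0)

    def test_point_mass_at_log_two_gives_or_two(self):
        df = odds_ratios(self._post(np.log(2.0), -40.0), ["x"], n_samples=500, seed=0)
        assert df.or_mean[0] == pytest.approx(2.0)

    def test_lognormal_quantiles(self):
        # sigma = 0.1: CrI endpoints approach exp(+-1.96 * 0.1)
        rho = np.log(np.expm1(0.1))  # softplus^-1(0.1)
        df = odds_ratios(self._post(0.0, rho), ["x"], n_samples=10_000, seed=1)
        assert df.ci_lower[0] == pytest.approx(np.exp(-1.96 * 0.1), abs=0.01)
        assert df.ci_upper[0] == pytest.approx(np.exp(1.96 * 0.1), abs=0.01)

    def test_interval_coverage_on_simulated_replicates(self):
        """~95% CrIs from the toy model cover the generating coefficient in
        at least 90% of replicates."""
        covered, total = 0, 0
        beta = np.array([0.8])
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            stays = _toy_stays(400, beta, rng)
            if len({s.label for s in stays}) < 2:
                continue
            net = ToyLogistic(1)
            post, _ = fit_bbb(stays, network=net, seed=rep, max_epochs=40,
                              patience=8,
                              config=TrainConfig(epochs=1, learning_rate=0.05,
                                                 seed=rep, class_weighting=False))
            df = odds_ratios(post, ["x"], n_samples=2000, seed=rep)
            lo, hi = np.log(df.ci_lower[0]), np.log(df.ci_upper[0])
            covered += lo <= beta[0] <= hi
            total += 1
        assert covered / total >= 0.90


def _nll(net, post, batch):
    post.set_mean()
    logits = net.logits(batch).data
    y = batch["label"]
    return float(np.sum(np.logaddexp(0.0, logits) - logits * y))
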