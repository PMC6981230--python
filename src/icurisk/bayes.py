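"""Variational Bayesian training (Bayes by Backprop) and interpretation.

A mean-field Gaussian posterior is learned over every network weight: each
weight w has variational parameters (mu, rho) with sigma = log(1 + e^rho),
sampled by the reparameterisation w = mu + sigma * eps. The prior is a scale
mixture of two zero-mean Gaussians (standard deviations sigma1 = 1 and
sigma2 = e^-6, mixture weight pi = 0.5), which encourages a-priori sparsity
of the weights. Each minibatch step draws one weight sample and minimises

    (log q(w) - log p(w)) / n_batches  +  class-weighted NLL(batch | w),

so the complexity term sums to exactly one KL per epoch. Training runs on
the entire data set and stops when the epoch loss has not improved for 10
consecutive epochs.

Interpretation: the final-layer weights of the attention model act like
logistic-regression coefficients, so exp(w) is an odds ratio per unit
covariate increase; per-code risk scores come from scoring single codes
under sampled weights. Both are summarised with 95% credible intervals from
repeated posterior sampling (default 10,000 draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data import Cohort, pad_batch, DXPROC
from .models import ArchSpec, RiskNetwork, build_model
from .training import TrainConfig, class_weights

__all__ = [
    "ScaleMixturePrior", "VariationalPosterior", "log_prior", "fit_bbb",
    "odds_ratios", "code_risk_ranking", "BayesianAttentionModel",
    "BayesianAttentionResults",
]


@dataclass
class ScaleMixturePrior:
    pi: float = 0.5
    sigma1: float = 1.0
    sigma2: float = float(np.exp(-6.0))

    def log_prob(self, w: np.ndarray) -> float:
        """Stable log-density summed over all weights (numpy, no gradients)."""
        return float(np.sum(self._log_terms(np.asarray(w, dtype=float))))

    def _log_terms(self, w):
        a1 = np.log(self.pi) - 0.5 * np.log(2 * np.pi * self.sigma1**2) \
            - w**2 / (2 * self.sigma1**2)
        a2 = np.log1p(-self.pi) - 0.5 * np.log(2 * np.pi * self.sigma2**2) \
            - w**2 / (2 * self.sigma2**2)
        m = np.maximum(a1, a2)
        return m + np.log(np.exp(a1 - m) + np.exp(a2 - m))

    def log_prob_graph(self, w: Tensor) -> Tensor:
        """Same log-density as a differentiable graph node (log-sum-exp)."""
        c1 = np.log(self.pi) - 0.5 * np.log(2 * np.pi * self.sigma1**2)
        c2 = np.log1p(-self.pi) - 0.5 * np.log(2 * np.pi * self.sigma2**2)
        a1 = w * w * (-1.0 / (2 * self.sigma1**2)) + c1
        a2 = w * w * (-1.0 / (2 * self.sigma2**2)) + c2
        m = np.maximum(a1.data, a2.data)  # constant shift
        return (((a1 - Tensor(m)).exp() + (a2 - Tensor(m)).exp()).log()
                + Tensor(m)).sum()


def log_prior(w, prior: ScaleMixturePrior | None = None) -> float:
    """Scale-mixture log prior of a weight vector (summed)."""
    return (prior or ScaleMixturePrior()).log_prob(w)


class VariationalPosterior:
    """Per-weight (mu, rho) Gaussian variational parameters over a network."""

    def __init__(self, network: RiskNetwork, prior: ScaleMixturePrior | None = None,
                 rho_init: float = -5.0):
        self.network = network
        self.prior = prior or ScaleMixturePrior()
        self.params = network.parameters()
        self.mus = [Tensor.param(p.data.copy()) for p in self.params]
        self.rhos = [Tensor.param(np.full_like(p.data, rho_init)) for p in self.params]

    @property
    def n_weights(self) -> int:
        return sum(m.data.size for m in self.mus)

    def sigmas(self) -> list[np.ndarray]:
        return [np.logaddexp(0.0, r.data) for r in self.rhos]

    def sample_weights(self, seed: int | np.random.Generator) -> list[np.ndarray]:
        """One posterior draw w = mu + sigma * eps; deterministic given seed."""
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        return [m.data + s * rng.standard_normal(m.data.shape)
                for m, s in zip(self.mus, self.sigmas())]

    def set_sample(self, draw: list[np.ndarray]) -> None:
        """Load one weight draw into the underlying network."""
        for p, w in zip(self.params, draw):
            p.data = np.asarray(w, dtype=float)

    def set_mean(self) -> None:
        self.set_sample([m.data.copy() for m in self.mus])

    def final_layer_index(self) -> tuple[int, int]:
        """(parameter index, row count) of the final fully connected weight."""
        for i, p in enumerate(self.params):
            if p is self.network.final.W:
                return i, p.data.shape[0]
        raise RuntimeError("final layer weight not found among parameters")


def elbo_loss(batch: dict, posterior: VariationalPosterior, n_batches: int,
              seed: int, w_pos: float = 1.0) -> float:
    """One-sample ELBO estimate for a batch (for monitoring / tests)."""
    value, _ = _elbo_step(batch, posterior, n_batches,
                          np.random.default_rng(seed), w_pos, update=False)
    return value


def _elbo_step(batch, posterior: VariationalPosterior, n_batches: int,
               rng: np.random.Generator, w_pos: float,
               update: bool = True, opt: Adam | None = None) -> tuple[float, float]:
    """Draw one weight sample, compute the ELBO term, optionally step Adam.

    The data term is backpropagated through the network to the sampled
    weights; the chain rule into (mu, rho) is closed by a small graph
    combining the analytic KL terms with a linear term carrying the data
    gradients (dNLL/dw treated as constants).
    """
    eps = [rng.standard_normal(m.data.shape) for m in posterior.mus]
    w_nodes, kl_terms = [], []
    for m, r, e in zip(posterior.mus, posterior.rhos, eps):
        sigma = r.softplus()
        w = m + sigma * Tensor(e)
        # log q(w | mu, sigma): full pathwise dependence through w and sigma
        logq = ((sigma.log() * -1.0)
                - ((w - m) * (w - m)) / (sigma * sigma * 2.0)).sum() \
            + Tensor(-0.5 * np.log(2 * np.pi) * e.size)
        logp = posterior.prior.log_prob_graph(w)
        kl_terms.append(logq - logp)
        w_nodes.append(w)
    posterior.set_sample([w.data for w in w_nodes])
    y = batch["label"]
    weights = 1.0 + (w_pos - 1.0) * y
    logits = posterior.network.logits(batch, rng=rng, training=False)
    nll = (Tensor(weights) * (logits.softplus() - logits * Tensor(y))).sum()
    for p in posterior.params:
        p.grad = None
    nll.backward()
    kl = kl_terms[0]
    for t in kl_terms[1:]:
        kl = kl + t
    value = float(kl.data) / n_batches + float(nll.data)
    if update:
        surrogate = kl / n_batches
        for p, w in zip(posterior.params, w_nodes):
            if p.grad is not None:
                surrogate = surrogate + (Tensor(p.grad) * w).sum()
        if opt is not None:
            opt.zero_grad()
        surrogate.backward()
        if opt is not None:
            opt.step()
    return value, float(nll.data)


def fit_bbb(cohort: Cohort | list, spec: ArchSpec | None = None,
            config: TrainConfig | None = None, seed: int = 0,
            patience: int = 10, max_epochs: int = 200,
            prior: ScaleMixturePrior | None = None,
            network: RiskNetwork | None = None
            ) -> tuple[VariationalPosterior, list[dict]]:
    """Variational training on the entire data set.

    Stops when the epoch loss (one-sample ELBO estimate summed over batches)
    has not decreased for ``patience`` consecutive epochs, or after
    ``max_epochs``. Returns the posterior and the per-epoch history.
    """
    stays = cohort.stays if isinstance(cohort, Cohort) else list(cohort)
    spec = spec or ArchSpec(name="Attention(concat time)", seed=seed)
    config = config or TrainConfig(epochs=max_epochs, seed=seed)
    if network is None:
        if not isinstance(cohort, Cohort):
            raise ValueError("pass a Cohort or a prebuilt network")
        network = build_model(spec, cohort.vocabulary, len(cohort.static_names))
    posterior = VariationalPosterior(network, prior=prior)
    labels = np.array([s.label for s in stays], dtype=float)
    w_pos = class_weights(labels)[1] if config.class_weighting else 1.0
    opt = Adam(posterior.mus + posterior.rhos, lr=config.learning_rate)
    rng = np.random.default_rng(seed)
    n = len(stays)
    n_batches = int(np.ceil(n / config.batch_size))
    history: list[dict] = []
    best, since_best = np.inf, 0
    for _ in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = pad_batch([stays[i] for i in idx])
            value, _ = _elbo_step(batch, posterior, n_batches, rng, w_pos,
                                  update=True, opt=opt)
            if not np.isfinite(value):
                raise RuntimeError("ELBO diverged (non-finite loss)")
            epoch_loss += value
        history.append({"elbo_loss": epoch_loss})
        if epoch_loss < best - 1e-9:
            best, since_best = epoch_loss, 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    posterior.set_mean()
    return posterior, history


def odds_ratios(posterior: VariationalPosterior, covariate_names: list[str],
                n_samples: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Odds ratios exp(w) of the final-layer weights, with 95% CrIs.

    Reports the posterior mean of exp(w) (median alongside) and the 2.5/97.5
    percentiles over ``n_samples`` weight draws.
    """
    i, n_rows = posterior.final_layer_index()
    mu = posterior.mus[i].data[:, 0]
    sigma = posterior.sigmas()[i][:, 0]
    if len(covariate_names) != n_rows:
        raise ValueError("covariate_names length does not match the final layer")
    rng = np.random.default_rng(seed)
    draws = mu + sigma * rng.standard_normal((n_samples, n_rows))
    ors = np.exp(draws)
    return pd.DataFrame({
        "covariate": covariate_names,
        "or_mean": ors.mean(axis=0),
        "or_median": np.median(ors, axis=0),
        "ci_lower": np.percentile(ors, 2.5, axis=0),
        "ci_upper": np.percentile(ors, 97.5, axis=0),
        "log_or_mean": draws.mean(axis=0),
    })


def code_risk_ranking(posterior: VariationalPosterior, stream: str,
                      n_samples: int = 10_000, seed: int = 0,
                      code_names: list[str] | None = None) -> pd.DataFrame:
    """Per-code risk scores with 95% CrIs, sorted descending by mean score.

    Each posterior draw scores every code as a single-event stay at elapsed
    time zero (attention weight exactly one), so the score is the value the
    fully connected head assigns to that code's embedding row.
    """
    network = posterior.network
    v = network.vocabulary.size(stream)
    enc = network.streams[stream]
    codes = np.arange(v)[:, None]
    elapsed = np.zeros((v, 1))
    mask = np.ones((v, 1))
    rng = np.random.default_rng(seed)
    scores = np.empty((n_samples, v))
    dummy = np.random.default_rng(0)
    for s in range(n_samples):
        posterior.set_sample(posterior.sample_weights(rng))
        scores[s] = enc(codes, elapsed, mask, dummy, training=False).data[:, 0]
    posterior.set_mean()
    df = pd.DataFrame({
        "code": np.arange(v),
        "score_mean": scores.mean(axis=0),
        "ci_lower": np.percentile(scores, 2.5, axis=0),
        "ci_upper": np.percentile(scores, 97.5, axis=0),
    })
    if code_names:
        df["name"] = [code_names[c] for c in df["code"]]
    return df.sort_values("score_mean", ascending=False).reset_index(drop=True)


# -- facade -------------------------------------------------------------------

class BayesianAttentionModel:
    """Bayesian attention model over a cohort, for patient-at-risk description.

    Wraps Bayes-by-Backprop training of the "Attention (concatenated time)"
    architecture on the entire cohort, exposing odds ratios for static
    covariates and ranked per-code risk scores, each with credible
    intervals.
    """

    def __init__(self, cohort: Cohort, spec: ArchSpec | None = None,
                 prior: ScaleMixturePrior | None = None):
        self.cohort = cohort
        self.spec = spec or ArchSpec(name="Attention(concat time)", dropout=0.0)
        self.prior = prior or ScaleMixturePrior()

    def fit(self, config: TrainConfig | None = None, seed: int = 0,
            patience: int = 10, max_epochs: int = 200) -> "BayesianAttentionResults":
        posterior, history = fit_bbb(self.cohort, self.spec, config, seed=seed,
                                     patience=patience, max_epochs=max_epochs,
                                     prior=self.prior)
        return BayesianAttentionResults(self, posterior, history)


@dataclass
class BayesianAttentionResults:
    model: BayesianAttentionModel
    posterior: VariationalPosterior
    history: list[dict]

    def odds_ratios(self, n_samples: int = 10_000, seed: int = 0) -> pd.DataFrame:
        names = list(self.model.cohort.static_names) + ["score_dxproc", "score_medvit"]
        return odds_ratios(self.posterior, names, n_samples=n_samples, seed=seed)

    def code_ranking(self, stream: str = DXPROC, n_samples: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
        names = self.model.cohort.vocabulary.code_names.get(stream)
        return code_risk_ranking(self.posterior, stream, n_samples=n_samples,
                                 seed=seed, code_names=names)

    def summary(self, n_samples: int = 2000, seed: int = 0) -> str:
        ors = self.odds_ratios(n_samples=n_samples, seed=seed)
        lines = ["Bayesian attention model (mean-field posterior)",
                 "=" * 56,
                 f"weights:        {self.posterior.n_weights}",
                 f"epochs:         {len(self.history)}",
                 f"final loss:     {self.history[-1]['elbo_loss']:.2f}",
                 "",
                 "Odds ratios (static covariates, 95% credible interval):"]
        for _, row in ors.iterrows():
            star = "*" if (row.ci_lower > 1.0 or row.ci_upper < 1.0) else " "
            lines.append(f"  {row.covariate:28s} {row.or_mean:6.3f} "
                         f"[{row.ci_lower:5.3f}, {row.ci_upper:5.3f}]{star}")
        return "\n".join(lines)
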