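"""Ensemble-MCMC fitting of Gaussian linear models.

Both fitted models in this package (the distance-decay litterfall model and
the diversity-interaction decomposition model) are linear in their
coefficients, observed with Gaussian noise. The Bayesian fit uses weakly
informative priors — normal(0, prior_scale^2) on each coefficient and a
half-normal prior on the noise scale — and samples the posterior with an
affine-invariant ensemble sampler (emcee). Walkers are grouped into chains
for a split-R-hat convergence diagnostic (groups of ensemble walkers are not
fully independent chains; the diagnostic is conservative in practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np


@dataclass
class LinearPosterior:
    """Posterior summary of a Gaussian linear model fit."""

    mean: np.ndarray        # posterior mean of coefficients
    sd: np.ndarray          # posterior sd of coefficients
    sigma: float            # posterior mean noise scale
    rhat: np.ndarray        # split-R-hat per coefficient
    converged: bool
    samples: np.ndarray     # (n_draws_total, n_coef)

    def warn_if_unconverged(self, context: str, threshold: float = 1.05) -> list[str]:
        warnings = []
        if not self.converged:
            warnings.append(
                f"{context}: max R-hat {float(np.max(self.rhat)):.3f} exceeds "
                f"{threshold}; increase draws or check identifiability"
            )
        return warnings


def sample_linear_model(
    X: np.ndarray,
    y: np.ndarray,
    prior_scale: float = 10.0,
    chains: int = 4,
    draws: int = 2000,
    warmup: int = 1000,
    seed: int | None = None,
    rhat_threshold: float = 1.05,
) -> LinearPosterior:
    """Sample ``y ~ N(X @ coef, sigma^2)`` with weakly informative priors.

    The sampler runs ``chains`` groups of walkers for ``warmup + draws``
    steps each and discards the warmup. Sampling is in
    ``(coef, log sigma)`` space with the half-normal prior's Jacobian
    applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    sigma_prior = max(5.0 * np.std(y), 1e-6)

    def log_prob(params: np.ndarray) -> float:
        coef, log_sigma = params[:-1], params[-1]
        if log_sigma > 50.0:
            return -np.inf
        sigma = np.exp(log_sigma)
        resid = y - X @ coef
        loglik = -0.5 * np.sum((resid / sigma) ** 2) - n * log_sigma
        lp_coef = -0.5 * np.sum((coef / prior_scale) ** 2)
        lp_sigma = -0.5 * (sigma / sigma_prior) ** 2 + log_sigma  # + Jacobian
        return loglik + lp_coef + lp_sigma

    dim = p + 1
    walkers_per_chain = max(-(-2 * dim // chains), 4)
    nwalkers = chains * walkers_per_chain

    rng = np.random.default_rng(seed)
    ls_coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ ls_coef
    sigma0 = max(float(np.std(resid)), 1e-3)
    scale = np.maximum(np.abs(ls_coef), 1e-3) * 0.05
    start = np.column_stack(
        [
            ls_coef + rng.normal(0.0, scale, size=(nwalkers, p)) * 1.0,
            np.log(sigma0) + rng.normal(0.0, 0.05, size=nwalkers),
        ]
    )

    sampler = emcee.EnsembleSampler(nwalkers, dim, log_prob)
    if seed is not None:
        sampler.random_state = np.random.RandomState(seed % (2**31)).get_state()
    sampler.run_mcmc(start, warmup + draws, progress=False)
    chain = sampler.get_chain(discard=warmup)  # (draws, nwalkers, dim)

    # group walkers into `chains` pseudo-chains for the diagnostic
    grouped = chain.reshape(draws, chains, walkers_per_chain, dim)
    grouped = grouped.transpose(1, 0, 2, 3).reshape(chains, draws * walkers_per_chain, dim)
    rhat = np.array(
        [float(az.rhat(az.convert_to_dataset(grouped[:, :, k]))["x"]) for k in range(p)]
    )

    flat = chain.reshape(-1, dim)
    coef_samples = flat[:, :p]
    sigma_samples = np.exp(flat[:, p])
    return LinearPosterior(
        mean=coef_samples.mean(axis=0),
        sd=coef_samples.std(axis=0),
        sigma=float(sigma_samples.mean()),
        rhat=rhat,
        converged=bool(np.all(rhat < rhat_threshold)),
        samples=coef_samples,
    )
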