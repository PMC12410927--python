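"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own likelihood code paths: densities
come from scipy.stats and the latent variables are enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import expit
from scipy.stats import norm


def enumerate_cell_likelihood(y, t, state) -> float:
    """log p(y | t, state) by exhaustive enumeration of the lineage
    assignment z and every dropout pattern gamma in {0,1}^G."""
    y = np.asarray(y, dtype=float)
    G, K = state.dynamics.G, state.dynamics.K
    mu_all = state.dynamics.mean(np.array([float(t)]))[0]  # (G, K)
    eps = state.noise.epsilon
    total = 0.0
    for k in range(K):
        mu_k = mu_all[:, k]
        s2_k = (1.0 + state.noise.phi) * mu_k + eps
        p_k = expit(state.noise.beta0 + state.noise.beta1 * mu_k)
        for pattern in itertools.product((0, 1), repeat=G):
            prob = state.pi[k]
            for j, gam in enumerate(pattern):
                if gam:
                    prob *= p_k[j] * (1.0 if y[j] == 0.0 else 0.0)
                else:
                    prob *= (1.0 - p_k[j]) * norm.pdf(y[j], mu_k[j], math.sqrt(s2_k[j]))
                if prob == 0.0:
                    break
            total += prob
    return math.log(total) if total > 0 else -math.inf


def kendall_pairs(x, y) -> float:
    """Kendall statistic by explicit O(n^2) ordered-pair enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    s = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                s += np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
    return s / (n * (n - 1))


def m0_marginal_by_quadrature(y, priors, sigma_scale=0.5, n_grid=400) -> float:
    """log marginal likelihood of the constant-expression model by 2-D
    grid quadrature over (mu, sigma)."""
    from scipy.special import logsumexp

    y = np.asarray(y, dtype=float)
    n = y.size
    amp = priors.gene_prior("delta")
    mus = np.linspace(amp.mean - 6 * amp.sd, amp.mean + 6 * amp.sd, n_grid)
    sigmas = np.linspace(1e-4, 5 * sigma_scale, n_grid)
    dmu = mus[1] - mus[0]
    dsig = sigmas[1] - sigmas[0]
    ll = (-0.5 * n * np.log(2 * np.pi) - n * np.log(sigmas)[None, :]
          - ((y[:, None] - mus[None, :]) ** 2).sum(axis=0)[:, None]
          / (2 * sigmas[None, :] ** 2))
    lp_mu = norm.logpdf(mus, amp.mean, amp.sd)
    lp_sig = (0.5 * np.log(2 / np.pi) - np.log(sigma_scale)
              - sigmas ** 2 / (2 * sigma_scale ** 2))
    grid = ll + lp_mu[:, None] + lp_sig[None, :]
    return float(logsumexp(grid) + np.log(dmu) + np.log(dsig))
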