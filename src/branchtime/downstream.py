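"""Downstream analyses: differentiation potential and branch-specific genes.

Differentiation potential (DP) is the Shannon entropy of a cell's branch
probabilities: maximal (log K) for a fully uncommitted cell, zero for a
committed one.

Branch-specific genes are detected by Bayesian model comparison along one
branch: M0 is constant expression y ~ N(mu, sigma^2); M1 is sigmoidal
activation y ~ N(2*delta/(1 + exp(-tau*(t - t0))), sigma^2).  Both are
sampled by NUTS and their marginal likelihoods estimated by bridge
sampling (with a Laplace fallback); BF10 = p(y | M1) / p(y | M0) is
categorized on the three-way evidence scale: strong above 10, moderate in
(1, 10], null at or below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .data import PriorSpec, ValidationError
from .nuts import sample_nuts
from .results import half_sample_mode

MIN_CELLS = 10
STRONG_BF = 10.0


def differentiation_potential(branch_prob: np.ndarray, base: str = "e") -> np.ndarray:
    """Shannon entropy of each cell's branch probabilities (0*log 0 = 0).

    Natural log by default (nats, maximum log K); ``base='2'`` for bits.
    """
    bp = np.asarray(branch_prob, dtype=float)
    if bp.ndim != 2:
        raise ValidationError("branch_prob must be an N x K matrix")
    if np.any(np.abs(bp.sum(axis=1) - 1.0) > 1e-6) or np.any(bp < -1e-12):
        raise ValidationError("rows must be probability vectors")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(bp > 0, bp * np.log(bp), 0.0)
    dp = -terms.sum(axis=1)
    if base == "2":
        dp = dp / np.log(2.0)
    elif base != "e":
        raise ValidationError("base must be 'e' or '2'")
    return dp


# ---------------------------------------------------------------------------
# marginal likelihood via bridge sampling


def bridge_sampling_logml(draws: np.ndarray, log_post, rng: np.random.Generator,
                          tol: float = 1e-8, max_iter: int = 1000):
    """Bridge-sampling estimate of the log marginal likelihood.

    ``draws`` are posterior samples on the unconstrained scale; ``log_post``
    is the vectorized unnormalized log posterior.  The proposal is a
    moment-matched Gaussian.  Returns (log_ml, converged).
    """
    draws = np.asarray(draws, dtype=float)
    n1, dim = draws.shape
    mean = draws.mean(axis=0)
    cov = np.cov(draws.T) if dim > 1 else np.array([[draws.var(ddof=1)]])
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(dim)
    chol = np.linalg.cholesky(cov)
    n2 = n1
    prop = mean + rng.standard_normal((n2, dim)) @ chol.T

    def log_q(x):
        diff = x - mean
        sol = np.linalg.solve(chol, diff.T)
        return (-0.5 * (sol ** 2).sum(axis=0)
                - 0.5 * dim * np.log(2 * np.pi)
                - np.log(np.diag(chol)).sum())

    l1 = log_post(draws) - log_q(draws)   # posterior samples
    l2 = log_post(prop) - log_q(prop)     # proposal samples
    l2 = l2[np.isfinite(l2)]
    if l2.size == 0:
        return -np.inf, False
    n2 = l2.size
    lstar = np.median(l1)
    s1 = n1 / (n1 + n2)
    s2 = n2 / (n1 + n2)
    log_r = 0.0
    converged = False
    for _ in range(max_iter):
        num = logsumexp(l2 - lstar - np.logaddexp(np.log(s1) + l2 - lstar,
                                                  np.log(s2) + log_r)) - np.log(n2)
        den = logsumexp(-np.logaddexp(np.log(s1) + l1 - lstar,
                                      np.log(s2) + log_r)) - np.log(n1)
        new_log_r = num - den
        if abs(new_log_r - log_r) < tol:
            log_r = new_log_r
            converged = True
            break
        log_r = new_log_r
    return float(log_r + lstar), converged


def laplace_logml(mode: np.ndarray, log_post_grad) -> float:
    """Laplace approximation from a mode and a finite-difference Hessian."""
    mode = np.asarray(mode, dtype=float)
    dim = mode.size
    h = 1e-5
    H = np.empty((dim, dim))
    for i in range(dim):
        e = np.zeros(dim)
        e[i] = h
        _, gp = log_post_grad(mode + e)
        _, gm = log_post_grad(mode - e)
        H[i] = (gp - gm) / (2 * h)
    H = -(H + H.T) / 2.0
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return float("nan")
    lp, _ = log_post_grad(mode)
    return float(lp + 0.5 * dim * np.log(2 * np.pi) - 0.5 * logdet)


# ---------------------------------------------------------------------------
# the two gene-level models (unconstrained parameterizations)


class _ConstantGeneModel:
    """M0: y ~ N(mu, sigma^2); params (mu, log sigma)."""

    dim = 2

    def __init__(self, y: np.ndarray, priors: PriorSpec):
        self.y = np.asarray(y, dtype=float)
        self.n = self.y.size
        amp = priors.gene_prior("delta")
        self.mu_prior = (amp.mean, amp.sd)
        self.sigma_scale = 0.5  # half-normal scale on sigma

    def batch_logpost(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(q)
        mu, lsig = q[:, 0], q[:, 1]
        sig = np.exp(lsig)
        ll = (-0.5 * self.n * np.log(2 * np.pi) - self.n * lsig
              - 0.5 * ((self.y[None, :] - mu[:, None]) ** 2).sum(axis=1) / sig ** 2)
        m, s = self.mu_prior
        lp = norm.logpdf(mu, m, s)
        lp = lp + (0.5 * np.log(2 / np.pi) - np.log(self.sigma_scale)
                   - sig ** 2 / (2 * self.sigma_scale ** 2) + lsig)
        return ll + lp

    def logpost_and_grad(self, q: np.ndarray):
        mu, lsig = q
        sig = np.exp(lsig)
        r = self.y - mu
        ss = (r ** 2).sum()
        ll = -0.5 * self.n * np.log(2 * np.pi) - self.n * lsig - 0.5 * ss / sig ** 2
        m, s = self.mu_prior
        lp = (norm.logpdf(mu, m, s) + 0.5 * np.log(2 / np.pi) - np.log(self.sigma_scale)
              - sig ** 2 / (2 * self.sigma_scale ** 2) + lsig)
        g_mu = r.sum() / sig ** 2 - (mu - m) / s ** 2
        g_lsig = -self.n + ss / sig ** 2 - sig ** 2 / self.sigma_scale ** 2 + 1.0
        return float(ll + lp), np.array([g_mu, g_lsig])


class _SigmoidGeneModel:
    """M1: y ~ N(2*delta*expit(tau*(t - t0)), sigma^2);
    params (log delta, tau, logit t0, log sigma)."""

    dim = 4

    def __init__(self, y: np.ndarray, t: np.ndarray, priors: PriorSpec):
        self.y = np.asarray(y, dtype=float)
        self.t = np.asarray(t, dtype=float)
        self.n = self.y.size
        d = priors.gene_prior("delta")
        tau = priors.gene_prior("tau")
        self.d_prior = (d.mean, d.sd)
        self.tau_prior = (tau.mean, tau.sd)
        self.t0_prior = (priors.t0.a, priors.t0.b)
        self.sigma_scale = 0.5

    def _log_prior_terms(self, ld, tau, lt0, lsig, delta, t0, sig):
        md, sd_ = self.d_prior
        mt, st = self.tau_prior
        a, b = self.t0_prior
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = (norm.logpdf(delta, md, sd_) - norm.logsf(0.0, md, sd_) + ld
                  + norm.logpdf(tau, mt, st)
                  + (a - 1) * np.log(t0) + (b - 1) * np.log1p(-t0)
                  + np.log(t0) + np.log1p(-t0)
                  + 0.5 * np.log(2 / np.pi) - np.log(self.sigma_scale)
                  - sig ** 2 / (2 * self.sigma_scale ** 2) + lsig)
        return lp

    def batch_logpost(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(q)
        ld, tau, lt0, lsig = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        delta, t0, sig = np.exp(ld), expit(lt0), np.exp(lsig)
        mu = 2 * delta[:, None] * expit(tau[:, None] * (self.t[None, :] - t0[:, None]))
        ll = (-0.5 * self.n * np.log(2 * np.pi) - self.n * lsig
              - 0.5 * ((self.y[None, :] - mu) ** 2).sum(axis=1) / sig ** 2)
        return ll + self._log_prior_terms(ld, tau, lt0, lsig, delta, t0, sig)

    def logpost_and_grad(self, q: np.ndarray):
        ld, tau, lt0, lsig = q
        delta, t0, sig = np.exp(ld), expit(lt0), np.exp(lsig)
        s = expit(tau * (self.t - t0))
        mu = 2 * delta * s
        r = self.y - mu
        ss = (r ** 2).sum()
        ll = -0.5 * self.n * np.log(2 * np.pi) - self.n * lsig - 0.5 * ss / sig ** 2
        lp = self._log_prior_terms(ld, tau, lt0, lsig, delta, t0, sig)
        dmu = r / sig ** 2  # d loglik / d mu_i
        md, sd_ = self.d_prior
        mt, st = self.tau_prior
        a, b = self.t0_prior
        g_ld = (dmu * mu).sum() - (delta - md) / sd_ ** 2 * delta + 1.0
        g_tau = (dmu * mu * (1 - s) * (self.t - t0)).sum() - (tau - mt) / st ** 2
        g_t0 = (dmu * mu * (1 - s) * (-tau)).sum()
        g_lt0 = g_t0 * t0 * (1 - t0) + a * (1 - t0) - b * t0
        g_lsig = -self.n + ss / sig ** 2 - sig ** 2 / self.sigma_scale ** 2 + 1.0
        return float(ll + lp), np.array([g_ld, g_tau, g_lt0, g_lsig])


def _sample_model(model, rng, n_chains=2, n_iter=1000, n_warmup=400, init_scale=0.5):
    draws = []
    for _ in range(n_chains):
        for _ in range(20):
            q0 = rng.normal(0.0, init_scale, model.dim)
            lp, _ = model.logpost_and_grad(q0)
            if np.isfinite(lp):
                break
        res = sample_nuts(model.logpost_and_grad, q0, n_iter, n_warmup, rng)
        draws.append(res.draws)
    return np.concatenate(draws, axis=0)


@dataclass(frozen=True)
class GeneTestResult:
    """Model-comparison outcome for one gene on one branch."""

    gene_id: str
    branch: object
    log_marginal_m0: float
    log_marginal_m1: float
    m1_params: dict = field(default_factory=dict)
    activation_time: float = float("nan")
    reliable: bool = True

    @property
    def bf10(self) -> float:
        return float(np.exp(self.log_marginal_m1 - self.log_marginal_m0))

    @property
    def evidence(self) -> str:
        bf = self.bf10
        if bf > STRONG_BF:
            return "strong"
        if bf > 1.0:
            return "moderate"
        return "null"


def test_branch_gene(y, t, priors: PriorSpec | None = None, *, gene_id: str = "",
                     branch=None, seed: int = 0, min_cells: int = MIN_CELLS,
                     n_iter: int = 1000, n_warmup: int = 400) -> GeneTestResult:
    """Compare sigmoidal (M1) against constant (M0) expression along a branch.

    ``y`` holds the normalized expression of cells assigned to the branch,
    ``t`` their pseudotimes in [0, 1].
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if y.shape != t.shape or y.ndim != 1:
        raise ValidationError("y and t must be equal-length vectors")
    if y.size < min_cells:
        raise ValidationError(f"need at least {min_cells} cells, got {y.size}")
    if np.ptp(t) == 0:
        raise ValidationError("pseudotimes are all equal: M1 is unidentifiable")
    if np.any((t < 0) | (t > 1)):
        raise ValidationError("pseudotimes must lie in [0, 1]")
    priors = priors if priors is not None else PriorSpec()
    rng = np.random.default_rng(seed)

    m0 = _ConstantGeneModel(y, priors)
    m1 = _SigmoidGeneModel(y, t, priors)
    reliable = True
    logmls = []
    for model in (m0, m1):
        draws = _sample_model(model, rng, n_iter=n_iter, n_warmup=n_warmup)
        logml, ok = bridge_sampling_logml(draws, model.batch_logpost, rng)
        if not ok or not np.isfinite(logml):
            mode = draws[np.argmax(model.batch_logpost(draws))]
            logml = laplace_logml(mode, model.logpost_and_grad)
            if not np.isfinite(logml):
                reliable = False
        logmls.append(logml)
        if model is m1:
            m1_draws = draws
    delta = np.exp(m1_draws[:, 0])
    tau = m1_draws[:, 1]
    t0 = expit(m1_draws[:, 2])
    sigma2 = np.exp(2 * m1_draws[:, 3])
    params = {
        "delta": half_sample_mode(delta),
        "tau": half_sample_mode(tau),
        "t0": half_sample_mode(t0),
        "sigma2": half_sample_mode(sigma2),
    }
    return GeneTestResult(gene_id, branch, logmls[0], logmls[1],
                          m1_params=params, activation_time=params["t0"],
                          reliable=reliable)


def rank_by_activation(results, top_n: int) -> list:
    """Top ``top_n`` genes by BF10, ordered by activation time.

    Ties break by gene id (lexicographic), making the ranking stable.
    """
    results = list(results)
    if not results:
        raise ValidationError("results must be non-empty")
    by_bf = sorted(results, key=lambda r: (-r.bf10, r.gene_id))
    top = by_bf[: int(top_n)]
    return sorted(top, key=lambda r: (r.activation_time, r.gene_id))
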