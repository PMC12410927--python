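"""Closed-form components of the hierarchical generative model.

A cell at pseudotime t on lineage k expresses gene j around a parametric
mean: switch-like genes follow a logistic curve

    mu = 2*delta / (1 + exp(-tau*(t - t0)))

and transient genes a Gaussian pulse

    mu = 2*eta * exp(-zeta*(t - t0)^2).

Observation noise is normal with mean-dependent variance
(1 + phi)*mu + eps, zero-inflated by a dropout indicator whose probability
is inverse-logit(beta0 + beta1*mu).  The per-cell likelihood marginalizes
both the dropout indicators and the discrete lineage assignment (a
K-component mixture weighted by lineage proportions pi).

Everything here is a pure, vectorized function of explicit parameters so
the same code serves the sampler, the simulator, and brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit, gammaln, log_expit, logsumexp
from scipy.stats import norm

from .data import ExpressionMatrix, MarkerPanel, PriorSpec, ValidationError

EPSILON = 0.01  # variance floor for numerical stability

SWITCH = "switch"
TRANSIENT = "transient"


def sigmoid_mean(t, delta, tau, t0):
    """Switch-like logistic mean 2*delta/(1 + exp(-tau*(t - t0)))."""
    t, delta, tau, t0 = np.broadcast_arrays(t, delta, tau, t0)
    return 2.0 * delta * expit(tau * (t - t0))


def pulse_mean(t, eta, zeta, t0):
    """Transient Gaussian-pulse mean 2*eta*exp(-zeta*(t - t0)^2)."""
    t, eta, zeta, t0 = np.broadcast_arrays(t, eta, zeta, t0)
    return 2.0 * eta * np.exp(-zeta * (t - t0) ** 2)


def variance_fn(mu, phi):
    """Mean-dependent observation variance (1 + phi)*mu + eps."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(mu < 0):
        raise ValidationError("mean expression must be non-negative")
    if np.any(phi < 0):
        raise ValidationError("dispersion phi must be non-negative")
    return (1.0 + phi) * mu + EPSILON


def dropout_prob(mu, beta0, beta1):
    """Dropout probability inverse-logit(beta0 + beta1*mu)."""
    return expit(np.asarray(beta0, dtype=float) + np.asarray(beta1, dtype=float) * np.asarray(mu, dtype=float))


def gene_loglik(y, mu, sigma2, p_drop):
    """Log-density of one observation under the zero-inflated normal.

    The dropout indicator is marginalized: an exact zero contributes
    p_drop + (1 - p_drop) * N(0; mu, sigma2) (point mass plus the density
    evaluated at zero); a nonzero value contributes
    (1 - p_drop) * N(y; mu, sigma2).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    p_drop = np.asarray(p_drop, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValidationError("sigma2 must be strictly positive")
    if np.any((p_drop < 0) | (p_drop > 1)):
        raise ValidationError("p_drop must lie in [0, 1]")
    logn = -0.5 * np.log(2.0 * np.pi * sigma2) - (y - mu) ** 2 / (2.0 * sigma2)
    with np.errstate(divide="ignore"):
        log_p = np.log(p_drop)
        log_1mp = np.log1p(-p_drop)
    return np.where(y == 0, np.logaddexp(log_p, log_1mp + logn), log_1mp + logn)


@dataclass(frozen=True)
class GeneDynamics:
    """Per-(gene, branch) curve parameters.

    ``switch`` is a (G, K) boolean mask: True entries follow the logistic
    curve with parameters (amplitude, shape, t0) = (delta, tau, t0); False
    entries follow the pulse with (eta, zeta, t0).  ``amplitude``, ``shape``
    and ``t0`` are (G, K) float arrays.
    """

    switch: np.ndarray
    amplitude: np.ndarray
    shape: np.ndarray
    t0: np.ndarray

    def __post_init__(self):
        sw = np.asarray(self.switch, dtype=bool)
        amp = np.asarray(self.amplitude, dtype=float)
        shp = np.asarray(self.shape, dtype=float)
        t0 = np.asarray(self.t0, dtype=float)
        if not (sw.shape == amp.shape == shp.shape == t0.shape) or sw.ndim != 2:
            raise ValidationError("GeneDynamics arrays must share a (G, K) shape")
        if np.any((t0 < 0) | (t0 > 1)):
            raise ValidationError("t0 must lie in [0, 1]")
        if np.any(amp[sw] < 0):
            raise ValidationError("switch amplitude delta must be >= 0")
        if np.any(amp[~sw] < 0) or np.any(shp[~sw] < 0):
            raise ValidationError("pulse eta and zeta must be >= 0")
        object.__setattr__(self, "switch", sw)
        object.__setattr__(self, "amplitude", amp)
        object.__setattr__(self, "shape", shp)
        object.__setattr__(self, "t0", t0)

    @property
    def G(self) -> int:
        return self.switch.shape[0]

    @property
    def K(self) -> int:
        return self.switch.shape[1]

    def mean(self, t) -> np.ndarray:
        """Mean expression for pseudotimes t: shape t.shape + (G, K)."""
        t = np.asarray(t, dtype=float)[..., None, None]
        sw = sigmoid_mean(t, self.amplitude, self.shape, self.t0)
        pu = pulse_mean(t, self.amplitude, self.shape, self.t0)
        return np.where(self.switch, sw, pu)


@dataclass(frozen=True)
class NoiseModel:
    """Per-gene dispersion and the global dropout coefficients."""

    phi: np.ndarray
    beta0: float
    beta1: float
    epsilon: float = EPSILON

    def __post_init__(self):
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        if np.any(phi < 0):
            raise ValidationError("phi must be >= 0")
        if self.epsilon <= 0:
            raise ValidationError("epsilon must be > 0")
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class ModelState:
    """One full parameter configuration (T, pi, dynamics, noise)."""

    T: np.ndarray
    pi: np.ndarray
    dynamics: GeneDynamics
    noise: NoiseModel

    def __post_init__(self):
        T = np.atleast_1d(np.asarray(self.T, dtype=float))
        pi = np.atleast_1d(np.asarray(self.pi, dtype=float))
        if np.any((T < 0) | (T > 1)):
            raise ValidationError("pseudotimes must lie in [0, 1]")
        if pi.shape != (self.dynamics.K,):
            raise ValidationError("pi length must equal number of branches")
        if abs(pi.sum() - 1.0) > 1e-12 or np.any(pi < 0):
            raise ValidationError("pi must be a probability simplex vector")
        if self.noise.phi.shape != (self.dynamics.G,):
            raise ValidationError("phi length must equal number of genes")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "pi", pi)

    @property
    def n_cells(self) -> int:
        return self.T.shape[0]


def _entry_logliks(Y: np.ndarray, t: np.ndarray, state: ModelState) -> np.ndarray:
    """(N, G, K) per-entry log-densities at pseudotimes t."""
    mu = state.dynamics.mean(t)  # (N, G, K)
    sigma2 = (1.0 + state.noise.phi[None, :, None]) * mu + state.noise.epsilon
    x = state.noise.beta0 + state.noise.beta1 * mu
    logn = -0.5 * np.log(2.0 * np.pi * sigma2) - (Y[:, :, None] - mu) ** 2 / (2.0 * sigma2)
    log_p = log_expit(x)
    log_1mp = log_expit(-x)
    return np.where(Y[:, :, None] == 0, np.logaddexp(log_p, log_1mp + logn), log_1mp + logn)


def cell_loglik(y: np.ndarray, t: float, state: ModelState, panel: MarkerPanel | None = None) -> float:
    """Log of the K-component mixture likelihood for one cell."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if y.shape[0] != state.dynamics.G:
        raise ValidationError(
            f"cell has {y.shape[0]} genes but the state describes {state.dynamics.G}"
        )
    entry = _entry_logliks(y[None, :], np.atleast_1d(float(t)), state)
    with np.errstate(divide="ignore"):
        comp = np.log(state.pi)[None, :] + entry.sum(axis=1)
    return float(logsumexp(comp, axis=1)[0])


def joint_loglik(m: ExpressionMatrix, state: ModelState, panel: MarkerPanel | None = None) -> float:
    """Sum of cell log-likelihoods (conditional independence across cells)."""
    if not m.normalized:
        raise ValidationError("joint_loglik requires a normalized (model-scale) matrix")
    if m.n_cells != state.n_cells:
        raise ValidationError("matrix and state disagree on the number of cells")
    if m.n_genes != state.dynamics.G:
        raise ValidationError("matrix and state disagree on the number of genes")
    if m.n_cells == 0:
        return 0.0
    entry = _entry_logliks(m.values, state.T, state)
    with np.errstate(divide="ignore"):
        comp = np.log(state.pi)[None, :] + entry.sum(axis=1)
    return float(logsumexp(comp, axis=1).sum())


def _trunc_norm_logpdf(x, mean, sd):
    """Log-density of N(mean, sd^2) truncated to x >= 0."""
    x = np.asarray(x, dtype=float)
    out = norm.logpdf(x, mean, sd) - norm.logsf(0.0, mean, sd)
    return np.where(x < 0, -np.inf, out)


def log_prior(state: ModelState, priors: PriorSpec, panel: MarkerPanel | None = None,
              gene_ids: list[str] | None = None) -> float:
    """Log prior density of a model state under the hierarchical priors.

    Tied parameters are counted once per gene and role: each gene has at
    most one switch parameter set (shared across the branches it marks) and
    one pulse set (shared across the rest).  Pseudotimes are Uniform(0,1);
    pi is symmetric Dirichlet; returns -inf outside the support.
    """
    dyn = state.dynamics
    T, pi = state.T, state.pi
    if np.any((T < 0) | (T > 1)):
        return -np.inf
    conc = priors.concentration(dyn.K)
    if np.any(pi <= 0):
        return -np.inf
    lp = float(gammaln(conc.sum()) - gammaln(conc).sum() + ((conc - 1.0) * np.log(pi)).sum())

    ids: list[str | None] = list(gene_ids) if gene_ids is not None else [None] * dyn.G
    for j in range(dyn.G):
        gid = ids[j]
        for role, mask in ((SWITCH, dyn.switch[j]), (TRANSIENT, ~dyn.switch[j])):
            if not mask.any():
                continue
            k = int(np.flatnonzero(mask)[0])  # tied across branches of this role
            amp, shp, t0 = dyn.amplitude[j, k], dyn.shape[j, k], dyn.t0[j, k]
            if role == SWITCH:
                pa = priors.gene_prior("delta", gid)
                ps = priors.gene_prior("tau", gid)
                lp += float(_trunc_norm_logpdf(amp, pa.mean, pa.sd))
                if priors.tau_positive:
                    lp += float(_trunc_norm_logpdf(shp, ps.mean, ps.sd))
                else:
                    lp += float(norm.logpdf(shp, ps.mean, ps.sd))
            else:
                pa = priors.gene_prior("eta", gid)
                ps = priors.gene_prior("zeta", gid)
                lp += float(_trunc_norm_logpdf(amp, pa.mean, pa.sd))
                lp += float(_trunc_norm_logpdf(shp, ps.mean, ps.sd))
            bt = priors.t0_prior(gid)
            if t0 <= 0 or t0 >= 1:
                if bt.a > 1 or bt.b > 1:
                    return -np.inf
            lp += float(
                (bt.a - 1) * np.log(t0) + (bt.b - 1) * np.log1p(-t0) - betaln(bt.a, bt.b)
            ) if 0 < t0 < 1 else 0.0
    gp = priors.phi
    phi = state.noise.phi
    if np.any(phi < 0):
        return -np.inf
    with np.errstate(divide="ignore"):
        lp += float(
            (gp.shape * np.log(gp.rate) - gammaln(gp.shape)
             + (gp.shape - 1.0) * np.log(phi) - gp.rate * phi).sum()
        )
    pb = priors.beta
    lp += float(norm.logpdf(state.noise.beta0, pb.mean, pb.sd))
    lp += float(norm.logpdf(state.noise.beta1, pb.mean, pb.sd))
    return lp
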