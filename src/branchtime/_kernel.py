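"""Fused likelihood/gradient kernel for the mixture model.

The sampler spends essentially all of its time evaluating the marginalized
log-likelihood and its gradient.  This module provides a numba-jitted
scalar-loop implementation; :mod:`branchtime.model` keeps a vectorized
numpy twin of the same computation that the tests cross-check against
brute-force enumeration and against this kernel.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap


LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True, error_model="numpy")
def _softplus(x):
    if x > 35.0:
        return x
    if x < -35.0:
        return 0.0
    return math.log1p(math.exp(x))


@njit(cache=True, error_model="numpy")
def loglik_and_grads(Y, zero, t, logpi, A, B, C, swmask, phi, b0, b1, eps):
    """Marginalized mixture log-likelihood and its raw gradients.

    Returns (loglik, g_t, gA_sw, gB_sw, gC_sw, gA_pu, gB_pu, gC_pu, g_phi,
    g_b0, g_b1, S_k); curve gradients are on the constrained scale, summed
    over branches per role (switch / pulse) so tied parameters accumulate.
    """
    N, G = Y.shape
    K = logpi.shape[0]
    L = np.empty((N, K))
    for i in range(N):
        ti = t[i]
        for k in range(K):
            acc = logpi[k]
            for j in range(G):
                d = ti - C[j, k]
                if swmask[j, k]:
                    mu = 2.0 * A[j, k] / (1.0 + math.exp(-B[j, k] * d))
                else:
                    mu = 2.0 * A[j, k] * math.exp(-B[j, k] * d * d)
                sig2 = (1.0 + phi[j]) * mu + eps
                x = b0 + b1 * mu
                y = Y[i, j]
                logn = -0.5 * (LOG_2PI + math.log(sig2)) - (y - mu) * (y - mu) / (2.0 * sig2)
                if zero[i, j]:
                    p = 1.0 / (1.0 + math.exp(-x))
                    acc += math.log(p + (1.0 - p) * math.exp(logn))
                else:
                    acc += -_softplus(x) + logn
            L[i, k] = acc

    total = 0.0
    wk = np.empty((N, K))
    for i in range(N):
        m = L[i, 0]
        for k in range(1, K):
            if L[i, k] > m:
                m = L[i, k]
        s = 0.0
        for k in range(K):
            s += math.exp(L[i, k] - m)
        cell = m + math.log(s)
        total += cell
        for k in range(K):
            wk[i, k] = math.exp(L[i, k] - cell)

    g_t = np.zeros(N)
    gA_sw = np.zeros(G)
    gB_sw = np.zeros(G)
    gC_sw = np.zeros(G)
    gA_pu = np.zeros(G)
    gB_pu = np.zeros(G)
    gC_pu = np.zeros(G)
    g_phi = np.zeros(G)
    g_b0 = 0.0
    g_b1 = 0.0
    S_k = np.zeros(K)

    for i in range(N):
        ti = t[i]
        for k in range(K):
            w = wk[i, k]
            S_k[k] += w
            for j in range(G):
                d = ti - C[j, k]
                issw = swmask[j, k]
                if issw:
                    s = 1.0 / (1.0 + math.exp(-B[j, k] * d))
                    mu = 2.0 * A[j, k] * s
                else:
                    gp = math.exp(-B[j, k] * d * d)
                    mu = 2.0 * A[j, k] * gp
                sig2 = (1.0 + phi[j]) * mu + eps
                x = b0 + b1 * mu
                p = 1.0 / (1.0 + math.exp(-x))
                y = Y[i, j]
                resid = (y - mu) / sig2
                dlogn_dmu = resid
                dlogn_ds2 = -0.5 / sig2 + 0.5 * resid * resid
                if zero[i, j]:
                    logn = -0.5 * (LOG_2PI + math.log(sig2)) - (y - mu) * (y - mu) / (2.0 * sig2)
                    n0 = math.exp(logn)
                    f0 = p + (1.0 - p) * n0
                    qw = (1.0 - p) * n0 / f0
                    dll_dx = (1.0 - n0) / f0 * p * (1.0 - p)
                else:
                    qw = 1.0
                    dll_dx = -p
                dll_dmu = qw * (dlogn_dmu + dlogn_ds2 * (1.0 + phi[j])) + dll_dx * b1
                g_phi[j] += w * qw * dlogn_ds2 * mu
                g_b0 += w * dll_dx
                g_b1 += w * dll_dx * mu
                wm = w * dll_dmu
                if issw:
                    g_t[i] += wm * 2.0 * A[j, k] * B[j, k] * s * (1.0 - s)
                    gA_sw[j] += wm * 2.0 * s
                    gB_sw[j] += wm * mu * (1.0 - s) * d
                    gC_sw[j] += -wm * mu * (1.0 - s) * B[j, k]
                else:
                    g_t[i] += -wm * 2.0 * B[j, k] * d * mu
                    gA_pu[j] += wm * 2.0 * gp
                    gB_pu[j] += -wm * mu * d * d
                    gC_pu[j] += wm * 2.0 * B[j, k] * d * mu
    return (total, g_t, gA_sw, gB_sw, gC_sw, gA_pu, gB_pu, gC_pu,
            g_phi, g_b0, g_b1, S_k)


@njit(cache=True, error_model="numpy")
def cell_logliks_grid(Y, zero, tg, logpi, A, B, C, swmask, phi, b0, b1, eps):
    """(N, n_grid) marginal cell log-likelihoods over a shared pseudotime grid."""
    N, G = Y.shape
    K = logpi.shape[0]
    M = tg.shape[0]
    out = np.empty((N, M))
    # precompute per-grid-point curves
    mu_g = np.empty((M, G, K))
    for m in range(M):
        for k in range(K):
            for j in range(G):
                d = tg[m] - C[j, k]
                if swmask[j, k]:
                    mu_g[m, j, k] = 2.0 * A[j, k] / (1.0 + math.exp(-B[j, k] * d))
                else:
                    mu_g[m, j, k] = 2.0 * A[j, k] * math.exp(-B[j, k] * d * d)
    for i in range(N):
        for m in range(M):
            mx = -np.inf
            vals = np.empty(K)
            for k in range(K):
                acc = logpi[k]
                for j in range(G):
                    mu = mu_g[m, j, k]
                    sig2 = (1.0 + phi[j]) * mu + eps
                    x = b0 + b1 * mu
                    y = Y[i, j]
                    logn = -0.5 * (LOG_2PI + math.log(sig2)) - (y - mu) * (y - mu) / (2.0 * sig2)
                    if zero[i, j]:
                        p = 1.0 / (1.0 + math.exp(-x))
                        acc += math.log(p + (1.0 - p) * math.exp(logn))
                    else:
                        acc += -_softplus(x) + logn
                vals[k] = acc
                if acc > mx:
                    mx = acc
            s = 0.0
            for k in range(K):
                s += math.exp(vals[k] - mx)
            out[i, m] = mx + math.log(s)
    return out


@njit(cache=True, error_model="numpy")
def cell_logliks_at(Y, zero, t, logpi, A, B, C, swmask, phi, b0, b1, eps):
    """(N,) marginal cell log-likelihoods at per-cell pseudotimes t."""
    N, G = Y.shape
    K = logpi.shape[0]
    out = np.empty(N)
    for i in range(N):
        ti = t[i]
        mx = -np.inf
        vals = np.empty(K)
        for k in range(K):
            acc = logpi[k]
            for j in range(G):
                d = ti - C[j, k]
                if swmask[j, k]:
                    mu = 2.0 * A[j, k] / (1.0 + math.exp(-B[j, k] * d))
                else:
                    mu = 2.0 * A[j, k] * math.exp(-B[j, k] * d * d)
                sig2 = (1.0 + phi[j]) * mu + eps
                x = b0 + b1 * mu
                y = Y[i, j]
                logn = -0.5 * (LOG_2PI + math.log(sig2)) - (y - mu) * (y - mu) / (2.0 * sig2)
                if zero[i, j]:
                    p = 1.0 / (1.0 + math.exp(-x))
                    acc += math.log(p + (1.0 - p) * math.exp(logn))
                else:
                    acc += -_softplus(x) + logn
            vals[k] = acc
            if acc > mx:
                mx = acc
        s = 0.0
        for k in range(K):
            s += math.exp(vals[k] - mx)
        out[i] = mx + math.log(s)
    return out


@njit(cache=True, error_model="numpy")
def gene_entries(Y, zero, t, j, Aj, Bj, Cj, swj, phi_j, b0, b1, eps):
    """(N, K) per-entry log-densities of gene j at its current parameters."""
    N = Y.shape[0]
    K = Aj.shape[0]
    out = np.empty((N, K))
    for i in range(N):
        ti = t[i]
        y = Y[i, j]
        isz = zero[i, j]
        for k in range(K):
            d = ti - Cj[k]
            if swj[k]:
                mu = 2.0 * Aj[k] / (1.0 + math.exp(-Bj[k] * d))
            else:
                mu = 2.0 * Aj[k] * math.exp(-Bj[k] * d * d)
            sig2 = (1.0 + phi_j) * mu + eps
            x = b0 + b1 * mu
            logn = -0.5 * (LOG_2PI + math.log(sig2)) - (y - mu) * (y - mu) / (2.0 * sig2)
            if isz:
                p = 1.0 / (1.0 + math.exp(-x))
                out[i, k] = math.log(p + (1.0 - p) * math.exp(logn))
            else:
                out[i, k] = -_softplus(x) + logn
    return out


@njit(cache=True, error_model="numpy")
def mixture_loglik_from_sums(Sent, logpi):
    """Total marginalized log-likelihood given per-cell per-branch sums."""
    N, K = Sent.shape
    total = 0.0
    for i in range(N):
        mx = -np.inf
        for k in range(K):
            v = Sent[i, k] + logpi[k]
            if v > mx:
                mx = v
        s = 0.0
        for k in range(K):
            s += math.exp(Sent[i, k] + logpi[k] - mx)
        total += mx + math.log(s)
    return total
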