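"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A self-contained NUTS implementation over a generic log-density interface:
the target supplies ``logp_and_grad(q) -> (float, ndarray)`` on an
unconstrained parameter vector.  The algorithm is the multinomial variant
(tree states weighted by exp(log-density minus energy), doubling until a
U-turn), with Stan-style adaptation: an initial step-size interval, an
expanding sequence of diagonal-metric estimation windows, and a terminal
step-size interval.  Divergences are declared when the Hamiltonian error
exceeds 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    draws: np.ndarray          # (n_kept, dim) post-warmup positions
    accept_stat: np.ndarray    # mean acceptance statistic per kept iteration
    divergent: np.ndarray      # divergence flag per kept iteration
    treedepth: np.ndarray
    energy: np.ndarray
    step_size: float
    inv_metric: np.ndarray     # diagonal of the inverse mass matrix


class _Target:
    def __init__(self, logp_and_grad: Callable, dim: int):
        self.f = logp_and_grad
        self.dim = dim
        self.n_evals = 0

    def __call__(self, q):
        self.n_evals += 1
        lp, g = self.f(q)
        if not np.isfinite(lp):
            lp = -np.inf
            g = np.zeros_like(q)
        return lp, np.asarray(g, dtype=float)


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    def update(self, accept_stat: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    def restart(self, eps0: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.m = 0

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar)) if self.m else float(np.exp(self.log_eps))


class _Welford:
    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def push(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit scale as Stan does
        w = self.n / (self.n + 5.0)
        return w * var + (1.0 - w) * 1e-3


def _find_reasonable_step_size(target, q, lp, grad, inv_metric, rng):
    eps = 1.0
    p = rng.standard_normal(q.shape) / np.sqrt(inv_metric)
    h0 = lp - 0.5 * np.sum(p * p * inv_metric)
    q1, p1, lp1, _ = _leapfrog(target, q, p, grad, eps, inv_metric)
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_metric)
    if not np.isfinite(h1):
        accept = 0.0
    else:
        accept = np.exp(min(0.0, h1 - h0))
    direction = 1.0 if accept > 0.5 else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, lp1, _ = _leapfrog(target, q, p, grad, eps, inv_metric)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_metric)
        accept = np.exp(min(0.0, h1 - h0)) if np.isfinite(h1) else 0.0
        if (direction > 0 and accept <= 0.5) or (direction < 0 and accept >= 0.5):
            break
    return max(min(eps, 10.0), 1e-8)


def _leapfrog(target, q, p, grad, eps, inv_metric):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_metric * p
    lp, g = target(q)
    p = p + 0.5 * eps * g
    return q, p, lp, g


class _TreeState:
    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "lp_prop", "g_prop", "log_weight", "n_divergent",
                 "sum_accept", "n_leapfrog", "turning")


def _build_tree(target, depth, q, p, grad, direction, eps, inv_metric, h0, rng):
    st = _TreeState()
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(target, q, direction * p, grad, eps, inv_metric)
        p1 = direction * p1
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_metric)
        delta = h1 - h0 if np.isfinite(h1) else -np.inf
        st.q_minus = st.q_plus = st.q_prop = q1
        st.p_minus = st.p_plus = p1
        st.g_minus = st.g_plus = st.g_prop = g1
        st.lp_prop = lp1
        st.log_weight = delta
        st.n_divergent = int(delta < -DIVERGENCE_THRESHOLD)
        st.sum_accept = float(np.exp(min(0.0, delta))) if np.isfinite(delta) else 0.0
        st.n_leapfrog = 1
        st.turning = st.n_divergent > 0
        return st
    first = _build_tree(target, depth - 1, q, p, grad, direction, eps, inv_metric, h0, rng)
    if first.turning:
        return first
    if direction > 0:
        second = _build_tree(target, depth - 1, first.q_plus, first.p_plus,
                             first.g_plus, direction, eps, inv_metric, h0, rng)
        first.q_plus, first.p_plus, first.g_plus = second.q_plus, second.p_plus, second.g_plus
    else:
        second = _build_tree(target, depth - 1, first.q_minus, first.p_minus,
                             first.g_minus, direction, eps, inv_metric, h0, rng)
        first.q_minus, first.p_minus, first.g_minus = second.q_minus, second.p_minus, second.g_minus
    total = np.logaddexp(first.log_weight, second.log_weight)
    if np.isfinite(second.log_weight) and np.log(rng.uniform()) < second.log_weight - total:
        first.q_prop, first.lp_prop, first.g_prop = second.q_prop, second.lp_prop, second.g_prop
    first.log_weight = total
    first.n_divergent += second.n_divergent
    first.sum_accept += second.sum_accept
    first.n_leapfrog += second.n_leapfrog
    dq = first.q_plus - first.q_minus
    first.turning = (
        second.turning
        or first.n_divergent > 0
        or np.dot(dq, inv_metric * first.p_minus) < 0
        or np.dot(dq, inv_metric * first.p_plus) < 0
    )
    return first


def _nuts_step(target, q, lp, grad, eps, inv_metric, max_treedepth, rng):
    p = rng.standard_normal(q.shape) / np.sqrt(inv_metric)
    h0 = lp - 0.5 * np.sum(p * p * inv_metric)
    q_minus = q_plus = q
    p_minus = p_plus = p
    g_minus = g_plus = grad
    q_sel, lp_sel, g_sel = q, lp, grad
    log_weight = 0.0  # weight of the initial point: exp(h - h0) = 1
    sum_accept = 0.0
    n_leapfrog = 0
    n_divergent = 0
    depth = 0
    while depth < max_treedepth:
        direction = 1.0 if rng.uniform() < 0.5 else -1.0
        if direction > 0:
            sub = _build_tree(target, depth, q_plus, p_plus, g_plus,
                              direction, eps, inv_metric, h0, rng)
        else:
            sub = _build_tree(target, depth, q_minus, p_minus, g_minus,
                              direction, eps, inv_metric, h0, rng)
        sum_accept += sub.sum_accept
        n_leapfrog += sub.n_leapfrog
        n_divergent += sub.n_divergent
        if sub.turning:
            break
        # biased progressive sampling: favor the new subtree
        if np.isfinite(sub.log_weight) and np.log(rng.uniform()) < sub.log_weight - log_weight:
            q_sel, lp_sel, g_sel = sub.q_prop, sub.lp_prop, sub.g_prop
        log_weight = np.logaddexp(log_weight, sub.log_weight)
        if direction > 0:
            q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            q_minus, p_minus, g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        dq = q_plus - q_minus
        if (np.dot(dq, inv_metric * p_minus) < 0) or (np.dot(dq, inv_metric * p_plus) < 0):
            depth += 1
            break
        depth += 1
    accept_stat = sum_accept / max(n_leapfrog, 1)
    energy = -(lp_sel - 0.5 * np.sum(p * p * inv_metric))
    return q_sel, lp_sel, g_sel, accept_stat, n_divergent > 0, depth, energy


def _adaptation_schedule(n_warmup: int):
    """(init_buffer, window starts, term_buffer) in Stan proportions."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    windows = []
    start = init
    size = 25
    while start + size < n_warmup - term:
        if start + 3 * size >= n_warmup - term:
            size = n_warmup - term - start
        windows.append((start, start + size))
        start += size
        size *= 2
    return init, windows, term


def sample_nuts(
    logp_and_grad: Callable,
    q0: np.ndarray,
    n_iter: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
    interleave: Callable | None = None,
    active_idx: np.ndarray | None = None,
) -> ChainResult:
    """Run one NUTS chain; returns post-warmup draws and sampler stats.

    ``interleave``, if given, is an extra MCMC move ``(q, rng) -> q``
    (e.g. a Metropolis-within-Gibbs refresh of conditionally independent
    coordinates) applied after every NUTS transition.

    ``active_idx`` restricts the Hamiltonian dynamics to a coordinate
    subset; the remaining coordinates are then expected to be sampled by
    the ``interleave`` move (a blocked NUTS-within-Gibbs scheme).  The
    recorded draws always span the full vector.
    """
    q_full = np.asarray(q0, dtype=float).copy()
    full_dim = q_full.shape[0]
    if active_idx is None:
        active_idx = np.arange(full_dim)
    else:
        active_idx = np.asarray(active_idx, dtype=np.intp)
        if interleave is None:
            raise ValueError("active_idx without interleave leaves coordinates frozen")
    dim = active_idx.shape[0]

    def f_active(qa):
        q_full[active_idx] = qa
        lp, g = logp_and_grad(q_full)
        return lp, g[active_idx]

    target = _Target(f_active, dim)
    q = q_full[active_idx].copy()
    lp, grad = target(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log-density")
    inv_metric = np.ones(dim)
    eps = _find_reasonable_step_size(target, q, lp, grad, inv_metric, rng)
    da = _DualAveraging(eps, target=target_accept)
    init, windows, term = _adaptation_schedule(n_warmup)
    welford = _Welford(dim)
    window_idx = 0

    n_kept = n_iter - n_warmup
    draws = np.empty((n_kept, full_dim))
    accept = np.empty(n_kept)
    divergent = np.zeros(n_kept, dtype=bool)
    treedepth = np.empty(n_kept, dtype=int)
    energy = np.empty(n_kept)

    for it in range(n_iter):
        q, lp, grad, a, div, depth, e = _nuts_step(
            target, q, lp, grad, eps, inv_metric, max_treedepth, rng
        )
        q_full[active_idx] = q
        if interleave is not None:
            q_new = interleave(q_full.copy(), rng)
            if not np.array_equal(q_new, q_full):
                q_full = q_new.copy()
                q = q_full[active_idx].copy()
                lp, grad = target(q)
        if it < n_warmup:
            eps = da.update(a)
            in_window = any(s <= it < t for s, t in windows)
            if in_window:
                welford.push(q)
            if window_idx < len(windows) and it == windows[window_idx][1] - 1:
                inv_metric = welford.variance()
                welford = _Welford(dim)
                window_idx += 1
                lp, grad = target(q)
                eps = _find_reasonable_step_size(target, q, lp, grad, inv_metric, rng)
                da.restart(eps)
            if it == n_warmup - 1:
                eps = da.adapted
        else:
            j = it - n_warmup
            q_full[active_idx] = q
            draws[j] = q_full
            accept[j] = a
            divergent[j] = div
            treedepth[j] = depth
            energy[j] = e
    return ChainResult(draws, accept, divergent, treedepth, energy, float(eps), inv_metric)
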