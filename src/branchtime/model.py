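"""The trajectory mixture model and its posterior geometry.

``TrajectoryModel`` binds a normalized expression matrix to a marker panel
and priors, exposes the unconstrained log-posterior with analytic
gradients, and fits by NUTS.  The parameterization ties dynamics per gene:
one switch parameter set (delta, tau, t0) shared across the branches a
gene marks, and one pulse set (eta, zeta, t0) shared across the rest, as
the per-gene subscripts of the generative model imply.

Unconstrained transforms: pseudotimes and t0 via logit; amplitudes, widths,
dispersions (and tau, when constrained positive) via log; lineage
proportions via additive log-ratio against the last branch.  Priors and
transform Jacobians are added in the unconstrained space, so NUTS samples
the correctly transformed posterior.

The likelihood/gradient hot path has two interchangeable implementations:
a numba-jitted kernel (default) and a vectorized numpy twin used as the
reference in tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, expit, log_expit, logsumexp
from scipy.stats import norm

from ._kernel import HAVE_NUMBA, loglik_and_grads
from .data import ExpressionMatrix, MarkerPanel, PriorSpec, ValidationError
from .dynamics import EPSILON, GeneDynamics, ModelState, NoiseModel
from .nuts import sample_nuts


@dataclass(frozen=True)
class SamplerConfig:
    """NUTS settings; defaults follow four chains of 6000 iterations with
    3000 warm-up.  ``init`` selects the chain initialization: a jittered
    posterior-mode polish (default), raw prior draws, or a caller-supplied
    state."""

    n_chains: int = 4
    n_iter: int = 6000
    n_warmup: int = 3000
    seed: int = 0
    target_accept: float = 0.8
    max_treedepth: int = 10
    init: str = "map"  # map | prior | custom
    gibbs_rounds: int = 1  # t/gene Gibbs sweeps interleaved per NUTS step
    # "non_t": Hamiltonian dynamics on everything except pseudotimes, which
    # the exact grid-Gibbs move owns (the bimodal per-cell conditionals are
    # what force tiny leapfrog steps); "all": full-vector NUTS.
    nuts_block: str = "non_t"

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.n_warmup >= self.n_iter:
            raise ValidationError("n_warmup must be smaller than n_iter")
        if self.init not in ("prior", "map", "custom"):
            raise ValidationError(f"unknown init strategy {self.init!r}")
        if self.gibbs_rounds < 0:
            raise ValidationError("gibbs_rounds must be >= 0")
        if self.nuts_block not in ("non_t", "all"):
            raise ValidationError(f"unknown nuts_block {self.nuts_block!r}")


class ParameterPacking:
    """Layout of the unconstrained parameter vector.

    Order: logit-pseudotimes (N), ALR lineage proportions (K-1), per
    switch-role gene (log delta, [log] tau, logit t0), per pulse-role gene
    (log eta, log zeta, logit t0), log phi (G), beta0, beta1.
    """

    def __init__(self, n_cells: int, panel: MarkerPanel, gene_ids: list[str],
                 tau_positive: bool = True):
        self.N = n_cells
        self.K = panel.K
        self.gene_ids = list(gene_ids)
        self.G = len(gene_ids)
        self.tau_positive = tau_positive
        self.switch_mask = panel.switch_mask(self.gene_ids)  # (G, K)
        self.sw_genes = np.flatnonzero(self.switch_mask.any(axis=1))
        self.pu_genes = np.flatnonzero((~self.switch_mask).any(axis=1))
        n = self.N
        self.sl_t = slice(0, n)
        self.sl_pi = slice(n, n + self.K - 1)
        n += self.K - 1
        self.sl_sw = slice(n, n + 3 * len(self.sw_genes))
        n += 3 * len(self.sw_genes)
        self.sl_pu = slice(n, n + 3 * len(self.pu_genes))
        n += 3 * len(self.pu_genes)
        self.sl_phi = slice(n, n + self.G)
        n += self.G
        self.sl_beta = slice(n, n + 2)
        self.dim = n + 2
        # flat (G*K) scatter indices for vectorized unpacking
        flat = np.arange(self.G * self.K).reshape(self.G, self.K)
        sw_idx, sw_rep, pu_idx, pu_rep = [], [], [], []
        for row, j in enumerate(self.sw_genes):
            cols = flat[j][self.switch_mask[j]]
            sw_idx.extend(cols)
            sw_rep.extend([row] * len(cols))
        for row, j in enumerate(self.pu_genes):
            cols = flat[j][~self.switch_mask[j]]
            pu_idx.extend(cols)
            pu_rep.extend([row] * len(cols))
        self._sw_idx = np.asarray(sw_idx, dtype=np.intp)
        self._sw_rep = np.asarray(sw_rep, dtype=np.intp)
        self._pu_idx = np.asarray(pu_idx, dtype=np.intp)
        self._pu_rep = np.asarray(pu_rep, dtype=np.intp)

    # -- constrained <-> unconstrained -------------------------------------

    def unpack(self, q: np.ndarray):
        """q -> (t, pi, A, B, C, phi, beta0, beta1) with (G, K) curve arrays."""
        t = expit(q[self.sl_t])
        w = q[self.sl_pi]
        logits = np.concatenate([w, [0.0]])
        pi = np.exp(logits - logsumexp(logits))
        sw = q[self.sl_sw].reshape(-1, 3)
        pu = q[self.sl_pu].reshape(-1, 3)
        A = np.zeros(self.G * self.K)
        B = np.zeros(self.G * self.K)
        C = np.full(self.G * self.K, 0.5)
        if self._sw_idx.size:
            A[self._sw_idx] = np.exp(sw[self._sw_rep, 0])
            B[self._sw_idx] = (np.exp(sw[self._sw_rep, 1]) if self.tau_positive
                               else sw[self._sw_rep, 1])
            C[self._sw_idx] = expit(sw[self._sw_rep, 2])
        if self._pu_idx.size:
            A[self._pu_idx] = np.exp(pu[self._pu_rep, 0])
            B[self._pu_idx] = np.exp(pu[self._pu_rep, 1])
            C[self._pu_idx] = expit(pu[self._pu_rep, 2])
        A = A.reshape(self.G, self.K)
        B = B.reshape(self.G, self.K)
        C = C.reshape(self.G, self.K)
        phi = np.exp(q[self.sl_phi])
        beta0, beta1 = q[self.sl_beta]
        return t, pi, A, B, C, phi, beta0, beta1

    def to_state(self, q: np.ndarray) -> ModelState:
        t, pi, A, B, C, phi, b0, b1 = self.unpack(q)
        dyn = GeneDynamics(self.switch_mask, A, B, C)
        return ModelState(t, pi, dyn, NoiseModel(phi, float(b0), float(b1)))

    def pack_state(self, state: ModelState) -> np.ndarray:
        """Inverse of :meth:`to_state` (tied values read from the first
        branch of each role)."""

        def _logit(v):
            v = np.clip(v, 1e-9, 1 - 1e-9)
            return np.log(v) - np.log1p(-v)

        q = np.zeros(self.dim)
        q[self.sl_t] = _logit(state.T)
        if self.K > 1:
            pi = np.clip(state.pi, 1e-12, None)
            q[self.sl_pi] = np.log(pi[:-1]) - np.log(pi[-1])
        sw = np.empty((len(self.sw_genes), 3))
        for row, j in enumerate(self.sw_genes):
            k = int(np.flatnonzero(self.switch_mask[j])[0])
            tau = state.dynamics.shape[j, k]
            sw[row] = [np.log(max(state.dynamics.amplitude[j, k], 1e-12)),
                       np.log(max(tau, 1e-12)) if self.tau_positive else tau,
                       _logit(state.dynamics.t0[j, k])]
        q[self.sl_sw] = sw.ravel()
        pu = np.empty((len(self.pu_genes), 3))
        for row, j in enumerate(self.pu_genes):
            k = int(np.flatnonzero(~self.switch_mask[j])[0])
            pu[row] = [np.log(max(state.dynamics.amplitude[j, k], 1e-12)),
                       np.log(max(state.dynamics.shape[j, k], 1e-12)),
                       _logit(state.dynamics.t0[j, k])]
        q[self.sl_pu] = pu.ravel()
        q[self.sl_phi] = np.log(np.clip(state.noise.phi, 1e-12, None))
        q[self.sl_beta] = [state.noise.beta0, state.noise.beta1]
        return q


class TrajectoryModel:
    """Semi-supervised Bayesian mixture model of branching differentiation.

    Parameters
    ----------
    data : ExpressionMatrix
        Normalized (model-scale) cells-by-genes matrix; columns outside the
        marker panel are dropped.
    panel : MarkerPanel
        Branch topology and per-gene switch roles.
    priors : PriorSpec, optional
    use_numba : bool
        Evaluate the likelihood with the jitted kernel (default when numba
        is importable); the numpy path is always available for reference.
    """

    def __init__(self, data: ExpressionMatrix, panel: MarkerPanel,
                 priors: PriorSpec | None = None, use_numba: bool | None = None):
        if not data.normalized:
            raise ValidationError("TrajectoryModel requires normalized expression")
        panel.validate_against(data)
        self.panel = panel
        self.priors = priors if priors is not None else PriorSpec()
        cols = [data.gene_index(g) for g in panel.gene_ids]
        self.gene_ids = list(panel.gene_ids)
        self.cell_ids = list(data.cell_ids)
        self.Y = np.ascontiguousarray(data.values[:, cols])
        self.N, self.G = self.Y.shape
        self.K = panel.K
        self.packing = ParameterPacking(self.N, panel, self.gene_ids,
                                        self.priors.tau_positive)
        self._zero = self.Y == 0.0
        self.use_numba = HAVE_NUMBA if use_numba is None else (use_numba and HAVE_NUMBA)
        self._prepare_prior_tables()

    @classmethod
    def from_files(cls, expression_path, panel_path, priors: PriorSpec | None = None,
                   normalized: bool = False, **read_kwargs) -> "TrajectoryModel":
        from .data import normalize as _normalize, parse_marker_panel, read_expression

        m = read_expression(expression_path, **read_kwargs)
        if normalized:
            m = ExpressionMatrix(m.values, m.cell_ids, m.gene_ids, normalized=True)
        else:
            m = _normalize(m)
        panel = parse_marker_panel(panel_path, m)
        return cls(m, panel, priors)

    def _prepare_prior_tables(self):
        pr, ids = self.priors, self.gene_ids
        pk = self.packing

        def table(param, genes):
            out = np.array([[pr.gene_prior(param, ids[j]).mean,
                             pr.gene_prior(param, ids[j]).sd] for j in genes])
            return out.reshape(-1, 2)

        self._sw_amp = table("delta", pk.sw_genes)
        self._sw_shp = table("tau", pk.sw_genes)
        self._pu_amp = table("eta", pk.pu_genes)
        self._pu_shp = table("zeta", pk.pu_genes)
        self._sw_t0 = np.array([[pr.t0_prior(ids[j]).a, pr.t0_prior(ids[j]).b]
                                for j in pk.sw_genes]).reshape(-1, 2)
        self._pu_t0 = np.array([[pr.t0_prior(ids[j]).a, pr.t0_prior(ids[j]).b]
                                for j in pk.pu_genes]).reshape(-1, 2)
        self._conc = pr.concentration(self.K)
        # normalizing constants, precomputed once
        from scipy.special import gammaln as _gl, log_ndtr

        half_log_2pi = 0.5 * np.log(2.0 * np.pi)

        def trunc_const(tab):  # -log sd - log Phi(m/s): half-normal truncation
            return (-half_log_2pi - np.log(tab[:, 1])
                    - log_ndtr(tab[:, 0] / tab[:, 1]))

        self._c_sw_amp = trunc_const(self._sw_amp)
        self._c_pu_amp = trunc_const(self._pu_amp)
        self._c_pu_shp = trunc_const(self._pu_shp)
        self._c_sw_shp = (trunc_const(self._sw_shp) if pr.tau_positive
                          else -half_log_2pi - np.log(self._sw_shp[:, 1]))
        self._c_sw_t0 = -betaln(self._sw_t0[:, 0], self._sw_t0[:, 1])
        self._c_pu_t0 = -betaln(self._pu_t0[:, 0], self._pu_t0[:, 1])
        self._c_dir = float(_gl(self._conc.sum()) - _gl(self._conc).sum())
        self._c_phi = float(pr.phi.shape * np.log(pr.phi.rate) - _gl(pr.phi.shape))
        self._c_beta = float(-2.0 * half_log_2pi - 2.0 * np.log(pr.beta.sd))

    # -- likelihood core ----------------------------------------------------

    def _core(self, q: np.ndarray):
        """loglik and raw gradients (constrained scale, tied per role)."""
        pk = self.packing
        t, pi, A, B, C, phi, b0, b1 = pk.unpack(q)
        with np.errstate(divide="ignore"):
            logpi = np.log(pi)
        if self.use_numba:
            out = loglik_and_grads(self.Y, self._zero, t, logpi, A, B, C,
                                   pk.switch_mask, phi, float(b0), float(b1), EPSILON)
        else:
            out = self._core_numpy(t, logpi, A, B, C, phi, b0, b1)
        return (t, pi, A, B, C, phi, b0, b1), out

    def _core_numpy(self, t, logpi, A, B, C, phi, b0, b1):
        pk = self.packing
        sw = pk.switch_mask[None, :, :]
        d = t[:, None, None] - C[None, :, :]
        s = expit(B[None, :, :] * d)
        g = np.exp(-B[None, :, :] * d * d)
        mu = np.where(sw, 2.0 * A[None] * s, 2.0 * A[None] * g)
        sigma2 = (1.0 + phi[None, :, None]) * mu + EPSILON
        x = b0 + b1 * mu
        logn = -0.5 * np.log(2.0 * np.pi * sigma2) - (self.Y[:, :, None] - mu) ** 2 / (2.0 * sigma2)
        zero = self._zero[:, :, None]
        entry = np.where(zero, np.logaddexp(log_expit(x), log_expit(-x) + logn),
                         log_expit(-x) + logn)
        comp = logpi[None, :] + entry.sum(axis=1)  # (N, K)
        cell = logsumexp(comp, axis=1)
        loglik = float(cell.sum())
        wk = np.exp(comp - cell[:, None])

        p = expit(x)
        n0 = np.exp(logn)  # bounded: sigma2 >= mu + eps keeps the exponent mild
        f0 = p + (1.0 - p) * n0
        resid = (self.Y[:, :, None] - mu) / sigma2
        dlogn_ds2 = -0.5 / sigma2 + 0.5 * resid * resid
        qw = np.where(zero, (1.0 - p) * n0 / f0, 1.0)
        dll_dx = np.where(zero, (1.0 - n0) / f0 * p * (1.0 - p), -p)
        dll_dmu = qw * (resid + dlogn_ds2 * (1.0 + phi[None, :, None])) + dll_dx * b1

        W = wk[:, None, :]
        wmu = W * dll_dmu
        dmu_dt = np.where(sw, 2.0 * A[None] * B[None] * s * (1.0 - s),
                          -2.0 * B[None] * d * mu)
        g_t = (wmu * dmu_dt).sum(axis=(1, 2))
        dmu_dA = np.where(sw, 2.0 * s, 2.0 * g)
        dmu_dB = np.where(sw, mu * (1.0 - s) * d, -mu * d * d)
        dmu_dC = np.where(sw, -mu * (1.0 - s) * B[None], 2.0 * B[None] * d * mu)
        gA_sw = (wmu * dmu_dA * sw).sum(axis=(0, 2))
        gB_sw = (wmu * dmu_dB * sw).sum(axis=(0, 2))
        gC_sw = (wmu * dmu_dC * sw).sum(axis=(0, 2))
        gA_pu = (wmu * dmu_dA * ~sw).sum(axis=(0, 2))
        gB_pu = (wmu * dmu_dB * ~sw).sum(axis=(0, 2))
        gC_pu = (wmu * dmu_dC * ~sw).sum(axis=(0, 2))
        g_phi = (W * qw * dlogn_ds2 * mu).sum(axis=(0, 2))
        g_b0 = float((W * dll_dx).sum())
        g_b1 = float((W * dll_dx * mu).sum())
        S_k = wk.sum(axis=0)
        return (loglik, g_t, gA_sw, gB_sw, gC_sw, gA_pu, gB_pu, gC_pu,
                g_phi, g_b0, g_b1, S_k)

    def loglik_terms(self, q: np.ndarray):
        """Mixture bookkeeping for one draw (numpy path, for reuse)."""
        pk = self.packing
        t, pi, A, B, C, phi, b0, b1 = pk.unpack(q)
        sw = pk.switch_mask[None, :, :]
        d = t[:, None, None] - C[None, :, :]
        s = expit(B[None, :, :] * d)
        g = np.exp(-B[None, :, :] * d * d)
        mu = np.where(sw, 2.0 * A[None] * s, 2.0 * A[None] * g)
        sigma2 = (1.0 + phi[None, :, None]) * mu + EPSILON
        x = b0 + b1 * mu
        logn = -0.5 * np.log(2.0 * np.pi * sigma2) - (self.Y[:, :, None] - mu) ** 2 / (2.0 * sigma2)
        zero = self._zero[:, :, None]
        entry = np.where(zero, np.logaddexp(log_expit(x), log_expit(-x) + logn),
                         log_expit(-x) + logn)
        with np.errstate(divide="ignore"):
            comp = np.log(pi)[None, :] + entry.sum(axis=1)
        cell = logsumexp(comp, axis=1)
        return dict(t=t, pi=pi, comp=comp, cell=cell)

    def branch_posterior(self, q: np.ndarray) -> np.ndarray:
        """(N, K) posterior branch probabilities for one draw."""
        terms = self.loglik_terms(q)
        return np.exp(terms["comp"] - terms["cell"][:, None])

    # -- log-posterior -------------------------------------------------------

    def logpost_and_grad(self, q: np.ndarray):
        """Unconstrained log-posterior and its analytic gradient."""
        pk = self.packing
        (t, pi, A, B, C, phi, b0, b1), core = self._core(q)
        (loglik, g_t, gA_sw, gB_sw, gC_sw, gA_pu, gB_pu, gC_pu,
         g_phi, g_b0, g_b1, S_k) = core

        grad = np.zeros(pk.dim)
        logp = loglik

        # pseudotimes: Uniform(0,1) prior, logit transform
        logp += float(np.sum(np.log(t) + np.log1p(-t)))
        grad[pk.sl_t] = g_t * t * (1.0 - t) + (1.0 - 2.0 * t)

        # lineage proportions: Dirichlet prior + ALR Jacobian (sum log pi)
        if self.K > 1:
            logp += self._c_dir + float((self._conc * np.log(pi)).sum())
            c_total = S_k + self._conc
            grad[pk.sl_pi] = c_total[:-1] - pi[:-1] * c_total.sum()

        # switch-role genes
        if pk.sw_genes.size:
            rows = pk.sw_genes
            qsw = q[pk.sl_sw].reshape(-1, 3)
            delta = np.exp(qsw[:, 0])
            t0 = expit(qsw[:, 2])
            m_, s_ = self._sw_amp[:, 0], self._sw_amp[:, 1]
            logp += float(np.sum(self._c_sw_amp - (delta - m_) ** 2 / (2 * s_**2) + qsw[:, 0]))
            gA = gA_sw[rows] * delta - (delta - m_) / s_**2 * delta + 1.0
            m2, s2_ = self._sw_shp[:, 0], self._sw_shp[:, 1]
            if pk.tau_positive:
                tau = np.exp(qsw[:, 1])
                logp += float(np.sum(self._c_sw_shp - (tau - m2) ** 2 / (2 * s2_**2) + qsw[:, 1]))
                gB = gB_sw[rows] * tau - (tau - m2) / s2_**2 * tau + 1.0
            else:
                tau = qsw[:, 1]
                logp += float(np.sum(self._c_sw_shp - (tau - m2) ** 2 / (2 * s2_**2)))
                gB = gB_sw[rows] - (tau - m2) / s2_**2
            a_, b_ = self._sw_t0[:, 0], self._sw_t0[:, 1]
            logp += float(np.sum(a_ * np.log(t0) + b_ * np.log1p(-t0) + self._c_sw_t0))
            gC = gC_sw[rows] * t0 * (1.0 - t0) + a_ * (1.0 - t0) - b_ * t0
            grad[pk.sl_sw] = np.column_stack([gA, gB, gC]).ravel()

        # pulse-role genes
        if pk.pu_genes.size:
            rows = pk.pu_genes
            qpu = q[pk.sl_pu].reshape(-1, 3)
            eta, zeta = np.exp(qpu[:, 0]), np.exp(qpu[:, 1])
            t0 = expit(qpu[:, 2])
            m_, s_ = self._pu_amp[:, 0], self._pu_amp[:, 1]
            logp += float(np.sum(self._c_pu_amp - (eta - m_) ** 2 / (2 * s_**2) + qpu[:, 0]))
            gA = gA_pu[rows] * eta - (eta - m_) / s_**2 * eta + 1.0
            m2, s2_ = self._pu_shp[:, 0], self._pu_shp[:, 1]
            logp += float(np.sum(self._c_pu_shp - (zeta - m2) ** 2 / (2 * s2_**2) + qpu[:, 1]))
            gB = gB_pu[rows] * zeta - (zeta - m2) / s2_**2 * zeta + 1.0
            a_, b_ = self._pu_t0[:, 0], self._pu_t0[:, 1]
            logp += float(np.sum(a_ * np.log(t0) + b_ * np.log1p(-t0) + self._c_pu_t0))
            gC = gC_pu[rows] * t0 * (1.0 - t0) + a_ * (1.0 - t0) - b_ * t0
            grad[pk.sl_pu] = np.column_stack([gA, gB, gC]).ravel()

        # dispersion: Gamma(shape, rate) prior, log transform
        gp = self.priors.phi
        lphi = q[pk.sl_phi]
        logp += float(np.sum(self._c_phi + gp.shape * lphi - gp.rate * phi))
        grad[pk.sl_phi] = g_phi * phi + gp.shape - gp.rate * phi

        # dropout coefficients
        pb = self.priors.beta
        logp += self._c_beta - float((b0 - pb.mean) ** 2 + (b1 - pb.mean) ** 2) / (2 * pb.sd**2)
        grad[pk.sl_beta] = [g_b0 - (b0 - pb.mean) / pb.sd**2,
                            g_b1 - (b1 - pb.mean) / pb.sd**2]

        return logp, grad

    def log_jacobian(self, q: np.ndarray) -> float:
        """Log-determinant of the unconstrained->constrained transform.

        logpost_and_grad(q) equals log_prior(state) + joint_loglik(state)
        + this quantity; the identity is exercised in the tests.
        """
        pk = self.packing
        t, pi, A, B, C, phi, b0, b1 = pk.unpack(q)
        jac = float(np.sum(np.log(t) + np.log1p(-t)))
        if self.K > 1:
            jac += float(np.log(pi).sum())
        for row, j in enumerate(pk.sw_genes):
            k = int(np.flatnonzero(pk.switch_mask[j])[0])
            jac += np.log(A[j, k])
            if pk.tau_positive:
                jac += np.log(B[j, k])
            t0 = C[j, k]
            jac += np.log(t0) + np.log1p(-t0)
        for row, j in enumerate(pk.pu_genes):
            k = int(np.flatnonzero(~pk.switch_mask[j])[0])
            jac += np.log(A[j, k]) + np.log(B[j, k])
            t0 = C[j, k]
            jac += np.log(t0) + np.log1p(-t0)
        jac += float(q[pk.sl_phi].sum())
        return jac

    def gibbs_refresh_t(self, q: np.ndarray, rng: np.random.Generator,
                        n_grid: int = 100) -> np.ndarray:
        """Metropolis-within-Gibbs refresh of all pseudotimes.

        Given the curve parameters, cells are conditionally independent, so
        each t_i can be proposed from its (gridded) conditional posterior
        and accepted with a Metropolis correction for the discretization.
        This jumps directly between the modes of multimodal per-cell
        pseudotime conditionals that leapfrog dynamics cross only rarely.
        """
        from ._kernel import cell_logliks_at, cell_logliks_grid

        pk = self.packing
        t, pi, A, B, C, phi, b0, b1 = pk.unpack(q)
        with np.errstate(divide="ignore"):
            logpi = np.log(pi)
        edges = np.linspace(0.0, 1.0, n_grid + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        args = (self.Y, self._zero, logpi, A, B, C, pk.switch_mask, phi,
                float(b0), float(b1), EPSILON)
        Wg = cell_logliks_grid(self.Y, self._zero, mids, *args[2:])
        logw = Wg - logsumexp(Wg, axis=1, keepdims=True)
        w = np.exp(logw)
        cdf = np.cumsum(w, axis=1)
        u = rng.uniform(size=pk.N)
        bins = np.minimum((u[:, None] > cdf).sum(axis=1), n_grid - 1)
        width = 1.0 / n_grid
        t_prop = np.clip(edges[bins] + rng.uniform(size=pk.N) * width, 1e-9, 1 - 1e-9)
        lp_prop = cell_logliks_at(self.Y, self._zero, t_prop, *args[2:])
        lp_cur = cell_logliks_at(self.Y, self._zero, t, *args[2:])
        bins_cur = np.clip((t * n_grid).astype(int), 0, n_grid - 1)
        rows = np.arange(pk.N)
        log_alpha = (lp_prop - lp_cur) + (logw[rows, bins_cur] - logw[rows, bins])
        accept = np.log(rng.uniform(size=pk.N)) < log_alpha
        if not accept.any():
            return q
        t_new = np.where(accept, t_prop, np.clip(t, 1e-9, 1 - 1e-9))
        q2 = q.copy()
        q2[pk.sl_t] = np.log(t_new) - np.log1p(-t_new)
        return q2

    def _draw_triple_prior(self, amp_tab, shp_tab, t0_tab, row, shp_exp,
                           rng: np.random.Generator) -> np.ndarray:
        def trunc(mean, sd):
            for _ in range(100):
                x = rng.normal(mean, sd)
                if x > 1e-4:
                    return x
            return max(mean, 1e-2)

        m_, s_ = amp_tab[row]
        m2, s2_ = shp_tab[row]
        a_, b_ = t0_tab[row]
        amp = trunc(m_, s_)
        shp = trunc(m2, s2_) if shp_exp else rng.normal(m2, s2_)
        t0 = np.clip(rng.beta(a_, b_), 1e-6, 1 - 1e-6)
        return np.array([np.log(amp), np.log(shp) if shp_exp else shp,
                         np.log(t0) - np.log1p(-t0)])

    def gibbs_refresh_genes(self, q: np.ndarray, rng: np.random.Generator,
                            width: float = 0.6) -> np.ndarray:
        """Slice-sampling sweep over per-gene curve parameter triples.

        Conditional on everything else, one gene's parameters enter the
        likelihood only through that gene's (N, K) entry matrix, so its
        full conditional is cheap to evaluate by caching the other genes'
        contributions.  Each unconstrained coordinate of each role triple
        is updated by univariate slice sampling (stepping-out/shrinkage),
        which decorrelates the weakly identified pulse blocks far faster
        than leapfrog dynamics alone.
        """
        from ._kernel import gene_entries, mixture_loglik_from_sums

        pk = self.packing
        q = q.copy()
        t, pi, A, B, C, phi, b0, b1 = pk.unpack(q)
        with np.errstate(divide="ignore"):
            logpi = np.log(pi)
        A = A.copy(); B = B.copy(); C = C.copy()
        sw_mask = pk.switch_mask

        def entries(j):
            return gene_entries(self.Y, self._zero, t, j, A[j], B[j], C[j],
                                sw_mask[j], phi[j], float(b0), float(b1), EPSILON)

        E = [entries(j) for j in range(pk.G)]
        Sent = np.sum(E, axis=0) if pk.G else np.zeros((pk.N, pk.K))

        def slice_1d(logf, x0, f0):
            y = f0 + np.log(rng.uniform())
            lo = x0 - width * rng.uniform()
            hi = lo + width
            j_lo = int(rng.integers(0, 8))
            j_hi = 7 - j_lo
            while j_lo > 0 and logf(lo) > y:
                lo -= width
                j_lo -= 1
            while j_hi > 0 and logf(hi) > y:
                hi += width
                j_hi -= 1
            while True:
                x1 = rng.uniform(lo, hi)
                f1 = logf(x1)
                if f1 > y:
                    return x1, f1
                if x1 < x0:
                    lo = x1
                else:
                    hi = x1

        def triple_prior(v, amp_tab, shp_tab, t0_tab, row, shp_exp):
            amp = np.exp(v[0])
            m_, s_ = amp_tab[row]
            lp = -(amp - m_) ** 2 / (2 * s_**2) + v[0]
            m2, s2_ = shp_tab[row]
            if shp_exp:
                shp = np.exp(v[1])
                lp += -(shp - m2) ** 2 / (2 * s2_**2) + v[1]
            else:
                lp += -(v[1] - m2) ** 2 / (2 * s2_**2)
            a_, b_ = t0_tab[row]
            t0 = expit(v[2])
            lp += a_ * np.log(t0) + b_ * np.log1p(-t0)
            return lp

        for role, rows_list, sl, amp_tab, shp_tab, t0_tab, shp_exp in (
            ("sw", pk.sw_genes, pk.sl_sw, self._sw_amp, self._sw_shp, self._sw_t0,
             pk.tau_positive),
            ("pu", pk.pu_genes, pk.sl_pu, self._pu_amp, self._pu_shp, self._pu_t0, True),
        ):
            if not len(rows_list):
                continue
            triples = q[sl].reshape(-1, 3)
            for row, j in enumerate(rows_list):
                cols = sw_mask[j] if role == "sw" else ~sw_mask[j]
                Sent -= E[j]
                v = triples[row].copy()

                def apply(vv):
                    A[j, cols] = np.exp(vv[0])
                    B[j, cols] = np.exp(vv[1]) if shp_exp else vv[1]
                    C[j, cols] = expit(vv[2])

                def logf_full(vv):
                    apply(vv)
                    Ej = entries(j)
                    return (mixture_loglik_from_sums(Sent + Ej, logpi)
                            + triple_prior(vv, amp_tab, shp_tab, t0_tab, row, shp_exp))

                f0 = logf_full(v)
                for c in range(3):
                    def logf_c(x, c=c):
                        vv = v.copy()
                        vv[c] = x
                        return logf_full(vv)

                    v[c], f0 = slice_1d(logf_c, v[c], f0)
                if role == "pu":
                    # independence jump from the prior: weakly identified
                    # pulse blocks regenerate wholesale (prior cancels, so
                    # the acceptance ratio is the marginal-likelihood ratio)
                    v_try = self._draw_triple_prior(amp_tab, shp_tab, t0_tab,
                                                    row, shp_exp, rng)
                    f_try = logf_full(v_try)
                    lik_try = f_try - triple_prior(v_try, amp_tab, shp_tab,
                                                   t0_tab, row, shp_exp)
                    lik_cur = f0 - triple_prior(v, amp_tab, shp_tab,
                                                t0_tab, row, shp_exp)
                    if np.log(rng.uniform()) < lik_try - lik_cur:
                        v, f0 = v_try, f_try
                apply(v)
                E[j] = entries(j)
                Sent += E[j]
                triples[row] = v
            q[sl] = triples.ravel()
        return q

    def gibbs_refresh_pi(self, q: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Conjugate refresh of lineage proportions via explicit assignments.

        Draw z_i from its current posterior, then pi | z from the conjugate
        Dirichlet, and discard z — the classic mixture-model Gibbs block,
        which moves pi jointly with the assignments it reflects.
        """
        pk = self.packing
        if pk.K == 1:
            return q
        wk = self.branch_posterior(q)
        u = rng.uniform(size=pk.N)
        z = (u[:, None] > np.cumsum(wk, axis=1)).sum(axis=1)
        counts = np.bincount(z, minlength=pk.K)
        pi_new = rng.dirichlet(self._conc + counts)
        pi_new = np.clip(pi_new, 1e-12, None)
        q2 = q.copy()
        q2[pk.sl_pi] = np.log(pi_new[:-1]) - np.log(pi_new[-1])
        return q2

    def collapsed_gene_jump(self, q: np.ndarray, rng: np.random.Generator,
                            n_genes: int = 2, step: float = 0.4,
                            n_grid: int = 100) -> np.ndarray:
        """Joint jump of one gene's curve triple and all pseudotimes.

        Pulse (and switch) parameters ride narrow posterior ridges with the
        pseudotimes of ambiguous cells: moving either alone is blocked.
        This move perturbs one gene's unconstrained triple by a random walk
        and re-draws every t_i from its gridded conditional under the
        perturbed parameters; the Metropolis ratio for the joint proposal
        only needs the grid weights of forward and reverse draws, so the
        whole ridge is traversed in a single accepted step.
        """
        from ._kernel import cell_logliks_at, cell_logliks_grid

        pk = self.packing
        q = q.copy()
        edges = np.linspace(0.0, 1.0, n_grid + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        rows = np.arange(pk.N)
        width = 1.0 / n_grid

        # all role triples as (role, row, gene)
        pool = ([("sw", r, j) for r, j in enumerate(pk.sw_genes)]
                + [("pu", r, j) for r, j in enumerate(pk.pu_genes)])
        if not pool:
            return q
        picks = [pool[i] for i in rng.choice(len(pool), size=min(n_genes, len(pool)),
                                             replace=False)]

        def unpack_aux(qq):
            t, pi, A, B, C, phi, b0, b1 = pk.unpack(qq)
            with np.errstate(divide="ignore"):
                logpi = np.log(pi)
            return t, logpi, (A, B, C, pk.switch_mask, phi, float(b0), float(b1), EPSILON)

        def prior_of(qq, role, row):
            sl = pk.sl_sw if role == "sw" else pk.sl_pu
            v = qq[sl].reshape(-1, 3)[row]
            if role == "sw":
                amp_tab, shp_tab, t0_tab = self._sw_amp, self._sw_shp, self._sw_t0
                shp_exp = pk.tau_positive
            else:
                amp_tab, shp_tab, t0_tab = self._pu_amp, self._pu_shp, self._pu_t0
                shp_exp = True
            amp = np.exp(v[0])
            m_, s_ = amp_tab[row]
            lp = -(amp - m_) ** 2 / (2 * s_**2) + v[0]
            m2, s2_ = shp_tab[row]
            if shp_exp:
                shp = np.exp(v[1])
                lp += -(shp - m2) ** 2 / (2 * s2_**2) + v[1]
            else:
                lp += -(v[1] - m2) ** 2 / (2 * s2_**2)
            a_, b_ = t0_tab[row]
            t0 = expit(v[2])
            lp += a_ * np.log(t0) + b_ * np.log1p(-t0)
            return lp

        t, logpi, aux = unpack_aux(q)
        Wg = cell_logliks_grid(self.Y, self._zero, mids, logpi, *aux[:5],
                               aux[5], aux[6], aux[7])
        logw = Wg - logsumexp(Wg, axis=1, keepdims=True)
        lik_cur = float(cell_logliks_at(self.Y, self._zero, t, logpi, *aux[:5],
                                        aux[5], aux[6], aux[7]).sum())
        for role, row, j in picks:
            sl = pk.sl_sw if role == "sw" else pk.sl_pu
            q_prop = q.copy()
            triples = q_prop[sl].reshape(-1, 3)
            triples[row] = triples[row] + rng.normal(0.0, step, 3)
            q_prop[sl] = triples.ravel()
            t_cur, _, _ = unpack_aux(q)
            _, logpi_p, aux_p = unpack_aux(q_prop)
            Wg_p = cell_logliks_grid(self.Y, self._zero, mids, logpi_p, *aux_p[:5],
                                     aux_p[5], aux_p[6], aux_p[7])
            logw_p = Wg_p - logsumexp(Wg_p, axis=1, keepdims=True)
            w_p = np.exp(logw_p)
            cdf = np.cumsum(w_p, axis=1)
            u = rng.uniform(size=pk.N)
            bins_p = np.minimum((u[:, None] > cdf).sum(axis=1), n_grid - 1)
            t_prop = np.clip(edges[bins_p] + rng.uniform(size=pk.N) * width,
                             1e-9, 1 - 1e-9)
            lik_prop = float(cell_logliks_at(self.Y, self._zero, t_prop, logpi_p,
                                             *aux_p[:5], aux_p[5], aux_p[6],
                                             aux_p[7]).sum())
            bins_cur = np.clip((t_cur * n_grid).astype(int), 0, n_grid - 1)
            log_alpha = (lik_prop + prior_of(q_prop, role, row)
                         + float(logw[rows, bins_cur].sum())
                         - lik_cur - prior_of(q, role, row)
                         - float(logw_p[rows, bins_p].sum()))
            if np.log(rng.uniform()) < log_alpha:
                q = q_prop
                q[pk.sl_t] = np.log(t_prop) - np.log1p(-t_prop)
                t = t_prop
                Wg, logw = Wg_p, logw_p
                lik_cur = lik_prop
        return q

    # -- initialization ------------------------------------------------------

    def _initial_point(self, cfg: SamplerConfig, rng: np.random.Generator,
                       custom: ModelState | None = None) -> np.ndarray:
        pk = self.packing
        if cfg.init == "custom":
            if custom is None:
                raise ValidationError("init='custom' requires an initial ModelState")
            return pk.pack_state(custom)
        q = np.zeros(pk.dim)
        q[pk.sl_t] = rng.normal(0.0, 1.0, self.N)  # logit of roughly U(0,1)
        if self.K > 1:
            q[pk.sl_pi] = rng.normal(0.0, 0.3, self.K - 1)
        pr = self.priors

        def draw_trunc(mean, sd):
            for _ in range(100):
                v = rng.normal(mean, sd)
                if v > 1e-3:
                    return v
            return max(mean, 1e-2)

        def draw_logit_t0(gid):
            bt = pr.t0_prior(gid)
            t0 = np.clip(rng.beta(bt.a, bt.b), 1e-6, 1 - 1e-6)
            return np.log(t0) - np.log1p(-t0)

        ids = self.gene_ids
        sw = []
        for j in pk.sw_genes:
            pd_, pt = pr.gene_prior("delta", ids[j]), pr.gene_prior("tau", ids[j])
            tau0 = draw_trunc(pt.mean, pt.sd) if pk.tau_positive else rng.normal(pt.mean, pt.sd)
            sw += [np.log(draw_trunc(pd_.mean, pd_.sd)),
                   np.log(tau0) if pk.tau_positive else tau0,
                   draw_logit_t0(ids[j])]
        q[pk.sl_sw] = sw
        pu = []
        for j in pk.pu_genes:
            pe, pz = pr.gene_prior("eta", ids[j]), pr.gene_prior("zeta", ids[j])
            pu += [np.log(draw_trunc(pe.mean, pe.sd)), np.log(draw_trunc(pz.mean, pz.sd)),
                   draw_logit_t0(ids[j])]
        q[pk.sl_pu] = pu
        q[pk.sl_phi] = np.log(rng.gamma(pr.phi.shape, 1.0 / pr.phi.rate, self.G) + 1e-6)
        q[pk.sl_beta] = rng.normal(pr.beta.mean, pr.beta.sd, 2)
        if cfg.init == "map":
            q = self._map_polish(q)
            q = q + rng.normal(0.0, 0.05, pk.dim)
        return q

    def _map_polish(self, q0: np.ndarray, maxiter: int = 500) -> np.ndarray:
        from scipy.optimize import minimize

        def fun(q):
            lp, g = self.logpost_and_grad(q)
            return -lp, -g

        res = minimize(fun, q0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        return res.x

    def _smart_init(self, rng: np.random.Generator, n_rounds: int = 3) -> np.ndarray:
        """Mode-seeking initialization.

        Pseudotimes start from each cell's overall marker-activation rank
        (markers accumulate along differentiation, the model's premise),
        which anchors the trajectory basin of the posterior: the rival
        basin, where pseudotime trades against branch identity, is thereby
        avoided.  A few block-coordinate rounds (curve parameters by
        L-BFGS given t; per-cell t by grid argmax given parameters) then a
        full polish land on the mode.
        """
        from scipy.optimize import minimize
        from scipy.special import log_expit as _lexp

        pk = self.packing
        act = self.Y.mean(axis=1)
        r = act.argsort().argsort() / max(len(act) - 1, 1)
        t = 0.02 + 0.96 * r
        q = self._initial_point(SamplerConfig(init="prior"), rng)
        q[pk.sl_t] = np.log(t) - np.log1p(-t)
        free = np.ones(pk.dim, dtype=bool)
        free[pk.sl_t] = False
        tg = np.linspace(0.005, 0.995, 120)
        for _ in range(n_rounds):
            def fun(sub):
                qq = q.copy()
                qq[free] = sub
                lp, g = self.logpost_and_grad(qq)
                return -lp, -g[free]

            res = minimize(fun, q[free], jac=True, method="L-BFGS-B",
                           options={"maxiter": 300})
            q[free] = res.x
            st = pk.to_state(q)
            mu = st.dynamics.mean(tg)  # (grid, G, K)
            s2 = (1.0 + st.noise.phi[None, :, None]) * mu + EPSILON
            x = st.noise.beta0 + st.noise.beta1 * mu
            lpd, l1m = _lexp(x), _lexp(-x)
            logn_c = -0.5 * np.log(2.0 * np.pi * s2)
            with np.errstate(divide="ignore"):
                logpi = np.log(st.pi)
            best = np.empty(pk.N)
            for i in range(pk.N):
                y = self.Y[i]
                logn = logn_c - (y[None, :, None] - mu) ** 2 / (2.0 * s2)
                lf = np.where((y == 0)[None, :, None],
                              np.logaddexp(lpd, l1m + logn), l1m + logn)
                cell = logsumexp(logpi[None, :] + lf.sum(axis=1), axis=1)
                best[i] = tg[np.argmax(cell)]
            q[pk.sl_t] = np.log(best) - np.log1p(-best)
        return self._map_polish(q, maxiter=1000)

    # -- fitting -------------------------------------------------------------

    def fit(self, cfg: SamplerConfig | None = None,
            initial_state: ModelState | None = None):
        """Run NUTS and return a :class:`~branchtime.results.TrajectoryResults`."""
        from .results import TrajectoryResults

        cfg = cfg if cfg is not None else SamplerConfig()
        q_base = None
        if cfg.init == "map":
            q_base = self._smart_init(np.random.default_rng((cfg.seed, 977)))
        chains = []
        for c in range(cfg.n_chains):
            rng = np.random.default_rng((cfg.seed, c))
            if q_base is not None:
                q0 = q_base + rng.normal(0.0, 0.05, self.packing.dim)
            else:
                q0 = self._initial_point(cfg, rng, initial_state)
            lp0, _ = self.logpost_and_grad(q0)
            tries = 0
            while not np.isfinite(lp0) and tries < 20:
                if q_base is not None:
                    q0 = q_base + rng.normal(0.0, 0.02, self.packing.dim)
                else:
                    q0 = self._initial_point(cfg, rng, initial_state)
                lp0, _ = self.logpost_and_grad(q0)
                tries += 1
            if not np.isfinite(lp0):
                raise ValidationError("could not find a finite initial point")
            def refresh(qq, r):
                for _ in range(cfg.gibbs_rounds):
                    qq = self.gibbs_refresh_t(qq, r)
                    qq = self.gibbs_refresh_pi(qq, r)
                    qq = self.gibbs_refresh_genes(qq, r)
                if cfg.gibbs_rounds:
                    qq = self.collapsed_gene_jump(qq, r, n_genes=3, step=0.35,
                                                  n_grid=60)
                return qq

            interleave = refresh if (self.use_numba and cfg.gibbs_rounds) else None
            pk = self.packing
            if cfg.nuts_block == "non_t" and interleave is not None:
                active = np.arange(pk.sl_t.stop, pk.dim)
            else:
                active = None
            chains.append(
                sample_nuts(self.logpost_and_grad, q0, cfg.n_iter, cfg.n_warmup,
                            rng, cfg.target_accept, cfg.max_treedepth,
                            interleave=interleave, active_idx=active)
            )
        return TrajectoryResults(self, cfg, chains)
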