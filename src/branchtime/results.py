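"""Posterior results: diagnostics, summaries, branch probabilities.

Convergence follows the usual MCMC criteria: split R-hat below 1.05 and
effective sample size above 200 for every scalar parameter.  Continuous
scalars are summarized by their posterior mode, estimated with the
half-sample mode on pooled draws; per-cell branch probabilities are
likewise summarized by the per-component posterior mode across draws and
renormalized (the posterior-mean summary remains available and is better
calibrated but flatter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ValidationError
from .dynamics import ModelState

PROGENITOR = 0  # sentinel branch label for uncommitted cells

RHAT_LIMIT = 1.05
ESS_FLOOR = 200.0
MAX_DIVERGENT_FRACTION = 0.10


class ConvergenceWarning(UserWarning):
    pass


def half_sample_mode(x: np.ndarray) -> float:
    """Robertson-Cryer half-sample mode of a 1-D sample."""
    x = np.sort(np.asarray(x, dtype=float).ravel())
    while x.size > 3:
        half = (x.size + 1) // 2
        widths = x[half - 1:] - x[: x.size - half + 1]
        i = int(np.argmin(widths))
        x = x[i: i + half]
    if x.size == 3:
        return float((x[0] + x[1]) / 2) if (x[1] - x[0]) < (x[2] - x[1]) else (
            float((x[1] + x[2]) / 2) if (x[2] - x[1]) < (x[1] - x[0]) else float(x[1]))
    return float(x.mean())


def _scalar_views(draws: dict[str, np.ndarray]):
    """Yield (name, (chain, draw) array) for every scalar parameter."""
    for name, arr in draws.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            yield name, arr
        else:
            flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for idx in range(flat.shape[2]):
                yield f"{name}[{idx}]", flat[:, :, idx]


def diagnostics(draws: dict[str, np.ndarray]):
    """Split R-hat and bulk ESS per scalar parameter.

    ``draws`` maps parameter name to a (chain, draw, ...) array.  Returns
    (rhat, ess, converged): dicts of per-scalar values and the overall flag
    (every R-hat < 1.05 and every ESS > 200).  With a single chain R-hat is
    unavailable (NaN) and the fit cannot be declared converged.
    """
    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    single_chain = False
    for name, arr in _scalar_views(draws):
        if arr.shape[0] < 2:
            single_chain = True
            rhat[name] = float("nan")
        else:
            rhat[name] = float(az.rhat(arr))
        ess[name] = float(az.ess(arr))
    if not rhat:
        return rhat, ess, False
    rh = np.array(list(rhat.values()))
    es = np.array(list(ess.values()))
    converged = (not single_chain) and bool(np.all(rh < RHAT_LIMIT) and np.all(es > ESS_FLOOR))
    return rhat, ess, converged


def classify_cells(branch_prob: np.ndarray, threshold: float = 0.7):
    """Threshold the branch-probability matrix into hard assignments.

    Cells whose maximum branch probability falls below ``threshold`` are
    labeled progenitors (sentinel 0); ties break to the lowest branch
    index.  ``threshold`` must exceed 1/K, otherwise every cell would be
    assigned and the progenitor notion is vacuous.
    """
    bp = np.asarray(branch_prob, dtype=float)
    if bp.ndim != 2:
        raise ValidationError("branch_prob must be an N x K matrix")
    K = bp.shape[1]
    if not (1.0 / K < threshold <= 1.0):
        raise ValidationError(f"threshold must lie in (1/{K}, 1]")
    if np.any(np.abs(bp.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("branch probability rows must sum to 1")
    p_max = bp.max(axis=1)
    assigned = np.argmax(bp, axis=1) + 1  # argmax takes the first (lowest) index on ties
    assigned = np.where(p_max >= threshold, assigned, PROGENITOR)
    return CellClassification(assigned, p_max, float(threshold))


@dataclass(frozen=True)
class CellClassification:
    assigned_branch: np.ndarray  # 1-based; 0 = progenitor
    p_max: np.ndarray
    threshold: float

    @property
    def is_progenitor(self) -> np.ndarray:
        return self.assigned_branch == PROGENITOR


class TrajectoryResults:
    """Posterior draws, diagnostics and point summaries of a fit."""

    def __init__(self, model, config, chains):
        self.model = model
        self.config = config
        self.chains = chains
        self._q = np.stack([c.draws for c in chains])  # (chains, kept, dim)
        self._draws_cache: dict[str, np.ndarray] | None = None
        self._diag_cache = None
        self._branch_prob: np.ndarray | None = None
        self._bp_draws: np.ndarray | None = None
        self._point: ModelState | None = None
        frac = self.divergent_fraction
        _, _, conv = self.diagnostics()
        if frac > MAX_DIVERGENT_FRACTION:
            warnings.warn(
                f"{frac:.1%} divergent transitions (limit {MAX_DIVERGENT_FRACTION:.0%}); "
                "posterior geometry is suspect", ConvergenceWarning)
        if not conv:
            warnings.warn(
                "sampler did not meet the convergence criteria "
                f"(all R-hat < {RHAT_LIMIT}, all ESS > {ESS_FLOOR:.0f})",
                ConvergenceWarning)

    # -- raw draws ----------------------------------------------------------

    @property
    def n_chains(self) -> int:
        return self._q.shape[0]

    @property
    def n_draws(self) -> int:
        """Post-warmup draws per chain."""
        return self._q.shape[1]

    @property
    def divergent_fraction(self) -> float:
        return float(np.mean([c.divergent.mean() for c in self.chains]))

    @property
    def draws(self) -> dict[str, np.ndarray]:
        """Constrained-scale draws keyed by parameter name, (chain, draw, ...)."""
        if self._draws_cache is not None:
            return self._draws_cache
        pk = self.model.packing
        C, D = self._q.shape[:2]
        out = {
            "t": np.empty((C, D, pk.N)),
            "phi": np.empty((C, D, pk.G)),
            "beta0": np.empty((C, D)),
            "beta1": np.empty((C, D)),
        }
        if pk.K > 1:
            out["pi"] = np.empty((C, D, pk.K))
        ns, npu = len(pk.sw_genes), len(pk.pu_genes)
        if ns:
            out["delta"] = np.empty((C, D, ns))
            out["tau"] = np.empty((C, D, ns))
            out["t0_switch"] = np.empty((C, D, ns))
        if npu:
            out["eta"] = np.empty((C, D, npu))
            out["zeta"] = np.empty((C, D, npu))
            out["t0_pulse"] = np.empty((C, D, npu))
        for c in range(C):
            for d in range(D):
                t, pi, A, B, Ct0, phi, b0, b1 = pk.unpack(self._q[c, d])
                out["t"][c, d] = t
                out["phi"][c, d] = phi
                out["beta0"][c, d] = b0
                out["beta1"][c, d] = b1
                if pk.K > 1:
                    out["pi"][c, d] = pi
                if ns:
                    cols = [np.flatnonzero(pk.switch_mask[j])[0] for j in pk.sw_genes]
                    out["delta"][c, d] = A[pk.sw_genes, cols]
                    out["tau"][c, d] = B[pk.sw_genes, cols]
                    out["t0_switch"][c, d] = Ct0[pk.sw_genes, cols]
                if npu:
                    cols = [np.flatnonzero(~pk.switch_mask[j])[0] for j in pk.pu_genes]
                    out["eta"][c, d] = A[pk.pu_genes, cols]
                    out["zeta"][c, d] = B[pk.pu_genes, cols]
                    out["t0_pulse"][c, d] = Ct0[pk.pu_genes, cols]
        self._draws_cache = out
        return out

    # -- diagnostics ---------------------------------------------------------

    def diagnostics(self):
        if self._diag_cache is None:
            self._diag_cache = diagnostics(self.draws)
        return self._diag_cache

    @property
    def rhat(self) -> dict[str, float]:
        return self.diagnostics()[0]

    @property
    def ess(self) -> dict[str, float]:
        return self.diagnostics()[1]

    @property
    def converged(self) -> bool:
        _, _, conv = self.diagnostics()
        return conv and self.divergent_fraction <= MAX_DIVERGENT_FRACTION

    # -- branch probabilities -------------------------------------------------

    def branch_prob_draws(self) -> np.ndarray:
        """(draws, N, K) per-draw branch probabilities, pooled over chains."""
        if self._bp_draws is None:
            pk = self.model.packing
            out = np.empty((self.n_chains * self.n_draws, pk.N, pk.K))
            i = 0
            for c in range(self.n_chains):
                for d in range(self.n_draws):
                    out[i] = self.model.branch_posterior(self._q[c, d])
                    i += 1
            self._bp_draws = out
        return self._bp_draws

    def branch_probabilities(self, summary: str = "mode") -> np.ndarray:
        """(N, K) per-cell branch probabilities summarized over draws.

        ``summary="mode"`` takes the half-sample mode of each component
        across pooled draws and renormalizes — the posterior-mode summary.
        ``summary="mean"`` is the posterior-mean (Rao-Blackwellized)
        alternative; it is better calibrated but flatter, since draws with
        transiently uncertain parameters pull every cell toward 1/K.
        """
        bp = self.branch_prob_draws()
        if summary == "mean":
            acc = bp.mean(axis=0)
        elif summary == "mode":
            n, N, K = bp.shape
            acc = np.empty((N, K))
            for i in range(N):
                for k in range(K):
                    acc[i, k] = half_sample_mode(bp[:, i, k])
            acc = np.clip(acc, 0.0, None)
        else:
            raise ValidationError(f"unknown summary {summary!r}")
        acc = acc / acc.sum(axis=1, keepdims=True)
        return acc

    @property
    def branch_prob(self) -> np.ndarray:
        """(N, K) posterior-mode branch probabilities (renormalized)."""
        if self._branch_prob is None:
            self._branch_prob = self.branch_probabilities("mode")
        return self._branch_prob

    def classify(self, threshold: float = 0.7) -> CellClassification:
        return classify_cells(self.branch_prob, threshold)

    # -- point summaries -------------------------------------------------------

    @property
    def point(self) -> ModelState:
        """Posterior-mode ModelState (half-sample mode per scalar)."""
        if self._point is not None:
            return self._point
        pk = self.model.packing
        dr = self.draws

        def hsm_vec(arr):  # (C, D, m) -> (m,)
            flat = arr.reshape(-1, arr.shape[-1])
            return np.array([half_sample_mode(flat[:, i]) for i in range(flat.shape[1])])

        t = np.clip(hsm_vec(dr["t"]), 0.0, 1.0)
        if pk.K > 1:
            pi = np.clip(hsm_vec(dr["pi"]), 1e-12, None)
            pi = pi / pi.sum()
        else:
            pi = np.ones(1)
        A = np.zeros((pk.G, pk.K))
        B = np.zeros((pk.G, pk.K))
        Ct0 = np.full((pk.G, pk.K), 0.5)
        if len(pk.sw_genes):
            dv, tv, cv = hsm_vec(dr["delta"]), hsm_vec(dr["tau"]), hsm_vec(dr["t0_switch"])
            for row, j in enumerate(pk.sw_genes):
                cols = pk.switch_mask[j]
                A[j, cols], B[j, cols], Ct0[j, cols] = dv[row], tv[row], np.clip(cv[row], 0, 1)
        if len(pk.pu_genes):
            ev, zv, cv = hsm_vec(dr["eta"]), hsm_vec(dr["zeta"]), hsm_vec(dr["t0_pulse"])
            for row, j in enumerate(pk.pu_genes):
                cols = ~pk.switch_mask[j]
                A[j, cols], B[j, cols], Ct0[j, cols] = ev[row], zv[row], np.clip(cv[row], 0, 1)
        phi = np.clip(hsm_vec(dr["phi"]), 0.0, None)
        b0 = half_sample_mode(dr["beta0"])
        b1 = half_sample_mode(dr["beta1"])
        from .dynamics import GeneDynamics, NoiseModel

        self._point = ModelState(t, pi, GeneDynamics(pk.switch_mask, A, B, Ct0),
                                 NoiseModel(phi, b0, b1))
        return self._point

    @property
    def pseudotime(self) -> np.ndarray:
        """Per-cell posterior-mean pseudotime.

        Per-cell pseudotime posteriors can be bimodal (branch-ambiguous
        cells); the mean orders cells stably where a mode estimator would
        discard the minor mode.  The half-sample-mode summary remains
        available as ``point.T``.
        """
        return self.draws["t"].mean(axis=(0, 1))

    # -- reporting -----------------------------------------------------------

    def summary(self, include_cells: bool = False) -> pd.DataFrame:
        """Posterior summary table: mode, mean, sd, R-hat, ESS per scalar."""
        rhat, ess, _ = self.diagnostics()
        rows = []
        for name, arr in _scalar_views(self.draws):
            if not include_cells and name.startswith("t["):
                continue
            pooled = arr.ravel()
            rows.append({
                "parameter": name,
                "mode": half_sample_mode(pooled),
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=1)),
                "rhat": rhat.get(name, float("nan")),
                "ess": ess.get(name, float("nan")),
            })
        df = pd.DataFrame(rows).set_index("parameter")
        df.attrs["converged"] = self.converged
        df.attrs["divergent_fraction"] = self.divergent_fraction
        return df

    def pseudotime_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.model.cell_ids,
                             "pseudotime": self.pseudotime}).set_index("cell_id")

    def branch_frame(self, threshold: float = 0.7) -> pd.DataFrame:
        cls = self.classify(threshold)
        bp = self.branch_prob
        names = self.model.panel.branch_names
        df = pd.DataFrame(bp, index=pd.Index(self.model.cell_ids, name="cell_id"),
                          columns=[f"p_{b}" for b in names])
        df["p_max"] = cls.p_max
        df["assignment"] = [
            names[a - 1] if a != PROGENITOR else "progenitor" for a in cls.assigned_branch
        ]
        return df
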