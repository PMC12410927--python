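"""Forward simulation of the branching generative process.

The simulator draws ground-truth pseudotimes and lineage assignments, then
samples marker-gene expression from the model itself: parametric means,
mean-dependent Gaussian noise (clipped at zero, since normalized expression
is non-negative), and expression-dependent dropout.  The global dropout
intercept beta0 is calibrated by bisection so the expected dropout fraction
matches a requested target; the slope beta1 = -5 encodes "highly expressed
genes drop out less".

Defaults emulate a K-branch differentiation benchmark: per-branch
switch-like markers with activation times staggered along the trajectory
and weak, narrow off-branch pulses (leaky transient expression on the
lineages a gene does not mark).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import ExpressionMatrix, MarkerPanel, PriorSpec, ValidationError
from .dynamics import EPSILON, GeneDynamics, ModelState, NoiseModel

# Benchmark generating conditions (per-branch marker behaviour).
DEFAULT_DELTA = 0.5    # switch amplitude: 2*delta spans the [0,1] scale
DEFAULT_TAU = 20.0     # switch steepness on the unit pseudotime axis
SWITCH_T0_RANGE = (0.05, 0.75)  # staggered activation times per branch
DEFAULT_ETA = 0.1      # weak off-branch pulse (peak 2*eta = 0.2)
DEFAULT_ZETA = 60.0    # narrow pulse (sd ~ 0.09)
PULSE_T0_RANGE = (0.2, 0.8)
DEFAULT_PHI = 0.05
DEFAULT_BETA1 = -5.0


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated expression with full ground truth."""

    expression: ExpressionMatrix
    true_time: np.ndarray
    true_branch: np.ndarray  # 1-based labels
    dropout_mask: np.ndarray
    generating_state: ModelState
    panel: MarkerPanel
    seed: int

    @property
    def n_cells(self) -> int:
        return self.expression.n_cells


def default_panel(
    n_branches: int = 3, markers_per_branch: int = 4, branch_names: list[str] | None = None
) -> MarkerPanel:
    """A benchmark panel: ``markers_per_branch`` exclusive markers per branch."""
    if branch_names is None:
        branch_names = [f"branch{k + 1}" for k in range(n_branches)]
    marker_map = {
        f"g{k + 1}_{m + 1}": frozenset({k + 1})
        for k in range(n_branches)
        for m in range(markers_per_branch)
    }
    return MarkerPanel(n_branches, branch_names, marker_map)


def _staggered(lo: float, hi: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([(lo + hi) / 2.0])
    return np.linspace(lo, hi, n)


def benchmark_state(
    panel: MarkerPanel,
    n_cells: int,
    rng: np.random.Generator,
    *,
    delta: float = DEFAULT_DELTA,
    tau: float = DEFAULT_TAU,
    eta: float = DEFAULT_ETA,
    zeta: float = DEFAULT_ZETA,
    phi: float = DEFAULT_PHI,
    pi: np.ndarray | None = None,
) -> ModelState:
    """The canonical generating state for the simulated benchmark.

    Switch activation times are staggered evenly along each branch's marker
    list; pulse midpoints are staggered per gene so off-branch dynamics also
    carry temporal information.  beta0 is left at 0 here and calibrated by
    :func:`simulate` to the requested dropout rate.
    """
    gene_ids = panel.gene_ids
    G, K = len(gene_ids), panel.K
    switch = panel.switch_mask(gene_ids)
    amplitude = np.where(switch, delta, eta)
    shape = np.where(switch, tau, zeta)
    t0 = np.empty((G, K))
    for k in range(1, K + 1):
        members = [gene_ids.index(g) for g in panel.markers_of(k)]
        for j, v in zip(members, _staggered(*SWITCH_T0_RANGE, len(members))):
            t0[j, k - 1] = v
    pulse_t0 = _staggered(*PULSE_T0_RANGE, G)
    for j in range(G):
        t0[j, ~switch[j]] = pulse_t0[j]
    # a gene marking several branches keeps one activation time; the loop
    # above already wrote each marked column, possibly differing per branch,
    # so tie them to the first marked column for consistency with the model
    for j in range(G):
        cols = np.flatnonzero(switch[j])
        if cols.size > 1:
            t0[j, cols] = t0[j, cols[0]]
    dyn = GeneDynamics(switch, amplitude, shape, t0)
    if pi is None:
        pi = np.full(K, 1.0 / K)
    T = rng.uniform(0.0, 1.0, n_cells)
    noise = NoiseModel(np.full(G, phi), 0.0, DEFAULT_BETA1)
    return ModelState(T, np.asarray(pi, dtype=float), dyn, noise)


def _state_from_priors(panel: MarkerPanel, n_cells: int, priors: PriorSpec,
                       rng: np.random.Generator) -> ModelState:
    """Draw a generating state from the hierarchical priors."""
    gene_ids = panel.gene_ids
    G, K = len(gene_ids), panel.K
    switch = panel.switch_mask(gene_ids)
    amplitude = np.empty((G, K))
    shape = np.empty((G, K))
    t0 = np.empty((G, K))
    bt = priors.t0
    for j, gid in enumerate(gene_ids):
        pd_, pt = priors.gene_prior("delta", gid), priors.gene_prior("tau", gid)
        pe, pz = priors.gene_prior("eta", gid), priors.gene_prior("zeta", gid)
        d = abs(rng.normal(pd_.mean, pd_.sd))
        tval = rng.normal(pt.mean, pt.sd)
        if priors.tau_positive:
            tval = abs(tval)
        e = abs(rng.normal(pe.mean, pe.sd))
        z = abs(rng.normal(pz.mean, pz.sd))
        tsw, tpu = rng.beta(bt.a, bt.b), rng.beta(bt.a, bt.b)
        amplitude[j] = np.where(switch[j], d, e)
        shape[j] = np.where(switch[j], tval, z)
        t0[j] = np.where(switch[j], tsw, tpu)
    dyn = GeneDynamics(switch, amplitude, shape, t0)
    pi = rng.dirichlet(priors.concentration(K))
    phi = rng.gamma(priors.phi.shape, 1.0 / priors.phi.rate, size=G)
    T = rng.uniform(0.0, 1.0, n_cells)
    noise = NoiseModel(phi, 0.0, DEFAULT_BETA1)
    return ModelState(T, pi, dyn, noise)


def _calibrate_beta0(mu: np.ndarray, beta1: float, target: float, tol: float = 1e-4) -> float:
    """Bisection on beta0 so mean dropout probability hits ``target``."""
    f = lambda b0: expit(b0 + beta1 * mu).mean() - target
    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:  # pragma: no cover - target in (0,1) guards this
        raise ValidationError("dropout target unattainable")
    return brentq(f, lo, hi, xtol=tol)


def simulate(
    n_cells: int,
    panel: MarkerPanel,
    state_or_priors: ModelState | PriorSpec | None = None,
    dropout_rate: float = 0.1,
    seed: int = 0,
) -> SyntheticDataset:
    """Sample a synthetic dataset from the generative process.

    ``state_or_priors`` may be a fully specified ModelState (its T is
    replaced by fresh Uniform(0,1) draws of length ``n_cells``), a PriorSpec
    (the state is drawn from the priors), or None (the benchmark state).
    Negative Gaussian draws are clipped to 0 but not marked as dropout.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if not (0.0 <= dropout_rate < 1.0):
        raise ValidationError("dropout_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if state_or_priors is None:
        state = benchmark_state(panel, n_cells, rng)
    elif isinstance(state_or_priors, PriorSpec):
        state = _state_from_priors(panel, n_cells, state_or_priors, rng)
    elif isinstance(state_or_priors, ModelState):
        state = state_or_priors
        if state.dynamics.G != len(panel.gene_ids) or state.dynamics.K != panel.K:
            raise ValidationError("state dimensions do not match the panel")
        if not np.array_equal(state.dynamics.switch, panel.switch_mask(panel.gene_ids)):
            raise ValidationError("state switch roles do not match the panel")
        T = rng.uniform(0.0, 1.0, n_cells)
        state = replace(state, T=T)
    else:
        raise ValidationError("state_or_priors must be ModelState, PriorSpec or None")

    G, K = state.dynamics.G, state.dynamics.K
    T = state.T
    z = rng.choice(K, size=n_cells, p=state.pi)  # 0-based here
    mu_all = state.dynamics.mean(T)  # (N, G, K)
    mu = mu_all[np.arange(n_cells), :, z]  # (N, G)
    sigma2 = (1.0 + state.noise.phi[None, :]) * mu + state.noise.epsilon
    y = rng.normal(mu, np.sqrt(sigma2))
    np.clip(y, 0.0, None, out=y)

    if dropout_rate > 0.0:
        beta0 = _calibrate_beta0(mu, state.noise.beta1, dropout_rate)
        p = expit(beta0 + state.noise.beta1 * mu)
        mask = rng.uniform(size=mu.shape) < p
        state = replace(state, noise=replace(state.noise, beta0=float(beta0)))
    else:
        mask = np.zeros_like(mu, dtype=bool)
    y[mask] = 0.0

    cells = [f"cell{i + 1}" for i in range(n_cells)]
    expr = ExpressionMatrix(y, cells, panel.gene_ids, normalized=True)
    return SyntheticDataset(
        expression=expr,
        true_time=T,
        true_branch=z + 1,
        dropout_mask=mask,
        generating_state=state,
        panel=panel,
        seed=seed,
    )


def ablate_topology(panel: MarkerPanel, keep_branches) -> MarkerPanel:
    """Collapse the topology to a subset of branches.

    Markers of dropped branches are retained as transient-everywhere genes
    (empty branch set), mirroring an incomplete user-supplied lineage prior.
    """
    keep = sorted(set(int(k) for k in keep_branches))
    if not keep:
        raise ValidationError("keep_branches must be non-empty")
    if any(k < 1 or k > panel.K for k in keep):
        raise ValidationError(f"keep_branches must be a subset of 1..{panel.K}")
    remap = {old: new + 1 for new, old in enumerate(keep)}
    marker_map = {
        g: frozenset(remap[k] for k in bs if k in remap)
        for g, bs in panel.marker_map.items()
    }
    return MarkerPanel(len(keep), [panel.branch_names[k - 1] for k in keep], marker_map)
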