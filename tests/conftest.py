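"""Shared fixtures.

The expensive posterior fits (the simulated-recovery benchmark and its
variants) are session-scoped so several tests can interrogate one fit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from branchtime import (
    ExpressionMatrix,
    MarkerPanel,
    PriorSpec,
    SamplerConfig,
    TrajectoryModel,
    default_panel,
    simulate,
)

# the reduced sampling budget used throughout: two chains of 2000
# iterations with 600 warmup (adaptation is fast from the polished init)
RECOVERY_CFG = dict(n_chains=2, n_iter=2000, n_warmup=600, seed=11)
RECOVERY_SEED = 1
ASSIGN_THRESHOLD = 0.7


@pytest.fixture(scope="session")
def recovery_dataset():
    """100 cells, two lineages, four markers each, 10% dropout."""
    panel = default_panel(2, 4)
    return simulate(100, panel, dropout_rate=0.10, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_fit(recovery_dataset):
    ds = recovery_dataset
    model = TrajectoryModel(ds.expression, ds.panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(SamplerConfig(**RECOVERY_CFG))


@pytest.fixture
def toy_panel():
    return MarkerPanel(2, ["A", "B"], {"g1": frozenset({1}), "g2": frozenset({2})})


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.0, 1.0, (5, 2))
    return ExpressionMatrix(vals, [f"c{i}" for i in range(5)], ["g1", "g2"],
                            normalized=True)


@pytest.fixture
def priors():
    return PriorSpec()


def random_tiny_state(rng, G, K, panel=None):
    """A random small ModelState consistent with a random role mask."""
    from branchtime import GeneDynamics, ModelState, NoiseModel

    if panel is None:
        switch = rng.uniform(size=(G, K)) < 0.5
    else:
        switch = panel.switch_mask(panel.gene_ids)
    amplitude = rng.uniform(0.05, 0.8, (G, K))
    shape = np.where(switch, rng.uniform(1.0, 30.0, (G, K)),
                     rng.uniform(1.0, 80.0, (G, K)))
    t0 = rng.uniform(0.05, 0.95, (G, K))
    pi = rng.dirichlet(np.ones(K))
    phi = rng.uniform(0.0, 1.0, G)
    noise = NoiseModel(phi, rng.normal(0, 0.5), rng.normal(0, 2.0))
    T = rng.uniform(0, 1, 1)
    return ModelState(T, pi, GeneDynamics(switch, amplitude, shape, t0), noise)
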