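"""Posterior geometry and the NUTS-within-Gibbs machinery."""

import warnings

import numpy as np
import pytest
from scipy.optimize import approx_fprime
from scipy.stats import kstest

from branchtime import (
    ExpressionMatrix,
    MarkerPanel,
    PriorSpec,
    SamplerConfig,
    TrajectoryModel,
    ValidationError,
    default_panel,
    joint_loglik,
    log_prior,
    simulate,
)
from branchtime.nuts import sample_nuts


@pytest.fixture(scope="module")
def small_model():
    panel = default_panel(2, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate(20, panel, dropout_rate=0.2, seed=8)
        return TrajectoryModel(ds.expression, panel)


class TestSamplerConfig:
    def test_warmup_must_be_smaller(self):
        with pytest.raises(ValidationError):
            SamplerConfig(n_iter=1000, n_warmup=1000)

    def test_defaults_mirror_full_run(self):
        cfg = SamplerConfig()
        assert (cfg.n_chains, cfg.n_iter, cfg.n_warmup) == (4, 6000, 3000)


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, small_model):
        rng = np.random.default_rng(0)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        _, grad = small_model.logpost_and_grad(q)
        fd = approx_fprime(q, lambda x: small_model.logpost_and_grad(x)[0], 1e-6)
        np.testing.assert_allclose(grad, fd, rtol=2e-3, atol=1e-3)

    def test_kernel_and_numpy_paths_agree(self, small_model):
        numpy_model = TrajectoryModel(
            ExpressionMatrix(small_model.Y, small_model.cell_ids,
                             small_model.gene_ids, normalized=True),
            small_model.panel, use_numba=False)
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = small_model._initial_point(SamplerConfig(init="prior"), rng)
            lp1, g1 = small_model.logpost_and_grad(q)
            lp2, g2 = numpy_model.logpost_and_grad(q)
            assert lp1 == pytest.approx(lp2, rel=1e-12, abs=1e-9)
            np.testing.assert_allclose(g1, g2, rtol=1e-9, atol=1e-9)

    def test_equals_prior_plus_likelihood_plus_jacobian(self, small_model):
        """The sampled density is exactly log_prior + joint_loglik in the
        constrained space plus the transform Jacobian."""
        m = small_model
        data = ExpressionMatrix(m.Y, m.cell_ids, m.gene_ids, normalized=True)
        rng = np.random.default_rng(2)
        for _ in range(100):
            q = m._initial_point(SamplerConfig(init="prior"), rng)
            lp, _ = m.logpost_and_grad(q)
            state = m.packing.to_state(q)
            expected = (log_prior(state, m.priors, gene_ids=m.gene_ids)
                        + joint_loglik(data, state)
                        + m.log_jacobian(q))
            assert lp == pytest.approx(expected, abs=1e-8)

    def test_pack_unpack_round_trip(self, small_model):
        rng = np.random.default_rng(3)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        state = small_model.packing.to_state(q)
        q2 = small_model.packing.pack_state(state)
        np.testing.assert_allclose(q, q2, atol=1e-9)


class TestGibbsMoves:
    def test_t_refresh_keeps_other_blocks(self, small_model):
        rng = np.random.default_rng(4)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        q2 = small_model.gibbs_refresh_t(q, rng)
        pk = small_model.packing
        np.testing.assert_array_equal(q2[pk.sl_t.stop:], q[pk.sl_t.stop:])

    def test_gene_sweep_keeps_t(self, small_model):
        rng = np.random.default_rng(5)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        q2 = small_model.gibbs_refresh_genes(q, rng)
        pk = small_model.packing
        np.testing.assert_array_equal(q2[pk.sl_t], q[pk.sl_t])
        assert np.isfinite(small_model.logpost_and_grad(q2)[0])

    def test_pi_refresh_stays_on_simplex(self, small_model):
        rng = np.random.default_rng(6)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        q2 = small_model.gibbs_refresh_pi(q, rng)
        _, pi, *_ = small_model.packing.unpack(q2)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_collapsed_jump_preserves_finiteness(self, small_model):
        rng = np.random.default_rng(7)
        q = small_model._initial_point(SamplerConfig(init="prior"), rng)
        q2 = small_model.collapsed_gene_jump(q, rng)
        assert np.isfinite(small_model.logpost_and_grad(q2)[0])


class TestNuts:
    def test_recovers_gaussian_moments(self):
        scales = np.array([0.3, 1.0, 3.0])

        def lpg(q):
            return -0.5 * np.sum((q / scales) ** 2), -q / scales**2

        res = sample_nuts(lpg, np.zeros(3), 1500, 500, np.random.default_rng(0))
        np.testing.assert_allclose(res.draws.mean(axis=0), 0.0, atol=0.25)
        np.testing.assert_allclose(res.draws.std(axis=0), scales, rtol=0.15)
        assert res.divergent.mean() == 0.0

    def test_active_idx_requires_interleave(self):
        def lpg(q):
            return -0.5 * q @ q, -q

        with pytest.raises(ValueError):
            sample_nuts(lpg, np.zeros(3), 100, 50, np.random.default_rng(0),
                        active_idx=np.array([0]))


def test_prior_sampling_pseudotimes_uniform():
    """With no genes the pseudotime posterior is its Uniform(0,1) prior."""
    m = ExpressionMatrix(np.empty((40, 0)), [f"c{i}" for i in range(40)], [],
                         normalized=True)
    panel = MarkerPanel(1, ["A"], {})
    model = TrajectoryModel(m, panel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(SamplerConfig(n_chains=2, n_iter=800, n_warmup=300,
                                      seed=0, init="prior"))
    pooled = res.draws["t"].reshape(-1, 40)
    # thin heavily so the KS test sees roughly independent draws
    sample = pooled[::25, :].ravel()
    assert kstest(sample, "uniform").pvalue > 0.01


def test_single_lineage_recovery():
    """With K=1 the mixture collapses to a linear generative model: the
    fit still orders cells along the single trajectory."""
    from scipy.stats import spearmanr

    panel = default_panel(1, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate(100, panel, dropout_rate=0.10, seed=1)
        model = TrajectoryModel(ds.expression, panel)
        res = model.fit(SamplerConfig(n_chains=2, n_iter=1200, n_warmup=400,
                                      seed=11))
    rho = spearmanr(res.pseudotime, ds.true_time).statistic
    assert abs(rho) >= 0.8
    np.testing.assert_allclose(res.branch_prob, 1.0)


def test_fit_warns_when_not_converged():
    panel = default_panel(2, 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = simulate(15, panel, dropout_rate=0.1, seed=0)
        model = TrajectoryModel(ds.expression, panel)
    with pytest.warns(UserWarning):
        res = model.fit(SamplerConfig(n_chains=2, n_iter=60, n_warmup=30, seed=0))
    assert res.converged is False
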