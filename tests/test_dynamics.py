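"""Closed-form model components against hand calculations and enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from branchtime import (
    ExpressionMatrix,
    GeneDynamics,
    ModelState,
    NoiseModel,
    PriorSpec,
    ValidationError,
    cell_loglik,
    dropout_prob,
    gene_loglik,
    joint_loglik,
    log_prior,
    pulse_mean,
    sigmoid_mean,
    variance_fn,
)
from oracles import enumerate_cell_likelihood

from conftest import random_tiny_state


class TestCurves:
    def test_sigmoid_midpoint_is_delta(self):
        assert sigmoid_mean(0.3, 0.7, 12.0, 0.3) == pytest.approx(0.7)

    def test_sigmoid_saturation(self):
        assert sigmoid_mean(1e3, 0.5, 5.0, 0.5) == pytest.approx(1.0)
        assert sigmoid_mean(-1e3, 0.5, 5.0, 0.5) == pytest.approx(0.0, abs=1e-300)

    def test_sigmoid_hand_value(self):
        # 2*0.5/(1+exp(-10*0.1)) = 1/(1+e^-1)
        assert sigmoid_mean(0.6, 0.5, 10.0, 0.5) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-6)

    def test_sigmoid_overflow_safe(self):
        assert np.isfinite(sigmoid_mean(0.0, 0.5, 1e6, 1.0))

    def test_pulse_peak(self):
        assert pulse_mean(0.4, 0.3, 50.0, 0.4) == pytest.approx(0.6)

    def test_pulse_zero_width_constant(self):
        t = np.linspace(0, 1, 7)
        np.testing.assert_allclose(pulse_mean(t, 0.3, 0.0, 0.5), 0.6)

    def test_pulse_hand_value(self):
        # 2*0.5*exp(-100*0.01) = e^-1
        assert pulse_mean(0.6, 0.5, 100.0, 0.5) == pytest.approx(np.exp(-1), abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(t0=st.floats(0, 1), d=st.floats(0, 2), eta=st.floats(0.01, 1),
           zeta=st.floats(0, 200))
    def test_pulse_symmetry(self, t0, d, eta, zeta):
        assert pulse_mean(t0 + d, eta, zeta, t0) == pytest.approx(
            pulse_mean(t0 - d, eta, zeta, t0), rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(delta=st.floats(0.01, 1), tau=st.floats(0.1, 50),
           t0=st.floats(0, 1), seed=st.integers(0, 100))
    def test_sigmoid_monotone_in_t(self, delta, tau, t0, seed):
        t = np.sort(np.random.default_rng(seed).uniform(0, 1, 10))
        mu = sigmoid_mean(t, delta, tau, t0)
        assert np.all(np.diff(mu) >= -1e-15)


class TestNoise:
    def test_variance_floor(self):
        assert variance_fn(0.0, 0.0) == pytest.approx(0.01)
        assert variance_fn(0.0, 3.7) == pytest.approx(0.01)

    def test_variance_substitutions(self):
        assert variance_fn(1.0, 0.0) == pytest.approx(1.01)
        assert variance_fn(0.5, 1.0) == pytest.approx(1.01)

    def test_variance_monotone(self):
        mus = np.linspace(0, 2, 9)
        assert np.all(np.diff(variance_fn(mus, 0.5)) > 0)
        phis = np.linspace(0, 3, 9)
        assert np.all(np.diff(variance_fn(1.0, phis)) > 0)

    def test_variance_domain_errors(self):
        with pytest.raises(ValidationError):
            variance_fn(-0.1, 0.5)
        with pytest.raises(ValidationError):
            variance_fn(0.5, -0.1)

    def test_dropout_at_zero_logit(self):
        assert dropout_prob(0.7, 0.0, 0.0) == pytest.approx(0.5)

    def test_dropout_limit(self):
        assert dropout_prob(0.5, -1e4, 0.0) == pytest.approx(0.0, abs=1e-300)

    def test_dropout_hand_value(self):
        assert dropout_prob(0.5, 1.0, -2.0) == pytest.approx(0.5)

    def test_dropout_monotone_with_slope_sign(self):
        mus = np.linspace(0, 1, 11)
        assert np.all(np.diff(dropout_prob(mus, 0.0, -5.0)) < 0)
        assert np.all(np.diff(dropout_prob(mus, 0.0, 5.0)) > 0)


class TestGeneLoglik:
    def test_certain_dropout_absorbs_zero(self):
        assert gene_loglik(0.0, 0.5, 0.1, 1.0) == pytest.approx(0.0)

    def test_certain_dropout_forbids_nonzero(self):
        assert gene_loglik(0.4, 0.5, 0.1, 1.0) == -np.inf

    def test_normal_at_mean(self):
        expected = -0.5 * np.log(2 * np.pi * 0.01)
        assert gene_loglik(0.4, 0.4, 0.01, 0.0) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1.383647, abs=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValidationError):
            gene_loglik(0.1, 0.1, 0.0, 0.2)

    def test_density_normalizes_with_point_mass(self):
        """Integral over nonzero y plus the dropout point mass is 1."""
        mu, s2, p = 0.35, 0.08, 0.3
        cont, _ = quad(lambda y: np.exp(gene_loglik(y, mu, s2, p)), -8, 8,
                       points=[0.0], limit=200)
        assert cont + p == pytest.approx(1.0, abs=1e-3)


class TestCellLoglik:
    def test_single_branch_collapses_to_sum(self):
        rng = np.random.default_rng(3)
        state = random_tiny_state(rng, G=3, K=1)
        y = rng.uniform(0, 1, 3)
        mu = state.dynamics.mean(state.T)[0, :, 0]
        s2 = (1 + state.noise.phi) * mu + state.noise.epsilon
        p = 1 / (1 + np.exp(-(state.noise.beta0 + state.noise.beta1 * mu)))
        direct = gene_loglik(y, mu, s2, p).sum()
        assert cell_loglik(y, state.T[0], state) == pytest.approx(direct, rel=1e-12)

    def test_identical_branches_ignore_pi(self):
        rng = np.random.default_rng(4)
        base = random_tiny_state(rng, G=2, K=1)
        from branchtime import GeneDynamics, ModelState, NoiseModel

        dup = lambda a: np.repeat(a, 2, axis=1)
        dyn = GeneDynamics(dup(base.dynamics.switch), dup(base.dynamics.amplitude),
                           dup(base.dynamics.shape), dup(base.dynamics.t0))
        y = rng.uniform(0, 1, 2)
        for pi in ([0.5, 0.5], [0.9, 0.1]):
            two = ModelState(base.T, np.array(pi), dyn, base.noise)
            assert cell_loglik(y, base.T[0], two) == pytest.approx(
                cell_loglik(y, base.T[0], base), rel=1e-10)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            G = int(rng.integers(1, 4))
            K = int(rng.integers(1, 4))
            state = random_tiny_state(rng, G=G, K=K)
            y = rng.uniform(0, 1, G)
            y[rng.uniform(size=G) < 0.4] = 0.0  # exercise the zero branch
            expected = enumerate_cell_likelihood(y, state.T[0], state)
            assert cell_loglik(y, state.T[0], state) == pytest.approx(
                expected, rel=1e-10)

    def test_dimension_mismatch(self):
        state = random_tiny_state(np.random.default_rng(0), G=2, K=2)
        with pytest.raises(ValidationError):
            cell_loglik(np.zeros(3), 0.5, state)


class TestJointLoglik:
    def _state_matrix(self, n, seed=0):
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        state = random_tiny_state(rng, G=2, K=2)
        state = replace(state, T=rng.uniform(0, 1, n))
        vals = rng.uniform(0, 1, (n, 2))
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(n)], ["g1", "g2"],
                             normalized=True)
        return state, m

    def test_empty_matrix_gives_zero(self):
        state, _ = self._state_matrix(0)
        m = ExpressionMatrix(np.empty((0, 2)), [], ["g1", "g2"], normalized=True)
        assert joint_loglik(m, state) == 0.0

    def test_sum_of_cells(self):
        state, m = self._state_matrix(3)
        total = sum(cell_loglik(m.values[i], state.T[i], state) for i in range(3))
        assert joint_loglik(m, state) == pytest.approx(total, rel=1e-12)

    def test_duplicated_cell_doubles_contribution(self):
        from dataclasses import replace

        state, m = self._state_matrix(1)
        single = joint_loglik(m, state)
        m2 = ExpressionMatrix(np.vstack([m.values, m.values]), ["c0", "c0b"],
                              m.gene_ids, normalized=True)
        state2 = replace(state, T=np.repeat(state.T, 2))
        assert joint_loglik(m2, state2) == pytest.approx(2 * single, rel=1e-12)

    def test_unnormalized_rejected(self):
        state, m = self._state_matrix(2)
        raw = ExpressionMatrix(m.values, m.cell_ids, m.gene_ids, normalized=False)
        with pytest.raises(ValidationError, match="normalized"):
            joint_loglik(raw, state)


class TestLogPrior:
    def test_pseudotime_outside_support(self):
        state = random_tiny_state(np.random.default_rng(0), G=1, K=1)
        object.__setattr__(state, "T", np.array([1.5]))
        assert log_prior(state, PriorSpec()) == -np.inf

    def test_symmetric_dirichlet_value(self):
        # Dirichlet(1/2, 1/2) at (0.5, 0.5): -log(pi) + log(2) ~ -0.451583
        state = random_tiny_state(np.random.default_rng(1), G=1, K=2)
        object.__setattr__(state, "pi", np.array([0.5, 0.5]))
        pr = PriorSpec()
        full = log_prior(state, pr)
        object.__setattr__(state, "pi", np.array([0.3, 0.7]))
        other = log_prior(state, pr)
        from scipy.special import gammaln

        def dir_ld(p):
            conc = np.full(2, 0.5)
            return (gammaln(conc.sum()) - gammaln(conc).sum()
                    + ((conc - 1) * np.log(p)).sum())

        assert dir_ld(np.array([0.5, 0.5])) == pytest.approx(-0.451583, abs=1e-6)
        assert full - other == pytest.approx(
            dir_ld(np.array([0.5, 0.5])) - dir_ld(np.array([0.3, 0.7])), rel=1e-9)

    def test_matches_per_term_oracle(self):
        """Sum of independent scipy densities for each tied parameter."""
        from scipy.stats import beta as sbeta
        from scipy.stats import gamma as sgamma
        from scipy.stats import norm as snorm

        rng = np.random.default_rng(7)
        from branchtime import GeneDynamics, ModelState, NoiseModel

        switch = np.array([[True, False]])
        dyn = GeneDynamics(switch, np.array([[0.4, 0.2]]), np.array([[12.0, 30.0]]),
                           np.array([[0.3, 0.6]]))
        state = ModelState(np.array([0.4]), np.array([0.5, 0.5]), dyn,
                           NoiseModel(np.array([0.3]), 0.05, -0.02))
        pr = PriorSpec()
        got = log_prior(state, pr)

        def trunc(x, m, s):
            return snorm.logpdf(x, m, s) - snorm.logsf(0, m, s)

        conc = np.full(2, 0.5)
        from scipy.special import gammaln

        expected = (gammaln(1.0) - gammaln(conc).sum() - 0.5 * np.log(0.25)
                    + trunc(0.4, 0.5, 0.5)           # delta
                    + trunc(12.0, 0.0, 10.0)         # tau (positive by default)
                    + sbeta.logpdf(0.3, 2, 2)        # switch t0
                    + trunc(0.2, 0.0, 0.25)          # eta
                    + trunc(30.0, 50.0, 25.0)        # zeta
                    + sbeta.logpdf(0.6, 2, 2)        # pulse t0
                    + sgamma.logpdf(0.3, 2, scale=1 / 4)  # phi
                    + snorm.logpdf(0.05, 0, 0.1) + snorm.logpdf(-0.02, 0, 0.1))
        assert got == pytest.approx(expected, rel=1e-9)
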