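"""Bayesian observer: transition kernel, Bayes updates, summaries, filter-vs-enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import enumeration_predictions
from seqpred.environments import EnvironmentConfig
from seqpred.optimal import (
    LatentGrid,
    PosteriorState,
    bayes_update,
    run_optimal_agent,
    summarize,
    transition,
    uniform_state,
)

GRID = LatentGrid(20)


class TestTransition:
    @pytest.mark.parametrize("structure", ["unigram", "bigram_independent", "bigram_coupled"])
    def test_zero_hazard_is_identity(self, structure):
        rng = np.random.default_rng(0)
        state = uniform_state(structure)
        state.mass = rng.dirichlet(np.ones(state.mass.size)).reshape(state.mass.shape)
        out = transition(state, 0.0)
        assert np.allclose(out.mass, state.mass)

    @pytest.mark.parametrize("structure", ["unigram", "bigram_coupled"])
    def test_full_hazard_is_uniform(self, structure):
        rng = np.random.default_rng(1)
        state = uniform_state(structure)
        state.mass = rng.dirichlet(np.ones(state.mass.size)).reshape(state.mass.shape)
        out = transition(state, 1.0)
        assert np.allclose(out.mass, 1.0 / state.mass.size)

    def test_independent_kernel_factorizes(self):
        """Joint transition of a point mass equals the explicit 400-cell kernel product."""
        pc = 0.3
        n = 20
        mass = np.zeros((n, n))
        mass[3, 17] = 1.0
        out = transition(PosteriorState(mass, "bigram_independent"), pc).mass
        # independent oracle: full 400 x 400 kernel built from the 1-D kernel
        k1 = (1 - pc) * np.eye(n) + pc / n
        kernel = np.kron(k1, k1)  # state ordering (i00 * n + i11)
        expected = (mass.ravel() @ kernel).reshape(n, n)
        assert np.allclose(out, expected, atol=1e-14)
        marg1 = (1 - pc) * np.eye(n)[3] + pc / n
        marg2 = (1 - pc) * np.eye(n)[17] + pc / n
        assert np.allclose(out, np.outer(marg1, marg2))


class TestBayesUpdate:
    def test_uniform_prior_single_one(self):
        """Posterior after one '1' is proportional to the bin value (20-term oracle)."""
        state = bayes_update(uniform_state("unigram"), 1, GRID)
        v = GRID.values
        assert np.allclose(state.mass, v / v.sum())
        _, means, _, _ = summarize(state, GRID)
        assert np.isclose(means[0], (v**2).sum() / v.sum())

    def test_update_order_commutes_without_hazard(self):
        a = bayes_update(bayes_update(uniform_state("unigram"), 1, GRID), 0, GRID)
        b = bayes_update(bayes_update(uniform_state("unigram"), 0, GRID), 1, GRID)
        assert np.allclose(a.mass, b.mass)

    def test_bigram_update_touches_relevant_marginal_only(self):
        """prev=0, obs=0 updates p00; the p11 marginal of a factorised prior is unchanged."""
        state = uniform_state("bigram_independent")
        state.prev_obs = 0
        out = bayes_update(state, 0, GRID)
        v = GRID.values
        marg00 = out.mass.sum(axis=-1)
        marg11 = out.mass.sum(axis=-2)
        assert np.allclose(marg00, v / v.sum())  # joint-grid oracle: mass prop. to p00
        assert np.allclose(marg11, 1.0 / 20)

    def test_prev_obs_recorded(self):
        out = bayes_update(uniform_state("bigram_independent"), 1, GRID)
        assert out.prev_obs == 1


class TestSummarize:
    def test_uniform_prior_summary(self):
        p, means, sds, psis = summarize(uniform_state("unigram"), GRID)
        v = GRID.values
        assert np.isclose(p, 0.5)
        assert np.isclose(means[0], 0.5)
        assert np.isclose(sds[0], np.sqrt(np.mean(v**2) - 0.25))
        assert np.isclose(psis[0], -np.log(sds[0]))

    def test_point_mass_prediction_and_degenerate_sd(self):
        mass = np.zeros(20)
        mass[7] = 1.0
        state = PosteriorState(mass, "unigram")
        with pytest.raises(FloatingPointError):
            summarize(state, GRID)

    def test_bigram_uniform_prediction_conditions_on_prev(self):
        state = uniform_state("bigram_independent")
        state.prev_obs = 1
        p, means, _, _ = summarize(state, GRID)
        assert np.isclose(p, 0.5)
        assert np.allclose(means, 0.5)


class TestRunOptimal:
    def test_beta_limit_without_changes(self):
        """With p_c = 0 the posterior mean approaches the Beta (Laplace) rule."""
        x = np.array([1] * 6 + [0] * 3)
        cfg = EnvironmentConfig("unigram", change_prob=0.0, length=x.size)
        trace = run_optimal_agent(x, cfg)
        expected = (6 + 1) / (9 + 2)
        # grid vs continuous Beta integral: discretisation error is O(1/n_bins^2)
        assert abs(trace.means[0, -1] - expected) < 0.01

    @pytest.mark.parametrize(
        "structure,T",
        [("unigram", 8), ("bigram_independent", 6), ("bigram_coupled", 7)],
    )
    def test_filter_equals_enumeration(self, structure, T):
        """Forward filter == exact sum over change configurations (brute force)."""
        rng = np.random.default_rng(42)
        pc = 0.2
        for _ in range(3):
            x = rng.integers(0, 2, T)
            cfg = EnvironmentConfig(structure, change_prob=pc, length=T)
            filt = run_optimal_agent(x, cfg).predictions
            oracle = enumeration_predictions(x, structure, pc)
            assert np.allclose(filt, oracle, atol=1e-12)

    def test_precision_grows_then_drops_after_surprise(self):
        cfg0 = EnvironmentConfig("unigram", change_prob=0.0, length=30)
        psi_const = run_optimal_agent(np.ones(30, dtype=int), cfg0).log_precisions[0]
        assert np.all(np.diff(psi_const) > 0)

        x = np.concatenate([np.ones(25, dtype=int), [0]])
        cfg = EnvironmentConfig("unigram", change_prob=0.1, length=x.size)
        psi = run_optimal_agent(x, cfg).log_precisions[0]
        assert psi[-1] < psi[-2]

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=10, deadline=None)
    def test_mass_stays_normalized(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 40)
        state = uniform_state("bigram_independent")
        for obs in x:
            state = bayes_update(state, int(obs), GRID)
            state = transition(state, 1 / 75)
            assert abs(state.mass.sum() - 1.0) < 1e-12
            assert np.all(state.mass >= 0)

    def test_predictions_strictly_inside_unit_interval(self):
        cfg = EnvironmentConfig("unigram", seed=1)
        from seqpred.environments import generate_sequence

        seq = generate_sequence(cfg)
        trace = run_optimal_agent(seq, cfg)
        assert np.all(trace.predictions > 0) and np.all(trace.predictions < 1)
        assert np.all(np.isfinite(trace.log_precisions))
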