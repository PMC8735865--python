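"""Analysis operations: performance scaling, learning rate, readouts, MI, subspace,
perturbation construction, power law, and group statistics."""

import numpy as np
import pytest
from scipy import optimize, stats

from seqpred.analyses import (
    PerturbationSpec,
    effective_learning_rate,
    evaluate_readout,
    fit_power_law,
    fit_readout,
    group_statistics,
    make_perturbation,
    mutual_information,
    percent_optimal,
    perturbation_experiment,
    project_subspace,
)
from seqpred.analyses.stats import welch_ci_halfwidth
from seqpred.heuristics import HeuristicParams, run_heuristic
from seqpred.networks import initialize_network
from seqpred.analyses.readout import ReadoutModel


class TestPercentOptimal:
    def test_endpoints_and_midpoint(self):
        assert percent_optimal(-100.0, -100.0, -200.0) == 100.0
        assert percent_optimal(-200.0, -100.0, -200.0) == 0.0
        assert percent_optimal(-150.0, -100.0, -200.0) == 50.0

    def test_affine_invariance(self):
        base = percent_optimal(-150.0, -100.0, -200.0)
        shifted = percent_optimal(-150.0 + 37.0, -100.0 + 37.0, -200.0 + 37.0)
        assert np.isclose(base, shifted)

    def test_invalid_reference(self):
        with pytest.raises(ValueError):
            percent_optimal(-150.0, -200.0, -100.0)


class TestEffectiveLearningRate:
    def test_single_step_arithmetic(self):
        trace = effective_learning_rate(np.array([0.5, 0.6]), np.array([0, 1]))
        # alpha_1 = (0.6 - 0.5)/(1 - 0.5) = 0.2
        assert np.isclose(trace.alpha[1], 0.2)

    def test_first_step_uses_half_reference(self):
        trace = effective_learning_rate(np.array([0.6]), np.array([1]))
        assert np.isclose(trace.alpha[0], (0.6 - 0.5) / (1 - 0.5))

    def test_delta_rule_constant(self):
        """The delta-rule agent's effective learning rate is alpha at every step."""
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 200)
        trace = run_heuristic(HeuristicParams("delta", "unigram", 0.17), x)
        lr = effective_learning_rate(trace.predictions, x)
        assert lr.valid.all()
        assert np.allclose(lr.alpha, 0.17)

    def test_degenerate_steps_masked(self):
        trace = effective_learning_rate(np.array([1.0, 0.4]), np.array([1, 1]))
        assert not trace.valid[1]  # x - p = 0 at the second step
        assert np.isnan(trace.alpha[1])


class TestReadout:
    def test_exact_linear_target_recovered(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(50, 100, 6))
        w = rng.normal(size=6)
        y = h @ w + 2.0
        model = fit_readout(h[:40], y[:40])
        assert np.isclose(evaluate_readout(model, h[40:], y[40:]), 1.0)
        assert np.allclose(model.weights, w)

    def test_noise_target_uncorrelated(self):
        """Held-out r stays near 0 for targets independent of the states."""
        rng = np.random.default_rng(2)
        h = rng.normal(size=(45_000, 6))
        y = rng.normal(size=45_000)
        model = fit_readout(h[:7000], y[:7000])
        assert abs(evaluate_readout(model, h[7000:], y[7000:])) < 0.05

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(3)
        h = rng.normal(size=(500, 4))
        w = rng.normal(size=4)
        y = h @ w
        model = fit_readout(h, y)
        flipped = ReadoutModel(weights=-model.weights, intercept=-model.intercept)
        assert np.isclose(evaluate_readout(flipped, h, y), -1.0)

    def test_zero_variance_rejected(self):
        model = ReadoutModel(weights=np.zeros(3), intercept=0.0)
        with pytest.raises(ValueError):
            evaluate_readout(model, np.random.normal(size=(10, 3)), np.ones(10))


class TestMutualInformation:
    def test_identity_reaches_log_bins(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=5000)
        assert np.isclose(mutual_information(a, a, n_bins=32), np.log(32))

    def test_independent_below_bias_bound(self):
        rng = np.random.default_rng(5)
        n, bins = 60_000, 32
        a, b = rng.normal(size=n), rng.normal(size=n)
        assert mutual_information(a, b, bins) < 2 * (bins - 1) ** 2 / (2 * n)

    def test_constant_series_warns_zero(self):
        with pytest.warns(UserWarning):
            assert mutual_information(np.ones(100), np.random.normal(size=100)) == 0.0


class TestSubspace:
    def test_orthogonal_axes_unchanged(self):
        w_pred = np.array([1.0, 0.0, 0.0])
        w_prec = np.array([0.0, 2.0, 0.0])
        coords = project_subspace(np.array([0.5, 0.3, 0.7]), w_pred, w_prec)
        assert np.allclose(coords, [0.5, 0.3])

    def test_state_on_prediction_axis_has_zero_y(self):
        rng = np.random.default_rng(6)
        w_pred = rng.normal(size=8)
        w_prec = rng.normal(size=8)
        coords = project_subspace(3.0 * w_pred, w_pred, w_prec)
        assert abs(coords[1]) < 1e-10

    def test_reconstruction_within_span(self):
        rng = np.random.default_rng(7)
        w_pred = rng.normal(size=8)
        w_prec = rng.normal(size=8)
        state = 0.7 * w_pred + 1.3 * w_prec
        coords = project_subspace(state, w_pred, w_prec)
        u = w_pred / np.linalg.norm(w_pred)
        resid = w_prec - (w_prec @ u) * u
        v = resid / np.linalg.norm(resid)
        assert np.allclose(coords[0] * u + coords[1] * v, state, atol=1e-10)

    def test_collinear_rejected(self):
        with pytest.raises(ValueError):
            project_subspace(np.zeros(4), np.ones(4), 2.0 * np.ones(4))


class TestPerturbation:
    def setup_method(self):
        rng = np.random.default_rng(8)
        self.w_pred = rng.normal(size=11)
        self.w_prec = rng.normal(size=11)

    def test_zero_delta_pure_residual(self):
        rng = np.random.default_rng(9)
        q = make_perturbation(self.w_pred, self.w_prec, 0.0, 0.5, rng)
        assert abs(q @ self.w_pred) < 1e-10
        assert abs(q @ self.w_prec) < 1e-10
        assert abs(np.linalg.norm(q) - 0.5) < 1e-10

    def test_constraints_hold_over_many_draws(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            delta = rng.uniform(-0.3, 0.3)
            q = make_perturbation(self.w_pred, self.w_prec, delta, 1.0, rng)
            assert abs(q @ self.w_pred) < 1e-10
            assert abs(q @ self.w_prec - delta) < 1e-10
            assert abs(np.linalg.norm(q) - 1.0) < 1e-10

    def test_matches_quadratic_programming_solution(self):
        """The deterministic component equals the minimum-norm constrained solution."""
        rng = np.random.default_rng(11)
        delta = 0.2
        q = make_perturbation(self.w_pred, self.w_prec, delta, 1.0, rng)
        res = optimize.minimize(
            lambda v: v @ v,
            np.zeros(11),
            constraints=[
                {"type": "eq", "fun": lambda v: v @ self.w_pred},
                {"type": "eq", "fun": lambda v: v @ self.w_prec - delta},
            ],
            method="SLSQP",
            tol=1e-14,
        )
        q_min = res.x
        # project q onto span(w_pred, w_prec): must coincide with the QP optimum
        basis = np.linalg.qr(np.stack([self.w_pred, self.w_prec]).T)[0]
        assert np.allclose(basis.T @ q, basis.T @ q_min, atol=1e-6)

    def test_infeasible_norm_rejected(self):
        rng = np.random.default_rng(12)
        with pytest.raises(ValueError):
            make_perturbation(self.w_pred, self.w_prec, 5.0, 1e-3, rng)

    def test_null_perturbation_changes_nothing(self):
        """delta = 0, c = 0 leaves the learning rate exactly unchanged."""
        rng = np.random.default_rng(13)
        params = initialize_network("gated", 6, 0.5, 0.5, rng=rng)
        readout = ReadoutModel(weights=rng.normal(size=6), intercept=0.0)
        seqs = rng.integers(0, 2, (20, 60))
        out = perturbation_experiment(
            params,
            readout,
            seqs,
            PerturbationSpec(delta_levels=(0.0,), norm=0.0, n_probes=50, t_min=5),
            rng,
        )
        assert np.allclose(out["changes"], 0.0)


class TestPowerLaw:
    def test_noiseless_recovery_exact(self):
        N = np.array([2, 3, 5, 8, 13, 21, 34])
        c, a = 40.0, 0.7
        p = 100.0 - c * (1.0 / N) ** a
        fit = fit_power_law(N, p)
        assert np.isclose(fit.coefficient, c)
        assert np.isclose(fit.exponent, a)
        assert np.isclose(fit.r_squared, 100.0)
        assert np.isclose(fit.predict_percent(1000), 100.0 - c / 1000**a)

    def test_noisy_recovery_within_ten_percent(self):
        rng = np.random.default_rng(14)
        N = np.unique(np.round(np.geomspace(2, 45, 12)).astype(int))
        c, a = 30.0, 0.6
        gap = c * (1.0 / N) ** a * rng.lognormal(0.0, 0.01, size=N.size)
        fit = fit_power_law(N, 100.0 - gap)
        assert abs(fit.exponent - a) < 0.1 * a

    def test_saturated_percent_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([2, 4], [99.0, 100.0])


class TestGroupStatistics:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = group_statistics(a, a.copy(), "welch_two_sided")
        assert out["statistic"] == 0.0
        assert np.isclose(out["p_value"], 1.0)

    def test_degenerate_paired_flagged(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = group_statistics(a + 1.0, a, "paired_one_sided")
        assert out.get("degenerate") is True
        assert out["statistic"] == np.inf

    def test_welch_matches_direct_formula(self):
        """Cross-check against the Welch statistic computed from first principles."""
        rng = np.random.default_rng(15)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(0.5, 2.0, 12)
        out = group_statistics(a, b, "welch_two_sided")
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_manual = (a.mean() - b.mean()) / np.sqrt(va + vb)
        dof_manual = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_manual = 2 * stats.t.sf(abs(t_manual), dof_manual)
        assert abs(out["statistic"] - t_manual) < 1e-10
        assert abs(out["p_value"] - p_manual) < 1e-10
        assert abs(out["dof"] - dof_manual) < 1e-10

    def test_one_sided_direction(self):
        rng = np.random.default_rng(16)
        big = rng.normal(1.0, 0.5, 15)
        small = rng.normal(0.0, 0.5, 15)
        assert group_statistics(big, small, "welch_one_sided")["p_value"] < 0.01
        assert group_statistics(small, big, "welch_one_sided")["p_value"] > 0.5

    def test_interaction_f_detects_crossover(self):
        rng = np.random.default_rng(17)
        noise = lambda: rng.normal(0.0, 0.1, 10)
        # strong interaction: the effect of factor B flips across factor A
        out = group_statistics(
            (1.0 + noise(), -1.0 + noise()), (-1.0 + noise(), 1.0 + noise()), "interaction_f"
        )
        assert out["statistic"] > 100
        assert out["p_value"] < 1e-6
        # additive design: no interaction
        out2 = group_statistics(
            (0.0 + noise(), 1.0 + noise()), (2.0 + noise(), 3.0 + noise()), "interaction_f"
        )
        assert out2["p_value"] > 0.01

    def test_interaction_f_matches_balanced_anova_formula(self):
        rng = np.random.default_rng(18)
        cells = [rng.normal(m, 1.0, 8) for m in (0.0, 0.8, 0.3, 1.9)]
        out = group_statistics((cells[0], cells[1]), (cells[2], cells[3]), "interaction_f")
        # balanced two-way ANOVA interaction F from cell means
        n = 8
        grand = np.mean([c.mean() for c in cells])
        a_means = [(cells[0].mean() + cells[1].mean()) / 2, (cells[2].mean() + cells[3].mean()) / 2]
        b_means = [(cells[0].mean() + cells[2].mean()) / 2, (cells[1].mean() + cells[3].mean()) / 2]
        ss_int = n * sum(
            (cells[2 * i + j].mean() - a_means[i] - b_means[j] + grand) ** 2
            for i in (0, 1)
            for j in (0, 1)
        )
        ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells)
        f_manual = (ss_int / 1) / (ss_err / (4 * n - 4))
        assert abs(out["statistic"] - f_manual) < 1e-8

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            group_statistics([1.0], [1.0, 2.0], "welch_two_sided")

    def test_welch_ci_halfwidth_positive(self):
        rng = np.random.default_rng(19)
        assert welch_ci_halfwidth(rng.normal(size=20), rng.normal(size=20)) > 0
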