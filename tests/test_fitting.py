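"""Likelihood objective, problem construction and multi-start fitting."""

import numpy as np
import pytest

from rtfit import (
    FitError,
    RTFParams,
    TimeCourseTable,
    build_problem,
    fit,
    initial_guesses,
    neg2_log_likelihood,
    objective_gradient,
    predict,
    simulate,
)
from rtfit.fitting import default_initial_guess, derive_seed
from rtfit.simulate import SimSpec


def _flat_table(n=10, y0=0.0, sigma_exp=None):
    t = np.linspace(0, 9, n)
    se = None if sigma_exp is None else np.full(n, sigma_exp)
    return TimeCourseTable(t=t, y=np.full(n, y0), sigma_exp=se)


class TestTimeCourseTable:
    def test_requires_three_points_and_two_times(self):
        with pytest.raises(ValueError):
            TimeCourseTable(t=np.array([0, 1]), y=np.array([1, 2]))
        with pytest.raises(ValueError):
            TimeCourseTable(t=np.zeros(4), y=np.arange(4.0))

    def test_sigma_exp_must_be_positive(self):
        with pytest.raises(ValueError):
            TimeCourseTable(
                t=np.arange(3.0), y=np.arange(3.0), sigma_exp=np.array([1, 0, 1.0])
            )

    def test_frame_round_trip(self):
        table = TimeCourseTable(
            t=np.arange(4.0), y=np.array([0.1, 0.5, 0.8, 1.0]),
            d=np.full(4, 2.0), sigma_exp=np.full(4, 0.05),
        )
        back = TimeCourseTable.from_frame(table.to_frame())
        assert np.array_equal(back.t, table.t)
        assert np.array_equal(back.d, table.d)
        assert np.array_equal(back.sigma_exp, table.sigma_exp)


class TestObjective:
    def test_zero_residuals_closed_form(self):
        # flat data fit exactly by the offset: -2lnL = n ln(2 pi) at sigma=1
        table = _flat_table(n=10, y0=0.7, sigma_exp=1.0)
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        theta = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.7])
        assert neg2_log_likelihood(theta, problem) == pytest.approx(
            10 * np.log(2 * np.pi), abs=1e-9
        )

    def test_single_point_residual_closed_form(self):
        # residual 2 at one point with sigma=1 adds Delta^2 = 4
        table = TimeCourseTable(
            t=np.array([0.0, 1.0, 2.0]),
            y=np.array([0.0, 0.0, 2.0]),
            sigma_exp=np.ones(3),
        )
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        theta = np.zeros(7)
        theta[2:5] = 1.0  # rates
        assert neg2_log_likelihood(theta, problem) == pytest.approx(
            3 * np.log(2 * np.pi) + 4.0, abs=1e-9
        )

    def test_sigma_scaling_algebra(self):
        # doubling all sigmaExp changes the objective by n ln4 - (3/4) sum(D^2/s^2)
        rng = np.random.default_rng(3)
        t = np.linspace(0, 9, 12)
        y = rng.normal(0, 1, 12)
        s = rng.uniform(0.5, 2.0, 12)
        theta = np.zeros(7)
        theta[2:5] = 1.0
        p1 = build_problem(TimeCourseTable(t=t, y=y, sigma_exp=s), "singleDose")
        p2 = build_problem(TimeCourseTable(t=t, y=y, sigma_exp=2 * s), "singleDose")
        delta_sq = y**2 / s**2  # model is identically 0 at theta
        expected = 12 * np.log(4.0) - 0.75 * delta_sq.sum()
        got = neg2_log_likelihood(theta, p2) - neg2_log_likelihood(theta, p1)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_sigma_gradient_at_zero_residuals(self):
        table = _flat_table(n=8, y0=0.5)
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        theta = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 0.0, 0.5, 0.3])
        g = objective_gradient(theta, problem)
        assert g[-1] == pytest.approx(2 * 8 / 0.3)

    @pytest.mark.parametrize("mode", ["singleDose", "doseDependent"])
    def test_gradient_matches_finite_differences(self, mode):
        if mode == "singleDose":
            table, _ = simulate(SimSpec(seed=4))
        else:
            table, _ = simulate(SimSpec(mode="doseDependent", times=(7, 10.0), seed=4))
        problem = build_problem(table, mode, sign_sus=1, sign_trans=1)
        rng = np.random.default_rng(10)
        bounds = np.array(problem.internal_bounds())
        for _ in range(20):
            z = rng.uniform(bounds[:, 0] + 0.05, bounds[:, 1] - 0.05)
            theta = problem.from_internal(z)
            g = objective_gradient(theta, problem)
            fd = np.empty_like(g)
            for j in range(theta.size):
                # relative step for strictly positive log-scale parameters
                # (an absolute 1e-6 step is too coarse when sigma ~ 1e-4)
                if problem.take_log10[j]:
                    s = 1e-5 * abs(theta[j])
                else:
                    s = 1e-6 * max(1.0, abs(theta[j]))
                tp, tm = theta.copy(), theta.copy()
                tp[j] += s
                tm[j] -= s
                fd[j] = (
                    neg2_log_likelihood(tp, problem) - neg2_log_likelihood(tm, problem)
                ) / (2 * s)
            # normwise comparison: components below the FD noise floor are
            # pure cancellation error and carry no information
            assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5


class TestBuildProblem:
    def test_sigma_free_only_without_sigma_exp(self):
        with_se = build_problem(_flat_table(sigma_exp=0.1), "singleDose")
        without = build_problem(_flat_table(y0=1.0), "singleDose")
        assert "sigma" not in with_se.param_names
        assert without.param_names[-1] == "sigma"

    def test_dose_mode_requires_doses(self, noisy_table):
        table, _ = noisy_table
        with pytest.raises(ValueError):
            build_problem(table, "doseDependent")

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning):
            build_problem(_flat_table(y0=3.0), "singleDose")

    def test_initial_guess_within_bounds_over_many_datasets(self):
        for seed in range(100):
            table, _ = simulate(SimSpec(seed=seed, noise_sd=0.05))
            problem = build_problem(table, "singleDose")
            g = problem.initial_guess
            assert np.all(g >= problem.lb) and np.all(g <= problem.ub)

    def test_fixed_and_bound_overrides(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(
            table, "singleDose", fixed={"tau": 0.0}, bounds={"A": (0.0, 5.0)}
        )
        assert problem.fixed == {"tau": 0.0}
        assert problem.ub[problem.index_of("A")] == 5.0
        assert "tau" not in problem.free_names


class TestInitialGuesses:
    def test_single_start_is_default_guess(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        (only,) = initial_guesses(problem, 1, seed=9)
        assert np.array_equal(only, default_initial_guess(problem, 1))

    def test_deterministic_given_seed(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        a = initial_guesses(problem, 20, seed=5)
        b = initial_guesses(problem, 20, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_all_guesses_feasible(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        for g in initial_guesses(problem, 1000, seed=2):
            assert np.all(np.isfinite(g))
            assert np.all(g >= problem.lb - 1e-12)
            assert np.all(g <= problem.ub + 1e-12)


class TestFit:
    def test_value_equals_objective_at_best(self, fitted_default):
        res = fitted_default
        assert res.value == neg2_log_likelihood(res.best, res.problem)
        assert np.all(res.best >= res.problem.lb)
        assert np.all(res.best <= res.problem.ub)

    def test_fixed_parameters_stay_fixed(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(
            table, "singleDose", sign_sus=1, sign_trans=1, fixed={"tau": 0.25}
        )
        res = fit(problem, n_starts=5, seed=3)
        assert res.best[problem.index_of("tau")] == 0.25

    def test_continuation_never_worsens(self, fitted_default):
        res2 = fit(fitted_default.problem, n_starts=0, seed=9, res_old=fitted_default)
        assert res2.value <= fitted_default.value

    def test_noise_free_objective_floor(self, scale, default_truth):
        # with sigma pinned at the (tiny) truth the objective cannot go
        # below the zero-residual closed form n ln(2 pi sigma^2)
        sigma = 1e-6
        table, _ = simulate(SimSpec(noise_sd=sigma, seed=6))
        se = np.full(table.n, sigma)
        table = TimeCourseTable(t=table.t, y=table.y, sigma_exp=se)
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        res = fit(problem, n_starts=20, seed=1)
        floor = table.n * np.log(2 * np.pi * sigma**2)
        assert res.value >= floor
        assert res.value <= floor + 2 * table.n  # residuals at the noise scale

    def test_sigma_stationarity(self):
        for seed in range(3):
            table, _ = simulate(SimSpec(seed=seed))
            problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
            res = fit(problem, n_starts=10, seed=seed)
            sigma_hat_sq = res.best[-1] ** 2
            assert sigma_hat_sq == pytest.approx(np.mean(res.residuals**2), rel=1e-4)

    def test_reproducibility_bit_identical(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose")
        a = fit(problem, n_starts=10, seed=7)
        b = fit(problem, n_starts=10, seed=7)
        assert np.array_equal(a.best, b.best)
        assert a.value == b.value

    def test_objective_monotone_along_accepted_iterates(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        trace = []

        def monitor(z):
            from rtfit.fitting import _internal_objective

            trace.append(_internal_objective(problem)(z)[0])

        fit(problem, n_starts=1, seed=1, callback=monitor)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_waterfall_plateau_on_default_fixture(self, noisy_table):
        table, _ = noisy_table
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        res = fit(problem, n_starts=50, seed=2)
        vals = res.sorted_values
        assert np.mean(vals <= vals[0] + 1e-3) >= 0.30

    def test_auto_signs_recover_inhibition(self, scale):
        truth = RTFParams(A=1.0, B=0.0, alpha=1.0, beta=1, gamma=1, tau=0.3, b=1.0,
                          signSus=-1)
        table, _ = simulate(SimSpec(truth=truth, noise_sd=0.005, seed=8))
        problem = build_problem(table, "singleDose")  # signs auto
        res = fit(problem, n_starts=16, seed=1)
        assert res.problem.sign_sus == -1

    def test_dose_dependent_low_noise_curve_recovery(self):
        # at near-zero noise the fitted dose-response surface reproduces
        # the generating surface even along sloppy parameter directions
        from rtfit.model import TimeScale, dose_rtf_evaluate
        from rtfit.simulate import default_dose_dependent_truth

        table, _ = simulate(
            SimSpec(mode="doseDependent", times=(11, 10.0), noise_sd=1e-4, seed=1)
        )
        problem = build_problem(table, "doseDependent", sign_sus=1, sign_trans=1)
        res = fit(problem, n_starts=20, seed=1)
        truth = default_dose_dependent_truth()
        scale = TimeScale(problem.T)
        truth_curve = dose_rtf_evaluate(truth, table.t, table.d, scale)
        fit_curve = dose_rtf_evaluate(res.best_params, table.t, table.d, scale)
        assert np.sqrt(np.mean((truth_curve - fit_curve) ** 2)) < 1e-3

    def test_low_noise_recovery(self, default_truth):
        # structural identifiability: at 0.01% noise the defaults are
        # recovered to a fraction of a percent
        table, _ = simulate(SimSpec(noise_sd=1e-4, seed=3))
        problem = build_problem(table, "singleDose", sign_sus=1, sign_trans=1)
        res = fit(problem, n_starts=30, seed=1)
        truth_vec = default_truth.to_vector()
        rel = np.abs(res.best[:7] - truth_vec) / np.maximum(np.abs(truth_vec), 1e-12)
        assert np.max(rel) < 0.05


class TestPredict:
    def test_training_points_match_residual_definition(self, fitted_default):
        table = fitted_default.problem.data
        pred = predict(fitted_default, table.t)
        assert np.allclose(table.y - pred, fitted_default.residuals)

    def test_time_zero_gives_offset(self, fitted_default):
        b = fitted_default.best[fitted_default.problem.index_of("b")]
        assert predict(fitted_default, [0.0])[0] == pytest.approx(b)

    def test_mode_errors(self, fitted_default):
        with pytest.raises(ValueError):
            predict(fitted_default, [0.0], doses=[1.0])

    def test_dose_predict_matches_expansion(self):
        table, _ = simulate(SimSpec(mode="doseDependent", times=(6, 10.0), seed=2))
        problem = build_problem(table, "doseDependent", sign_sus=1, sign_trans=1)
        res = fit(problem, n_starts=4, seed=1)
        times = np.array([0.0, 2.5, 10.0])
        d0 = float(np.unique(table.d)[1])
        from rtfit.model import TimeScale, dose_expand, rtf_evaluate

        direct = rtf_evaluate(
            dose_expand(res.best_params, d0), times, TimeScale(problem.T)
        )
        assert np.allclose(predict(res, times, [d0])[:, 0], direct)


def test_derived_seeds_are_stable_and_bounded():
    assert derive_seed(1, "a") == derive_seed(1, "a")
    assert derive_seed(1, "a") != derive_seed(2, "a")
    assert 0 <= derive_seed(123456789, "x", 7) < 2**31
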