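"""Balance sums, the sign condition and the light/energy solvers."""

import numpy as np
import pytest

import clockbalance as cb
from clockbalance.balance import (
    BalanceInfeasibleError,
    BalanceSpec,
    balance_sums,
    solvability_check,
    true_temperature_sums,
)
from clockbalance.sensitivity import hilbert_norm


class TestBalanceSums:
    def test_zero_derivative_gives_zero_sums(self, pc_rel, demo_model):
        spec = BalanceSpec(demo_model.light_params, np.zeros(3))
        report = balance_sums(pc_rel, spec)
        assert np.all(report.sums == 0)
        assert report.response_norm == 0

    def test_single_parameter_reads_off_column(self, pc_abs):
        name = pc_abs.param_names[4]
        report = balance_sums(pc_abs, BalanceSpec([name], np.array([1.0])))
        assert np.allclose(report.sums, pc_abs.W[:, 4])

    def test_linear_in_derivative(self, pc_rel, demo_model):
        rng = np.random.default_rng(3)
        d1, d2 = rng.standard_normal((2, 3))
        s = lambda d: balance_sums(pc_rel, BalanceSpec(demo_model.light_params, d)).sums
        assert np.allclose(s(2.5 * d1 - 0.7 * d2), 2.5 * s(d1) - 0.7 * s(d2))

    def test_unknown_parameter_rejected(self, pc_rel):
        with pytest.raises(KeyError):
            balance_sums(pc_rel, BalanceSpec(["nope"], np.array([1.0])))


class TestSolvabilityCheck:
    def test_uniform_sign_infeasible(self):
        W = np.array([[1.0, 2.0, 0.5], [1.0, -2.0, 0.5]])
        flags = solvability_check(W, [0, 1, 2])
        assert list(flags) == [False, True]

    def test_matches_bruteforce_on_random_rows(self):
        rng = np.random.default_rng(11)
        W = rng.standard_normal((100, 6))
        W[::7] = np.abs(W[::7])  # force some infeasible rows
        flags = solvability_check(W, np.arange(6))
        brute = np.array([(row > 0).any() and (row < 0).any() for row in W])
        assert np.array_equal(flags, brute)

    def test_weights_affect_signs(self):
        W = np.array([[1.0, -1.0]])
        assert solvability_check(W, [0, 1])[0]
        assert not solvability_check(W, [0, 1], weights=np.array([1.0, -1.0]))[0]


class TestLightBalance:
    def test_solved_weights_zero_leading_sums(self, demo_model, pc_rel):
        mod = cb.solve_light_balance(pc_rel, demo_model.light_params,
                                     fixed_c={"q2": 1.0}, r=2)
        assert mod.c["q2"] == 1.0
        report = balance_sums(
            pc_rel, BalanceSpec(demo_model.light_params, mod.c_vector(demo_model.light_params))
        )
        assert abs(report.sums[0]) < 1e-8
        assert abs(report.sums[1]) < 1e-8
        assert abs(report.sums[2]) > 1e-4  # untargeted component untouched

    def test_requires_relative_mode(self, pc_abs, demo_model):
        with pytest.raises(ValueError, match="relative"):
            cb.solve_light_balance(pc_abs, demo_model.light_params, fixed_c={"q2": 1.0}, r=2)

    def test_free_count_must_match_r(self, pc_rel, demo_model):
        with pytest.raises(ValueError, match="free weights"):
            cb.solve_light_balance(pc_rel, demo_model.light_params, fixed_c={}, r=2)

    def test_single_light_param_homogeneous_solution(self, demo_sens):
        # one light parameter and one equation: the only solution is c = 0,
        # i.e. full decoupling of the light amplitude
        pc = cb.principal_components(demo_sens, mode="relative")
        mod = cb.solve_light_balance(pc, ["q1"], fixed_c=None, r=1)
        assert mod.c["q1"] == pytest.approx(0.0, abs=1e-12)

    def test_solved_model_identical_at_alpha_one(self, demo_model, demo_orbit,
                                                 balanced_light_model):
        orbit_b = cb.find_entrained_orbit(
            balanced_light_model, alpha=1.0, x0=demo_orbit.x0, tol=1e-10
        )
        assert np.max(np.abs(orbit_b.values - demo_orbit.values)) < 1e-8

    def test_response_reduction_under_light_step(self, demo_model, demo_orbit,
                                                 balanced_light_model):
        # zeroing the two leading balance sums shrinks the realized response
        # to a sustained 5% light-amplitude step by well over half
        def response(model):
            up = cb.find_entrained_orbit(model, alpha=1.05, x0=demo_orbit.x0, tol=1e-11)
            base = cb.find_entrained_orbit(model, alpha=1.0, x0=demo_orbit.x0, tol=1e-11)
            return hilbert_norm(up.values - base.values, up.ts)

        ratio = response(balanced_light_model) / response(demo_model)
        assert ratio < 0.3


class TestArrheniusBalance:
    def test_zero_energies_zero_sums(self, pc_abs, demo_model, demo_k):
        report = cb.arrhenius_balance_sums(
            pc_abs, demo_model.temp_params, demo_k, np.zeros(5), T=288.15
        )
        assert np.all(report.sums == 0)

    def test_matches_bruteforce_dot_products(self, pc_abs, demo_model, demo_k):
        E = np.array([30.0, 45.0, 20.0, 60.0, 10.0])
        report = cb.arrhenius_balance_sums(pc_abs, demo_model.temp_params, demo_k, E, T=288.15)
        idx = [pc_abs.param_names.index(p) for p in demo_model.temp_params]
        kv = np.array([demo_k[p] for p in demo_model.temp_params])
        brute = pc_abs.W[:, idx] @ (kv * E)
        assert np.allclose(report.sums, brute)

    def test_lambda_scaling_exact(self, pc_abs, demo_model, demo_k):
        E = np.array([30.0, 45.0, 20.0, 60.0, 10.0])
        r1 = cb.arrhenius_balance_sums(pc_abs, demo_model.temp_params, demo_k, E, T=288.15)
        # a power-of-two factor keeps the scaling exact in floating point
        r2 = cb.arrhenius_balance_sums(pc_abs, demo_model.temp_params, demo_k, 2.0 * E, T=288.15)
        assert np.array_equal(r2.sums, 2.0 * r1.sums)
        r3 = cb.arrhenius_balance_sums(pc_abs, demo_model.temp_params, demo_k, 3.0 * E, T=288.15)
        assert np.allclose(r3.sums, 3.0 * r1.sums, rtol=1e-13)

    def test_true_sums_carry_rt2_factor(self, pc_abs, demo_model, demo_k):
        E = np.full(5, 30.0)
        report = cb.arrhenius_balance_sums(pc_abs, demo_model.temp_params, demo_k, E, T=290.15)
        truth = true_temperature_sums(report, 290.15)
        assert np.allclose(truth, report.sums / (cb.GAS_CONSTANT * 290.15**2))

    def test_day_night_blocks(self, pc_abs, demo_model):
        # separate day and night sums from the two parameter sets
        sched = cb.demo_temperature_schedule(demo_model, 40.0)
        E = {p: 40.0 for p in demo_model.temp_params}
        day = cb.arrhenius_balance_sums(
            pc_abs, demo_model.temp_params, sched.day_values(), E, T=sched.T_day
        )
        night = cb.arrhenius_balance_sums(
            pc_abs, demo_model.temp_params, sched.night_values(), E, T=sched.T_night
        )
        assert not np.allclose(day.sums, night.sums)


class TestEnergyBalance:
    def test_reduces_leading_weighted_sum(self, pc_abs, demo_model, demo_k):
        ea = cb.solve_energy_balance(pc_abs, demo_model.temp_params, demo_k, r=2)
        assert np.all(ea.E >= 1.0) and np.all(ea.E <= 150.0)
        baseline = cb.arrhenius_balance_sums(
            pc_abs, demo_model.temp_params, demo_k,
            np.full(5, float(np.mean(ea.E))), T=288.15,
        )
        solved = ea.report
        for i in range(2):
            num = abs(pc_abs.sigma[i] * solved.sums[i])
            den = abs(pc_abs.sigma[i] * baseline.sums[i])
            assert num <= den / 10.0

    def test_fixed_energies_respected(self, pc_abs, demo_model, demo_k):
        ea = cb.solve_energy_balance(
            pc_abs, demo_model.temp_params, demo_k, fixed_E={"m1": 40.0}, r=2
        )
        assert ea.as_dict()["m1"] == 40.0

    def test_target_mean_rescaling_keeps_balance(self, pc_abs, demo_model, demo_k):
        ea = cb.solve_energy_balance(
            pc_abs, demo_model.temp_params, demo_k, r=2, target_mean=30.0
        )
        assert np.mean(ea.E) == pytest.approx(30.0, rel=0.2)
        assert abs(ea.report.sums[0]) < 1e-10
        assert abs(ea.report.sums[1]) < 1e-10

    def test_infeasible_sign_pattern_raises(self, pc_abs, demo_model, demo_k):
        from dataclasses import replace

        W_pos = np.abs(pc_abs.W)
        pc_bad = replace(pc_abs, W=W_pos)
        with pytest.raises(BalanceInfeasibleError, match="sign condition"):
            cb.solve_energy_balance(pc_bad, demo_model.temp_params, demo_k, r=2)

    def test_iterative_rebalancing_converges(self, demo_model, demo_k, pc_abs):
        # refresh: recompute the decomposition with the temperature-sensitive
        # parameters set to their day-temperature Arrhenius values
        T_eval, T_ref = 290.15, 288.15

        def refresh(E_map):
            arr = {
                p: cb.ArrheniusParam(energy=E, k_ref=demo_k[p], T_ref=T_ref)
                for p, E in E_map.items()
            }
            k_new = demo_model.param_values.copy()
            k_eval = {p: cb.arrhenius_value(a, T_eval) for p, a in arr.items()}
            for p, v in k_eval.items():
                k_new[demo_model.param_index(p)] = v
            orbit = cb.find_entrained_orbit(demo_model, k=k_new)
            sens = cb.compute_sensitivities(orbit)
            return cb.principal_components(sens), k_eval

        ea = cb.solve_energy_balance(
            pc_abs, demo_model.temp_params, demo_k,
            r=2, refresh=refresh, max_iterations=20,
        )
        assert ea.converged
        assert ea.n_iterations <= 20
        assert abs(ea.report.sums[0]) < 1e-8
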