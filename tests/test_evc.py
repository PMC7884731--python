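"""EVC allocation model: closed-form checks and grid-oracle properties."""

import numpy as np
import pytest

from evcontrol.evc import (
    EvcParams,
    IncentiveCondition,
    evc_curve,
    optimal_control_surface,
    payoff,
    success_probability,
)

PARAMS = EvcParams()


class TestSuccessProbability:
    def test_logistic_midpoint(self):
        # linear predictor 0: intercept -1, slope 4, u = 0.25, congruent
        p = success_probability(0.25, "congruent", PARAMS)
        assert p == pytest.approx(0.5)

    def test_closed_form_value(self):
        # logistic(-1 + 4*0.5 - 2) = logistic(-1) = 0.26894...
        params = EvcParams(performance_intercept=-1, performance_slope=4,
                           congruency_penalty=1)
        p = success_probability(0.5, "incongruent", params)
        assert p == pytest.approx(1 / (1 + np.exp(1)), abs=1e-9)

    def test_monotone_in_control_and_congruency(self):
        u = np.linspace(0, 1, 50)
        for cong in ("congruent", "neutral", "incongruent"):
            p = success_probability(u, cong, PARAMS)
            assert np.all(np.diff(p) > 0)
        assert success_probability(1.0, "congruent", PARAMS) > success_probability(
            0.0, "congruent", PARAMS
        )
        assert (
            success_probability(0.5, "congruent", PARAMS)
            > success_probability(0.5, "neutral", PARAMS)
            > success_probability(0.5, "incongruent", PARAMS)
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            success_probability(-0.1, "neutral", PARAMS)
        with pytest.raises(ValueError):
            success_probability(1.1, "neutral", PARAMS)
        with pytest.raises(ValueError):
            success_probability(0.5, "sideways", PARAMS)


class TestPayoff:
    def test_zero_efficacy_flat(self):
        params = EvcParams(intrinsic_accuracy_value=0.0)
        cond = IncentiveCondition(reward_magnitude=1.0, efficacy=0.0)
        vals = payoff(np.linspace(0, 1, 11), cond, params)
        assert np.allclose(vals, 1.0 * params.noncontingent_reward_rate)

    def test_zero_reward_zero_intrinsic(self):
        params = EvcParams(intrinsic_accuracy_value=0.0)
        cond = IncentiveCondition(reward_magnitude=0.0, efficacy=1.0)
        assert np.allclose(payoff(np.linspace(0, 1, 11), cond, params), 0.0)

    def test_low_efficacy_shrinks_control_benefit(self):
        # relative payoff of high vs low control decreases with efficacy
        hi = IncentiveCondition(reward_magnitude=1.0, efficacy=1.0)
        lo = IncentiveCondition(reward_magnitude=1.0, efficacy=0.2)
        gain_hi = payoff(0.9, hi, PARAMS) - payoff(0.1, hi, PARAMS)
        gain_lo = payoff(0.9, lo, PARAMS) - payoff(0.1, lo, PARAMS)
        assert gain_lo < gain_hi

    def test_invalid_condition(self):
        with pytest.raises(ValueError):
            IncentiveCondition(reward_magnitude=1.0, efficacy=1.5)
        with pytest.raises(ValueError):
            IncentiveCondition(reward_magnitude=-0.1, efficacy=0.5)


class TestEvcCurve:
    def test_identity_payoff_minus_cost(self):
        cond = IncentiveCondition(reward_magnitude=1.0, efficacy=0.75)
        curve = evc_curve(cond, PARAMS)
        assert np.all(np.abs(curve.evc - (curve.payoff - curve.cost)) < 1e-12)

    def test_free_effort_max_control(self):
        params = EvcParams(cost_coefficient=0.0)
        cond = IncentiveCondition(reward_magnitude=1.0, efficacy=1.0)
        assert evc_curve(cond, params).u_star == 1.0

    def test_zero_efficacy_zero_intrinsic_no_control(self):
        params = EvcParams(intrinsic_accuracy_value=0.0)
        cond = IncentiveCondition(reward_magnitude=1.0, efficacy=0.0)
        assert evc_curve(cond, params).u_star == 0.0

    def test_curve_table_export(self):
        frame = evc_curve(IncentiveCondition(1.0, 1.0), PARAMS).to_frame()
        assert list(frame.columns) == ["u", "payoff", "cost", "evc"]
        assert len(frame) == 101
        assert np.allclose(frame.evc, frame.payoff - frame.cost)

    def test_grid_size_error(self):
        cond = IncentiveCondition(reward_magnitude=1.0, efficacy=1.0)
        with pytest.raises(ValueError):
            evc_curve(cond, PARAMS, grid_size=1)

    def test_reward_raises_allocated_control(self):
        hi = evc_curve(IncentiveCondition(1.00, 1.0), PARAMS).u_star
        lo = evc_curve(IncentiveCondition(0.10, 1.0), PARAMS).u_star
        assert hi > lo

    @pytest.mark.parametrize("reward,efficacy", [(0.1, 0.25), (1.0, 1.0),
                                                 (0.4, 0.5), (0.8, 0.75)])
    def test_grid_argmax_matches_fine_oracle(self, reward, efficacy):
        # brute-force oracle: a 10,001-point grid bounds the discretization
        cond = IncentiveCondition(reward, efficacy)
        coarse = evc_curve(cond, PARAMS, grid_size=101).u_star
        fine = evc_curve(cond, PARAMS, grid_size=10001).u_star
        assert abs(coarse - fine) <= 1.0 / 100 + 1e-12


class TestOptimalControlSurface:
    def test_single_cell_consistency(self):
        surf = optimal_control_surface([0.5], [0.5], PARAMS)
        expected = evc_curve(IncentiveCondition(0.5, 0.5), PARAMS).u_star
        assert surf.shape == (1, 1) and surf[0, 0] == expected

    def test_study3_surface_monotone(self):
        surf = optimal_control_surface(
            [0.10, 0.20, 0.40, 0.80], [0.25, 0.50, 0.75, 1.00], PARAMS
        )
        assert surf.shape == (4, 4)
        assert np.all(np.diff(surf, axis=0) >= 0)
        assert np.all(np.diff(surf, axis=1) >= 0)

    def test_doubling_rewards_never_decreases(self):
        rewards = [0.10, 0.20, 0.40, 0.80]
        effs = [0.25, 0.50, 0.75, 1.00]
        base = optimal_control_surface(rewards, effs, PARAMS)
        doubled = optimal_control_surface([2 * r for r in rewards], effs, PARAMS)
        assert np.all(doubled >= base)

    def test_monotone_20x20_sweep(self):
        rewards = np.linspace(0.05, 1.0, 20)
        effs = np.linspace(0.05, 1.0, 20)
        surf = optimal_control_surface(rewards, effs, PARAMS)
        assert np.all(np.diff(surf, axis=0) >= 0)
        assert np.all(np.diff(surf, axis=1) >= 0)

    def test_reward_efficacy_interaction(self):
        # the control boost from extra reward is larger under high efficacy
        surf = optimal_control_surface([0.10, 1.00], [0.25, 1.00], PARAMS)
        assert (surf[1, 1] - surf[0, 1]) >= (surf[1, 0] - surf[0, 0])

    def test_empty_levels_error(self):
        with pytest.raises(ValueError):
            optimal_control_surface([], [0.5], PARAMS)
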