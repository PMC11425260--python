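"""Unit and property tests for the two-pool calcium model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caflux.errors import InsufficientDataError, IntegrationError, ValidationError
from caflux.model import (
    CaState,
    ModelParams,
    SimSettings,
    classify_trajectory,
    condition_params,
    cycle_average,
    fixed_point,
    hill_activation,
    jacobian,
    rhs,
    simulate,
    stability,
    sweep,
)
from conftest import random_valid_params


class TestHillActivation:
    def test_zero_calcium_gives_zero(self):
        assert hill_activation(0.0, 1.3, 4) == 0.0

    def test_half_saturation_at_delta(self):
        assert hill_activation(1.3, 1.3, 4) == pytest.approx(0.5)

    def test_hand_value(self):
        # 1 / (1 + 1.3^4) evaluated by hand
        assert hill_activation(1.0, 1.3, 4) == pytest.approx(1.0 / (1.0 + 1.3**4), rel=1e-12)
        assert hill_activation(1.0, 1.3, 4) == pytest.approx(0.2593295, abs=1e-6)

    @pytest.mark.parametrize("bad", [(-0.1, 1.3, 4), (1.0, 0.0, 4), (1.0, -1.0, 4), (1.0, 1.3, 0)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValidationError):
            hill_activation(*bad)

    @given(
        ca=st.floats(0.0, 1e6, allow_nan=False),
        delta=st.floats(1e-3, 1e3),
        n=st.integers(1, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, ca, delta, n):
        h = hill_activation(ca, delta, n)
        assert 0.0 <= h <= 1.0  # sup is 1, approached to float precision
        assert hill_activation(ca + 0.5, delta, n) >= h


class TestRhs:
    def test_hand_value_at_zero_cytosol(self, control_params):
        # Hill and ca_i-proportional terms vanish: (k*100 + gamma, -(k*100)) = (3, -1)
        d = rhs(CaState(0.0, 100.0), control_params)
        assert d == pytest.approx((3.0, -1.0), rel=1e-12)

    def test_hand_value_at_empty_er(self, control_params):
        # ca_er=0 kills CICR and leak: d_ca_i = -k1*1.3 + gamma - beta*1.3
        #                                      = -2.6 + 2.0 - 2.6 = -3.2
        d = rhs(CaState(1.3, 0.0), control_params)
        assert d[0] == pytest.approx(-3.2, rel=1e-12)
        assert d[1] == pytest.approx(2.6, rel=1e-12)

    def test_mass_balance_identity_random(self, rng):
        # d_ca_i + d_ca_er == gamma - beta*ca_i exactly, 1000 random draws
        for _ in range(1000):
            p = random_valid_params(rng)
            s = CaState(float(rng.uniform(0, 10)), float(rng.uniform(0, 50)))
            d_i, d_er = rhs(s, p)
            assert d_i + d_er == pytest.approx(p.gamma - p.beta * s.ca_i, rel=1e-13, abs=1e-13)


class TestFixedPoint:
    def test_control_ca_i_is_one(self, control_params):
        assert fixed_point(control_params).ca_i == pytest.approx(1.0, abs=1e-15)

    def test_control_ca_er_closed_form(self, control_params):
        # 2 / (0.01 + 1.3 * hill(1.0)) computed by hand
        assert fixed_point(control_params).ca_er == pytest.approx(5.7615, abs=1e-3)

    def test_high_condition_ratio(self):
        p = condition_params("high").params
        assert fixed_point(p).ca_i == pytest.approx(2.1 / 1.9, rel=1e-12)

    def test_rhs_residual_random(self, rng):
        for _ in range(100):
            p = random_valid_params(rng)
            fp = fixed_point(p)
            d = rhs(fp, p)
            assert abs(d[0]) < 1e-10 and abs(d[1]) < 1e-10


class TestStability:
    def test_control_is_unstable_with_positive_trace(self, control_params):
        rep = stability(control_params)
        assert rep.classification == "unstable"
        # hand differentiation of the Jacobian at the control fixed point
        assert rep.jacobian_trace == pytest.approx(1.4075, abs=1e-3)

    def test_no_cicr_is_stable(self):
        p = ModelParams(alpha=1e-9)
        rep = stability(p)
        assert rep.classification == "stable"
        assert rep.jacobian_trace < 0

    def test_analytic_jacobian_matches_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(20):
            p = random_valid_params(rng)
            s = CaState(float(rng.uniform(0.1, 5)), float(rng.uniform(0.1, 20)))
            jac = jacobian(s, p)
            num = np.zeros((2, 2))
            for col, (dc, de) in enumerate([(eps, 0.0), (0.0, eps)]):
                up = rhs(CaState(s.ca_i + dc, s.ca_er + de), p)
                dn = rhs(CaState(s.ca_i - dc, s.ca_er - de), p)
                num[0, col] = (up[0] - dn[0]) / (2 * eps)
                num[1, col] = (up[1] - dn[1]) / (2 * eps)
            assert np.allclose(jac, num, rtol=1e-5, atol=1e-5)

    def test_classification_consistent_with_eigenvalues(self, rng):
        for _ in range(20):
            p = random_valid_params(rng)
            rep = stability(p)
            max_re = max(ev.real for ev in rep.eigenvalues)
            expected = "unstable" if max_re > 1e-9 else ("stable" if max_re < -1e-9 else "center/marginal")
            assert rep.classification == expected


class TestSimulate:
    def test_zero_duration_returns_init_only(self, control_params, default_init):
        traj = simulate(control_params, default_init, duration=0.0)
        assert len(traj) == 1
        assert traj.ca_i[0] == default_init.ca_i

    def test_first_state_equals_init(self, control_params, default_init):
        traj = simulate(control_params, default_init, duration=1.0)
        assert traj.ca_i[0] == default_init.ca_i and traj.ca_er[0] == default_init.ca_er

    def test_self_convergence_on_dt_halving(self, control_params, default_init):
        a = simulate(control_params, default_init, duration=20.0, dt=2e-3)
        b = simulate(control_params, default_init, duration=20.0, dt=1e-3)
        assert abs(a.ca_i[-1] - b.ca_i[-1]) < 1e-6

    def test_fourth_order_error_decay(self, control_params, default_init):
        ref = simulate(control_params, default_init, duration=10.0, dt=1e-4)
        errs = []
        for dt in (4e-3, 2e-3, 1e-3):
            t = simulate(control_params, default_init, duration=10.0, dt=dt)
            errs.append(abs(t.ca_i[-1] - ref.ca_i[-1]))
        # halving dt should shrink the endpoint error by ~2^4
        assert errs[0] / errs[1] > 8
        assert errs[1] / errs[2] > 8

    def test_stable_variant_converges_to_fixed_point(self):
        # CICR off; leak raised so the ER relaxes well within the window
        p = ModelParams(alpha=1e-9, k=0.5)
        fp = fixed_point(p)
        traj = simulate(p, CaState(0.1, 5.0), duration=200.0, dt=1e-3)
        assert abs(traj.ca_i[-1] - fp.ca_i) < 1e-6
        assert abs(traj.ca_er[-1] - fp.ca_er) < 1e-6

    def test_adaptive_matches_rk4(self, control_params, default_init):
        a = simulate(control_params, default_init, duration=30.0, dt=1e-3)
        b = simulate(control_params, default_init, duration=30.0, dt=1e-3, method="adaptive")
        assert abs(a.ca_i[-1] - b.ca_i[-1]) < 1e-4

    def test_nonnegativity_random_inits(self, control_params, rng):
        for _ in range(10):
            init = CaState(float(rng.uniform(0, 10)), float(rng.uniform(0, 10)))
            traj = simulate(control_params, init, duration=50.0, dt=1e-3)
            assert traj.ca_i.min() > -1e-12 and traj.ca_er.min() > -1e-12

    def test_unstable_step_raises_named_time(self, control_params, default_init):
        with pytest.raises(IntegrationError, match="t="):
            simulate(control_params, default_init, duration=100.0, dt=5.0)

    def test_invalid_settings(self, control_params, default_init):
        with pytest.raises(ValidationError):
            simulate(control_params, default_init, duration=-1.0)
        with pytest.raises(ValidationError):
            simulate(control_params, default_init, duration=1.0, dt=0.0)


class TestCycleAverage:
    def test_stable_variant_plateau_equals_gamma_over_beta(self):
        p = ModelParams(alpha=1e-9, k=0.5)
        traj = simulate(p, CaState(0.1, 5.0), duration=200.0, dt=1e-3)
        assert cycle_average(traj) == pytest.approx(p.gamma / p.beta, rel=1e-6)

    @pytest.mark.parametrize("label", ["low", "control", "high"])
    def test_condition_average_is_gamma_over_beta(self, label):
        p = condition_params(label).params
        traj = simulate(p, CaState(0.1, 5.0), duration=300.0, dt=1e-3)
        assert classify_trajectory(traj) == "oscillatory"
        assert cycle_average(traj) == pytest.approx(p.gamma / p.beta, rel=0.01)

    def test_too_short_window_raises(self, control_params, default_init):
        traj = simulate(control_params, default_init, duration=5.0, dt=1e-3)
        with pytest.raises(InsufficientDataError):
            cycle_average(traj)

    def test_attractor_independent_of_init(self, control_params, rng):
        # the cycle-average law holds from any positive start
        for _ in range(3):
            init = CaState(float(rng.uniform(0.05, 5)), float(rng.uniform(0.5, 10)))
            traj = simulate(control_params, init, duration=300.0, dt=1e-3)
            assert cycle_average(traj) == pytest.approx(1.0, rel=0.01)


class TestConditions:
    def test_control_values(self):
        c = condition_params("control")
        assert c.params.beta == 2.0 and c.params.gamma == 2.0

    def test_antagonistic_pairing(self):
        hi, lo = condition_params("high").params, condition_params("low").params
        assert (hi.gamma, hi.beta) == (2.1, 1.9)
        assert (lo.gamma, lo.beta) == (1.9, 2.1)
        assert hi.gamma / hi.beta > lo.gamma / lo.beta

    def test_shared_defaults_across_conditions(self):
        for label in ("low", "control", "high"):
            p = condition_params(label).params
            assert (p.alpha, p.n, p.delta, p.k, p.k1) == (1.3, 4, 1.3, 0.01, 2.0)

    def test_unknown_label(self):
        with pytest.raises(ValidationError):
            condition_params("medium")


class TestSweep:
    SETTINGS = SimSettings(duration=200.0)

    def test_conditions_strictly_ordered(self):
        rows = []
        for label in ("low", "control", "high"):
            p = condition_params(label).params
            tab = sweep([p.beta], [p.gamma], self.SETTINGS)
            rows.append(float(tab.mean_ca_i_uM.iloc[0]))
        assert rows[0] < rows[1] < rows[2]

    def test_doubling_beta_halves_mean(self):
        tab = sweep([2.0, 4.0], [2.0], self.SETTINGS)
        means = dict(zip(tab.beta_per_s, tab.mean_ca_i_uM))
        assert means[4.0] == pytest.approx(means[2.0] / 2.0, rel=0.02)

    def test_single_point_control(self):
        tab = sweep([2.0], [2.0], self.SETTINGS)
        assert len(tab) == 1
        assert tab.mean_ca_i_uM.iloc[0] == pytest.approx(1.0, rel=0.01)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            sweep([], [2.0])


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"beta": 0.0}, {"alpha": -1.0}, {"gamma": float("nan")},
        {"n": 0}, {"delta": 0.0}, {"k1": -2.0},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValidationError):
            ModelParams(**kwargs)

    def test_negative_state(self):
        with pytest.raises(ValidationError):
            CaState(-0.1, 1.0)
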