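"""One-step maps: weights, closed forms, invariance and absorption."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epibim import (
    DomainViolationError,
    EpidemicParams,
    InvalidInputError,
    StepInputs,
    StepSizeWarning,
    bim_step_sir,
    bim_step_sis,
    bim_weight_sir,
    bim_weight_sis,
    builtin_rates,
    em_step,
    generate_increments,
    implicit_residual_sir,
    implicit_residual_sis,
    in_domain,
    simulate_path,
)
from conftest import random_states


STEP = dict(dt=0.01, dW1=0.1, dW2=-0.2)


class TestWeights:
    def test_sir_worked_example(self, eq46_params, const_rates):
        # (alpha+gamma+mu+beta*I)dt + K|F1 dW1| + (K/R)|F2 dW2|
        #   = 27.013*0.01 + 200*0.001 + 4*0.002
        w = bim_weight_sir([100, 50, 50], eq46_params, const_rates, StepInputs(**STEP))
        assert float(w.a_n) == pytest.approx(0.47813, rel=1e-12)
        assert float(w.damping) * (1 + float(w.a_n)) == pytest.approx(1.0, rel=1e-12)

    def test_sis_worked_example(self, eq46_params, const_rates):
        w = bim_weight_sis([190, 10], eq46_params, const_rates, StepInputs(**STEP))
        assert float(w.a_n) == pytest.approx(0.26213 + 0.2 + 0.4 / 190, rel=1e-12)

    def test_floor_when_noise_and_infectives_vanish(self, eq46_params, const_rates):
        step = StepInputs(dt=0.01, dW1=0.0, dW2=0.0)
        w = bim_weight_sir([100, 0, 50], eq46_params, const_rates, step)
        assert float(w.a_n) == pytest.approx(eq46_params.loss_rate * 0.01, rel=1e-12)

    def test_invariant_under_increment_sign_flip(self, eq46_params, const_rates):
        a = bim_weight_sir([100, 50, 50], eq46_params, const_rates, StepInputs(0.01, 0.3, -0.7))
        b = bim_weight_sir([100, 50, 50], eq46_params, const_rates, StepInputs(0.01, -0.3, 0.7))
        assert float(a.a_n) == float(b.a_n)

    def test_nonpositive_divisor_rejected(self, eq46_params, const_rates):
        with pytest.raises(DomainViolationError):
            bim_weight_sir([100, 50, 0], eq46_params, const_rates, StepInputs(**STEP))
        with pytest.raises(DomainViolationError):
            bim_weight_sis([0, 50], eq46_params, const_rates, StepInputs(**STEP))

    def test_large_step_warns(self):
        with pytest.warns(StepSizeWarning):
            StepInputs(dt=2.0, dW1=0.0, dW2=0.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(InvalidInputError):
            StepInputs(dt=0.0, dW1=0.0, dW2=0.0)


def _explicit_sir_oracle(x, p, f1, f2, dt, dW1, dW2):
    # direct transcription of the closed-form update, kept independent of the
    # package's internal grouping
    S, I, R = x
    A = (p.alpha + p.gamma + p.mu + p.beta * I) * dt \
        + p.K * abs(f1 * dW1) + (p.K / R) * abs(f2 * dW2)
    damp = 1.0 / (1.0 + A)
    return np.array([
        S + damp * ((-p.beta * S * I + p.mu * (p.K - S)) * dt - S * I * f1 * dW1),
        I + damp * ((p.beta * S * I - (p.alpha + p.gamma + p.mu) * I) * dt
                    + S * I * f1 * dW1 - I * f2 * dW2),
        R + damp * ((p.alpha * I - p.mu * R) * dt + I * f2 * dW2),
    ])


class TestBimSteps:
    def test_sir_worked_example(self, eq46_params, const_rates):
        y = bim_step_sir([100, 50, 50], eq46_params, const_rates, StepInputs(**STEP))
        expected = _explicit_sir_oracle((100, 50, 50), eq46_params, 0.01, 0.01, 0.01, 0.1, -0.2)
        np.testing.assert_allclose(y, expected, rtol=1e-13)
        # frozen values of the hand-evaluated closed form
        np.testing.assert_allclose(
            y, [95.94961200976910, 45.32754223241528, 54.32539763079026], rtol=1e-12
        )
        assert y.sum() <= eq46_params.K

    def test_sis_worked_example(self, eq46_params, const_rates):
        y = bim_step_sis([190, 10], eq46_params, const_rates, StepInputs(**STEP))
        p = eq46_params
        A = 0.26213 + 0.2 + 0.4 / 190
        damp = 1 / (1 + A)
        n1, n2 = 190 * 10 * 0.01 * 0.1, 10 * 0.01 * -0.2
        expected = [
            190 + damp * ((-p.beta * 1900 + p.mu * 10 + p.alpha * 10) * 0.01 - n1 + n2),
            10 + damp * ((p.beta * 1900 - p.loss_rate * 10) * 0.01 + n1 - n2),
        ]
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    def test_small_step_continuity(self, eq46_params, const_rates):
        y = bim_step_sir([100, 50, 50], eq46_params, const_rates, StepInputs(1e-12, 0.0, 0.0))
        np.testing.assert_allclose(y, [100, 50, 50], rtol=1e-9)

    def test_zero_infectives_absorbing(self, eq46_params, const_rates):
        y = bim_step_sir([100, 0, 50], eq46_params, const_rates, StepInputs(0.5, 3.0, -4.0))
        assert y[1] == 0.0
        y = bim_step_sis([100, 0], eq46_params, const_rates, StepInputs(0.5, 3.0, -4.0))
        assert y[1] == 0.0
        # S follows the damped pure-renewal update (the weight keeps its
        # noise terms even at I=0)
        p = eq46_params
        A = p.loss_rate * 0.5 + p.K * abs(0.01 * 3.0) + (p.K / 100) * abs(0.01 * -4.0)
        assert y[0] == pytest.approx(100 + p.mu * (p.K - 100) * 0.5 / (1 + A), rel=1e-12)

    def test_disease_free_fixed_point_without_noise(self, eq46_params, const_rates):
        y = bim_step_sis([200, 0], eq46_params, const_rates, StepInputs(0.1, 0.0, 0.0))
        np.testing.assert_array_equal(y, [200, 0])

    def test_out_of_domain_input_rejected(self, eq46_params, const_rates):
        with pytest.raises(DomainViolationError):
            bim_step_sir([-5, 10, 10], eq46_params, const_rates, StepInputs(**STEP))


class TestImplicitExplicitEquivalence:
    @pytest.mark.parametrize("model", ["sir", "sis"])
    def test_residual_vanishes_at_closed_form(self, model, eq46_params):
        # the closed-form update solves the implicit balanced relation:
        # residual <= 1e-10 relative at 1e4 random (state, dt, increment) triples
        p = eq46_params
        rng = np.random.default_rng(7)
        n = 10_000
        x = random_states(rng, n, model, p.K)
        dt = 10.0 ** rng.uniform(-4, 0.5, n)
        dW = rng.normal(0, np.sqrt(dt)[:, None] * 10, (n, 2))
        rates = builtin_rates("sis-linear" if model == "sis" else "sir-linear-indicator", p)
        with pytest.warns(StepSizeWarning):
            step = StepInputs(dt=dt, dW1=dW[:, 0], dW2=dW[:, 1])
        if model == "sir":
            y = bim_step_sir(x, p, rates, step)
            res = implicit_residual_sir(x, y, p, rates, step)
        else:
            y = bim_step_sis(x, p, rates, step)
            res = implicit_residual_sis(x, y, p, rates, step)
        rel = np.abs(res) / (1.0 + np.abs(y))
        assert rel.max() <= 1e-10


class TestEulerComparator:
    def test_worked_example_is_undamped_update(self, eq46_params, const_rates):
        y = em_step([100, 50, 50], eq46_params, const_rates, StepInputs(**STEP), "sir")
        np.testing.assert_allclose(y, [94.013, 43.0935, 56.3935], rtol=1e-12)

    def test_vanishing_step_is_identity(self, eq46_params, const_rates):
        y = em_step([100, 50, 50], eq46_params, const_rates, StepInputs(1e-300, 0.0, 0.0), "sir")
        np.testing.assert_allclose(y, [100, 50, 50], rtol=1e-12)

    def test_leaves_domain_where_bim_does_not(self, eq46_params):
        # large recovery-channel increment drives I negative under Euler
        rates = builtin_rates("constant", eq46_params, c1=0.0, c2=1.0)
        step = StepInputs(dt=0.1, dW1=0.0, dW2=2.0)
        y_em = em_step([100, 10], eq46_params, rates, step, "sis")
        assert not in_domain(y_em, "sis", eq46_params.K).ok
        y_bim = bim_step_sis([100, 10], eq46_params, rates, step)
        assert in_domain(y_bim, "sis", eq46_params.K).ok


class TestDampingMonotonicity:
    @settings(derandomize=True, max_examples=100)
    @given(
        base=st.floats(min_value=0.0, max_value=5.0),
        extra=st.floats(min_value=0.0, max_value=5.0),
        channel=st.sampled_from([0, 1]),
    )
    def test_larger_increments_never_increase_damping(self, base, extra, channel):
        eq46_params = EpidemicParams(alpha=13, beta=0.02, gamma=13, mu=0.013, K=200)
        const_rates = builtin_rates("constant", eq46_params, c1=0.01, c2=0.01)
        dw = [0.3, -0.4]
        dw2 = list(dw)
        dw[channel] = base * np.sign(dw[channel] or 1)
        dw2[channel] = (base + extra) * np.sign(dw2[channel] or 1)
        w1 = bim_weight_sir([100, 50, 50], eq46_params, const_rates, StepInputs(0.01, *dw))
        w2 = bim_weight_sir([100, 50, 50], eq46_params, const_rates, StepInputs(0.01, *dw2))
        assert float(w2.damping) <= float(w1.damping)


class TestSimulatePath:
    def test_replay_is_bit_identical(self, eq46_params, const_rates):
        incs = generate_increments(1.0, 100, 1, seed=3).path(0)
        a = simulate_path("sis", eq46_params, const_rates, "bim", (190, 10), 0.01, incs)
        b = simulate_path("sis", eq46_params, const_rates, "bim", (190, 10), 0.01, incs)
        np.testing.assert_array_equal(a.states, b.states)

    def test_single_step_matches_one_step_map(self, eq46_params, const_rates):
        inc = np.array([[0.1, -0.2]])
        traj = simulate_path("sis", eq46_params, const_rates, "bim", (190, 10), 0.01, inc)
        y = bim_step_sis([190, 10], eq46_params, const_rates, StepInputs(0.01, 0.1, -0.2))
        np.testing.assert_array_equal(traj.states[1], y)

    def test_zero_increments_at_disease_free_is_constant(self, eq46_params, const_rates):
        traj = simulate_path(
            "sis", eq46_params, const_rates, "bim", (200, 0), 0.01, np.zeros((50, 2))
        )
        assert np.all(traj.states == [200, 0])

    def test_em_exits_are_flagged_not_rejected(self, eq46_params):
        rates = builtin_rates("constant", eq46_params, c1=0.0, c2=1.0)
        inc = np.array([[0.0, 2.0], [0.0, 0.0]])
        traj = simulate_path("sis", eq46_params, rates, "em", (100, 10), 0.1, inc)
        assert traj.exited.any()


class TestPopulationIdentity:
    @pytest.mark.parametrize("model", ["sir", "sis"])
    def test_total_population_follows_damped_renewal(self, model, eq46_params):
        # N_{n+1} = N_n + dt*(mu*(K-N_n) - gamma*I_n)/(1+A_n), both models
        p = eq46_params
        rates = builtin_rates("sis-linear" if model == "sis" else "constant", p)
        rng = np.random.default_rng(11)
        n = 5_000
        x = random_states(rng, n, model, p.K)
        dt = 10.0 ** rng.uniform(-3, 0, n)
        dW = rng.normal(0, np.sqrt(dt)[:, None], (n, 2))
        step = StepInputs(dt=dt, dW1=dW[:, 0], dW2=dW[:, 1])
        if model == "sir":
            from epibim import bim_weight_sir as weight, bim_step_sir as stepper
        else:
            from epibim import bim_weight_sis as weight, bim_step_sis as stepper
        w = weight(x, p, rates, step)
        y = stepper(x, p, rates, step)
        n_new = y.sum(axis=-1)
        n_old = x.sum(axis=-1)
        expected = n_old + dt * (p.mu * (p.K - n_old) - p.gamma * x[:, 1]) * np.asarray(w.damping)
        np.testing.assert_allclose(n_new, expected, rtol=1e-10)
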