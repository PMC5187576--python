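"""Plant model tests: closed forms, superposition, convergence, stability."""

import numpy as np
import pytest

from cerebloop import (
    ExperimentConfig,
    MotorParams,
    MotorState,
    RobotParams,
    RobotState,
    TipOverError,
    motor_mossy_spec,
    motor_step,
    robot_mossy_spec,
    robot_step,
    run_trial,
)
from cerebloop.plants import robot_drift_matrix
from cerebloop.teaching import CFMode


class TestMotor:
    def test_equilibrium_at_rest(self):
        p = MotorParams()
        s = motor_step(MotorState(), 0.0, p)
        assert s.phi == 0.0 and s.phi_dot == 0.0

    def test_steady_state_velocity(self):
        p = MotorParams()
        s = MotorState()
        for _ in range(2000):  # 20 s >> J/B = 50 ms
            s = motor_step(s, 0.2, p)
        assert s.phi_dot == pytest.approx(p.Kt * 0.2 / p.B, rel=1e-9)

    def test_step_response_matches_linear_ode_solution(self):
        p = MotorParams()
        i = 0.5
        s = MotorState()
        for k in range(1, 101):
            s = motor_step(s, i, p)
            t = 0.01 * k
            expected = (p.Kt * i / p.B) * (1.0 - np.exp(-p.B * t / p.J))
            assert s.phi_dot == pytest.approx(expected, abs=1e-6)

    def test_superposition(self, rng):
        p = MotorParams()
        i1, i2 = rng.normal(0, 0.3, (2, 50))
        def rollout(currents):
            s = MotorState()
            out = []
            for i in currents:
                s = motor_step(s, i, p)
                out.append([s.phi, s.phi_dot])
            return np.array(out)
        np.testing.assert_allclose(
            rollout(i1) + rollout(i2), rollout(i1 + i2), atol=1e-9
        )

    def test_inner_step_convergence(self):
        coarse = MotorParams(dt_inner=1e-3)
        fine = MotorParams(dt_inner=5e-4)
        s1, s2 = MotorState(), MotorState()
        for k in range(1000):  # 10 s of sinusoidal drive
            i = 0.3 * np.sin(2 * np.pi * 0.5 * 0.01 * k)
            s1 = motor_step(s1, i, coarse)
            s2 = motor_step(s2, i, fine)
        assert abs(s1.phi - s2.phi) < 1e-6

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            motor_step(MotorState(phi=np.nan), 0.0, MotorParams())


class TestRobot:
    def test_upright_equilibrium_exact(self):
        s = robot_step(RobotState(), 0.0, RobotParams())
        assert s.phi == 0.0 and s.theta == 0.0 and s.theta_dot == 0.0

    def test_open_loop_unstable_eigenvalue(self):
        a = robot_drift_matrix(RobotParams())
        assert np.max(np.linalg.eigvals(a).real) > 1.0

    def test_small_tilt_grows_monotonically(self):
        # open loop; 0.25 s keeps the divergence below the tip-over limit
        p = RobotParams()
        s = RobotState(theta=0.01)
        prev = 0.01
        for _ in range(25):
            s = robot_step(s, 0.0, p)
            assert abs(s.theta) > prev
            prev = abs(s.theta)

    def test_superposition(self, rng):
        p = RobotParams()
        i1, i2 = rng.normal(0, 0.02, (2, 20))
        def rollout(currents):
            s = RobotState()
            out = []
            for i in currents:
                s = robot_step(s, i, p)
                out.append([s.phi, s.phi_dot, s.theta, s.theta_dot])
            return np.array(out)
        np.testing.assert_allclose(rollout(i1) + rollout(i2), rollout(i1 + i2), atol=1e-9)

    def test_tip_over_raises_with_time(self):
        p = RobotParams()
        s = RobotState(theta=0.2)
        with pytest.raises(TipOverError) as err:
            t = 0.0
            for _ in range(200):
                s = robot_step(s, 0.0, p, time=t)
                t += 0.01
        assert err.value.time > 0

    def test_pd_alone_balances_design_trajectory(self):
        """The published PD gains keep the robot up on the 0.1-Hz design
        sinusoid with the cerebellum disconnected."""
        cfg = ExperimentConfig(
            plant_kind="robot", cf_mode=CFMode.NONE, frequency=0.1, n_cycles=10
        )
        trial = run_trial(cfg, 1, cerebellum_enabled=False)
        assert not trial.failed
        assert np.max(np.abs(trial.theta)) < RobotParams().theta_limit


class TestMossySpecs:
    def test_channel_counts(self):
        assert len(motor_mossy_spec()) == 5
        assert len(robot_mossy_spec()) == 7

    def test_efference_copy_is_last_channel(self):
        for spec in (motor_mossy_spec(), robot_mossy_spec()):
            assert spec.selectors[-1] == "efference"

    def test_gain_vectors(self):
        np.testing.assert_allclose(motor_mossy_spec().gains, [0.1, 0.19, 0.5, 0.07, 1.0])
        np.testing.assert_allclose(
            robot_mossy_spec().gains, [0.03, 0.04, 1.0, 0.5, 0.1, 0.2, 0.5]
        )
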