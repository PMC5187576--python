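"""Simulated control plants: a brushed DC motor shaft and a two-wheeled
balancing robot (wheeled inverted pendulum).

Both are linear ODE systems integrated with fixed-step RK4 at ``dt_inner``
under zero-order-hold current over each 10-ms control period.

Motor (shaft angle phi):       J*phi'' = Kt*i - B*phi'

Robot (wheel angle phi, body tilt theta), the standard linearized
wheeled-inverted-pendulum pair::

    (I_w + (m_w + m_b) r^2) phi'' + m_b r l theta''      = tau
    (I_b + m_b l^2) theta'' + m_b r l phi'' - m_b g l theta = -tau

with the wheel-motor polarity tau = -Kt*i: relative to the rotation sense
in which the encoders count positive, a positive current torques the wheel
axle in the negative direction.  Of the two possible polarities this is
the one under which the standard PD gains (stiff tilt controller plus weak
wheel-position controller) stabilize the pendulum — on balancing robots
the effective current-to-wheel-position gain under a stabilized tilt is
inverted, so the hardware must have realized this polarity.  Upright is an
unstable equilibrium (gravity term +m_b*g*l*theta in the tilt dynamics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "MotorParams",
    "RobotParams",
    "MotorState",
    "RobotState",
    "MossyFiberSpec",
    "TipOverError",
    "motor_step",
    "robot_step",
    "robot_drift_matrix",
    "motor_mossy_spec",
    "robot_mossy_spec",
]


@dataclass(frozen=True)
class MotorParams:
    """DC-motor constants: rotor+shaft inertia J (kg m^2), viscous friction
    B (N m s) and torque constant Kt (N m/A).

    Defaults model a small hobby-class brushed motor with a light shaft:
    the PD position loop over it has a natural frequency of ~4.5 Hz, so a
    0.5-Hz sinusoid is tracked competently but with a clearly visible
    error for the cerebellar pathway to learn away.
    """

    J: float = 1e-5
    B: float = 2e-4
    Kt: float = 0.01
    dt_inner: float = 1e-3

    def __post_init__(self):
        if min(self.J, self.B, self.Kt, self.dt_inner) <= 0:
            raise ValueError("all motor constants must be > 0")


@dataclass(frozen=True)
class RobotParams:
    """Wheeled-inverted-pendulum constants.

    m_b/m_w: body and wheel mass (kg); r: wheel radius (m); l: axle-to-COM
    distance (m); I_b/I_w: body and wheel inertia (kg m^2); Kt: torque per
    ampere.  ``theta_limit`` is the tip-over tilt beyond which a trial is
    declared failed.
    """

    m_b: float = 0.8
    m_w: float = 0.05
    r: float = 0.025
    l: float = 0.1
    I_b: float = field(default=0.8 * 0.1**2 / 3)
    I_w: float = field(default=0.05 * 0.025**2 / 2)
    g: float = 9.81
    Kt: float = 0.1
    dt_inner: float = 1e-3
    theta_limit: float = np.pi / 4

    def __post_init__(self):
        vals = (self.m_b, self.m_w, self.r, self.l, self.I_b, self.I_w, self.g, self.Kt,
                self.dt_inner, self.theta_limit)
        if min(vals) <= 0:
            raise ValueError("all robot constants must be > 0")


@dataclass
class MotorState:
    phi: float = 0.0
    phi_dot: float = 0.0


@dataclass
class RobotState:
    phi: float = 0.0
    phi_dot: float = 0.0
    theta: float = 0.0
    theta_dot: float = 0.0


class TipOverError(RuntimeError):
    """Raised when the robot's tilt exceeds the tip-over limit."""

    def __init__(self, time: float):
        super().__init__(f"robot tipped over at t = {time:.3f} s")
        self.time = time


def _rk4_propagator(
    a: np.ndarray, b: np.ndarray, dt: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact one-control-period map of fixed-step RK4 on x' = A x + B u.

    For a linear system under zero-order-hold input, one RK4 substep is the
    affine map x -> P1 x + Q1 u with P1 the degree-4 Taylor polynomial of
    exp(dt A); composing n substeps gives x -> P1^n x + (sum P1^j) Q1 u.
    Identical (in exact arithmetic) to looping RK4, but one matrix-vector
    product per control period.
    """
    dim = a.shape[0]
    ident = np.eye(dim)
    da = dt * a
    p1 = ident + da @ (ident + da @ (ident + da @ (ident + da / 4.0) / 3.0) / 2.0)
    q1 = dt * (ident + da @ (ident + da @ (ident + da / 4.0) / 3.0) / 2.0) @ b
    p = ident
    geom = np.zeros((dim, dim))
    for _ in range(n_steps):
        geom = geom + p
        p = p1 @ p
    return p, geom @ q1


@lru_cache(maxsize=32)
def _motor_propagator(params: MotorParams, control_period: float):
    a = np.array([[0.0, 1.0], [0.0, -params.B / params.J]])
    b = np.array([0.0, params.Kt / params.J])
    return _rk4_propagator(a, b, params.dt_inner,
                           _n_substeps(control_period, params.dt_inner))


@lru_cache(maxsize=32)
def _robot_propagator(params: RobotParams, control_period: float):
    a = robot_drift_matrix(params)
    minv, _ = _robot_matrices(params)
    # per unit current: tau = -Kt*i enters the wheel equation as +tau and
    # the tilt equation as -tau
    acc = minv @ np.array([-params.Kt, params.Kt])
    b = np.array([0.0, acc[0], 0.0, acc[1]])
    return _rk4_propagator(a, b, params.dt_inner,
                           _n_substeps(control_period, params.dt_inner))


def _n_substeps(control_period: float, dt_inner: float) -> int:
    n = control_period / dt_inner
    n_round = round(n)
    if n_round < 1 or abs(n - n_round) > 1e-9 * max(1, n_round):
        raise ValueError(
            f"dt_inner = {dt_inner} must divide the control period {control_period}"
        )
    return n_round


def motor_step(
    state: MotorState, current: float, params: MotorParams, control_period: float = 0.010
) -> MotorState:
    """Integrate the motor ODE for one control period under constant current."""
    if not (np.isfinite(state.phi) and np.isfinite(state.phi_dot) and np.isfinite(current)):
        raise FloatingPointError("non-finite motor state or command")
    p, q = _motor_propagator(params, control_period)
    x = p @ np.array([state.phi, state.phi_dot]) + q * current
    return MotorState(phi=float(x[0]), phi_dot=float(x[1]))


def _robot_matrices(params: RobotParams) -> tuple[np.ndarray, np.ndarray]:
    """Inverse mass matrix and gravity coefficient of the linearized robot."""
    m11 = params.I_w + (params.m_w + params.m_b) * params.r**2
    m12 = params.m_b * params.r * params.l
    m22 = params.I_b + params.m_b * params.l**2
    mass = np.array([[m11, m12], [m12, m22]])
    return np.linalg.inv(mass), np.array([0.0, params.m_b * params.g * params.l])


def robot_drift_matrix(params: RobotParams) -> np.ndarray:
    """Open-loop state matrix A for state (phi, phi_dot, theta, theta_dot).

    Used to verify instability: A must have an eigenvalue with positive
    real part for the shipped defaults.
    """
    minv, grav = _robot_matrices(params)
    a = np.zeros((4, 4))
    a[0, 1] = 1.0
    a[2, 3] = 1.0
    # accelerations from the gravity term (proportional to theta); the
    # torque enters as [tau, -tau] with tau = -Kt*i (see module docstring)
    acc = minv @ grav
    a[1, 2] = acc[0]
    a[3, 2] = acc[1]
    return a


def robot_step(
    state: RobotState,
    current: float,
    params: RobotParams,
    control_period: float = 0.010,
    time: float = 0.0,
) -> RobotState:
    """Integrate the robot ODE for one control period under constant current.

    Raises :class:`TipOverError` (carrying the failure time) if the tilt
    magnitude reaches ``params.theta_limit`` at the end of the period.
    """
    vec = np.array([state.phi, state.phi_dot, state.theta, state.theta_dot])
    if not (np.all(np.isfinite(vec)) and np.isfinite(current)):
        raise FloatingPointError("non-finite robot state or command")
    if abs(state.theta) >= params.theta_limit:
        raise TipOverError(time)
    p, q = _robot_propagator(params, control_period)
    x = p @ vec + q * current
    new = RobotState(phi=float(x[0]), phi_dot=float(x[1]), theta=float(x[2]),
                     theta_dot=float(x[3]))
    if abs(new.theta) >= params.theta_limit:
        raise TipOverError(time + control_period)
    return new


@dataclass(frozen=True)
class MossyFiberSpec:
    """Ordered mossy-fiber channels: (name, source-signal selector, gain).

    Selectors are keys into the dictionary of raw signals assembled each
    control step (desired kinematics, kinematic errors and the efference
    copy of the previous total motor command).  Gains normalize each
    channel's physical units before the shared sigmoidal encoding.
    """

    channels: tuple

    @property
    def names(self):
        return tuple(name for name, _, _ in self.channels)

    @property
    def selectors(self):
        return tuple(sel for _, sel, _ in self.channels)

    @property
    def gains(self) -> np.ndarray:
        return np.array([gain for _, _, gain in self.channels])

    def raw_vector(self, signals: dict) -> np.ndarray:
        return np.array([signals[sel] for sel in self.selectors])

    def __len__(self):
        return len(self.channels)


def motor_mossy_spec() -> MossyFiberSpec:
    """The five motor channels with their scaling gains."""
    return MossyFiberSpec(
        channels=(
            ("des. shaft ang. pos.", "phi_des", 0.1),      # rad^-1
            ("des. shaft ang. vel.", "phi_dot_des", 0.19), # s/rad
            ("shaft ang. pos. error", "phi_e", 0.5),       # rad^-1
            ("shaft ang. vel. error", "phi_dot_e", 0.07),  # s/rad
            ("efference copy", "efference", 1.0),          # A^-1
        )
    )


def robot_mossy_spec() -> MossyFiberSpec:
    """The seven robot channels with their scaling gains."""
    return MossyFiberSpec(
        channels=(
            ("des. wheel ang. pos.", "phi_des", 0.03),       # rad^-1
            ("des. wheel ang. vel.", "phi_dot_des", 0.04),   # s/rad
            ("body tilt ang. pos. error", "theta_e", 1.0),   # rad^-1
            ("body tilt ang. vel. error", "theta_dot_e", 0.5),  # s/rad
            ("wheel ang. pos. error", "phi_e", 0.1),         # rad^-1
            ("wheel ang. vel. error", "phi_dot_e", 0.2),     # s/rad
            ("efference copy", "efference", 0.5),            # A^-1
        )
    )
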