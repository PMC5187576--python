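"""Teaching signals and motor-command composition.

The non-cerebellar pathway is a PD feedback controller; its output is both
the baseline motor command and, scaled by ``c1``, the motor-error (ME)
teaching signal of feedback-error-learning.  The sensory error (SE) is a
linear combination of kinematic errors (position/velocity, rad).  The
climbing fiber carries SE, ME, their sum, or nothing; the plant command is
the PD output minus the Purkinje rate (the vestibular-nucleus combination).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "CFMode",
    "PDGains",
    "ErrorCoefficients",
    "TeachingSignalSpec",
    "ErrorState",
    "pd_command",
    "compute_se",
    "compute_me",
    "compose_cf",
    "combine_command",
]


class CFMode(str, Enum):
    """Content of the climbing-fiber teaching signal."""

    SE = "se"
    ME = "me"
    SE_PLUS_ME = "se+me"
    NONE = "none"  # learning disabled, CF == 0


@dataclass(frozen=True)
class PDGains:
    """Proportional/derivative gains of the non-cerebellar pathway.

    The motor uses a single shaft-position controller (kp, kd).  The robot
    uses two controllers in parallel: body tilt (kp, kd) and wheel position
    (kp_star, kd_star); their summed output is the PD command.
    """

    kp: float
    kd: float
    kp_star: float = 0.0
    kd_star: float = 0.0

    def __post_init__(self):
        if min(self.kp, self.kd, self.kp_star, self.kd_star) < 0:
            raise ValueError("PD gains must be non-negative")


MOTOR_PD_GAINS = PDGains(kp=0.8, kd=0.01)
ROBOT_PD_GAINS = PDGains(kp=5.0, kd=0.5, kp_star=0.2, kd_star=0.05)


@dataclass(frozen=True)
class ErrorCoefficients:
    """Scaling constants equalizing the error components' contributions.

    a1 (rad^-1) and a2 (s/rad) weight the wheel/shaft position and velocity
    errors; b1, b2 weight the body-tilt errors (robot only); c1 (A^-1)
    converts the PD output into the motor-error signal.

    The sign of ``c1`` is fixed by the requirement that motor-error
    teaching implements feedback-error-learning, i.e. that the plasticity
    loop it closes is negative feedback.  Because the sensory-error and
    motor-error signals respond to a Purkinje-rate perturbation through
    the same plant pathway (scaled by a1 and c1*kp respectively), c1 must
    carry the same sign as a1 under this package's convention that the
    Purkinje rate is subtracted from the motor command — with opposite
    signs exactly one of the two modes is driven by runaway positive
    feedback, whichever operating point the network is in.
    """

    a1: float = 0.5
    a2: float = 0.02
    b1: float = 5.0
    b2: float = 0.5
    c1: float = 0.4


@dataclass(frozen=True)
class TeachingSignalSpec:
    mode: CFMode = CFMode.SE
    coefficients: ErrorCoefficients = field(default_factory=ErrorCoefficients)
    clip: float | None = None  # optional symmetric CF saturation, default off


@dataclass
class ErrorState:
    """Kinematic errors, desired minus actual (rad, rad/s)."""

    phi_e: float = 0.0
    phi_dot_e: float = 0.0
    theta_e: float = 0.0
    theta_dot_e: float = 0.0


def pd_command(errors: ErrorState, gains: PDGains, plant_kind: str) -> float:
    """PD motor command in amperes.

    Motor: kp*phi_e + kd*phi_dot_e.  Robot: the parallel sum of the body
    controller (kp, kd on tilt errors) and wheel controller (kp*, kd* on
    wheel errors).  This value is also the input to :func:`compute_me`.
    """
    if plant_kind == "motor":
        return gains.kp * errors.phi_e + gains.kd * errors.phi_dot_e
    if plant_kind == "robot":
        body = gains.kp * errors.theta_e + gains.kd * errors.theta_dot_e
        wheel = gains.kp_star * errors.phi_e + gains.kd_star * errors.phi_dot_e
        return body + wheel
    raise ValueError(f"unknown plant kind: {plant_kind!r}")


def compute_se(errors: ErrorState, coeff: ErrorCoefficients, plant_kind: str) -> float:
    """Sensory-error teaching signal (kinematic coordinates)."""
    se = coeff.a1 * errors.phi_e + coeff.a2 * errors.phi_dot_e
    if plant_kind == "robot":
        se += coeff.b1 * errors.theta_e + coeff.b2 * errors.theta_dot_e
    elif plant_kind != "motor":
        raise ValueError(f"unknown plant kind: {plant_kind!r}")
    return se


def compute_me(pd_output: float, coeff: ErrorCoefficients) -> float:
    """Motor-error teaching signal: the scaled PD output (same for both plants)."""
    return coeff.c1 * pd_output


def compose_cf(se: float, me: float, mode: CFMode, clip: float | None = None) -> float:
    """Select the climbing-fiber value for the configured mode."""
    mode = CFMode(mode)
    if mode is CFMode.SE:
        cf = se
    elif mode is CFMode.ME:
        cf = me
    elif mode is CFMode.SE_PLUS_ME:
        cf = se + me
    elif mode is CFMode.NONE:
        cf = 0.0
    else:  # pragma: no cover
        raise ValueError(f"invalid CF mode: {mode}")
    if clip is not None:
        cf = max(-clip, min(clip, cf))
    return cf


def combine_command(pd_output: float, y_pc: float, output_gain: float = 1.0) -> float:
    """Total plant current: PD output minus the (inhibitory) Purkinje rate."""
    return pd_output - output_gain * y_pc
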