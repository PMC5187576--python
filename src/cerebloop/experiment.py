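"""Closed-loop learning experiments.

Protocol: a sinusoidal desired trajectory (amplitude pi rad) is tracked for
up to 100 cycles at a 10-ms control period.  Each sample the loop reads the
plant state, forms kinematic errors, computes the PD command and the
teaching signals, sigmoid-encodes the mossy-fiber channels, advances the
cerebellar network one step, combines the plant command (PD minus Purkinje
rate), steps the plant, and applies the CF-gated weight update.
Performance is the per-cycle root-mean-square error (RSE) of the tracked
angle; a battery runs five weight initializations per CF mode plus a
PD-only baseline with the cerebellar output disconnected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import network as net
from . import plants
from . import teaching
from .teaching import CFMode

__all__ = [
    "ExperimentConfig",
    "TrialResult",
    "BatteryResult",
    "desired_trajectory",
    "run_trial",
    "run_seed_battery",
]

DEFAULT_SEEDS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class ExperimentConfig:
    """One experimental condition (plant, CF mode, stimulus, protocol)."""

    plant_kind: str = "robot"
    cf_mode: CFMode = CFMode.SE
    amplitude: float = float(np.pi)
    frequency: float | None = None  # Hz; None -> 0.5 motor / 0.2 robot
    n_cycles: int = 100
    ts: float = 0.010
    seeds: tuple = DEFAULT_SEEDS
    output_gain: float | None = None  # None -> per-plant default
    record_y_pf: bool = False
    network: net.NetworkConfig | None = None
    motor_params: plants.MotorParams = field(default_factory=plants.MotorParams)
    robot_params: plants.RobotParams = field(default_factory=plants.RobotParams)
    pd_gains: teaching.PDGains | None = None
    coefficients: teaching.ErrorCoefficients = field(
        default_factory=teaching.ErrorCoefficients
    )
    cf_clip: float | None = None

    def __post_init__(self):
        if self.plant_kind not in ("motor", "robot"):
            raise ValueError(f"unknown plant kind: {self.plant_kind!r}")
        if self.frequency is None:
            object.__setattr__(
                self, "frequency", 0.5 if self.plant_kind == "motor" else 0.2
            )
        if self.frequency <= 0 or self.ts <= 0 or self.n_cycles < 1:
            raise ValueError("frequency, ts and n_cycles must be positive")

    @property
    def mossy_spec(self) -> plants.MossyFiberSpec:
        if self.plant_kind == "motor":
            return plants.motor_mossy_spec()
        return plants.robot_mossy_spec()

    def resolved_network(self) -> net.NetworkConfig:
        if self.network is not None:
            return self.network
        balance = net.MOTOR_BALANCE if self.plant_kind == "motor" else net.ROBOT_BALANCE
        return net.NetworkConfig(n_mf=len(self.mossy_spec), balance=dict(balance))

    def resolved_output_gain(self) -> float:
        """Purkinje-to-command gain; per-plant default if unset.

        The defaults (motor 0.3, robot 0.15 A per unit rate) scale the
        bounded Purkinje rate to the current range each plant needs; at
        much larger gains the per-sample weight updates slew the Purkinje
        drive across its whole sensitive range within a cycle and the
        loop rail-locks instead of learning.
        """
        if self.output_gain is not None:
            return self.output_gain
        return 0.3 if self.plant_kind == "motor" else 0.15

    def resolved_gains(self) -> teaching.PDGains:
        if self.pd_gains is not None:
            return self.pd_gains
        return (
            teaching.MOTOR_PD_GAINS
            if self.plant_kind == "motor"
            else teaching.ROBOT_PD_GAINS
        )

    @property
    def n_steps(self) -> int:
        return int(round(self.n_cycles / self.frequency / self.ts))


@dataclass
class TrialResult:
    """Time series, per-cycle RSE and weight snapshots for one trial."""

    config: ExperimentConfig
    seed: int | None
    t: np.ndarray
    phi_des: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    cf: np.ndarray
    y_pc: np.ndarray
    pd: np.ndarray
    command: np.ndarray
    rse_per_cycle: np.ndarray
    w_initial: np.ndarray
    w_final: np.ndarray
    w_cycle_snapshots: np.ndarray  # (n_recorded_cycles + 1, n_gc), row 0 = initial
    ba_pc_rescale: float
    y_pf_history: np.ndarray | None = None  # (n_steps, n_gc) float32, optional
    failed: bool = False
    failure_time: float | None = None

    @property
    def phi_e(self) -> np.ndarray:
        return self.phi_des - self.phi

    @property
    def n_completed_cycles(self) -> int:
        return len(self.rse_per_cycle)


def desired_trajectory(amplitude: float, frequency: float, t):
    """Sinusoidal desired angle and its rate: A sin(2 pi f t)."""
    w = 2.0 * np.pi * frequency
    t = np.asarray(t, dtype=float)
    return amplitude * np.sin(w * t), amplitude * w * np.cos(w * t)


def _per_cycle_rse(errors: np.ndarray, t: np.ndarray, frequency: float) -> np.ndarray:
    from .analysis import rse_series

    cycle_index = np.floor(t * frequency + 1e-12).astype(int)
    n_full = int(cycle_index[-1]) + 1 if len(t) else 0
    boundaries = np.searchsorted(cycle_index, np.arange(n_full + 1))
    return rse_series(errors, boundaries)


def run_trial(config: ExperimentConfig, seed, cerebellum_enabled: bool = True) -> TrialResult:
    """Run one closed-loop trial; deterministic for a given seed.

    With ``cerebellum_enabled=False`` the Purkinje contribution is
    disconnected and learning is off (the PD-only baseline), but the loop
    timing is otherwise identical.  A robot tip-over marks the trial failed
    and returns the partial record.
    """
    ncfg = config.resolved_network()
    spec = config.mossy_spec
    if ncfg.n_mf != len(spec):
        raise ValueError(
            f"network has {ncfg.n_mf} mossy fibers but the {config.plant_kind} "
            f"plant provides {len(spec)} channels"
        )
    gains = config.resolved_gains()
    coeff = config.coefficients
    mode = CFMode(config.cf_mode)
    learning_on = cerebellum_enabled and mode is not CFMode.NONE
    output_gain = config.resolved_output_gain() if cerebellum_enabled else 0.0

    masks = net.build_connectivity(ncfg, np.random.SeedSequence([int(seed), 0]))
    weights = net.initialize_weights(ncfg, masks, np.random.SeedSequence([int(seed), 1]))
    w_initial = weights.w_pf_pc.copy()
    state = net.initial_state(ncfg)

    if config.plant_kind == "motor":
        plant_state = plants.MotorState()
    else:
        plant_state = plants.RobotState()

    n_steps = config.n_steps
    steps_per_cycle = max(1, int(round(1.0 / (config.frequency * config.ts))))
    rec = {
        key: np.empty(n_steps)
        for key in ("t", "phi_des", "phi", "theta", "cf", "y_pc", "pd", "command")
    }
    y_pf_hist = (
        np.empty((n_steps, ncfg.n_gc), dtype=np.float32) if config.record_y_pf else None
    )
    snapshots = [w_initial.copy()]
    gain_vec = spec.gains
    mf_sel = spec.selectors
    prev_command = 0.0
    failed = False
    failure_time = None
    k = 0

    for k in range(n_steps):
        t = k * config.ts
        phi_des, phi_dot_des = desired_trajectory(config.amplitude, config.frequency, t)
        if config.plant_kind == "motor":
            errors = teaching.ErrorState(
                phi_e=phi_des - plant_state.phi,
                phi_dot_e=phi_dot_des - plant_state.phi_dot,
            )
            theta = np.nan
        else:
            errors = teaching.ErrorState(
                phi_e=phi_des - plant_state.phi,
                phi_dot_e=phi_dot_des - plant_state.phi_dot,
                theta_e=-plant_state.theta,  # desired tilt is zero
                theta_dot_e=-plant_state.theta_dot,
            )
            theta = plant_state.theta

        pd = teaching.pd_command(errors, gains, config.plant_kind)
        se = teaching.compute_se(errors, coeff, config.plant_kind)
        me = teaching.compute_me(pd, coeff)
        cf = teaching.compose_cf(se, me, mode, clip=config.cf_clip)

        signals = {
            "phi_des": phi_des,
            "phi_dot_des": phi_dot_des,
            "phi_e": errors.phi_e,
            "phi_dot_e": errors.phi_dot_e,
            "theta_e": errors.theta_e,
            "theta_dot_e": errors.theta_dot_e,
            "efference": prev_command,
        }
        y_mf = net.encode_mossy_fibers(
            np.array([signals[s] for s in mf_sel]), gain_vec, ncfg.sigma, ncfg.mu
        )
        y_pc, state = net.network_step(state, weights, masks, y_mf, ncfg)
        command = teaching.combine_command(pd, y_pc, output_gain)

        rec["t"][k] = t
        rec["phi_des"][k] = phi_des
        rec["phi"][k] = plant_state.phi
        rec["theta"][k] = theta
        rec["cf"][k] = cf
        rec["y_pc"][k] = y_pc
        rec["pd"][k] = pd
        rec["command"][k] = command
        if y_pf_hist is not None:
            y_pf_hist[k] = state.y_pf

        try:
            if config.plant_kind == "motor":
                plant_state = plants.motor_step(
                    plant_state, command, config.motor_params, config.ts
                )
            else:
                plant_state = plants.robot_step(
                    plant_state, command, config.robot_params, config.ts, time=t
                )
        except plants.TipOverError as err:
            failed = True
            failure_time = err.time
            k += 1
            break

        if learning_on:
            net.apply_cf_learning(weights, state.y_pf, cf, ncfg.gamma)
        prev_command = command
        if (k + 1) % steps_per_cycle == 0:
            snapshots.append(weights.w_pf_pc.copy())
    else:
        k = n_steps

    rec = {key: val[:k] for key, val in rec.items()}
    if y_pf_hist is not None:
        y_pf_hist = y_pf_hist[:k]
    phi_e = rec["phi_des"] - rec["phi"]
    rse = _per_cycle_rse(phi_e, rec["t"], config.frequency)
    return TrialResult(
        config=config,
        seed=int(seed),
        t=rec["t"],
        phi_des=rec["phi_des"],
        phi=rec["phi"],
        theta=rec["theta"],
        cf=rec["cf"],
        y_pc=rec["y_pc"],
        pd=rec["pd"],
        command=rec["command"],
        rse_per_cycle=rse,
        w_initial=w_initial,
        w_final=weights.w_pf_pc.copy(),
        w_cycle_snapshots=np.asarray(snapshots),
        ba_pc_rescale=weights.ba_pc_rescale,
        y_pf_history=y_pf_hist,
        failed=failed,
        failure_time=failure_time,
    )


@dataclass
class BatteryResult:
    """Per-seed RSE curves, their mean, and the PD-only baseline."""

    config: ExperimentConfig
    seeds: tuple
    trials: list
    rse_curves: np.ndarray  # (n_seeds, n_cycles)
    rse_mean: np.ndarray
    baseline: TrialResult

    @property
    def baseline_rse(self) -> np.ndarray:
        return self.baseline.rse_per_cycle


def run_seed_battery(config: ExperimentConfig, seeds=None) -> BatteryResult:
    """Run the condition over all seeds plus the PD-only baseline.

    The baseline uses the identical loop with the cerebellar output
    disconnected and learning off; it contains no randomness and is shared
    across seeds.  A failed (tipped-over) trial propagates its seed in the
    raised error.
    """
    seeds = tuple(config.seeds if seeds is None else seeds)
    if not seeds:
        raise ValueError("at least one seed is required")
    trials = []
    for seed in seeds:
        trial = run_trial(config, seed)
        if trial.failed:
            raise plants.TipOverError(trial.failure_time) from None
        trials.append(trial)
    baseline = run_trial(config, seeds[0], cerebellum_enabled=False)
    curves = np.vstack([tr.rse_per_cycle for tr in trials])
    return BatteryResult(
        config=config,
        seeds=seeds,
        trials=trials,
        rse_curves=curves,
        rse_mean=curves.mean(axis=0),
        baseline=baseline,
    )
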