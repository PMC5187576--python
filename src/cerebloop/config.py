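"""Configuration loading, validation and serialization.

A single YAML (or JSON) document describes the network, plants, controller
and protocol.  Every field has a default; an empty document yields the
standard conditions (755 granule cells, gamma = 0.008, 10-ms control
period, five replicate seeds).  Unknown keys are rejected with their full
path so typos fail loudly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import network as net
from . import plants, teaching
from .experiment import DEFAULT_SEEDS, ExperimentConfig
from .teaching import CFMode

__all__ = ["default_config", "load_config", "save_config", "build_experiment", "config_hash"]


def default_config() -> dict:
    """The full default configuration document."""
    return {
        "experiment": {
            "plant": "robot",
            "cf_mode": "se",
            "amplitude": float(np.pi),
            "frequency": None,  # None -> 0.5 Hz motor / 0.2 Hz robot
            "n_cycles": 100,
            "ts": 0.010,
            "seeds": list(DEFAULT_SEEDS),
            "output_gain": None,  # None -> per-plant default
            "cf_clip": None,
            "record_y_pf": False,
        },
        "network": {
            "n_mf": None,  # None -> one per mossy-fiber channel of the plant
            "n_gc": 755,
            "n_go": 5,
            "n_ba": 15,
            "n_pc": 1,
            "sigma": 8.0,
            "mu": 0.5,
            "gamma": 0.008,
            "convergence": dict(net.DEFAULT_CONVERGENCE),
            "balance": None,  # None -> per-plant preset
        },
        "motor": {"J": 1e-5, "B": 2e-4, "Kt": 0.01, "dt_inner": 1e-3},
        "robot": {
            "m_b": 0.8,
            "m_w": 0.05,
            "r": 0.025,
            "l": 0.1,
            "I_b": 0.8 * 0.1**2 / 3,
            "I_w": 0.05 * 0.025**2 / 2,
            "g": 9.81,
            "Kt": 0.1,
            "dt_inner": 1e-3,
            "theta_limit": float(np.pi / 4),
        },
        "pd_gains": None,  # None -> per-plant published gains
        "coefficients": {"a1": 0.5, "a2": 0.02, "b1": 5.0, "b2": 0.5, "c1": 0.4},
    }


def _merge(defaults, overrides, path=""):
    """Merge ``overrides`` into ``defaults``, rejecting unknown keys."""
    if overrides is None:
        return copy.deepcopy(defaults)
    if not isinstance(defaults, dict):
        return copy.deepcopy(overrides)
    if not isinstance(overrides, dict):
        raise ValueError(f"config field {path or '<root>'} must be a mapping")
    merged = copy.deepcopy(defaults)
    for key, value in overrides.items():
        where = f"{path}.{key}" if path else key
        # pd_gains / balance / n_mf default to None but accept mappings
        if key not in defaults and defaults:
            raise ValueError(f"unknown configuration key: {where}")
        base = defaults.get(key)
        merged[key] = _merge(base, value, where) if isinstance(base, dict) else copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Read, merge with defaults, and validate a configuration document."""
    doc = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    cfg = _merge(default_config(), doc)
    if overrides:
        cfg = _merge(cfg, overrides)
    build_experiment(cfg)  # validation side effect: raises on bad values
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying a configuration."""
    canon = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_experiment(cfg: dict) -> ExperimentConfig:
    """Construct a validated :class:`ExperimentConfig` from a document."""
    exp = cfg["experiment"]
    plant_kind = exp["plant"]
    if plant_kind not in ("motor", "robot"):
        raise ValueError(f"experiment.plant must be 'motor' or 'robot', got {plant_kind!r}")

    ncfg = None
    ncfg_doc = cfg["network"]
    n_channels = 5 if plant_kind == "motor" else 7
    n_mf = ncfg_doc["n_mf"] if ncfg_doc["n_mf"] is not None else n_channels
    balance = ncfg_doc["balance"]
    if balance is None:
        balance = dict(net.MOTOR_BALANCE if plant_kind == "motor" else net.ROBOT_BALANCE)
    ncfg = net.NetworkConfig(
        n_mf=n_mf,
        n_gc=ncfg_doc["n_gc"],
        n_go=ncfg_doc["n_go"],
        n_ba=ncfg_doc["n_ba"],
        n_pc=ncfg_doc["n_pc"],
        sigma=ncfg_doc["sigma"],
        mu=ncfg_doc["mu"],
        gamma=ncfg_doc["gamma"],
        convergence=dict(ncfg_doc["convergence"]),
        balance=balance,
    )

    pd_doc = cfg["pd_gains"]
    pd_gains = None
    if pd_doc is not None:
        pd_gains = teaching.PDGains(
            kp=pd_doc["kp"],
            kd=pd_doc["kd"],
            kp_star=pd_doc.get("kp_star", 0.0),
            kd_star=pd_doc.get("kd_star", 0.0),
        )

    return ExperimentConfig(
        plant_kind=plant_kind,
        cf_mode=CFMode(exp["cf_mode"]),
        amplitude=exp["amplitude"],
        frequency=exp["frequency"],
        n_cycles=exp["n_cycles"],
        ts=exp["ts"],
        seeds=tuple(exp["seeds"]),
        output_gain=exp["output_gain"],
        record_y_pf=exp["record_y_pf"],
        network=ncfg,
        motor_params=plants.MotorParams(**cfg["motor"]),
        robot_params=plants.RobotParams(**cfg["robot"]),
        pd_gains=pd_gains,
        coefficients=teaching.ErrorCoefficients(**cfg["coefficients"]),
        cf_clip=exp["cf_clip"],
    )
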