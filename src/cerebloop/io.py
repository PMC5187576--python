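"""Result serialization, run manifests, and deterministic test fixtures.

Time series go to tidy CSV, weight/rate histories to NPZ archives (masks
stored as sparse presynaptic index lists), and every run is described by a
JSON manifest (config hash, seeds, guard scalars, output paths) from which
it can be reconstructed.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import network as net
from .experiment import TrialResult

__all__ = [
    "trial_frame",
    "save_trial",
    "save_network",
    "load_network",
    "write_manifest",
    "make_toy_network",
]


def trial_frame(trial: TrialResult) -> pd.DataFrame:
    """Tidy per-sample record of a trial."""
    return pd.DataFrame(
        {
            "t": trial.t,
            "phi_des": trial.phi_des,
            "phi": trial.phi,
            "theta": trial.theta,
            "phi_e": trial.phi_e,
            "cf": trial.cf,
            "y_pc": trial.y_pc,
            "pd": trial.pd,
            "command": trial.command,
        }
    )


def save_trial(trial: TrialResult, outdir: str | Path, stem: str) -> dict:
    """Write a trial's CSV + NPZ pair; returns the manifest entry."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    npz_path = outdir / f"{stem}.npz"
    trial_frame(trial).to_csv(csv_path, index=False)
    arrays = {
        "rse_per_cycle": trial.rse_per_cycle,
        "w_initial": trial.w_initial,
        "w_final": trial.w_final,
        "w_cycle_snapshots": trial.w_cycle_snapshots,
    }
    if trial.y_pf_history is not None:
        arrays["y_pf_history"] = trial.y_pf_history
    np.savez_compressed(npz_path, **arrays)
    return {
        "seed": trial.seed,
        "csv": csv_path.name,
        "npz": npz_path.name,
        "failed": trial.failed,
        "failure_time": trial.failure_time,
        "ba_pc_rescale": trial.ba_pc_rescale,
        "final_rse": float(trial.rse_per_cycle[-1]) if len(trial.rse_per_cycle) else None,
    }


def _mask_indices(mask: np.ndarray) -> list:
    """Sparse representation: presynaptic index list per postsynaptic cell."""
    return [np.flatnonzero(mask[:, j]).tolist() for j in range(mask.shape[1])]


def save_network(
    path: str | Path,
    config: net.NetworkConfig,
    masks: net.ConnectivityMasks,
    weights: net.SynapseWeights,
) -> None:
    """Portable NPZ snapshot of a network (masks as sparse index lists)."""
    payload = {
        f"w_{name}": getattr(weights, f"w_{name}")
        for name in ("mf_gc", "go_gc", "mf_go", "pf_go", "pf_ba", "pf_pc", "ba_pc")
    }
    for name in ("mf_gc", "go_gc", "mf_go", "pf_go", "pf_ba"):
        idx = _mask_indices(getattr(masks, f"m_{name}"))
        payload[f"idx_{name}"] = np.array(json.dumps(idx))
    payload["ba_pc_rescale"] = np.array(weights.ba_pc_rescale)
    payload["config"] = np.array(
        json.dumps(
            {
                "n_mf": config.n_mf,
                "n_gc": config.n_gc,
                "n_go": config.n_go,
                "n_ba": config.n_ba,
                "n_pc": config.n_pc,
                "sigma": config.sigma,
                "mu": config.mu,
                "gamma": config.gamma,
                "convergence": config.convergence,
                "balance": config.balance,
            }
        )
    )
    np.savez_compressed(path, **payload)


def load_network(path: str | Path):
    """Inverse of :func:`save_network`."""
    data = np.load(path, allow_pickle=False)
    cfg_doc = json.loads(str(data["config"]))
    config = net.NetworkConfig(**cfg_doc)
    sizes = {
        "mf_gc": (config.n_mf, config.n_gc),
        "go_gc": (config.n_go, config.n_gc),
        "mf_go": (config.n_mf, config.n_go),
        "pf_go": (config.n_gc, config.n_go),
        "pf_ba": (config.n_gc, config.n_ba),
    }
    mask_arrays = {}
    for name, shape in sizes.items():
        idx = json.loads(str(data[f"idx_{name}"]))
        m = np.zeros(shape, dtype=np.int8)
        for j, pre in enumerate(idx):
            m[pre, j] = 1
        mask_arrays[f"m_{name}"] = m
    masks = net.ConnectivityMasks(**mask_arrays)
    weights = net.SynapseWeights(
        w_mf_gc=data["w_mf_gc"],
        w_go_gc=data["w_go_gc"],
        w_mf_go=data["w_mf_go"],
        w_pf_go=data["w_pf_go"],
        w_pf_ba=data["w_pf_ba"],
        w_pf_pc=data["w_pf_pc"],
        w_ba_pc=data["w_ba_pc"],
        ba_pc_rescale=float(data["ba_pc_rescale"]),
    )
    return config, masks, weights


def write_manifest(
    outdir: str | Path,
    config_doc: dict,
    entries: list,
    extra: dict | None = None,
) -> Path:
    """JSON manifest from which a run is fully reconstructible."""
    from . import __version__
    from .config import config_hash

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config_hash": config_hash(config_doc),
        "config": config_doc,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seeds": [e.get("seed") for e in entries],
        "trials": entries,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    missing = [e[k] for e in entries for k in ("csv", "npz") if not (outdir / e[k]).exists()]
    if missing:
        raise FileNotFoundError(f"manifest lists missing outputs: {missing}")
    return path


def make_toy_network(sizes=(2, 3, 1, 1, 1)):
    """Tiny fully-connected network with hand-settable weights.

    ``sizes`` = (n_mf, n_gc, n_go, n_ba, n_pc).  All masks are full, all
    excitatory weights 0.5 and inhibitory -0.5, and no balance rescaling
    is applied, so every quantity in a hand computation is explicit.
    """
    n_mf, n_gc, n_go, n_ba, n_pc = sizes
    config = net.NetworkConfig(
        n_mf=n_mf,
        n_gc=n_gc,
        n_go=n_go,
        n_ba=n_ba,
        n_pc=n_pc,
        convergence={
            "mf_gc": n_mf,
            "go_gc": n_go,
            "pf_go": n_gc,
            "pf_ba": n_gc,
            "mf_go": None,
            "pf_pc": None,
            "ba_pc": None,
        },
        balance=None,
    )
    masks = net.ConnectivityMasks(
        m_mf_gc=np.ones((n_mf, n_gc), dtype=np.int8),
        m_go_gc=np.ones((n_go, n_gc), dtype=np.int8),
        m_mf_go=np.ones((n_mf, n_go), dtype=np.int8),
        m_pf_go=np.ones((n_gc, n_go), dtype=np.int8),
        m_pf_ba=np.ones((n_gc, n_ba), dtype=np.int8),
    )
    weights = net.SynapseWeights(
        w_mf_gc=np.full((n_mf, n_gc), 0.5),
        w_go_gc=np.full((n_go, n_gc), -0.5),
        w_mf_go=np.full((n_mf, n_go), 0.5),
        w_pf_go=np.full((n_gc, n_go), 0.5),
        w_pf_ba=np.full((n_gc, n_ba), 0.5),
        w_pf_pc=np.full(n_gc, 0.5),
        w_ba_pc=np.full(n_ba, -0.5),
    )
    return config, masks, weights
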