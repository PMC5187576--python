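"""Post-hoc analyses of closed-loop trials.

Covers the per-cycle RSE metric, LTD/LTP statistics of the plastic PF->PC
weights, per-granule-cell Pearson correlation profiles against a reference
signal (climbing fiber, kinematic error, desired motion) sorted from the
most-depressed to the most-potentiated cell, and the rotated XY view of
desired-vs-yielded trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightChangeSummary",
    "CorrelationProfile",
    "rse_series",
    "ltd_ltp_fractions",
    "moving_average",
    "gc_correlation",
    "rotate_trajectory",
]

#: Weight changes smaller than this magnitude count as "unchanged".
TIE_TOLERANCE = 1e-12


def rse_series(errors: np.ndarray, cycle_boundaries) -> np.ndarray:
    """Root-mean-square error per cycle.

    ``cycle_boundaries`` are sample indices partitioning the record:
    cycle k spans ``[boundaries[k], boundaries[k+1])``.  Empty cycles are
    rejected.
    """
    errors = np.asarray(errors, dtype=float)
    b = np.asarray(cycle_boundaries, dtype=int)
    if len(b) < 2:
        return np.empty(0)
    out = np.empty(len(b) - 1)
    for k in range(len(b) - 1):
        chunk = errors[b[k] : b[k + 1]]
        if chunk.size == 0:
            raise ValueError(f"cycle {k} contains no samples")
        out[k] = np.sqrt(np.mean(chunk**2))
    return out


@dataclass
class WeightChangeSummary:
    """Final-minus-initial PF->PC weight changes and their sign census."""

    delta: np.ndarray
    sort_order: np.ndarray  # GC indices, most depressed first
    depressed_fraction: float
    potentiated_fraction: float
    unchanged_fraction: float


def ltd_ltp_fractions(
    w_initial: np.ndarray, w_final: np.ndarray, tol: float = TIE_TOLERANCE
) -> WeightChangeSummary:
    """Census of depressed / potentiated / unchanged plastic weights.

    Changes within ``tol`` of zero count as unchanged (ties), so the three
    fractions always sum to one.
    """
    w_initial = np.asarray(w_initial, dtype=float)
    w_final = np.asarray(w_final, dtype=float)
    if w_initial.shape != w_final.shape:
        raise ValueError("weight vectors must have equal length")
    delta = w_final - w_initial
    n = delta.size
    depressed = np.count_nonzero(delta < -tol)
    potentiated = np.count_nonzero(delta > tol)
    return WeightChangeSummary(
        delta=delta,
        sort_order=np.argsort(delta, kind="stable"),
        depressed_fraction=depressed / n,
        potentiated_fraction=potentiated / n,
        unchanged_fraction=(n - depressed - potentiated) / n,
    )


def moving_average(values: np.ndarray, window: int = 13) -> np.ndarray:
    """Centred moving average with symmetrically truncated edges.

    Output has the same length as the input; near the ends the window
    shrinks to the largest symmetric window that fits.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(values)
    n = values.size
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h : i + h + 1].mean()
    return out


@dataclass
class CorrelationProfile:
    """Per-GC Pearson correlation against a reference, in sorted GC order."""

    gc_order: np.ndarray  # GC indices, most depressed -> most potentiated
    r: np.ndarray  # correlation coefficient per sorted cell
    r_smoothed: np.ndarray  # moving average (same length)
    delta_w: np.ndarray  # weight change per sorted cell


def gc_correlation(
    y_pf_history: np.ndarray,
    reference: np.ndarray,
    weight_summary: WeightChangeSummary,
    window: int = 13,
) -> CorrelationProfile:
    """Correlate every granule cell's rate series with a reference signal.

    ``y_pf_history`` is (n_samples, n_gc).  Cells are ordered by their
    PF->PC weight change, most depressed first.  A constant reference or a
    constant cell series has no defined coefficient and raises.
    """
    y = np.asarray(y_pf_history, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if y.ndim != 2 or y.shape[0] != ref.shape[0]:
        raise ValueError("y_pf_history must be (n_samples, n_gc) matching the reference")
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    if ref_ss == 0.0:
        raise ValueError("reference signal is constant; correlation undefined")
    y_c = y - y.mean(axis=0)
    y_ss = np.einsum("ij,ij->j", y_c, y_c)
    if np.any(y_ss == 0.0):
        bad = np.flatnonzero(y_ss == 0.0)
        raise ValueError(f"granule cell series constant (undefined correlation): {bad[:5]}")
    r = (ref_c @ y_c) / np.sqrt(ref_ss * y_ss)
    order = weight_summary.sort_order
    r_sorted = r[order]
    return CorrelationProfile(
        gc_order=order,
        r=r_sorted,
        r_smoothed=moving_average(r_sorted, window),
        delta_w=weight_summary.delta[order],
    )


def rotate_trajectory(phi_des: np.ndarray, phi: np.ndarray):
    """Rotate the (desired, yielded) plane by -45 degrees.

    Perfect tracking maps onto the horizontal line y' = 0; the signed
    vertical coordinate is (phi - phi_des)/sqrt(2).
    """
    phi_des = np.asarray(phi_des, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi_des.shape != phi.shape:
        raise ValueError("series must have equal length")
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    return (phi_des + phi) * inv_sqrt2, (phi - phi_des) * inv_sqrt2
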