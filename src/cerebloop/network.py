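"""Firing-rate model of a cerebellar cortical microcircuit.

The circuit contains four populations — granule cells (GC, whose axons are
the parallel fibers, PF), Golgi cells (GO), basket/stellate cells (BA) and a
single Purkinje cell (PC) — driven by mossy-fiber (MF) inputs.  GO cells
form an inhibitory feedback loop onto GC; BA cells provide feedforward
inhibition onto the PC.  Every neuron is a static sigmoidal rate unit; the
only plastic synapses are PF->PC, updated each control sample by a
climbing-fiber (CF) teaching signal: weights are depressed (LTD) when the
zero-centred PF rate and the CF have the same sign and potentiated (LTP)
when they differ.

Connectivity is random but respects fixed per-cell convergence counts
(e.g. each granule cell receives exactly 4 mossy fibers and 3 Golgi cells).
Weights are drawn from truncated normal laws — excitatory in (0, 1],
inhibitory in [-1, 0) — and then rescaled per projection so that the
network operates in the sensitive range of its sigmoids (see
``initialize_weights``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "MOTOR_BALANCE",
    "ROBOT_BALANCE",
    "NetworkConfig",
    "ConnectivityMasks",
    "SynapseWeights",
    "NetworkState",
    "sigmoid_rate",
    "build_connectivity",
    "truncated_normal",
    "initialize_weights",
    "encode_mossy_fibers",
    "initial_state",
    "network_step",
    "apply_cf_learning",
]

#: Default per-projection convergence counts (presynaptic partners per
#: postsynaptic cell).  ``None`` means full (all-to-all) connectivity:
#: MF->GO, PF->PC and BA->PC are not subsampled.
DEFAULT_CONVERGENCE = {
    "mf_gc": 4,
    "go_gc": 3,
    "pf_go": 150,
    "pf_ba": 50,
    "mf_go": None,
    "pf_pc": None,
    "ba_pc": None,
}

#: Per-projection target column sums used by the drive-balance rescaling at
#: initialization (see ``initialize_weights``).  Two presets set the
#: operating point appropriate to each plant's mossy-fiber statistics, in
#: the same spirit as the plant-specific pre-cerebellar gains:
#:
#: * motor — granule drive dominated by mossy input with light Golgi
#:   feedback; basket pathway balanced against a large plastic pool
#:   (PF->PC column sum 16) so depression has headroom.
#: * robot — strong delayed Golgi feedback (PF->GO 0.9) that puts the
#:   granular layer into its alternating (period-2) regime, which cancels
#:   the common-mode component of successive plasticity updates and slows
#:   effective learning ~two orders of magnitude; basket cells driven into
#:   saturation (PF->BA 3) act as a near-constant inhibitory bias
#:   balancing a still larger plastic pool (PF->PC 31).
MOTOR_BALANCE = {
    "mf_gc": 1.5,
    "go_gc": -0.5,
    "mf_go": 0.5,
    "pf_go": 0.5,
    "pf_ba": 1.0,
    "pf_pc": 16.0,
    "ba_pc": -15.0,
}

ROBOT_BALANCE = {
    "mf_gc": 1.3,
    "go_gc": -1.0,
    "mf_go": 0.1,
    "pf_go": 0.9,
    "pf_ba": 3.0,
    "pf_pc": 31.0,
    "ba_pc": -15.0,
}

#: Lower clip bound keeping plastic PF->PC weights strictly positive.
W_PFPC_MIN = 1e-6


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and dynamical parameters of the microcircuit.

    ``n_mf`` is 5 for the DC-motor plant and 7 for the balancing robot
    (one channel per sensor/efference signal).  ``sigma`` and ``mu`` are
    the steepness and midpoint shared by every sigmoidal unit; ``gamma``
    is the per-sample learning rate of the PF->PC synapses.
    """

    n_mf: int = 7
    n_gc: int = 755
    n_go: int = 5
    n_ba: int = 15
    n_pc: int = 1
    sigma: float = 8.0
    mu: float = 0.5
    gamma: float = 0.008
    convergence: dict = field(default_factory=lambda: dict(DEFAULT_CONVERGENCE))
    balance: dict | None = field(default_factory=lambda: dict(ROBOT_BALANCE))

    def __post_init__(self) -> None:
        for name in ("n_mf", "n_gc", "n_go", "n_ba", "n_pc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.n_pc != 1:
            raise ValueError("the model has a single Purkinje cell")
        pre_sizes = {
            "mf_gc": self.n_mf,
            "go_gc": self.n_go,
            "pf_go": self.n_gc,
            "pf_ba": self.n_gc,
            "mf_go": self.n_mf,
            "pf_pc": self.n_gc,
            "ba_pc": self.n_ba,
        }
        unknown = set(self.convergence) - set(pre_sizes)
        if unknown:
            raise ValueError(f"unknown projection(s) in convergence: {sorted(unknown)}")
        for proj, count in self.convergence.items():
            if count is None:
                continue
            if not 1 <= count <= pre_sizes[proj]:
                raise ValueError(
                    f"convergence[{proj!r}] = {count} exceeds presynaptic "
                    f"population size {pre_sizes[proj]}"
                )

    def convergence_count(self, proj: str) -> int:
        """Realized number of presynaptic partners for ``proj``."""
        pre_sizes = {
            "mf_gc": self.n_mf,
            "go_gc": self.n_go,
            "pf_go": self.n_gc,
            "pf_ba": self.n_gc,
            "mf_go": self.n_mf,
            "pf_pc": self.n_gc,
            "ba_pc": self.n_ba,
        }
        count = self.convergence.get(proj)
        return pre_sizes[proj] if count is None else count


@dataclass
class ConnectivityMasks:
    """Binary masks (presynaptic x postsynaptic), 1 where a synapse exists.

    Every postsynaptic column carries exactly the configured convergence
    count of ones, with partners drawn uniformly without replacement.
    MF->GO, PF->PC and BA->PC are fully connected and carry no mask.
    """

    m_mf_gc: np.ndarray
    m_go_gc: np.ndarray
    m_mf_go: np.ndarray
    m_pf_go: np.ndarray
    m_pf_ba: np.ndarray


@dataclass
class SynapseWeights:
    """All synaptic weight matrices; only ``w_pf_pc`` is plastic.

    Excitatory entries lie in (0, 1], inhibitory in [-1, 0); entries are
    zero where the corresponding mask is zero.  ``w_pf_pc`` and ``w_ba_pc``
    are stored as vectors (single Purkinje cell).  ``ba_pc_rescale`` logs
    the scalar applied to ``w_ba_pc`` by the Purkinje-saturation guard.
    """

    w_mf_gc: np.ndarray
    w_go_gc: np.ndarray
    w_mf_go: np.ndarray
    w_pf_go: np.ndarray
    w_pf_ba: np.ndarray
    w_pf_pc: np.ndarray
    w_ba_pc: np.ndarray
    ba_pc_rescale: float = 1.0

    def copy(self) -> "SynapseWeights":
        return SynapseWeights(
            w_mf_gc=self.w_mf_gc.copy(),
            w_go_gc=self.w_go_gc.copy(),
            w_mf_go=self.w_mf_go.copy(),
            w_pf_go=self.w_pf_go.copy(),
            w_pf_ba=self.w_pf_ba.copy(),
            w_pf_pc=self.w_pf_pc.copy(),
            w_ba_pc=self.w_ba_pc.copy(),
            ba_pc_rescale=self.ba_pc_rescale,
        )


@dataclass
class NetworkState:
    """Population firing rates at one control sample.

    ``y_go_prev`` holds the previous sample's Golgi rates: the GC<->GO
    recurrent loop is broken by a one-sample delay on the GO->GC feedback.
    """

    y_mf: np.ndarray
    y_pf: np.ndarray
    y_go: np.ndarray
    y_ba: np.ndarray
    y_pc: float
    y_go_prev: np.ndarray


def sigmoid_rate(x, sigma: float = 8.0, mu: float = 0.5):
    """Logistic activation 1 / (1 + exp(-sigma * (x - mu))), in (0, 1)."""
    return expit(sigma * (np.asarray(x, dtype=float) - mu))


def _draw_mask(rng: np.random.Generator, n_pre: int, n_post: int, k: int) -> np.ndarray:
    """Binary (n_pre x n_post) mask with exactly k ones per column."""
    mask = np.zeros((n_pre, n_post), dtype=np.int8)
    for j in range(n_post):
        partners = rng.choice(n_pre, size=k, replace=False)
        mask[partners, j] = 1
    return mask


def build_connectivity(config: NetworkConfig, seed) -> ConnectivityMasks:
    """Draw the random convergence-respecting masks.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``Generator``; per-projection substreams are spawned deterministically
    so each mask is independent of the others.
    """
    streams = _spawn_streams(seed, ["mf_gc", "go_gc", "mf_go", "pf_go", "pf_ba"])
    c = config.convergence_count
    return ConnectivityMasks(
        m_mf_gc=_draw_mask(streams["mf_gc"], config.n_mf, config.n_gc, c("mf_gc")),
        m_go_gc=_draw_mask(streams["go_gc"], config.n_go, config.n_gc, c("go_gc")),
        m_mf_go=_draw_mask(streams["mf_go"], config.n_mf, config.n_go, c("mf_go")),
        m_pf_go=_draw_mask(streams["pf_go"], config.n_gc, config.n_go, c("pf_go")),
        m_pf_ba=_draw_mask(streams["pf_ba"], config.n_gc, config.n_ba, c("pf_ba")),
    )


def _spawn_streams(seed, names):
    if isinstance(seed, np.random.Generator):
        # Already a generator: spawn children from fresh entropy of the
        # generator itself so repeated calls differ.
        base = np.random.SeedSequence(seed.integers(0, 2**63 - 1))
    elif isinstance(seed, np.random.SeedSequence):
        base = seed
    else:
        base = np.random.SeedSequence(seed)
    children = base.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    size,
) -> np.ndarray:
    """Sample Normal(mean, sd) restricted to (low, high] by rejection.

    Rejection (rather than clipping) keeps the density shape inside the
    interval and puts no point mass at the bounds.
    """
    out = np.empty(int(np.prod(size)), dtype=float)
    n_filled = 0
    while n_filled < out.size:
        draw = rng.normal(mean, sd, size=out.size - n_filled)
        keep = draw[(draw > low) & (draw <= high)]
        out[n_filled : n_filled + keep.size] = keep
        n_filled += keep.size
    return out.reshape(size)


def _balance_scale(config: NetworkConfig, proj: str) -> float:
    """Deterministic per-projection rescale applied after sampling.

    Scales the matrix so its expected column sum equals the balance target
    (expected entry magnitude is 0.5 on c nonzero entries per column); the
    scale is capped at 1 so entries never leave (0,1] / [-1,0).
    """
    if config.balance is None:
        return 1.0
    c = config.convergence_count(proj)
    target = abs(config.balance[proj])
    return min(1.0, target / (0.5 * c))


def initialize_weights(config: NetworkConfig, masks: ConnectivityMasks, seed) -> SynapseWeights:
    """Draw all weight matrices and set the network's operating point.

    Excitatory weights ~ Normal(0.5, 1) truncated to (0, 1]; inhibitory
    ~ Normal(-0.5, 1) truncated to [-1, 0).  Two corrections follow:

    1. *Drive balance* (``config.balance``): each projection is rescaled
       by a single deterministic scalar toward its preset column-sum
       target (:data:`MOTOR_BALANCE` / :data:`ROBOT_BALANCE`).  Without
       this the summed drives (755 parallel fibers onto the Purkinje cell,
       150 onto each Golgi cell) saturate every sigmoid and the GC<->GO
       loop destabilizes.
    2. *Purkinje-saturation guard*: ``w_ba_pc`` is rescaled by one scalar
       (logged in ``ba_pc_rescale``) so that the nominal Purkinje drive
       with all presynaptic rates at 0.5 is exactly the midpoint mu,
       preventing over-inhibition of the sole output cell.  The guard
       scalar can stretch basket weights beyond the unit interval the raw
       draw respects; the drawn (pre-guard) weights are recoverable by
       dividing by ``ba_pc_rescale``.
    """
    names = ["mf_gc", "go_gc", "mf_go", "pf_go", "pf_ba", "pf_pc", "ba_pc"]
    streams = _spawn_streams(seed, names)

    def exc(name, shape):
        return truncated_normal(streams[name], 0.5, 1.0, 0.0, 1.0, shape) * _balance_scale(
            config, name
        )

    def inh(name, shape):
        # Normal(-0.5, 1) on [-1, 0): sample magnitude on (0, 1] and negate.
        mag = truncated_normal(streams[name], 0.5, 1.0, 0.0, 1.0, shape)
        return -mag * _balance_scale(config, name)

    w = SynapseWeights(
        w_mf_gc=exc("mf_gc", (config.n_mf, config.n_gc)) * masks.m_mf_gc,
        w_go_gc=inh("go_gc", (config.n_go, config.n_gc)) * masks.m_go_gc,
        w_mf_go=exc("mf_go", (config.n_mf, config.n_go)) * masks.m_mf_go,
        w_pf_go=exc("pf_go", (config.n_gc, config.n_go)) * masks.m_pf_go,
        w_pf_ba=exc("pf_ba", (config.n_gc, config.n_ba)) * masks.m_pf_ba,
        w_pf_pc=exc("pf_pc", config.n_gc),
        w_ba_pc=inh("ba_pc", config.n_ba),
    )

    if config.balance is not None:
        # Guard: nominal x_PC at presynaptic rates 0.5 must sit mid-range.
        exc_sum = w.w_pf_pc.sum()
        inh_sum = w.w_ba_pc.sum()  # negative
        target_inh = 2 * config.mu - exc_sum  # so that 0.5*(exc+inh) = mu
        scale = target_inh / inh_sum if inh_sum != 0 else 1.0
        w.w_ba_pc = w.w_ba_pc * scale
        w.ba_pc_rescale = float(scale)
    return w


def encode_mossy_fibers(raw_signals, gains, sigma: float = 8.0, mu: float = 0.5) -> np.ndarray:
    """Scale raw physical signals channel-wise and sigmoid-encode to rates.

    ``raw_signals`` and ``gains`` must have one entry per mossy-fiber
    channel; the gains normalize heterogeneous units (rad, rad/s, A) so
    the scaled signal spans roughly one sigmoid width.  The scaled signal
    is centred on the activation midpoint: a zero physical signal encodes
    to the mid rate 0.5, positive and negative excursions to rates above
    and below it.  This keeps the parallel-fiber rates straddling 0.5, the
    operating point the learning rule assumes (the zero-centred factor
    y_pf - 0.5 must take both signs for balanced depression and
    potentiation).
    """
    raw = np.asarray(raw_signals, dtype=float)
    g = np.asarray(gains, dtype=float)
    if raw.shape != g.shape:
        raise ValueError(
            f"channel-count mismatch: {raw.shape[0]} raw signals for {g.shape[0]} gains"
        )
    return sigmoid_rate(g * raw + mu, sigma, mu)


def initial_state(config: NetworkConfig) -> NetworkState:
    """State with all rates at the balanced operating point (0.5)."""
    return NetworkState(
        y_mf=np.full(config.n_mf, 0.5),
        y_pf=np.full(config.n_gc, 0.5),
        y_go=np.full(config.n_go, 0.5),
        y_ba=np.full(config.n_ba, 0.5),
        y_pc=0.0,
        y_go_prev=np.full(config.n_go, 0.5),
    )


def network_step(
    state: NetworkState,
    weights: SynapseWeights,
    masks: ConnectivityMasks,
    y_mf: np.ndarray,
    config: NetworkConfig,
) -> tuple[float, NetworkState]:
    """Advance the rate dynamics by one control sample.

    Evaluation order: granule drive uses the *previous* sample's Golgi
    rates (one-sample delay closing the GC<->GO loop); Golgi drive uses the
    current parallel-fiber rates; the Purkinje rate is the sigmoid shifted
    down by 0.5 so it can be subtracted from the motor command.
    Masked projections contribute via elementwise mask*weight followed by
    the rate-vector x matrix product.
    """
    sigma, mu = config.sigma, config.mu
    y_mf = np.asarray(y_mf, dtype=float)

    x_gc = y_mf @ (masks.m_mf_gc * weights.w_mf_gc) + state.y_go_prev @ (
        masks.m_go_gc * weights.w_go_gc
    )
    y_pf = sigmoid_rate(x_gc, sigma, mu)
    x_go = y_mf @ (masks.m_mf_go * weights.w_mf_go) + y_pf @ (masks.m_pf_go * weights.w_pf_go)
    y_go = sigmoid_rate(x_go, sigma, mu)
    x_ba = y_pf @ (masks.m_pf_ba * weights.w_pf_ba)
    y_ba = sigmoid_rate(x_ba, sigma, mu)
    x_pc = y_pf @ weights.w_pf_pc + y_ba @ weights.w_ba_pc
    if not np.isfinite(x_pc):
        raise FloatingPointError("non-finite Purkinje drive")
    y_pc = float(sigmoid_rate(x_pc, sigma, mu) - 0.5)

    new_state = NetworkState(
        y_mf=y_mf,
        y_pf=y_pf,
        y_go=y_go,
        y_ba=y_ba,
        y_pc=y_pc,
        y_go_prev=y_go,
    )
    return y_pc, new_state


def apply_cf_learning(
    weights: SynapseWeights,
    y_pf: np.ndarray,
    cf_value: float,
    gamma: float,
    w_min: float = W_PFPC_MIN,
) -> SynapseWeights:
    """CF-gated plasticity at the PF->PC synapses (in place).

    dW = -gamma * (y_pf - 0.5) * CF: same-sign PF activity and CF depress
    the synapse (LTD), opposite signs potentiate it (LTP).  The updated
    weights are clipped to [w_min, 1] to stay excitatory.  No other matrix
    is touched.
    """
    if not np.isfinite(cf_value):
        raise FloatingPointError("non-finite climbing-fiber value")
    dw = -gamma * (np.asarray(y_pf, dtype=float) - 0.5) * cf_value
    np.clip(weights.w_pf_pc + dw, w_min, 1.0, out=weights.w_pf_pc)
    return weights
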