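import numpy as np
import pytest

from cerebloop import make_toy_network


@pytest.fixture
def toy():
    """(config, masks, weights) for the fully-connected 2-3-1-1-1 network."""
    return make_toy_network((2, 3, 1, 1, 1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def reference_network_step(state, weights, masks, y_mf, config):
    """Independent scalar-loop evaluation of the rate dynamics.

    Deliberately written as nested loops over explicit sums, with the same
    evaluation order as the vectorized implementation (granule drive uses
    the previous sample's Golgi rates), so it can serve as an oracle.
    """
    import math

    def sig(x):
        return 1.0 / (1.0 + math.exp(-config.sigma * (x - config.mu)))

    n_mf, n_gc = config.n_mf, config.n_gc
    n_go, n_ba = config.n_go, config.n_ba
    y_pf = []
    for j in range(n_gc):
        x = 0.0
        for i in range(n_mf):
            x += y_mf[i] * masks.m_mf_gc[i, j] * weights.w_mf_gc[i, j]
        for g in range(n_go):
            x += state.y_go_prev[g] * masks.m_go_gc[g, j] * weights.w_go_gc[g, j]
        y_pf.append(sig(x))
    y_go = []
    for g in range(n_go):
        x = 0.0
        for i in range(n_mf):
            x += y_mf[i] * masks.m_mf_go[i, g] * weights.w_mf_go[i, g]
        for j in range(n_gc):
            x += y_pf[j] * masks.m_pf_go[j, g] * weights.w_pf_go[j, g]
        y_go.append(sig(x))
    y_ba = []
    for b in range(n_ba):
        x = 0.0
        for j in range(n_gc):
            x += y_pf[j] * masks.m_pf_ba[j, b] * weights.w_pf_ba[j, b]
        y_ba.append(sig(x))
    x_pc = 0.0
    for j in range(n_gc):
        x_pc += y_pf[j] * weights.w_pf_pc[j]
    for b in range(n_ba):
        x_pc += y_ba[b] * weights.w_ba_pc[b]
    y_pc = sig(x_pc) - 0.5
    return y_pc, np.array(y_pf), np.array(y_go), np.array(y_ba)
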