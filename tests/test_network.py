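"""Unit and property tests for the cerebellar microcircuit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerebloop import (
    NetworkConfig,
    apply_cf_learning,
    build_connectivity,
    encode_mossy_fibers,
    initial_state,
    initialize_weights,
    network_step,
    sigmoid_rate,
)
from cerebloop.network import truncated_normal
from conftest import reference_network_step


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_rate(0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 1.0 / (1.0 + np.exp(4.0))), (1.0, 1.0 / (1.0 + np.exp(-4.0)))],
    )
    def test_tail_values(self, x, expected):
        assert sigmoid_rate(x) == pytest.approx(expected, abs=1e-12)

    def test_extreme_drive_is_finite(self):
        assert sigmoid_rate(-1e6) == 0.0
        assert sigmoid_rate(1e6) == 1.0


class TestConnectivity:
    @pytest.mark.parametrize(
        "proj, attr",
        [
            ("mf_gc", "m_mf_gc"),
            ("go_gc", "m_go_gc"),
            ("pf_go", "m_pf_go"),
            ("pf_ba", "m_pf_ba"),
            ("mf_go", "m_mf_go"),
        ],
    )
    def test_column_sums_equal_convergence(self, proj, attr):
        cfg = NetworkConfig(n_mf=7)
        masks = build_connectivity(cfg, 7)
        mask = getattr(masks, attr)
        assert mask.sum(axis=0).tolist() == [cfg.convergence_count(proj)] * mask.shape[1]
        # no duplicate partners possible: entries are binary
        assert set(np.unique(mask)) <= {0, 1}

    def test_total_pf_go_synapses(self):
        masks = build_connectivity(NetworkConfig(n_mf=7), 3)
        assert masks.m_pf_go.sum() == 150 * 5

    def test_reproducible(self):
        cfg = NetworkConfig(n_mf=5)
        a = build_connectivity(cfg, 11)
        b = build_connectivity(cfg, 11)
        assert np.array_equal(a.m_mf_gc, b.m_mf_gc)
        assert np.array_equal(a.m_pf_ba, b.m_pf_ba)

    def test_single_mf_forces_full_row(self):
        cfg = NetworkConfig(
            n_mf=1, n_gc=10, convergence={"mf_gc": 1, "go_gc": 3, "pf_go": 5, "pf_ba": 5}
        )
        masks = build_connectivity(cfg, 0)
        assert np.array_equal(masks.m_mf_gc, np.ones((1, 10)))

    def test_infeasible_convergence_rejected(self):
        with pytest.raises(ValueError, match="convergence"):
            NetworkConfig(n_mf=5, n_gc=10, convergence={"pf_go": 150})


class TestWeights:
    def test_truncated_normal_stays_in_interval_with_symmetric_mean(self, rng):
        x = truncated_normal(rng, 0.5, 1.0, 0.0, 1.0, 100_000)
        assert x.min() > 0.0 and x.max() <= 1.0
        # interval symmetric about the mean -> truncation leaves mean at 0.5
        assert x.mean() == pytest.approx(0.5, abs=0.005)

    def test_weight_ranges_and_mask_support(self):
        cfg = NetworkConfig(n_mf=7)
        masks = build_connectivity(cfg, 5)
        w = initialize_weights(cfg, masks, 5)
        for name, mask in [("w_mf_gc", masks.m_mf_gc), ("w_mf_go", masks.m_mf_go),
                           ("w_pf_go", masks.m_pf_go), ("w_pf_ba", masks.m_pf_ba)]:
            arr = getattr(w, name)
            on = arr[mask.astype(bool)]
            assert np.all(on > 0) and np.all(on <= 1)
            assert np.all(arr[~mask.astype(bool)] == 0)
        assert np.all(w.w_pf_pc > 0) and np.all(w.w_pf_pc <= 1)
        on = w.w_go_gc[masks.m_go_gc.astype(bool)]
        assert np.all(on < 0) and np.all(on >= -1)
        # basket weights are the drawn [-1, 0) values times the logged guard
        drawn = w.w_ba_pc / w.ba_pc_rescale
        assert np.all(drawn < 0) and np.all(drawn >= -1)

    def test_guard_centres_nominal_purkinje_drive(self):
        cfg = NetworkConfig(n_mf=7)
        masks = build_connectivity(cfg, 5)
        w = initialize_weights(cfg, masks, 5)
        baseline = 0.5 * w.w_pf_pc.sum() + 0.5 * w.w_ba_pc.sum()
        assert baseline == pytest.approx(cfg.mu, abs=1e-9)

    def test_same_seed_identical(self):
        cfg = NetworkConfig(n_mf=5)
        masks = build_connectivity(cfg, 2)
        a = initialize_weights(cfg, masks, 9)
        b = initialize_weights(cfg, masks, 9)
        assert np.array_equal(a.w_pf_pc, b.w_pf_pc)
        assert np.array_equal(a.w_mf_gc, b.w_mf_gc)


class TestMossyEncoding:
    def test_zero_signal_encodes_midrate(self):
        y = encode_mossy_fibers(np.zeros(5), np.ones(5))
        assert np.allclose(y, 0.5)

    def test_signed_signals_straddle_midrate(self):
        y = encode_mossy_fibers(np.array([-10.0, 10.0]), np.array([1.0, 1.0]))
        assert y[0] < 0.01 and y[1] > 0.99

    def test_channel_mismatch_raises(self):
        with pytest.raises(ValueError, match="channel-count mismatch"):
            encode_mossy_fibers(np.zeros(5), np.ones(7))


class TestNetworkStep:
    def test_matches_scalar_reference_on_toy(self, toy):
        cfg, masks, weights = toy
        state = initial_state(cfg)
        y_mf = np.array([0.3, 0.8])
        # perturb weights off the uniform default to exercise every term
        weights.w_mf_gc[0, 1] = 0.9
        weights.w_go_gc[0, 2] = -0.25
        weights.w_pf_pc[:] = [0.2, 0.6, 0.9]
        for _ in range(3):  # several steps so y_go_prev propagates
            expected = reference_network_step(state, weights, masks, y_mf, cfg)
            y_pc, state = network_step(state, weights, masks, y_mf, cfg)
            assert y_pc == pytest.approx(expected[0], abs=1e-12)
            np.testing.assert_allclose(state.y_pf, expected[1], atol=1e-12)
            np.testing.assert_allclose(state.y_go, expected[2], atol=1e-12)
            np.testing.assert_allclose(state.y_ba, expected[3], atol=1e-12)

    def test_matches_reference_on_random_networks(self, rng):
        cfg = NetworkConfig(
            n_mf=3, n_gc=5, n_go=2, n_ba=2,
            convergence={"mf_gc": 2, "go_gc": 2, "pf_go": 3, "pf_ba": 4},
        )
        masks = build_connectivity(cfg, 21)
        weights = initialize_weights(cfg, masks, 22)
        state = initial_state(cfg)
        for _ in range(5):
            y_mf = rng.uniform(0.05, 0.95, cfg.n_mf)
            expected = reference_network_step(state, weights, masks, y_mf, cfg)
            y_pc, state = network_step(state, weights, masks, y_mf, cfg)
            assert y_pc == pytest.approx(expected[0], abs=1e-12)
            np.testing.assert_allclose(state.y_pf, expected[1], atol=1e-12)

    def test_rate_bounds_hold(self, rng):
        cfg = NetworkConfig(n_mf=7)
        masks = build_connectivity(cfg, 1)
        weights = initialize_weights(cfg, masks, 1)
        state = initial_state(cfg)
        for _ in range(20):
            y_mf = rng.uniform(0.0, 1.0, cfg.n_mf)
            y_pc, state = network_step(state, weights, masks, y_mf, cfg)
            # mathematically open intervals; deeply saturated drives can
            # round onto the bound at double precision
            assert -0.5 <= y_pc <= 0.5
            for arr in (state.y_pf, state.y_go, state.y_ba):
                assert np.all(arr >= 0) and np.all(arr <= 1)

    def test_zero_drive_purkinje(self, toy):
        cfg, masks, weights = toy
        weights.w_pf_pc[:] = 0.0
        weights.w_ba_pc[:] = 0.0
        state = initial_state(cfg)
        y_pc, _ = network_step(state, weights, masks, np.full(2, 0.5), cfg)
        assert y_pc == pytest.approx(sigmoid_rate(0.0) - 0.5, abs=1e-12)

    def test_nonfinite_drive_raises(self, toy):
        cfg, masks, weights = toy
        weights.w_pf_pc[:] = np.inf
        with pytest.raises(FloatingPointError):
            network_step(initial_state(cfg), weights, masks, np.full(2, 0.5), cfg)


class TestLearning:
    @pytest.mark.parametrize(
        "y_pf, cf, expected_dw",
        [
            (0.5, 0.7, 0.0),  # zero-centred rate -> no change
            (1.0, 0.5, -0.002),  # same signs -> depression
            (0.0, 0.5, +0.002),  # opposite signs -> potentiation
        ],
    )
    def test_rule_values(self, toy, y_pf, cf, expected_dw):
        cfg, masks, weights = toy
        w0 = weights.w_pf_pc.copy()
        apply_cf_learning(weights, np.full(cfg.n_gc, y_pf), cf, gamma=0.008)
        np.testing.assert_allclose(weights.w_pf_pc - w0, expected_dw, atol=1e-15)

    def test_only_pf_pc_changes(self, toy, rng):
        cfg, masks, weights = toy
        frozen = {
            name: getattr(weights, name).copy()
            for name in ("w_mf_gc", "w_go_gc", "w_mf_go", "w_pf_go", "w_pf_ba", "w_ba_pc")
        }
        for _ in range(50):
            apply_cf_learning(weights, rng.uniform(0, 1, cfg.n_gc), rng.normal(), 0.008)
        for name, orig in frozen.items():
            assert np.array_equal(getattr(weights, name), orig)

    def test_null_cf_is_exact_identity(self, toy, rng):
        cfg, masks, weights = toy
        w0 = weights.w_pf_pc.copy()
        for _ in range(100):
            apply_cf_learning(weights, rng.uniform(0, 1, cfg.n_gc), 0.0, 0.008)
        assert np.array_equal(weights.w_pf_pc, w0)

    def test_clipping_keeps_weights_positive_and_bounded(self, toy):
        cfg, masks, weights = toy
        for _ in range(10_000):
            apply_cf_learning(weights, np.ones(cfg.n_gc), 1.0, 0.008)
        assert np.all(weights.w_pf_pc >= 1e-6)
        for _ in range(20_000):
            apply_cf_learning(weights, np.zeros(cfg.n_gc), 1.0, 0.008)
        assert np.all(weights.w_pf_pc <= 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        y=st.floats(0.0, 1.0),
        cf=st.floats(-2.0, 2.0),
        gamma=st.floats(1e-4, 0.05),
    )
    def test_antisymmetry_before_clipping(self, y, cf, gamma):
        """dw(y, cf) == dw(1 - y, -cf) for the unclipped update."""
        dw1 = -gamma * (y - 0.5) * cf
        dw2 = -gamma * ((1.0 - y) - 0.5) * (-cf)
        assert dw1 == pytest.approx(dw2, abs=1e-15)

    def test_rule_matches_bruteforce_triples(self, rng):
        y = rng.uniform(0, 1, 10_000)
        cf = rng.normal(0, 0.5, 10_000)
        gammas = rng.uniform(1e-4, 0.02, 10_000)
        from cerebloop.network import SynapseWeights

        for k in range(0, 10_000, 500):
            w = np.full(1, 0.5)
            weights = _single_weight(w.copy())
            apply_cf_learning(weights, np.array([y[k]]), cf[k], gammas[k])
            expected = np.clip(0.5 - gammas[k] * (y[k] - 0.5) * cf[k], 1e-6, 1.0)
            assert weights.w_pf_pc[0] == pytest.approx(expected, abs=1e-15)


def _single_weight(w):
    from cerebloop.network import SynapseWeights

    z = np.zeros((1, 1))
    return SynapseWeights(
        w_mf_gc=z, w_go_gc=z, w_mf_go=z, w_pf_go=z, w_pf_ba=z, w_pf_pc=w, w_ba_pc=np.zeros(1)
    )
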