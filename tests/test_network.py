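"""Surrogate network: normalization, forward pass, residuals, and the
analytic Jacobian against finite differences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorhythm.integrate import Dataset
from neurorhythm.network import (
    MLPSurrogate,
    NormalizationMap,
    forward,
    get_weights,
    init_network,
    jacobian,
    load_network,
    n_weights,
    residuals,
    save_network,
    set_weights,
)


def toy_dataset(n=11, k=3, seed=0):
    rng = np.random.default_rng(seed)
    return Dataset(inputs=np.linspace(0, 5, n), targets=rng.normal(size=(k, n)))


class TestNormalization:
    def test_round_trip(self):
        m = NormalizationMap.fit(np.linspace(0, 5, 100))
        x = np.array([0.0, 1.3, 5.0])
        np.testing.assert_allclose(m.inverse(m.transform(x)), x, atol=1e-12)
        np.testing.assert_allclose(m.transform(np.array([0.0, 5.0])), [-1.0, 1.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        lo=st.floats(-100, 100),
        span=st.floats(1e-6, 200),
        frac=st.floats(0, 1),
    )
    def test_round_trip_property(self, lo, span, frac):
        m = NormalizationMap(lo, lo + span)
        x = np.array([lo + frac * span])
        np.testing.assert_allclose(m.inverse(m.transform(x)), x,
                                   rtol=1e-12, atol=1e-9)

    def test_degenerate_range_maps_to_zero(self):
        m = NormalizationMap.fit(np.full(5, 2.0))
        np.testing.assert_array_equal(m.transform(np.array([2.0, 7.0])), [0.0, 0.0])
        np.testing.assert_array_equal(m.inverse(np.array([0.0])), [2.0])


class TestInit:
    @pytest.mark.parametrize("H, expected", [(20, 103), (50, 253), (100, 503)])
    def test_weight_count(self, H, expected):
        assert n_weights(H) == expected
        net = init_network(H, toy_dataset(), seed=0)
        assert net.n_weights == expected

    def test_seed_determinism(self):
        data = toy_dataset()
        a = init_network(8, data, seed=42)
        b = init_network(8, data, seed=42)
        c = init_network(8, data, seed=43)
        np.testing.assert_array_equal(get_weights(a), get_weights(b))
        assert not np.array_equal(get_weights(a), get_weights(c))

    def test_rejects_bad_width(self):
        with pytest.raises(ValueError, match=">= 1"):
            init_network(0, toy_dataset(), seed=0)


class TestForward:
    def test_zero_weights_give_bias(self):
        net = init_network(4, toy_dataset(), seed=0)
        net = set_weights(net, np.zeros(net.n_weights))
        net = MLPSurrogate(input_map=net.input_map, W1=net.W1, b1=net.b1,
                           W2=net.W2, b2=np.array([1.5, -2.0, 0.0]))
        out = forward(net, np.linspace(0, 5, 7))
        np.testing.assert_allclose(out, np.tile([[1.5], [-2.0], [0.0]], 7))

    def test_single_unit_sigma_zero_is_half(self):
        net = MLPSurrogate(
            input_map=NormalizationMap(0.0, 5.0),
            W1=np.array([0.0]), b1=np.array([0.0]),
            W2=np.array([[1.0]]), b2=np.array([0.0]),
        )
        np.testing.assert_allclose(forward(net, np.array([0.0, 2.5, 5.0])), 0.5)

    def test_hand_computed_two_unit_net(self):
        # H=2, k=1, integer weights; value at t=5 (normalised input 1):
        #   a = [sigma(1*1+0), sigma(-2*1+1)] = [sigma(1), sigma(-1)]
        #   out = 2*sigma(1) - 3*sigma(-1) + 1
        net = MLPSurrogate(
            input_map=NormalizationMap(0.0, 5.0),
            W1=np.array([1.0, -2.0]), b1=np.array([0.0, 1.0]),
            W2=np.array([[2.0, -3.0]]), b2=np.array([1.0]),
        )
        sig = lambda z: 1 / (1 + np.exp(-z))
        expected = 2 * sig(1.0) - 3 * sig(-1.0) + 1.0
        np.testing.assert_allclose(forward(net, np.array([5.0]))[0, 0], expected,
                                   rtol=1e-14)

    def test_bounded_by_output_weights(self):
        net = init_network(16, toy_dataset(), seed=3)
        out = forward(net, np.linspace(-10, 10, 201))
        bound = np.abs(net.b2)[:, None] + np.abs(net.W2).sum(axis=1)[:, None]
        assert (np.abs(out) <= bound + 1e-12).all()

    def test_batch_order_independence(self):
        net = init_network(6, toy_dataset(), seed=1)
        t = np.linspace(0, 5, 13)
        perm = np.random.default_rng(0).permutation(13)
        np.testing.assert_array_equal(forward(net, t)[:, perm], forward(net, t[perm]))


class TestResiduals:
    def test_matching_constant_net_zero_residuals(self):
        data = Dataset(inputs=np.linspace(0, 5, 9), targets=np.full((3, 9), 2.0))
        net = init_network(4, data, seed=0)
        net = set_weights(net, np.zeros(net.n_weights))
        net = MLPSurrogate(input_map=net.input_map, W1=net.W1, b1=net.b1,
                           W2=net.W2, b2=np.full(3, 2.0))
        e = residuals(net, data, np.arange(9))
        np.testing.assert_array_equal(e, np.zeros(27))

    def test_unit_bias_against_zero_targets(self):
        data = Dataset(inputs=np.linspace(0, 5, 5), targets=np.zeros((3, 5)))
        net = init_network(2, data, seed=0)
        net = set_weights(net, np.zeros(net.n_weights))
        net = MLPSurrogate(input_map=net.input_map, W1=net.W1, b1=net.b1,
                           W2=net.W2, b2=np.ones(3))
        e = residuals(net, data, np.arange(5))
        np.testing.assert_array_equal(e, -np.ones(15))
        assert np.mean(e**2) == 1.0

    def test_mse_matches_naive_loop(self):
        data = toy_dataset(n=17, seed=4)
        net = init_network(5, data, seed=5)
        subset = np.array([0, 3, 4, 10, 16])
        e = residuals(net, data, subset)
        total, count = 0.0, 0
        out = forward(net, data.inputs)
        for q in range(3):
            for i in subset:
                total += (data.targets[q, i] - out[q, i]) ** 2
                count += 1
        np.testing.assert_allclose(np.mean(e**2), total / count, rtol=1e-12)

    def test_empty_subset_rejected(self):
        data = toy_dataset()
        net = init_network(3, data, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            residuals(net, data, np.array([], dtype=int))


class TestJacobian:
    def test_dimensions(self):
        data = toy_dataset(n=9)
        net = init_network(7, data, seed=0)
        J = jacobian(net, data, np.arange(4))
        assert J.shape == (12, n_weights(7))

    def test_output_bias_columns(self):
        data = toy_dataset(n=6)
        net = init_network(4, data, seed=2)
        J = jacobian(net, data, np.arange(6))
        H = 4
        for q in range(3):
            col = J[:, 2 * H + 3 * H + q]
            expected = np.zeros(18)
            expected[q * 6 : (q + 1) * 6] = -1.0
            np.testing.assert_array_equal(col, expected)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_central_finite_differences(self, trial):
        """Analytic backprop columns vs (e(w+h) - e(w-h)) / 2h."""
        rng = np.random.default_rng(trial)
        n, H = 7, 3
        data = Dataset(inputs=np.linspace(0, 5, n), targets=rng.normal(size=(3, n)))
        net = init_network(H, data, seed=trial + 100)
        subset = np.arange(n)
        J = jacobian(net, data, subset)
        w0 = get_weights(net)
        h = 1e-6
        for col in range(w0.size):
            wp, wm = w0.copy(), w0.copy()
            wp[col] += h
            wm[col] -= h
            fd = (residuals(set_weights(net, wp), data, subset)
                  - residuals(set_weights(net, wm), data, subset)) / (2 * h)
            np.testing.assert_allclose(J[:, col], fd, rtol=1e-5, atol=1e-8)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        net = init_network(6, toy_dataset(), seed=9)
        path = tmp_path / "net.json"
        save_network(net, path)
        again = load_network(path)
        np.testing.assert_array_equal(get_weights(net), get_weights(again))
        assert again.input_map == net.input_map
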