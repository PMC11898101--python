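"""KAN layers and models: scalar oracles, gradients, accounting, round-trips."""

import numpy as np
import pytest

import kandetect as kd
from kandetect.kan import edge_activation
from kandetect.splines import bspline_basis, make_grid
from kandetect.training import _softmax_ce


def scalar_edge(x, coeffs, w, s, cfg):
    """Independent scalar oracle for one edge activation."""
    grid = make_grid(cfg.grid_size, cfg.grid_range)
    basis = bspline_basis(float(x), grid, cfg.spline_order)
    base = x / (1.0 + np.exp(-x)) if cfg.base_function == "silu" else (
        x if cfg.base_function == "identity" else 0.0
    )
    return w * base + s * float(np.dot(coeffs, basis))


def scalar_layer(x, layer):
    """Double loop over edges — the brute-force layer oracle."""
    out = np.zeros(layer.out_dim)
    for o in range(layer.out_dim):
        for i in range(layer.in_dim):
            out[o] += scalar_edge(
                x[i],
                layer.spline_coeffs[o, i],
                layer.base_weight[o, i],
                layer.spline_scale[o, i],
                layer.cfg,
            )
    return out


def scalar_model(x, model):
    h = np.asarray(x, dtype=float)
    for lay in model.layers:
        h = scalar_layer(h, lay)
    return h


class TestEdgeActivation:
    def test_zero_parameters_give_zero(self):
        cfg = kd.SplineConfig()
        for x in (-2.0, 0.0, 0.7, 3.5):
            assert edge_activation(x, np.zeros(cfg.n_basis), 0.0, 1.0, cfg) == 0.0

    def test_linear_in_coefficients(self, rng):
        cfg = kd.SplineConfig()
        c = rng.normal(size=cfg.n_basis)
        x = rng.uniform(-1, 1, 50)
        one = edge_activation(x, c, 0.0, 1.0, cfg)
        two = edge_activation(x, 2 * c, 0.0, 1.0, cfg)
        np.testing.assert_allclose(two, 2 * one, atol=1e-12)

    def test_least_squares_fit_recovers_sine(self, rng):
        """A G=20 cubic spline fit of sin reaches max error below 1e-3."""
        cfg = kd.SplineConfig(grid_size=20, spline_order=3, base_function="none")
        grid = make_grid(20, (-1, 1))
        xs = np.linspace(-1, 1, 400)
        design = bspline_basis(xs, grid, 3)
        coeffs, *_ = np.linalg.lstsq(design, np.sin(xs), rcond=None)
        dense = np.linspace(-0.999, 0.999, 2000)
        fit = edge_activation(dense, coeffs, 0.0, 1.0, cfg)
        assert np.max(np.abs(fit - np.sin(dense))) < 1e-3

    def test_rejects_non_finite_parameters(self):
        cfg = kd.SplineConfig()
        with pytest.raises(ValueError, match="finite"):
            edge_activation(0.5, np.full(cfg.n_basis, np.nan), 0.0, 1.0, cfg)


class TestForwardOracles:
    def test_single_edge_layer_reduces_to_edge_activation(self, rng):
        lay = kd.KANLayer(1, 1, rng=rng)
        for x in rng.uniform(-2, 2, 10):
            expect = edge_activation(
                float(x),
                lay.spline_coeffs[0, 0],
                float(lay.base_weight[0, 0]),
                float(lay.spline_scale[0, 0]),
                lay.cfg,
            )
            np.testing.assert_allclose(lay.forward([[x]])[0, 0], expect, atol=1e-10)

    def test_layer_forward_matches_double_loop(self, rng):
        lay = kd.KANLayer(3, 2, rng=rng)
        x = rng.uniform(-1.5, 1.5, (8, 3))
        out = lay.forward(x)
        for n in range(8):
            np.testing.assert_allclose(out[n], scalar_layer(x[n], lay), atol=1e-8)

    def test_model_forward_matches_nested_loops_many_instances(self, rng):
        """100+ random small models agree with the fully scalar oracle."""
        checked = 0
        for trial in range(100):
            dims = rng.integers(1, 6, size=rng.integers(2, 4))
            spec = "I-" + "-".join(str(d) for d in dims[1:-1]) + "-O" if len(dims) > 2 else "I-O"
            model = kd.KANModel.from_spec(spec, int(dims[0]), int(dims[-1]), seed=int(trial))
            x = rng.uniform(-2, 2, int(dims[0]))
            np.testing.assert_allclose(model.forward(x)[0], scalar_model(x, model), atol=1e-8)
            checked += 1
        assert checked == 100

    def test_batched_equals_per_sample(self, rng):
        model = kd.KANModel.from_spec("I-4-O", 3, 2, seed=0)
        x = rng.uniform(-2, 2, (16, 3))
        batched = model.forward(x)
        single = np.vstack([model.forward(x[i]) for i in range(16)])
        np.testing.assert_allclose(batched, single, atol=1e-12)

    def test_input_permutation_symmetry(self, rng):
        """Permuting inputs together with edge-parameter slices is a no-op."""
        lay = kd.KANLayer(4, 3, rng=rng)
        x = rng.uniform(-1, 1, (5, 4))
        perm = np.array([2, 0, 3, 1])
        out = lay.forward(x)
        lay.spline_coeffs = lay.spline_coeffs[:, perm]
        lay.base_weight = lay.base_weight[:, perm]
        lay.spline_scale = lay.spline_scale[:, perm]
        np.testing.assert_allclose(lay.forward(x[:, perm]), out, atol=1e-12)

    def test_identity_second_layer_passthrough(self):
        """A second layer configured as identity leaves layer-1 output alone."""
        model = kd.KANModel.from_spec("I-2-O", 3, 2, seed=1)
        second = model.layers[1]
        cfg = kd.SplineConfig(base_function="identity")
        ident = kd.KANLayer(2, 2, cfg=cfg)
        ident.spline_coeffs[...] = 0.0
        ident.base_weight[...] = np.eye(2)
        model.layers[1] = ident
        x = np.random.default_rng(0).uniform(-1, 1, (6, 3))
        np.testing.assert_allclose(model.forward(x), model.layers[0].forward(x), atol=1e-12)

    def test_shape_errors_name_dims(self):
        lay = kd.KANLayer(3, 2)
        with pytest.raises(ValueError, match="in_dim=3"):
            lay.forward(np.zeros((4, 5)))


class TestExactForm:
    def test_two_input_exact_form_has_width_five_hidden(self):
        model = kd.exact_form_model(2)
        assert model.widths == [2, 5, 1]

    def test_general_width_rule(self):
        for n in (1, 3, 7):
            assert kd.exact_form_model(n).widths == [n, 2 * n + 1, 1]


class TestGradients:
    def test_gradients_match_central_differences(self, rng):
        """Analytic grads of the cross-entropy match finite differences."""
        model = kd.KANModel.from_spec("I-4-3-O", 3, 2, seed=7)
        x = rng.uniform(-2.5, 2.5, (6, 3))
        y = rng.integers(0, 2, 6)
        loss, grad = _softmax_ce(model.forward(x, cache=True), y)
        model.backward(grad)
        eps = 1e-6
        for lay in model.layers:
            for name, p in lay.parameters().items():
                flat = p.ravel()
                g = lay.grads[name].ravel()
                for idx in rng.choice(flat.size, size=min(8, flat.size), replace=False):
                    old = flat[idx]
                    flat[idx] = old + eps
                    lp = _softmax_ce(model.forward(x), y)[0]
                    flat[idx] = old - eps
                    lm = _softmax_ce(model.forward(x), y)[0]
                    flat[idx] = old
                    fd = (lp - lm) / (2 * eps)
                    assert abs(fd - g[idx]) <= 1e-4 * max(1.0, abs(fd)), (name, idx)


class TestArchStats:
    def test_neuron_reduction_against_printed_table(self):
        base = "I-764-256-O"
        d = 19 * 23 * 125
        assert kd.arch_stats("I-32-32-O", d, 2, baseline=base).neuron_reduction_pct == 6.27
        assert kd.arch_stats("I-32-16-O", d, 2, baseline=base).neuron_reduction_pct == 4.71

    def test_self_comparison_is_100(self):
        st = kd.arch_stats("I-764-256-O", 100, 2, baseline="I-764-256-O")
        assert st.neuron_reduction_pct == 100.00
        assert st.param_reduction_pct == 100.00

    def test_hidden_neuron_and_layer_counts(self):
        st = kd.arch_stats("I-32-16-O", 10, 2)
        assert st.hidden_neurons == 48
        assert st.n_layers == 3

    def test_parameter_count_matches_live_model(self):
        model = kd.KANModel.from_spec("I-5-3-O", 4, 2, seed=0)
        assert kd.arch_stats("I-5-3-O", 4, 2).n_parameters == model.n_parameters

    def test_parameter_count_monotonicity(self):
        d, o = 10, 2
        base = kd.arch_stats("I-8-4-O", d, o).n_parameters
        assert kd.arch_stats("I-9-4-O", d, o).n_parameters > base
        assert kd.arch_stats("I-8-5-O", d, o).n_parameters > base
        g = kd.arch_stats("I-8-4-O", d, o, cfg=kd.SplineConfig(grid_size=6)).n_parameters
        k = kd.arch_stats("I-8-4-O", d, o, cfg=kd.SplineConfig(spline_order=4)).n_parameters
        assert g > base and k > base

    @pytest.mark.parametrize("bad", ["32-16", "I-32--16-O", "I-0-O", "I-32-x-O", "O-32-I"])
    def test_malformed_spec_raises_with_token(self, bad):
        with pytest.raises(ValueError):
            kd.parse_spec(bad)


class TestSerialization:
    def test_round_trip_preserves_forward(self, tmp_path, rng):
        model = kd.KANModel.from_spec("I-6-4-O", 5, 2, seed=3)
        path = tmp_path / "model.npz"
        kd.save_model(model, path)
        loaded = kd.load_model(path)
        x = rng.uniform(-2, 2, (100, 5))
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))

    def test_two_saves_are_byte_identical(self, tmp_path):
        model = kd.KANModel.from_spec("I-4-O", 3, 2, seed=9)
        p1, p2 = tmp_path / "a.npz", tmp_path / "b.npz"
        kd.save_model(model, p1)
        kd.save_model(model, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_file_raises_format_error(self, tmp_path):
        path = tmp_path / "empty.npz"
        path.write_bytes(b"")
        with pytest.raises(ValueError, match="checkpoint"):
            kd.load_model(path)

    def test_config_survives_round_trip(self, tmp_path):
        cfg = kd.SplineConfig(grid_size=7, spline_order=2, grid_range=(-2, 2),
                              base_function="identity")
        model = kd.KANModel.from_spec("I-3-O", 2, 2, cfg=cfg, seed=0)
        kd.save_model(model, tmp_path / "m.npz")
        loaded = kd.load_model(tmp_path / "m.npz")
        assert loaded.layers[0].cfg == cfg


class TestFunctionRecovery:
    def test_recovers_additive_target_for_most_seeds(self):
        """An I-5-O net (G=10, k=3) learns sin(pi x1) + x2^2 to RMSE < 0.05."""
        passed = 0
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(-1, 1, (2048, 2))
            y = np.sin(np.pi * x[:, 0]) + x[:, 1] ** 2
            xh = rng.uniform(-1, 1, (512, 2))
            yh = np.sin(np.pi * xh[:, 0]) + xh[:, 1] ** 2
            cfg = kd.SplineConfig(grid_size=10, spline_order=3)
            model = kd.KANModel.from_spec("I-5-O", 2, 1, cfg=cfg, seed=seed)
            kd.fit_regression(model, x, y, epochs=250, lr=2e-2, batch_size=256, seed=seed)
            rmse = float(np.sqrt(np.mean((model.forward(xh)[:, 0] - yh) ** 2)))
            passed += rmse < 0.05
        assert passed >= 4
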