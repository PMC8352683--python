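"""Network forward/backward correctness against independent oracles."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from symdx.nn import (
    NetworkParams,
    forward,
    gradients,
    hidden_size,
    init_network,
    loss,
    one_hot,
    predict,
    train,
)


def naive_forward(params, x):
    """Straight loop transcription of the layer equations; the oracle
    deliberately avoids every vectorised shortcut of the implementation."""
    N, Y, G = params.n_in, params.n_hidden, params.n_out
    hn = [sum(params.w_in[n, p] * x[n] for n in range(N))
          - params.w_in[N, p] for p in range(Y)]
    ho = [1.0 / (1.0 + math.exp(-v)) for v in hn]
    yn = [sum(params.w_out[p, q] * ho[p] for p in range(Y))
          - params.w_out[Y, q] for q in range(G)]
    exps = [math.exp(v) for v in yn]
    yo = [e / sum(exps) for e in exps]
    return hn, ho, yn, yo


def finite_difference_grads(params, x, d, weight=1.0, h=1e-5):
    """Central differences of loss(forward(.)) in every weight."""
    def loss_at(p):
        return loss(forward(p, x).yo, d, weight)

    g_out = np.zeros_like(params.w_out)
    g_in = np.zeros_like(params.w_in)
    for mat, grad in ((params.w_out, g_out), (params.w_in, g_in)):
        it = np.nditer(mat, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = mat[idx]
            mat[idx] = orig + h
            up = loss_at(params)
            mat[idx] = orig - h
            down = loss_at(params)
            mat[idx] = orig
            grad[idx] = (up - down) / (2 * h)
    return g_out, g_in


class TestArchitecture:
    @pytest.mark.parametrize("n_in, n_out, y", [(11, 10, 31), (2, 2, 14), (40, 3, 53)])
    def test_hidden_width_rule(self, n_in, n_out, y):
        assert hidden_size(n_in, n_out) == y
        params = init_network(n_in, n_out, seed=0)
        assert params.n_hidden == y
        assert params.w_in.shape == (n_in + 1, y)
        assert params.w_out.shape == (y + 1, n_out)

    def test_seeded_init_is_bit_identical(self):
        a = init_network(5, 3, seed=42)
        b = init_network(5, 3, seed=42)
        assert np.array_equal(a.w_in, b.w_in) and np.array_equal(a.w_out, b.w_out)
        c = init_network(5, 3, seed=43)
        assert not np.array_equal(a.w_in, c.w_in)

    @pytest.mark.parametrize("n_in, n_out", [(0, 3), (3, 1), (3, 0)])
    def test_degenerate_dimensions_rejected(self, n_in, n_out):
        with pytest.raises(ValueError):
            init_network(n_in, n_out, seed=0)

    def test_json_round_trip(self, tmp_path):
        params = init_network(4, 3, seed=5)
        path = tmp_path / "net.json"
        params.to_json(path)
        loaded = NetworkParams.from_json(path)
        assert np.array_equal(loaded.w_in, params.w_in)
        assert np.array_equal(loaded.w_out, params.w_out)
        assert loaded.eta == params.eta


class TestForward:
    def test_matches_naive_transcription(self, rng):
        for _ in range(10):
            n_in = int(rng.integers(2, 6))
            n_out = int(rng.integers(2, 5))
            params = init_network(n_in, n_out, seed=int(rng.integers(1 << 30)))
            x = rng.integers(0, 2, size=n_in).astype(float)
            trace = forward(params, x)
            hn, ho, yn, yo = naive_forward(params, x)
            np.testing.assert_allclose(trace.hn, hn, atol=1e-12)
            np.testing.assert_allclose(trace.ho, ho, atol=1e-12)
            np.testing.assert_allclose(trace.yn, yn, atol=1e-12)
            np.testing.assert_allclose(trace.yo, yo, atol=1e-12)

    def test_zero_weights_give_uniform_output(self):
        params = init_network(3, 4, seed=0)
        params.w_in[:] = 0.0
        params.w_out[:] = 0.0
        trace = forward(params, [1, 0, 1])
        np.testing.assert_allclose(trace.yo, 0.25, atol=1e-15)
        assert predict(params, [1, 0, 1]) == 0  # tie broken to lowest index

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_softmax_normalisation_and_range(self, seed):
        rng = np.random.default_rng(seed)
        params = init_network(int(rng.integers(1, 8)), int(rng.integers(2, 6)),
                              seed=seed)
        params.w_in *= rng.uniform(0.1, 5)
        params.w_out *= rng.uniform(0.1, 5)
        x = rng.integers(0, 2, size=params.n_in)
        trace = forward(params, x)
        assert abs(trace.yo.sum() - 1.0) <= 1e-12
        assert np.all(trace.yo > 0) and np.all(trace.yo < 1)
        assert np.all((trace.ho > 0) & (trace.ho < 1))

    def test_extreme_weights_stay_finite_and_normalised(self, rng):
        # saturation regime: activations clip to the interval ends in
        # float arithmetic, but nothing overflows and softmax still sums to 1
        params = init_network(6, 4, seed=1)
        params.w_in *= 500
        params.w_out *= 500
        trace = forward(params, rng.integers(0, 2, size=6))
        assert np.isfinite(trace.yo).all() and np.isfinite(trace.ho).all()
        assert abs(trace.yo.sum() - 1.0) <= 1e-12
        assert np.all((trace.ho >= 0) & (trace.ho <= 1))

    def test_dimension_mismatch_rejected(self):
        params = init_network(3, 2, seed=0)
        with pytest.raises(ValueError):
            forward(params, [1, 0])


class TestLoss:
    def test_uniform_output_costs_log_gamma(self):
        for gamma in (2, 5, 9):
            yo = np.full(gamma, 1.0 / gamma)
            assert loss(yo, one_hot(0, gamma)) == pytest.approx(math.log(gamma))

    def test_confident_correct_output_costs_nothing(self):
        assert loss([1.0, 0.0, 0.0], one_hot(0, 3)) == 0.0

    def test_weight_scales_linearly(self, rng):
        yo = rng.dirichlet(np.ones(4))
        d = one_hot(2, 4)
        assert loss(yo, d, weight=2.0) == pytest.approx(2 * loss(yo, d))


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        for _ in range(10):
            params = init_network(3, 3, eta=0.1, seed=int(rng.integers(1 << 30)))
            x = rng.integers(0, 2, size=3).astype(float)
            d = one_hot(int(rng.integers(3)), 3)
            g_out, g_in = gradients(params, x, d)
            fd_out, fd_in = finite_difference_grads(params, x, d)
            assert np.max(np.abs(g_out - fd_out)) <= 1e-6
            assert np.max(np.abs(g_in - fd_in)) <= 1e-6

    def test_weight_scales_gradients_exactly(self, rng):
        params = init_network(4, 3, seed=11)
        x = rng.integers(0, 2, size=4).astype(float)
        d = one_hot(1, 3)
        g_out1, g_in1 = gradients(params, x, d, weight=1.0)
        g_out3, g_in3 = gradients(params, x, d, weight=3.0)
        np.testing.assert_allclose(g_out3, 3 * g_out1, rtol=1e-15)
        np.testing.assert_allclose(g_in3, 3 * g_in1, rtol=1e-15)

    def test_zero_gradient_when_output_equals_target(self):
        # feeding the network's own output back as the target puts the
        # output error signal exactly at zero, so nothing propagates
        params = init_network(3, 3, seed=2)
        x = np.array([1.0, 0.0, 1.0])
        yo = forward(params, x).yo
        g_out, g_in = gradients(params, x, yo)
        assert np.allclose(g_out, 0, atol=1e-15)
        assert np.allclose(g_in, 0, atol=1e-15)


class TestTraining:
    def _toy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        D = np.array([one_hot(0, 2), one_hot(0, 2), one_hot(1, 2), one_hot(1, 2)])
        return X, D

    def test_zero_learning_rate_changes_nothing(self):
        X, D = self._toy()
        params = init_network(2, 2, seed=0)
        params.eta = 0.0
        trained, _ = train(params, X, D, epochs=5, shuffle_seed=0)
        assert np.array_equal(trained.w_in, params.w_in)
        assert np.array_equal(trained.w_out, params.w_out)

    def test_loss_decreases_on_separable_toy(self):
        X, D = self._toy()
        params = init_network(2, 2, eta=0.5, seed=3)
        _, history = train(params, X, D, epochs=500, shuffle_seed=1)
        assert history[-1] < history[0]
        assert history[-1] < 0.1

    def test_single_small_step_does_not_increase_sample_loss(self, rng):
        for _ in range(10):
            params = init_network(3, 3, eta=1e-4, seed=int(rng.integers(1 << 30)))
            x = rng.integers(0, 2, size=3).astype(float)
            d = one_hot(int(rng.integers(3)), 3)
            before = loss(forward(params, x).yo, d)
            trained, _ = train(params, [x], [d], epochs=1, shuffle_seed=0)
            after = loss(forward(trained, x).yo, d)
            assert after <= before + 1e-12

    def test_training_is_deterministic_per_seed(self):
        X, D = self._toy()
        runs = [train(init_network(2, 2, seed=7), X, D, epochs=50,
                      shuffle_seed=9)[0] for _ in range(2)]
        assert np.array_equal(runs[0].w_in, runs[1].w_in)
        assert np.array_equal(runs[0].w_out, runs[1].w_out)

    def test_learns_disjoint_category_profiles(self):
        from symdx.cascade import CascadeConfig
        from symdx.synthetic import GeneratorConfig, generate_records, generate_taxonomy

        cfg = GeneratorConfig(B=3, t_b_range=(1, 1), t_bj_range=(2, 2),
                              n_symptoms=20, profile_size_range=(3, 3),
                              within_subclass_overlap=0.0, flip_noise=0.0,
                              gender_bias=(0.5, 0.5), n_per_disease=6, seed=4)
        tax, prof = generate_taxonomy(cfg)
        records = generate_records(tax, prof, cfg)
        X = np.array([r.symptoms for r in records], dtype=float)
        cats = {c: i for i, c in enumerate(tax.codes_at("main"))}
        D = np.array([one_hot(cats[tax.decode(r.disease_code)[1][0]], 3)
                      for r in records])
        params = init_network(tax.n_symptoms, 3, eta=0.1, seed=1)
        trained, _ = train(params, X, D, epochs=100, shuffle_seed=2)
        acc = np.mean([predict(trained, x) == np.argmax(d)
                       for x, d in zip(X, D)])
        assert acc >= 0.95

    def test_predict_agrees_with_forward_argmax(self, rng):
        for _ in range(20):
            params = init_network(4, 5, seed=int(rng.integers(1 << 30)))
            x = rng.integers(0, 2, size=4)
            assert predict(params, x) == int(np.argmax(forward(params, x).yo))
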