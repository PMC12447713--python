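"""Forecasters: univariance, FiLM composition, the copy baseline, linear
baselines, batch consistency, and checkpointing."""

import numpy as np
import pytest

import poco
from poco.forecasters import moving_average


@pytest.fixture
def mlp():
    return poco.MlpCore(context=12, horizon=5, hidden_size=8,
                        rng=np.random.default_rng(3))


class TestMlp:
    def test_constant_head_with_zero_weights(self, mlp, rng):
        mlp.w_in.data[...] = 0.0
        mlp.w_out.data[...] = 0.0
        mlp.b_out.data[...] = np.arange(5.0)
        out = poco.mlp_forecast(rng.normal(size=(12, 7)), mlp)
        np.testing.assert_array_equal(out, np.tile(np.arange(5.0)[:, None], 7))

    def test_identical_columns_give_identical_predictions(self, mlp, rng):
        col = rng.normal(size=(12, 1))
        ctx = np.concatenate([col, rng.normal(size=(12, 2)), col], axis=1)
        out = poco.mlp_forecast(ctx, mlp)
        np.testing.assert_array_equal(out[:, 0], out[:, 3])

    def test_matches_per_neuron_loop_oracle(self, mlp, rng):
        ctx = rng.normal(size=(12, 9))
        out = poco.mlp_forecast(ctx, mlp)
        w_in, b_in = mlp.w_in.data, mlp.b_in.data
        w_out, b_out = mlp.w_out.data, mlp.b_out.data
        for n in range(9):
            h = np.maximum(w_in @ ctx[:, n] + b_in, 0.0)
            np.testing.assert_allclose(out[:, n], w_out @ h + b_out, atol=1e-6)


class TestPocoComposition:
    def test_identity_film_equals_mlp(self, tiny_poco, rng):
        ctx = rng.normal(size=(4, 12, 6))
        out = poco.poco_forecast(ctx, "sess_a", tiny_poco)
        ref = poco.mlp_forecast(ctx, tiny_poco.mlp)
        np.testing.assert_array_equal(out, ref)

    def test_manual_gamma_beta_composition(self, rng):
        # gamma = 0 and very negative beta kill every hidden unit: output b_out
        tok = poco.TokenizerConfig(token_length=4, context=12, embed_dim=16)
        enc = poco.EncoderConfig(num_latents=2, num_self_layers=0, heads=2,
                                 embed_dim=16)
        model = poco.PocoCore(tok, enc, horizon=5, hidden_size=8,
                              rng=np.random.default_rng(1))
        model.register_session("s", ["a", "b"], rng=2)
        model.encoder.gamma_head.bias.data[...] = 0.0
        model.encoder.beta_head.bias.data[...] = -1e9
        out = poco.poco_forecast(rng.normal(size=(12, 2)), "s", model)
        np.testing.assert_allclose(
            out, np.tile(model.mlp.b_out.data[:, None], 2), atol=1e-6)

    def test_unregistered_session_raises(self, tiny_poco, rng):
        from poco.encoder import MissingEmbeddingError
        with pytest.raises(MissingEmbeddingError):
            poco.poco_forecast(rng.normal(size=(12, 6)), "nope", tiny_poco)


class TestCopy:
    def test_all_rows_equal_last_observation(self, rng):
        ctx = rng.normal(size=(12, 4))
        out = poco.copy_forecast(ctx, 16)
        assert out.shape == (16, 4)
        np.testing.assert_array_equal(out, np.tile(ctx[-1], (16, 1)))

    def test_zero_error_on_constant_data(self):
        ctx = np.full((12, 3), 2.5)
        target = np.full((6, 3), 2.5)
        from poco.training import forecast_loss
        assert forecast_loss(poco.copy_forecast(ctx, 6), target) == 0.0


class TestLinearBaselines:
    def test_nlinear_zero_weights_equals_copy(self, rng):
        model = poco.NLinearCore(context=12, horizon=5,
                                 rng=np.random.default_rng(0))
        ctx = rng.normal(size=(12, 4))
        np.testing.assert_allclose(poco.nlinear_forecast(ctx, model),
                                   poco.copy_forecast(ctx, 5), atol=1e-12)

    def test_nlinear_univariance_under_permutation(self, rng):
        model = poco.NLinearCore(12, 5, np.random.default_rng(0))
        model.weight.data[...] = rng.normal(size=(5, 12))
        ctx = rng.normal(size=(12, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            poco.nlinear_forecast(ctx[:, perm], model),
            poco.nlinear_forecast(ctx, model)[:, perm], atol=1e-12)

    def test_dlinear_univariance_under_permutation(self, rng):
        model = poco.DLinearCore(12, 5, np.random.default_rng(0))
        ctx = rng.normal(size=(12, 6))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            poco.dlinear_forecast(ctx[:, perm], model),
            poco.dlinear_forecast(ctx, model)[:, perm], atol=1e-10)

    def test_dlinear_matches_loop_oracle(self, rng):
        model = poco.DLinearCore(12, 5, np.random.default_rng(4), kernel=5)
        ctx = rng.normal(size=(12, 3))
        out = poco.dlinear_forecast(ctx, model)
        for n in range(3):
            x = ctx[:, n]
            trend = moving_average(x[:, None], 5)[:, 0]
            rem = x - trend
            expected = (model.w_trend.data @ trend + model.b_trend.data
                        + model.w_rem.data @ rem + model.b_rem.data)
            np.testing.assert_allclose(out[:, n], expected, atol=1e-8)

    def test_dlinear_learns_to_extrapolate_ramps(self, rng):
        # linear ramps have an exact linear continuation; training should find it
        from poco.autodiff import AdamW
        from poco.training import forecast_loss

        model = poco.DLinearCore(12, 5, np.random.default_rng(0), kernel=5)
        opt = AdamW(model.parameters(), lr=0.05, weight_decay=0.0,
                    clip_norm=None)
        slopes = rng.uniform(-2, 2, size=(64, 1, 8))
        offsets = rng.uniform(-1, 1, size=(64, 1, 8))
        t = np.arange(17)[None, :, None]
        series = offsets + slopes * t
        ctx, tgt = series[:, :12], series[:, 12:]
        best, best_state = np.inf, None
        for _ in range(1500):
            opt.zero_grad()
            loss = forecast_loss(model.forward(ctx), tgt)
            loss.backward()
            opt.step()
            if float(loss.data) < best:
                best = float(loss.data)
                best_state = [p.data.copy() for p in model.parameters()]
        for p, s in zip(model.parameters(), best_state):
            p.data[...] = s
        fresh = offsets[:4] + slopes[:4] * (t + 3)
        pred = poco.dlinear_forecast(fresh[:, :12], model)
        assert np.abs(pred - fresh[:, 12:]).max() < 1e-3

    def test_moving_average_constant_invariant(self):
        x = np.full((30, 2), 1.7)
        np.testing.assert_allclose(moving_average(x, 25), x, atol=1e-12)


class TestBatchConsistency:
    def test_single_vs_batched_evaluation_identical(self, tiny_poco, rng):
        # FiLM heads perturbed so the population path is active
        r = np.random.default_rng(5)
        tiny_poco.encoder.gamma_head.weight.data[...] = r.normal(0, 0.3, (8, 16))
        ctx = rng.normal(size=(6, 12, 6))
        batched = poco.poco_forecast(ctx, "sess_a", tiny_poco)
        singles = np.stack([
            poco.poco_forecast(ctx[i], "sess_a", tiny_poco) for i in range(6)
        ])
        np.testing.assert_allclose(batched, singles, atol=1e-6)
        tiny_poco.encoder.gamma_head.weight.data[...] = 0.0

    def test_mlp_batch_consistency(self, mlp, rng):
        ctx = rng.normal(size=(5, 12, 3))
        batched = poco.mlp_forecast(ctx, mlp)
        singles = np.stack([poco.mlp_forecast(ctx[i], mlp) for i in range(5)])
        np.testing.assert_allclose(batched, singles, atol=1e-6)


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, rng):
        tok = poco.TokenizerConfig(token_length=4, context=12, embed_dim=16)
        enc = poco.EncoderConfig(num_latents=4, num_self_layers=1, heads=2,
                                 embed_dim=16)
        model = poco.PocoCore(tok, enc, horizon=5, hidden_size=8,
                              rng=np.random.default_rng(0))
        model.register_session("s1", ["a", "b", "c"], rng=1)
        r = np.random.default_rng(6)
        model.encoder.gamma_head.weight.data[...] = r.normal(0, 0.3, (8, 16))
        model.save(tmp_path / "ckpt.npz")
        back = poco.PocoCore.load(tmp_path / "ckpt.npz")
        assert back.tables.session_ids == ["s1"]
        ctx = rng.normal(size=(2, 12, 3))
        np.testing.assert_array_equal(
            poco.poco_forecast(ctx, "s1", model),
            poco.poco_forecast(ctx, "s1", back))


class TestEstimators:
    def test_sklearn_params_roundtrip(self):
        from sklearn.base import clone
        est = poco.PocoForecaster(context=12, horizon=5, hidden_size=8,
                                  embed_dim=16, token_length=4, max_steps=5)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est2 = est.set_params(max_steps=7)
        assert est2.max_steps == 7

    def test_copy_estimator_predict(self, rng):
        est = poco.CopyForecaster(horizon=4).fit()
        ctx = rng.normal(size=(12, 3))
        np.testing.assert_array_equal(est.predict(ctx),
                                      poco.copy_forecast(ctx, 4))
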