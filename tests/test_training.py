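"""Training loop mechanics: loss weighting, batching, freeze contracts,
multi-dataset aggregation, fine-tuning preconditions, determinism."""

import numpy as np
import pandas as pd
import pytest

import poco
from poco.training import (WindowStore, build_window_stores, forecast_loss,
                           multi_dataset_step)


def small_model(sessions, seed=0, hidden=16, d=16):
    tok = poco.TokenizerConfig(token_length=4, context=12, embed_dim=d)
    enc = poco.EncoderConfig(num_latents=4, num_self_layers=1, heads=2,
                             embed_dim=d)
    model = poco.PocoCore(tok, enc, horizon=5, hidden_size=hidden,
                          rng=np.random.default_rng(seed))
    for rec in sessions:
        model.register_session(rec, rng=np.random.default_rng(seed + 1))
    return model


def small_cfg(**kw):
    base = dict(max_steps=20, eval_every=10, batch_size=8, seed=0,
                context=12, horizon=5, segment_length=600,
                eval_max_windows=16)
    base.update(kw)
    return poco.TrainConfig(**base)


class TestLoss:
    def test_zero_for_perfect_prediction(self, rng):
        x = rng.normal(size=(5, 3))
        assert forecast_loss(x, x) == 0.0

    def test_unit_offset_gives_one(self, rng):
        x = rng.normal(size=(5, 3))
        assert forecast_loss(x + 1.0, x) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        pred = rng.normal(size=(4, 6))
        tgt = rng.normal(size=(4, 6))
        acc = 0.0
        for i in range(4):
            for j in range(6):
                acc += (pred[i, j] - tgt[i, j]) ** 2
        assert forecast_loss(pred, tgt) == pytest.approx(acc / 24)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            forecast_loss(rng.normal(size=(4, 3)), rng.normal(size=(4, 2)))

    def test_batch_loss_equals_mean_of_sample_losses(self, rng):
        pred = rng.normal(size=(7, 4, 3))
        tgt = rng.normal(size=(7, 4, 3))
        per_sample = [forecast_loss(pred[i], tgt[i]) for i in range(7)]
        assert forecast_loss(pred, tgt) == pytest.approx(np.mean(per_sample))


class TestTrainLoop:
    def test_capacity_sanity_on_copyable_data(self):
        # constant traces after the context: target always equals last value
        t = np.linspace(0, 2 * np.pi * 3, 600)
        traces = np.column_stack([np.sin(t), np.cos(t), np.sin(2 * t)])
        rec = poco.SessionRecording(traces=traces, fs=2.0,
                                    unit_ids=["a", "b", "c"], session_id="s")
        model = small_model([rec])
        cfg = small_cfg(max_steps=60, eval_every=20)
        model, hist = poco.train(model, [rec], cfg)
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]

    def test_history_schema_and_best_checkpoint(self, small_cohort):
        model = small_model(small_cohort)
        model, hist = poco.train(model, small_cohort, small_cfg())
        assert list(hist.columns) == ["step", "train_loss", "val_loss"]
        assert hist["step"].iloc[0] == 0    # pre-training validation point
        assert len(hist) >= 3

    def test_deterministic_under_fixed_seed(self, small_cohort):
        out = []
        for _ in range(2):
            model = small_model(small_cohort, seed=3)
            model, hist = poco.train(model, small_cohort, small_cfg(seed=3))
            out.append(hist["val_loss"].to_numpy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_no_windows_raises_before_training(self):
        rec = poco.SessionRecording(traces=np.zeros((30, 2)) + np.arange(30)[:, None],
                                    fs=1.0, unit_ids=["a", "b"], session_id="s")
        model = small_model([rec])
        with pytest.raises(ValueError):
            poco.train(model, [rec], small_cfg(segment_length=30, context=12,
                                               horizon=5))

    def test_single_session_equals_multi_session_on_lone_session(self, small_cohort):
        rec = [small_cohort[0]]
        hists = []
        for mode in ("single_session", "multi_session"):
            model = small_model(rec, seed=2)
            _, hist = poco.train(model, rec, small_cfg(seed=2, mode=mode))
            hists.append(hist["val_loss"].to_numpy())
        np.testing.assert_array_equal(hists[0], hists[1])


class TestFreezeContract:
    def test_embedding_only_touches_only_new_session_embeddings(self, small_cohort):
        pre = [small_cohort[0]]
        model = small_model(pre)
        model, _ = poco.train(model, pre, small_cfg())
        before = {k: p.data.copy() for k, p in model.named_parameters().items()}
        cfg = small_cfg(max_steps=15, finetune_mode="embedding_only")
        model, curve = poco.finetune(model, small_cohort[1], cfg)
        after = model.named_parameters()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k].data, v,
                                          err_msg=f"{k} changed")
        new_keys = set(after) - set(before)
        assert {k for k in new_keys if small_cohort[1].session_id in k} == new_keys
        assert len(curve) >= 2

    def test_frozen_parameters_receive_no_gradient(self, small_cohort):
        model = small_model(small_cohort)
        for name, p in model.named_parameters().items():
            if "sessions." not in name:
                p.requires_grad = False
        ctx = small_cohort[0].traces[None, :12].astype(np.float64)
        tgt = small_cohort[0].traces[None, 12:17].astype(np.float64)
        loss = forecast_loss(model.forward(ctx, small_cohort[0].session_id), tgt)
        loss.backward()
        for name, p in model.named_parameters().items():
            if "sessions." not in name:
                assert p.grad is None, name

    def test_finetuning_registered_session_rejected(self, small_cohort):
        model = small_model(small_cohort)
        cfg = small_cfg(finetune_mode="embedding_only")
        with pytest.raises(ValueError, match="already registered"):
            poco.finetune(model, small_cohort[0], cfg)

    def test_zero_step_finetune_predicts_without_crash(self, small_cohort):
        model = small_model([small_cohort[0]])
        model.register_session(small_cohort[1], rng=9)
        ctx = small_cohort[1].traces[:12]
        out = poco.poco_forecast(ctx, small_cohort[1].session_id, model)
        assert out.shape == (5, 20)
        assert np.isfinite(out).all()


class TestMultiDataset:
    def _datasets(self, small_cohort, plan):
        a = build_window_stores([small_cohort[0]], plan)
        b = build_window_stores([small_cohort[1]], plan)
        return {"ds_a": a["train"], "ds_b": b["train"]}

    def test_two_datasets_consume_one_batch_each(self, small_cohort, monkeypatch):
        cfg = small_cfg()
        datasets = self._datasets(small_cohort, cfg.split_plan())
        model = small_model(small_cohort)
        calls = []
        orig = WindowStore.batch

        def counting(self, rng, size):
            calls.append(self.session_id)
            return orig(self, rng, size)

        monkeypatch.setattr(WindowStore, "batch", counting)
        opt = poco.AdamW(model.parameters(), lr=1e-3)
        loss = multi_dataset_step(model, datasets, opt, cfg,
                                  np.random.default_rng(0))
        assert len(calls) == 2
        assert np.isfinite(loss)

    def test_single_dataset_reduces_to_ordinary_step(self, small_cohort):
        cfg = small_cfg()
        plan = cfg.split_plan()
        stores = build_window_stores([small_cohort[0]], plan)
        model = small_model(small_cohort)
        opt = poco.AdamW(model.parameters(), lr=1e-3)
        loss = multi_dataset_step(model, {"only": stores["train"]}, opt, cfg,
                                  np.random.default_rng(0))
        assert np.isfinite(loss)

    def test_empty_dataset_skipped_with_warning(self, small_cohort):
        cfg = small_cfg()
        plan = cfg.split_plan()
        stores = build_window_stores([small_cohort[0]], plan)
        empty = {
            small_cohort[0].session_id: WindowStore(
                small_cohort[0], np.empty(0, dtype=int), plan, stride=1)
        }
        model = small_model(small_cohort)
        opt = poco.AdamW(model.parameters(), lr=1e-3)
        with pytest.warns(RuntimeWarning, match="skipped"):
            loss = multi_dataset_step(
                model, {"good": stores["train"], "empty": empty}, opt, cfg,
                np.random.default_rng(0))
        assert np.isfinite(loss)

    def test_identical_datasets_sum_losses(self, small_cohort, monkeypatch):
        # duplicating a dataset doubles the summed loss under a fixed draw
        cfg = small_cfg()
        stores = build_window_stores([small_cohort[0]], cfg.split_plan())

        losses = []
        for datasets in ({"a": stores["train"]},
                         {"a": stores["train"], "b": stores["train"]}):
            model = small_model(small_cohort, seed=4)
            opt = poco.AdamW(model.parameters(), lr=0.0)
            loss = multi_dataset_step(model, datasets, opt, cfg,
                                      np.random.default_rng(5))
            losses.append(loss)
        assert losses[1] == pytest.approx(2 * losses[0], rel=0.5)
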