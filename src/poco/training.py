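"""Training: MSE loss, multi-session batching, the AdamW optimization loop
with validation-based checkpoint selection, multi-dataset aggregation, and
fine-tuning (full or embedding-only) on held-out sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autodiff import AdamW, Parameter, Tensor, no_grad
from .forecasters import PocoCore
from .io_preprocess import (SessionRecording, SplitPlan, make_windows,
                            segment_and_split)
from .nn import Module


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults are the standard forecasting setup
    (AdamW, lr 3e-4, weight decay 1e-4)."""

    lr: float = 3e-4
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_steps: int = 2000
    eval_every: int = 100
    seed: int = 0
    context: int = 48
    horizon: int = 16
    segment_length: int = 1000
    ratios: tuple[int, int, int] = (3, 1, 1)
    train_stride: int = 1
    mode: str = "multi_session"          # single_session | multi_session | multi_dataset
    finetune_mode: str = "none"          # none | full | embedding_only
    clip_norm: float | None = 1.0
    eval_max_windows: int = 256

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("lr and batch_size must be positive")
        if self.mode not in {"single_session", "multi_session", "multi_dataset"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.finetune_mode not in {"none", "full", "embedding_only"}:
            raise ValueError(f"unknown finetune_mode {self.finetune_mode!r}")

    def split_plan(self) -> SplitPlan:
        return SplitPlan(segment_length=self.segment_length, ratios=self.ratios,
                         context=self.context, horizon=self.horizon,
                         train_stride=self.train_stride)


def forecast_loss(pred, target):
    """Mean squared error over all P*N entries (and batch, if present)."""
    if isinstance(pred, Tensor):
        t = target if isinstance(target, Tensor) else Tensor(target)
        if pred.shape != t.shape:
            raise ValueError(f"shape mismatch {pred.shape} vs {t.shape}")
        diff = pred - t
        return (diff * diff).mean()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


class WindowStore:
    """Stacked (context, target) windows for one partition of one session."""

    def __init__(self, rec: SessionRecording, indices: np.ndarray,
                 plan: SplitPlan, stride: int):
        samples = make_windows(rec, indices, plan, stride=stride)
        self.session_id = rec.session_id
        self.n_windows = len(samples)
        if samples:
            self.contexts = np.stack([s.context for s in samples]).astype(np.float64)
            self.targets = np.stack([s.target for s in samples]).astype(np.float64)
        else:
            n = rec.n_units
            self.contexts = np.empty((0, plan.context, n))
            self.targets = np.empty((0, plan.horizon, n))

    def batch(self, rng: np.random.Generator, size: int):
        idx = rng.integers(0, self.n_windows, size=size)
        return self.contexts[idx], self.targets[idx]


def build_window_stores(
    sessions: list[SessionRecording], plan: SplitPlan
) -> dict[str, dict[str, WindowStore]]:
    """Per partition, one WindowStore per session (training uses stride 1,
    evaluation uses non-overlapping targets)."""
    stores: dict[str, dict[str, WindowStore]] = {"train": {}, "val": {}, "test": {}}
    for rec in sessions:
        parts = segment_and_split(rec, plan)
        stores["train"][rec.session_id] = WindowStore(
            rec, parts["train"], plan, stride=plan.train_stride)
        for part in ("val", "test"):
            stores[part][rec.session_id] = WindowStore(
                rec, parts[part], plan, stride=plan.eval_stride_)
    return stores


def _evaluate_loss(model: Module, stores: dict[str, WindowStore],
                   batch_size: int, max_windows: int,
                   rng: np.random.Generator) -> float:
    """Pooled MSE over (a capped subsample of) the given windows."""
    total_sq, total_n = 0.0, 0
    for store in stores.values():
        if store.n_windows == 0:
            continue
        if store.n_windows > max_windows:
            idx = rng.choice(store.n_windows, size=max_windows, replace=False)
        else:
            idx = np.arange(store.n_windows)
        for start in range(0, idx.size, batch_size):
            sel = idx[start:start + batch_size]
            with no_grad():
                pred = model.forward(store.contexts[sel], store.session_id).data
            err = pred - store.targets[sel]
            total_sq += float(np.sum(err * err))
            total_n += err.size
    if total_n == 0:
        raise ValueError("no evaluation windows")
    return total_sq / total_n


def _trainable_parameters(model: Module, cfg: TrainConfig,
                          new_session: str | None = None) -> dict[str, Parameter]:
    named = model.named_parameters()
    if cfg.finetune_mode != "embedding_only":
        return named
    keep = {}
    for name, p in named.items():
        if ".sessions." in name or name.startswith("tables.sessions."):
            sid = name.split(".sessions.", 1)[1].rsplit(".", 1)[0]
            if new_session is None or sid == new_session:
                keep[name] = p
    if not keep:
        raise ValueError("embedding_only finetuning found no embedding parameters")
    return keep


def train(
    model: Module,
    sessions: list[SessionRecording],
    cfg: TrainConfig,
    stores: dict[str, dict[str, WindowStore]] | None = None,
    new_session: str | None = None,
):
    """Optimize ``model`` on the sessions' training windows.

    Batches are drawn from one session at a time, the session chosen with
    probability proportional to its number of training windows (unbiased
    per-window sampling).  The best checkpoint by validation loss is
    restored before returning.  Returns (model, history DataFrame).
    """
    if stores is None:
        stores = build_window_stores(sessions, cfg.split_plan())
    train_stores = {k: v for k, v in stores["train"].items() if v.n_windows > 0}
    if not train_stores:
        raise ValueError("no training windows in any session")

    rng = np.random.default_rng(cfg.seed)
    eval_rng = np.random.default_rng(cfg.seed + 1)

    named = _trainable_parameters(model, cfg, new_session)
    all_named = model.named_parameters()
    frozen = [p for name, p in all_named.items() if name not in named]
    for p in frozen:
        p.requires_grad = False
    opt = AdamW(named.values(), lr=cfg.lr, weight_decay=cfg.weight_decay,
                clip_norm=cfg.clip_norm)

    sids = list(train_stores)
    weights = np.array([train_stores[s].n_windows for s in sids], dtype=float)
    weights /= weights.sum()

    history: list[dict] = []
    best_val = np.inf
    best_state: dict[str, np.ndarray] | None = None

    def log_eval(step: int, train_loss: float) -> None:
        nonlocal best_val, best_state
        val = _evaluate_loss(model, stores["val"], cfg.batch_size,
                             cfg.eval_max_windows, eval_rng)
        history.append({"step": step, "train_loss": train_loss, "val_loss": val})
        if val < best_val:
            best_val = val
            best_state = {k: p.data.copy() for k, p in all_named.items()}

    log_eval(0, np.nan)
    running = []
    for step in range(1, cfg.max_steps + 1):
        sid = sids[rng.choice(len(sids), p=weights)]
        ctx, tgt = train_stores[sid].batch(rng, cfg.batch_size)
        opt.zero_grad()
        loss = forecast_loss(model.forward(ctx, sid), tgt)
        loss.backward()
        opt.step()
        running.append(float(loss.data))
        if step % cfg.eval_every == 0 or step == cfg.max_steps:
            log_eval(step, float(np.mean(running)))
            running = []

    if best_state is not None:
        for k, p in all_named.items():
            p.data[...] = best_state[k]
    for p in frozen:
        p.requires_grad = True
    return model, pd.DataFrame(history)


def multi_dataset_step(
    model: Module,
    datasets: dict[str, dict[str, WindowStore]],
    opt: AdamW,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> float:
    """One update aggregating one random batch from each dataset.

    Per-dataset losses are summed (unweighted) into a single objective and
    one optimizer step is taken.  Empty datasets are skipped with a warning.
    """
    import warnings

    opt.zero_grad()
    total = None
    n_used = 0
    for name, train_stores in datasets.items():
        nonempty = {k: v for k, v in train_stores.items() if v.n_windows > 0}
        if not nonempty:
            warnings.warn(f"dataset {name!r} has no training windows; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        sids = list(nonempty)
        weights = np.array([nonempty[s].n_windows for s in sids], dtype=float)
        weights /= weights.sum()
        sid = sids[rng.choice(len(sids), p=weights)]
        ctx, tgt = nonempty[sid].batch(rng, cfg.batch_size)
        loss = forecast_loss(model.forward(ctx, sid), tgt)
        total = loss if total is None else total + loss
        n_used += 1
    if total is None:
        raise ValueError("all datasets empty")
    total.backward()
    opt.step()
    return float(total.data)


def finetune(
    model: PocoCore,
    new_session: SessionRecording,
    cfg: TrainConfig,
):
    """Adapt a pre-trained model to an unseen session.

    ``cfg.finetune_mode`` selects full fine-tuning or embedding-only
    (freezing everything except the new session's unit/session embeddings).
    Returns (model, adaptation-curve DataFrame).
    """
    if new_session.session_id in model.tables.session_ids:
        raise ValueError(
            f"session {new_session.session_id!r} was already registered; "
            "finetuning expects an unseen session"
        )
    if cfg.finetune_mode == "none":
        raise ValueError("set finetune_mode to 'full' or 'embedding_only'")
    model.register_session(new_session, rng=np.random.default_rng(cfg.seed))
    return train(model, [new_session], cfg, new_session=new_session.session_id)
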