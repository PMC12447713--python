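"""Forecasting models: univariate MLP, its population-conditioned (FiLM)
composition, the copy baseline, and NLinear/DLinear baselines.

All trainable models share one weight set across sessions and neurons
(univariate weight sharing): the prediction for a neuron depends only on
that neuron's own context, and per-neuron specialization enters solely
through the FiLM parameters produced by the population encoder.

Estimator classes follow scikit-learn conventions (``fit`` /
``predict`` / ``get_params`` / ``set_params``, fitted attributes with a
trailing underscore); module-level functions (:func:`mlp_forecast`,
:func:`poco_forecast`, :func:`copy_forecast`, ...) are thin functional
wrappers used by the evaluation harness and tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Parameter, Tensor, no_grad
from .encoder import (EmbeddingTables, EncoderConfig, PopulationEncoder,
                      TokenizerConfig)
from .io_preprocess import SessionRecording
from .nn import Module


def _as_batch(context: np.ndarray) -> tuple[np.ndarray, bool]:
    context = np.asarray(context, dtype=np.float64)
    if context.ndim == 2:
        return context[None], True
    if context.ndim == 3:
        return context, False
    raise ValueError("context must be (C, N) or (B, C, N)")


# ---------------------------------------------------------------------------
# core models (autodiff modules)
# ---------------------------------------------------------------------------

class MlpCore(Module):
    """Univariate MLP: per-neuron context C -> hidden M -> horizon P."""

    def __init__(self, context: int, horizon: int, hidden_size: int,
                 rng: np.random.Generator):
        self.context = context
        self.horizon = horizon
        self.hidden_size = hidden_size
        m, c, p = hidden_size, context, horizon
        self.w_in = Parameter(rng.normal(0.0, 1.0 / np.sqrt(c), size=(m, c)))
        self.b_in = Parameter(np.zeros(m))
        self.w_out = Parameter(rng.normal(0.0, 1.0 / np.sqrt(m), size=(p, m)))
        self.b_out = Parameter(np.zeros(p))

    def hidden(self, x: Tensor) -> Tensor:
        """Pre-activation hidden state, shape (B, N, M)."""
        return x.transpose(0, 2, 1) @ self.w_in.transpose(1, 0) + self.b_in

    def head(self, h: Tensor) -> Tensor:
        """Map ReLU'd hidden (B, N, M) to predictions (B, P, N)."""
        out = h.relu() @ self.w_out.transpose(1, 0) + self.b_out
        return out.transpose(0, 2, 1)

    def forward(self, context, session_id: str | None = None) -> Tensor:
        x = context if isinstance(context, Tensor) else Tensor(context)
        return self.head(self.hidden(x))


class PocoCore(Module):
    """MLP forecaster modulated by population-level FiLM conditioning.

    hidden = (W_in x + b_in) * gamma + beta, then ReLU and the output head;
    (gamma, beta) come from the population encoder and depend on the whole
    population's context and on the unit/session embeddings.
    """

    def __init__(self, tok_cfg: TokenizerConfig, enc_cfg: EncoderConfig,
                 horizon: int, hidden_size: int, rng: np.random.Generator):
        self.mlp = MlpCore(tok_cfg.context, horizon, hidden_size, rng)
        self.encoder = PopulationEncoder(tok_cfg, enc_cfg, hidden_size, rng)
        self.tables = EmbeddingTables(enc_cfg.embed_dim)

    def register_session(self, rec_or_id, unit_ids: list[str] | None = None,
                         rng: np.random.Generator | int | None = None):
        if isinstance(rec_or_id, SessionRecording):
            sid, units = rec_or_id.session_id, rec_or_id.unit_ids
        else:
            sid, units = rec_or_id, unit_ids
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.tables.init_new_session(sid, units, rng)
        return self

    def forward(self, context, session_id: str) -> Tensor:
        x = context if isinstance(context, Tensor) else Tensor(context)
        h = self.mlp.hidden(x)                       # (B, N, M)
        gamma, beta = self.encoder(x, session_id, self.tables)
        return self.mlp.head(h * gamma + beta)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint: NPZ of parameters + JSON manifest."""
        path = Path(path)
        named = self.named_parameters()
        arrays = {k: v.data for k, v in named.items()}
        manifest = {
            "sessions": self.tables.manifest(),
            "tok_cfg": vars(self.encoder.tok_cfg) | {},
            "enc_cfg": vars(self.encoder.enc_cfg) | {},
            "horizon": self.mlp.horizon,
            "hidden_size": self.mlp.hidden_size,
        }
        arrays["__manifest__"] = np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PocoCore":
        with np.load(Path(path)) as f:
            manifest = json.loads(bytes(f["__manifest__"].tobytes()).decode())
            arrays = {k: f[k] for k in f.files if k != "__manifest__"}
        tok_cfg = TokenizerConfig(**{k: v for k, v in manifest["tok_cfg"].items()})
        enc_cfg = EncoderConfig(**{k: v for k, v in manifest["enc_cfg"].items()})
        model = cls(tok_cfg, enc_cfg, manifest["horizon"],
                    manifest["hidden_size"], np.random.default_rng(0))
        for sid, units in manifest["sessions"].items():
            model.tables.init_new_session(sid, units, np.random.default_rng(0))
        named = model.named_parameters()
        for k, v in arrays.items():
            named[k].data[...] = v
        return model


class NLinearCore(Module):
    """Shared univariate linear map on the last-value-subtracted context."""

    def __init__(self, context: int, horizon: int, rng: np.random.Generator):
        self.context = context
        self.horizon = horizon
        self.weight = Parameter(np.zeros((horizon, context)))
        self.bias = Parameter(np.zeros(horizon))
        del rng  # deterministic zero init: starts at the copy baseline

    def forward(self, context, session_id: str | None = None) -> Tensor:
        x = context if isinstance(context, Tensor) else Tensor(context)
        last = x[:, -1:, :]                              # (B, 1, N)
        centered = (x - last).transpose(0, 2, 1)          # (B, N, C)
        out = centered @ self.weight.transpose(1, 0) + self.bias
        return out.transpose(0, 2, 1) + last


def moving_average(x: np.ndarray, kernel: int) -> np.ndarray:
    """Centered moving average along axis 0 with replicate end-padding."""
    left = (kernel - 1) // 2
    right = kernel - 1 - left
    pad = np.concatenate([
        np.repeat(x[:1], left, axis=0), x, np.repeat(x[-1:], right, axis=0)
    ], axis=0)
    cs = np.cumsum(pad, axis=0, dtype=np.float64)
    cs = np.concatenate([np.zeros_like(cs[:1]), cs], axis=0)
    return (cs[kernel:] - cs[:-kernel]) / kernel


class DLinearCore(Module):
    """Trend/remainder decomposition with separate linear maps."""

    def __init__(self, context: int, horizon: int, rng: np.random.Generator,
                 kernel: int = 25):
        self.context = context
        self.horizon = horizon
        self.kernel = kernel
        std = 1.0 / np.sqrt(context)
        self.w_trend = Parameter(rng.normal(0.0, std, size=(horizon, context)))
        self.b_trend = Parameter(np.zeros(horizon))
        self.w_rem = Parameter(rng.normal(0.0, std, size=(horizon, context)))
        self.b_rem = Parameter(np.zeros(horizon))

    def forward(self, context, session_id: str | None = None) -> Tensor:
        batch, _ = _as_batch(np.asarray(
            context.data if isinstance(context, Tensor) else context))
        trend = np.stack([moving_average(b, self.kernel) for b in batch])
        x = Tensor(batch)
        t = Tensor(trend)
        rem = (x - t).transpose(0, 2, 1)
        tr = t.transpose(0, 2, 1)
        out = (tr @ self.w_trend.transpose(1, 0) + self.b_trend
               + rem @ self.w_rem.transpose(1, 0) + self.b_rem)
        return out.transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def mlp_forecast(context: np.ndarray, model: MlpCore) -> np.ndarray:
    """Univariate MLP prediction for a (C, N) or (B, C, N) context."""
    batch, squeeze = _as_batch(context)
    with no_grad():
        out = model.forward(batch).data
    return out[0] if squeeze else out


def poco_forecast(context: np.ndarray, session_id: str,
                  model: PocoCore) -> np.ndarray:
    """Population-conditioned prediction for a registered session."""
    batch, squeeze = _as_batch(context)
    with no_grad():
        out = model.forward(batch, session_id).data
    return out[0] if squeeze else out


def copy_forecast(context: np.ndarray, horizon: int) -> np.ndarray:
    """Repeat the last observed population state for ``horizon`` steps."""
    batch, squeeze = _as_batch(context)
    out = np.repeat(batch[:, -1:, :], horizon, axis=1)
    return out[0] if squeeze else out


def nlinear_forecast(context: np.ndarray, model: NLinearCore) -> np.ndarray:
    batch, squeeze = _as_batch(context)
    with no_grad():
        out = model.forward(batch).data
    return out[0] if squeeze else out


def dlinear_forecast(context: np.ndarray, model: DLinearCore) -> np.ndarray:
    batch, squeeze = _as_batch(context)
    with no_grad():
        out = model.forward(batch).data
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# sklearn-style estimators
# ---------------------------------------------------------------------------

class _TrainedForecaster(BaseEstimator):
    """Shared fit/predict machinery for gradient-trained forecasters."""

    def _build(self, rng: np.random.Generator) -> Module:
        raise NotImplementedError

    def fit(self, sessions, y=None):
        """Train on a list of SessionRecording (or a single one)."""
        from .training import TrainConfig, train

        if isinstance(sessions, SessionRecording):
            sessions = [sessions]
        cfg = TrainConfig(
            lr=self.lr, weight_decay=self.weight_decay,
            batch_size=self.batch_size, max_steps=self.max_steps,
            eval_every=self.eval_every, seed=self.seed,
            context=self.context, horizon=self.horizon,
        )
        rng = np.random.default_rng(self.seed)
        model = self._build(rng)
        if isinstance(model, PocoCore):
            for rec in sessions:
                model.register_session(rec, rng=rng)
        self.model_, self.history_ = train(model, sessions, cfg)
        self.n_sessions_ = len(sessions)
        return self

    def predict(self, context: np.ndarray, session_id: str | None = None) -> np.ndarray:
        batch, squeeze = _as_batch(context)
        with no_grad():
            out = self.model_.forward(batch, session_id).data
        return out[0] if squeeze else out


class MlpForecaster(_TrainedForecaster):
    """Univariate MLP forecaster (population-agnostic)."""

    def __init__(self, context=48, horizon=16, hidden_size=1024,
                 lr=3e-4, weight_decay=1e-4, batch_size=64,
                 max_steps=2000, eval_every=100, seed=0):
        self.context = context
        self.horizon = horizon
        self.hidden_size = hidden_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.seed = seed

    def _build(self, rng):
        return MlpCore(self.context, self.horizon, self.hidden_size, rng)


class PocoForecaster(_TrainedForecaster):
    """Population-conditioned forecaster (MLP + FiLM population encoder)."""

    def __init__(self, context=48, horizon=16, hidden_size=1024,
                 token_length=16, embed_dim=128, num_latents=8,
                 num_self_layers=1, heads=4, rotary=True,
                 lr=3e-4, weight_decay=1e-4, batch_size=64,
                 max_steps=2000, eval_every=100, seed=0):
        self.context = context
        self.horizon = horizon
        self.hidden_size = hidden_size
        self.token_length = token_length
        self.embed_dim = embed_dim
        self.num_latents = num_latents
        self.num_self_layers = num_self_layers
        self.heads = heads
        self.rotary = rotary
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.seed = seed

    def _build(self, rng):
        tok = TokenizerConfig(token_length=self.token_length,
                              context=self.context,
                              embed_dim=self.embed_dim, rotary=self.rotary)
        enc = EncoderConfig(num_latents=self.num_latents,
                            num_self_layers=self.num_self_layers,
                            heads=self.heads, embed_dim=self.embed_dim)
        return PocoCore(tok, enc, self.horizon, self.hidden_size, rng)


class NLinearForecaster(_TrainedForecaster):
    """Last-value-anchored univariate linear forecaster."""

    def __init__(self, context=48, horizon=16, lr=3e-4, weight_decay=1e-4,
                 batch_size=64, max_steps=2000, eval_every=100, seed=0):
        self.context = context
        self.horizon = horizon
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.seed = seed

    def _build(self, rng):
        return NLinearCore(self.context, self.horizon, rng)


class DLinearForecaster(_TrainedForecaster):
    """Trend/remainder decomposed univariate linear forecaster."""

    def __init__(self, context=48, horizon=16, kernel=25, lr=3e-4,
                 weight_decay=1e-4, batch_size=64, max_steps=2000,
                 eval_every=100, seed=0):
        self.context = context
        self.horizon = horizon
        self.kernel = kernel
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.eval_every = eval_every
        self.seed = seed

    def _build(self, rng):
        return DLinearCore(self.context, self.horizon, rng, kernel=self.kernel)


class CopyForecaster(BaseEstimator):
    """Repeat-last-observation baseline; nothing to fit."""

    def __init__(self, horizon=16):
        self.horizon = horizon

    def fit(self, sessions=None, y=None):
        self.fitted_ = True
        return self

    def predict(self, context: np.ndarray, session_id: str | None = None) -> np.ndarray:
        return copy_forecast(context, self.horizon)
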