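"""Evaluation: pooled MSE/MAE, the prediction score relative to the copy
baseline, per-horizon-step error curves, context-length sweeps, and
unit-embedding region-similarity analysis.

The prediction score is 1 - L(model)/L(copy): 0 means no better than
repeating the last observation (a strong baseline for slow calcium
dynamics), 1 means a perfect forecast, negative means worse than copying.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity

from .autodiff import no_grad
from .encoder import EmbeddingTables
from .forecasters import copy_forecast
from .io_preprocess import ForecastSample, SessionRecording


class UndefinedScoreError(ValueError):
    """Copy-baseline MSE is zero (constant test data); score is undefined."""


def prediction_score(model_mse: float, copy_mse: float) -> float:
    """Relative improvement over the copy baseline: 1 - model/copy."""
    if copy_mse == 0.0:
        raise UndefinedScoreError(
            "copy-baseline MSE is zero; the evaluation data are constant"
        )
    return 1.0 - model_mse / copy_mse


@dataclass
class EvalReport:
    mse: float
    mae: float
    copy_mse: float
    prediction_score: float
    per_step_mse: np.ndarray          # length-P horizon curve
    n_windows: int
    per_session: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "mse": self.mse, "mae": self.mae, "copy_mse": self.copy_mse,
            "prediction_score": self.prediction_score,
            "per_step_mse": list(map(float, self.per_step_mse)),
            "n_windows": self.n_windows,
            "per_session": self.per_session,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def per_step_csv(self, path: str | Path) -> Path:
        pd.DataFrame({
            "horizon_step": np.arange(1, len(self.per_step_mse) + 1),
            "mse": self.per_step_mse,
        }).to_csv(path, index=False)
        return Path(path)


def _predict(model, contexts: np.ndarray, session_id: str) -> np.ndarray:
    if hasattr(model, "predict"):
        return model.predict(contexts, session_id)
    with no_grad():
        return model.forward(contexts, session_id).data


def evaluate(model, samples: list[ForecastSample],
             batch_size: int = 64) -> EvalReport:
    """Score a forecaster on (context, target) samples, pooled over sessions.

    The pooled MSE mirrors the training objective: a single expectation over
    all sessions' windows and entries.  The copy baseline is computed on the
    same samples, so the prediction score of the copy forecaster is exactly 0.
    Per-session scores are reported alongside for session-level analyses.
    """
    if not samples:
        raise ValueError("no evaluation samples")
    horizon = samples[0].target.shape[0]
    by_session: dict[str, list[ForecastSample]] = {}
    for s in samples:
        by_session.setdefault(s.session_id, []).append(s)

    tot_sq = tot_abs = tot_copy = 0.0
    tot_n = 0
    step_sq = np.zeros(horizon)
    step_n = np.zeros(horizon)
    per_session: dict[str, dict] = {}

    for sid, group in by_session.items():
        contexts = np.stack([s.context for s in group]).astype(np.float64)
        targets = np.stack([s.target for s in group]).astype(np.float64)
        preds = np.empty_like(targets)
        for start in range(0, len(group), batch_size):
            sl = slice(start, start + batch_size)
            preds[sl] = _predict(model, contexts[sl], sid)
        err = preds - targets
        cerr = copy_forecast(contexts, horizon) - targets
        s_sq = float(np.sum(err ** 2))
        s_abs = float(np.sum(np.abs(err)))
        s_copy = float(np.sum(cerr ** 2))
        s_n = err.size
        tot_sq += s_sq
        tot_abs += s_abs
        tot_copy += s_copy
        tot_n += s_n
        step_sq += np.sum(err ** 2, axis=(0, 2))
        step_n += err.shape[0] * err.shape[2]
        sess_mse = s_sq / s_n
        sess_copy = s_copy / s_n
        per_session[sid] = {
            "mse": sess_mse,
            "mae": s_abs / s_n,
            "copy_mse": sess_copy,
            "prediction_score": (
                prediction_score(sess_mse, sess_copy) if sess_copy > 0 else None
            ),
            "n_windows": len(group),
        }

    mse = tot_sq / tot_n
    copy_mse = tot_copy / tot_n
    return EvalReport(
        mse=mse,
        mae=tot_abs / tot_n,
        copy_mse=copy_mse,
        prediction_score=prediction_score(mse, copy_mse),
        per_step_mse=step_sq / step_n,
        n_windows=len(samples),
        per_session=per_session,
    )


def context_length_sweep(make_model, sessions, contexts: list[int],
                         train_fn, eval_samples_fn) -> pd.DataFrame:
    """Train and score one model per context length; returns a tidy frame.

    ``make_model(C)`` builds a model, ``train_fn(model, sessions, C)`` trains
    it, ``eval_samples_fn(C)`` yields the test samples for that context.
    """
    rows = []
    for c in contexts:
        model = make_model(c)
        model = train_fn(model, sessions, c)
        report = evaluate(model, eval_samples_fn(c))
        rows.append({"context": c, "mse": report.mse,
                     "prediction_score": report.prediction_score})
    return pd.DataFrame(rows)


def embedding_region_similarity(
    tables: EmbeddingTables,
    session_id: str,
    region_labels: list[str] | None = None,
    rec: SessionRecording | None = None,
) -> pd.DataFrame:
    """Region-by-region mean cosine similarity of unit embeddings.

    Entry (a, b) is the average pairwise cosine similarity between unit
    embeddings in region a and region b; within-region entries exclude
    self-pairs.  Each row is then min-max normalized to [0, 1]; a constant
    row (no contrast) maps to all 0.5, and a within-region entry for a
    single-unit region is reported as NaN.
    """
    if region_labels is None:
        if rec is None or rec.region_labels is None:
            raise ValueError("region labels required")
        region_labels = rec.region_labels
    units = tables.unit_embeddings(session_id).data
    if len(region_labels) != units.shape[0]:
        raise ValueError("one region label per registered unit required")
    regions = sorted(set(region_labels))
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    labels = np.asarray(region_labels)
    sim = cosine_similarity(units)
    raw = np.full((len(regions), len(regions)), np.nan)
    for i, a in enumerate(regions):
        ia = np.flatnonzero(labels == a)
        for j, b in enumerate(regions):
            ib = np.flatnonzero(labels == b)
            block = sim[np.ix_(ia, ib)]
            if i == j:
                if ia.size < 2:
                    continue  # single-unit region: diagonal undefined
                vals = block[~np.eye(ia.size, dtype=bool)]
            else:
                vals = block.ravel()
            raw[i, j] = vals.mean()
    norm = np.empty_like(raw)
    for i in range(len(regions)):
        row = raw[i]
        finite = np.isfinite(row)
        lo, hi = np.nanmin(row), np.nanmax(row)
        if not finite.any() or hi == lo:
            norm[i] = np.where(finite, 0.5, np.nan)
        else:
            norm[i] = (row - lo) / (hi - lo)
    return pd.DataFrame(norm, index=regions, columns=regions)
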