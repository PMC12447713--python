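"""Session loading, normalization, PCA reduction, filtering and windowing.

A *session* is one continuous recording from one animal: a T x N matrix of
fluorescence (or principal-component) traces at a fixed sampling rate.
Neuron identity is only meaningful within a session.  Preprocessing follows
the standard calcium-trace pipeline: per-neuron z-scoring over the full
session, optional PCA with preserved component magnitudes, optional
zero-phase low-pass filtering, then segmentation into fixed-length blocks
that are split 3:1:1 into train/validation/test spans in temporal order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
import h5py
import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import PCA


@dataclass
class SessionRecording:
    """One session's traces plus identifying metadata.

    Traces are stored float32; statistics are always computed in float64.
    """

    traces: np.ndarray              # T x N
    fs: float                       # sampling frequency, Hz
    unit_ids: list[str]
    session_id: str
    region_labels: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.traces = np.asarray(self.traces, dtype=np.float32)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a T x N matrix")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError(f"session {self.session_id!r}: non-finite traces")
        if self.traces.shape[1] != len(self.unit_ids):
            raise ValueError("unit_ids length must match trace columns")
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise ValueError(f"session {self.session_id!r}: duplicate unit_ids")
        if self.region_labels is not None and len(self.region_labels) != self.n_units:
            raise ValueError("region_labels length must match trace columns")

    @property
    def n_steps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_units(self) -> int:
        return self.traces.shape[1]


@dataclass(frozen=True)
class SplitPlan:
    """Segmentation and windowing plan.

    Sessions are cut into ``segment_length``-step segments; within each
    segment the first 3/5 of steps go to training, the next 1/5 to
    validation, the last 1/5 to test (with default ratios).  Forecast
    windows of ``context + horizon`` steps are then drawn entirely inside
    one partition span, so no window leaks across a partition boundary.
    """

    segment_length: int = 1000
    ratios: tuple[int, int, int] = (3, 1, 1)
    context: int = 48
    horizon: int = 16
    train_stride: int = 1
    eval_stride: int | None = None   # defaults to horizon

    def __post_init__(self):
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if self.segment_length < self.context + self.horizon:
            raise ValueError("segment_length must be >= context + horizon")

    @property
    def window(self) -> int:
        return self.context + self.horizon

    @property
    def eval_stride_(self) -> int:
        return self.horizon if self.eval_stride is None else self.eval_stride


@dataclass(frozen=True)
class ForecastSample:
    """A (context, target) pair cut from one session.

    The target starts exactly one step after the context ends.
    """

    context: np.ndarray      # C x N
    target: np.ndarray       # P x N
    session_id: str
    start_step: int


# ---------------------------------------------------------------------------
# normalization / reduction / filtering
# ---------------------------------------------------------------------------

def zscore_traces(rec: SessionRecording) -> SessionRecording:
    """Z-score each neuron to zero mean and unit variance over the session.

    Constant traces (dead ROIs) are centered and left at zero; a warning
    records which units were affected.
    """
    x = rec.traces.astype(np.float64)
    mean = x.mean(axis=0)
    std = x.std(axis=0)  # population (1/T) variance
    dead = std == 0.0
    if dead.any():
        names = [rec.unit_ids[i] for i in np.flatnonzero(dead)]
        warnings.warn(
            f"session {rec.session_id!r}: constant trace(s) for units {names}; "
            "centered and left at zero",
            RuntimeWarning,
            stacklevel=2,
        )
    z = (x - mean) / np.where(dead, 1.0, std)
    return replace(rec, traces=z.astype(np.float32),
                   meta={**rec.meta, "zscored": True})


def reduce_to_pcs(rec: SessionRecording, k: int) -> SessionRecording:
    """Project z-scored traces onto the leading ``k`` principal components.

    Component magnitudes are preserved (scores are not rescaled to unit
    variance), so large PCs dominate the forecasting loss just as dominant
    population modes dominate the data.  The fitted PCA object is kept in
    ``meta['pca']`` so the projection can be inverted.
    """
    t, n = rec.traces.shape
    if not 1 <= k <= min(t, n):
        raise ValueError(f"k={k} must be in [1, min(T, N)={min(t, n)}]")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(rec.traces.astype(np.float64))
    return SessionRecording(
        traces=scores.astype(np.float32),
        fs=rec.fs,
        unit_ids=[f"pc_{i + 1}" for i in range(k)],
        session_id=rec.session_id,
        region_labels=None,
        meta={**rec.meta, "pca": pca},
    )


def lowpass_filter(rec: SessionRecording, cutoff_hz: float, order: int = 2) -> SessionRecording:
    """Zero-phase Butterworth low-pass filter along time."""
    nyquist = rec.fs / 2.0
    if not 0.0 < cutoff_hz < nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.traces.astype(np.float64), axis=0)
    return replace(rec, traces=filtered.astype(np.float32),
                   meta={**rec.meta, "lowpass_hz": cutoff_hz})


# ---------------------------------------------------------------------------
# segmentation / splitting / windowing
# ---------------------------------------------------------------------------

def segment_and_split(rec: SessionRecording, plan: SplitPlan) -> dict[str, np.ndarray]:
    """Partition the session's step indices into train/val/test sets.

    Each full segment of ``plan.segment_length`` steps is split by
    ``plan.ratios`` in temporal order (600/200/200 by default).  A trailing
    partial segment is split by the same proportions rounded down, with the
    remainder after train/val going to test.  The three index sets are
    disjoint and cover every step.
    """
    if rec.n_steps < plan.window:
        raise ValueError(
            f"session {rec.session_id!r} has T={rec.n_steps} < "
            f"context+horizon={plan.window}"
        )
    total = sum(plan.ratios)
    parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    for seg_start in range(0, rec.n_steps, plan.segment_length):
        seg_len = min(plan.segment_length, rec.n_steps - seg_start)
        n_train = seg_len * plan.ratios[0] // total
        n_val = seg_len * plan.ratios[1] // total
        n_test = seg_len - n_train - n_val
        a = seg_start
        parts["train"].append(np.arange(a, a + n_train))
        parts["val"].append(np.arange(a + n_train, a + n_train + n_val))
        parts["test"].append(np.arange(a + n_train + n_val, a + seg_len))
    return {k: np.concatenate(v) if v else np.empty(0, dtype=int)
            for k, v in parts.items()}


def _contiguous_runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Return (start, length) of each maximal run of consecutive indices."""
    if indices.size == 0:
        return []
    indices = np.sort(indices)
    breaks = np.flatnonzero(np.diff(indices) != 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [indices.size - 1]])
    return [(int(indices[s]), int(indices[e] - indices[s] + 1))
            for s, e in zip(starts, ends)]


def make_windows(
    rec: SessionRecording,
    indices: np.ndarray,
    plan: SplitPlan,
    stride: int | None = None,
) -> list[ForecastSample]:
    """Cut (context, target) windows from contiguous runs of ``indices``.

    Every window's context+horizon steps lie inside a single run, so no
    sample straddles a partition boundary.  Runs shorter than the window
    yield nothing.
    """
    if stride is None:
        stride = plan.train_stride
    c, p = plan.context, plan.horizon
    samples: list[ForecastSample] = []
    for run_start, run_len in _contiguous_runs(np.asarray(indices)):
        for s in range(run_start, run_start + run_len - (c + p) + 1, stride):
            samples.append(ForecastSample(
                context=rec.traces[s:s + c],
                target=rec.traces[s + c:s + c + p],
                session_id=rec.session_id,
                start_step=s,
            ))
    return samples


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_session(rec: SessionRecording, path: str | Path) -> Path:
    """Write a session to HDF5 (``.h5``) or NPZ (``.npz``), by extension."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=rec.traces)
            f.create_dataset("fs", data=float(rec.fs))
            f.create_dataset("unit_ids", data=np.array(rec.unit_ids, dtype="S"))
            if rec.region_labels is not None:
                f.create_dataset(
                    "region_labels", data=np.array(rec.region_labels, dtype="S")
                )
            f.attrs["session_id"] = rec.session_id
    elif path.suffix == ".npz":
        payload = {
            "traces": rec.traces,
            "fs": np.float64(rec.fs),
            "unit_ids": np.array(rec.unit_ids),
            "session_id": np.str_(rec.session_id),
        }
        if rec.region_labels is not None:
            payload["region_labels"] = np.array(rec.region_labels)
        np.savez(path, **payload)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r}")
    return path


def load_session(path: str | Path) -> SessionRecording:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            regions = (
                [s.decode() for s in f["region_labels"][()]]
                if "region_labels" in f else None
            )
            return SessionRecording(
                traces=f["traces"][()],
                fs=float(f["fs"][()]),
                unit_ids=[s.decode() for s in f["unit_ids"][()]],
                session_id=str(f.attrs["session_id"]),
                region_labels=regions,
            )
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            regions = (
                [str(s) for s in f["region_labels"]]
                if "region_labels" in f.files else None
            )
            return SessionRecording(
                traces=f["traces"],
                fs=float(f["fs"]),
                unit_ids=[str(s) for s in f["unit_ids"]],
                session_id=str(f["session_id"]),
                region_labels=regions,
            )
    raise ValueError(f"unsupported extension {path.suffix!r}")


def load_dataset(directory: str | Path) -> list[SessionRecording]:
    """Load every session file in a directory, sorted by filename."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix in {".h5", ".hdf5", ".npz"}
    )
    if not files:
        raise FileNotFoundError(f"no session files found in {directory}")
    return [load_session(p) for p in files]


def export_unit_summary(rec: SessionRecording, path: str | Path) -> pd.DataFrame:
    """Write per-neuron summary statistics to CSV for quick inspection."""
    x = rec.traces.astype(np.float64)
    df = pd.DataFrame({
        "unit_id": rec.unit_ids,
        "mean": x.mean(axis=0),
        "std": x.std(axis=0),
        "min": x.min(axis=0),
        "max": x.max(axis=0),
    })
    if rec.region_labels is not None:
        df["region"] = rec.region_labels
    df.to_csv(path, index=False)
    return df
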