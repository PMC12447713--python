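"""Cohort simulator: multi-individual synthetic recordings with
controllable inter-individual similarity.

Each cohort shares a template connectivity matrix J0 with i.i.d. standard
normal entries.  Individual i receives

    J_i = sqrt(1 - eta^2) * J0 + eta * eps_i,      eps_i ~ N(0, I)

so entries of J_i keep unit variance for every eta in [0, 1], while the
correlation between two individuals' connectivities is 1 - eta^2: eta = 0
gives identical individuals, eta = 1 independent ones.  Each J_i drives a
noisy spontaneous rate network

    r_{t+1} = r_t + dt * (-r_t + tanh((gain / sqrt(n)) * J_i @ r_t))
                  + noise_std * sqrt(dt) * xi_t

whose rates, after a burn-in, are passed through an exponential filter with
time constant ``calcium_tau`` steps to mimic slow calcium-indicator
dynamics, then z-scored per neuron.  The gain/sqrt(n) scaling puts the
spectral radius of the coupling near ``gain``, so gain > 1 yields rich
ongoing fluctuations rather than decay to the fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import SessionRecording


@dataclass(frozen=True)
class CohortSpec:
    """Simulation settings for one cohort of individuals."""

    n: int = 300                 # neurons per individual
    individuals: int = 16
    eta: float = 0.0             # inter-individual dissimilarity in [0, 1]
    T: int = 2000                # recorded steps per session (post burn-in)
    gain: float = 1.5            # recurrent gain; > 1 sustains fluctuations
    noise_std: float = 0.1      # process noise amplitude
    dt: float = 0.1              # integration step
    calcium_tau: float = 10.0    # slow-filter time constant, in steps
    burn_in: int = 500
    seed: int = 0
    fs: float = 2.0              # nominal sampling rate written to sessions, Hz

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta={self.eta} must be in [0, 1]")
        if self.n < 2:
            raise ValueError("need at least 2 neurons")
        if self.T < 1:
            raise ValueError("T must be positive")


def sample_template(n: int, seed: int) -> np.ndarray:
    """n x n template connectivity with i.i.d. N(0, 1) entries."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, n))


def mix_connectivity(j0: np.ndarray, eta: float,
                     seed: int | np.random.Generator) -> np.ndarray:
    """Blend the template with an individual deviation, preserving variance.

    The sqrt(1 - eta^2) coefficient is the unique scaling for which the
    mixture of two unit-variance components keeps unit variance.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta={eta} must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    eps = rng.standard_normal(j0.shape)
    return np.sqrt(1.0 - eta ** 2) * j0 + eta * eps


def simulate_rnn(ji: np.ndarray, spec: CohortSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Run the noisy rate network; return T x n z-scored calcium-like traces."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = ji.shape[0]
    coupling = (spec.gain / np.sqrt(n)) * ji
    sqrt_dt = np.sqrt(spec.dt)
    r = 0.1 * rng.standard_normal(n)
    total = spec.burn_in + spec.T
    noise = spec.noise_std * sqrt_dt * rng.standard_normal((total, n))
    rates = np.empty((spec.T, n))
    alpha = 1.0 / spec.calcium_tau
    c = np.zeros(n)
    for t in range(total):
        r = r + spec.dt * (-r + np.tanh(coupling @ r)) + noise[t]
        if np.abs(r).max() > 1e6:
            raise FloatingPointError(
                f"diverging trajectory (gain={spec.gain}, dt={spec.dt}, "
                f"noise_std={spec.noise_std}) at step {t}"
            )
        c = c + alpha * (r - c)          # slow calcium-like filter
        if t >= spec.burn_in:
            rates[t - spec.burn_in] = c
    mean = rates.mean(axis=0)
    std = rates.std(axis=0)
    std[std == 0.0] = 1.0
    return (rates - mean) / std


def generate_cohort(spec: CohortSpec) -> list[SessionRecording]:
    """One session per individual, all mixed from the same template.

    Per-individual randomness is derived deterministically from
    (cohort seed, individual index), so cohorts are reproducible piecewise.
    """
    j0 = sample_template(spec.n, spec.seed)
    sessions = []
    for i in range(spec.individuals):
        child = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,)))
        ji = mix_connectivity(j0, spec.eta, child)
        traces = simulate_rnn(ji, spec, rng=child)
        sessions.append(SessionRecording(
            traces=traces.astype(np.float32),
            fs=spec.fs,
            unit_ids=[f"u{j:04d}" for j in range(spec.n)],
            session_id=f"cohort{spec.seed}_ind{i:02d}",
            meta={"eta": spec.eta, "individual": i},
        ))
    return sessions
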