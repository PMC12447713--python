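# Methods

This note documents the model, the preprocessing conventions, the
simulator, the numerical choices, and the limits of what the synthetic
studies demonstrate.

## Forecasting setup

Each session is a `T × N` matrix of per-neuron traces at a fixed sampling
rate.  A forecaster maps the last `C = 48` steps to the next `P = 16`
steps and is scored by mean squared error pooled over all entries of all
evaluation windows, mirroring a single expectation over sessions and time.
The prediction score `1 − MSE(model)/MSE(copy)` normalizes by the
repeat-last-observation baseline, which is strong for slow calcium-like
signals; the copy forecaster itself scores exactly 0 by construction, and
scores may be negative.

## Preprocessing

- **Z-scoring** uses full-session statistics (mean and population variance
  per neuron), not train-partition statistics.  This is a deliberate,
  mild form of leakage matching common practice for this task; constant
  traces (dead ROIs) are centered, left at zero, and reported by warning.
- **PCA** is fit on the full z-scored session before segmentation, and
  component magnitudes are preserved — large population modes keep their
  scale, so they dominate the loss exactly as they dominate the data.
  Fitting PCA on the training partition only is available via the same
  function applied to a truncated recording.
- **Low-pass filtering** is off by default.  When enabled it is a
  zero-phase (forward-backward) second-order Butterworth filter with a
  configurable cutoff; zero-phase filtering avoids introducing lag into
  the forecasting targets.
- **Segmentation and splitting**: sessions are cut into 1000-step
  segments; within each segment the first 3/5 of steps are training, the
  next 1/5 validation, the last 1/5 test, in temporal order.  A trailing
  partial segment is split by the same proportions rounded down, with the
  remainder after train/val assigned to test, so every step is used and
  ratios are approximately preserved.  Forecast windows (context +
  horizon) are constrained to lie inside one partition span — no window
  straddles a boundary.  Training windows advance with stride 1 (dense);
  evaluation windows with stride `P` (non-overlapping targets).
- Traces are stored float32; all statistics and model arithmetic use
  float64.

## Model

The univariate MLP forecaster (`hidden size M = 1024` by default) shares
one weight set across all neurons and sessions; per-neuron specialization
enters only through FiLM.  The population encoder tokenizes each neuron's
context into `C/T_C` segments of length `T_C = 16` (configs where `C` is
not divisible by `T_C` are rejected at validation); each token embedding is
a linear projection of the segment plus learnable unit and session
embeddings (dimension `d = 128`, 4 attention heads by default — small
encoders suffice for this task).  `N_L = 8` latents cross-attend to the
tokens, pass through `L = 1` latent self-attention layers, and a final
cross-attention with unit embeddings as queries yields one read-out vector
per neuron; affine heads map it to the FiLM scale γ and shift β (`L + 2`
attention layers in total).  Attention blocks are pre-norm residual with a
small two-layer GELU MLP, as in common Perceiver-IO practice.

Numerical/initialization choices:

- The γ head starts with zero weights and unit bias, the β head all zero,
  so a fresh conditioned model coincides with the bare MLP forecaster to
  machine precision.  This stabilizes early training: the encoder fades in
  rather than scrambling the forecaster at step 0.
- Embeddings are drawn from N(0, 1/d) so their norms are O(1).
- Rotary position embeddings act on query/key vectors using token
  timestamps in units of steps (a token carries the time of its segment
  end).  Latents have no intrinsic time, so they carry learnable rotary
  positions initialized at 0; the unit-embedding queries of the read-out
  layer carry the timestamp of the last context step.  Whether the token
  projection is shared across datasets in multi-dataset runs: it is shared
  here.
- The engine underneath is a compact reverse-mode autodiff on float64
  NumPy arrays (`poco.autodiff`) whose op set covers exactly what these
  models need; every op's gradient is tested against central finite
  differences.

## Training

AdamW with learning rate 3e-4, weight decay 1e-4, betas (0.9, 0.999), and
gradient clipping at global norm 1 (clipping is a stability choice, not
part of the objective).  Batches are drawn from one session at a time,
with the session chosen with probability proportional to its number of
training windows — unbiased sampling per window.  Validation loss is
evaluated every `eval_every` steps (on a capped subsample of validation
windows for speed) and the best checkpoint by validation loss is restored
at the end; this guards the small synthetic runs against overfitting and
against the transient loss spikes Adam exhibits near convergence.
Multi-dataset training aggregates one random batch per dataset into an
unweighted summed loss per update.  Fine-tuning on an unseen session
first allocates fresh unit/session embeddings; `embedding_only` mode
freezes every other parameter (frozen parameters receive no gradient at
all, and the freeze is asserted bit-exactly in tests), while `full` mode
updates everything.  New-session embeddings are drawn from the same
N(0, 1/d) as at pre-training rather than warm-started from other sessions'
means; this is a tunable.

## Cohort simulator

A cohort shares a template connectivity `J0` with i.i.d. N(0, 1) entries.
Individual `i` gets `J_i = √(1−η²) J0 + η ε_i` with `ε_i` i.i.d. N(0, 1):
the square-root coefficient is the unique choice that keeps the entries of
`J_i` at unit variance for every η, and the expected correlation between
two individuals' connectivities is `1 − η²`.  Each `J_i`, scaled by
`gain/√n` so the coupling's spectral radius is near `gain`, drives a noisy
rate network

```
r_{t+1} = r_t + dt·(−r_t + tanh((gain/√n)·J_i·r_t)) + noise_std·√dt·ξ_t
```

with defaults gain 1.5 (supercritical: rich ongoing fluctuations instead
of decay), dt 0.1, noise_std 0.1, 500 burn-in steps.  Rates pass through
an exponential filter with a 10-step time constant to mimic slow calcium
indicator dynamics, then are z-scored per neuron.  Per-individual
randomness derives deterministically from (cohort seed, individual index),
so cohorts are reproducible piecewise.  Divergent trajectories raise an
error naming the unstable configuration.

What the simulator does *not* emulate: non-stationarity, heterogeneous
per-neuron noise, behavioral covariates, indicator nonlinearity, motion
artifacts, and session-to-session differences in sampling rate or
preprocessing.  Tests passing on this generator therefore demonstrate the
machinery and the qualitative phenomena (multi-session benefit under
shared structure, fast embedding-only adaptation), not performance on real
recordings.

## Desk-scale study conditions

The simulation studies in `poco.experiments` run on one CPU core, so their
problem sizes are deliberately modest; they are the package's standard
study conditions and all reported numbers use them:

- cohorts: 40 neurons per individual, 4 individuals, 1500 steps per
  session, η ∈ {0.05, 1};
- model: embedding dim 32, 4 heads, 8 latents, 1 self-attention layer,
  hidden size 128, `C=48`, `P=16`, `T_C=16`;
- optimization: batch 24, 240 multi-session steps; single-session models
  get 240/4 = 60 steps each so the total optimization budget matches;
  fine-tuning and from-scratch comparisons use a 200-step budget;
- the learning sanity check uses a 2-individual cohort with process noise
  0.05 and 200 training steps.

At these sizes the multi-session gain (multi-session score minus mean
single-session score) is measured per cohort and averaged over 3 cohort
seeds per η.  The contrast of interest — larger gain at η = 0.05 than at
η = 1 — is a qualitative, stochastic claim: individual seeds can tie or
reverse, the 3-seed average is what the acceptance suite asserts.

## Known limitations

- The autodiff engine is single-threaded NumPy; wall-clock cost grows
  quickly with neuron count and hidden size, which is why the default
  `M=1024` model is configured down in the desk-scale studies.
- Full-session z-scoring and PCA leak test-partition statistics into
  preprocessing (deliberately, see above); anyone needing strict causal
  preprocessing should fit statistics on the training partition.
- The evaluation pools MSE over sessions within a dataset; per-session
  scores are reported alongside but the headline score weights sessions by
  their number of windows and neurons.
- Region-similarity analysis of unit embeddings excludes self-pairs on the
  diagonal and min-max normalizes each row; a constant row is mapped to
  0.5 to flag lack of contrast rather than dividing by zero.
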