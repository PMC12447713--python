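"""Desk-scale simulation studies packaged as reusable experiment functions.

These reproduce, at reduced size, the qualitative phenomena the
population-conditioned forecaster is built around: multi-session training
helps most when individuals share connectivity structure (small eta), and a
pre-trained model adapts to an unseen session faster than training from
scratch, even when only its embeddings are tuned.

Problem sizes (40 neurons, 4 individuals, 1500 steps, embed dim 32, hidden
size 128, a few hundred optimizer steps) are chosen so each study runs in
minutes on a single CPU core while leaving the phenomena measurable; they
are the package's standard study conditions and are documented in the
methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .encoder import EncoderConfig, TokenizerConfig
from .evaluation import evaluate
from .forecasters import PocoCore
from .io_preprocess import SessionRecording, SplitPlan, make_windows, segment_and_split
from .simulate import CohortSpec, generate_cohort
from .training import TrainConfig, finetune, train


@dataclass(frozen=True)
class StudyConfig:
    """Shared desk-scale conditions for the simulation studies."""

    n: int = 40
    individuals: int = 4
    T: int = 1500
    gain: float = 1.5
    noise_std: float = 0.1
    embed_dim: int = 32
    heads: int = 4
    num_latents: int = 8
    num_self_layers: int = 1
    token_length: int = 16
    context: int = 48
    horizon: int = 16
    hidden_size: int = 128
    batch_size: int = 24
    ms_steps: int = 240
    eval_every: int = 60
    eval_max_windows: int = 48

    def cohort_spec(self, eta: float, seed: int, **kw) -> CohortSpec:
        return CohortSpec(n=self.n, individuals=self.individuals, eta=eta,
                          T=self.T, gain=self.gain, noise_std=self.noise_std,
                          seed=seed, **kw)

    def train_config(self, seed: int, **kw) -> TrainConfig:
        base = dict(lr=3e-4, weight_decay=1e-4, batch_size=self.batch_size,
                    max_steps=self.ms_steps, eval_every=self.eval_every,
                    seed=seed, context=self.context, horizon=self.horizon,
                    eval_max_windows=self.eval_max_windows)
        base.update(kw)
        return TrainConfig(**base)


def build_poco(sessions: list[SessionRecording], seed: int,
               study: StudyConfig = StudyConfig()) -> PocoCore:
    tok = TokenizerConfig(token_length=study.token_length,
                          context=study.context, embed_dim=study.embed_dim)
    enc = EncoderConfig(num_latents=study.num_latents,
                        num_self_layers=study.num_self_layers,
                        heads=study.heads, embed_dim=study.embed_dim)
    rng = np.random.default_rng(seed)
    model = PocoCore(tok, enc, study.horizon, study.hidden_size, rng)
    for rec in sessions:
        model.register_session(rec, rng=rng)
    return model


def held_out_test_samples(sessions: list[SessionRecording], plan: SplitPlan):
    out = []
    for rec in sessions:
        parts = segment_and_split(rec, plan)
        out += make_windows(rec, parts["test"], plan, stride=plan.eval_stride_)
    return out


def multisession_gain(eta: float, seed: int,
                      study: StudyConfig = StudyConfig()) -> dict:
    """Multi-session vs single-session training on one simulated cohort.

    One shared model is trained on all individuals for ``ms_steps``; one
    model per individual is trained for ``ms_steps / individuals`` so the
    total optimization budget matches.  Returns test prediction scores and
    the multi-session gain (MS minus mean SS).
    """
    sessions = generate_cohort(study.cohort_spec(eta, seed))
    cfg = study.train_config(seed)
    plan = cfg.split_plan()

    ms = build_poco(sessions, seed, study)
    ms, _ = train(ms, sessions, cfg)
    ms_score = evaluate(ms, held_out_test_samples(sessions, plan)).prediction_score

    ss_cfg = replace(cfg, max_steps=max(1, study.ms_steps // study.individuals))
    ss_scores = []
    for rec in sessions:
        model = build_poco([rec], seed, study)
        model, _ = train(model, [rec], ss_cfg)
        ss_scores.append(
            evaluate(model, held_out_test_samples([rec], plan)).prediction_score)
    ss_mean = float(np.mean(ss_scores))
    return {"eta": eta, "seed": seed, "ms_score": float(ms_score),
            "ss_score": ss_mean, "gain": float(ms_score) - ss_mean}


def eta_contrast(seeds: list[int], etas=(0.05, 1.0),
                 study: StudyConfig = StudyConfig()) -> dict:
    """Mean multi-session gain per eta, averaged over seeds."""
    gains = {eta: [] for eta in etas}
    for seed in seeds:
        for eta in etas:
            gains[eta].append(multisession_gain(eta, seed, study)["gain"])
    return {eta: float(np.mean(v)) for eta, v in gains.items()}


def finetune_comparison(seed: int, eta: float = 0.05,
                        finetune_steps: int = 200,
                        study: StudyConfig = StudyConfig()) -> dict:
    """Embedding-only adaptation of a pre-trained model vs from-scratch.

    Pre-trains on all but the last individual, then adapts to the held-out
    one by tuning only its fresh unit/session embeddings for a small step
    budget; a fresh model is trained from scratch on the same session with
    the same budget.  Also verifies that every non-embedding parameter is
    bit-identical after embedding-only fine-tuning.
    """
    sessions = generate_cohort(study.cohort_spec(eta, seed))
    pre, held = sessions[:-1], sessions[-1]
    cfg = study.train_config(seed)
    model = build_poco(pre, seed, study)
    model, _ = train(model, pre, cfg)

    backbone_before = {k: p.data.copy()
                       for k, p in model.named_parameters().items()}
    ft_cfg = study.train_config(seed, max_steps=finetune_steps, eval_every=25,
                                finetune_mode="embedding_only")
    model, curve = finetune(model, held, ft_cfg)
    backbone_delta = max(
        (float(np.max(np.abs(p.data - backbone_before[k])))
         for k, p in model.named_parameters().items() if k in backbone_before),
        default=0.0,
    )

    scratch = build_poco([held], seed, study)
    scratch_cfg = study.train_config(seed, max_steps=finetune_steps,
                                     eval_every=25)
    scratch, scratch_curve = train(scratch, [held], scratch_cfg)

    return {
        "seed": seed,
        "finetune_val": float(curve["val_loss"].min()),
        "scratch_val": float(scratch_curve["val_loss"].min()),
        "backbone_delta": backbone_delta,
        "adaptation_curve": list(map(float, curve["val_loss"])),
    }


def learning_sanity(seed: int, study: StudyConfig = StudyConfig(),
                    noise_std: float = 0.05, steps: int = 200) -> dict:
    """Train on a low-noise two-individual cohort; report the test score.

    Low process noise makes the dynamics highly predictable, so a briefly
    trained model should comfortably beat the copy baseline (score > 0).
    """
    study = replace(study, individuals=2, noise_std=noise_std)
    sessions = generate_cohort(study.cohort_spec(0.0, seed))
    cfg = study.train_config(seed, max_steps=steps)
    model = build_poco(sessions, seed, study)
    model, _ = train(model, sessions, cfg)
    report = evaluate(model, held_out_test_samples(sessions, cfg.split_plan()))
    return {"seed": seed, "prediction_score": float(report.prediction_score),
            "mse": float(report.mse), "copy_mse": float(report.copy_mse)}
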