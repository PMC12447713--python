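"""Configuration loading and validation.

Configs are nested YAML key/value files.  Every model hyperparameter has a
named default (C=48, P=16, M=1024, T_C=16, N_L=8, L=1, lr=3e-4,
weight_decay=1e-4) so a config file only needs to state deviations, and
deviations are visible in diffs.  Unknown keys and inconsistent
combinations (e.g. a context not divisible by the token length) are
rejected with explicit messages.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "data": {
        "context": 48,
        "horizon": 16,
        "segment_length": 1000,
        "ratios": [3, 1, 1],
        "train_stride": 1,
        "pca_components": None,      # None: no PCA reduction
        "lowpass_hz": None,          # None: no temporal filter
        "zscore": True,
    },
    "model": {
        "kind": "poco",              # poco | mlp | nlinear | dlinear | copy
        "hidden_size": 1024,
        "token_length": 16,
        "embed_dim": 128,
        "num_latents": 8,
        "num_self_layers": 1,
        "heads": 4,
        "rotary": True,
    },
    "train": {
        "lr": 3.0e-4,
        "weight_decay": 1.0e-4,
        "batch_size": 64,
        "max_steps": 2000,
        "eval_every": 100,
        "seed": 0,
        "mode": "multi_session",
        "finetune_mode": "none",
    },
    "simulate": {
        "n": 300,
        "individuals": 16,
        "eta": 0.0,
        "T": 2000,
        "gain": 1.5,
        "noise_std": 0.1,
        "dt": 0.1,
        "calcium_tau": 10.0,
        "seed": 0,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    unknown = []
    for key, value in override.items():
        here = f"{path}{key}"
        if key not in base:
            unknown.append(here)
            continue
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, f"{here}.")
        else:
            out[key] = value
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return out


def validate_config(cfg: dict) -> dict:
    data, model, train = cfg["data"], cfg["model"], cfg["train"]
    c, tc = data["context"], model["token_length"]
    if model["kind"] == "poco" and c % tc != 0:
        raise ConfigError(
            f"context C={c} must be divisible by token_length T_C={tc}"
        )
    if model["embed_dim"] % model["heads"] != 0:
        raise ConfigError("embed_dim must be divisible by heads")
    if data["horizon"] < 1 or data["context"] < 1:
        raise ConfigError("context and horizon must be positive")
    if train["lr"] <= 0 or train["batch_size"] <= 0:
        raise ConfigError("lr and batch_size must be positive")
    if len(data["ratios"]) != 3 or any(r <= 0 for r in data["ratios"]):
        raise ConfigError("ratios must be three positive integers")
    return cfg


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Load a YAML config, fill defaults, and validate.

    An empty (or absent) file yields the full default configuration.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return validate_config(cfg)
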