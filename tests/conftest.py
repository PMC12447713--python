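import numpy as np
import pytest
from hypothesis import settings

import poco

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_poco():
    """A small population-conditioned model with one registered session."""
    tok = poco.TokenizerConfig(token_length=4, context=12, embed_dim=16)
    enc = poco.EncoderConfig(num_latents=4, num_self_layers=1, heads=2,
                             embed_dim=16)
    model = poco.PocoCore(tok, enc, horizon=5, hidden_size=8,
                          rng=np.random.default_rng(0))
    model.register_session("sess_a", [f"u{i}" for i in range(6)], rng=1)
    return model


@pytest.fixture(scope="session")
def small_cohort():
    """Two-individual low-noise cohort used across training tests."""
    spec = poco.CohortSpec(n=20, individuals=2, eta=0.0, T=600,
                           noise_std=0.05, seed=7)
    return poco.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_plan():
    return poco.SplitPlan(segment_length=600, context=12, horizon=5)
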