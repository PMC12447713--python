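"""Population encoder: per-neuron tokenization, latent-bottleneck attention,
and per-neuron FiLM conditioning parameters.

Each neuron's context trace of C steps is cut into C/T_C segments; each
segment becomes one token whose embedding is a linear projection of the
segment plus learnable unit and session embeddings.  A small set of N_L
learnable latents cross-attends to all tokens (cost linear in neuron
count), passes through L latent self-attention layers, and a final
cross-attention with the unit embeddings as queries reads out one vector
per neuron.  Affine heads map these vectors to the FiLM scale gamma and
shift beta applied inside the univariate MLP forecaster.

The gamma head is initialized to emit exactly 1 and the beta head exactly
0, so a fresh population-conditioned model starts out identical to the bare
MLP forecaster — this stabilizes early training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor
from .nn import AttentionBlock, Linear, Module


@dataclass(frozen=True)
class TokenizerConfig:
    """Tokenization settings: context C must divide into T_C-step segments."""

    token_length: int = 16
    context: int = 48
    embed_dim: int = 128
    rotary: bool = True

    def __post_init__(self):
        if self.context % self.token_length != 0:
            raise ValueError(
                f"context C={self.context} must be divisible by "
                f"token_length T_C={self.token_length}"
            )

    @property
    def tokens_per_unit(self) -> int:
        return self.context // self.token_length


@dataclass(frozen=True)
class EncoderConfig:
    num_latents: int = 8
    num_self_layers: int = 1
    heads: int = 4
    embed_dim: int = 128

    def __post_init__(self):
        if self.num_latents < 1:
            raise ValueError("need at least one latent")
        if self.num_self_layers < 0:
            raise ValueError("num_self_layers must be >= 0")
        if self.embed_dim % self.heads != 0:
            raise ValueError("embed_dim must be divisible by heads")


class MissingEmbeddingError(KeyError):
    """A session/unit has no embedding yet; call init_new_session first."""


class EmbeddingTables(Module):
    """Learnable per-(session, unit) and per-session embedding vectors.

    The only session-specific parameters in the whole model.  New sessions
    are registered with :meth:`init_new_session`; embeddings are drawn from
    N(0, 1/d) so their norms are O(1).
    """

    def __init__(self, embed_dim: int):
        self.embed_dim = embed_dim
        self._sessions: dict[str, dict] = {}

    # Module discovery does not descend into plain dicts; do it explicitly.
    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for sid, entry in self._sessions.items():
            out[f"{prefix}sessions.{sid}.session"] = entry["session"]
            out[f"{prefix}sessions.{sid}.units"] = entry["units"]
        return out

    @property
    def session_ids(self) -> list[str]:
        return list(self._sessions)

    def init_new_session(
        self,
        session_id: str,
        unit_ids: list[str],
        rng: np.random.Generator,
    ) -> "EmbeddingTables":
        """Allocate fresh trainable embeddings for an unseen session."""
        if session_id in self._sessions:
            raise ValueError(f"session {session_id!r} already registered")
        if len(set(unit_ids)) != len(unit_ids):
            raise ValueError("unit_ids must be unique")
        d = self.embed_dim
        std = 1.0 / np.sqrt(d)
        self._sessions[session_id] = {
            "session": Parameter(rng.normal(0.0, std, size=d)),
            "units": Parameter(rng.normal(0.0, std, size=(len(unit_ids), d))),
            "unit_index": {u: i for i, u in enumerate(unit_ids)},
            "unit_ids": list(unit_ids),
        }
        return self

    def _entry(self, session_id: str) -> dict:
        try:
            return self._sessions[session_id]
        except KeyError:
            raise MissingEmbeddingError(
                f"session {session_id!r} has no embeddings; "
                "call init_new_session first"
            ) from None

    def session_embedding(self, session_id: str) -> Parameter:
        return self._entry(session_id)["session"]

    def unit_embeddings(self, session_id: str,
                        unit_ids: list[str] | None = None) -> Tensor:
        """(N, d) matrix of unit embeddings, optionally reordered."""
        entry = self._entry(session_id)
        if unit_ids is None:
            return entry["units"]
        index = entry["unit_index"]
        try:
            rows = np.array([index[u] for u in unit_ids])
        except KeyError as e:
            raise MissingEmbeddingError(
                f"unit {e.args[0]!r} unregistered in session {session_id!r}"
            ) from None
        return entry["units"].take(rows, axis=0)

    def unit_ids(self, session_id: str) -> list[str]:
        return list(self._entry(session_id)["unit_ids"])

    def manifest(self) -> dict:
        return {sid: list(e["unit_ids"]) for sid, e in self._sessions.items()}


class PopulationEncoder(Module):
    """Latent-bottleneck attention encoder emitting FiLM (gamma, beta)."""

    def __init__(
        self,
        tok_cfg: TokenizerConfig,
        enc_cfg: EncoderConfig,
        hidden_size: int,
        rng: np.random.Generator,
    ):
        if tok_cfg.embed_dim != enc_cfg.embed_dim:
            raise ValueError("tokenizer and encoder embed_dim must match")
        d = enc_cfg.embed_dim
        self.tok_cfg = tok_cfg
        self.enc_cfg = enc_cfg
        self.hidden_size = hidden_size
        self.token_proj = Linear(tok_cfg.token_length, d, rng)
        self.latents = Parameter(rng.normal(0.0, 1.0 / np.sqrt(d), size=(enc_cfg.num_latents, d)))
        # latents have no intrinsic time; they carry learned rotary positions
        self.latent_pos = Parameter(np.zeros(enc_cfg.num_latents))
        rot = tok_cfg.rotary
        self.cross_in = AttentionBlock(d, enc_cfg.heads, rng, rotary=rot)
        self.self_blocks = [
            AttentionBlock(d, enc_cfg.heads, rng, rotary=rot)
            for _ in range(enc_cfg.num_self_layers)
        ]
        self.cross_out = AttentionBlock(d, enc_cfg.heads, rng, rotary=rot)
        # identity-FiLM initialization: gamma = 1, beta = 0 at step 0
        self.gamma_head = Linear(d, hidden_size, rng, zero_init=True, bias_init=1.0)
        self.beta_head = Linear(d, hidden_size, rng, zero_init=True, bias_init=0.0)

    # -- tokenization -------------------------------------------------------

    def tokenize(
        self,
        context: np.ndarray | Tensor,
        session_id: str,
        tables: EmbeddingTables,
        unit_ids: list[str] | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        """Embed a (B, C, N) context into (B, N*K, d) tokens with timestamps.

        Token (i, k) = W @ segment_k(neuron i) + b + UnitEmbed(i) +
        SessionEmbed; its timestamp is the context step at the segment end.
        """
        cfg = self.tok_cfg
        x = context if isinstance(context, Tensor) else Tensor(context)
        if x.ndim == 2:
            x = x.reshape(1, *x.shape)
        b, c, n = x.shape
        if c != cfg.context:
            raise ValueError(f"context length {c} != configured C={cfg.context}")
        k = cfg.tokens_per_unit
        segments = x.transpose(0, 2, 1).reshape(b, n, k, cfg.token_length)
        tokens = self.token_proj(segments)                        # (B,N,K,d)
        units = tables.unit_embeddings(session_id, unit_ids)      # (N,d)
        tokens = tokens + units.reshape(1, n, 1, cfg.embed_dim)
        tokens = tokens + tables.session_embedding(session_id)
        tokens = tokens.reshape(b, n * k, cfg.embed_dim)
        timestamps = np.tile((np.arange(1, k + 1) * cfg.token_length), n)
        return tokens, timestamps

    # -- encoding -----------------------------------------------------------

    def __call__(
        self,
        context: np.ndarray | Tensor,
        session_id: str,
        tables: EmbeddingTables,
        unit_ids: list[str] | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return FiLM (gamma, beta), each of shape (B, N, M)."""
        tokens, t_tok = self.tokenize(context, session_id, tables, unit_ids)
        b, _, d = tokens.shape
        n = tokens.shape[1] // self.tok_cfg.tokens_per_unit

        lat = self.latents.reshape(1, self.enc_cfg.num_latents, d)
        lat = self.cross_in(lat, tokens, t_q=self.latent_pos, t_k=t_tok)
        for blk in self.self_blocks:
            lat = blk(lat, t_q=self.latent_pos, t_k=self.latent_pos)

        units = tables.unit_embeddings(session_id, unit_ids)
        queries = units.reshape(1, n, d)
        # unit queries carry the timestamp of the last context step
        t_units = np.full(n, self.tok_cfg.context, dtype=float)
        readout = self.cross_out(queries, lat, t_q=t_units, t_k=self.latent_pos)
        gamma = self.gamma_head(readout)                          # (B,N,M)
        beta = self.beta_head(readout)
        return gamma, beta


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def tokenize(context, session_id, cfg: TokenizerConfig, tables: EmbeddingTables,
             encoder: PopulationEncoder | None = None):
    """Tokenize a context window (thin wrapper over PopulationEncoder)."""
    if encoder is None:
        rng = np.random.default_rng(0)
        encoder = PopulationEncoder(cfg, EncoderConfig(embed_dim=cfg.embed_dim),
                                    hidden_size=1, rng=rng)
    return encoder.tokenize(context, session_id, tables)


def encode_population(encoder: PopulationEncoder, context, session_id,
                      tables: EmbeddingTables):
    """Return the FiLM conditioning pair for one context window."""
    return encoder(context, session_id, tables)


def init_new_session(tables: EmbeddingTables, session_id: str,
                     unit_ids: list[str],
                     rng: np.random.Generator | int | None = None) -> EmbeddingTables:
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return tables.init_new_session(session_id, unit_ids, rng)
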