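"""Channel-agnostic multimodal PSG encoder.

Architecture, per modality stream:

1. **Tokenizer** — six 1-D conv blocks with feature maps 1-4-8-16-32-64-128,
   each block Conv -> BatchNorm -> ELU -> LayerNorm; adaptive average
   pooling collapses the temporal axis and a linear layer emits the fixed
   128-d token embedding. Every 5-s token (640 samples at 128 Hz) is
   embedded independently.
2. **Channel pooling** — one transformer-encoder layer contextualizes token
   embeddings across the channel axis per time segment (masked channels are
   excluded from attention), followed by a masked mean over channels. The
   result is channel-count and channel-order agnostic.
3. **Temporal transformer** — sinusoidal positional encoding plus three
   transformer-encoder layers (eight heads) over token sequences of at most
   one 5-min context window (60 tokens); longer recordings are processed in
   consecutive non-overlapping windows.
4. **Temporal pooling** — learned-query attention produces non-negative
   weights summing to one over valid tokens; the weighted average is the
   128-d modality embedding.

The default configuration uses per-modality tokenizer and channel-pooling
streams with a shared temporal transformer, and a transformer feed-forward
width of 2048; this reproduces the intended parameter scale of the
pretraining model (~4.4M) and of the downstream fine-tuning head (~0.9M).
A reduced shared-stream configuration is provided for desk-scale training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _nn
from ._autograd import Tensor, no_grad
from .preprocess import MODALITIES, TOKEN_LEN, TokenArray


@dataclass
class EncoderConfig:
    token_dim: int = 128
    conv_feature_maps: tuple[int, ...] = (1, 4, 8, 16, 32, 64, 128)
    conv_kernel: int = 3
    conv_stride: int = 3
    n_temporal_layers: int = 3
    n_heads: int = 8
    channel_pool_heads: int = 8
    dropout: float = 0.3
    ffn_width: int = 2048
    max_context_tokens: int = 60  # 5 min of 5-s tokens
    per_modality_streams: bool = True
    modalities: tuple[str, ...] = tuple(MODALITIES)
    seed: int = 0

    def __post_init__(self):
        if self.token_dim != 128:
            raise ValueError("token_dim is fixed at 128")
        if len(self.conv_feature_maps) != 7:
            raise ValueError("conv_feature_maps must list six transitions (7 sizes)")
        if self.conv_kernel % 2 != 1:
            raise ValueError("conv_kernel must be odd")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def desk_config(**overrides) -> EncoderConfig:
    """Reduced configuration for CPU-scale studies (shared streams,
    narrower feed-forward); the architecture is otherwise identical."""
    base = dict(ffn_width=512, per_modality_streams=False)
    base.update(overrides)
    return EncoderConfig(**base)


class ConvTokenizer(_nn.Module):
    """Six fused conv blocks + adaptive average pool + linear projection."""

    def __init__(self, rng, cfg: EncoderConfig):
        super().__init__()
        maps = cfg.conv_feature_maps
        pad = cfg.conv_kernel // 2
        self.blocks: list[_nn.FusedConvBlock] = []
        for i in range(6):
            blk = _nn.FusedConvBlock(rng, maps[i], maps[i + 1],
                                     kernel=cfg.conv_kernel,
                                     stride=cfg.conv_stride, padding=pad)
            setattr(self, f"block{i}", blk)
            self.blocks.append(blk)
        self.proj = _nn.Linear(rng, maps[-1], cfg.token_dim)

    def forward(self, tokens: Tensor) -> Tensor:
        """(N, 640) raw tokens -> (N, 128) embeddings."""
        x = tokens.reshape(tokens.data.shape[0], tokens.data.shape[1], 1)
        for blk in self.blocks:
            x = blk(x)
        return self.proj(x.mean(axis=1))


class ChannelPool(_nn.Module):
    """Transformer layer across channels per time segment + masked mean."""

    def __init__(self, rng, cfg: EncoderConfig):
        super().__init__()
        self.layer = _nn.TransformerEncoderLayer(
            rng, cfg.token_dim, cfg.channel_pool_heads, cfg.ffn_width, cfg.dropout)

    def forward(self, x: Tensor, channel_mask: np.ndarray) -> Tensor:
        """x (B', C, D) with boolean mask (B', C) -> (B', D)."""
        if not channel_mask.any(axis=1).all():
            raise ValueError("a present modality has all channels masked")
        h = self.layer(x, key_padding_mask=channel_mask)
        m = channel_mask.astype(h.data.dtype)
        w = m / m.sum(axis=1, keepdims=True)
        return (h * Tensor(w[:, :, None])).sum(axis=1)


class TemporalTransformer(_nn.Module):
    """Sinusoidal positions + stacked self-attention over token sequences."""

    def __init__(self, rng, cfg: EncoderConfig):
        super().__init__()
        self.max_tokens = cfg.max_context_tokens
        self.layers: list[_nn.TransformerEncoderLayer] = []
        for i in range(cfg.n_temporal_layers):
            layer = _nn.TransformerEncoderLayer(
                rng, cfg.token_dim, cfg.n_heads, cfg.ffn_width, cfg.dropout)
            setattr(self, f"layer{i}", layer)
            self.layers.append(layer)
        self._pe = _nn.sinusoidal_encoding(cfg.max_context_tokens, cfg.token_dim)

    def forward(self, x: Tensor, token_mask: np.ndarray | None = None) -> Tensor:
        b, s, d = x.data.shape
        if s > self.max_tokens:
            raise ValueError(
                f"sequence of {s} tokens exceeds the {self.max_tokens}-token "
                "context; chunk into consecutive windows first")
        x = x + Tensor(self._pe[:s].astype(x.data.dtype))
        for layer in self.layers:
            x = layer(x, key_padding_mask=token_mask)
        return x


class SleepEncoder(_nn.Module):
    """The full channel-agnostic multimodal encoder."""

    def __init__(self, config: EncoderConfig | None = None):
        super().__init__()
        self.config = config or EncoderConfig()
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 12_345])
        streams = cfg.modalities if cfg.per_modality_streams else ("shared",)
        for name in streams:
            setattr(self, f"tokenizer_{name}", ConvTokenizer(rng, cfg))
            setattr(self, f"channel_pool_{name}", ChannelPool(rng, cfg))
        self.temporal = TemporalTransformer(rng, cfg)
        self.time_pool = _nn.AttentionPool(rng, cfg.token_dim)

    # -- stream lookup ----------------------------------------------------

    def _stream(self, modality: str) -> str:
        return modality if self.config.per_modality_streams else "shared"

    def tokenizer(self, modality: str) -> ConvTokenizer:
        return getattr(self, f"tokenizer_{self._stream(modality)}")

    def channel_pool_module(self, modality: str) -> ChannelPool:
        return getattr(self, f"channel_pool_{self._stream(modality)}")

    # -- spec operations --------------------------------------------------

    def encode_tokens(self, tokens: Tensor | np.ndarray, modality: str) -> Tensor:
        """(B, C, S, 640) -> (B, C, S, 128), each token embedded independently."""
        t = tokens if isinstance(tokens, Tensor) else Tensor(tokens)
        b, c, s, length = t.data.shape
        if length != TOKEN_LEN:
            raise ValueError(
                f"{modality}: token length {length} != {TOKEN_LEN} samples")
        flat = t.reshape(b * c * s, length)
        emb = self.tokenizer(modality)(flat)
        return emb.reshape(b, c, s, self.config.token_dim)

    def pool_channels(self, embeddings: Tensor, modality: str,
                      channel_mask: np.ndarray | None = None) -> Tensor:
        """(B, C, S, 128) -> (B, S, 128); invariant to channel order."""
        b, c, s, d = embeddings.data.shape
        if c < 1:
            raise ValueError(f"{modality}: no channels to pool")
        if channel_mask is None:
            channel_mask = np.ones((b, c), dtype=bool)
        channel_mask = np.broadcast_to(np.asarray(channel_mask, dtype=bool), (b, c))
        x = embeddings.transpose(0, 2, 1, 3).reshape(b * s, c, d)
        mask = np.repeat(channel_mask[:, None, :], s, axis=1).reshape(b * s, c)
        pooled = self.channel_pool_module(modality)(x, mask)
        return pooled.reshape(b, s, d)

    def temporal_context(self, sequence: Tensor,
                         token_mask: np.ndarray | None = None) -> Tensor:
        """(B, S<=60, 128) -> contextualized (B, S, 128)."""
        return self.temporal(sequence, token_mask)

    def pool_time(self, sequence: Tensor,
                  token_mask: np.ndarray | None = None) -> Tensor:
        """(B, S, 128) -> (B, 128) via learned-query attention."""
        b, s, d = sequence.data.shape
        if token_mask is None:
            token_mask = np.ones((b, s), dtype=bool)
        token_mask = np.broadcast_to(np.asarray(token_mask, dtype=bool), (b, s))
        if not token_mask.any(axis=1).all():
            raise ValueError("pool_time requires at least one valid token")
        return self.time_pool(sequence, token_mask)

    def pool_time_weights(self, sequence: Tensor,
                          token_mask: np.ndarray | None = None) -> np.ndarray:
        b, s, _ = sequence.data.shape
        if token_mask is None:
            token_mask = np.ones((b, s), dtype=bool)
        return self.time_pool.weights(sequence, token_mask).data

    # -- composite passes -------------------------------------------------

    def forward_window(self, window: dict[str, np.ndarray],
                       channel_masks: dict[str, np.ndarray] | None = None,
                       token_mask: np.ndarray | None = None) -> dict[str, Tensor]:
        """One <=5-min window per modality: (B, C, S, 640) -> (B, 128)."""
        out = {}
        for mod, tokens in window.items():
            if tokens.shape[1] == 0:
                continue
            emb = self.encode_tokens(Tensor(tokens), mod)
            cmask = channel_masks.get(mod) if channel_masks else None
            seq = self.pool_channels(emb, mod, cmask)
            seq = self.temporal_context(seq, token_mask)
            out[mod] = self.pool_time(seq, token_mask)
        if not out:
            raise ValueError("window contains no present modality")
        return out

    def embed_recording(self, tokens: TokenArray) -> "RecordingEmbedding":
        """Full-recording inference: per-modality token-level and pooled
        embeddings, computed in consecutive non-overlapping 5-min windows.

        Absent modalities are flagged absent, never fabricated.
        """
        cfg = self.config
        was_training = self.training
        self.eval()
        token_level: dict[str, np.ndarray] = {}
        pooled: dict[str, np.ndarray] = {}
        s_total = tokens.n_tokens
        w = cfg.max_context_tokens
        try:
            with no_grad():
                for mod in tokens.modalities:
                    arr = tokens.data[mod]  # (C, S, 640)
                    seq_parts = []
                    for lo in range(0, s_total, w):
                        chunk = arr[None, :, lo : lo + w, :]
                        mask_chunk = tokens.token_mask[None, lo : lo + w]
                        if not mask_chunk.any():
                            seq_parts.append(np.zeros(
                                (chunk.shape[2], cfg.token_dim), dtype=np.float32))
                            continue
                        emb = self.encode_tokens(Tensor(chunk), mod)
                        seq = self.pool_channels(emb, mod)
                        seq = self.temporal_context(seq, mask_chunk)
                        seq_parts.append(seq.data[0])
                    full = np.concatenate(seq_parts, axis=0)  # (S, 128)
                    token_level[mod] = full
                    valid = tokens.token_mask
                    pooled[mod] = self.pool_time(
                        Tensor(full[None]), valid[None]).data[0]
        finally:
            self.train(was_training)
        return RecordingEmbedding(
            patient_id=tokens.patient_id,
            token_level=token_level,
            pooled=pooled,
            token_mask=tokens.token_mask.copy(),
        )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "SleepEncoder":
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        cfg_raw = json.loads(state.pop("__config__").tobytes().decode())
        for key in ("conv_feature_maps", "modalities"):
            cfg_raw[key] = tuple(cfg_raw[key])
        enc = cls(EncoderConfig(**cfg_raw))
        enc.load_state_dict(state)
        return enc


@dataclass
class RecordingEmbedding:
    """Per-modality 5-s token embeddings and pooled modality embeddings."""

    patient_id: str
    token_level: dict[str, np.ndarray]  # modality -> (S, 128)
    pooled: dict[str, np.ndarray]  # modality -> (128,)
    token_mask: np.ndarray

    def present(self, modality: str) -> bool:
        return modality in self.token_level

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if self.present(m)]
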