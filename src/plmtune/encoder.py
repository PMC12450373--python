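"""Tiny per-residue transformer encoder with LoRA adapter support.

The encoder follows the standard contract of a protein language model:
tokens in, one embedding vector per token out (last hidden layer), plus
vocabulary logits for the masked-token objective.  It is a pre-norm
transformer with learned positional embeddings, deterministic given its
seed, and deliberately small — a desk-scale stand-in for billion-parameter
encoders that share the same interface.

LoRA (low-rank adaptation) attaches rank-``r`` factor pairs ``(A, B)`` to
the attention query/key/value projections.  The base weights stay frozen;
the adapted projection computes ``h = x·W + (alpha/r)·(x·Aᵀ)·Bᵀ``.  ``B``
starts at zero so the adapted model is exactly the base model before any
training, and the update can be merged into the base weights afterwards.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, softmax
from .vocab import AminoAcidVocabulary, tokenize

PROJECTIONS = ("query", "key", "value")


@dataclass(frozen=True)
class EncoderConfig:
    embedding_dim: int = 32
    num_layers: int = 2
    num_heads: int = 4
    max_sequence_length: int = 512
    feedforward_dim: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.embedding_dim <= 0 or self.num_layers <= 0 or self.num_heads <= 0:
            raise ValueError("model dimensions must be positive")
        if self.embedding_dim % self.num_heads:
            raise ValueError("embedding_dim must be divisible by num_heads")
        if self.max_sequence_length < 2:
            raise ValueError("max_sequence_length must be at least 2")


@dataclass(frozen=True)
class LoRAConfig:
    """Low-rank adapter hyper-parameters (rank 8 on Wq/Wk/Wv by default)."""

    rank_r: int = 8
    scaling_alpha: float | None = None  # defaults to rank_r (net factor 1)
    target_projections: tuple[str, ...] = PROJECTIONS
    init_seed: int = 0

    def __post_init__(self):
        if self.rank_r <= 0:
            raise ValueError("rank_r must be positive")
        if not self.target_projections:
            raise ValueError("target_projections must be nonempty")
        for t in self.target_projections:
            if t not in PROJECTIONS:
                raise ValueError(f"unknown projection target {t!r}")

    @property
    def scale(self) -> float:
        alpha = self.rank_r if self.scaling_alpha is None else self.scaling_alpha
        return alpha / self.rank_r


class ReferenceEncoder:
    """Deterministic pre-norm transformer mapping tokens to residue vectors."""

    def __init__(self, config: EncoderConfig, vocab: AminoAcidVocabulary):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d, ff, V = config.embedding_dim, config.feedforward_dim, vocab.size
        s = 0.05

        def w(*shape):
            return Tensor(rng.normal(0.0, s, shape))

        p: dict[str, Tensor] = {
            "tok_emb": w(V, d),
            "pos_emb": w(config.max_sequence_length, d),
            "ln_f.g": Tensor(np.ones(d)),
            "ln_f.b": Tensor(np.zeros(d)),
            "head.W": w(d, V),
            "head.b": Tensor(np.zeros(V)),
        }
        for i in range(config.num_layers):
            p[f"l{i}.ln1.g"] = Tensor(np.ones(d))
            p[f"l{i}.ln1.b"] = Tensor(np.zeros(d))
            p[f"l{i}.ln2.g"] = Tensor(np.ones(d))
            p[f"l{i}.ln2.b"] = Tensor(np.zeros(d))
            for proj in ("query", "key", "value", "out"):
                p[f"l{i}.{proj}.W"] = w(d, d)
            p[f"l{i}.ff.W1"] = w(d, ff)
            p[f"l{i}.ff.b1"] = Tensor(np.zeros(ff))
            p[f"l{i}.ff.W2"] = w(ff, d)
            p[f"l{i}.ff.b2"] = Tensor(np.zeros(d))
        self.params = p

    # -- forward --------------------------------------------------------------
    @staticmethod
    def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-6) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + eps) ** 0.5 * g + b

    def _project(self, h: Tensor, layer: int, proj: str, lora) -> Tensor:
        out = h @ self.params[f"l{layer}.{proj}.W"]
        if lora is not None and (layer, proj) in lora:
            A, B, scale = lora[(layer, proj)]
            out = out + (h @ A.T) @ B.T * scale
        return out

    def forward(
        self, token_ids: list[int] | np.ndarray, lora=None
    ) -> tuple[Tensor, Tensor]:
        """Return (hidden L×d, logits L×V) for one token sequence."""
        ids = np.asarray(token_ids, dtype=np.intp)
        L = len(ids)
        if L == 0:
            raise ValueError("empty token sequence")
        if L > self.config.max_sequence_length:
            raise ValueError(
                f"token sequence of length {L} exceeds max_sequence_length "
                f"{self.config.max_sequence_length}"
            )
        cfg = self.config
        dh = cfg.embedding_dim // cfg.num_heads
        x = self.params["tok_emb"][ids] + self.params["pos_emb"][np.arange(L)]
        for i in range(cfg.num_layers):
            h = self._layer_norm(x, self.params[f"l{i}.ln1.g"], self.params[f"l{i}.ln1.b"])
            q = self._project(h, i, "query", lora)
            k = self._project(h, i, "key", lora)
            v = self._project(h, i, "value", lora)
            # (L, d) -> (heads, L, d_head)
            q = q.reshape(L, cfg.num_heads, dh).transpose((1, 0, 2))
            k = k.reshape(L, cfg.num_heads, dh).transpose((1, 0, 2))
            v = v.reshape(L, cfg.num_heads, dh).transpose((1, 0, 2))
            scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
            ctx = softmax(scores, axis=-1) @ v
            ctx = ctx.transpose((1, 0, 2)).reshape(L, cfg.embedding_dim)
            x = x + ctx @ self.params[f"l{i}.out.W"]
            h2 = self._layer_norm(x, self.params[f"l{i}.ln2.g"], self.params[f"l{i}.ln2.b"])
            ff = (h2 @ self.params[f"l{i}.ff.W1"] + self.params[f"l{i}.ff.b1"]).relu()
            x = x + ff @ self.params[f"l{i}.ff.W2"] + self.params[f"l{i}.ff.b2"]
        hidden = self._layer_norm(x, self.params["ln_f.g"], self.params["ln_f.b"])
        logits = hidden @ self.params["head.W"] + self.params["head.b"]
        return hidden, logits

    def encode(self, sequence: str, lora=None) -> tuple[Tensor, Tensor, list[int]]:
        ids = tokenize(sequence, self.vocab, self.config.max_sequence_length)
        hidden, logits = self.forward(ids, lora=lora)
        return hidden, logits, ids

    # -- bookkeeping ----------------------------------------------------------
    def weight_hash(self) -> str:
        """SHA-256 over all base parameters, for freeze verification."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cfg = dict(self.config.__dict__)
        cfg["include_bos_eos"] = self.vocab.include_bos_eos
        (directory / "encoder_config.json").write_text(json.dumps(cfg, indent=2))
        np.savez(
            directory / "base_weights.npz",
            **{k: v.data for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceEncoder":
        directory = Path(directory)
        cfg = json.loads((directory / "encoder_config.json").read_text())
        vocab = AminoAcidVocabulary(include_bos_eos=cfg.pop("include_bos_eos"))
        enc = cls(EncoderConfig(**cfg), vocab)
        with np.load(directory / "base_weights.npz") as data:
            for k in enc.params:
                enc.params[k] = Tensor(data[k])
        return enc


def build_reference_encoder(
    config: EncoderConfig, vocab: AminoAcidVocabulary | None = None
) -> ReferenceEncoder:
    return ReferenceEncoder(config, vocab or AminoAcidVocabulary())


class AdaptedEncoder:
    """A frozen base encoder plus trainable LoRA factors on Wq/Wk/Wv.

    Only the LoRA factors (and any task head added by a training objective)
    are trainable; the base weights are never touched by a gradient step.
    """

    def __init__(self, base: ReferenceEncoder, lora_config: LoRAConfig):
        d = base.config.embedding_dim
        if lora_config.rank_r >= d:
            raise ValueError(
                f"LoRA rank {lora_config.rank_r} must be smaller than the "
                f"projection dimension {d}"
            )
        self.base = base
        self.lora_config = lora_config
        rng = np.random.default_rng(lora_config.init_seed)
        self.factors: dict[tuple[int, str], tuple[Tensor, Tensor]] = {}
        for layer in range(base.config.num_layers):
            for proj in lora_config.target_projections:
                A = Tensor(rng.normal(0.0, 0.02, (lora_config.rank_r, d)), requires_grad=True)
                B = Tensor(np.zeros((d, lora_config.rank_r)), requires_grad=True)
                self.factors[(layer, proj)] = (A, B)

    @property
    def vocab(self) -> AminoAcidVocabulary:
        return self.base.vocab

    @property
    def config(self) -> EncoderConfig:
        return self.base.config

    def _lora_map(self):
        scale = self.lora_config.scale
        return {k: (A, B, scale) for k, (A, B) in self.factors.items()}

    def forward(self, token_ids) -> tuple[Tensor, Tensor]:
        return self.base.forward(token_ids, lora=self._lora_map())

    def encode(self, sequence: str) -> tuple[Tensor, Tensor, list[int]]:
        return self.base.encode(sequence, lora=self._lora_map())

    def trainable_parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for A, B in self.factors.values():
            out.extend((A, B))
        return out

    def trainable_parameter_count(self) -> int:
        return sum(t.data.size for t in self.trainable_parameters())

    def base_weight_hash(self) -> str:
        return self.base.weight_hash()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.base.save(directory)
        cfg = dict(self.lora_config.__dict__)
        cfg["target_projections"] = list(cfg["target_projections"])
        (directory / "lora_config.json").write_text(json.dumps(cfg, indent=2))
        arrays = {}
        for (layer, proj), (A, B) in self.factors.items():
            arrays[f"l{layer}.{proj}.A"] = A.data
            arrays[f"l{layer}.{proj}.B"] = B.data
        np.savez(directory / "lora_factors.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "AdaptedEncoder":
        directory = Path(directory)
        base = ReferenceEncoder.load(directory)
        cfg = json.loads((directory / "lora_config.json").read_text())
        cfg["target_projections"] = tuple(cfg["target_projections"])
        adapted = cls(base, LoRAConfig(**cfg))
        with np.load(directory / "lora_factors.npz") as data:
            for (layer, proj), (A, B) in adapted.factors.items():
                A.data = data[f"l{layer}.{proj}.A"]
                B.data = data[f"l{layer}.{proj}.B"]
        return adapted


def inject_lora(encoder: ReferenceEncoder, lora: LoRAConfig) -> AdaptedEncoder:
    """Attach zero-initialised LoRA adapters; adapted == base at init."""
    return AdaptedEncoder(encoder, lora)


def merge_lora(adapted: AdaptedEncoder) -> ReferenceEncoder:
    """Fold the learned low-rank updates into a plain encoder.

    For each adapted projection the merged weight is
    ``W' = W + (alpha/r)·AᵀBᵀ`` so the merged forward pass reproduces the
    adapted one without adapter machinery.
    """
    merged = ReferenceEncoder(adapted.base.config, adapted.base.vocab)
    merged.params = {k: Tensor(v.data.copy()) for k, v in adapted.base.params.items()}
    scale = adapted.lora_config.scale
    for (layer, proj), (A, B) in adapted.factors.items():
        key = f"l{layer}.{proj}.W"
        merged.params[key] = Tensor(merged.params[key].data + scale * (A.data.T @ B.data.T))
    return merged
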