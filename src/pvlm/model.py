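"""Dual-stream SMILES / property-vector transformer.

Two unimodal self-attention encoders (one per modality) feed a single fusion
encoder that performs cross-attention and is reused with either modality as
the query side.  Contrastive projection heads, a token-prediction head
(next-word prediction over the SMILES vocabulary), a scalar property head
(next-property prediction) and a binary matching head sit on top.

A molecule enters as a pair: the BPE-tokenized SMILES framed by [CLS_S]/[SEP],
and a property vector of P z-scored descriptors framed by a learned [CLS_P]
embedding, with masked properties replaced by a learned [UNK] vector.  Causal
attention turns either stream into an autoregressive generator conditioned on
the other.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, no_grad
from .properties import NormalizationStats, PropertyRegistry, PropertyVector
from .tokenizer import BpeVocab


@dataclass
class ModelConfig:
    hidden_dim: int = 64
    n_layers_unimodal: int = 2
    n_layers_fusion: int = 2
    n_heads: int = 4
    max_smiles_len: int = 100
    n_properties: int = 12
    vocab_size: int = 300
    contrastive_dim: int = 64
    dropout: float = 0.0
    norm_style: str = "pre"  # 'post' gives the classic BERT block ordering

    def __post_init__(self):
        if self.hidden_dim % self.n_heads != 0:
            raise ValueError("hidden_dim must be divisible by n_heads")
        for f in ("hidden_dim", "n_layers_unimodal", "n_layers_fusion", "n_heads",
                  "max_smiles_len", "n_properties", "vocab_size", "contrastive_dim"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    #: preset matching the full-scale configuration (BERT-base-like)
    @classmethod
    def base(cls, vocab_size: int = 300, n_properties: int = 53) -> "ModelConfig":
        return cls(hidden_dim=768, n_layers_unimodal=6, n_layers_fusion=6, n_heads=12,
                   n_properties=n_properties, vocab_size=vocab_size,
                   contrastive_dim=256, norm_style="post")


def pad_batch(sequences: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad token id lists; returns (B, L) ids and (B, L) validity mask."""
    L = max(len(s) for s in sequences)
    ids = np.full((len(sequences), L), pad_id, dtype=np.intp)
    valid = np.zeros((len(sequences), L), dtype=bool)
    for i, s in enumerate(sequences):
        ids[i, :len(s)] = s
        valid[i, :len(s)] = True
    return ids, valid


def batch_pvs(pvs: list[PropertyVector]) -> tuple[np.ndarray, np.ndarray]:
    values = np.stack([pv.values for pv in pvs])
    known = np.stack([pv.known for pv in pvs])
    return values, known


class DualStreamModel(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.hidden_dim

        # SMILES side
        self.token_emb = nn.Embedding(config.vocab_size, d, rng)
        self.smiles_pos_emb = nn.Embedding(config.max_smiles_len, d, rng)
        self.smiles_encoder = nn.Encoder(config.n_layers_unimodal, d, config.n_heads,
                                         rng, norm_style=config.norm_style)

        # PV side: one shared linear value encoding + per-property positional rows
        self.value_enc = nn.Linear(1, d, rng)
        self.pv_pos_emb = nn.Embedding(config.n_properties, d, rng)
        self.unk_emb = nn.Parameter(rng.normal(0, 0.02, size=d))
        self.cls_p_emb = nn.Parameter(rng.normal(0, 0.02, size=d))
        self.pv_encoder = nn.Encoder(config.n_layers_unimodal, d, config.n_heads,
                                     rng, norm_style=config.norm_style)

        # single fusion encoder, query/key-value roles alternate
        self.fusion_encoder = nn.FusionEncoder(config.n_layers_fusion, d, config.n_heads,
                                               rng, norm_style=config.norm_style)

        # heads
        self.proj_s = nn.Linear(d, config.contrastive_dim, rng)  # h_S
        self.proj_p = nn.Linear(d, config.contrastive_dim, rng)  # h_P
        self.nwp_head = nn.Linear(d, config.vocab_size, rng)
        self.npp_head = nn.Linear(d, 1, rng)
        self.spm_head = nn.Linear(2 * d, 2, rng)

        # learnable contrastive temperature (clamped during training)
        self.log_tau = nn.Parameter(np.array([np.log(0.07)]))

    # -- embedding ----------------------------------------------------------
    def embed_smiles(self, ids: np.ndarray) -> Tensor:
        B, L = ids.shape
        pos = np.arange(L)
        return self.token_emb(ids) + self.smiles_pos_emb(pos)

    def embed_property_vector(self, values: np.ndarray, known: np.ndarray) -> Tensor:
        """(B, P) values + known flags -> (B, P+1, D) with [CLS_P] at position 0.

        Property position i embeds as value_encoding(v_i) + pos_emb_i when
        known, or unk_vector + pos_emb_i when masked.  [CLS_P] is a bare
        learned embedding (no positional row), so jointly permuting the
        properties and the positional rows permutes positions 1..P only.
        """
        values = np.asarray(values, dtype=np.float64)
        known = np.asarray(known, dtype=bool)
        B, P = values.shape
        if P != self.config.n_properties:
            raise ValueError(f"expected {self.config.n_properties} properties, got {P}")
        if not np.all(np.isfinite(values[known])):
            raise ValueError("known property values must be finite")

        safe = np.where(known, values, 0.0)
        val_feats = self.value_enc(Tensor(safe.reshape(B, P, 1)))  # (B,P,D)
        known_f = Tensor(known[:, :, None].astype(np.float64))
        mixed = val_feats * known_f + self.unk_emb * (1.0 - known_f)
        seq = mixed + self.pv_pos_emb(np.arange(P))
        cls = (self.cls_p_emb * Tensor(np.ones((B, 1, 1))))  # broadcast to (B,1,D)
        return nn.concat([cls, seq], axis=1)

    # -- unimodal encoders --------------------------------------------------
    @staticmethod
    def _attn_mask(L: int, valid: np.ndarray | None, causal: bool) -> np.ndarray | None:
        mask = None
        if valid is not None:
            mask = nn.padding_mask(valid)
        if causal:
            cm = nn.causal_mask(L)[None, None]
            mask = cm if mask is None else mask + cm
        return mask

    def encode_smiles(self, ids: np.ndarray, valid: np.ndarray | None = None,
                      causal: bool = False) -> Tensor:
        if ids.shape[1] > self.config.max_smiles_len:
            raise ValueError("sequence longer than max_smiles_len")
        x = self.embed_smiles(ids)
        return self.smiles_encoder(x, mask=self._attn_mask(ids.shape[1], valid, causal))

    def encode_pv(self, values: np.ndarray, known: np.ndarray,
                  causal: bool = False) -> Tensor:
        x = self.embed_property_vector(values, known)
        return self.pv_encoder(x, mask=self._attn_mask(x.shape[1], None, causal))

    # -- fusion -------------------------------------------------------------
    def fuse(self, query_feats: Tensor, kv_feats: Tensor,
             query_valid: np.ndarray | None = None,
             kv_valid: np.ndarray | None = None,
             causal: bool = False) -> Tensor:
        """Fusion pass; the same weights serve either modality as the query.

        The causal mask applies to the query side's self-attention only:
        cross-attention sees the full key/value sequence, which is a fully
        known conditioning input.
        """
        self_mask = self._attn_mask(query_feats.shape[1], query_valid, causal)
        cross_mask = nn.padding_mask(kv_valid) if kv_valid is not None else None
        return self.fusion_encoder(query_feats, kv_feats,
                                   self_mask=self_mask, cross_mask=cross_mask)

    # -- projections --------------------------------------------------------
    def project_smiles_cls(self, feats: Tensor) -> Tensor:
        return nn.l2_normalize(self.proj_s(feats[:, 0]))

    def project_pv_cls(self, feats: Tensor) -> Tensor:
        return nn.l2_normalize(self.proj_p(feats[:, 0]))

    @property
    def tau(self) -> float:
        return float(np.exp(self.log_tau.data[0]))

    def clamp_tau(self, lo: float = 1e-3, hi: float = 0.5):
        self.log_tau.data = np.clip(self.log_tau.data, np.log(lo), np.log(hi))


def init_momentum_copy(model: DualStreamModel) -> DualStreamModel:
    """Exact teacher copy; its parameters never receive gradients (EMA only)."""
    teacher = DualStreamModel(model.config, seed=0)
    teacher.load_state_dict(model.state_dict())
    for p in teacher.parameters():
        p.requires_grad = False
    teacher.eval()
    return teacher


# ---------------------------------------------------------------------------
# checkpointing: weights (npz) + config/vocab/stats/registry (JSON) in one dir
# ---------------------------------------------------------------------------
@dataclass
class Checkpoint:
    model: DualStreamModel
    vocab: BpeVocab
    registry: PropertyRegistry
    stats: NormalizationStats

    def save(self, out_dir: str | Path):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.model.state_dict())
        (out / "config.json").write_text(json.dumps(asdict(self.model.config), indent=1))
        self.vocab.save(out / "vocab.json")
        (out / "registry.json").write_text(self.registry.to_json())
        (out / "stats.json").write_text(self.stats.to_json(self.registry.names))

    @classmethod
    def load(cls, in_dir: str | Path) -> "Checkpoint":
        p = Path(in_dir)
        config = ModelConfig(**json.loads((p / "config.json").read_text()))
        model = DualStreamModel(config, seed=0)
        with np.load(p / "weights.npz") as z:
            model.load_state_dict({k: z[k] for k in z.files})
        vocab = BpeVocab.load(p / "vocab.json")
        registry = PropertyRegistry.from_json((p / "registry.json").read_text())
        stats = NormalizationStats.from_json((p / "stats.json").read_text(), registry.names)
        if len(registry) != config.n_properties:
            raise ValueError("registry length does not match model configuration")
        if len(vocab) != config.vocab_size:
            raise ValueError("vocabulary size does not match model configuration")
        return cls(model=model, vocab=vocab, registry=registry, stats=stats)
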