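"""Bidirectional inference and evaluation.

* property vector -> SMILES: autoregressive token decoding (greedy, stochastic
  sampling, or beam search; beam width 2 by default) conditioned on the
  bidirectionally encoded PV through cross-attention;
* SMILES -> property vector: autoregressive scalar decoding conditioned on the
  bidirectionally encoded SMILES, reported on the raw (de-normalized) scale;
* generation metrics (validity / uniqueness / novelty), normalized RMSE of
  controlled properties, and cross-attention maps for inspection.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem

from . import nn
from .nn import Tensor, no_grad
from .model import Checkpoint
from .properties import (NormalizationStats, PropertyRegistry, PropertyVector,
                         denormalize, normalize, parse_smiles)
from .tokenizer import detokenize, tokenize

logger = logging.getLogger(__name__)


@dataclass
class GenerationConfig:
    mode: str = "beam"  # greedy | stochastic | beam
    beam_width: int = 2
    max_len: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("greedy", "stochastic", "beam"):
            raise ValueError(f"unknown decoding mode {self.mode!r}")
        if self.beam_width < 1:
            raise ValueError("beam width must be >= 1")


# ---------------------------------------------------------------------------
# generic decoders over a step function: prefix ids -> next-token log-probs
# ---------------------------------------------------------------------------
StepFn = Callable[[list[int]], np.ndarray]


def greedy_decode(step_fn: StepFn, bos_id: int, eos_id: int, max_len: int) -> list[int]:
    ids = [bos_id]
    while len(ids) < max_len:
        nxt = int(np.argmax(step_fn(ids)))
        ids.append(nxt)
        if nxt == eos_id:
            break
    return ids


def stochastic_decode(step_fn: StepFn, bos_id: int, eos_id: int, max_len: int,
                      rng: np.random.Generator) -> list[int]:
    ids = [bos_id]
    while len(ids) < max_len:
        logp = step_fn(ids)
        p = np.exp(logp - logp.max())
        p /= p.sum()
        nxt = int(rng.choice(len(p), p=p))
        ids.append(nxt)
        if nxt == eos_id:
            break
    return ids


def beam_decode(step_fn: StepFn, bos_id: int, eos_id: int, max_len: int,
                k: int) -> list[tuple[list[int], float]]:
    """Beam search by raw joint log-probability (no length normalization).

    Finished hypotheses (those that emitted the end token) are held aside and
    compared against live beams; returns the top-k (ids, logprob) pairs.
    Sequences hitting ``max_len`` without the end token are kept as-is.
    """
    live: list[tuple[float, list[int]]] = [(0.0, [bos_id])]
    done: list[tuple[float, list[int]]] = []
    while live:
        expansions: list[tuple[float, list[int]]] = []
        for score, ids in live:
            if len(ids) >= max_len:
                done.append((score, ids))
                continue
            logp = step_fn(ids)
            top = np.argsort(logp)[::-1][:k]
            for t in top:
                cand = (score + float(logp[t]), ids + [int(t)])
                if int(t) == eos_id:
                    done.append(cand)
                else:
                    expansions.append(cand)
        live = heapq.nlargest(k, expansions, key=lambda c: c[0])
        # stop when no live beam can beat the k-th best finished hypothesis
        if len(done) >= k:
            kth = heapq.nlargest(k, done, key=lambda c: c[0])[-1][0]
            if not live or max(c[0] for c in live) <= kth:
                break
    done.extend(live)
    best = heapq.nlargest(k, done, key=lambda c: c[0])
    return [(ids, score) for score, ids in best]


# ---------------------------------------------------------------------------
# PV -> SMILES
# ---------------------------------------------------------------------------
def _smiles_step_fn(ckpt: Checkpoint, kv_feats: Tensor) -> StepFn:
    model = ckpt.model

    def step(prefix: list[int]) -> np.ndarray:
        ids = np.asarray([prefix], dtype=np.intp)
        with no_grad():
            s_causal = model.encode_smiles(ids, causal=True)
            fused = model.fuse(s_causal, kv_feats, causal=True)
            logits = model.nwp_head(fused[:, -1]).data[0]
        logits = logits - logits.max()
        return logits - np.log(np.exp(logits).sum())

    return step


def generate_smiles(pv: PropertyVector, ckpt: Checkpoint,
                    config: GenerationConfig | None = None) -> list[str]:
    """Decode SMILES conditioned on a (possibly partially [UNK]) PV.

    Returns one string for greedy/stochastic mode, ``beam_width`` strings
    (best first) for beam mode.
    """
    config = config or GenerationConfig()
    if len(pv) != ckpt.model.config.n_properties:
        raise ValueError("property vector length does not match the checkpoint")
    vocab = ckpt.vocab
    with no_grad():
        kv = ckpt.model.encode_pv(pv.values[None, :], pv.known[None, :], causal=False)
    step = _smiles_step_fn(ckpt, kv)
    max_len = min(config.max_len, ckpt.model.config.max_smiles_len)
    if config.mode == "greedy":
        seqs = [greedy_decode(step, vocab.cls_id, vocab.sep_id, max_len)]
    elif config.mode == "stochastic":
        rng = np.random.default_rng(config.seed)
        seqs = [stochastic_decode(step, vocab.cls_id, vocab.sep_id, max_len, rng)]
    else:
        seqs = [ids for ids, _ in beam_decode(step, vocab.cls_id, vocab.sep_id,
                                              max_len, config.beam_width)]
    out = []
    for ids in seqs:
        if ids[-1] != vocab.sep_id:
            ids = ids + [vocab.sep_id]  # unterminated: close the frame, keep the text
        out.append(detokenize(ids, vocab))
    return out


# ---------------------------------------------------------------------------
# SMILES -> PV
# ---------------------------------------------------------------------------
def generate_pv(smiles: str, ckpt: Checkpoint) -> np.ndarray:
    """Predict all P properties autoregressively; returns raw-scale values.

    The first property is predicted from [CLS_P] alone; each later one from
    all previously predicted values, cross-attending to the bidirectionally
    encoded SMILES.  The SMILES encoding is computed once and reused across
    steps.
    """
    model = ckpt.model
    P = model.config.n_properties
    toks = tokenize(smiles, ckpt.vocab, max_len=model.config.max_smiles_len)
    ids = np.asarray([toks.ids], dtype=np.intp)
    with no_grad():
        s_feats = model.encode_smiles(ids, causal=False)
        pred = np.zeros(P)
        for i in range(P):
            values = np.zeros((1, P))
            known = np.zeros((1, P), dtype=bool)
            values[0, :i] = pred[:i]
            known[0, :i] = True
            p_causal = model.encode_pv(values, known, causal=True)
            fused = model.fuse(p_causal, s_feats, causal=True)
            pred[i] = float(model.npp_head(fused[:, i]).data[0, 0])
    return denormalize(pred, ckpt.stats)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------
@dataclass
class GenerationMetrics:
    validity: float
    uniqueness: float
    novelty: float
    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int


def generation_metrics(generated: Sequence[str],
                       pretraining_set: set[str]) -> GenerationMetrics:
    """validity = valid/generated; uniqueness = distinct-canonical/valid;
    novelty = unique-not-in-pretraining/unique.  ``pretraining_set`` must be
    pre-canonicalized."""
    if not generated:
        raise ValueError("no generated SMILES to score")
    canon = []
    for s in generated:
        mol = Chem.MolFromSmiles(s) if s else None
        if mol is not None:
            canon.append(Chem.MolToSmiles(mol))
    unique = set(canon)
    novel = unique - pretraining_set
    n_gen, n_val, n_uni, n_nov = len(generated), len(canon), len(unique), len(novel)
    return GenerationMetrics(
        validity=n_val / n_gen,
        uniqueness=n_uni / n_val if n_val else 0.0,
        novelty=n_nov / n_uni if n_uni else 0.0,
        n_generated=n_gen, n_valid=n_val, n_unique=n_uni, n_novel=n_nov)


def normalized_rmse(pv_input: PropertyVector, generated: Sequence[str],
                    stats: NormalizationStats, registry: PropertyRegistry) -> float:
    """Mean over controlled (non-[UNK]) properties of the RMSE between the
    z-scored target and the z-scored recomputed descriptor of each valid
    generated molecule."""
    controlled = np.nonzero(pv_input.known)[0]
    if len(controlled) == 0:
        raise ValueError("no controlled properties in the conditioning PV")
    rows = []
    for s in generated:
        try:
            rows.append(normalize(registry.compute(s), stats).values)
        except ValueError:
            logger.warning("normalized_rmse: skipping invalid SMILES %r", s)
    if not rows:
        raise ValueError("no valid generated molecules to score")
    got = np.stack(rows)  # (n_valid, P), normalized
    per_prop = []
    for j in controlled:
        resid = got[:, j] - pv_input.values[j]
        per_prop.append(float(np.sqrt(np.mean(resid ** 2))))
    return float(np.mean(per_prop))


# ---------------------------------------------------------------------------
# attention inspection
# ---------------------------------------------------------------------------
def attention_map(smiles: str, pv: PropertyVector, ckpt: Checkpoint) -> tuple[np.ndarray, list[str]]:
    """Head-averaged cross-attention of the last fusion layer, with property
    features as queries and SMILES token features as keys/values.

    Returns a (P, n_tokens) matrix (the [CLS_P] query row is dropped; rows
    sum to 1) and the SMILES token strings labelling the columns.
    """
    model = ckpt.model
    toks = tokenize(smiles, ckpt.vocab, max_len=model.config.max_smiles_len)
    ids = np.asarray([toks.ids], dtype=np.intp)
    with no_grad():
        s_feats = model.encode_smiles(ids, causal=False)
        p_feats = model.encode_pv(pv.values[None, :], pv.known[None, :], causal=False)
        model.fuse(p_feats, s_feats, causal=False)
    weights = model.fusion_encoder.last_cross_attention  # (1, H, P+1, T)
    mat = weights[0].mean(axis=0)[1:, :]  # drop the [CLS_P] query row
    return mat, toks.tokens


def write_attention_map(mat: np.ndarray, tokens: list[str],
                        property_names: Sequence[str], path: str | Path):
    lines = ["\t".join(["property"] + tokens)]
    for name, row in zip(property_names, mat):
        lines.append("\t".join([name] + [f"{v:.6g}" for v in row]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# condition files
# ---------------------------------------------------------------------------
def pv_from_conditions(conditions: dict[str, float | str],
                       registry: PropertyRegistry,
                       stats: NormalizationStats) -> PropertyVector:
    """Build a conditioning PV from {property name: raw value | "UNK"}."""
    unknown_names = set(conditions) - set(registry.names)
    if unknown_names:
        raise ValueError(f"conditions name unknown properties: {sorted(unknown_names)}")
    values = np.zeros(len(registry))
    known = np.zeros(len(registry), dtype=bool)
    for i, name in enumerate(registry.names):
        v = conditions.get(name, "UNK")
        if isinstance(v, str):
            if v.upper() != "UNK":
                raise ValueError(f"condition for {name!r} must be a number or 'UNK'")
            continue
        values[i] = (float(v) - stats.mean[i]) / stats.std[i]
        known[i] = True
    return PropertyVector(values=values, known=known)


def load_conditions(path: str | Path) -> dict[str, float | str]:
    return json.loads(Path(path).read_text())
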