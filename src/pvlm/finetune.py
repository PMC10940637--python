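"""Downstream adaptation of a pre-trained checkpoint.

* scalar regression / (multi-label) binary classification from the SMILES
  encoder's [CLS_S] feature through a one-hidden-layer MLP head;
* forward / retro reaction prediction as SMILES-to-SMILES sequence-to-sequence
  through the fusion encoder (source side encoded bidirectionally, target side
  decoded causally), with non-canonical SMILES augmentation;
* a scaffold splitter (Bemis-Murcko cores, greedy largest-first assignment)
  so benchmark-style splits need no external tooling.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from . import nn
from .nn import Tensor, no_grad
from .fixtures import ReactionPair
from .generate import GenerationConfig, beam_decode, _smiles_step_fn
from .model import Checkpoint, DualStreamModel, pad_batch
from .properties import parse_smiles
from .tokenizer import detokenize, tokenize

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# task specification and scaffold splitting
# ---------------------------------------------------------------------------
@dataclass
class TaskSpec:
    kind: Literal["regression", "classification", "seq2seq"]
    label_columns: tuple[str, ...] = ()
    split: dict[str, str] = field(default_factory=dict)  # smiles -> train|valid|test

    def molecules(self, part: str) -> list[str]:
        return [s for s, p in self.split.items() if p == part]


def bemis_murcko_scaffold(smiles: str) -> str:
    """Canonical Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    mol = parse_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def scaffold_split(molecules: Sequence[str],
                   fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0) -> dict[str, str]:
    """Assign molecules to train/valid/test keeping each scaffold in one split.

    Scaffold groups are filled greedily largest-first into train, then valid,
    then test; molecules without a ring scaffold form singleton groups.  The
    seed shuffles equal-size group order (deterministically).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[str]] = {}
    singletons = 0
    for smi in molecules:
        key = bemis_murcko_scaffold(smi)
        if key == "":
            key = f"__acyclic_{singletons}"  # own singleton group
            singletons += 1
        groups.setdefault(key, []).append(smi)
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: shuffled order breaks ties

    n = len(molecules)
    n_train, n_valid = fractions[0] * n, fractions[1] * n
    split: dict[str, str] = {}
    filled_train = filled_valid = 0
    for k in keys:
        members = groups[k]
        if filled_train + len(members) <= n_train or filled_train < n_train:
            part, bump = "train", True
        elif filled_valid + len(members) <= n_valid or filled_valid < n_valid:
            part, bump = "valid", False
        else:
            part, bump = "test", False
        if part == "train":
            filled_train += len(members)
        elif part == "valid":
            filled_valid += len(members)
        for m in members:
            split[m] = part
    return split


# ---------------------------------------------------------------------------
# scalar prediction head
# ---------------------------------------------------------------------------
class ScalarHead(nn.Module):
    """One-hidden-layer MLP on the [CLS_S] feature."""

    def __init__(self, dim: int, out_dim: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.fc1 = nn.Linear(dim, dim, rng)
        self.fc2 = nn.Linear(dim, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def _encode_cls(model: DualStreamModel, smiles_list: Sequence[str], vocab,
                grad: bool = False) -> Tensor:
    seqs = [tokenize(s, vocab, max_len=model.config.max_smiles_len).ids
            for s in smiles_list]
    ids, valid = pad_batch(seqs, vocab.pad_id)
    if grad:
        return model.encode_smiles(ids, valid, causal=False)[:, 0]
    with no_grad():
        return model.encode_smiles(ids, valid, causal=False)[:, 0]


def predict_scalar(smiles: str | Sequence[str], ckpt: Checkpoint, head: ScalarHead,
                   kind: str = "regression") -> np.ndarray:
    """Regression value(s) or class probabilities from the [CLS_S] feature."""
    single = isinstance(smiles, str)
    batch = [smiles] if single else list(smiles)
    cls = _encode_cls(ckpt.model, batch, ckpt.vocab)
    with no_grad():
        out = head(cls)
        if kind == "classification":
            out = nn.softmax(out, axis=-1)
    res = out.data
    return res[0] if single else res


@dataclass
class FinetuneReport:
    best_epoch: int
    valid_losses: list[float]
    test_metric: float
    metric_name: str

    def to_json(self) -> str:
        return json.dumps({"best_epoch": self.best_epoch,
                           "valid_losses": self.valid_losses,
                           self.metric_name: self.test_metric}, indent=1)


def finetune_supervised(table, ckpt: Checkpoint, task: TaskSpec,
                        epochs: int = 10, lr: float = 1e-4, batch_size: int = 16,
                        seed: int = 0) -> tuple[ScalarHead, FinetuneReport]:
    """Fine-tune encoder + head; keep the weights with the lowest validation
    loss; report test RMSE (regression) or AUROC (classification).

    ``table`` is a DataFrame with a 'smiles' column and the task's label
    column(s); ``task.split`` assigns each molecule to a partition.
    """
    rng = np.random.default_rng(seed)
    model, vocab = ckpt.model, ckpt.vocab
    labels = {r["smiles"]: np.atleast_1d(np.asarray(
        [r[c] for c in task.label_columns], dtype=np.float64))
        for _, r in table.iterrows()}

    parts = {p: [s for s in table["smiles"] if task.split.get(s) == p]
             for p in ("train", "valid", "test")}
    for p, mols in parts.items():
        if not mols:
            raise ValueError(f"empty {p} split")

    out_dim = len(task.label_columns) if task.kind == "regression" else 2
    head = ScalarHead(model.config.hidden_dim, out_dim, seed=seed)
    params = model.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=lr, weight_decay=0.02)

    def batch_loss(mols: list[str], grad: bool) -> Tensor:
        cls = _encode_cls(model, mols, vocab, grad=grad)
        out = head(cls)
        y = np.stack([labels[s] for s in mols])
        if task.kind == "regression":
            diff = out - Tensor(y)
            return (diff * diff).mean()
        probs = nn.softmax(out, axis=-1)
        onehot = np.zeros((len(mols), 2))
        onehot[np.arange(len(mols)), y[:, 0].astype(int)] = 1.0
        return -(Tensor(onehot) * (probs + 1e-12).log()).sum(axis=-1).mean()

    best_state, best_head, best_loss, best_epoch = None, None, np.inf, -1
    valid_losses = []
    train_mols = parts["train"]
    for epoch in range(epochs):
        order = rng.permutation(len(train_mols))
        for lo in range(0, len(order), batch_size):
            batch = [train_mols[i] for i in order[lo:lo + batch_size]]
            loss = batch_loss(batch, grad=True)
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, 5.0)
            opt.step()
        with no_grad():
            v = float(batch_loss(parts["valid"], grad=False).data)
        valid_losses.append(v)
        if v < best_loss:
            best_loss, best_epoch = v, epoch
            best_state = model.state_dict()
            best_head = head.state_dict()

    model.load_state_dict(best_state)
    head.load_state_dict(best_head)

    test_mols = parts["test"]
    with no_grad():
        cls = _encode_cls(model, test_mols, vocab)
        out = head(cls)
        y = np.stack([labels[s] for s in test_mols])
        if task.kind == "regression":
            metric = float(np.sqrt(np.mean((out.data - y) ** 2)))
            name = "rmse"
        else:
            probs = nn.softmax(out, axis=-1).data[:, 1]
            from sklearn.metrics import roc_auc_score  # scoring only
            metric = float(roc_auc_score(y[:, 0].astype(int), probs))
            name = "auroc"
    return head, FinetuneReport(best_epoch=best_epoch, valid_losses=valid_losses,
                                test_metric=metric, metric_name=name)


# ---------------------------------------------------------------------------
# SMILES augmentation
# ---------------------------------------------------------------------------
def augment_smiles(smiles: str, p: float, rng: np.random.Generator) -> str:
    """With probability ``p``, rewrite each fragment with a random atom order
    (a non-canonical SMILES of the same molecule); otherwise return unchanged."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if rng.random() >= p:
        parse_smiles(smiles)  # still validate
        return smiles
    frags = smiles.split(".")
    out = []
    for frag in frags:
        mol = parse_smiles(frag)
        perm = list(rng.permutation(mol.GetNumAtoms()))
        mol = Chem.RenumberAtoms(mol, [int(i) for i in perm])
        out.append(Chem.MolToSmiles(mol, canonical=False))
    return ".".join(out)


# ---------------------------------------------------------------------------
# reaction sequence-to-sequence
# ---------------------------------------------------------------------------
def _seq2seq_nwp_loss(model: DualStreamModel, vocab, sources: list[str],
                      targets: list[str]) -> Tensor:
    src_ids, src_valid = pad_batch(
        [tokenize(s, vocab, max_len=model.config.max_smiles_len).ids for s in sources],
        vocab.pad_id)
    tgt_ids, tgt_valid = pad_batch(
        [tokenize(t, vocab, max_len=model.config.max_smiles_len).ids for t in targets],
        vocab.pad_id)
    src_feats = model.encode_smiles(src_ids, src_valid, causal=False)
    tgt_causal = model.encode_smiles(tgt_ids, tgt_valid, causal=True)
    fused = model.fuse(tgt_causal, src_feats, query_valid=tgt_valid,
                       kv_valid=src_valid, causal=True)
    logits = model.nwp_head(fused)
    B, L, V = logits.shape
    shift_ids = np.zeros_like(tgt_ids)
    shift_ids[:, :-1] = tgt_ids[:, 1:]
    shift_valid = np.zeros_like(tgt_valid)
    shift_valid[:, :-1] = tgt_valid[:, 1:]
    probs = nn.softmax(logits, axis=-1)
    onehot = np.zeros((B, L, V))
    b, l = np.nonzero(shift_valid)
    onehot[b, l, shift_ids[b, l]] = 1.0
    per_pos = -(Tensor(onehot) * (probs + 1e-12).log()).sum(axis=-1)
    return per_pos.sum(axis=-1).mean()


def reaction_seq2seq(pairs: Sequence[ReactionPair], direction: str, ckpt: Checkpoint,
                     epochs: int = 30, lr: float = 1e-4, batch_size: int = 8,
                     augment_p: float = 0.5, seed: int = 0) -> list[float]:
    """Fine-tune the checkpoint for forward (reactants -> product) or retro
    (product -> reactants) prediction; returns the per-epoch mean loss."""
    if direction not in ("forward", "retro"):
        raise ValueError("direction must be 'forward' or 'retro'")
    rng = np.random.default_rng(seed)
    model, vocab = ckpt.model, ckpt.vocab
    data = []
    for pr in pairs:
        src, tgt = ((pr.reactants, pr.product) if direction == "forward"
                    else (pr.product, pr.reactants))
        try:
            tokenize(src, vocab, max_len=model.config.max_smiles_len)
            tokenize(tgt, vocab, max_len=model.config.max_smiles_len)
        except ValueError as e:
            logger.warning("skipping reaction pair (%s)", e)
            continue
        data.append((src, tgt))
    if not data:
        raise ValueError("no usable reaction pairs")

    opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=0.02)
    epoch_losses = []
    for _ in range(epochs):
        order = rng.permutation(len(data))
        losses = []
        for lo in range(0, len(order), batch_size):
            batch = [data[i] for i in order[lo:lo + batch_size]]
            srcs, tgts = [], []
            for s, t in batch:
                try:
                    srcs.append(augment_smiles(s, augment_p, rng))
                    tgts.append(augment_smiles(t, augment_p, rng))
                except ValueError:
                    srcs.append(s)
                    tgts.append(t)
            loss = _seq2seq_nwp_loss(model, vocab, srcs, tgts)
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(model.parameters(), 5.0)
            opt.step()
            losses.append(float(loss.data))
        epoch_losses.append(float(np.mean(losses)))
    return epoch_losses


def predict_reaction(source: str, ckpt: Checkpoint,
                     config: GenerationConfig | None = None) -> list[str]:
    """Decode target SMILES candidates for a reaction source, best first."""
    config = config or GenerationConfig(mode="beam", beam_width=2)
    model, vocab = ckpt.model, ckpt.vocab
    toks = tokenize(source, vocab, max_len=model.config.max_smiles_len)
    ids = np.asarray([toks.ids], dtype=np.intp)
    with no_grad():
        src_feats = model.encode_smiles(ids, causal=False)
    step = _smiles_step_fn(ckpt, src_feats)
    max_len = min(config.max_len, model.config.max_smiles_len)
    seqs = beam_decode(step, vocab.cls_id, vocab.sep_id, max_len,
                       max(config.beam_width, 1))
    out = []
    for s, _ in seqs:
        if s[-1] != vocab.sep_id:
            s = s + [vocab.sep_id]
        out.append(detokenize(s, vocab))
    return out


def top_k_accuracy(pairs: Sequence[ReactionPair], direction: str, ckpt: Checkpoint,
                   k: int, config: GenerationConfig | None = None) -> float:
    """Fraction of pairs whose true target (canonical form) appears among the
    k best decoded candidates."""
    config = config or GenerationConfig(mode="beam", beam_width=k)
    config.beam_width = max(config.beam_width, k)
    hits = 0
    for pr in pairs:
        src, tgt = ((pr.reactants, pr.product) if direction == "forward"
                    else (pr.product, pr.reactants))
        target_canon = _canonical_multi(tgt)
        cands = predict_reaction(src, ckpt, config)[:k]
        if any(_try_canonical(c) == target_canon for c in cands):
            hits += 1
    return hits / len(pairs)


def _canonical_multi(smiles: str) -> str:
    return ".".join(sorted(Chem.MolToSmiles(parse_smiles(f))
                           for f in smiles.split(".")))


def _try_canonical(smiles: str) -> str | None:
    try:
        return _canonical_multi(smiles)
    except ValueError:
        return None
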