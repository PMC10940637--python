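"""Pre-training: contrastive alignment, next-word prediction (NWP),
next-property prediction (NPP) and SMILES-PV matching (SPM).

Per batch the model runs two passes of each unimodal encoder — bidirectional
(contrastive / matching features) and causal (autoregressive objectives) —
plus fusion passes, all sharing weights.  A momentum teacher (EMA of the
student) supplies soft pseudo-labels mixed into the contrastive and NWP
targets with weight alpha, and feeds two fixed-capacity FIFO feature queues
that enlarge the contrastive candidate sets beyond the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor, no_grad
from .model import Checkpoint, DualStreamModel, ModelConfig, batch_pvs, init_momentum_copy, pad_batch
from .properties import (NormalizationStats, PropertyRegistry, PropertyVector,
                         apply_unk_mask, fit_normalization, normalize)
from .tokenizer import BpeVocab, tokenize, train_bpe

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature queue
# ---------------------------------------------------------------------------
class FeatureQueue:
    """Fixed-capacity FIFO of projected [CLS] features (one per modality)."""

    def __init__(self, capacity: int, dim: int):
        if capacity < 0:
            raise ValueError("capacity must be nonnegative")
        self.capacity = capacity
        self.dim = dim
        self._buf = np.zeros((0, dim))

    def __len__(self) -> int:
        return len(self._buf)

    @property
    def features(self) -> np.ndarray:
        return self._buf

    def enqueue(self, feats: np.ndarray):
        feats = np.atleast_2d(np.asarray(feats, dtype=np.float64))
        self._buf = np.concatenate([self._buf, feats], axis=0)
        if len(self._buf) > self.capacity:
            self._buf = self._buf[len(self._buf) - self.capacity:]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------
@dataclass
class LossBundle:
    contrastive: Tensor
    nwp: Tensor
    npp: Tensor
    spm: Tensor

    @property
    def total(self) -> Tensor:
        # unit-weight sum of the four objectives
        return self.contrastive + self.nwp + self.npp + self.spm

    def to_floats(self) -> dict[str, float]:
        return {"contrastive": self.contrastive.item(), "nwp": self.nwp.item(),
                "npp": self.npp.item(), "spm": self.spm.item(),
                "total": self.total.item()}


def similarity(s_proj: Tensor | np.ndarray, p_proj: Tensor | np.ndarray) -> np.ndarray:
    """Pairwise dot products of already-L2-normalized projections."""
    s = s_proj.data if isinstance(s_proj, Tensor) else np.asarray(s_proj)
    p = p_proj.data if isinstance(p_proj, Tensor) else np.asarray(p_proj)
    return s @ p.T


def _softmax_rows(logits: Tensor) -> Tensor:
    return nn.softmax(logits, axis=-1)


def intermodal_similarities(anchor_proj: Tensor, candidate_feats: np.ndarray,
                            tau: Tensor | float):
    """Temperature-scaled softmax of anchor-vs-candidate similarities.

    ``candidate_feats`` rows are (teacher-projected) candidates: the in-batch
    other-side features first, then queue contents.  Returns a (B, N)
    distribution whose rows sum to 1.
    """
    tau_t = tau if isinstance(tau, Tensor) else Tensor(np.array([float(tau)]))
    if np.any(tau_t.data <= 0):
        raise ValueError("temperature must be positive")
    logits = (anchor_proj @ Tensor(candidate_feats.T)) / tau_t
    return _softmax_rows(logits)


def soft_cross_entropy(target: Tensor | np.ndarray, dist: Tensor,
                       eps: float = 1e-12) -> Tensor:
    """H(target, dist) per row, averaged over rows."""
    t = target if isinstance(target, Tensor) else Tensor(target)
    if t.shape != dist.shape:
        raise ValueError(f"target/distribution shape mismatch {t.shape} vs {dist.shape}")
    return -(t * (dist + eps).log()).sum(axis=-1).mean()


def contrastive_loss(dists: dict[str, Tensor], targets: dict[str, np.ndarray],
                     momentum_dists: dict[str, np.ndarray] | None,
                     alpha: float) -> Tensor:
    """Half the sum over the four directions (s2p, p2s, s2s, p2p) of the
    cross-entropy against targets optionally softened by the teacher."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    terms = []
    for key in ("s2p", "p2s", "s2s", "p2p"):
        y = targets[key].astype(np.float64)
        if momentum_dists is not None and alpha > 0:
            y = (1.0 - alpha) * y + alpha * momentum_dists[key]
        terms.append(soft_cross_entropy(y, dists[key]))
    return 0.5 * (terms[0] + terms[1] + terms[2] + terms[3])


def nwp_loss(logits: Tensor, target_ids: np.ndarray, target_valid: np.ndarray,
             momentum_probs: np.ndarray | None = None, alpha: float = 0.0) -> Tensor:
    """Next-token cross-entropy, optionally soft-labeled by the teacher.

    ``logits``: (B, L, V) scores where position i predicts token i+1 of the
    framed sequence; ``target_ids``/``target_valid``: (B, L) shifted targets
    with padding (and positions past [SEP]) marked invalid.  Per-sequence sum
    over valid positions, averaged over the batch.
    """
    B, L, V = logits.shape
    if target_ids.max(initial=0) >= V:
        raise ValueError("target id out of vocabulary")
    probs = _softmax_rows(logits)
    onehot = np.zeros((B, L, V))
    b_idx, l_idx = np.nonzero(target_valid)
    onehot[b_idx, l_idx, target_ids[b_idx, l_idx]] = 1.0
    y = onehot
    if momentum_probs is not None and alpha > 0:
        y = (1.0 - alpha) * onehot + alpha * momentum_probs
    y = y * target_valid[:, :, None]  # exclude pad positions entirely
    per_pos = -(Tensor(y) * (probs + 1e-12).log()).sum(axis=-1)
    return per_pos.sum(axis=-1).mean()


def npp_loss(pred: Tensor, target_values: np.ndarray, target_known: np.ndarray) -> Tensor:
    """Squared-error next-property loss; [UNK] target positions contribute 0.

    ``pred``: (B, P) predictions where column i predicts property i (the
    first from [CLS_P] alone).  Per-molecule sum over known positions,
    averaged over the batch.
    """
    if pred.shape != target_values.shape:
        raise ValueError("prediction/target shape mismatch")
    w = target_known.astype(np.float64)
    diff = (pred - Tensor(target_values)) * Tensor(w)
    return (diff * diff).sum(axis=-1).mean()


def select_hard_negatives(sim_probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """For each anchor row, sample one non-matching column index with
    probability proportional to its similarity weight (diagonal excluded)."""
    sim_probs = np.asarray(sim_probs, dtype=np.float64)
    B = sim_probs.shape[0]
    if B < 2:
        raise ValueError("hard-negative mining needs a batch of at least 2")
    picks = np.empty(B, dtype=np.intp)
    for i in range(B):
        w = sim_probs[i, :B].copy()
        w[i] = 0.0
        total = w.sum()
        if total <= 0:
            w = np.ones(B)
            w[i] = 0.0
            total = w.sum()
        picks[i] = rng.choice(B, p=w / total)
    return picks


def spm_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean 2-way cross-entropy of the matching head (label 1 = true pair)."""
    probs = _softmax_rows(logits)
    n = logits.shape[0]
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), labels.astype(int)] = 1.0
    return soft_cross_entropy(onehot, probs)


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------
@dataclass
class PretrainSchedule:
    total_steps: int = 500
    batch_size: int = 96
    warmup_steps: int = 50
    peak_lr: float = 1e-4
    final_lr: float = 1e-5
    weight_decay: float = 0.02
    alpha_max: float = 0.4
    ema_lambda: float = 0.995
    mask_rate: float = 0.5
    queue_capacity: int = 24576
    grad_clip: float = 5.0

    def lr(self, step: int) -> float:
        return nn.warmup_cosine_lr(step, self.total_steps, self.warmup_steps,
                                   self.peak_lr, self.final_lr)

    def alpha(self, step: int, steps_per_epoch: int) -> float:
        return nn.alpha_ramp(step, steps_per_epoch, self.alpha_max)


# ---------------------------------------------------------------------------
# single pre-training step (exposed for testing against straight-line oracles)
# ---------------------------------------------------------------------------
def pretrain_step_losses(model: DualStreamModel, teacher: DualStreamModel | None,
                         token_batch: list[list[int]], pvs: list[PropertyVector],
                         queues: tuple[FeatureQueue, FeatureQueue] | None,
                         alpha: float, rng: np.random.Generator,
                         pad_id: int, return_intermediates: bool = False):
    """Compute the four losses on one batch.

    Returns a LossBundle plus (optionally) the raw distributions/targets so
    an external reference implementation can recompute every term.
    """
    ids, valid = pad_batch(token_batch, pad_id)
    values, known = batch_pvs(pvs)
    B, L = ids.shape
    tau = self_tau = model.log_tau.exp()

    # ---- bidirectional unimodal passes + projections ----
    s_feats = model.encode_smiles(ids, valid, causal=False)
    p_feats = model.encode_pv(values, known, causal=False)
    s_proj = model.project_smiles_cls(s_feats)
    p_proj = model.project_pv_cls(p_feats)

    # ---- teacher features / distributions ----
    if teacher is not None:
        with no_grad():
            ts_feats = teacher.encode_smiles(ids, valid, causal=False)
            tp_feats = teacher.encode_pv(values, known, causal=False)
            ts_proj = teacher.project_smiles_cls(ts_feats).data
            tp_proj = teacher.project_pv_cls(tp_feats).data
    else:
        ts_proj, tp_proj = s_proj.data.copy(), p_proj.data.copy()

    sq = queues[0].features if queues else np.zeros((0, ts_proj.shape[1]))
    pq = queues[1].features if queues else np.zeros((0, tp_proj.shape[1]))
    s_cands = np.concatenate([ts_proj, sq], axis=0)  # SMILES-side candidates
    p_cands = np.concatenate([tp_proj, pq], axis=0)  # PV-side candidates

    dists = {
        "s2p": intermodal_similarities(s_proj, p_cands, tau),
        "p2s": intermodal_similarities(p_proj, s_cands, tau),
        "s2s": intermodal_similarities(s_proj, s_cands, tau),
        "p2p": intermodal_similarities(p_proj, p_cands, tau),
    }
    eye_p = np.zeros((B, p_cands.shape[0]))
    eye_p[np.arange(B), np.arange(B)] = 1.0  # queue entries are negatives
    eye_s = np.zeros((B, s_cands.shape[0]))
    eye_s[np.arange(B), np.arange(B)] = 1.0
    targets = {"s2p": eye_p, "p2s": eye_s, "s2s": eye_s, "p2p": eye_p}

    momentum_dists = None
    if teacher is not None and alpha > 0:
        tau_v = float(tau.data[0])
        with no_grad():
            momentum_dists = {
                "s2p": intermodal_similarities(Tensor(ts_proj), p_cands, tau_v).data,
                "p2s": intermodal_similarities(Tensor(tp_proj), s_cands, tau_v).data,
                "s2s": intermodal_similarities(Tensor(ts_proj), s_cands, tau_v).data,
                "p2p": intermodal_similarities(Tensor(tp_proj), p_cands, tau_v).data,
            }
    l_contrastive = contrastive_loss(dists, targets, momentum_dists, alpha)

    # ---- NWP: causal SMILES stream fused with bidirectional PV features ----
    s_causal = model.encode_smiles(ids, valid, causal=True)
    s_fused = model.fuse(s_causal, p_feats, query_valid=valid, causal=True)
    nwp_logits = model.nwp_head(s_fused)  # (B, L, V): position i predicts token i+1
    tgt_ids = np.zeros_like(ids)
    tgt_ids[:, :-1] = ids[:, 1:]
    tgt_valid = np.zeros_like(valid)
    tgt_valid[:, :-1] = valid[:, 1:]

    momentum_nwp = None
    if teacher is not None and alpha > 0:
        with no_grad():
            t_s_causal = teacher.encode_smiles(ids, valid, causal=True)
            t_s_fused = teacher.fuse(t_s_causal, tp_feats, query_valid=valid, causal=True)
            momentum_nwp = nn.softmax(teacher.nwp_head(t_s_fused), axis=-1).data
    l_nwp = nwp_loss(nwp_logits, tgt_ids, tgt_valid, momentum_nwp, alpha)

    # ---- NPP: causal PV stream fused with bidirectional SMILES features ----
    p_causal = model.encode_pv(values, known, causal=True)
    p_fused = model.fuse(p_causal, s_feats, kv_valid=valid, causal=True)
    npp_pred = model.npp_head(p_fused[:, :-1]).reshape(B, -1)  # position i -> property i
    l_npp = npp_loss(npp_pred, values, known)

    # ---- SPM: fused [CLS] pairs, positives + hard-mined negatives ----
    with no_grad():
        sim_s2p = nn.softmax(Tensor(similarity(s_proj, p_proj) / float(tau.data[0])),
                             axis=-1).data
        sim_p2s = nn.softmax(Tensor(similarity(p_proj, s_proj) / float(tau.data[0])),
                             axis=-1).data
    neg_p_for_s = select_hard_negatives(sim_s2p, rng)  # PV index per SMILES anchor
    neg_s_for_p = select_hard_negatives(sim_p2s, rng)  # SMILES index per PV anchor

    order_s = np.concatenate([np.arange(B), np.arange(B), neg_s_for_p])
    order_p = np.concatenate([np.arange(B), neg_p_for_s, np.arange(B)])
    spm_labels = np.concatenate([np.ones(B), np.zeros(2 * B)])

    sf = s_feats[order_s]
    pf = p_feats[order_p]
    sv = valid[order_s]
    fused_s = model.fuse(sf, pf, query_valid=sv, causal=False)
    fused_p = model.fuse(pf, sf, kv_valid=sv, causal=False)
    pair_feat = nn.concat([fused_s[:, 0], fused_p[:, 0]], axis=-1)
    spm_logits = model.spm_head(pair_feat)
    l_spm = spm_loss(spm_logits, spm_labels)

    bundle = LossBundle(contrastive=l_contrastive, nwp=l_nwp, npp=l_npp, spm=l_spm)
    if not return_intermediates:
        return bundle
    inter = {
        "dists": {k: v.data for k, v in dists.items()},
        "targets": targets, "momentum_dists": momentum_dists, "alpha": alpha,
        "nwp_logits": nwp_logits.data, "nwp_target_ids": tgt_ids,
        "nwp_target_valid": tgt_valid, "momentum_nwp": momentum_nwp,
        "npp_pred": npp_pred.data, "pv_values": values, "pv_known": known,
        "spm_logits": spm_logits.data, "spm_labels": spm_labels,
        "teacher_proj": (ts_proj, tp_proj),
    }
    return bundle, inter


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------
@dataclass
class PretrainResult:
    checkpoint: Checkpoint
    loss_log: list[dict[str, float]] = field(default_factory=list)

    def write_log(self, path: str | Path):
        cols = ["step", "lr", "alpha", "contrastive", "nwp", "npp", "spm", "total"]
        lines = ["\t".join(cols)]
        for row in self.loss_log:
            lines.append("\t".join(f"{row[c]:.6g}" for c in cols))
        Path(path).write_text("\n".join(lines) + "\n")


def pretrain(corpus: list[str], config: ModelConfig, schedule: PretrainSchedule,
             seed: int = 0, registry: PropertyRegistry | None = None,
             vocab: BpeVocab | None = None,
             stats: NormalizationStats | None = None,
             log_every: int = 1) -> PretrainResult:
    """Full pre-training on a SMILES corpus.

    Fits the tokenizer and normalization statistics on the corpus when they
    are not supplied, then optimizes the summed objective with AdamW under
    the warmup-cosine learning-rate and linear-alpha schedules, updating the
    momentum teacher by EMA and the feature queues after every step.
    """
    rng = np.random.default_rng(seed)
    registry = registry or PropertyRegistry.toy()
    if vocab is None:
        vocab = train_bpe(corpus, config.vocab_size)
    if len(vocab) != config.vocab_size:
        raise ValueError(f"vocabulary has {len(vocab)} tokens but the model "
                         f"expects {config.vocab_size}")
    if stats is None:
        stats = fit_normalization(corpus, registry)

    # pre-tokenize and pre-compute normalized descriptor vectors once
    examples = []
    for smi in corpus:
        try:
            toks = tokenize(smi, vocab, max_len=config.max_smiles_len)
            pv = normalize(registry.compute(smi), stats)
        except ValueError:
            logger.warning("skipping molecule %r", smi)
            continue
        examples.append((toks.ids, pv))
    if not examples:
        raise ValueError("no usable molecules in corpus")

    model = DualStreamModel(config, seed=int(rng.integers(2 ** 31)))
    teacher = init_momentum_copy(model)
    opt = nn.AdamW(model.parameters(), lr=schedule.peak_lr,
                   weight_decay=schedule.weight_decay)
    queues = (FeatureQueue(schedule.queue_capacity, config.contrastive_dim),
              FeatureQueue(schedule.queue_capacity, config.contrastive_dim))
    steps_per_epoch = max(len(examples) // schedule.batch_size, 1)

    loss_log: list[dict[str, float]] = []
    order = rng.permutation(len(examples))
    cursor = 0
    for step in range(schedule.total_steps):
        if cursor + schedule.batch_size > len(order):
            order = rng.permutation(len(examples))
            cursor = 0
        batch_idx = order[cursor:cursor + schedule.batch_size]
        cursor += schedule.batch_size

        token_batch = [examples[i][0] for i in batch_idx]
        pv_batch = [apply_unk_mask(examples[i][1], schedule.mask_rate, rng)
                    for i in batch_idx]

        alpha = schedule.alpha(step, steps_per_epoch)
        bundle = pretrain_step_losses(model, teacher, token_batch, pv_batch,
                                      queues, alpha, rng, vocab.pad_id)
        total = bundle.total
        if not np.isfinite(total.data):
            parts = bundle.to_floats()
            bad = [k for k, v in parts.items() if not np.isfinite(v)]
            raise FloatingPointError(f"non-finite pre-training loss in {bad}: {parts}")

        opt.zero_grad()
        total.backward()
        nn.clip_grad_norm(model.parameters(), schedule.grad_clip)
        opt.lr = schedule.lr(step)
        opt.step()
        model.clamp_tau()
        nn.ema_update(model.parameters(), teacher.parameters(), schedule.ema_lambda)

        # enqueue the teacher's projected [CLS] features for future negatives
        with no_grad():
            ids, valid = pad_batch(token_batch, vocab.pad_id)
            values, known = batch_pvs(pv_batch)
            ts = teacher.project_smiles_cls(teacher.encode_smiles(ids, valid)).data
            tp = teacher.project_pv_cls(teacher.encode_pv(values, known)).data
        queues[0].enqueue(ts)
        queues[1].enqueue(tp)

        if step % log_every == 0 or step == schedule.total_steps - 1:
            row = {"step": step, "lr": opt.lr, "alpha": alpha, **bundle.to_floats()}
            loss_log.append(row)

    ckpt = Checkpoint(model=model, vocab=vocab, registry=registry, stats=stats)
    return PretrainResult(checkpoint=ckpt, loss_log=loss_log)
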