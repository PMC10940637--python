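# Methods

## Model

Two modalities describe one molecule.  The SMILES stream is tokenized with a
byte-pair-encoding vocabulary (default 300 subwords) trained on the corpus,
framed as `[CLS_S] … [SEP]`, and embedded as token + learned positional
embeddings.  The property stream is an ordered vector of P scalar
descriptors computed from the SMILES with RDKit and z-scored per property
with corpus mean/std (population convention, σ floored at 1e-8).  Each value
passes through one shared linear *value encoding* (1 → d); a per-property
learned positional row gives the slot its identity; masked slots use a
learned `[UNK]` vector instead of the value encoding; a learned `[CLS_P]`
embedding (no positional row) heads the sequence.

Both streams run through their own stack of transformer encoder layers
(default 6 at full scale, 2 in the toy preset), then a single fusion stack
of [self-attention → cross-attention → feed-forward] layers whose weights
are shared between the two query/key-value role assignments.  Attention is
the standard scaled-dot form, Softmax(QKᵀ/√d_k)V, with additive masks.  The
causal mask applies to the query side's self-attention only; cross-attention
always sees the full conditioning sequence, which is fully known at decode
time.  Blocks are pre-norm by default (`norm_style="post"` switches to the
classic BERT ordering; pre-norm is markedly more stable for the small,
short-schedule models this codebase targets).

Heads: linear projections h_S, h_P to a contrastive space with L2
normalization; a vocabulary-sized next-token head on fused SMILES features;
a scalar-per-position next-property head on fused PV features; and a 2-way
matching head on the concatenated fused `[CLS]` pair.

## Pre-training objectives

Per batch the unimodal encoders run twice with shared weights — once
bidirectional (contrastive/matching features) and once causal
(autoregressive objectives).

* **Contrastive.**  sim(S,P) is the dot product of the normalized
  projections.  Four softmax distributions (s2p, p2s, s2s, p2p) at learnable
  temperature τ (init 0.07, clamped to [1e-3, 0.5]) are formed over
  candidates = momentum-projected in-batch features of the relevant modality
  plus a FIFO feature queue per modality.  Loss: ½ Σ over the four
  directions of the cross-entropy against targets ỹ = (1−α)·one-hot +
  α·(teacher distribution).  Queue entries are labeled negative.
* **NWP.**  Causal SMILES self-attention, fusion onto bidirectional PV
  features, per-position soft cross-entropy against the shifted token
  targets mixed with teacher next-token distributions; summed per sequence
  over non-pad positions, averaged over the batch.
* **NPP.**  Causal PV self-attention, fusion onto bidirectional SMILES
  features; position i's output predicts property i (the first from
  `[CLS_P]` alone).  Squared error summed over *known* target positions
  only — `[UNK]` targets contribute nothing — averaged over the batch.
* **SPM.**  One hard negative per anchor per direction, sampled with
  probability proportional to the intermodal softmax weight (positives
  excluded, renormalized).  Positive and negative pairs are fused in both
  query directions; the concatenated `[CLS]` features feed the matching
  head; mean 2-way cross-entropy.

Total = contrastive + NWP + NPP + SPM, unit weights.  After each AdamW step
(weight decay 0.02, gradient norm clipped at 5.0) the teacher is updated by
EMA with λ = 0.995 and its projected `[CLS]` features are enqueued.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| P (properties) | 53 full / 12 toy | registry is configurable; order fixed per model |
| vocab size | 300 | BPE merges; ties broken lexicographically for determinism |
| mask rate | 0.5 | fraction of known PV slots replaced by `[UNK]` per example |
| peak / final LR | 1e-4 / 1e-5 | linear warmup, cosine decay |
| α (pseudo-label weight) | 0 → 0.4 | per-step linear ramp across epoch 1, then constant |
| λ (EMA) | 0.995 | effective teacher horizon ≈ 200 steps |
| queue capacity | 24,576 | see scaled-down note below |
| batch size | 96 full / 32 toy | toy value chosen for single-CPU runtimes |
| beam width | 2 | raw joint log-probability, no length normalization |

## Scaled-down study conditions

The toy preset used by the test suite and `scripts/acceptance.py` is:
hidden 64, 2+2 layers, 4 heads, P = 12, 2,000 training molecules, 500 steps,
batch 32, warmup 50 steps, queue 64.  The **queue capacity does not scale
like the full run's 24,576**: the all-negative labeling of queue entries is
valid only while the probability that a queued feature comes from the same
molecule as an in-batch anchor is negligible (true for a 24,576-slot queue
over 50M molecules).  On a 2,000-molecule corpus the queue is therefore kept
to ~3% of the corpus (64 slots); a proportionally larger queue would label
same-molecule pairs as negatives and corrupt the contrastive targets.

## Synthetic data

`pvlm.fixtures` assembles molecules by concatenating short, chemically
composable SMILES fragments (chains, rings, aromatics, heteroatom
substituents) and validates every candidate with RDKit before emission;
reactions are esterification-style joins of an acid-bearing and an
alcohol-bearing fragment.  The corpora are deterministic per seed, cover a
nonzero spread of each toy descriptor, and make a 300-subword vocabulary
learnable from 2,000 molecules.  They do **not** emulate: the size and
diversity of a real pre-training corpus, drug-like property distributions,
stereochemistry, charged/ionic species, or real reaction chemistry.
Passing tests therefore demonstrate that the machinery — objectives,
decoding, metrics — is correct and trainable, not that the model reaches
literature-level generation quality on real molecules; that requires
full-scale pre-training that is out of this codebase's scope.

## Numerical choices and degenerate inputs

* Autodiff is a minimal reverse-mode engine over float64 NumPy arrays;
  softmax subtracts a detached row max; cross-entropies add 1e-12 inside the
  log.  Loss-oracle agreement is asserted to 1e-5 in the tests.
* Attention masks are additive (−1e9); a mask excluding every key for some
  query raises rather than producing a degenerate softmax.
* An all-`[UNK]` PV is legal everywhere (unconditional generation); an
  all-`[UNK]` NPP target contributes zero loss.
* Invalid SMILES: descriptor computation raises a named error; corpus
  fitting skips and counts them; generation metrics count them as invalid
  rather than discarding them; sequences that hit the length cap without
  `[SEP]` are kept and scored (usually invalid).
* BPE stops early when no adjacent pair occurs twice; the vocabulary can
  therefore be smaller than requested for tiny corpora, and the model's
  `vocab_size` must match the actual vocabulary.
* Hard-negative mining requires batch ≥ 2; a constant similarity row falls
  back to uniform sampling over non-positives.
* Scaffold splitting assigns acyclic molecules (empty Bemis–Murcko core) to
  singleton groups; groups are filled greedily largest-first into train,
  then valid, then test, so a dominant scaffold lands in train.

## Open design points resolved here

* Contrastive vs causal feature coexistence: two encoder passes per batch
  (bidirectional + causal) sharing all weights.
* Queues are fed by the momentum teacher, the convention of the
  momentum-distillation literature this design follows.
* SPM uses two weight-shared fusion passes, one per query modality, and
  concatenates the two fused `[CLS]` outputs.
* One hard negative per anchor per direction (2 per molecule overall).
* The value encoding is one shared linear layer for all properties;
  positional rows alone disambiguate property identity (verified by the
  permutation-invariance tests).
* Stochastic decoding samples the full softmax at temperature 1; beam
  search keeps finished hypotheses aside and compares them against live
  beams on raw joint log-probability.

## Known limitations

* No stereochemistry-aware descriptors or tokens.
* Single-device, full-precision only; no attention KV caching (decoding
  re-encodes the prefix each step — irrelevant at toy lengths).
* The default 53-descriptor registry is a documented, configurable choice
  of common RDKit descriptors, not a canonical list.
* AUROC/RMSE fine-tuning reports use scikit-learn conventions; multi-label
  classification heads are limited to independent binary columns.
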