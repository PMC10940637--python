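"""Byte-pair-encoding tokenizer for SMILES strings.

Training starts from the set of single characters observed in the corpus and
repeatedly merges the most frequent adjacent token pair until the vocabulary
reaches the requested size (default 300) or no pair occurs twice.  Frequency
ties are broken by lexicographic order of the merged string so retraining on
the same corpus is bit-identical.  Multi-character atoms such as "Cl"/"Br"
are not seeded; they emerge as merges when frequent.

Token sequences are framed as ``[CLS_S] subwords... [SEP]``; tokenization is
a partition of the input, so detokenize(tokenize(s)) == s exactly.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

PAD, CLS_S, SEP, MASK = "[PAD]", "[CLS_S]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, CLS_S, SEP, MASK)


@dataclass
class BpeVocab:
    merges: list[tuple[str, str]]
    token_to_id: dict[str, int]
    alphabet: tuple[str, ...]

    def __post_init__(self):
        ids = sorted(self.token_to_id.values())
        if ids != list(range(len(ids))):
            raise ValueError("token ids must be dense starting at 0")
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS_S]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    @property
    def mask_id(self) -> int:
        return self.token_to_id[MASK]

    def save(self, path: str | Path):
        payload = {
            "merges": [list(m) for m in self.merges],
            "token_to_id": self.token_to_id,
            "alphabet": list(self.alphabet),
            "special_tokens": list(SPECIAL_TOKENS),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "BpeVocab":
        d = json.loads(Path(path).read_text())
        return cls(merges=[tuple(m) for m in d["merges"]],
                   token_to_id=d["token_to_id"],
                   alphabet=tuple(d["alphabet"]))


def _pair_counts(corpus_tokens: list[list[str]]) -> Counter:
    counts: Counter = Counter()
    for toks in corpus_tokens:
        for a, b in zip(toks, toks[1:]):
            counts[(a, b)] += 1
    return counts


def _apply_merge(tokens: list[str], pair: tuple[str, str]) -> list[str]:
    out, i, n = [], 0, len(tokens)
    a, b = pair
    while i < n:
        if i + 1 < n and tokens[i] == a and tokens[i + 1] == b:
            out.append(a + b)
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def train_bpe(corpus: Iterable[str], vocab_size: int = 300) -> BpeVocab:
    """Learn a merge list and vocabulary of ``vocab_size`` tokens from a corpus."""
    corpus = [s for s in corpus if s]
    if not corpus:
        raise ValueError("corpus is empty")
    alphabet = tuple(sorted({ch for s in corpus for ch in s}))
    floor = len(alphabet) + len(SPECIAL_TOKENS)
    if vocab_size < floor:
        raise ValueError(
            f"vocab_size={vocab_size} too small: need >= {floor} "
            f"({len(alphabet)} characters + {len(SPECIAL_TOKENS)} special tokens)")

    corpus_tokens = [list(s) for s in corpus]
    merges: list[tuple[str, str]] = []
    n_tokens = floor
    while n_tokens < vocab_size:
        counts = _pair_counts(corpus_tokens)
        if not counts:
            break
        # most frequent pair; ties broken by lexicographic merged string
        best_freq = max(counts.values())
        if best_freq < 2:
            break
        best = min((p for p, c in counts.items() if c == best_freq),
                   key=lambda p: p[0] + p[1])
        merges.append(best)
        corpus_tokens = [_apply_merge(t, best) for t in corpus_tokens]
        n_tokens += 1

    tokens = list(SPECIAL_TOKENS) + list(alphabet) + [a + b for a, b in merges]
    token_to_id = {t: i for i, t in enumerate(tokens)}
    return BpeVocab(merges=merges, token_to_id=token_to_id, alphabet=alphabet)


@dataclass
class TokenSequence:
    ids: list[int]
    vocab: BpeVocab = field(repr=False)

    def __post_init__(self):
        if not self.ids or self.ids[0] != self.vocab.cls_id or self.ids[-1] != self.vocab.sep_id:
            raise ValueError("token sequence must start with [CLS_S] and end with [SEP]")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def tokens(self) -> list[str]:
        return [self.vocab.id_to_token[i] for i in self.ids]


def tokenize(smiles: str, vocab: BpeVocab, max_len: int | None = 100) -> TokenSequence:
    """Apply learned merges in order and frame with [CLS_S] ... [SEP]."""
    unknown = [ch for ch in smiles if ch not in vocab.alphabet]
    if unknown:
        raise ValueError(f"character(s) outside tokenizer alphabet: {sorted(set(unknown))}")
    toks = list(smiles)
    for pair in vocab.merges:
        if len(toks) < 2:
            break
        toks = _apply_merge(toks, pair)
    ids = [vocab.cls_id] + [vocab.token_to_id[t] for t in toks] + [vocab.sep_id]
    if max_len is not None and len(ids) > max_len:
        raise ValueError(f"tokenized length {len(ids)} exceeds max length {max_len}")
    return TokenSequence(ids=ids, vocab=vocab)


def detokenize(tokens: TokenSequence | Sequence[int], vocab: BpeVocab | None = None) -> str:
    """Concatenate subwords between the [CLS_S]/[SEP] frame."""
    if isinstance(tokens, TokenSequence):
        ids, vocab = tokens.ids, tokens.vocab
    else:
        if vocab is None:
            raise ValueError("vocab required when passing raw ids")
        ids = list(tokens)
    for i in ids:
        if i not in vocab.id_to_token:
            raise ValueError(f"unknown token id {i}")
    if not ids or ids[0] != vocab.cls_id:
        raise ValueError("sequence must start with [CLS_S]")
    body = []
    for i in ids[1:]:
        if i == vocab.sep_id:
            break
        body.append(vocab.id_to_token[i])
    return "".join(body)


def load_corpus(path: str | Path) -> list[str]:
    """Read a .smi file: one SMILES per line, blank lines ignored."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
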