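"""Deterministic toy data: valid SMILES corpora and synthetic reaction pairs.

Molecules are assembled by concatenating short, chemically composable SMILES
fragments and every candidate is validated with RDKit before emission, so the
corpora contain only parseable molecules while still exercising rings,
aromatics, heteroatoms and branching.  Reactions are esterification-style
joins of an acid-bearing and an alcohol-bearing fragment; they exercise the
sequence-to-sequence machinery and make no claim of chemical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .properties import parse_smiles

#: Short fragments chosen so that most concatenations remain valid SMILES and
#: a ~300-subword vocabulary is learnable from small corpora.
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "N", "O", "CO", "CN", "C(C)", "C(N)", "C(O)",
    "C(=O)", "C(=O)O", "C(N)=O", "C#N", "C=C", "CCl", "CF", "CBr",
    "c1ccccc1", "c1ccncc1", "c1ccco1", "c1cccs1", "C1CCCC1", "C1CCCCC1",
    "C1CCNCC1", "C1CCOCC1", "OC", "NC", "S",
)

#: Fragments safe as the left body of an ester product (no trailing branch).
_ACID_BODIES: tuple[str, ...] = ("C", "CC", "CCC", "CCCC", "CCO", "CCN",
                                 "c1ccccc1", "C1CCCCC1C", "CC(C)")
_ALCOHOL_TAILS: tuple[str, ...] = ("C", "CC", "CCC", "C(C)C", "CCO", "CCN",
                                   "Cc1ccccc1", "CC1CCCC1")


@dataclass
class ToyCorpusSpec:
    n: int
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    max_fragments: int = 4
    seed: int = 0


@dataclass
class ReactionPair:
    reactants: str  # possibly dot-separated multi-molecule SMILES
    product: str


def _is_valid(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def generate_toy_corpus(spec: ToyCorpusSpec) -> list[str]:
    """Sample ``spec.n`` valid SMILES; reproducible from ``spec.seed``."""
    if spec.n < 1:
        raise ValueError("need n >= 1")
    if not spec.fragments:
        raise ValueError("fragment alphabet is empty")
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    while len(out) < spec.n:
        k = int(rng.integers(1, spec.max_fragments + 1))
        idx = rng.integers(0, len(spec.fragments), size=k)
        candidate = "".join(spec.fragments[i] for i in idx)
        if _is_valid(candidate):
            out.append(candidate)
    return out


def generate_toy_reactions(n: int, seed: int = 0) -> list[ReactionPair]:
    """Esterification-style synthetic pairs: R-C(=O)O + H-O-R' -> R-C(=O)-O-R'."""
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[ReactionPair] = []
    while len(pairs) < n:
        body = _ACID_BODIES[int(rng.integers(0, len(_ACID_BODIES)))]
        tail = _ALCOHOL_TAILS[int(rng.integers(0, len(_ALCOHOL_TAILS)))]
        acid = body + "C(=O)O"
        alcohol = "O" + tail
        product = body + "C(=O)O" + tail
        reactants = acid + "." + alcohol
        if _is_valid(acid) and _is_valid(alcohol) and _is_valid(product):
            pairs.append(ReactionPair(reactants=reactants, product=product))
    return pairs


def canonical(smiles: str) -> str:
    return Chem.MolToSmiles(parse_smiles(smiles))


def write_corpus(smiles: list[str], path: str | Path):
    Path(path).write_text("\n".join(smiles) + "\n")


def write_reactions(pairs: list[ReactionPair], path: str | Path):
    lines = [f"{p.reactants}\t{p.product}" for p in pairs]
    Path(path).write_text("\n".join(lines) + "\n")


def read_reactions(path: str | Path) -> list[ReactionPair]:
    pairs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        reactants, product = line.split("\t")
        pairs.append(ReactionPair(reactants=reactants, product=product))
    return pairs
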