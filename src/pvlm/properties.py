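"""Molecular property vectors: descriptor computation, normalization, masking.

A molecule's "property sentence" is an ordered vector of scalar descriptors
(molar mass, logP, TPSA, ring counts, ...) computed from its SMILES.  Each
value is z-scored with corpus statistics, and during pre-training a fraction
of positions is replaced by a learned [UNK] marker so the model never becomes
dependent on any single property being present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-8

#: Default registry: 53 RDKit descriptors spanning simple counts (atoms,
#: bonds, rings, H-donors/acceptors), topology/shape indices, and continuous
#: physicochemical properties (molar mass, logP, TPSA, molar refractivity,
#: QED, solubility-related fragments).  The order is fixed but arbitrary;
#: positional embeddings give each slot its identity.
DEFAULT_PROPERTY_NAMES: tuple[str, ...] = (
    "MolWt", "ExactMolWt", "HeavyAtomMolWt", "HeavyAtomCount", "NumValenceElectrons",
    "NHOHCount", "NOCount", "NumHAcceptors", "NumHDonors", "NumHeteroatoms",
    "NumRotatableBonds", "RingCount", "NumAromaticRings", "NumAliphaticRings",
    "NumSaturatedRings", "NumAromaticCarbocycles", "NumAromaticHeterocycles",
    "NumAliphaticCarbocycles", "NumAliphaticHeterocycles", "NumSaturatedCarbocycles",
    "NumSaturatedHeterocycles", "FractionCSP3", "MolLogP", "MolMR", "TPSA", "qed",
    "LabuteASA", "BalabanJ", "BertzCT", "Chi0", "Chi1", "Chi0n", "Chi1n", "Chi2n",
    "Chi0v", "Chi1v", "Chi2v", "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3",
    "MaxPartialCharge", "MinPartialCharge", "MaxAbsPartialCharge", "MinAbsPartialCharge",
    "NumRadicalElectrons", "fr_NH0", "fr_NH1", "fr_NH2", "fr_ester", "fr_ether",
    "fr_halogen", "fr_benzene",
)

#: Small 12-descriptor subset used throughout the toy-scale examples/tests.
TOY_PROPERTY_NAMES: tuple[str, ...] = (
    "MolWt", "HeavyAtomCount", "RingCount", "NumAromaticRings", "NumRotatableBonds",
    "NumHAcceptors", "NumHDonors", "MolLogP", "TPSA", "FractionCSP3", "MolMR", "qed",
)


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES: {smiles!r}")
    return mol


@dataclass
class PropertyRegistry:
    """Ordered, named set of descriptor functions (SMILES -> scalar).

    The order is fixed for the lifetime of a model: positional embeddings and
    normalization statistics are indexed by it.
    """

    names: tuple[str, ...] = DEFAULT_PROPERTY_NAMES
    compute_fns: dict[str, Callable[[Chem.Mol], float]] = field(default_factory=dict)

    def __post_init__(self):
        self.names = tuple(self.names)
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")
        for name in self.names:
            if name not in self.compute_fns:
                fn = getattr(Descriptors, name, None)
                if fn is None:
                    raise KeyError(f"no descriptor function for {name!r}; "
                                   "register one in compute_fns")
                self.compute_fns[name] = fn

    def __len__(self) -> int:
        return len(self.names)

    def compute(self, smiles: str) -> np.ndarray:
        """Raw (unnormalized) descriptor values in registry order."""
        mol = parse_smiles(smiles)
        values = np.array([float(self.compute_fns[n](mol)) for n in self.names])
        # a handful of RDKit descriptors emit NaN on exotic inputs; map to 0
        values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
        return values

    def to_json(self) -> str:
        return json.dumps(list(self.names))

    @classmethod
    def from_json(cls, text: str) -> "PropertyRegistry":
        return cls(names=tuple(json.loads(text)))

    @classmethod
    def toy(cls) -> "PropertyRegistry":
        return cls(names=TOY_PROPERTY_NAMES)


def compute_descriptors(smiles: str, registry: PropertyRegistry) -> np.ndarray:
    return registry.compute(smiles)


@dataclass
class NormalizationStats:
    """Per-property mean and standard deviation (population convention)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.std = np.asarray(self.std, dtype=np.float64)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean/std length mismatch")
        if np.any(self.std <= 0):
            raise ValueError("std must be positive everywhere")

    def __len__(self) -> int:
        return len(self.mean)

    def to_json(self, names: Sequence[str]) -> str:
        return json.dumps({n: {"mean": float(m), "std": float(s)}
                           for n, m, s in zip(names, self.mean, self.std)}, indent=1)

    @classmethod
    def from_json(cls, text: str, names: Sequence[str]) -> "NormalizationStats":
        d = json.loads(text)
        return cls(mean=np.array([d[n]["mean"] for n in names]),
                   std=np.array([d[n]["std"] for n in names]))


@dataclass
class PropertyVector:
    """Normalized descriptor values with per-position known/[UNK] flags."""

    values: np.ndarray
    known: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.known = np.asarray(self.known, dtype=bool)
        if self.values.shape != self.known.shape:
            raise ValueError("values/known length mismatch")
        if not np.all(np.isfinite(self.values[self.known])):
            raise ValueError("known positions must hold finite values")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def all_unknown(cls, n: int) -> "PropertyVector":
        return cls(values=np.zeros(n), known=np.zeros(n, dtype=bool))


def fit_normalization(corpus: Iterable[str], registry: PropertyRegistry,
                      sigma_floor: float = SIGMA_FLOOR) -> NormalizationStats:
    """Per-property mean/std over a SMILES corpus (invalid entries skipped)."""
    rows, n_bad = [], 0
    for smi in corpus:
        try:
            rows.append(registry.compute(smi))
        except InvalidSmilesError:
            n_bad += 1
    if n_bad:
        logger.warning("fit_normalization: skipped %d invalid SMILES", n_bad)
    if not rows:
        raise ValueError("no valid SMILES in corpus")
    raw = np.stack(rows)
    mean = raw.mean(axis=0)
    std = raw.std(axis=0)  # population (1/n)
    degenerate = std < sigma_floor
    if np.any(degenerate):
        logger.warning("fit_normalization: %d constant properties floored at sigma=%g",
                       int(degenerate.sum()), sigma_floor)
        std = np.where(degenerate, sigma_floor, std)
    return NormalizationStats(mean=mean, std=std)


def normalize(raw: np.ndarray, stats: NormalizationStats) -> PropertyVector:
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != stats.mean.shape:
        raise ValueError(f"length mismatch: {raw.shape} vs {stats.mean.shape}")
    return PropertyVector(values=(raw - stats.mean) / stats.std,
                          known=np.ones(len(raw), dtype=bool))


def denormalize(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.shape != stats.mean.shape:
        raise ValueError("length mismatch")
    return values * stats.std + stats.mean


def apply_unk_mask(pv: PropertyVector, rate: float,
                   rng: np.random.Generator) -> PropertyVector:
    """Independently mark each known position [UNK] with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mask rate must lie in [0, 1]")
    drop = rng.random(len(pv)) < rate
    return PropertyVector(values=pv.values.copy(), known=pv.known & ~drop)


def smiles_to_pv(smiles: str, registry: PropertyRegistry,
                 stats: NormalizationStats) -> PropertyVector:
    return normalize(registry.compute(smiles), stats)


def load_property_table(path: str | Path, registry: PropertyRegistry):
    """Read a TSV with a 'smiles' column plus one column per registry name."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("smiles", *registry.names) if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing columns: {missing}")
    return df
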