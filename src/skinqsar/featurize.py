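"""The three molecular views.

Every compound is encoded three ways:

* **Morgan fingerprint** — radius-2 circular environments hashed into a
  2048-bit binary vector (ECFP4-style). Hash collisions are accepted as-is;
  bits are presence/absence, not counts.
* **MACCS keys** — the public 166-key substructure dictionary, reported
  1-based (``MACCS_1`` … ``MACCS_166``).
* **2-D descriptor panel** — continuous physicochemical/topological
  descriptors from a pluggable :class:`DescriptorProvider`; columns with any
  missing or non-finite value on the fitted set are removed wholesale, and
  the retained-column list is frozen for reuse on query compounds.

Fingerprinters are exposed both as functions and as stateless sklearn-style
transformers so they drop into pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Protocol, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import MACCSkeys
from rdkit.Chem.rdFingerprintGenerator import GetMorganGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .records import MoleculeRecord

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048
MACCS_NBITS = 166


class EmptyFeatureError(ValueError):
    """Cleaning or selection removed every column."""


@dataclass
class FingerprintBlock:
    kind: str                 # "morgan" | "maccs"
    bits: np.ndarray          # n x w uint8 matrix, entries in {0,1}
    row_ids: List[str]

    def __post_init__(self) -> None:
        expected = {"morgan": MORGAN_NBITS, "maccs": MACCS_NBITS}[self.kind]
        if self.bits.ndim != 2 or self.bits.shape[1] != expected:
            raise ValueError(
                f"{self.kind} block must be n x {expected}, got {self.bits.shape}"
            )

    @property
    def width(self) -> int:
        return self.bits.shape[1]

    def take(self, rows) -> "FingerprintBlock":
        rows = np.asarray(rows)
        return FingerprintBlock(self.kind, self.bits[rows],
                                [self.row_ids[i] for i in rows])

    def column_names(self) -> List[str]:
        if self.kind == "maccs":
            # 1-based to match the conventional MACCS_<k> naming
            return [f"MACCS_{i + 1}" for i in range(self.width)]
        return [f"morgan_{i}" for i in range(self.width)]


@dataclass
class DescriptorBlock:
    values: np.ndarray        # n x d float matrix
    names: List[str]
    row_ids: List[str]

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names must match column count")
        if len(set(self.names)) != len(self.names):
            raise ValueError("descriptor names must be unique")

    def subset(self, keep: Sequence[str]) -> "DescriptorBlock":
        idx = [self.names.index(n) for n in keep]
        return DescriptorBlock(self.values[:, idx], list(keep), self.row_ids)

    def take(self, rows) -> "DescriptorBlock":
        rows = np.asarray(rows)
        return DescriptorBlock(self.values[rows], list(self.names),
                               [self.row_ids[i] for i in rows])


class DescriptorProvider(Protocol):
    """Maps a molecule to a named vector of 2-D descriptors.

    Must be deterministic for a fixed molecule and return the same name set
    for every molecule; missing values (NaN) are allowed pre-cleaning.
    """

    names: List[str]

    def __call__(self, mol: Chem.Mol) -> np.ndarray: ...


def _mols(records: Sequence[MoleculeRecord]) -> List[Chem.Mol]:
    mols = []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        if mol is None:  # upstream validation should make this unreachable
            raise ValueError(f"invalid SMILES slipped through for id {r.id!r}")
        mols.append(mol)
    return mols


def morgan_fingerprint(records: Sequence[MoleculeRecord]) -> FingerprintBlock:
    """Radius-2, 2048-bit hashed circular fingerprints."""
    gen = GetMorganGenerator(radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS)
    rows = np.zeros((len(records), MORGAN_NBITS), dtype=np.uint8)
    for i, mol in enumerate(_mols(records)):
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return FingerprintBlock("morgan", rows, [r.id for r in records])


def maccs_fingerprint(records: Sequence[MoleculeRecord]) -> FingerprintBlock:
    """166-bit MACCS substructure keys (RDKit's 167-bit vector minus bit 0)."""
    rows = np.zeros((len(records), MACCS_NBITS), dtype=np.uint8)
    for i, mol in enumerate(_mols(records)):
        fp = MACCSkeys.GenMACCSKeys(mol)   # 167 bits, index 0 always unset
        on = [b - 1 for b in fp.GetOnBits() if b >= 1]
        rows[i, on] = 1
    return FingerprintBlock("maccs", rows, [r.id for r in records])


def compute_descriptors(
    records: Sequence[MoleculeRecord], provider: DescriptorProvider
) -> DescriptorBlock:
    """Uncleaned descriptor matrix; provider failures become NaN rows."""
    n, names = len(records), list(provider.names)
    values = np.full((n, len(names)), np.nan)
    for i, mol in enumerate(_mols(records)):
        try:
            values[i] = provider(mol)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"descriptor provider failed on {records[i].id!r}: {exc}")
    return DescriptorBlock(values, names, [r.id for r in records])


def drop_missing_descriptors(block: DescriptorBlock) -> DescriptorBlock:
    """Remove every column with >= 1 missing/non-finite entry.

    Returns the cleaned block; the surviving name list is what gets frozen
    for prediction-time reuse.
    """
    finite = np.isfinite(block.values).all(axis=0)
    if not finite.any():
        raise EmptyFeatureError("all descriptor columns contain missing values")
    keep = [n for n, ok in zip(block.names, finite) if ok]
    return block.subset(keep)


# --------------------------------------------------------------------------
# sklearn-style transformer facades

class MorganFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: records -> n x 2048 binary matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[MoleculeRecord]) -> np.ndarray:
        return morgan_fingerprint(X).bits.astype(float)


class MACCSFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: records -> n x 166 binary matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: Sequence[MoleculeRecord]) -> np.ndarray:
        return maccs_fingerprint(X).bits.astype(float)


# --------------------------------------------------------------------------
# Built-in descriptor providers

class ToyDescriptorProvider:
    """~20 closed-form 2-D descriptors, cheap enough to verify by inspection.

    Counts (heavy atoms, rings, aromatic atoms, heteroatoms, bond types,
    H-bond donors/acceptors, rotatable bonds) plus a crude logP surrogate
    and TPSA. Deterministic by construction.
    """

    names = [
        "HeavyAtoms", "RingCount", "AromaticAtoms", "AromaticBonds",
        "NCount", "OCount", "SCount", "HalogenCount", "HeteroFraction",
        "HBD", "HBA", "RotatableBonds", "SingleBonds", "DoubleBonds",
        "TripleBonds", "MolWt", "CrippenLogP", "TPSA", "FractionCSP3",
        "FormalCharge",
    ]

    def __call__(self, mol: Chem.Mol) -> np.ndarray:
        heavy = mol.GetNumHeavyAtoms()
        atoms = list(mol.GetAtoms())
        bonds = list(mol.GetBonds())
        n_arom_at = sum(a.GetIsAromatic() for a in atoms)
        halogens = sum(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in atoms)
        hetero = sum(a.GetAtomicNum() not in (1, 6) for a in atoms)
        bt = [b.GetBondType() for b in bonds]
        return np.array([
            heavy,
            rdMolDescriptors.CalcNumRings(mol),
            n_arom_at,
            sum(b.GetIsAromatic() for b in bonds),
            sum(a.GetSymbol() == "N" for a in atoms),
            sum(a.GetSymbol() == "O" for a in atoms),
            sum(a.GetSymbol() == "S" for a in atoms),
            halogens,
            hetero / heavy if heavy else 0.0,
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumRotatableBonds(mol),
            sum(t == Chem.BondType.SINGLE for t in bt),
            sum(t == Chem.BondType.DOUBLE for t in bt),
            sum(t == Chem.BondType.TRIPLE for t in bt),
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            rdMolDescriptors.CalcFractionCSP3(mol),
            Chem.GetFormalCharge(mol),
        ], dtype=float)


class RDKit2DDescriptorProvider:
    """The full RDKit 2-D descriptor panel (~200 continuous descriptors)."""

    def __init__(self) -> None:
        self._funcs = [(n, f) for n, f in Descriptors.descList]
        self.names = [n for n, _ in self._funcs]

    def __call__(self, mol: Chem.Mol) -> np.ndarray:
        out = np.empty(len(self._funcs))
        for i, (_, f) in enumerate(self._funcs):
            try:
                out[i] = f(mol)
            except Exception:
                out[i] = np.nan
        return out
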