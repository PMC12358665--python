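"""Synthetic compound libraries with a planted structure–activity signal.

The generator assembles small organic molecules from a fragment grammar
(alkyl chains with optional heteroatom insertions, branches and terminal
decorations) and plants a "toxicophore" — by default an aromatic nitro
group, an acrylate ester, or a thiol — in a label-dependent fraction of
them. Labels follow the two conditionals P(toxic | motif) and
P(toxic | no motif) (defaults 0.9 / 0.1), so the structure carries a strong
but noisy signal: the Bayes-optimal classifier on motif presence alone has
AUC 0.90 at the defaults. Class counts are exact, structures are unique by
canonical SMILES, and everything is reproducible from the seed.

Presets mirror the class shapes of the curated endpoint datasets
(317 / 695 for irritation-corrosion, 382 / 2234 for acute dermal toxicity)
so balancing behaviour can be exercised at realistic scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chemio import canonical_smiles
from .featurize import DescriptorBlock, ToyDescriptorProvider
from .records import MoleculeRecord

#: SMARTS used to verify motif presence after assembly.
DEFAULT_TOXICOPHORE_SMARTS = (
    "[c][N+](=O)[O-]",      # aromatic nitro
    "C=CC(=O)O",            # acrylate (ester or acid)
    "[SX2H1]",              # thiol
)

#: Appendable SMILES fragments that realize each motif at a chain terminus.
_MOTIF_FRAGMENTS = (
    "c1ccc([N+](=O)[O-])cc1",
    "OC(=O)C=C",
    "S",
)

_BRANCHES = ("C", "CC", "O", "N", "Cl", "F", "CO")
_DECORATIONS = ("", "O", "N", "Cl", "c1ccccc1", "C(=O)O", "C#N",
                "c1ccncc1", "C(=O)C", "OC")


@dataclass
class SynthConfig:
    n_toxic: int = 300
    n_nontoxic: int = 300
    toxicophore_smarts: Sequence[str] = DEFAULT_TOXICOPHORE_SMARTS
    p_toxic_given_motif: float = 0.9
    p_toxic_given_no_motif: float = 0.1
    fragment_pool: Sequence[str] = _DECORATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_toxic_given_motif, self.p_toxic_given_no_motif):
            if not 0.0 <= p <= 1.0:
                raise ValueError("conditional probabilities must lie in [0,1]")
        if self.n_toxic < 0 or self.n_nontoxic < 0 or \
                self.n_toxic + self.n_nontoxic == 0:
            raise ValueError("infeasible class counts")
        if not self.fragment_pool:
            raise ValueError("fragment pool must be non-empty")


def irritation_preset(seed: int = 0) -> SynthConfig:
    """Class shape of the irritation-corrosion dataset (317 vs 695)."""
    return SynthConfig(n_toxic=317, n_nontoxic=695, seed=seed)


def dermal_preset(seed: int = 0) -> SynthConfig:
    """Class shape of the acute dermal toxicity dataset (382 vs 2234)."""
    return SynthConfig(n_toxic=382, n_nontoxic=2234, seed=seed)


def has_motif(smiles: str, smarts_list: Sequence[str] = DEFAULT_TOXICOPHORE_SMARTS
              ) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return any(mol.HasSubstructMatch(Chem.MolFromSmarts(s)) for s in smarts_list)


def _assemble(rng: np.random.Generator, with_motif: bool,
              pool: Sequence[str]) -> str:
    """One random SMILES from the fragment grammar."""
    chain_len = int(rng.integers(2, 13))
    atoms = ["C"] * chain_len
    if chain_len >= 4 and rng.random() < 0.5:      # interior heteroatom
        pos = int(rng.integers(1, chain_len - 1))
        atoms[pos] = str(rng.choice(["O", "N"]))
    if rng.random() < 0.6:                          # one branch on a carbon
        carbons = [i for i, a in enumerate(atoms) if a == "C" and i > 0]
        if carbons:
            pos = int(rng.choice(carbons))
            atoms[pos] = atoms[pos] + f"({rng.choice(_BRANCHES)})"
    smiles = "".join(atoms)
    if with_motif:
        smiles += str(rng.choice(_MOTIF_FRAGMENTS))
    else:
        smiles += str(rng.choice(list(pool)))
    return smiles


def generate_library(cfg: SynthConfig) -> List[MoleculeRecord]:
    """Generate the library with exact class counts and unique structures."""
    rng = np.random.default_rng(cfg.seed)
    pm, pn = cfg.p_toxic_given_motif, cfg.p_toxic_given_no_motif
    # motif prior 0.5 -> posterior motif probability given each label
    p_motif_toxic = pm / (pm + pn) if (pm + pn) > 0 else 0.0
    p_motif_nontoxic = (1 - pm) / ((1 - pm) + (1 - pn)) \
        if ((1 - pm) + (1 - pn)) > 0 else 1.0

    seen = set()
    records: List[MoleculeRecord] = []
    counter = 1
    for label, count, p_motif in ((1, cfg.n_toxic, p_motif_toxic),
                                  (0, cfg.n_nontoxic, p_motif_nontoxic)):
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * max(count, 1):
                raise ValueError(
                    f"could not assemble {count} unique class-{label} "
                    "molecules; counts infeasible for the fragment space")
            want_motif = bool(rng.random() < p_motif)
            smi = _assemble(rng, want_motif, cfg.fragment_pool)
            can = canonical_smiles(smi)
            if can is None or can in seen:
                continue
            if has_motif(can, cfg.toxicophore_smarts) != want_motif:
                continue   # grammar accident: decoration created/blocked a motif
            seen.add(can)
            records.append(MoleculeRecord(id=f"syn{counter:05d}", smiles=can,
                                          label=label))
            counter += 1
            made += 1
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def toy_descriptor_provider() -> ToyDescriptorProvider:
    """The built-in ~20-descriptor closed-form 2-D panel."""
    return ToyDescriptorProvider()


def make_informative_descriptors(
    n: int = 500,
    n_informative: int = 5,
    n_noise: int = 45,
    effect: float = 1.0,
    seed: int = 0,
) -> Tuple[DescriptorBlock, np.ndarray, List[str]]:
    """Numeric descriptor matrix with a planted informative support.

    Informative columns are shifted by ``effect`` standard deviations in the
    toxic class; noise columns are label-independent. Used to check that the
    selection cascade recovers a known support.
    """
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    info = rng.normal(0, 1, (n, n_informative)) + effect * y[:, None]
    noise = rng.normal(0, 1, (n, n_noise))
    values = np.column_stack([info, noise])
    names = [f"inf_{i}" for i in range(n_informative)] + \
        [f"noise_{i}" for i in range(n_noise)]
    ids = [f"s{i}" for i in range(n)]
    return DescriptorBlock(values, names, ids), y, names[:n_informative]
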