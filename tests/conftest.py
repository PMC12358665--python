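import numpy as np
import pytest
from rdkit import Chem

from skinqsar.records import MoleculeRecord


@pytest.fixture
def small_records():
    raw = [("m1", "CCO", 0), ("m2", "c1ccccc1", 1), ("m3", "CC(=O)O", 0),
           ("m4", "CCS", 1), ("m5", "CCCCN", 0),
           ("m6", "c1ccc(cc1)[N+](=O)[O-]", 1)]
    return [MoleculeRecord(i, Chem.CanonSmiles(s), l) for i, s, l in raw]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
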