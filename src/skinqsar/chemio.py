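"""Reading and writing compound tables and model reports.

Input formats are the two a screening chemist actually has on disk: a SMILES
CSV (one compound per row) and an SDF. Structures are validated with RDKit
and canonicalized on the way in; multi-component entries (SMILES containing
".") are rejected by default, matching the upstream curation convention of
removing inorganics and mixtures. Outputs are a flat predictions CSV and a
model-card JSON summarising the trained model, its applicability domain and
its performance metrics.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .records import MoleculeRecord, PredictionRecord

RDLogger.DisableLog("rdApp.*")


class EmptyInputError(ValueError):
    """No parseable compound survived reading."""


def canonical_smiles(smiles: str, keep_largest_fragment: bool = False) -> Optional[str]:
    """Canonical SMILES for a single-component structure, or None if invalid.

    Multi-component inputs (containing ".") are rejected unless
    ``keep_largest_fragment`` is set, in which case the fragment with the
    most heavy atoms is kept.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    smiles = smiles.strip()
    if "." in smiles:
        if not keep_largest_fragment:
            return None
        frags = smiles.split(".")
        mols = [Chem.MolFromSmiles(f) for f in frags]
        mols = [m for m in mols if m is not None]
        if not mols:
            return None
        mol = max(mols, key=lambda m: m.GetNumHeavyAtoms())
    else:
        mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return Chem.MolToSmiles(mol)


def _dedupe(records: List[MoleculeRecord], source: str) -> List[MoleculeRecord]:
    """Enforce unique ids (hard error) and unique structures (first wins)."""
    seen_ids = set()
    for r in records:
        if r.id in seen_ids:
            raise ValueError(f"duplicate id {r.id!r} in {source}")
        seen_ids.add(r.id)
    seen_smiles = {}
    out = []
    dup = 0
    for r in records:
        if r.smiles in seen_smiles:
            dup += 1
            continue
        seen_smiles[r.smiles] = r.id
        out.append(r)
    if dup:
        warnings.warn(f"{dup} duplicate structure(s) dropped from {source} "
                      "(first occurrence kept)")
    return out


def read_smiles_table(
    path,
    id_col: str = "id",
    smiles_col: str = "smiles",
    label_col: Optional[str] = None,
    keep_largest_fragment: bool = False,
) -> List[MoleculeRecord]:
    """Read a compound CSV into validated :class:`MoleculeRecord` objects.

    Rows whose SMILES does not parse to a valid single-component structure
    are dropped with a warning carrying the count. Labels must be exactly
    0 or 1; anything else is a hard error.
    """
    df = pd.read_csv(path)
    for col in filter(None, (id_col, smiles_col, label_col)):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path}")
    records: List[MoleculeRecord] = []
    dropped = 0
    for _, row in df.iterrows():
        can = canonical_smiles(str(row[smiles_col]), keep_largest_fragment)
        if can is None:
            dropped += 1
            continue
        label = None
        if label_col is not None:
            raw = row[label_col]
            if pd.isna(raw):
                label = None
            else:
                fl = float(raw)
                if fl not in (0.0, 1.0):
                    raise ValueError(
                        f"label {raw!r} for id {row[id_col]!r} is not 0 or 1"
                    )
                label = int(fl)
        records.append(MoleculeRecord(id=str(row[id_col]), smiles=can, label=label))
    if dropped:
        warnings.warn(f"{dropped} row(s) with unparseable SMILES dropped from {path}")
    if not records:
        raise EmptyInputError(f"no parseable compounds in {path}")
    return _dedupe(records, str(path))


def read_sdf(path) -> List[MoleculeRecord]:
    """Read an SDF (V2000/V3000); ids from the title line or generated."""
    if Path(path).stat().st_size == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records: List[MoleculeRecord] = []
    dropped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            dropped += 1
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        rid = name.strip() or f"mol_{i + 1}"
        records.append(MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol)))
    if dropped:
        warnings.warn(f"{dropped} unreadable mol block(s) dropped from {path}")
    return _dedupe(records, str(path)) if records else []


def write_sdf(records: Sequence[MoleculeRecord], path) -> None:
    """Write records to an SDF; the record id becomes the title line."""
    writer = Chem.SDWriter(str(path))
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            mol.SetProp("_Name", r.id)
            writer.write(mol)
    finally:
        writer.close()


PREDICTION_HEADER = ["id", "endpoint", "class", "probability", "reliable"]


def write_predictions(preds: Sequence[PredictionRecord], path) -> None:
    """Write a predictions CSV (probability at 4 decimals)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PREDICTION_HEADER)
        for p in preds:
            w.writerow([p.id, p.endpoint, p.predicted_class,
                        f"{p.probability:.4f}", p.reliable])


def read_predictions(path) -> List[PredictionRecord]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        PredictionRecord(
            id=r["id"],
            endpoint=r["endpoint"],
            predicted_class=int(r["class"]),
            probability=float(r["probability"]),
            reliable=r["reliable"] == "True",
        )
        for r in rows
    ]


def write_model_card(model, metrics, ad, path, extra: Optional[dict] = None) -> dict:
    """Write the model-card JSON: algorithm, hyperparameters, feature views,
    AD thresholds, metrics, and optional Y-randomization summary.

    ``model``, ``metrics`` and ``ad`` are duck-typed: each must expose a
    ``to_dict()`` method (TrainedModel, MetricReport, ADBundle all do).
    """
    card = {
        "algorithm": model.algorithm,
        "view": model.view,
        "hyperparameters": model.hyperparameters,
        "decision_threshold": model.threshold,
        "feature_views": model.feature_summary(),
        "metrics": metrics.to_dict(),
        "applicability_domain": ad.to_dict(),
    }
    if extra:
        card.update(extra)
    Path(path).write_text(json.dumps(card, indent=2, sort_keys=True, default=_json_default))
    return card


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def records_to_csv(records: Sequence[MoleculeRecord], path) -> None:
    """Write records as a SMILES CSV consumable by :func:`read_smiles_table`."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=["id", "smiles", "label", "split_tag"])
    df.to_csv(path, index=False)
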