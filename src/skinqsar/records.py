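"""Core record types shared across the pipeline.

A :class:`MoleculeRecord` is one curated compound: a stable identifier, a
canonical SMILES, an optional binary toxicity label (1 = toxic class of the
endpoint) and a split tag. A :class:`PredictionRecord` is one row of a
prediction report: class call, probability of the toxic class, and the
consensus applicability-domain reliability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

VALID_SPLIT_TAGS = ("train", "test", "external", "unassigned")
VALID_ENDPOINTS = ("sensitization", "irritation", "dermal_toxicity")


@dataclass
class MoleculeRecord:
    id: str
    smiles: str
    label: Optional[int] = None
    split_tag: str = "unassigned"

    def __post_init__(self) -> None:
        if self.label is not None:
            if self.label not in (0, 1):
                raise ValueError(
                    f"label must be 0 or 1, got {self.label!r} for id {self.id!r}"
                )
            self.label = int(self.label)
        if self.split_tag not in VALID_SPLIT_TAGS:
            raise ValueError(f"unknown split_tag {self.split_tag!r}")


@dataclass
class PredictionRecord:
    id: str
    endpoint: str
    predicted_class: int
    probability: float
    reliable: bool

    def __post_init__(self) -> None:
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.predicted_class not in (0, 1):
            raise ValueError("predicted_class must be 0 or 1")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")
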