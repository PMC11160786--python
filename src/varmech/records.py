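"""Shared variant-level record types."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError

PATHOGENICITY_CLASSES = ("benign", "ambiguous", "pathogenic")
STABILITY_CLASSES = ("stabilising", "neutral", "destabilising")
MECHANISMS = ("stability", "pocket", "interface", "unclassified")


@dataclass
class VariantRecord:
    """One missense change on one protein.

    ``am_score`` is a sequence-based pathogenicity score in [0, 1]
    (AlphaMissense-like); ``ddg`` the predicted folding free-energy change
    in kcal/mol (positive = destabilising).  Class labels stay ``None``
    until the classification operations run.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    am_score: Optional[float] = None
    ddg: Optional[float] = None
    pathogenicity_class: Optional[str] = None
    stability_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"{self.protein_id}:{self.position} ref and alt amino acid identical"
            )
        if self.position < 1:
            raise ValidationError("position must be 1-based (>= 1)")
        if self.am_score is not None and not 0.0 <= self.am_score <= 1.0:
            raise ValidationError(f"am_score {self.am_score} outside [0, 1]")


@dataclass(frozen=True)
class MechanismCall:
    """Primary mechanism assigned to one pathogenic variant, with the
    evidence (which residue sets the position matched)."""

    variant: VariantRecord
    mechanism: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
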