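"""Peptide records, sequence validation, and labeled training datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional

from .scales import ALPHABET


class SequenceError(ValueError):
    """Raised when a peptide sequence fails validation."""


@dataclass(frozen=True)
class PeptideRecord:
    """A validated peptide sequence.

    Parameters
    ----------
    id : str
        Free-text identifier.
    sequence : str
        Uppercase string over the 20 canonical one-letter codes.
    label : int, optional
        Binary class: 1 = cell-penetrating (CPP), 0 = non-CPP.
    chirality_note : str, optional
        Metadata only (e.g. ``"all-D"``); descriptors are computed from
        the letter sequence regardless of chirality.
    """

    id: str
    sequence: str
    label: Optional[int] = None
    chirality_note: Optional[str] = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.label is not None and self.label not in (0, 1):
            raise SequenceError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: int) -> "PeptideRecord":
        return replace(self, label=label)


def _check_sequence(seq: str) -> None:
    if not seq:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in ALPHABET:
            raise SequenceError(
                f"non-canonical residue {ch!r} at position {pos}")


def validate_sequence(raw: str, id: str = "", label: Optional[int] = None,
                      chirality_note: Optional[str] = None) -> PeptideRecord:
    """Strip whitespace, uppercase, and validate a raw sequence string.

    Raises :class:`SequenceError` for an empty sequence or for the first
    non-canonical character (B, J, O, U, X, Z, digits, punctuation),
    naming the character and its 1-based position.
    """
    seq = "".join(raw.split()).upper()
    return PeptideRecord(id=id, sequence=seq, label=label,
                         chirality_note=chirality_note)


@dataclass
class LabeledDataset:
    """Ordered collection of labeled peptide records for training.

    Training requires at least one record of each class; duplicate
    (sequence, label) pairs are rejected unless ``allow_duplicates``.
    Conflicting labels for the same sequence are always rejected when
    duplicates are disallowed.
    """

    records: List[PeptideRecord] = field(default_factory=list)
    provenance: str = ""

    @property
    def sequences(self) -> List[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> List[int]:
        return [r.label for r in self.records]  # type: ignore[misc]

    def class_counts(self) -> dict:
        pos = sum(1 for r in self.records if r.label == 1)
        return {1: pos, 0: len(self.records) - pos}

    def __len__(self) -> int:
        return len(self.records)


def make_dataset(records: Iterable[PeptideRecord], provenance: str = "",
                 allow_duplicates: bool = False,
                 require_both_classes: bool = True) -> LabeledDataset:
    """Assemble and validate a :class:`LabeledDataset`."""
    recs = list(records)
    for r in recs:
        if r.label is None:
            raise ValueError(f"record {r.id!r} has no label")
    if not allow_duplicates:
        seen: dict = {}
        for r in recs:
            if r.sequence in seen:
                if seen[r.sequence] != r.label:
                    raise ValueError("conflicting labels for duplicate "
                                     f"sequence {r.sequence!r}")
                raise ValueError("duplicate (sequence, label) pair "
                                 f"{r.sequence!r} (pass allow_duplicates=True "
                                 "to keep)")
            seen[r.sequence] = r.label
    if require_both_classes:
        counts = {r.label for r in recs}
        if counts != {0, 1}:
            raise ValueError("training requires both classes")
    return LabeledDataset(records=recs, provenance=provenance)
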