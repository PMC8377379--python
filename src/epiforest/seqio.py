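"""Peptide input, validation and fixed-width windowing.

Epitope candidate peptides are short (typically 5-24 residues).  All
downstream encoders consume a fixed-width window of ``DEFAULT_WIDTH`` (24)
positions; shorter peptides are padded *downstream* with a gap symbol so
that position ``m`` of the window always refers to residue ``m`` of the
original peptide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical residues, alphabetical by one-letter code.  This order is
#: the column order of every profile matrix and the pair order of the
#: composition encoders.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AMINO_ACIDS)
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Gap symbol used only for downstream padding; never accepted in input.
GAP: str = "-"

DEFAULT_WIDTH: int = 24

POSITIVE = "positive"
NEGATIVE = "negative"


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """Raised when a sequence contains a non-canonical residue letter."""


def _validate_sequence(seq_id: str, sequence: str) -> None:
    bad = sorted({c for c in sequence if c not in AA_SET})
    if bad:
        raise SequenceValidationError(
            f"sequence {seq_id!r} contains non-canonical residue letter(s): "
            + ", ".join(repr(c) for c in bad)
        )
    if len(sequence) < 1:
        raise SequenceValidationError(f"sequence {seq_id!r} is empty")


@dataclass(frozen=True)
class Peptide:
    """A raw peptide: identifier, residue string and optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        _validate_sequence(self.id, self.sequence)
        if self.label is not None and self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(
                f"label for {self.id!r} must be {POSITIVE!r} or {NEGATIVE!r}, "
                f"got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PaddedPeptide:
    """A peptide embedded in a fixed-width window, gap-padded downstream.

    Invariants: ``len(window) == width``; all gaps occur strictly after
    ``original_length``; ``window[:original_length]`` is the source sequence.
    """

    id: str
    window: str
    original_length: int
    label: str | None = None

    def __post_init__(self) -> None:
        body = self.window[: self.original_length]
        tail = self.window[self.original_length :]
        if GAP in body or set(tail) - {GAP}:
            raise ValueError(
                f"window for {self.id!r} is not downstream-padded: {self.window!r}"
            )
        _validate_sequence(self.id, body)

    @property
    def width(self) -> int:
        return len(self.window)

    @property
    def sequence(self) -> str:
        """The original (unpadded) residue string."""
        return self.window[: self.original_length]


def pad_peptide(
    p: Peptide, width: int = DEFAULT_WIDTH, truncate: bool = False
) -> PaddedPeptide:
    """Embed ``p`` in a ``width``-wide window, padding downstream with gaps.

    Sequences longer than ``width`` are rejected unless ``truncate`` is set,
    in which case only the first ``width`` residues are kept (with a logged
    warning).
    """
    seq = p.sequence
    if len(seq) > width:
        if not truncate:
            raise ValueError(
                f"sequence {p.id!r} has length {len(seq)} > window width {width} "
                "(pass truncate=True to keep the first residues)"
            )
        logger.warning(
            "truncating %s from %d to %d residues", p.id, len(seq), width
        )
        seq = seq[:width]
    return PaddedPeptide(
        id=p.id,
        window=seq + GAP * (width - len(seq)),
        original_length=len(seq),
        label=p.label,
    )


class LabeledDataset:
    """An ordered collection of padded peptides with class labels.

    For training use both classes must be non-empty and all ids unique.
    """

    def __init__(self, peptides: Sequence[PaddedPeptide], require_both_classes: bool = True):
        ids = [p.id for p in peptides]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peptide ids: {', '.join(dups)}")
        self.peptides: list[PaddedPeptide] = list(peptides)
        self.n_pos = sum(1 for p in peptides if p.label == POSITIVE)
        self.n_neg = sum(1 for p in peptides if p.label == NEGATIVE)
        if require_both_classes and (self.n_pos == 0 or self.n_neg == 0):
            raise ValueError(
                f"both classes must be non-empty (got {self.n_pos} positive, "
                f"{self.n_neg} negative)"
            )

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def labels(self):
        """Class labels as a 0/1 integer vector (1 = positive)."""
        import numpy as np

        return np.array(
            [1 if p.label == POSITIVE else 0 for p in self.peptides], dtype=int
        )

    @property
    def width(self) -> int:
        return self.peptides[0].width if self.peptides else DEFAULT_WIDTH

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.peptides[i] for i in indices], require_both_classes=False
        )


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from a FASTA file (ids = header up to first whitespace)."""
    path = Path(path)
    _precheck_fasta(path)
    peptides = []
    for rec in SeqIO.parse(str(path), "fasta"):
        peptides.append(Peptide(id=rec.id, sequence=str(rec.seq).upper()))
    return peptides


def _precheck_fasta(path: Path) -> None:
    # Bio.SeqIO silently skips leading junk; reject it with a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected a '>' header, got {line.strip()!r}"
                )
            return


def read_labeled_tsv(path: str | Path) -> list[Peptide]:
    """Read peptides from a TSV with columns ``id``, ``sequence``, ``label``."""
    import csv

    peptides = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "sequence", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            peptides.append(
                Peptide(id=row["id"], sequence=row["sequence"].upper(), label=row["label"])
            )
    return peptides


def load_labeled_dataset(
    pos_path: str | Path,
    neg_path: str | Path,
    width: int = DEFAULT_WIDTH,
    truncate: bool = False,
) -> LabeledDataset:
    """Load positive and negative FASTA files into one padded dataset.

    Ids must be unique across the two files; both classes must be non-empty.
    """
    pos = read_fasta(pos_path)
    neg = read_fasta(neg_path)
    if not pos:
        raise ValueError(f"positive class is empty ({pos_path})")
    if not neg:
        raise ValueError(f"negative class is empty ({neg_path})")
    shared = sorted({p.id for p in pos} & {p.id for p in neg})
    if shared:
        raise ValueError(
            "duplicate ids across positive and negative files: " + ", ".join(shared)
        )
    padded = [
        pad_peptide(Peptide(p.id, p.sequence, POSITIVE), width, truncate) for p in pos
    ] + [
        pad_peptide(Peptide(p.id, p.sequence, NEGATIVE), width, truncate) for p in neg
    ]
    return LabeledDataset(padded)
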