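"""Peptide records, labeled datasets, and FASTA / table I/O.

Anticancer-peptide (ACP) benchmarks come as two FASTA files — experimentally
validated ACPs (positives) and antimicrobial peptides without anticancer
activity (negatives).  This module reads and validates those files, assembles
them into a deduplicated :class:`LabeledDataset`, and writes feature tables
and prediction files.

The dataset contract mirrors the standard benchmark construction: the whole
dataset is the union of the positive and negative sets, and the two sets are
disjoint as sets of residue strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FastaParseError(ValueError):
    """A FASTA record is structurally malformed (e.g. empty sequence)."""


class ResidueError(ValueError):
    """A residue falls outside the 20-letter amino acid alphabet."""

    def __init__(self, peptide_id: str, position: int, character: str):
        self.peptide_id = peptide_id
        self.position = position  # 1-based
        self.character = character
        super().__init__(
            f"peptide {peptide_id!r}: invalid residue {character!r} at "
            f"position {position} (allowed: {AMINO_ACIDS})"
        )


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence with an identifier and optional binary label.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header up to the first whitespace).
    residues : str
        Sequence over the 20-letter alphabet; uppercased and validated.
    label : int or None
        1 for anticancer, 0 for non-anticancer, None if unknown.
    """

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self):
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise FastaParseError(f"peptide {self.id!r} has an empty sequence")
        for pos, ch in enumerate(residues, start=1):
            if ch not in _AA_SET:
                raise ResidueError(self.id, pos, ch)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0, 1 or None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def with_label(self, label: int) -> "Peptide":
        return Peptide(self.id, self.residues, label)


@dataclass
class LabeledDataset:
    """An ordered, deduplicated collection of labeled peptides.

    Invariants: every peptide is labeled; no two peptides share a residue
    string; the positive and negative subsets partition the dataset.
    """

    peptides: list[Peptide]
    name: str = "dataset"

    def __post_init__(self):
        seen: set[str] = set()
        for p in self.peptides:
            if p.label is None:
                raise ValueError(f"peptide {p.id!r} is unlabeled")
            if p.residues in seen:
                raise ValueError(
                    f"duplicate residue string in dataset: {p.residues!r}"
                )
            seen.add(p.residues)

    @property
    def n_total(self) -> int:
        return len(self.peptides)

    @property
    def n_positive(self) -> int:
        return sum(1 for p in self.peptides if p.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.peptides if p.label == 0)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.peptides], dtype=int)

    def positives(self) -> list[Peptide]:
        return [p for p in self.peptides if p.label == 1]

    def negatives(self) -> list[Peptide]:
        return [p for p in self.peptides if p.label == 0]

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    def __getitem__(self, i):
        return self.peptides[i]


def _parse_header_label(description: str) -> int | None:
    # alternative dialect: ">id ... |label=0" or ">id|label=1"
    for token in description.replace("|", " |").split():
        if token.startswith("|label="):
            value = token[len("|label="):]
            if value not in ("0", "1"):
                raise ValueError(f"bad label value in header: {token!r}")
            return int(value)
    return None


def read_fasta(path: str | Path, skip_invalid: bool = False) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Residues are uppercased; ids are the header up to the first whitespace.
    A ``|label=0`` / ``|label=1`` suffix in the header is honoured as an
    inline label.  Records containing residues outside the 20-letter
    alphabet raise :class:`ResidueError` naming the id, position and
    character, unless ``skip_invalid`` is set, in which case they are
    dropped with a logged warning.
    """
    path = Path(path)
    peptides: list[Peptide] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if not seq:
            raise FastaParseError(
                f"{path}: record {record.id!r} has an empty sequence"
            )
        label = _parse_header_label(record.description)
        try:
            peptides.append(Peptide(record.id, seq, label))
        except ResidueError as exc:
            if skip_invalid:
                logger.warning("skipping record %s: %s", record.id, exc)
            else:
                raise
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides as FASTA; labels (if any) are kept as a header suffix."""
    with open(path, "w") as fh:
        for p in peptides:
            header = p.id if p.label is None else f"{p.id} |label={p.label}"
            fh.write(f">{header}\n{p.residues}\n")


def assemble_dataset(
    positives: Sequence[Peptide],
    negatives: Sequence[Peptide],
    name: str = "dataset",
) -> LabeledDataset:
    """Assemble a labeled dataset from positive and negative peptides.

    Exact-duplicate residue strings are removed, keeping the first
    occurrence; a duplicate appearing in both classes keeps the positive
    copy (the experimentally validated ACP).  Each removal is logged.
    Similarity-based redundancy removal (CD-HIT style clustering) is out of
    scope — inputs are expected to be pre-filtered if that matters.
    """
    if not positives or not negatives:
        raise ValueError("both positive and negative collections must be non-empty")
    seen: dict[str, str] = {}
    kept: list[Peptide] = []
    for p in positives:
        if p.residues in seen:
            logger.warning(
                "dropping duplicate positive %s (same sequence as %s)",
                p.id, seen[p.residues],
            )
            continue
        seen[p.residues] = p.id
        kept.append(p.with_label(1))
    for p in negatives:
        if p.residues in seen:
            logger.warning(
                "dropping duplicate negative %s (same sequence as %s)",
                p.id, seen[p.residues],
            )
            continue
        seen[p.residues] = p.id
        kept.append(p.with_label(0))
    return LabeledDataset(kept, name=name)


def load_dataset(
    positive_fasta: str | Path,
    negative_fasta: str | Path,
    name: str | None = None,
    skip_invalid: bool = False,
) -> LabeledDataset:
    """Read a two-FASTA-file benchmark and assemble it into a dataset."""
    pos = read_fasta(positive_fasta, skip_invalid=skip_invalid)
    neg = read_fasta(negative_fasta, skip_invalid=skip_invalid)
    if name is None:
        name = Path(positive_fasta).stem
    return assemble_dataset(pos, neg, name=name)


def write_feature_table(features, path: str | Path) -> None:
    """Write feature vectors as CSV: id, label, f_000 ... f_NNN.

    All vectors must share one length; floats are written at full precision.
    """
    features = list(features)
    lengths = {len(f.values) for f in features}
    if len(lengths) > 1:
        raise ValueError(f"feature vectors have mixed lengths: {sorted(lengths)}")
    width = lengths.pop() if lengths else 0
    ndigits = max(3, len(str(max(width - 1, 0))))
    header = ["id", "label"] + [f"f_{i:0{ndigits}d}" for i in range(width)]
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for f in features:
            label = "" if f.label is None else str(f.label)
            row = [f.source_id, label] + [repr(float(v)) for v in f.values]
            fh.write(",".join(row) + "\n")


def write_predictions(
    ids: Sequence[str],
    scores: Sequence[float],
    predicted: Sequence[int],
    path: str | Path,
) -> None:
    """Write predictions as TSV: id, score, predicted_label."""
    if not (len(ids) == len(scores) == len(predicted)):
        raise ValueError("ids, scores and predicted labels must align")
    with open(path, "w") as fh:
        fh.write("id\tscore\tpredicted_label\n")
        for i, s, y in zip(ids, scores, predicted):
            fh.write(f"{i}\t{float(s):.10g}\t{int(y)}\n")
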