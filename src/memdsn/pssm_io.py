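"""Reading and writing protein sequences and PSI-BLAST ASCII PSSM profiles.

A PSSM is the L x 20 position-specific scoring matrix produced by iterative
PSI-BLAST search (typically 3 iterations, E-value 0.001 for membrane protein
profiling); each row holds the log-odds scores of the 20 amino acids at one
sequence position, in the fixed PSI-BLAST column order ``A R N D C Q E G H I
L K M F P S T W Y V``.  Only the first (log-odds) 20-column block of the
ASCII file is read; the weighted-percentage block and trailing statistics are
ignored.  Positions are 1-based in the file and 0-based in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

from memdsn.errors import FormatError, ValidationError

#: PSI-BLAST amino-acid column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Residues accepted in input sequences; X marks an unknown residue.
ACCEPTED_ALPHABET = frozenset(AA_ORDER) | {"X"}

N_CLASSES = 8  # the eight membrane protein types


@dataclass
class ProteinSequence:
    """A protein sequence with an optional membrane-protein-type label (1-8)."""

    id: str
    residues: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residue string")
        bad = set(self.residues) - ACCEPTED_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: illegal residue character(s) {sorted(bad)!r}"
            )
        if self.label is not None and not (1 <= int(self.label) <= N_CLASSES):
            raise ValidationError(
                f"sequence {self.id!r}: label {self.label} outside [1, {N_CLASSES}]"
            )

    @property
    def has_unknown_residues(self) -> bool:
        return "X" in self.residues

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PSSM:
    """An L x 20 position-specific scoring matrix with its protein identifier."""

    id: str
    scores: np.ndarray
    residues: Optional[str] = None  # residue letter column of the ASCII file
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValidationError(
                f"PSSM {self.id!r}: expected L x 20 matrix, got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValidationError(f"PSSM {self.id!r}: empty matrix")
        if self.residues is not None and len(self.residues) != self.scores.shape[0]:
            raise ValidationError(
                f"PSSM {self.id!r}: residue column length {len(self.residues)} != L={self.scores.shape[0]}"
            )

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


def parse_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into a list of :class:`ProteinSequence`, in file order.

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`FormatError` if the file holds no records and
    :class:`ValidationError` (naming the record) on illegal residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _is_data_row(tokens: list[str]) -> bool:
    return len(tokens) >= 2 and tokens[0].isdigit() and len(tokens[1]) == 1 and tokens[1].isalpha()


def parse_ascii_pssm(path: str | Path, id: Optional[str] = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file into a :class:`PSSM`.

    Only the first block of 20 log-odds values per data row is kept.  The
    protein id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not _is_data_row(tokens):
                if rows and not tokens:
                    break  # blank line after the matrix body: trailing statistics follow
                continue
            values = tokens[2:]
            if len(values) < 20:
                raise FormatError(
                    f"{path}:{lineno}: expected 20 log-odds values, found {len(values)}"
                )
            try:
                rows.append([float(v) for v in values[:20]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score field") from exc
            letters.append(tokens[1])
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    scores = np.array(rows)
    if np.allclose(scores, np.round(scores)):
        scores = scores.astype(np.int64)
    return PSSM(id=id or path.stem, scores=scores, residues="".join(letters))


def write_ascii_pssm(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect accepted by :func:`parse_ascii_pssm`.

    Scores round-trip exactly; the percentage block and trailing statistics of
    real PSI-BLAST output are omitted.
    """
    path = Path(path)
    residues = pssm.residues or "X" * pssm.length
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted observed "
            "percentages rounded down, information per position, and relative "
            "weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 11 + "  ".join(AA_ORDER) + "\n")
        for i in range(pssm.length):
            vals = " ".join(f"{v:6g}" for v in pssm.scores[i])
            fh.write(f"{i + 1:5d} {residues[i]}  {vals}\n")
        fh.write("\n")


def parse_labels(path: str | Path) -> dict[str, int]:
    """Read a tab-separated ``protein_id<TAB>class_index`` label file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'id<TAB>class', got {line!r}")
            try:
                cls = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: class index {parts[1]!r} not an integer") from exc
            if not (1 <= cls <= N_CLASSES):
                raise ValidationError(f"{path}:{lineno}: class {cls} outside [1, {N_CLASSES}]")
            labels[parts[0]] = cls
    if not labels:
        raise FormatError(f"{path}: no label rows found")
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, cls in labels.items():
            fh.write(f"{pid}\t{cls}\n")
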