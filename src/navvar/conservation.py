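"""Per-position conservedness from a multiple alignment of channel homologs.

The score for a reference position is the mean Gonnet-250 substitution score
between the reference residue and each other row's residue in the aligned
column; a row showing a gap contributes a fixed gap penalty (default: one
less than the smallest matrix entry).  High scores therefore mark columns
where the homologs agree with the reference residue or substitute it
conservatively.  Alignment construction itself (e.g. a Clustal run with the
same Gonnet matrix) is out of scope: readers accept aligned FASTA and
Clustal ``.aln`` files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .properties import AMINO_ACIDS, gonnet_matrix

GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Named aligned rows, one of which is the reference (SCN5A)."""

    names: list[str]
    rows: list[str]
    reference_name: str

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("alignment rows differ in length")
        if self.reference_name not in self.names:
            raise AlignmentError(
                f"reference {self.reference_name!r} not among rows")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.names.index(self.reference_name)]

    @property
    def reference_length(self) -> int:
        return sum(c != GAP for c in self.reference_row)

    @classmethod
    def from_file(cls, path: str | Path, reference_name: str,
                  fmt: str | None = None) -> "Alignment":
        """Read an aligned FASTA or Clustal file (format from extension)."""
        path = Path(path)
        if fmt is None:
            fmt = "clustal" if path.suffix in {".aln", ".clustal"} else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls(names=[rec.id for rec in aln],
                   rows=[str(rec.seq).upper() for rec in aln],
                   reference_name=reference_name)


def map_columns_to_reference(alignment: Alignment) -> list[int | None]:
    """Per-column 1-based reference position, or None where the reference
    row has a gap."""
    mapping: list[int | None] = []
    pos = 0
    for ch in alignment.reference_row:
        if ch == GAP:
            mapping.append(None)
        else:
            pos += 1
            mapping.append(pos)
    return mapping


def default_gap_penalty(matrix=None) -> float:
    """One less than the smallest matrix entry, so a gap scores below any
    residue pair."""
    if matrix is None:
        matrix = gonnet_matrix()
    return float(matrix.values.min()) - 1.0


def conservedness_profile(
    alignment: Alignment,
    matrix=None,
    gap_penalty: float | None = None,
) -> np.ndarray:
    """Conservedness score for every reference position (1..reference_length).

    Mean over non-reference rows of Gonnet-250(reference residue, row
    residue), with ``gap_penalty`` for gap rows.  Deterministic and invariant
    to row order.
    """
    if matrix is None:
        matrix = gonnet_matrix()
    if gap_penalty is None:
        gap_penalty = default_gap_penalty(matrix)
    others = [row for name, row in zip(alignment.names, alignment.rows)
              if name != alignment.reference_name]
    if not others:
        raise AlignmentError("alignment needs at least one non-reference row")
    ref_row = alignment.reference_row
    scores = []
    for col, ref_aa in enumerate(ref_row):
        if ref_aa == GAP:
            continue
        if ref_aa not in AMINO_ACIDS:
            raise AlignmentError(
                f"nonstandard reference residue {ref_aa!r} in column {col + 1}")
        total = 0.0
        for row in others:
            ch = row[col]
            if ch == GAP or ch not in AMINO_ACIDS:
                total += gap_penalty
            else:
                total += float(matrix.loc[ref_aa, ch])
        scores.append(total / len(others))
    return np.asarray(scores)


def conservedness(alignment: Alignment, position: int, matrix=None,
                  gap_penalty: float | None = None) -> float:
    """Score for one 1-based reference position."""
    n = alignment.reference_length
    if not 1 <= position <= n:
        raise AlignmentError(f"position {position} unmapped (1..{n})")
    return float(conservedness_profile(alignment, matrix, gap_penalty)[position - 1])
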