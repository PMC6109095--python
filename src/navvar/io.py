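"""Shared readers/writers and small parsing utilities."""

from __future__ import annotations

import re
from pathlib import Path

from Bio import SeqIO

from .ep import Variant, isoform2_to_isoform1


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named sequences in file order; rejects empty files and empty records."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # malformed record
        raise ParseError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).strip()
        if not rec.id:
            raise ParseError(f"{path}: record with empty name")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in out:
            raise ParseError(f"{path}: duplicate record name {rec.id!r}")
        out[rec.id] = seq.upper()
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


_VARIANT_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def parse_variant(token: str, isoform: int = 1) -> Variant:
    """Parse "H558R" or "p.H558R" into a :class:`Variant`; isoform-2
    numbering is shifted onto isoform 1."""
    m = _VARIANT_RE.match(token.strip())
    if not m:
        raise ParseError(f"cannot parse variant token {token!r}")
    from_aa, pos, to_aa = m.group(1), int(m.group(2)), m.group(3)
    if isoform == 2:
        pos = isoform2_to_isoform1(pos)
    elif isoform != 1:
        raise ParseError(f"unknown isoform {isoform}")
    return Variant(pos, from_aa, to_aa)
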