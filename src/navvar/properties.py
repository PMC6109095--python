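"""Amino-acid physico-chemical property tables and pairwise matrices.

Seven scalar tables (average residue mass, percentage buried, van der Waals
volume, polarity ranking, charge, hydrophobicity ranking, alpha-helix
propensity) ship as a versioned TSV; substitution features are signed deltas,
new residue minus old.  Two pairwise matrices complement them: the Grantham
physico-chemical distance (symmetric, zero diagonal) and the Gonnet-250
log-odds substitution matrix, a population-based substitution likelihood.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SCALAR_TABLES = ("mass", "buried_pct", "vdw_volume", "polarity",
                 "charge", "hydrophobicity", "helix_propensity")


class PropertyError(ValueError):
    """Raised for nonstandard residues or malformed property data."""


@dataclass(frozen=True)
class PropertyTable:
    """One per-residue property: exactly one value per standard residue."""

    name: str
    values: dict  # residue -> float
    kind: str = "scalar-delta"

    def __post_init__(self):
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise PropertyError(
                f"table {self.name}: missing residues {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        _check_aa(aa)
        return self.values[aa]


def _check_aa(aa: str) -> None:
    if aa not in AMINO_ACIDS:
        raise PropertyError(f"nonstandard residue code {aa!r}")


def _data_text(filename: str) -> str:
    ref = resources.files("navvar.data") / filename
    text = ref.read_text()
    _verify_checksum(filename, text)
    return text


def _verify_checksum(filename: str, text: str) -> None:
    sums = (resources.files("navvar.data") / "CHECKSUMS.sha256").read_text()
    expected = {line.split()[1]: line.split()[0]
                for line in sums.splitlines() if line.strip()}
    digest = hashlib.sha256(text.encode()).hexdigest()
    if expected.get(filename) != digest:
        raise PropertyError(f"data file {filename} fails checksum verification")


def load_scalar_tables() -> dict[str, PropertyTable]:
    """The seven shipped scalar property tables, keyed by name."""
    lines = [l for l in _data_text("aa_properties.tsv").splitlines()
             if l and not l.startswith("#")]
    header = lines[0].split("\t")
    frame = pd.DataFrame([l.split("\t") for l in lines[1:]], columns=header)
    frame = frame.set_index("aa").astype(float)
    tables = {}
    for name in SCALAR_TABLES:
        if name not in frame.columns:
            raise PropertyError(f"property column {name} missing from data file")
        tables[name] = PropertyTable(name, frame[name].to_dict())
    return tables


def grantham_matrix() -> pd.DataFrame:
    """Grantham distance matrix (20x20, symmetric, zero diagonal)."""
    lines = [l for l in _data_text("grantham.tsv").splitlines()
             if l and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    rows = [l.split("\t") for l in lines[1:]]
    m = pd.DataFrame([r[1:] for r in rows], index=[r[0] for r in rows],
                     columns=header).astype(int)
    if not np.array_equal(m.values, m.values.T) or np.any(np.diag(m.values)):
        raise PropertyError("Grantham matrix must be symmetric with zero diagonal")
    return m


def gonnet_matrix() -> pd.DataFrame:
    """Gonnet-250 log-odds substitution matrix as a 20x20 frame."""
    m = substitution_matrices.load("GONNET1992")
    aas = list(AMINO_ACIDS)
    data = [[float(m[a, b]) for b in aas] for a in aas]
    return pd.DataFrame(data, index=aas, columns=aas)


def delta(table: PropertyTable, from_aa: str, to_aa: str) -> float:
    """Signed property change of a substitution: new minus old."""
    if table.kind != "scalar-delta":
        raise PropertyError(f"table {table.name} is not a scalar table")
    return table[to_aa] - table[from_aa]


def pairwise(matrix: pd.DataFrame, from_aa: str, to_aa: str) -> float:
    """Pairwise matrix lookup (Grantham distance or Gonnet score)."""
    _check_aa(from_aa)
    _check_aa(to_aa)
    return float(matrix.loc[from_aa, to_aa])
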