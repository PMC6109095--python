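"""Exhaustive enumeration of single-nucleotide missense substitutions.

Every codon of a coding sequence has nine single-nucleotide neighbours; those
that change the encoded residue (excluding stop-gains and synonymous changes)
form the set of reachable missense substitutions.  Two counts matter: the
with-duplicates total (distinct nucleotide changes, so the same amino-acid
switch reached through different bases counts repeatedly) and the unique
total (distinct (position, target-residue) pairs).  The census also yields
the 20x20 matrix of reachable x->y transitions, the expected transition
frequencies under unbiased nucleotide change, and observed/expected ratios
for a set of reported substitutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_BASES = "ACGT"

# standard nuclear genetic code; human-only scope
CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class SequenceError(ValueError):
    """Raised for malformed coding sequences or mismatched observations."""


@dataclass
class CodonSubstitutions:
    """Reachable missense substitutions for one codon position."""

    position: int              # 1-based residue position
    codon: str
    from_aa: str
    #: (to_aa, number of distinct nucleotide changes producing it)
    targets: dict[str, int] = field(default_factory=dict)

    @property
    def with_duplicates(self) -> int:
        return sum(self.targets.values())

    @property
    def unique(self) -> int:
        return len(self.targets)


@dataclass
class SubstitutionCensus:
    """Census of all single-nucleotide missense substitutions in a CDS."""

    protein: str
    per_codon: list[CodonSubstitutions]
    total_with_duplicates: int
    total_unique: int
    #: with-duplicates counts of x->y transitions, indexed by AA_ORDER
    transition_matrix: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.per_codon)

    @property
    def per_position_rate(self) -> float:
        """Unique reachable substitutions per residue position."""
        return self.total_unique / self.n_positions


def _codon_targets(codon: str) -> dict[str, int]:
    ref = CODON_TABLE[codon]
    targets: dict[str, int] = {}
    for i in range(3):
        for base in _BASES:
            if base == codon[i]:
                continue
            alt = CODON_TABLE[codon[:i] + base + codon[i + 1:]]
            if alt == "*" or alt == ref:
                continue  # stop-gain / synonymous
            targets[alt] = targets.get(alt, 0) + 1
    return targets


def enumerate_missense(cds: str) -> SubstitutionCensus:
    """Enumerate every missense substitution reachable by one nucleotide
    change in ``cds``.

    The CDS need not begin with a start codon.  Internal stop codons produce
    a warning (their position is skipped); non-ACGT characters or a length
    not divisible by 3 are errors.
    """
    seq = cds.upper().replace("\n", "").replace(" ", "")
    for i, ch in enumerate(seq):
        if ch not in _BASES:
            raise SequenceError(f"non-ACGT character {ch!r} at position {i + 1}")
    if len(seq) % 3 != 0:
        raise SequenceError(f"CDS length {len(seq)} not divisible by 3")
    per_codon: list[CodonSubstitutions] = []
    protein = []
    matrix = np.zeros((20, 20), dtype=int)
    pos = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        ref = CODON_TABLE[codon]
        if ref == "*":
            if i + 3 < len(seq):
                warnings.warn(f"internal stop codon {codon} at codon {i // 3 + 1}")
            continue
        pos += 1
        targets = _codon_targets(codon)
        per_codon.append(CodonSubstitutions(pos, codon, ref, targets))
        protein.append(ref)
        for to_aa, count in targets.items():
            matrix[AA_INDEX[ref], AA_INDEX[to_aa]] += count
    if not per_codon:
        raise SequenceError("empty coding sequence")
    return SubstitutionCensus(
        protein="".join(protein),
        per_codon=per_codon,
        total_with_duplicates=int(matrix.sum()),
        total_unique=sum(c.unique for c in per_codon),
        transition_matrix=matrix,
    )


def expected_transition_frequencies(census: SubstitutionCensus) -> np.ndarray:
    """20x20 matrix of transition proportions expected under unbiased
    single-nucleotide change; entries sum to 1."""
    total = census.transition_matrix.sum()
    if total == 0:
        raise SequenceError("census is empty")
    return census.transition_matrix / total


def observed_expected_ratio(
    observed: list[tuple[int, str, str]],
    census: SubstitutionCensus,
) -> np.ndarray:
    """Ratio of observed to expected x->y transition proportions.

    ``observed`` holds (position, from_aa, to_aa) triples on the census
    protein's numbering.  Cells whose expected proportion is zero are
    returned as NaN (undefined); an observed substitution not reachable by
    one nucleotide change raises a warning and contributes to such a cell.
    A ``from_aa`` that contradicts the reference sequence is an error.
    """
    expected = expected_transition_frequencies(census)
    counts = np.zeros((20, 20), dtype=float)
    reachable = {(c.position, t) for c in census.per_codon for t in c.targets}
    for position, from_aa, to_aa in observed:
        if not 1 <= position <= len(census.protein):
            raise SequenceError(f"position {position} outside protein")
        ref = census.protein[position - 1]
        if from_aa != ref:
            raise SequenceError(
                f"reference mismatch at {position}: expected {ref}, got {from_aa}")
        if (position, to_aa) not in reachable:
            warnings.warn(
                f"substitution {from_aa}{position}{to_aa} not reachable by a "
                "single nucleotide change")
        counts[AA_INDEX[from_aa], AA_INDEX[to_aa]] += 1
    if observed:
        counts /= len(observed)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = counts / expected
    ratio[expected == 0] = np.nan
    return ratio


def census_frame(census: SubstitutionCensus):
    """Long-form table of the census: one row per (position, target)."""
    import pandas as pd

    rows = [
        (c.position, c.from_aa, to_aa, n)
        for c in census.per_codon
        for to_aa, n in sorted(c.targets.items())
    ]
    return pd.DataFrame(
        rows, columns=["position", "from_aa", "to_aa", "n_nt_changes"])
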