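"""Membrane topology of the Nav1.5 channel protein.

The 2016-residue pore-forming alpha-subunit is modelled as an ordered list of
regions tiling positions 1..length: the cytoplasmic N- and C-termini, four
homologous domains of six transmembrane segments (S1-S6) with their
intra-domain loops, and the three cytoplasmic inter-domain linkers.  The
voltage-sensing segment is S4 of each domain; the S5-S6 loop folds back to
form the pore and faces the extracellular side.

Region boundaries are not hard-coded: they ship as an editable TSV config
(``data/scn5a_topology.tsv``) validated at load, so alternative annotations
are drop-in replacements.  Distances are residue counts along the chain, not
spatial distances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

REGION_KINDS = ("terminus", "segment", "segment-linker", "domain-linker")
SIDES = ("cytoplasmic", "transmembrane", "extracellular")

#: selector for the pore-forming S5-S6 loop class
PORE = "pore"

_SEGMENT_CLASS = re.compile(r"^S([1-6])$")
_SEGLINK_CLASS = re.compile(r"^L([1-5])([2-6])$")


class TopologyError(ValueError):
    """Raised for invalid topology configs or unknown region selectors."""


@dataclass(frozen=True)
class Region:
    """One contiguous stretch of the protein chain.

    ``domain`` and ``segment`` are 1-based indices, 0 where not applicable
    (termini and inter-domain linkers have domain 0; loops have segment 0).
    """

    name: str
    kind: str
    domain: int
    segment: int
    start: int  # 1-based, inclusive
    end: int    # 1-based, inclusive
    side: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise TopologyError(f"unknown region kind {self.kind!r}")
        if self.side not in SIDES:
            raise TopologyError(f"unknown side {self.side!r}")
        if self.start > self.end:
            raise TopologyError(
                f"region {self.name}: start {self.start} > end {self.end}")
        if self.kind == "segment" and self.side != "transmembrane":
            raise TopologyError(
                f"segment {self.name} must be transmembrane, got {self.side}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def is_voltage_sensor(self) -> bool:
        return self.kind == "segment" and self.segment == 4

    @property
    def is_pore_linker(self) -> bool:
        """The S5-S6 loop that folds back into the membrane to form the pore."""
        return self.kind == "segment-linker" and self.name.endswith("L56")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


class ProteinTopology:
    """Ordered, gap-free tiling of residues 1..length by :class:`Region`."""

    def __init__(self, length: int, regions: Sequence[Region]):
        self.length = int(length)
        self.regions = tuple(regions)
        self._by_name = {r.name: r for r in self.regions}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_table(cls, path: str | Path) -> "ProteinTopology":
        """Load a topology from a TSV config; reject invalid files."""
        length = None
        rows = []
        header = None
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if line.startswith("#"):
                m = re.search(r"length\s*=\s*(\d+)", line)
                if m:
                    length = int(m.group(1))
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = fields
                expected = ["name", "kind", "domain", "segment",
                            "start", "end", "side"]
                if header != expected:
                    raise TopologyError(
                        f"{path}: bad header {header!r}, expected {expected!r}")
                continue
            if len(fields) != len(header):
                raise TopologyError(f"{path}:{lineno}: wrong column count")
            rows.append(dict(zip(header, fields)))
        if length is None:
            raise TopologyError(f"{path}: missing '# length=' directive")
        regions = [
            Region(name=r["name"], kind=r["kind"], domain=int(r["domain"]),
                   segment=int(r["segment"]), start=int(r["start"]),
                   end=int(r["end"]), side=r["side"])
            for r in rows
        ]
        topo = cls(length, regions)
        problems = topo.validate()
        if problems:
            raise TopologyError(f"{path}: invalid topology: " + "; ".join(problems))
        return topo

    @classmethod
    def default(cls) -> "ProteinTopology":
        """The shipped Nav1.5 (SCN5A isoform 1) topology."""
        with resources.as_file(
                resources.files("navvar.data") / "scn5a_topology.tsv") as p:
            return cls.from_table(p)

    # -- queries -----------------------------------------------------------

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside protein range 1..{self.length}")

    def region_of(self, position: int) -> Region:
        """The unique region containing ``position`` (1-based)."""
        self._check_position(position)
        for region in self.regions:
            if position in region:
                return region
        raise TopologyError(f"no region contains position {position}")

    def side_of(self, position: int) -> str:
        return self.region_of(position).side

    def matching_regions(self, selector: str) -> list[Region]:
        """Regions matched by a name ("D1S4", "L34") or class selector.

        Class selectors: "S1".."S6" (that segment in every domain), "pore"
        (every S5-S6 loop), kind names, and "N"/"C" (exact region names).
        """
        if selector in self._by_name:
            return [self._by_name[selector]]
        if selector == PORE:
            out = [r for r in self.regions if r.is_pore_linker]
        elif selector in REGION_KINDS:
            out = [r for r in self.regions if r.kind == selector]
        elif m := _SEGMENT_CLASS.match(selector):
            idx = int(m.group(1))
            out = [r for r in self.regions
                   if r.kind == "segment" and r.segment == idx]
        elif m := _SEGLINK_CLASS.match(selector):
            out = [r for r in self.regions
                   if r.kind == "segment-linker"
                   and r.name.endswith("L" + m.group(1) + m.group(2))]
        else:
            out = []
        if not out:
            raise TopologyError(f"unknown region selector {selector!r}")
        return out

    def distance_to(self, position: int, selector: str) -> int:
        """Residue-count distance from ``position`` to the nearest matching
        region: 0 inside a match, else residues to the nearest boundary
        (adjacent residue = 1)."""
        self._check_position(position)
        best = None
        for region in self.matching_regions(selector):
            if position in region:
                return 0
            d = min(abs(position - region.start), abs(position - region.end))
            best = d if best is None else min(best, d)
        return best

    def region_class(self, region: Region) -> str:
        """Class label pooling equivalent regions across domains
        (D1S4..D4S4 -> "S4"; D1L56.. -> "L56"; others keep their name)."""
        if region.kind == "segment":
            return f"S{region.segment}"
        if region.kind == "segment-linker":
            return region.name[2:]  # strip the D<i> prefix
        return region.name

    def domain_label(self, region: Region) -> str:
        """Domain-level label: D1..D4, or the region's own name for
        termini and inter-domain linkers."""
        return f"D{region.domain}" if region.domain else region.name

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty iff valid)."""
        problems: list[str] = []
        regs = self.regions
        if not regs:
            return ["no regions"]
        if regs[0].start != 1:
            problems.append(f"gap: first region starts at {regs[0].start}, not 1")
        if regs[-1].end != self.length:
            problems.append(
                f"gap: last region ends at {regs[-1].end}, not {self.length}")
        for a, b in zip(regs, regs[1:]):
            if b.start > a.end + 1:
                problems.append(f"gap between {a.name} and {b.name}")
            elif b.start <= a.end:
                problems.append(f"overlap between {a.name} and {b.name}")
        if regs[0].kind != "terminus" or regs[0].name != "N":
            problems.append("first region is not the N-terminus")
        if regs[-1].kind != "terminus" or regs[-1].name != "C":
            problems.append("last region is not the C-terminus")
        seen = set()
        for r in regs:
            if r.name in seen:
                problems.append(f"duplicate region name {r.name}")
            seen.add(r.name)
        segments = [(r.domain, r.segment) for r in regs if r.kind == "segment"]
        expected = {(d, s) for d in range(1, 5) for s in range(1, 7)}
        if set(segments) != expected or len(segments) != 24:
            problems.append("segments do not form 4 domains x 6 segments")
        n_dl = sum(r.kind == "domain-linker" for r in regs)
        if n_dl != 3:
            problems.append(f"expected 3 inter-domain linkers, found {n_dl}")
        return problems

    def __repr__(self) -> str:
        return (f"ProteinTopology(length={self.length}, "
                f"regions={len(self.regions)})")


def validate_topology(topology: ProteinTopology) -> list[str]:
    """Functional alias for :meth:`ProteinTopology.validate`."""
    return topology.validate()
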