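"""Relative mutation densities and per-region outcome tallies.

The density of a region is its count of unique amino-acid substitutions
(distinct (position, target) pairs; two targets at one position count twice)
divided by region length; subtracting the gene-wide density gives the
relative density, positive where mutations cluster and negative where they
are scarce.  Relative densities obey an exact zero-sum identity:
sum over regions of relative_density x length = 0.

Outcome tallies count, per region, how many resolved variants affect each
outcome; a variant affecting k outcomes contributes once to each of the k
tallies.
"""

from __future__ import annotations

import pandas as pd

from .ep import OUTCOMES, VariantRecord
from .topology import ProteinTopology

GROUPINGS = ("region", "domain", "region-class")


class DensityError(ValueError):
    pass


def _group_label(topology: ProteinTopology, region, grouping: str) -> str:
    if grouping == "region":
        return region.name
    if grouping == "domain":
        return topology.domain_label(region)
    if grouping == "region-class":
        return topology.region_class(region)
    raise DensityError(f"unknown grouping {grouping!r}")


def _group_lengths(topology: ProteinTopology, grouping: str) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for region in topology.regions:
        label = _group_label(topology, region, grouping)
        lengths[label] = lengths.get(label, 0) + region.length
    return lengths


def relative_density(
    substitutions,
    topology: ProteinTopology,
    grouping: str = "region",
) -> pd.DataFrame:
    """Per-group mutation counts, densities and relative densities.

    ``substitutions`` is an iterable of (position, to_aa) pairs; duplicates
    are collapsed (unique substitutions are counted).  The gene-wide density
    is stored in ``frame.attrs["gene_density"]``.
    """
    unique = set()
    for position, to_aa in substitutions:
        if not 1 <= position <= topology.length:
            raise DensityError(
                f"position {position} outside protein range 1..{topology.length}")
        unique.add((position, to_aa))
    lengths = _group_lengths(topology, grouping)
    counts = {label: 0 for label in lengths}
    for position, _ in unique:
        region = topology.region_of(position)
        counts[_group_label(topology, region, grouping)] += 1
    gene_density = len(unique) / topology.length
    frame = pd.DataFrame({
        "group": list(lengths),
        "count": [counts[g] for g in lengths],
        "length": [lengths[g] for g in lengths],
    })
    frame["density"] = frame["count"] / frame["length"]
    frame["relative_density"] = frame["density"] - gene_density
    frame.attrs["gene_density"] = gene_density
    return frame


def outcome_tally(
    records: list[VariantRecord],
    topology: ProteinTopology,
    grouping: str = "region",
    include_unchanged: bool = False,
) -> pd.DataFrame:
    """Per-group counts of variants affecting each outcome.

    A variant affecting several outcomes is counted once per affected
    outcome.  With ``include_unchanged``, variants whose overall label is
    'unaffected' add to an extra ``unchanged`` column.
    """
    lengths = _group_lengths(topology, grouping)
    columns = list(OUTCOMES) + (["unchanged"] if include_unchanged else [])
    tally = {label: {c: 0 for c in columns} for label in lengths}
    for record in records:
        region = topology.region_of(record.variant.position)
        label = _group_label(topology, region, grouping)
        for outcome in OUTCOMES:
            if record.labels[outcome] == "affected":
                tally[label][outcome] += 1
        if include_unchanged and record.labels["changed_unchanged"] == "unaffected":
            tally[label]["unchanged"] += 1
    frame = pd.DataFrame.from_dict(tally, orient="index")[columns]
    frame.index.name = "group"
    return frame.reset_index()
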