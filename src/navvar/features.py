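"""Per-variant feature vectors: topology, property deltas, conservedness.

Positional features come from the topology (membrane side, region kind,
region type, residue-count distances to configured region classes);
substitution features are new-minus-old property deltas plus Grantham
distance and Gonnet-250 score; conservedness is the alignment-derived score
of the position.  Categorical features use fixed vocabularies and can be
one-hot encoded for numeric-only learners.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import properties as props
from .ep import Variant
from .topology import ProteinTopology

#: default region classes for distance features; covers every region named
#: in the feature set (nearest segment of each class, the pore loop, the
#: inter-domain linkers and both termini)
DEFAULT_DISTANCE_CLASSES = ("S1", "S2", "S3", "S4", "S5", "S6", "pore",
                            "L12", "L23", "L34", "N", "C")

CATEGORICAL_FEATURES = ("side", "segment_type", "region_type")


class FeatureError(ValueError):
    pass


def featurize(
    variant: Variant,
    topology: ProteinTopology,
    tables: dict[str, props.PropertyTable] | None = None,
    grantham: pd.DataFrame | None = None,
    gonnet: pd.DataFrame | None = None,
    conservation_scores: np.ndarray | None = None,
    reference: str | None = None,
    distance_classes: tuple[str, ...] = DEFAULT_DISTANCE_CLASSES,
) -> dict:
    """Deterministic feature vector for one substitution.

    ``reference`` (the protein sequence) is optional; when given, the
    variant's from_aa must match it.  ``conservation_scores`` is the
    per-position profile; absent, the conservedness feature is NaN.
    """
    if tables is None:
        tables = props.load_scalar_tables()
    if grantham is None:
        grantham = props.grantham_matrix()
    if gonnet is None:
        gonnet = props.gonnet_matrix()
    if reference is not None:
        ref_aa = reference[variant.position - 1]
        if ref_aa != variant.from_aa:
            raise FeatureError(
                f"reference mismatch at {variant.position}: sequence has "
                f"{ref_aa}, variant claims {variant.from_aa}")
    region = topology.region_of(variant.position)
    vector: dict = {
        "side": region.side,
        "segment_type": region.kind,
        "region_type": topology.region_class(region),
    }
    for cls in distance_classes:
        vector[f"dist_{cls}"] = topology.distance_to(variant.position, cls)
    for name, table in tables.items():
        vector[f"d_{name}"] = props.delta(table, variant.from_aa, variant.to_aa)
    vector["grantham"] = props.pairwise(grantham, variant.from_aa, variant.to_aa)
    vector["gonnet"] = props.pairwise(gonnet, variant.from_aa, variant.to_aa)
    if conservation_scores is not None:
        vector["conservedness"] = float(conservation_scores[variant.position - 1])
    else:
        vector["conservedness"] = float("nan")
    return vector


def feature_table(
    variants: pd.DataFrame,
    topology: ProteinTopology,
    conservation_scores: np.ndarray | None = None,
    reference: str | None = None,
    distance_classes: tuple[str, ...] = DEFAULT_DISTANCE_CLASSES,
) -> pd.DataFrame:
    """Feature matrix for a variant frame with position/from_aa/to_aa columns.

    Column order is stable; a ``label`` column, if present, is carried
    through unchanged.
    """
    if conservation_scores is None:
        warnings.warn("no conservation profile: conservedness feature absent")
    tables = props.load_scalar_tables()
    grantham = props.grantham_matrix()
    gonnet = props.gonnet_matrix()
    rows = []
    for row in variants.itertuples(index=False):
        variant = Variant(int(row.position), row.from_aa, row.to_aa)
        vector = featurize(variant, topology, tables, grantham, gonnet,
                           conservation_scores, reference, distance_classes)
        if hasattr(row, "label"):
            vector["label"] = row.label
        rows.append(vector)
    frame = pd.DataFrame(rows)
    if conservation_scores is None:
        frame = frame.drop(columns=["conservedness"])
    return frame


def one_hot(frame: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode the categorical features for numeric-only learners."""
    cats = [c for c in CATEGORICAL_FEATURES if c in frame.columns]
    return pd.get_dummies(frame, columns=cats, dtype=float)


def write_feature_table(frame: pd.DataFrame, path) -> None:
    """Delimited export with a stable column order and header manifest."""
    with open(path, "w") as fh:
        fh.write("# feature table; columns: " + ", ".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", index=False)
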