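"""Electrophysiology (EP) report store and per-variant label resolution.

One :class:`EPReport` is one publication's whole-cell I_Na characterization
of one variant under stated conditions (cell type, alpha-subunit clone,
beta1 co-expression).  Four qualitative outcomes are tracked per report —
whether the channel conducts any current, and whether activation,
inactivation (incl. recovery) or the late component were affected — each
recorded as affected / unaffected / not_measured.  Midpoint shifts of
(in)activation are kept in mV where reported.

Variants measured by several studies are resolved by majority vote per
outcome (ties are excluded); quantitative shifts come from one preferred
report chosen by an experimental-conditions cascade (beta1 co-expression,
then isoform-2 'b' alpha-subunit, then HEK cells, then most recent year).
"""

from __future__ import annotations

import math
import sqlite3
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from sklearn.model_selection import train_test_split as _sk_split

#: qualitative outcome fields of a report, fixed vocabulary
OUTCOMES = ("zero_current", "activation", "inactivation", "late")
#: classification problems: the four outcomes plus their disjunction
PROBLEMS = ("changed_unchanged",) + OUTCOMES

FINDINGS = ("affected", "unaffected", "not_measured")
CELL_TYPES = ("HEK", "oocyte", "CHO", "COS", "myocyte", "unknown")
ALPHA_SUBUNITS = ("a", "a*", "b", "b*", "unknown")
BETA1 = ("yes", "no", "unknown")

SHIFT_BINS = ("neg", "mid", "pos")


class EPDataError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """One amino-acid substitution on isoform-1 numbering."""

    position: int
    from_aa: str
    to_aa: str

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class EPReport:
    """One published EP measurement of one variant."""

    variant: Variant
    study_id: str
    year: int
    cell_type: str = "unknown"
    alpha_subunit: str = "unknown"
    beta1: str = "unknown"
    findings: dict = field(default_factory=dict)
    act_shift_mV: float | None = None
    inact_shift_mV: float | None = None

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise EPDataError(f"unknown cell type {self.cell_type!r}")
        if self.alpha_subunit not in ALPHA_SUBUNITS:
            raise EPDataError(f"unknown alpha-subunit {self.alpha_subunit!r}")
        if self.beta1 not in BETA1:
            raise EPDataError(f"unknown beta1 flag {self.beta1!r}")
        findings = dict(self.findings)
        for outcome in OUTCOMES:
            findings.setdefault(outcome, "not_measured")
        unknown = set(findings) - set(OUTCOMES)
        if unknown:
            raise EPDataError(f"unknown outcome fields {sorted(unknown)}")
        for outcome, value in findings.items():
            if value not in FINDINGS:
                raise EPDataError(f"bad finding {value!r} for {outcome}")
        if self.act_shift_mV is not None and findings["activation"] == "not_measured":
            raise EPDataError("activation shift given but activation not measured")
        if self.inact_shift_mV is not None and findings["inactivation"] == "not_measured":
            raise EPDataError("inactivation shift given but inactivation not measured")
        object.__setattr__(self, "findings", findings)

    def finding(self, outcome: str) -> str:
        return self.findings[outcome]


@dataclass
class VariantRecord:
    """Per-variant resolved labels after majority voting across reports."""

    variant: Variant
    labels: dict            # outcome/problem -> affected/unaffected/excluded_tie/unknown
    shift_bins: dict        # "activation"/"inactivation" -> neg/mid/pos or None
    preferred_study: str    # report chosen for quantitative data
    n_reports: int


def isoform2_to_isoform1(position: int) -> int:
    """Shift isoform-2 (Q1077del, 2015 aa) numbering onto isoform 1."""
    return position + 1 if position >= 1077 else position


def _check_same_variant(reports: list[EPReport]) -> Variant:
    if not reports:
        raise EPDataError("empty report list")
    variants = {r.variant for r in reports}
    if len(variants) > 1:
        raise EPDataError(f"reports mix variants: {sorted(map(str, variants))}")
    return reports[0].variant


def majority_vote(reports: list[EPReport], outcome: str) -> str:
    """Resolve one outcome across reports of one variant.

    Only measured reports vote; a strict majority wins, equal nonzero counts
    give ``excluded_tie``, and no measured report gives ``unknown``.
    """
    _check_same_variant(reports)
    if outcome not in OUTCOMES:
        raise EPDataError(f"unknown outcome {outcome!r}")
    votes = Counter(r.finding(outcome) for r in reports
                    if r.finding(outcome) != "not_measured")
    n_aff, n_un = votes["affected"], votes["unaffected"]
    if n_aff == n_un == 0:
        return "unknown"
    if n_aff == n_un:
        return "excluded_tie"
    return "affected" if n_aff > n_un else "unaffected"


def discretize_shift(shift_mV: float) -> str:
    """Bin a midpoint shift: (-inf,-3) -> neg, [-3,3] -> mid, (3,inf) -> pos."""
    if not math.isfinite(shift_mV):
        raise EPDataError(f"non-finite shift {shift_mV!r}")
    if shift_mV < -3:
        return "neg"
    if shift_mV > 3:
        return "pos"
    return "mid"


def select_preferred_report(reports: list[EPReport]) -> EPReport:
    """Pick one report by experimental conditions: beta1 co-expression,
    then alpha-subunit 'b', then HEK cells, then most recent year.  Each
    filter applies only if it leaves at least one report; remaining ties
    break deterministically on study_id."""
    _check_same_variant(reports)
    pool = list(reports)
    for keep in (lambda r: r.beta1 == "yes",
                 lambda r: r.alpha_subunit == "b",
                 lambda r: r.cell_type == "HEK"):
        filtered = [r for r in pool if keep(r)]
        if filtered:
            pool = filtered
    best_year = max(r.year for r in pool)
    pool = [r for r in pool if r.year == best_year]
    return min(pool, key=lambda r: r.study_id)


def resolve_variants(reports: list[EPReport]) -> list[VariantRecord]:
    """Group reports by variant and resolve labels and shift bins."""
    groups: dict[Variant, list[EPReport]] = {}
    for report in reports:
        groups.setdefault(report.variant, []).append(report)
    records = []
    for variant in sorted(groups, key=lambda v: (v.position, v.to_aa)):
        group = groups[variant]
        labels = {o: majority_vote(group, o) for o in OUTCOMES}
        # "changed": any outcome affected; "unchanged" requires evidence that
        # something was measured and nothing was affected; ties exclude.
        if any(labels[o] == "affected" for o in OUTCOMES):
            labels["changed_unchanged"] = "affected"
        elif any(labels[o] == "excluded_tie" for o in OUTCOMES):
            labels["changed_unchanged"] = "excluded_tie"
        elif any(labels[o] == "unaffected" for o in OUTCOMES):
            labels["changed_unchanged"] = "unaffected"
        else:
            labels["changed_unchanged"] = "unknown"
        preferred = select_preferred_report(group)
        shift_bins = {}
        for key, attr in (("activation", "act_shift_mV"),
                          ("inactivation", "inact_shift_mV")):
            shift = getattr(preferred, attr)
            shift_bins[key] = discretize_shift(shift) if shift is not None else None
        records.append(VariantRecord(
            variant=variant, labels=labels, shift_bins=shift_bins,
            preferred_study=preferred.study_id, n_reports=len(group)))
    return records


def build_problem_dataset(
    records: list[VariantRecord], outcome: str,
) -> tuple[pd.DataFrame, float]:
    """Labelled dataset for one classification problem.

    Returns (frame, excluded_fraction): the frame has one row per variant
    with a definite affected/unaffected label; the fraction counts tie
    exclusions among variants with any measured evidence for the outcome.
    """
    if outcome not in PROBLEMS:
        raise EPDataError(f"unknown problem {outcome!r}")
    rows, ties = [], 0
    for record in records:
        label = record.labels[outcome]
        if label == "excluded_tie":
            ties += 1
        elif label in ("affected", "unaffected"):
            rows.append((record.variant.position, record.variant.from_aa,
                         record.variant.to_aa, label))
    frame = pd.DataFrame(rows, columns=["position", "from_aa", "to_aa", "label"])
    measured = len(rows) + ties
    return frame, (ties / measured if measured else 0.0)


def build_shift_dataset(records: list[VariantRecord],
                        which: str = "inactivation") -> pd.DataFrame:
    """Three-bin midpoint-shift dataset (neg/mid/pos) from preferred reports."""
    if which not in ("activation", "inactivation"):
        raise EPDataError(f"shift dataset must be activation/inactivation")
    rows = [(r.variant.position, r.variant.from_aa, r.variant.to_aa,
             r.shift_bins[which])
            for r in records if r.shift_bins[which] is not None]
    return pd.DataFrame(rows, columns=["position", "from_aa", "to_aa", "label"])


def split_train_test(dataset: pd.DataFrame, train_fraction: float = 2 / 3,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, reproducible train/test split (default 66.7% / 33.3%)."""
    if len(dataset) < 3:
        raise EPDataError("dataset too small to split")
    counts = dataset["label"].value_counts()
    stratify = dataset["label"]
    if len(counts) < 2:
        warnings.warn("single-class dataset: split is not stratified")
        stratify = None
    elif counts.min() < 2:
        warnings.warn("a class has <2 members: split is not stratified")
        stratify = None
    train, test = _sk_split(dataset, train_size=train_fraction,
                            random_state=seed, stratify=stratify)
    return train.reset_index(drop=True), test.reset_index(drop=True)


# -- storage -----------------------------------------------------------------

_REPORT_COLUMNS = ["position", "from_aa", "to_aa", "study_id", "year",
                   "cell_type", "alpha_subunit", "beta1",
                   "zero_current", "activation", "inactivation", "late",
                   "act_shift_mV", "inact_shift_mV"]


def reports_to_frame(reports: list[EPReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append([r.variant.position, r.variant.from_aa, r.variant.to_aa,
                     r.study_id, r.year, r.cell_type, r.alpha_subunit, r.beta1]
                    + [r.findings[o] for o in OUTCOMES]
                    + [r.act_shift_mV, r.inact_shift_mV])
    return pd.DataFrame(rows, columns=_REPORT_COLUMNS)


def frame_to_reports(frame: pd.DataFrame) -> list[EPReport]:
    reports = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        def _shift(key):
            v = d[key]
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        reports.append(EPReport(
            variant=Variant(int(d["position"]), d["from_aa"], d["to_aa"]),
            study_id=str(d["study_id"]), year=int(d["year"]),
            cell_type=d["cell_type"], alpha_subunit=d["alpha_subunit"],
            beta1=d["beta1"],
            findings={o: d[o] for o in OUTCOMES},
            act_shift_mV=_shift("act_shift_mV"),
            inact_shift_mV=_shift("inact_shift_mV")))
    return reports


def save_reports_tsv(reports: list[EPReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def load_reports_tsv(path: str | Path) -> list[EPReport]:
    return frame_to_reports(pd.read_csv(path, sep="\t"))


def save_reports_sqlite(reports: list[EPReport], path: str | Path) -> None:
    """Write reports into a single-file SQLite store (table ``ep_report``)."""
    frame = reports_to_frame(reports)
    with sqlite3.connect(path) as conn:
        frame.to_sql("ep_report", conn, if_exists="replace", index=False)


def load_reports_sqlite(path: str | Path) -> list[EPReport]:
    with sqlite3.connect(path) as conn:
        frame = pd.read_sql("SELECT * FROM ep_report", conn)
    return frame_to_reports(frame)
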