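"""Synthetic EP-report generator with the statistical structure of the
curated literature database.

The curated database itself is not redistributable, so every pipeline stage
is exercised on generated data reproducing its headline structure: 243
variants with EP data, a 72/28 changed/unchanged imbalance, 74/243 variants
with more than one report of which 58% conflict, per-outcome measurement
missingness, and region-dependent outcome probabilities.

Outcomes follow a per-outcome logistic model: each outcome has a base rate
(on the logit scale) plus log odds-multipliers for the region classes of the
substituted position.  A global intercept shift is calibrated numerically so
that the expected changed/unchanged fraction equals ``p_changed`` for any
effect map, keeping the imbalance a config-honoured invariant.  A variant
whose channel conducts no current has no measurable gating, so its other
outcomes are recorded as not measured.

The reference coding sequence is synthetic (random non-stop codons, fixed
seed): real SCN5A coordinates matter only to the topology, which is supplied
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import Alignment
from .ep import EPReport, OUTCOMES, Variant, resolve_variants, build_problem_dataset
from .enumeration import enumerate_missense
from .features import feature_table
from .topology import ProteinTopology

_GATED = ("activation", "inactivation", "late")


class ConfigError(ValueError):
    pass


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    return 1 / (1 + math.exp(-x))


@dataclass
class GeneratorConfig:
    """Study conditions of the emulated database.

    Defaults mirror the curated database's reported structure: 243 variants
    with EP data, 72% changed, 74/243 with multiple reports, 58% of those
    conflicting.  Per-outcome base rates are set so expected affected counts
    match the database's category counts (zero current 30/243, activation
    69, inactivation 125, late 40) given the measurement rates.
    """

    n_variants: int = 243
    p_changed: float = 0.72
    p_multireport: float = 74 / 243
    p_conflict_given_multi: float = 0.58
    #: truth P(affected) per outcome before region effects and calibration
    base_rates: dict = field(default_factory=lambda: {
        "zero_current": 0.123, "activation": 0.41,
        "inactivation": 0.65, "late": 0.34})
    #: probability each gated outcome is measured for a conducting variant
    measurement_rates: dict = field(default_factory=lambda: {
        "activation": 0.80, "inactivation": 0.90, "late": 0.55})
    #: per-outcome odds multipliers keyed by region selector
    region_effects: dict = field(default_factory=lambda: {
        "zero_current": {"pore": 4.0},
        "activation": {"S4": 3.0, "domain-linker": 2.0},
        "inactivation": {"S4": 2.0, "S6": 1.5, "domain-linker": 1.5, "C": 1.5},
        "late": {"C": 2.5, "domain-linker": 2.0},
    })
    #: per-residue sampling weight by region selector (unlisted classes: 1)
    position_weights: dict = field(default_factory=lambda: {
        "S4": 2.0, "L34": 2.0, "pore": 1.3, "L12": 0.7, "L23": 0.7})
    #: midpoint shifts (mV): |shift| for affected ~ N(mean, sd), sign random;
    #: unaffected ~ N(0, sd)
    shift_affected_mean_mV: float = 10.0
    shift_affected_sd_mV: float = 5.0
    shift_unaffected_sd_mV: float = 1.5
    cell_type_probs: dict = field(default_factory=lambda: {
        "HEK": 0.52, "oocyte": 0.25, "CHO": 0.12, "COS": 0.04,
        "myocyte": 0.02, "unknown": 0.05})
    alpha_probs: dict = field(default_factory=lambda: {
        "a": 0.18, "a*": 0.12, "b": 0.45, "b*": 0.05, "unknown": 0.20})
    beta1_probs: dict = field(default_factory=lambda: {
        "yes": 0.45, "no": 0.35, "unknown": 0.20})
    seed: int = 0

    def validate(self) -> None:
        probs = [self.p_changed, self.p_multireport, self.p_conflict_given_multi,
                 *self.base_rates.values(), *self.measurement_rates.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        for effects in self.region_effects.values():
            if any(m <= 0 for m in effects.values()):
                raise ConfigError("odds multipliers must be positive")
        if self.p_conflict_given_multi > 0 and self.p_multireport == 0:
            raise ConfigError(
                "conflicts require multi-report variants (p_multireport=0)")


def strong_effect_config(odds: float = 8.0, **kwargs) -> GeneratorConfig:
    """Recovery-experiment config: activation odds x ``odds`` in the
    voltage-sensing segments and the inter-domain linkers, no other
    effects."""
    return GeneratorConfig(region_effects={
        "zero_current": {}, "inactivation": {}, "late": {},
        "activation": {"S4": odds, "domain-linker": odds},
    }, **kwargs)


def null_effect_config(**kwargs) -> GeneratorConfig:
    """All odds multipliers 1: no region signal by construction."""
    return GeneratorConfig(
        region_effects={o: {} for o in OUTCOMES},
        position_weights={}, **kwargs)


# -- synthetic reference sequence and alignment -------------------------------

def synthetic_reference(length: int = 2016, seed: int = 2016) -> str:
    """Random stop-free CDS of ``length`` codons (synthetic stand-in for a
    real coding sequence; only its codon structure matters)."""
    rng = np.random.default_rng(seed)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    bases = "ACGT"
    while len(codons) < length:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in stops:
            codons.append(codon)
    return "".join(codons)


def synthetic_alignment(protein: str, n_homologs: int = 7,
                        sub_rate: float = 0.15, gap_rate: float = 0.02,
                        seed: int = 7) -> Alignment:
    """Synthetic homolog alignment: rows are the reference with random
    substitutions and gaps (no insertions, so columns map 1:1)."""
    rng = np.random.default_rng(seed)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows, names = [protein], ["SCN5A"]
    for h in range(n_homologs):
        row = []
        for ch in protein:
            u = rng.random()
            if u < gap_rate:
                row.append("-")
            elif u < gap_rate + sub_rate:
                row.append(aas[rng.integers(20)])
            else:
                row.append(ch)
        rows.append("".join(row))
        names.append(f"homolog{h + 1}")
    return Alignment(names=names, rows=rows, reference_name="SCN5A")


# -- outcome model ------------------------------------------------------------

def _region_multiplier(topology: ProteinTopology, region, effects: dict) -> float:
    mult = 1.0
    for selector, m in effects.items():
        if region in topology.matching_regions(selector):
            mult *= m
    return mult


def _outcome_probs(config: GeneratorConfig, topology: ProteinTopology,
                   delta: float) -> dict:
    """Per-region-name, per-outcome affected probabilities under intercept
    shift ``delta``."""
    probs = {}
    for region in topology.regions:
        probs[region.name] = {
            o: _sigmoid(_logit(config.base_rates[o]) + delta
                        + math.log(_region_multiplier(
                            topology, region, config.region_effects.get(o, {}))))
            for o in OUTCOMES}
    return probs


def _expected_changed(config: GeneratorConfig, topology: ProteinTopology,
                      delta: float, weights: dict) -> float:
    probs = _outcome_probs(config, topology, delta)
    total_w = sum(weights[r.name] * r.length for r in topology.regions)
    acc = 0.0
    for region in topology.regions:
        p = probs[region.name]
        cond = 1.0
        for o in _GATED:
            cond *= 1 - config.measurement_rates[o] * p[o]
        p_changed = p["zero_current"] + (1 - p["zero_current"]) * (1 - cond)
        acc += weights[region.name] * region.length * p_changed
    return acc / total_w


def _position_weights(config: GeneratorConfig,
                      topology: ProteinTopology) -> dict:
    weights = {r.name: 1.0 for r in topology.regions}
    for selector, w in config.position_weights.items():
        for region in topology.matching_regions(selector):
            weights[region.name] *= w
    return weights


def _calibrate_intercept(config: GeneratorConfig,
                         topology: ProteinTopology) -> float:
    """Bisect the global intercept shift so E[changed] = p_changed."""
    weights = _position_weights(config, topology)
    lo, hi = -12.0, 12.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if _expected_changed(config, topology, mid, weights) < config.p_changed:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# -- generation ---------------------------------------------------------------

def generate(config: GeneratorConfig, topology: ProteinTopology | None = None,
             seed: int | None = None,
             ) -> tuple[list[EPReport], pd.DataFrame]:
    """Generate EP reports plus a ground-truth table, reproducibly by seed.

    Returns ``(reports, truth)`` where ``truth`` has one row per variant with
    columns position/from_aa/to_aa, the true per-outcome label (affected /
    unaffected / unknown when unmeasured) and ``changed``.
    """
    config.validate()
    if topology is None:
        topology = ProteinTopology.default()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    census = enumerate_missense(synthetic_reference(topology.length))
    protein = census.protein
    delta = _calibrate_intercept(config, topology)
    probs = _outcome_probs(config, topology, delta)
    weights = _position_weights(config, topology)
    residue_w = np.array([weights[topology.region_of(p).name]
                          for p in range(1, topology.length + 1)])
    residue_w /= residue_w.sum()

    variants: list[Variant] = []
    seen = set()
    while len(variants) < config.n_variants:
        position = int(rng.choice(topology.length, p=residue_w)) + 1
        targets = sorted(census.per_codon[position - 1].targets)
        if not targets:
            continue
        to_aa = targets[rng.integers(len(targets))]
        if (position, to_aa) in seen:
            continue
        seen.add((position, to_aa))
        variants.append(Variant(position, protein[position - 1], to_aa))

    def _choice(table: dict) -> str:
        keys = list(table)
        p = np.array([table[k] for k in keys], dtype=float)
        return keys[rng.choice(len(keys), p=p / p.sum())]

    reports: list[EPReport] = []
    truth_rows = []
    for v_idx, variant in enumerate(variants):
        region = topology.region_of(variant.position)
        p = probs[region.name]
        zero = rng.random() < p["zero_current"]
        measured = {"zero_current": True}
        truth = {"zero_current": "affected" if zero else "unaffected"}
        for o in _GATED:
            if zero:
                measured[o] = False
                truth[o] = "unknown"
            else:
                measured[o] = rng.random() < config.measurement_rates[o]
                truth[o] = (("affected" if rng.random() < p[o] else "unaffected")
                            if measured[o] else "unknown")
        changed = any(truth[o] == "affected" for o in OUTCOMES)
        truth_rows.append([variant.position, variant.from_aa, variant.to_aa,
                           truth["zero_current"], truth["activation"],
                           truth["inactivation"], truth["late"],
                           "affected" if changed else "unaffected"])

        multi = rng.random() < config.p_multireport
        n_reports = 2 + rng.poisson(0.6) if multi else 1
        conflict_report = (rng.integers(1, n_reports)
                           if multi and rng.random() < config.p_conflict_given_multi
                           else None)
        measured_gated = [o for o in OUTCOMES
                          if measured[o] and truth[o] != "unknown"]
        for r_idx in range(n_reports):
            findings = {}
            for o in OUTCOMES:
                findings[o] = truth[o] if measured[o] else "not_measured"
            if r_idx == conflict_report and measured_gated:
                o = measured_gated[rng.integers(len(measured_gated))]
                findings[o] = ("unaffected" if findings[o] == "affected"
                               else "affected")

            def _shift(outcome):
                if findings[outcome] == "not_measured":
                    return None
                if findings[outcome] == "affected":
                    size = abs(rng.normal(config.shift_affected_mean_mV,
                                          config.shift_affected_sd_mV))
                    return float(size if rng.random() < 0.5 else -size)
                return float(rng.normal(0.0, config.shift_unaffected_sd_mV))

            reports.append(EPReport(
                variant=variant,
                study_id=f"study_{v_idx:04d}_{r_idx}",
                year=int(1995 + rng.integers(24)),
                cell_type=_choice(config.cell_type_probs),
                alpha_subunit=_choice(config.alpha_probs),
                beta1=_choice(config.beta1_probs),
                findings=findings,
                act_shift_mV=_shift("activation"),
                inact_shift_mV=_shift("inactivation")))
    truth = pd.DataFrame(truth_rows, columns=[
        "position", "from_aa", "to_aa", "zero_current", "activation",
        "inactivation", "late", "changed"])
    return reports, truth


# -- recovery experiment ------------------------------------------------------

def recovery_experiment(
    config: GeneratorConfig | None = None,
    methods=("naive_bayes", "random_forest"),
    problem: str = "activation",
    n_seeds: int = 20,
    base_seed: int = 0,
    top_k: int = 3,
    topology: ProteinTopology | None = None,
) -> pd.DataFrame:
    """Run the full pipeline (generate -> resolve -> featurize -> tune ->
    evaluate) over ``n_seeds`` replicates and report, per seed, the
    best-method test MCC and whether the region-type feature ranks in the
    information-gain top ``top_k``.
    """
    from .model import OutcomeModel

    if config is None:
        config = strong_effect_config()
    if topology is None:
        topology = ProteinTopology.default()
    census = enumerate_missense(synthetic_reference(topology.length))
    alignment = synthetic_alignment(census.protein)
    profile = None  # lazy: computed once below
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        reports, _ = generate(config, topology, seed=seed)
        records = resolve_variants(reports)
        dataset, _ = build_problem_dataset(records, problem)
        if profile is None:
            from .conservation import conservedness_profile
            profile = conservedness_profile(alignment)
        feats = feature_table(dataset, topology, conservation_scores=profile,
                              reference=census.protein)
        model = OutcomeModel(feats, problem=problem, seed=seed)
        fit = model.fit_all(methods, seed=seed)
        best = fit["best"]
        top = list(best.info_gain.index[:top_k])
        rows.append({
            "seed": seed, "method": best.method, "test_mcc": best.mcc,
            "test_auc": best.auc, "cv_mcc": best.cv_mcc,
            "zero_r_accuracy": best.baseline["accuracy"],
            "accuracy": best.accuracy,
            "region_type_in_top_k": "region_type" in top,
            "top_features": ",".join(top),
        })
    return pd.DataFrame(rows)
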