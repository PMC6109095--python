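"""End-to-end pipeline: reports -> resolved labels -> features -> metrics.

``run_pipeline`` ties the stages together and writes per-problem datasets,
feature tables, density reports and a metrics JSON, plus a manifest with
input checksums and seeds.  Outputs are deterministic for a fixed config:
rerunning with the same seeds produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .conservation import Alignment, conservedness_profile
from .density import outcome_tally, relative_density
from .enumeration import enumerate_missense
from .ep import (PROBLEMS, build_problem_dataset, load_reports_tsv,
                 resolve_variants, save_reports_tsv)
from .features import feature_table, write_feature_table
from .io import read_fasta
from .model import OutcomeModel
from .synthetic import GeneratorConfig, generate, synthetic_alignment, \
    synthetic_reference
from .topology import ProteinTopology


@dataclass
class RunConfig:
    """Paths, problems, methods and seeds for one pipeline run.

    With ``reports_path`` unset, reports are generated synthetically from
    ``generator`` (seeded); a missing alignment only disables the
    conservedness feature.
    """

    out_dir: str | Path = "navvar_run"
    reports_path: str | Path | None = None
    topology_path: str | Path | None = None
    cds_path: str | Path | None = None
    alignment_path: str | Path | None = None
    alignment_reference: str = "SCN5A"
    problems: tuple = PROBLEMS
    methods: tuple = ("naive_bayes", "random_forest")
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        for p in (self.reports_path, self.topology_path, self.cds_path,
                  self.alignment_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        unknown = set(self.problems) - set(PROBLEMS)
        if unknown:
            raise ValueError(f"unknown problems {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}

    stage = "topology"
    try:
        if config.topology_path:
            topology = ProteinTopology.from_table(config.topology_path)
            inputs["topology"] = _sha256(Path(config.topology_path))
        else:
            topology = ProteinTopology.default()

        stage = "reference sequence"
        if config.cds_path:
            cds = next(iter(read_fasta(config.cds_path).values()))
            inputs["cds"] = _sha256(Path(config.cds_path))
        else:
            cds = synthetic_reference(topology.length)
        census = enumerate_missense(cds)

        stage = "reports"
        if config.reports_path:
            reports = load_reports_tsv(config.reports_path)
            inputs["reports"] = _sha256(Path(config.reports_path))
        else:
            reports, _ = generate(config.generator, topology, seed=config.seed)
        save_reports_tsv(reports, out / "reports.tsv")

        stage = "conservation"
        profile = None
        if config.alignment_path:
            alignment = Alignment.from_file(config.alignment_path,
                                            config.alignment_reference)
            inputs["alignment"] = _sha256(Path(config.alignment_path))
            profile = conservedness_profile(alignment)
        elif config.reports_path is None:
            # synthetic run: synthetic homologs keep the feature exercised
            profile = conservedness_profile(synthetic_alignment(census.protein))
        else:
            warnings.warn("no alignment given: conservedness feature absent")

        stage = "label resolution"
        records = resolve_variants(reports)

        stage = "density"
        subs = [(r.variant.position, r.variant.to_aa) for r in records]
        for grouping in ("region", "domain", "region-class"):
            frame = relative_density(subs, topology, grouping)
            frame.to_csv(out / f"density_{grouping}.tsv", sep="\t",
                         index=False, float_format="%.6g")
        outcome_tally(records, topology, "region-class").to_csv(
            out / "outcome_tally.tsv", sep="\t", index=False)

        stage = "classification"
        all_metrics = {}
        reference = census.protein if config.reports_path is None else None
        for problem in config.problems:
            dataset, excluded = build_problem_dataset(records, problem)
            if dataset.empty or dataset["label"].nunique() < 2:
                warnings.warn(f"problem {problem}: degenerate dataset, skipped")
                continue
            feats = feature_table(dataset, topology,
                                  conservation_scores=profile,
                                  reference=reference)
            write_feature_table(feats, out / f"features_{problem}.tsv")
            model = OutcomeModel(feats, problem=problem, seed=config.seed)
            all_metrics[problem] = {
                "excluded_tie_fraction": round(excluded, 6),
                "n_variants": len(dataset),
                "methods": {m: model.fit(m, seed=config.seed).metrics_dict()
                            for m in config.methods},
            }

        stage = "manifest"
        (out / "metrics.json").write_text(
            json.dumps(all_metrics, indent=2, sort_keys=True) + "\n")
        manifest = {"navvar_version": __version__, "seed": config.seed,
                    "problems": list(config.problems),
                    "methods": list(config.methods),
                    "input_checksums": inputs}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
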