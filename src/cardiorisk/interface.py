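"""Pipeline configuration and orchestration.

One YAML config describes a full run: input paths, score weight overrides,
intervention settings and analysis options. :func:`run_pipeline` executes
read -> lab carry-forward -> score -> intervene -> compare and writes four
artifacts to the output directory:

* ``scores.csv``         — per patient-day component points, totals, classes
* ``substitutions.csv``  — the substitution/withdrawal log
* ``report.json``        — the machine-readable before/after report
* ``summary.txt``        — the human-readable summary

All floats are rounded half-even to three decimals at serialization so
repeated runs on identical inputs produce byte-identical artifacts.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import BeforeAfterReport, compare_before_after
from .cohort import Cohort, ValidationReport, carry_forward_cohort, read_cohort
from .intervention import InterventionConfig, InterventionResult, apply_intervention
from .knowledge import KnowledgeBase, default_knowledge_base, load_knowledge_base
from .scoring import COMPONENTS, RiskThresholds, TisdaleWeights, daily_score

__all__ = ["RunConfig", "run_pipeline", "write_scores_csv", "write_substitution_log"]


@dataclass
class RunConfig:
    patients_path: str
    days_path: str
    output_dir: str = "cardiorisk_out"
    kb_path: str | None = None  # None -> bundled knowledge base
    weights: TisdaleWeights = field(default_factory=TisdaleWeights)
    thresholds: RiskThresholds = field(default_factory=RiskThresholds)
    intervention: InterventionConfig = field(default_factory=InterventionConfig)
    wilcoxon_alternative: str = "greater"
    seed: int | None = None  # recorded in the report for provenance

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        paths = doc.get("paths", {})
        tisdale = doc.get("tisdale", {})
        interv = doc.get("intervention", {})
        analysis = doc.get("analysis", {})
        kwargs: dict = dict(
            patients_path=paths.get("patients", ""),
            days_path=paths.get("days", ""),
            output_dir=paths.get("output", "cardiorisk_out"),
            kb_path=paths.get("kb"),
            weights=TisdaleWeights(**tisdale.get("weights", {})),
            thresholds=RiskThresholds(**tisdale.get("thresholds", {})),
            intervention=InterventionConfig(
                enabled_rules=(
                    frozenset(interv["enabled_rules"])
                    if interv.get("enabled_rules") is not None
                    else None
                ),
                replacement_policy=interv.get("replacement_policy", "first_listed"),
                fixed_choices=interv.get("fixed_choices", {}),
            ),
            wilcoxon_alternative=analysis.get("wilcoxon_alternative", "greater"),
            seed=doc.get("seed"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def load_kb(self) -> KnowledgeBase:
        if self.kb_path is None:
            return default_knowledge_base()
        return load_knowledge_base(self.kb_path)


def _round_floats(obj, ndigits: int = 3):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def write_scores_csv(
    cohort: Cohort,
    kb: KnowledgeBase,
    weights: TisdaleWeights,
    thresholds: RiskThresholds,
    path: str | Path,
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "day_index", *COMPONENTS, "qt_drug_count", "total", "risk_class"]
        )
        for patient in cohort:
            for day in patient.days:
                s = daily_score(patient, day, kb, weights, thresholds)
                writer.writerow(
                    [
                        patient.patient_id,
                        day.day_index,
                        *[s.components[c] for c in COMPONENTS],
                        s.qt_drug_count,
                        s.total,
                        s.risk_class,
                    ]
                )


def write_substitution_log(result: InterventionResult, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "day_index", "rule_id", "removed", "added"])
        for entry in result.log:
            writer.writerow(
                [entry.patient_id, entry.day_index, entry.rule_id, entry.removed,
                 entry.added or ""]
            )


def run_pipeline(config: RunConfig) -> BeforeAfterReport:
    """Execute the full analysis and write all artifacts.

    Raises ``FileNotFoundError``/schema errors on invalid inputs; the CLI
    maps those to a non-zero exit status.
    """
    kb = config.load_kb()
    cohort, validation = read_cohort(config.patients_path, config.days_path, kb)
    cohort = carry_forward_cohort(cohort)
    result = apply_intervention(
        cohort, kb, config.intervention, config.weights, config.thresholds
    )
    report = compare_before_after(
        result, kb, config.weights, config.thresholds,
        alternative=config.wilcoxon_alternative,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_scores_csv(cohort, kb, config.weights, config.thresholds, out / "scores.csv")
    write_substitution_log(result, out / "substitutions.csv")
    doc = {
        "validation": validation.to_dict(),
        "report": report.to_dict(),
        "config": {
            "patients": str(config.patients_path),
            "days": str(config.days_path),
            "kb": config.kb_path or "bundled",
            "weights": dataclasses.asdict(config.weights),
            "thresholds": dataclasses.asdict(config.thresholds),
            "wilcoxon_alternative": config.wilcoxon_alternative,
            "seed": config.seed,
        },
    }
    (out / "report.json").write_text(
        json.dumps(_round_floats(doc), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    summary = report.summary()
    if validation.unknown_drugs:
        summary += (
            f"\nunknown drugs encountered: {len(validation.unknown_drugs)} "
            f"({sum(validation.unknown_drugs.values())} administrations)"
        )
    (out / "summary.txt").write_text(summary + "\n", encoding="utf-8")
    return report
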