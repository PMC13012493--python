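"""Counterfactual prescription intervention and QT-synergism detection.

The intervention applies the six-rule substitution/withdrawal set to every
patient-day's medication list and recomputes the risk score with all other
clinical variables (labs, sepsis, comorbidities) held fixed. Because every
replacement drug is non-QT-prolonging by knowledge-base invariant and
withdrawals only remove drugs, the post-intervention daily total can never
exceed the pre-intervention total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

from .cohort import ClinicalDay, Cohort, PatientRecord
from .knowledge import KnowledgeBase, SubstitutionRule
from .scoring import RiskThresholds, ScoreBreakdown, TisdaleWeights, daily_score

__all__ = [
    "InterventionConfig",
    "SubstitutionLogEntry",
    "InterventionResult",
    "SynergyReport",
    "substitute_day",
    "apply_intervention",
    "detect_synergism",
]


@dataclass(frozen=True)
class InterventionConfig:
    """Which rules run and how a replacement is chosen.

    ``replacement_policy`` is ``first_listed`` (default: the first candidate
    in the rule's ordered list) or ``fixed_choice``, in which case
    ``fixed_choices`` maps rule_id -> candidate name.
    """

    enabled_rules: frozenset[str] | None = None  # None = all rules
    replacement_policy: str = "first_listed"
    fixed_choices: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replacement_policy not in ("first_listed", "fixed_choice"):
            raise ValueError(
                f"unknown replacement policy {self.replacement_policy!r}"
            )

    def rule_enabled(self, rule_id: str) -> bool:
        return self.enabled_rules is None or rule_id in self.enabled_rules

    def pick_replacement(self, rule: SubstitutionRule) -> str:
        if self.replacement_policy == "fixed_choice":
            choice = self.fixed_choices.get(rule.rule_id)
            if choice is None:
                raise ValueError(f"no fixed choice configured for rule {rule.rule_id}")
            if choice not in rule.replacement_candidates:
                raise ValueError(
                    f"fixed choice {choice!r} is not a candidate of rule {rule.rule_id}"
                )
            return choice
        return rule.replacement_candidates[0]


@dataclass(frozen=True)
class SubstitutionLogEntry:
    patient_id: str
    day_index: int
    rule_id: str
    removed: str
    added: str | None  # None for withdrawals or already-present replacements


@dataclass
class PairedScores:
    """Pre/post score series for one patient, aligned by day."""

    patient_id: str
    pre: list[ScoreBreakdown]
    post: list[ScoreBreakdown]


@dataclass
class InterventionResult:
    cohort_pre: Cohort
    cohort_post: Cohort
    paired_scores: list[PairedScores]
    log: list[SubstitutionLogEntry]

    def pre_max_totals(self) -> list[int]:
        return [max(s.total for s in p.pre) for p in self.paired_scores]

    def post_max_totals(self) -> list[int]:
        return [max(s.total for s in p.post) for p in self.paired_scores]


def substitute_day(
    meds,
    kb: KnowledgeBase,
    config: InterventionConfig = InterventionConfig(),
) -> tuple[tuple[str, ...], list[tuple[str, str, str | None]]]:
    """Apply the enabled rules to one day's med list.

    Returns the transformed list (original order, first-occurrence position
    for replacements, no duplicates — a day is a drug set) and log tuples
    ``(rule_id, removed, added_or_None)``. Deterministic for a fixed config.
    """
    rule_of: dict[str, SubstitutionRule] = {}
    for rule in kb.rules:
        if config.rule_enabled(rule.rule_id):
            for src in rule.source_drugs:
                rule_of[src] = rule
    new_meds: list[str] = []
    log: list[tuple[str, str, str | None]] = []
    for med in meds:
        rule = rule_of.get(med)
        if rule is None:
            if med not in new_meds:
                new_meds.append(med)
            continue
        if rule.action == "withdraw":
            log.append((rule.rule_id, med, None))
            continue
        candidate = config.pick_replacement(rule)
        already = candidate in new_meds or candidate in meds
        if not already:
            new_meds.append(candidate)
        log.append((rule.rule_id, med, None if already else candidate))
    return tuple(new_meds), log


def apply_intervention(
    cohort: Cohort,
    kb: KnowledgeBase,
    config: InterventionConfig = InterventionConfig(),
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
) -> InterventionResult:
    """Transform every patient-day and score the cohort before and after.

    Only medication lists change; labs, sepsis and comorbidities are held
    fixed, so the pre/post score difference isolates the prescribing change.
    """
    post_patients: list[PatientRecord] = []
    paired: list[PairedScores] = []
    log: list[SubstitutionLogEntry] = []
    for patient in cohort:
        new_days: list[ClinicalDay] = []
        for day in patient.days:
            new_meds, day_log = substitute_day(day.meds, kb, config)
            new_days.append(dc_replace(day, meds=new_meds))
            log.extend(
                SubstitutionLogEntry(patient.patient_id, day.day_index, *entry)
                for entry in day_log
            )
        post_patient = dc_replace(patient, days=tuple(new_days))
        post_patients.append(post_patient)
        paired.append(
            PairedScores(
                patient_id=patient.patient_id,
                pre=[daily_score(patient, d, kb, weights, thresholds) for d in patient.days],
                post=[
                    daily_score(post_patient, d, kb, weights, thresholds)
                    for d in post_patient.days
                ],
            )
        )
    cohort_post = Cohort(
        patients=post_patients, provenance=f"{cohort.provenance}|intervened"
    )
    return InterventionResult(
        cohort_pre=cohort, cohort_post=cohort_post, paired_scores=paired, log=log
    )


@dataclass(frozen=True)
class SynergyReport:
    """QT-synergism screen for one med list.

    Synergy means two or more distinct QT-prolonging drugs administered
    together, compounding the probability of a serious cardiovascular event.
    """

    qt_drugs: frozenset[str]
    by_class: dict[str, tuple[str, ...]]
    synergy: bool

    @property
    def n_qt_drugs(self) -> int:
        return len(self.qt_drugs)

    @property
    def n_classes(self) -> int:
        return len(self.by_class)


def detect_synergism(meds, kb: KnowledgeBase) -> SynergyReport:
    """Group a day's QT-prolonging drugs by therapeutic class."""
    qt_drugs = sorted({m for m in meds if kb.is_qt_drug(m)})
    by_class: dict[str, list[str]] = {}
    for name in qt_drugs:
        by_class.setdefault(kb.therapeutic_class(name), []).append(name)
    return SynergyReport(
        qt_drugs=frozenset(qt_drugs),
        by_class={c: tuple(ds) for c, ds in sorted(by_class.items())},
        synergy=len(qt_drugs) >= 2,
    )
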