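"""Daily cardiovascular risk scoring (Tisdale-style rubric).

The score is an additive rubric over demographic, laboratory, ECG,
comorbidity and medication components, computed per patient-day:

====================================  ======
component                             points
====================================  ======
age >= 68 years                            1
female sex                                 1
on a diuretic that day                     1
serum potassium <= 3.5 mmol/L              2
QT interval >= 450 ms                      2
exactly 1 QT-prolonging drug               3
2 or more QT-prolonging drugs         3 + 3
history of acute myocardial infarct        2
CHF with reduced ejection fraction         3
sepsis (that day)                          3
====================================  ======

Totals classify as low (<= 6), moderate (7-10) or high (>= 11) risk; the
maximum attainable total with default weights is 21. Missing labs contribute
zero points — absent data never inflates risk. All weights and band
boundaries are configuration with these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import ClinicalDay, PatientRecord
from .knowledge import KnowledgeBase

__all__ = [
    "TisdaleWeights",
    "RiskThresholds",
    "ScoreBreakdown",
    "count_qt_drugs",
    "daily_score",
    "classify_risk",
    "patient_risk",
]

RISK_CLASSES = ("low", "moderate", "high")

COMPONENTS = (
    "age_ge_68",
    "female",
    "diuretic",
    "potassium_le_3_5",
    "qt_ge_450",
    "qt_drugs",
    "ami_history",
    "chf_reduced_ef",
    "sepsis",
)


@dataclass(frozen=True)
class TisdaleWeights:
    """Points per rubric component (non-negative integers)."""

    age_ge_68: int = 1
    female: int = 1
    diuretic: int = 1
    potassium_le_3_5: int = 2
    qt_ge_450: int = 2
    one_qt_drug: int = 3
    two_plus_qt_drugs_additional: int = 3
    ami_history: int = 2
    chf_reduced_ef: int = 3
    sepsis: int = 3

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"weight {name} must be non-negative, got {value}")

    @property
    def max_total(self) -> int:
        return (
            self.age_ge_68
            + self.female
            + self.diuretic
            + self.potassium_le_3_5
            + self.qt_ge_450
            + self.one_qt_drug
            + self.two_plus_qt_drugs_additional
            + self.ami_history
            + self.chf_reduced_ef
            + self.sepsis
        )


@dataclass(frozen=True)
class RiskThresholds:
    """Band boundaries: low <= low_max < total <= moderate_max < high."""

    low_max: int = 6
    moderate_max: int = 10

    def __post_init__(self) -> None:
        if not self.low_max < self.moderate_max:
            raise ValueError("low_max must be < moderate_max")


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-component awarded points, the total and the risk class."""

    components: dict[str, int]
    qt_drug_count: int
    total: int
    risk_class: str
    day_index: int | None = None

    def __post_init__(self) -> None:
        if self.total != sum(self.components.values()):
            raise ValueError("total does not equal the component sum")


def count_qt_drugs(meds, kb: KnowledgeBase) -> int:
    """Number of distinct QT-prolonging drugs in a day's med list."""
    return sum(1 for name in set(meds) if kb.is_qt_drug(name))


def classify_risk(total: int, thresholds: RiskThresholds = RiskThresholds()) -> str:
    if total < 0:
        raise ValueError(f"score total must be non-negative, got {total}")
    if total <= thresholds.low_max:
        return "low"
    if total <= thresholds.moderate_max:
        return "moderate"
    return "high"


def daily_score(
    patient: PatientRecord,
    day: ClinicalDay,
    kb: KnowledgeBase,
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
) -> ScoreBreakdown:
    """Score one patient-day against the rubric.

    Labs are taken as recorded on the day (apply carry-forward first if
    desired); a missing potassium or QT value scores zero for that
    component. Chronic and pre-admission self-medication never enter the
    score — only drugs administered that day count.
    """
    n_qt = count_qt_drugs(day.meds, kb)
    if n_qt >= 2:
        qt_drug_points = weights.one_qt_drug + weights.two_plus_qt_drugs_additional
    elif n_qt == 1:
        qt_drug_points = weights.one_qt_drug
    else:
        qt_drug_points = 0
    k = day.potassium_mmol_per_l
    components = {
        "age_ge_68": weights.age_ge_68 if patient.age_years >= 68 else 0,
        "female": weights.female if patient.sex == "female" else 0,
        "diuretic": weights.diuretic if day.on_diuretic(kb) else 0,
        "potassium_le_3_5": (
            weights.potassium_le_3_5 if k is not None and k <= 3.5 else 0
        ),
        "qt_ge_450": (
            weights.qt_ge_450 if day.qt_ms is not None and day.qt_ms >= 450 else 0
        ),
        "qt_drugs": qt_drug_points,
        "ami_history": (
            weights.ami_history if "ami_history" in patient.comorbidities else 0
        ),
        "chf_reduced_ef": (
            weights.chf_reduced_ef if "chf_reduced_ef" in patient.comorbidities else 0
        ),
        "sepsis": weights.sepsis if day.sepsis else 0,
    }
    total = sum(components.values())
    return ScoreBreakdown(
        components=components,
        qt_drug_count=n_qt,
        total=total,
        risk_class=classify_risk(total, thresholds),
        day_index=day.day_index,
    )


def patient_risk(
    patient: PatientRecord,
    kb: KnowledgeBase,
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
) -> tuple[ScoreBreakdown, list[ScoreBreakdown]]:
    """Per-day score series plus the patient-level summary.

    The patient-level class is that of the day with the maximal total —
    maximum exposure over the stay; ties break to the earliest day.
    """
    if not patient.days:
        raise ValueError(f"{patient.patient_id}: patient has no days to score")
    series = [daily_score(patient, d, kb, weights, thresholds) for d in patient.days]
    best = max(series, key=lambda s: s.total)  # max() keeps the earliest tie
    return best, series
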