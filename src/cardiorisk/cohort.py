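"""Patient/cohort data model and tabular readers.

A cohort is a list of patients; each patient carries static demographics and
comorbidities plus an ordered sequence of ICU days. Each day records the
administered drug list, serum potassium (mmol/L), the (corrected) QT interval
(ms) and a sepsis flag — exactly the inputs of the daily risk score.

Input format is two CSV files (``patients.csv`` and ``days.csv``); drug name
lists are semicolon-separated within a cell. Reading validates referential
integrity, value plausibility and drug-name coverage against a knowledge
base, and returns a machine-readable validation report alongside the cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .knowledge import KnowledgeBase

__all__ = [
    "ClinicalDay",
    "PatientRecord",
    "Cohort",
    "ValidationReport",
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "carry_forward_labs",
]

SEXES = ("male", "female")
OUTCOMES = ("death", "discharge_with_sequelae", "transfer", "discharge")
COMORBIDITY_FLAGS = (
    "sah",  # systemic arterial hypertension
    "ami_history",  # prior acute myocardial infarction
    "chf_reduced_ef",  # congestive heart failure with reduced ejection fraction
    "diabetes",
    "obesity",
    "arrhythmia",
)
ADDICTION_FLAGS = ("smoker", "alcohol", "illicit_drugs")

# plausibility gates for daily labs
POTASSIUM_RANGE = (1.0, 9.0)  # mmol/L, exclusive
QT_RANGE = (200.0, 700.0)  # ms, exclusive


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates its schema or referential integrity."""


@dataclass(frozen=True)
class ClinicalDay:
    """One patient-day: administered drugs, labs and sepsis status."""

    day_index: int
    meds: tuple[str, ...] = ()
    potassium_mmol_per_l: float | None = None
    qt_ms: float | None = None
    sepsis: bool = False

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")
        if len(set(self.meds)) != len(self.meds):
            raise ValueError(f"day {self.day_index}: duplicate meds {self.meds}")
        k = self.potassium_mmol_per_l
        if k is not None and not (POTASSIUM_RANGE[0] < k < POTASSIUM_RANGE[1]):
            raise ValueError(f"day {self.day_index}: implausible potassium {k}")
        if self.qt_ms is not None and not (QT_RANGE[0] < self.qt_ms < QT_RANGE[1]):
            raise ValueError(f"day {self.day_index}: implausible QT {self.qt_ms}")

    def on_diuretic(self, kb: KnowledgeBase) -> bool:
        return any(kb.ade_flags(m).diuretic for m in self.meds)


@dataclass(frozen=True)
class PatientRecord:
    """Static patient attributes plus the ordered ICU-day sequence."""

    patient_id: str
    age_years: int
    sex: str
    comorbidities: frozenset[str] = frozenset()
    addiction_flags: frozenset[str] = frozenset()
    chronic_meds: frozenset[str] = frozenset()
    self_meds: frozenset[str] = frozenset()
    outcome: str = "discharge"
    days: tuple[ClinicalDay, ...] = ()

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.age_years < 18:
            raise ValueError(f"{self.patient_id}: age must be >= 18 (adult cohort)")
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: sex must be one of {SEXES}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"{self.patient_id}: unknown outcome {self.outcome!r}")
        indices = [d.day_index for d in self.days]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"{self.patient_id}: days must be consecutively indexed from 1, "
                f"got {indices}"
            )


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_ids in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def n_patient_days(self) -> int:
        return sum(len(p.days) for p in self.patients)


@dataclass
class ValidationReport:
    """Counts of data-quality issues observed while reading a cohort."""

    unknown_drugs: dict[str, int] = field(default_factory=dict)
    n_missing_potassium: int = 0
    n_missing_qt: int = 0
    n_days: int = 0
    n_patients: int = 0

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_days": self.n_days,
            "n_missing_potassium": self.n_missing_potassium,
            "n_missing_qt": self.n_missing_qt,
            "n_unknown_drugs": len(self.unknown_drugs),
            "unknown_drugs": dict(sorted(self.unknown_drugs.items())),
        }


# ---------------------------------------------------------------------------
# CSV input/output

_PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    *COMORBIDITY_FLAGS,
    *ADDICTION_FLAGS,
    "chronic_meds",
    "self_meds",
    "outcome",
]
_DAY_COLUMNS = ["patient_id", "day_index", "meds", "potassium_mmol_l", "qt_ms", "sepsis"]

_BOOL = {"true": True, "false": False, "1": True, "0": False, "": False}


def _parse_bool(value: str, where: str) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise CohortSchemaError(f"{where}: expected boolean, got {value!r}") from None


def _parse_float(value: str, where: str) -> float | None:
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortSchemaError(f"{where}: expected a number, got {value!r}") from None


def _split_meds(
    cell: str, kb: KnowledgeBase, report: ValidationReport
) -> tuple[str, ...]:
    names: list[str] = []
    for token in str(cell or "").split(";"):
        token = token.strip()
        if not token:
            continue
        name = kb.normalize(token)
        if kb.ade_flags(name).unknown:
            report.unknown_drugs[name] = report.unknown_drugs.get(name, 0) + 1
        if name not in names:
            names.append(name)
    return tuple(names)


def read_cohort(
    patients_path: str | Path,
    days_path: str | Path,
    kb: KnowledgeBase,
) -> tuple[Cohort, ValidationReport]:
    """Read and validate a cohort from ``patients.csv`` + ``days.csv``.

    Drug names are normalized through the knowledge base; unknown drugs are
    tallied in the returned :class:`ValidationReport`, never fatal. Schema
    violations (missing columns, non-numeric labs, orphan day rows,
    duplicate day indices) raise :class:`CohortSchemaError` naming the line.
    """
    patients_path, days_path = Path(patients_path), Path(days_path)
    for p in (patients_path, days_path):
        if not p.exists():
            raise FileNotFoundError(f"cohort file not found: {p}")
    report = ValidationReport()

    static: dict[str, dict] = {}
    with open(patients_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_PATIENT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortSchemaError(f"{patients_path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{patients_path}:{lineno}"
            pid = str(row["patient_id"]).strip()
            if not pid:
                raise CohortSchemaError(f"{where}: empty patient_id")
            if pid in static:
                raise CohortSchemaError(f"{where}: duplicate patient_id {pid!r}")
            try:
                age = int(str(row["age_years"]).strip())
            except ValueError:
                raise CohortSchemaError(
                    f"{where}: non-integer age {row['age_years']!r}"
                ) from None
            static[pid] = dict(
                patient_id=pid,
                age_years=age,
                sex=str(row["sex"]).strip().lower(),
                comorbidities=frozenset(
                    f for f in COMORBIDITY_FLAGS if _parse_bool(row[f], where)
                ),
                addiction_flags=frozenset(
                    f for f in ADDICTION_FLAGS if _parse_bool(row[f], where)
                ),
                chronic_meds=frozenset(_split_meds(row["chronic_meds"], kb, report)),
                self_meds=frozenset(_split_meds(row["self_meds"], kb, report)),
                outcome=str(row["outcome"]).strip().lower(),
            )

    days: dict[str, dict[int, ClinicalDay]] = {pid: {} for pid in static}
    with open(days_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(_DAY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CohortSchemaError(f"{days_path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{days_path}:{lineno}"
            pid = str(row["patient_id"]).strip()
            if pid not in static:
                raise CohortSchemaError(f"{where}: day row for unknown patient {pid!r}")
            try:
                idx = int(str(row["day_index"]).strip())
            except ValueError:
                raise CohortSchemaError(
                    f"{where}: non-integer day_index {row['day_index']!r}"
                ) from None
            if idx in days[pid]:
                raise CohortSchemaError(f"{where}: duplicate day {idx} for {pid!r}")
            potassium = _parse_float(row["potassium_mmol_l"], where)
            qt = _parse_float(row["qt_ms"], where)
            if potassium is None:
                report.n_missing_potassium += 1
            if qt is None:
                report.n_missing_qt += 1
            try:
                day = ClinicalDay(
                    day_index=idx,
                    meds=_split_meds(row["meds"], kb, report),
                    potassium_mmol_per_l=potassium,
                    qt_ms=qt,
                    sepsis=_parse_bool(row["sepsis"], where),
                )
            except ValueError as exc:
                raise CohortSchemaError(f"{where}: {exc}") from None
            days[pid][idx] = day

    patients = []
    for pid, attrs in static.items():
        ordered = tuple(days[pid][i] for i in sorted(days[pid]))
        patients.append(PatientRecord(days=ordered, **attrs))
    cohort = Cohort(patients=patients, provenance=str(patients_path))
    report.n_patients = len(patients)
    report.n_days = cohort.n_patient_days()
    return cohort, report


def write_cohort(
    cohort: Cohort, patients_path: str | Path, days_path: str | Path
) -> None:
    """Write a cohort back to the two-file CSV layout read by :func:`read_cohort`."""
    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PATIENT_COLUMNS)
        for p in cohort:
            writer.writerow(
                [
                    p.patient_id,
                    p.age_years,
                    p.sex,
                    *[str(f in p.comorbidities).lower() for f in COMORBIDITY_FLAGS],
                    *[str(f in p.addiction_flags).lower() for f in ADDICTION_FLAGS],
                    ";".join(sorted(p.chronic_meds)),
                    ";".join(sorted(p.self_meds)),
                    p.outcome,
                ]
            )
    with open(days_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DAY_COLUMNS)
        for p in cohort:
            for d in p.days:
                writer.writerow(
                    [
                        p.patient_id,
                        d.day_index,
                        ";".join(d.meds),
                        "" if d.potassium_mmol_per_l is None else d.potassium_mmol_per_l,
                        "" if d.qt_ms is None else d.qt_ms,
                        str(d.sepsis).lower(),
                    ]
                )


def carry_forward_labs(patient: PatientRecord) -> PatientRecord:
    """Impute missing daily labs by last observation carried forward.

    A missing potassium or QT value inherits the most recent earlier
    measurement; days before the first measurement stay missing. Idempotent;
    meds and all other fields are untouched.
    """
    new_days = []
    last_k: float | None = None
    last_qt: float | None = None
    for day in patient.days:
        k = day.potassium_mmol_per_l if day.potassium_mmol_per_l is not None else last_k
        qt = day.qt_ms if day.qt_ms is not None else last_qt
        last_k, last_qt = k, qt
        if k is not day.potassium_mmol_per_l or qt is not day.qt_ms:
            day = replace(day, potassium_mmol_per_l=k, qt_ms=qt)
        new_days.append(day)
    return replace(patient, days=tuple(new_days))


def carry_forward_cohort(cohort: Cohort) -> Cohort:
    """Apply :func:`carry_forward_labs` to every patient."""
    return Cohort(
        patients=[carry_forward_labs(p) for p in cohort.patients],
        provenance=cohort.provenance,
    )
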