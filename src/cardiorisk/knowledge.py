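"""Drug adverse-event knowledge base and substitution rules.

The knowledge base assigns each drug a therapeutic class and four binary
adverse-event flags relevant to cardiovascular safety in the ICU:

* ``qt``       — possible serious QT-interval prolongation,
* ``torsades`` — Torsades de pointes (an aggravated QT phenotype, so
  ``torsades`` implies ``qt``),
* ``ss``       — serotonin syndrome,
* ``diuretic`` — whether the drug is a diuretic (a risk-score component).

It also carries the six-rule substitution/withdrawal set used by the
counterfactual intervention simulator: QT-prolonging opioids, antipsychotics,
tricyclics, antihistamines and antiemetics are replaced with non-QT
alternatives with the same clinical indication; ineffective COVID-era
therapies (antimalarials, anti-HIV antivirals, cyclobenzaprine) are withdrawn.

A bundled default knowledge base covers the drugs that appear in the study
cohort's printed characterization; it is deliberately small and text-based
(CSV + YAML) so it can be audited and extended by hand.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import yaml

__all__ = [
    "DrugEntry",
    "SubstitutionRule",
    "KnowledgeBase",
    "AdeFlags",
    "KnowledgeBaseError",
    "THERAPEUTIC_CLASSES",
    "load_knowledge_base",
    "write_knowledge_base",
    "default_knowledge_base",
    "normalize_drug_name",
]

THERAPEUTIC_CLASSES = frozenset(
    {
        "opioid_analgesic",
        "antipsychotic",
        "tricyclic_antidepressant",
        "antihistamine",
        "antiemetic",
        "antimalarial",
        "anti_hiv_antiviral",
        "muscle_relaxant",
        "sedative",
        "antibiotic",
        "diuretic",
        "other",
    }
)

_WS = re.compile(r"\s+")


class KnowledgeBaseError(ValueError):
    """Raised when a knowledge-base file violates its schema or invariants."""


def _normalize(raw: str) -> str:
    if raw is None or not str(raw).strip():
        raise ValueError("drug name must be a non-empty string")
    return _WS.sub(" ", str(raw).strip().lower())


@dataclass(frozen=True)
class DrugEntry:
    """One drug with its therapeutic class and adverse-event flags.

    ``cv_caution`` marks drugs carrying a non-QT cardiovascular caution
    (e.g. bradycardia/hypotension risk); it never contributes to the
    QT-drug count of the risk score.
    """

    name: str
    therapeutic_class: str
    qt_prolongation: bool
    torsades: bool
    serotonin_syndrome: bool
    is_diuretic: bool
    cv_caution: bool = False

    def __post_init__(self) -> None:
        if self.name != _normalize(self.name):
            raise KnowledgeBaseError(f"drug name not normalized: {self.name!r}")
        if self.therapeutic_class not in THERAPEUTIC_CLASSES:
            raise KnowledgeBaseError(
                f"unknown therapeutic class {self.therapeutic_class!r} "
                f"for drug {self.name!r}"
            )
        if self.torsades and not self.qt_prolongation:
            raise KnowledgeBaseError(
                f"{self.name!r}: torsades flag requires qt_prolongation"
            )


@dataclass(frozen=True)
class SubstitutionRule:
    """One intervention rule: replace or withdraw a set of source drugs."""

    rule_id: str
    action: str  # "replace" | "withdraw"
    source_drugs: frozenset[str]
    replacement_candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.action not in ("replace", "withdraw"):
            raise KnowledgeBaseError(
                f"rule {self.rule_id}: action must be replace|withdraw"
            )
        if not self.source_drugs:
            raise KnowledgeBaseError(f"rule {self.rule_id}: empty source set")
        if self.action == "replace" and not self.replacement_candidates:
            raise KnowledgeBaseError(
                f"rule {self.rule_id}: replace rule needs candidates"
            )
        if self.action == "withdraw" and self.replacement_candidates:
            raise KnowledgeBaseError(
                f"rule {self.rule_id}: withdraw rule cannot list candidates"
            )
        overlap = self.source_drugs & set(self.replacement_candidates)
        if overlap:
            raise KnowledgeBaseError(
                f"rule {self.rule_id}: drugs {sorted(overlap)} appear as both "
                "source and replacement"
            )


class AdeFlags(NamedTuple):
    """Adverse-event flags for one drug; ``unknown`` marks coverage gaps."""

    qt: bool
    torsades: bool
    ss: bool
    diuretic: bool
    unknown: bool = False


@dataclass
class KnowledgeBase:
    """Validated container for drug entries, rules and name synonyms."""

    drugs: dict[str, DrugEntry] = field(default_factory=dict)
    rules: list[SubstitutionRule] = field(default_factory=list)
    synonym_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ----------------------------------------------------------

    def normalize(self, raw: str) -> str:
        """Lowercase, trim, collapse whitespace and resolve synonyms.

        Unknown names pass through normalized; callers decide whether to
        flag them (see :meth:`ade_flags`).
        """
        name = _normalize(raw)
        return self.synonym_map.get(name, name)

    def ade_flags(self, name: str) -> AdeFlags:
        """Flags for a normalized drug name; unknown drugs are all-false."""
        entry = self.drugs.get(name)
        if entry is None:
            return AdeFlags(False, False, False, False, unknown=True)
        return AdeFlags(
            entry.qt_prolongation,
            entry.torsades,
            entry.serotonin_syndrome,
            entry.is_diuretic,
            unknown=False,
        )

    def is_qt_drug(self, name: str) -> bool:
        entry = self.drugs.get(name)
        return entry is not None and entry.qt_prolongation

    def qt_drugs(self) -> list[str]:
        return sorted(n for n, e in self.drugs.items() if e.qt_prolongation)

    def therapeutic_class(self, name: str) -> str | None:
        entry = self.drugs.get(name)
        return None if entry is None else entry.therapeutic_class

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        seen_sources: set[str] = set()
        for rule in self.rules:
            if rule.source_drugs & seen_sources:
                raise KnowledgeBaseError(
                    f"rule {rule.rule_id}: source drugs overlap another rule"
                )
            seen_sources |= rule.source_drugs
            for name in sorted(rule.source_drugs | set(rule.replacement_candidates)):
                resolved = self.synonym_map.get(name, name)
                if resolved not in self.drugs:
                    raise KnowledgeBaseError(
                        f"rule {rule.rule_id} references unknown drug {name!r}"
                    )
            for cand in rule.replacement_candidates:
                resolved = self.synonym_map.get(cand, cand)
                if self.drugs[resolved].qt_prolongation:
                    raise KnowledgeBaseError(
                        f"rule {rule.rule_id}: replacement {cand!r} is itself "
                        "QT-prolonging"
                    )
        for alias, canonical in self.synonym_map.items():
            if canonical not in self.drugs:
                raise KnowledgeBaseError(
                    f"synonym {alias!r} maps to unknown drug {canonical!r}"
                )


# ---------------------------------------------------------------------------
# module-level functional API


def normalize_drug_name(raw: str, kb: KnowledgeBase | None = None) -> str:
    """Normalize a raw drug name, resolving synonyms when a KB is given."""
    if kb is not None:
        return kb.normalize(raw)
    return _normalize(raw)


def ade_flags(name: str, kb: KnowledgeBase) -> AdeFlags:
    return kb.ade_flags(name)


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def _parse_bool(value: str, where: str) -> bool:
    try:
        return _BOOL[str(value).strip().lower()]
    except KeyError:
        raise KnowledgeBaseError(f"{where}: expected a boolean, got {value!r}") from None


def _read_drugs_csv(path: Path) -> dict[str, DrugEntry]:
    drugs: dict[str, DrugEntry] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "therapeutic_class", "qt", "torsades", "ss", "diuretic"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise KnowledgeBaseError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}:{lineno}"
            try:
                name = _normalize(row["name"])
            except ValueError:
                raise KnowledgeBaseError(f"{where}: empty drug name") from None
            if name in drugs:
                raise KnowledgeBaseError(f"{where}: duplicate drug name {name!r}")
            entry = DrugEntry(
                name=name,
                therapeutic_class=str(row["therapeutic_class"]).strip(),
                qt_prolongation=_parse_bool(row["qt"], where),
                torsades=_parse_bool(row["torsades"], where),
                serotonin_syndrome=_parse_bool(row["ss"], where),
                is_diuretic=_parse_bool(row["diuretic"], where),
                cv_caution=_parse_bool(row.get("cv_caution", "false"), where),
            )
            drugs[name] = entry
    return drugs


def _read_rules_yaml(path: Path) -> list[SubstitutionRule]:
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        return []
    if not isinstance(raw, list):
        raise KnowledgeBaseError(f"{path}: rules file must be a YAML list")
    rules = []
    for item in raw:
        try:
            rules.append(
                SubstitutionRule(
                    rule_id=str(item["rule_id"]),
                    action=str(item["action"]),
                    source_drugs=frozenset(_normalize(d) for d in item["source_drugs"]),
                    replacement_candidates=tuple(
                        _normalize(d) for d in item.get("replacement_candidates") or []
                    ),
                )
            )
        except (KeyError, TypeError) as exc:
            raise KnowledgeBaseError(f"{path}: malformed rule entry {item!r}") from exc
    return rules


def _read_synonyms_csv(path: Path) -> dict[str, str]:
    synonyms: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"alias", "canonical"} <= set(reader.fieldnames):
            raise KnowledgeBaseError(f"{path}: expected columns alias,canonical")
        for lineno, row in enumerate(reader, start=2):
            alias = _normalize(row["alias"])
            if alias in synonyms:
                raise KnowledgeBaseError(f"{path}:{lineno}: duplicate alias {alias!r}")
            synonyms[alias] = _normalize(row["canonical"])
    return synonyms


def load_knowledge_base(
    path: str | Path,
    rules_path: str | Path | None = None,
    synonyms_path: str | Path | None = None,
) -> KnowledgeBase:
    """Load and validate a knowledge base.

    ``path`` is either a directory holding ``drugs.csv`` (plus optional
    ``rules.yaml`` and ``synonyms.csv``) or the drug-table CSV itself, with
    the rules/synonyms files given explicitly.
    """
    path = Path(path)
    if path.is_dir():
        drugs_path = path / "drugs.csv"
        rules_path = rules_path or (
            path / "rules.yaml" if (path / "rules.yaml").exists() else None
        )
        synonyms_path = synonyms_path or (
            path / "synonyms.csv" if (path / "synonyms.csv").exists() else None
        )
    else:
        drugs_path = path
    if not drugs_path.exists():
        raise FileNotFoundError(f"drug table not found: {drugs_path}")
    drugs = _read_drugs_csv(drugs_path)
    rules = _read_rules_yaml(Path(rules_path)) if rules_path else []
    synonyms = _read_synonyms_csv(Path(synonyms_path)) if synonyms_path else {}
    return KnowledgeBase(drugs=drugs, rules=rules, synonym_map=synonyms)


def write_knowledge_base(kb: KnowledgeBase, directory: str | Path) -> None:
    """Write ``drugs.csv``, ``rules.yaml`` and ``synonyms.csv`` to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "drugs.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "therapeutic_class", "qt", "torsades", "ss", "diuretic", "cv_caution"]
        )
        for entry in sorted(kb.drugs.values(), key=lambda e: e.name):
            writer.writerow(
                [
                    entry.name,
                    entry.therapeutic_class,
                    str(entry.qt_prolongation).lower(),
                    str(entry.torsades).lower(),
                    str(entry.serotonin_syndrome).lower(),
                    str(entry.is_diuretic).lower(),
                    str(entry.cv_caution).lower(),
                ]
            )
    rules_doc = [
        {
            "rule_id": r.rule_id,
            "action": r.action,
            "source_drugs": sorted(r.source_drugs),
            "replacement_candidates": list(r.replacement_candidates),
        }
        for r in kb.rules
    ]
    (directory / "rules.yaml").write_text(
        yaml.safe_dump(rules_doc, sort_keys=False), encoding="utf-8"
    )
    with open(directory / "synonyms.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["alias", "canonical"])
        for alias in sorted(kb.synonym_map):
            writer.writerow([alias, kb.synonym_map[alias]])


def default_knowledge_base() -> KnowledgeBase:
    """The bundled knowledge base covering the study cohort's drugs."""
    data_dir = resources.files("cardiorisk") / "data"
    with resources.as_file(data_dir) as path:
        return load_knowledge_base(path)
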