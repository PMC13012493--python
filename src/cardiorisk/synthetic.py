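"""Synthetic ICU cohort generator.

Generates cohorts with the marginal structure of the study population — a
2020 COVID-19 ICU cohort: 65% male, majority aged 60+, high prevalence of
systemic arterial hypertension and diabetes, long ICU stays, and a daily
drug burden dominated by sedation/analgesia (fentanyl the most administered
drug) — so that every pipeline stage is testable without access to any real
patient data.

Demographics, comorbidities and length of stay are drawn from configured
marginals; each ICU day then draws a drug set (weighted sampling without
replacement), serum potassium, QT interval and a sepsis flag. Days are
conditionally independent given the patient. All randomness flows from a
single integer seed, so a fixed parameter set reproduces the cohort exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .cohort import ClinicalDay, Cohort, PatientRecord
from .knowledge import KnowledgeBase

__all__ = ["GeneratorParams", "generate_cohort", "scenario_presets"]

# Table-calibrated marginals, expressed as exact count fractions of the
# 106-patient study population so each block sums to one.
_N = 106
AGE_BANDS = ((25, 39), (40, 49), (50, 59), (60, 90))
DEFAULT_AGE_BAND_PROBS = (8 / _N, 15 / _N, 24 / _N, 59 / _N)
LOS_BANDS = ((1, 6), (7, 13), (14, 20), (21, 27), (28, 45))
DEFAULT_LOS_BAND_PROBS = (18 / _N, 13 / _N, 29 / _N, 18 / _N, 28 / _N)
DEFAULT_OUTCOME_PROBS = {
    "death": 78 / _N,
    "discharge_with_sequelae": 10 / _N,
    "transfer": 10 / _N,
    "discharge": 8 / _N,
}
DEFAULT_COMORBIDITY_PROBS = {
    "sah": 0.58,
    "diabetes": 0.36,
    "obesity": 0.396,
    "ami_history": 0.08,
    "chf_reduced_ef": 0.02,
    "arrhythmia": 0.05,
}
# administration frequencies of the most-used serious-ADE drugs; the
# remaining probability mass is spread uniformly over the rest of the KB
DEFAULT_DRUG_WEIGHTS = {
    "fentanyl": 0.048,
    "ondansetron": 0.033,
    "dexmedetomidine": 0.018,
    "azithromycin": 0.013,
}

_CHRONIC_QT_POOL = (
    "propranolol",
    "clonidine",
    "promethazine",
    "amiodarone",
    "amitriptyline",
    "sertraline",
    "escitalopram",
    "nortriptyline",
    "haloperidol",
    "risperidone",
    "tacrolimus",
)
_SELF_MED_QT_POOL = ("azithromycin", "chloroquine", "hydroxychloroquine", "moxifloxacin")


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic generator, defaulting to the study marginals.

    Per-day lab/sepsis probabilities are calibration knobs (no per-day
    prevalences are printed for the study cohort); defaults are chosen so
    the baseline scenario lands in the study's qualitative regime of
    majority high risk.
    """

    n_patients: int = 106
    seed: int = 0
    p_male: float = 0.65
    age_band_probs: tuple[float, ...] = DEFAULT_AGE_BAND_PROBS
    comorbidity_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_PROBS)
    )
    p_chronic_meds: float = 0.65
    p_chronic_qt_drug: float = 0.14 / 0.65  # chronic QT drug | chronic user
    p_self_med: float = 0.20
    p_self_med_qt_drug: float = 0.17 / 0.20  # QT self-medication | self-medicator
    los_band_probs: tuple[float, ...] = DEFAULT_LOS_BAND_PROBS
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS)
    )
    drug_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_WEIGHTS)
    )
    mean_drugs_per_day: float = 8.0
    p_hypokalemia_day: float = 0.15
    p_long_qt_day: float = 0.25
    p_sepsis_day: float = 0.20
    min_qt_drugs_per_day: int = 0
    restrict_to_drugs: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.mean_drugs_per_day < 1:
            raise ValueError("mean_drugs_per_day must be >= 1")
        if self.min_qt_drugs_per_day < 0:
            raise ValueError("min_qt_drugs_per_day must be >= 0")
        probs = [
            self.p_male,
            self.p_chronic_meds,
            self.p_chronic_qt_drug,
            self.p_self_med,
            self.p_self_med_qt_drug,
            self.p_hypokalemia_day,
            self.p_long_qt_day,
            self.p_sepsis_day,
            *self.comorbidity_probs.values(),
            *self.drug_weights.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for name, bands, expect in (
            ("age_band_probs", self.age_band_probs, len(AGE_BANDS)),
            ("los_band_probs", self.los_band_probs, len(LOS_BANDS)),
        ):
            if len(bands) != expect:
                raise ValueError(f"{name} must have {expect} entries")
            if any(not (0.0 <= p <= 1.0) for p in bands):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(bands) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if abs(sum(self.outcome_probs.values()) - 1.0) > 1e-9:
            raise ValueError("outcome_probs must sum to 1")


def _day_drug_sets(
    rng: np.random.Generator,
    n_days: int,
    pool: list[str],
    weights: np.ndarray,
    mean_k: float,
    min_qt: int,
    qt_mask: np.ndarray,
) -> list[tuple[str, ...]]:
    """Weighted sampling without replacement of one drug set per day.

    Uses the Gumbel-top-k trick: per (day, drug) perturbed log-weights are
    drawn once and each day's set is the top-k of its row, which reproduces
    successive weighted draws without replacement. ``min_qt`` QT-flagged
    drugs per day are forced into the set first.
    """
    n_pool = len(pool)
    n_positive = int((weights > 0).sum())
    with np.errstate(divide="ignore"):
        logw = np.log(weights)
    scores = logw[None, :] + rng.gumbel(size=(n_days, n_pool))
    if min_qt > 0:
        qt_idx = np.flatnonzero(qt_mask & (weights > 0))
        if len(qt_idx) < min_qt:
            raise ValueError(
                f"cannot force {min_qt} QT drugs/day: only {len(qt_idx)} "
                "QT drugs have positive weight"
            )
        qt_scores = scores[:, qt_idx]
        forced = np.argpartition(-qt_scores, min_qt - 1, axis=1)[:, :min_qt]
        rows = np.repeat(np.arange(n_days), min_qt)
        scores[rows, qt_idx[forced.ravel()]] = np.inf
    k_per_day = rng.poisson(mean_k, size=n_days)
    k_per_day = np.clip(k_per_day, max(1, min_qt), n_positive)
    sets: list[tuple[str, ...] | None] = [None] * n_days
    for k in np.unique(k_per_day):
        rows = np.flatnonzero(k_per_day == k)
        top = np.argpartition(-scores[rows], k - 1, axis=1)[:, :k]
        top.sort(axis=1)  # stable pool order inside a day
        for r, cols in zip(rows, top):
            sets[r] = tuple(pool[c] for c in cols)
    return sets  # type: ignore[return-value]


def generate_cohort(
    params: GeneratorParams, kb: KnowledgeBase, seed: int | None = None
) -> Cohort:
    """Draw a full synthetic cohort; identical params + seed => identical cohort."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = params.n_patients

    male = rng.random(n) < params.p_male
    band = rng.choice(len(AGE_BANDS), size=n, p=params.age_band_probs)
    lo = np.array([b[0] for b in AGE_BANDS])
    hi = np.array([b[1] for b in AGE_BANDS])
    ages = rng.integers(lo[band], hi[band] + 1)
    comorbid_draws = {
        flag: rng.random(n) < p for flag, p in params.comorbidity_probs.items()
    }
    outcomes = rng.choice(
        list(params.outcome_probs), size=n, p=list(params.outcome_probs.values())
    )
    los_band = rng.choice(len(LOS_BANDS), size=n, p=params.los_band_probs)
    los_lo = np.array([b[0] for b in LOS_BANDS])
    los_hi = np.array([b[1] for b in LOS_BANDS])
    los = rng.integers(los_lo[los_band], los_hi[los_band] + 1)

    chronic_user = rng.random(n) < params.p_chronic_meds
    chronic_qt = chronic_user & (rng.random(n) < params.p_chronic_qt_drug)
    chronic_qt_pick = rng.integers(0, len(_CHRONIC_QT_POOL), size=n)
    self_med_user = rng.random(n) < params.p_self_med
    self_qt = self_med_user & (rng.random(n) < params.p_self_med_qt_drug)
    self_qt_pick = rng.integers(0, len(_SELF_MED_QT_POOL), size=n)

    if params.restrict_to_drugs is not None:
        pool = sorted(params.restrict_to_drugs)
        missing = [d for d in pool if d not in kb.drugs]
        if missing:
            raise ValueError(f"restrict_to_drugs not in knowledge base: {missing}")
    else:
        pool = sorted(kb.drugs)
    weights = np.zeros(len(pool))
    named_mass = 0.0
    for i, name in enumerate(pool):
        if name in params.drug_weights:
            weights[i] = params.drug_weights[name]
            named_mass += weights[i]
    unnamed = [i for i, name in enumerate(pool) if name not in params.drug_weights]
    if unnamed:
        weights[unnamed] = max(0.0, 1.0 - named_mass) / len(unnamed)
    if weights.sum() <= 0:
        raise ValueError("drug weights sum to zero over the sampling pool")
    qt_mask = np.array([kb.is_qt_drug(name) for name in pool])

    total_days = int(los.sum())
    day_meds = _day_drug_sets(
        rng,
        total_days,
        pool,
        weights,
        params.mean_drugs_per_day,
        params.min_qt_drugs_per_day,
        qt_mask,
    )
    hypo = rng.random(total_days) < params.p_hypokalemia_day
    k_low = np.clip(rng.normal(3.1, 0.25, total_days), 1.5, 3.5)
    k_norm = np.clip(rng.normal(4.2, 0.4, total_days), 3.51, 8.5)
    potassium = np.round(np.where(hypo, k_low, k_norm), 2)
    long_qt = rng.random(total_days) < params.p_long_qt_day
    qt_long = np.clip(rng.normal(465, 12, total_days), 450, 650)
    qt_norm = np.clip(rng.normal(410, 20, total_days), 250, 449)
    qt_ms = np.round(np.where(long_qt, qt_long, qt_norm), 0)
    sepsis = rng.random(total_days) < params.p_sepsis_day

    patients: list[PatientRecord] = []
    cursor = 0
    width = len(str(n))
    for i in range(n):
        days = tuple(
            ClinicalDay(
                day_index=j + 1,
                meds=day_meds[cursor + j],
                potassium_mmol_per_l=float(potassium[cursor + j]),
                qt_ms=float(qt_ms[cursor + j]),
                sepsis=bool(sepsis[cursor + j]),
            )
            for j in range(int(los[i]))
        )
        cursor += int(los[i])
        chronic: set[str] = set()
        if chronic_user[i]:
            chronic.add("paracetamol")
            if chronic_qt[i]:
                chronic.add(_CHRONIC_QT_POOL[chronic_qt_pick[i]])
        self_meds: set[str] = set()
        if self_med_user[i]:
            self_meds.add("paracetamol")
            if self_qt[i]:
                self_meds.add(_SELF_MED_QT_POOL[self_qt_pick[i]])
        patients.append(
            PatientRecord(
                patient_id=f"SYN{i + 1:0{width}d}",
                age_years=int(ages[i]),
                sex="male" if male[i] else "female",
                comorbidities=frozenset(
                    f for f, draws in comorbid_draws.items() if draws[i]
                ),
                addiction_flags=frozenset(),
                chronic_meds=frozenset(chronic),
                self_meds=frozenset(self_meds),
                outcome=str(outcomes[i]),
                days=days,
            )
        )
    return Cohort(
        patients=patients,
        provenance=f"synthetic(seed={params.seed if seed is None else seed})",
    )


def scenario_presets() -> dict[str, GeneratorParams]:
    """Named generator configurations.

    * ``baseline_covid_icu`` — the study-calibrated defaults.
    * ``low_risk`` — short drug lists restricted to non-QT drugs, near-normal
      labs, rare sepsis: almost the whole cohort should score low.
    * ``qt_saturated`` — every day carries at least two QT-prolonging drugs,
      with frequent hypokalemia, long QT and sepsis: emulates a
      near-saturated high-risk cohort whose risk collapses once the
      substitution rules fire.
    """
    safe_pool = (
        "morphine",
        "fentanyl",
        "hydromorphone",
        "metoclopramide",
        "propofol",
        "midazolam",
        "dexmedetomidine",
        "ketamine",
        "paracetamol",
    )
    return {
        "baseline_covid_icu": GeneratorParams(),
        "low_risk": GeneratorParams(
            restrict_to_drugs=safe_pool,
            mean_drugs_per_day=4.0,
            p_hypokalemia_day=0.02,
            p_long_qt_day=0.02,
            p_sepsis_day=0.02,
        ),
        "qt_saturated": GeneratorParams(
            min_qt_drugs_per_day=2,
            p_hypokalemia_day=0.35,
            p_long_qt_day=0.60,
            p_sepsis_day=0.50,
            los_band_probs=(0.0, 0.20, 0.30, 0.20, 0.30),
            # administration mass concentrated on the COVID-era prescribing
            # pattern the substitution rules target (antiemetics, typical
            # antipsychotics, opioids, repurposed antimalarials/antivirals)
            # plus the usual sedation/analgesia backbone
            drug_weights={
                "fentanyl": 0.10,
                "ondansetron": 0.10,
                "haloperidol": 0.08,
                "propofol": 0.08,
                "furosemide": 0.06,
                "midazolam": 0.06,
                "chloroquine": 0.06,
                "dexmedetomidine": 0.05,
                "paracetamol": 0.05,
                "methadone": 0.04,
                "tramadol": 0.04,
                "promethazine": 0.04,
                "hydroxychloroquine": 0.04,
                "lopinavir": 0.04,
                "morphine": 0.04,
                "domperidone": 0.03,
                "metoclopramide": 0.03,
                "nortriptyline": 0.02,
                "cyclobenzaprine": 0.02,
            },
        ),
    }


def get_preset(name: str) -> GeneratorParams:
    presets = scenario_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def preset_with(name: str, **overrides) -> GeneratorParams:
    """A preset with fields replaced, e.g. ``preset_with('low_risk', seed=7)``."""
    return dataclasses.replace(get_preset(name), **overrides)
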