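"""Rubric scoring: brute-force oracle equivalence, bands, patient summaries."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiorisk import (
    RiskThresholds,
    TisdaleWeights,
    classify_risk,
    count_qt_drugs,
    daily_score,
    patient_risk,
)

from conftest import make_day, make_patient

QT_DRUGS = ("haloperidol", "ondansetron", "amiodarone")  # distinct QT-flagged
SAFE_DRUGS = ("paracetamol", "morphine")


def brute_force_total(
    age_ge_68, female, diuretic, low_k, long_qt, n_qt_drugs, ami, chf, sepsis
):
    """Independent re-statement of the additive rubric."""
    total = 0
    total += 1 if age_ge_68 else 0
    total += 1 if female else 0
    total += 1 if diuretic else 0
    total += 2 if low_k else 0
    total += 2 if long_qt else 0
    if n_qt_drugs == 1:
        total += 3
    elif n_qt_drugs >= 2:
        total += 6
    total += 2 if ami else 0
    total += 3 if chf else 0
    total += 3 if sepsis else 0
    return total


def test_daily_score_matches_brute_force_over_all_component_combinations(kb):
    """Exhaustive oracle: every boolean combination x qt-drug count in 0..3."""
    max_seen = 0
    for flags in itertools.product([False, True], repeat=8):
        age68, female, diuretic, low_k, long_qt, ami, chf, sepsis = flags
        for n_qt in range(4):
            meds = list(QT_DRUGS[:n_qt])
            if diuretic:
                meds.append("furosemide")
            patient = make_patient(
                age=70 if age68 else 50,
                sex="female" if female else "male",
                comorbidities=(
                    (("ami_history",) if ami else ())
                    + (("chf_reduced_ef",) if chf else ())
                ),
            )
            day = make_day(
                meds=meds,
                potassium=3.2 if low_k else 4.2,
                qt=460.0 if long_qt else 400.0,
                sepsis=sepsis,
            )
            expected = brute_force_total(
                age68, female, diuretic, low_k, long_qt, n_qt, ami, chf, sepsis
            )
            got = daily_score(patient, day, kb)
            assert got.total == expected
            assert got.qt_drug_count == n_qt
            assert got.risk_class == classify_risk(expected)
            max_seen = max(max_seen, got.total)
    assert max_seen == 21
    assert TisdaleWeights().max_total == 21


def test_worked_example_high_risk_day(kb):
    """70y female, diuretic, K=3.2, QT=460, two QT drugs, sepsis -> 16, high."""
    patient = make_patient(age=70, sex="female")
    day = make_day(
        meds=["furosemide", "haloperidol", "ondansetron"],
        potassium=3.2,
        qt=460.0,
        sepsis=True,
    )
    s = daily_score(patient, day, kb)
    assert s.components == {
        "age_ge_68": 1,
        "female": 1,
        "diuretic": 1,
        "potassium_le_3_5": 2,
        "qt_ge_450": 2,
        "qt_drugs": 6,
        "ami_history": 0,
        "chf_reduced_ef": 0,
        "sepsis": 3,
    }
    assert s.total == 16
    assert s.risk_class == "high"


def test_zero_and_small_scores(kb):
    quiet = daily_score(
        make_patient(age=30), make_day(potassium=4.2, qt=400.0), kb
    )
    assert quiet.total == 0 and quiet.risk_class == "low"
    older = daily_score(
        make_patient(age=68), make_day(meds=["haloperidol"]), kb
    )
    assert older.total == 4 and older.risk_class == "low"


def test_missing_labs_score_zero_points(kb):
    s = daily_score(make_patient(), make_day(potassium=None, qt=None), kb)
    assert s.components["potassium_le_3_5"] == 0
    assert s.components["qt_ge_450"] == 0


@pytest.mark.parametrize(
    "total,expected",
    [(0, "low"), (5, "low"), (6, "low"), (7, "moderate"), (8, "moderate"),
     (10, "moderate"), (11, "high"), (21, "high")],
)
def test_risk_band_boundaries(total, expected):
    assert classify_risk(total) == expected


def test_negative_total_rejected():
    with pytest.raises(ValueError):
        classify_risk(-1)


def test_custom_thresholds_shift_bands():
    t = RiskThresholds(low_max=3, moderate_max=7)
    assert classify_risk(4, t) == "moderate"
    assert classify_risk(8, t) == "high"


def test_count_qt_drugs_distinctness_and_unknowns(kb):
    assert count_qt_drugs(["haloperidol", "ondansetron", "paracetamol"], kb) == 2
    assert count_qt_drugs([], kb) == 0
    assert count_qt_drugs(["chloroquine", "chloroquine"], kb) == 1
    assert count_qt_drugs(["totally-unknown-drug"], kb) == 0


def test_patient_risk_max_day_and_tie_break(kb):
    # day totals: 0 (nothing), 6 (2 QT drugs), 3 (1 QT drug)
    patient = make_patient(
        days=[[], ["haloperidol", "ondansetron"], ["haloperidol"]]
    )
    best, series = patient_risk(patient, kb)
    assert [s.total for s in series] == [0, 6, 3]
    assert best.day_index == 2 and best.total == 6

    tied = make_patient(days=[["haloperidol"], ["ondansetron"]])
    best, series = patient_risk(tied, kb)
    assert [s.total for s in series] == [3, 3]
    assert best.day_index == 1  # ties break to the earliest day


def test_patient_risk_requires_days(kb):
    with pytest.raises(ValueError):
        patient_risk(make_patient(days=[]), kb)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    meds=st.lists(
        st.sampled_from(QT_DRUGS + SAFE_DRUGS + ("furosemide",)),
        max_size=6, unique=True,
    ),
    data=st.data(),
)
def test_score_invariant_to_med_order_and_monotone_in_qt_drugs(kb, meds, data):
    patient = make_patient(age=70, sex="female")
    perm = data.draw(st.permutations(meds))
    day = make_day(meds=meds, potassium=3.0, qt=455.0, sepsis=True)
    day_perm = make_day(meds=perm, potassium=3.0, qt=455.0, sepsis=True)
    s = daily_score(patient, day, kb)
    assert s.total == daily_score(patient, day_perm, kb).total
    # dropping any QT-flagged drug never increases the total
    for drug in meds:
        if kb.is_qt_drug(drug):
            reduced = make_day(
                meds=[m for m in meds if m != drug],
                potassium=3.0, qt=455.0, sepsis=True,
            )
            assert daily_score(patient, reduced, kb).total <= s.total
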