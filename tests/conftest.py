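import pytest

from cardiorisk import ClinicalDay, PatientRecord, default_knowledge_base


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


def make_patient(
    patient_id="p1",
    age=50,
    sex="male",
    comorbidities=(),
    days=(),
    **kwargs,
):
    if days and isinstance(days[0], (list, tuple)) and not isinstance(days[0], ClinicalDay):
        days = tuple(
            ClinicalDay(day_index=i + 1, meds=tuple(meds)) for i, meds in enumerate(days)
        )
    return PatientRecord(
        patient_id=patient_id,
        age_years=age,
        sex=sex,
        comorbidities=frozenset(comorbidities),
        days=tuple(days),
        **kwargs,
    )


def make_day(index=1, meds=(), potassium=None, qt=None, sepsis=False):
    return ClinicalDay(
        day_index=index,
        meds=tuple(meds),
        potassium_mmol_per_l=potassium,
        qt_ms=qt,
        sepsis=sepsis,
    )
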