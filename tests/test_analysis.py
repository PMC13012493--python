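"""Cohort statistics: prevalence ratios, paired Wilcoxon, before/after report."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from cardiorisk import (
    Cohort,
    ContingencyTable,
    ade_drug_inventory,
    apply_intervention,
    compare_before_after,
    contingency_by_feature,
    paired_wilcoxon,
    prevalence_ratio,
    prevalence_ratio_glm,
    risk_distribution,
    score_increased,
)

from conftest import make_day, make_patient

# ---------------------------------------------------------------------------
# prevalence ratios — the study's stratified 2x2 tables

TABLE_CASES = [
    ("male_vs_female", ContingencyTable(19, 69, 7, 37), 1.455),
    ("multiracial_vs_white", ContingencyTable(7, 27, 5, 13), 0.674),
    ("no_sah_vs_sah", ContingencyTable(11, 45, 15, 61), 0.994),
    ("no_obesity_vs_obesity", ContingencyTable(12, 62, 14, 44), 0.608),
    ("no_smoker_vs_smoker", ContingencyTable(16, 72, 10, 34), 0.756),
]


@pytest.mark.parametrize("label,table,expected", TABLE_CASES, ids=[c[0] for c in TABLE_CASES])
def test_prevalence_ratio_point_estimates(label, table, expected):
    assert round(prevalence_ratio(table).pr, 3) == expected


@pytest.mark.parametrize("label,table,expected", TABLE_CASES, ids=[c[0] for c in TABLE_CASES])
def test_prevalence_ratio_equals_poisson_log_link_glm(label, table, expected):
    """The direct ratio of proportions equals the log-link count-model fit."""
    assert prevalence_ratio_glm(table) == pytest.approx(prevalence_ratio(table).pr, rel=1e-6)


def test_prevalence_ratio_edge_cases():
    equal = ContingencyTable(5, 50, 10, 100)
    r = prevalence_ratio(equal)
    assert r.pr == pytest.approx(1.0)
    assert r.ci_low < 1.0 < r.ci_high
    with pytest.raises(ValueError, match="infinite"):
        prevalence_ratio(ContingencyTable(3, 10, 0, 10))
    assert prevalence_ratio(ContingencyTable(0, 10, 3, 10)).pr == 0.0
    with pytest.raises(ValueError):
        ContingencyTable(11, 10, 1, 10)  # k > n


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank vs full sign-assignment enumeration


def brute_force_wilcoxon(pre, post, alternative, zero_method):
    """Enumerate all 2^m sign assignments of the nonzero differences."""
    d = np.asarray(pre, float) - np.asarray(post, float)
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size == 0 or not np.any(d):
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    nz = ranks[d != 0]
    w_obs = float(ranks[d > 0].sum())
    ge = le = 0
    for signs in itertools.product([0, 1], repeat=len(nz)):
        w = float(sum(r for r, s in zip(nz, signs) if s))
        ge += w >= w_obs - 1e-12
        le += w <= w_obs + 1e-12
    total = 2 ** len(nz)
    sf, cdf = ge / total, le / total
    if alternative == "greater":
        p = sf
    elif alternative == "less":
        p = cdf
    else:
        p = min(1.0, 2 * min(sf, cdf))
    return w_obs, p


def test_wilcoxon_all_reductions_exact_p():
    pre = list(range(10, 20))
    post = [x - 1 for x in pre]
    res = paired_wilcoxon(pre, post, alternative="greater")
    assert res.statistic == 55.0  # full positive rank sum for n = 10
    assert res.p_value == pytest.approx(2 ** -10)


def test_wilcoxon_all_identical_pairs_is_no_evidence():
    res = paired_wilcoxon([3, 3, 3], [3, 3, 3])
    assert res.p_value == 1.0 and res.statistic == 0.0


@pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
@pytest.mark.parametrize("zero_method", ["pratt", "wilcox"])
def test_wilcoxon_matches_enumeration_on_random_small_samples(alternative, zero_method):
    """Statistic and exact p equal full enumeration for n <= 10, with ties
    and zero differences included."""
    rng = np.random.default_rng(20240915)
    for _ in range(40):
        n = rng.integers(2, 11)
        pre = rng.integers(0, 6, n).astype(float)
        post = rng.integers(0, 6, n).astype(float)
        got = paired_wilcoxon(pre, post, alternative=alternative, zero_method=zero_method)
        w, p = brute_force_wilcoxon(pre, post, alternative, zero_method)
        if got.n_nonzero == 0:
            assert got.p_value == 1.0
            continue
        assert got.statistic == pytest.approx(w)
        assert got.p_value == pytest.approx(p), (pre, post)


def test_wilcoxon_matches_scipy_without_zeros_or_ties():
    """Independent route: scipy's exact signed-rank on tie-free data."""
    from scipy.stats import wilcoxon as scipy_wilcoxon

    rng = np.random.default_rng(7)
    pre = rng.permutation(20).astype(float)
    post = pre + rng.choice([-1, 1], 20) * rng.permutation(np.arange(1, 21)) / 10
    ours = paired_wilcoxon(pre, post, alternative="two-sided")
    ref = scipy_wilcoxon(pre, post, alternative="two-sided", mode="exact")
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_wilcoxon_normal_approximation_for_large_n():
    rng = np.random.default_rng(11)
    pre = rng.normal(10, 2, 60)
    post = pre - rng.normal(0.8, 1.0, 60)
    res = paired_wilcoxon(pre, post, alternative="greater")
    assert res.method == "normal"
    assert 0 < res.p_value < 0.05


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        paired_wilcoxon([1, 2], [1])
    with pytest.raises(ValueError):
        paired_wilcoxon([], [])
    with pytest.raises(ValueError):
        paired_wilcoxon([1], [1], alternative="sideways")


# ---------------------------------------------------------------------------
# distributions, inventories, before/after report


def toy_cohort():
    # hand-scored patient totals: 0 (low), 9 (moderate), 16 (high)
    quiet = make_patient(
        patient_id="quiet", age=30,
        days=(make_day(1, ["paracetamol"], potassium=4.2, qt=400.0),),
    )
    moderate = make_patient(
        patient_id="mod", age=70, sex="female",
        days=(make_day(1, ["haloperidol"], potassium=3.2, qt=455.0),),
    )  # age 1 + female 1 + K 2 + QT 2 + one QT drug 3 = 9
    high = make_patient(
        patient_id="high", age=70, sex="female",
        days=(
            make_day(
                1, ["haloperidol", "ondansetron", "furosemide"],
                potassium=3.2, qt=455.0, sepsis=True,
            ),
        ),
    )  # 1+1+1+2+2+6+3 = 16
    return Cohort(patients=[quiet, moderate, high])


def test_risk_distribution_toy(kb):
    dist = risk_distribution(toy_cohort(), kb)
    assert (dist.n_low, dist.n_moderate, dist.n_high) == (1, 1, 1)
    assert dist.fraction("high") == pytest.approx(1 / 3)
    with pytest.raises(ValueError):
        risk_distribution(Cohort(patients=[]), kb)


def test_ade_drug_inventory_counts_distinct_drugs(kb):
    cohort = Cohort(
        patients=[
            make_patient(days=[["haloperidol", "metoclopramide"], ["paracetamol",
                                                                   "haloperidol"]])
        ]
    )
    inv = ade_drug_inventory(cohort, kb)
    assert inv.n_distinct_drugs == 3
    assert inv.n_qt == 1 and inv.n_any_serious_ade == 1
    assert inv.n_torsades == 0 and inv.n_ss == 0

    empty = ade_drug_inventory(Cohort(patients=[]), kb)
    assert empty.n_distinct_drugs == 0 and empty.n_any_serious_ade == 0


def test_inventory_orderings_and_torsades_ss_counts(kb):
    cohort = Cohort(
        patients=[make_patient(days=[["methadone", "chloroquine", "morphine"]])]
    )
    inv = ade_drug_inventory(cohort, kb)
    assert inv.n_distinct_drugs == 3
    assert inv.n_qt == 2 and inv.n_torsades == 1 and inv.n_ss == 1
    assert inv.n_torsades <= inv.n_qt <= inv.n_any_serious_ade <= inv.n_distinct_drugs


def test_compare_before_after_toy(kb):
    cohort = toy_cohort()
    result = apply_intervention(cohort, kb)
    report = compare_before_after(result, kb)
    # the high-risk patient loses both QT drugs (rules ii and iii) -> 6 points
    assert report.pre_risk.n_high == 1 and report.post_risk.n_high == 0
    assert report.high_risk_change == pytest.approx(1 / 3)
    assert report.post_inventory.n_qt < report.pre_inventory.n_qt
    assert "Before/after" in report.summary()


def test_compare_before_after_identity(kb):
    cohort = Cohort(
        patients=[make_patient(days=[["paracetamol"]], age=30)]
    )
    report = compare_before_after(apply_intervention(cohort, kb), kb)
    assert report.pre_risk == report.post_risk
    assert report.high_risk_change == 0.0
    assert report.wilcoxon.p_value == 1.0


def test_score_increased_and_contingency(kb):
    rising = make_patient(
        patient_id="r", days=[[], ["haloperidol", "ondansetron"]]
    )
    flat = make_patient(patient_id="f", days=[["haloperidol"], ["haloperidol"]])
    assert score_increased(rising, kb)
    assert not score_increased(flat, kb)
    cohort = Cohort(patients=[rising, flat])
    table = contingency_by_feature(
        cohort,
        exposed=lambda p: p.patient_id == "r",
        event=lambda p: score_increased(p, kb),
    )
    assert (table.k1, table.n1, table.k2, table.n2) == (1, 1, 0, 1)
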