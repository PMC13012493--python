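"""Cohort-level aggregation and statistics.

This module turns per-day scores into the cohort-level quantities a
pharmacovigilance analysis reports:

* the distribution of patient-level risk classes (low/moderate/high),
* inventories of distinct drugs carrying serious cardiovascular adverse
  events (QT prolongation, Torsades de pointes, serotonin syndrome),
* prevalence ratios from 2x2 contingency counts, with a log-link Poisson
  GLM equivalence route,
* a paired Wilcoxon signed-rank test (Pratt zero handling, exact small-n
  null) for before/after score comparisons,
* the assembled before/after intervention report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .cohort import Cohort, PatientRecord
from .intervention import InterventionResult
from .knowledge import KnowledgeBase
from .scoring import RiskThresholds, TisdaleWeights, patient_risk

__all__ = [
    "RiskDistribution",
    "AdeDrugInventory",
    "ContingencyTable",
    "PrevalenceRatio",
    "WilcoxonResult",
    "BeforeAfterReport",
    "risk_distribution",
    "ade_drug_inventory",
    "prevalence_ratio",
    "prevalence_ratio_glm",
    "paired_wilcoxon",
    "compare_before_after",
    "score_increased",
    "contingency_by_feature",
]


# ---------------------------------------------------------------------------
# risk distribution


@dataclass(frozen=True)
class RiskDistribution:
    n_low: int
    n_moderate: int
    n_high: int

    @property
    def n_total(self) -> int:
        return self.n_low + self.n_moderate + self.n_high

    def fraction(self, risk_class: str) -> float:
        counts = {"low": self.n_low, "moderate": self.n_moderate, "high": self.n_high}
        return counts[risk_class] / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_low": self.n_low,
            "n_moderate": self.n_moderate,
            "n_high": self.n_high,
            "pct_low": 100.0 * self.fraction("low"),
            "pct_moderate": 100.0 * self.fraction("moderate"),
            "pct_high": 100.0 * self.fraction("high"),
        }


def risk_distribution(
    cohort: Cohort,
    kb: KnowledgeBase,
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
) -> RiskDistribution:
    """Tally patient-level risk classes (maximum daily score per patient)."""
    if len(cohort) == 0:
        raise ValueError("cannot compute a risk distribution for an empty cohort")
    counts = {"low": 0, "moderate": 0, "high": 0}
    for patient in cohort:
        best, _ = patient_risk(patient, kb, weights, thresholds)
        counts[best.risk_class] += 1
    return RiskDistribution(counts["low"], counts["moderate"], counts["high"])


# ---------------------------------------------------------------------------
# ADE drug inventory


@dataclass(frozen=True)
class AdeDrugInventory:
    """Distinct-drug counts over a cohort's in-ICU prescriptions.

    Flags are counted per distinct drug, not per administration; "any
    serious ADE" means QT prolongation, Torsades de pointes or serotonin
    syndrome.
    """

    n_distinct_drugs: int
    n_any_serious_ade: int
    n_qt: int
    n_torsades: int
    n_ss: int

    def __post_init__(self) -> None:
        if not (
            max(self.n_qt, self.n_torsades, self.n_ss)
            <= self.n_any_serious_ade
            <= self.n_distinct_drugs
        ):
            raise ValueError("inventory counts violate containment ordering")
        if self.n_torsades > self.n_qt:
            raise ValueError("torsades count cannot exceed QT count")

    def to_dict(self) -> dict:
        return {
            "n_distinct_drugs": self.n_distinct_drugs,
            "n_any_serious_ade": self.n_any_serious_ade,
            "n_qt": self.n_qt,
            "n_torsades": self.n_torsades,
            "n_ss": self.n_ss,
        }


def ade_drug_inventory(cohort: Cohort, kb: KnowledgeBase) -> AdeDrugInventory:
    """Count distinct drugs prescribed in-ICU and their serious-ADE flags.

    Chronic and pre-admission self-medication lists are excluded; only drugs
    administered on an ICU day enter the denominator.
    """
    distinct: set[str] = set()
    for patient in cohort:
        for day in patient.days:
            distinct.update(day.meds)
    n_qt = n_tdp = n_ss = n_any = 0
    for name in distinct:
        flags = kb.ade_flags(name)
        n_qt += flags.qt
        n_tdp += flags.torsades
        n_ss += flags.ss
        n_any += flags.qt or flags.torsades or flags.ss
    return AdeDrugInventory(len(distinct), n_any, n_qt, n_tdp, n_ss)


# ---------------------------------------------------------------------------
# prevalence ratio


@dataclass(frozen=True)
class ContingencyTable:
    """Events/totals for an exposed and a reference arm."""

    k1: int  # exposed events
    n1: int  # exposed total
    k2: int  # reference events
    n2: int  # reference total

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("arm totals must be positive")
        if not (0 <= self.k1 <= self.n1 and 0 <= self.k2 <= self.n2):
            raise ValueError("event counts must lie in [0, n] for each arm")


@dataclass(frozen=True)
class PrevalenceRatio:
    pr: float
    ci_low: float
    ci_high: float

    def rounded(self, ndigits: int = 3) -> "PrevalenceRatio":
        return PrevalenceRatio(
            round(self.pr, ndigits), round(self.ci_low, ndigits), round(self.ci_high, ndigits)
        )


def prevalence_ratio(table: ContingencyTable, alpha: float = 0.05) -> PrevalenceRatio:
    """Prevalence ratio (k1/n1)/(k2/n2) with a log-normal Wald interval.

    The interval uses var(log PR) = 1/k1 - 1/n1 + 1/k2 - 1/n2. A reference
    arm with zero events has an infinite ratio and raises; an exposed arm
    with zero events yields PR = 0 with an undefined lower interval.
    """
    if table.k2 == 0:
        raise ValueError(
            "reference arm has zero events: prevalence ratio is infinite"
        )
    pr = (table.k1 / table.n1) / (table.k2 / table.n2)
    if table.k1 == 0:
        return PrevalenceRatio(0.0, 0.0, math.nan)
    var = 1 / table.k1 - 1 / table.n1 + 1 / table.k2 - 1 / table.n2
    z = norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var)
    return PrevalenceRatio(pr, pr * math.exp(-half), pr * math.exp(half))


def prevalence_ratio_glm(table: ContingencyTable) -> float:
    """Prevalence ratio via a Poisson GLM with log link on aggregated counts.

    Algebraically identical to the direct ratio of proportions in the
    univariate case; provided as an independent cross-check route.
    """
    import warnings

    import statsmodels.api as sm

    endog = np.array([table.k1, table.k2], dtype=float)
    exog = sm.add_constant(np.array([1.0, 0.0]))
    offset = np.log(np.array([table.n1, table.n2], dtype=float))
    with warnings.catch_warnings():
        # two aggregated rows, two parameters: the fit is saturated by design
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Poisson(), offset=offset).fit()
    return float(np.exp(fit.params[1]))


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive (pre - post) differences
    p_value: float
    n_nonzero: int
    method: str  # "exact" | "normal"


def _exact_sf_cdf(doubled_ranks: Sequence[int], w2: int) -> tuple[float, float]:
    """P(W+ >= w) and P(W+ <= w) under the exact sign-permutation null.

    ``doubled_ranks`` are the (tie-midrank) ranks of the nonzero differences
    multiplied by two so they are integers; ``w2`` is the doubled observed
    statistic. Computed by dynamic programming over subset sums, equivalent
    to full enumeration of the 2^m sign assignments.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else counts[r:] + counts
    denom = 2.0 ** len(doubled_ranks)
    sf = float(counts[w2:].sum()) / denom
    cdf = float(counts[: w2 + 1].sum()) / denom
    return sf, cdf


def paired_wilcoxon(
    pre: Sequence[float],
    post: Sequence[float],
    alternative: str = "two-sided",
    zero_method: str = "pratt",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on (pre, post) measurements.

    Differences are ``pre - post``; ``alternative='greater'`` asks whether
    pre exceeds post (a score reduction). Zero differences are handled by
    the Pratt method by default (ranked with the rest, then dropped) or
    classic zero-drop (``zero_method='wilcox'``). The null distribution is
    exact (full sign enumeration) when the number of nonzero differences is
    at most ``exact_max_n``, otherwise a tie-corrected normal approximation
    with continuity correction.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if zero_method not in ("pratt", "wilcox"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size == 0:
        raise ValueError("pre and post must be equal-length non-empty 1-d vectors")
    d = pre - post
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size == 0 or not np.any(d):
        # no nonzero differences: no evidence either way
        return WilcoxonResult(0.0, 1.0, 0, "exact")
    ranks = rankdata(np.abs(d))  # midranks; zeros (Pratt) share the lowest ranks
    nonzero = d != 0
    w_plus = float(ranks[d > 0].sum())
    nz_ranks = ranks[nonzero]
    m = int(nonzero.sum())
    if m <= exact_max_n:
        doubled = np.rint(2 * nz_ranks).astype(int)
        sf, cdf = _exact_sf_cdf(doubled, int(round(2 * w_plus)))
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2 * min(sf, cdf))
        return WilcoxonResult(w_plus, p, m, "exact")
    mean = float(nz_ranks.sum()) / 2
    sd = math.sqrt(float((nz_ranks**2).sum()) / 4)
    if alternative == "greater":
        p = norm.sf((w_plus - 0.5 - mean) / sd)
    elif alternative == "less":
        p = norm.cdf((w_plus + 0.5 - mean) / sd)
    else:
        z = (w_plus - mean - math.copysign(0.5, w_plus - mean)) / sd
        p = 2 * norm.sf(abs(z))
    return WilcoxonResult(w_plus, min(1.0, float(p)), m, "normal")


# ---------------------------------------------------------------------------
# before/after comparison


@dataclass(frozen=True)
class BeforeAfterReport:
    pre_risk: RiskDistribution
    post_risk: RiskDistribution
    pre_inventory: AdeDrugInventory
    post_inventory: AdeDrugInventory
    wilcoxon: WilcoxonResult
    high_risk_change: float  # (pre_high - post_high) / cohort size

    def to_dict(self) -> dict:
        return {
            "pre_risk": self.pre_risk.to_dict(),
            "post_risk": self.post_risk.to_dict(),
            "pre_inventory": self.pre_inventory.to_dict(),
            "post_inventory": self.post_inventory.to_dict(),
            "wilcoxon": {
                "statistic": self.wilcoxon.statistic,
                "p_value": self.wilcoxon.p_value,
                "n_nonzero": self.wilcoxon.n_nonzero,
                "method": self.wilcoxon.method,
            },
            "high_risk_change_pct": 100.0 * self.high_risk_change,
        }

    def summary(self) -> str:
        pre, post = self.pre_risk, self.post_risk
        lines = [
            "Before/after hypothetical intervention",
            "=" * 40,
            f"patients: {pre.n_total}",
            (
                f"risk classes pre : low {pre.n_low} ({100 * pre.fraction('low'):.1f}%), "
                f"moderate {pre.n_moderate} ({100 * pre.fraction('moderate'):.1f}%), "
                f"high {pre.n_high} ({100 * pre.fraction('high'):.1f}%)"
            ),
            (
                f"risk classes post: low {post.n_low} ({100 * post.fraction('low'):.1f}%), "
                f"moderate {post.n_moderate} ({100 * post.fraction('moderate'):.1f}%), "
                f"high {post.n_high} ({100 * post.fraction('high'):.1f}%)"
            ),
            f"high-risk change: {100 * self.high_risk_change:.1f} points of cohort",
            (
                f"serious-ADE drugs: {self.pre_inventory.n_any_serious_ade} -> "
                f"{self.post_inventory.n_any_serious_ade} "
                f"(QT {self.pre_inventory.n_qt} -> {self.post_inventory.n_qt}, "
                f"Torsades {self.pre_inventory.n_torsades} -> {self.post_inventory.n_torsades}, "
                f"SS {self.pre_inventory.n_ss} -> {self.post_inventory.n_ss})"
            ),
            (
                f"paired Wilcoxon on max daily scores: W+ = {self.wilcoxon.statistic:.1f}, "
                f"p = {self.wilcoxon.p_value:.3g} ({self.wilcoxon.method})"
            ),
        ]
        return "\n".join(lines)


def compare_before_after(
    result: InterventionResult,
    kb: KnowledgeBase,
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
    alternative: str = "greater",
) -> BeforeAfterReport:
    """Assemble the full before/after comparison for an intervention run.

    The Wilcoxon test is paired on each patient's maximum daily score; the
    default alternative asks whether the intervention reduced scores.
    """
    pre_risk = risk_distribution(result.cohort_pre, kb, weights, thresholds)
    post_risk = risk_distribution(result.cohort_post, kb, weights, thresholds)
    pre_inv = ade_drug_inventory(result.cohort_pre, kb)
    post_inv = ade_drug_inventory(result.cohort_post, kb)
    wil = paired_wilcoxon(
        result.pre_max_totals(), result.post_max_totals(), alternative=alternative
    )
    change = (pre_risk.n_high - post_risk.n_high) / pre_risk.n_total
    return BeforeAfterReport(pre_risk, post_risk, pre_inv, post_inv, wil, change)


# ---------------------------------------------------------------------------
# "score increased" outcome and feature-stratified contingency tables


def score_increased(
    patient: PatientRecord,
    kb: KnowledgeBase,
    weights: TisdaleWeights = TisdaleWeights(),
    thresholds: RiskThresholds = RiskThresholds(),
) -> bool:
    """Whether the patient's daily score rose above its admission-day value."""
    best, series = patient_risk(patient, kb, weights, thresholds)
    return best.total > series[0].total


def contingency_by_feature(
    cohort: Cohort,
    exposed: Callable[[PatientRecord], bool],
    event: Callable[[PatientRecord], bool],
) -> ContingencyTable:
    """Build a 2x2 table splitting the cohort by an exposure predicate."""
    k1 = n1 = k2 = n2 = 0
    for patient in cohort:
        if exposed(patient):
            n1 += 1
            k1 += bool(event(patient))
        else:
            n2 += 1
            k2 += bool(event(patient))
    return ContingencyTable(k1, n1, k2, n2)


def plot_before_after(report: BeforeAfterReport, path: str) -> None:
    """Two-panel bar chart: risk classes and serious-ADE drug counts, pre/post."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    x = np.arange(3)
    width = 0.38
    pre = [report.pre_risk.n_low, report.pre_risk.n_moderate, report.pre_risk.n_high]
    post = [report.post_risk.n_low, report.post_risk.n_moderate, report.post_risk.n_high]
    ax1.bar(x - width / 2, pre, width, label="before")
    ax1.bar(x + width / 2, post, width, label="after")
    ax1.set_xticks(x, ["low", "moderate", "high"])
    ax1.set_ylabel("patients")
    ax1.set_title("Risk class")
    ax1.legend()
    labels = ["any serious", "QT", "Torsades", "SS"]
    pre_inv = [
        report.pre_inventory.n_any_serious_ade,
        report.pre_inventory.n_qt,
        report.pre_inventory.n_torsades,
        report.pre_inventory.n_ss,
    ]
    post_inv = [
        report.post_inventory.n_any_serious_ade,
        report.post_inventory.n_qt,
        report.post_inventory.n_torsades,
        report.post_inventory.n_ss,
    ]
    x = np.arange(4)
    ax2.bar(x - width / 2, pre_inv, width, label="before")
    ax2.bar(x + width / 2, post_inv, width, label="after")
    ax2.set_xticks(x, labels)
    ax2.set_ylabel("distinct drugs")
    ax2.set_title("Serious cardiovascular ADE drugs")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
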