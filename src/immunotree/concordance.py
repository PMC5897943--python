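"""Concordance statistics between predicted and clinical responses.

Match scores (percent agreement), responder rates, and 2×2 contingency
comparisons between patient groups via Pearson's chi-square test or Fisher's
exact test.  The two-sided Fisher p-value follows the point-probability
convention: it sums the hypergeometric probabilities, at fixed margins, of
every table no more probable than the observed one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .classifier import DecisionTrace, classify_cohort, Thresholds
from .cohort import Cohort, Dataset, Response

__all__ = [
    "ConcordanceTable",
    "TestMethod",
    "TestResult",
    "match_score",
    "responder_rate",
    "fisher_exact",
    "chi_square",
    "concordance_report",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention for reported rates)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceTable:
    """A 2×2 contingency table of nonnegative counts with axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("outcome1", "outcome2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError(
                f"contingency table must be 2x2, got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("contingency counts must be nonnegative")


class TestMethod(str, enum.Enum):
    __test__ = False  # API class, not a pytest collection target

    CHI_SQUARE_NO_CORRECTION = "chi_square_no_correction"
    CHI_SQUARE_YATES = "chi_square_yates"
    FISHER_EXACT_TWO_SIDED = "fisher_exact_two_sided"


@dataclass
class TestResult:
    __test__ = False  # API class, not a pytest collection target

    statistic: float | None
    p_value: float
    method: TestMethod
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


def match_score(predicted: list, clinical: list) -> float:
    """Percent of positions where predicted and clinical labels agree."""
    if len(predicted) != len(clinical):
        raise ValueError(
            f"label lists differ in length: {len(predicted)} vs {len(clinical)}"
        )
    if len(predicted) == 0:
        raise ValueError("cannot compute a match score of empty label lists")
    matches = sum(p == c for p, c in zip(predicted, clinical))
    return 100.0 * matches / len(predicted)


def responder_rate(labels: list) -> float:
    """Percent of labels equal to responder."""
    if len(labels) == 0:
        raise ValueError("cannot compute a responder rate of an empty list")
    n_resp = sum(
        Response(label) == Response.RESPONDER for label in labels
    )
    return 100.0 * n_resp / len(labels)


def _degenerate(table: ConcordanceTable) -> bool:
    margins_rows = table.counts.sum(axis=1)
    margins_cols = table.counts.sum(axis=0)
    return bool((margins_rows == 0).any() or (margins_cols == 0).any())


def fisher_exact(table: ConcordanceTable) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    A degenerate table (a zero row or column margin) carries no evidence of
    association; by convention p = 1 and the result is flagged.
    """
    if _degenerate(table):
        return TestResult(None, 1.0, TestMethod.FISHER_EXACT_TWO_SIDED,
                          degenerate=True)
    _, p = stats.fisher_exact(table.counts, alternative="two-sided")
    return TestResult(None, float(p), TestMethod.FISHER_EXACT_TWO_SIDED)


def chi_square(table: ConcordanceTable, correction: bool = False) -> TestResult:
    """Pearson chi-square test (1 df) on a 2×2 table, upper-tail p-value."""
    if _degenerate(table):
        raise ValueError(
            "chi-square test undefined for a table with a zero margin "
            "(an expected count would be zero)"
        )
    statistic, p, _, _ = stats.chi2_contingency(
        table.counts, correction=correction
    )
    method = (
        TestMethod.CHI_SQUARE_YATES
        if correction
        else TestMethod.CHI_SQUARE_NO_CORRECTION
    )
    return TestResult(float(statistic), float(p), method)


def _labels(cohort: Cohort, traces: dict[str, DecisionTrace], dataset=None):
    records = list(cohort) if dataset is None else list(cohort.subset(dataset))
    clinical = [r.clinical_response.value for r in records]
    predicted = [traces[r.study_id].label.value for r in records]
    return predicted, clinical


def concordance_report(
    cohort: Cohort,
    traces: dict[str, DecisionTrace] | None = None,
    thresholds: Thresholds | None = None,
) -> dict:
    """Full concordance summary of a classified two-dataset cohort.

    Reports per-dataset and pooled match scores, clinical and predicted
    responder rates, the mismatching study IDs, and the three
    discovery-vs-validation comparisons: clinical responder rates by
    uncorrected chi-square, predicted responder rates by two-sided Fisher,
    and match/mismatch counts by two-sided Fisher (the test choices that
    the published comparisons are consistent with).

    Match scores are rounded to one decimal with ties to even, matching the
    source table's convention (81.25 -> 81.2); responder rates round ties up.
    """
    if traces is None:
        traces, _ = classify_cohort(cohort, thresholds)
    missing = [r.study_id for r in cohort if r.study_id not in traces]
    if missing:
        raise ValueError(f"traces missing for study IDs {missing}")

    report: dict = {"match_scores": {}, "responder_rates": {}}
    groups = {
        "discovery": Dataset.DISCOVERY,
        "validation": Dataset.VALIDATION,
    }
    matches = {}
    resp_counts: dict[str, dict[str, list]] = {}
    for key, dataset in groups.items():
        predicted, clinical = _labels(cohort, traces, dataset)
        if not predicted:
            continue
        score = match_score(predicted, clinical)
        report["match_scores"][key] = {
            "value": score,
            "rounded": round(score, 1),
            "n": len(predicted),
        }
        report["responder_rates"][key] = {
            "clinical": round_half_up(responder_rate(clinical), 1),
            "predicted": round_half_up(responder_rate(predicted), 1),
        }
        n_match = sum(p == c for p, c in zip(predicted, clinical))
        matches[key] = (n_match, len(predicted) - n_match)
        resp_counts[key] = {"predicted": predicted, "clinical": clinical}

    predicted_all, clinical_all = _labels(cohort, traces)
    overall = match_score(predicted_all, clinical_all)
    report["match_scores"]["overall"] = {
        "value": overall,
        "rounded": round(overall, 1),
        "n": len(predicted_all),
    }
    report["overall_correct"] = sum(
        p == c for p, c in zip(predicted_all, clinical_all)
    )
    report["mismatches"] = sorted(
        r.study_id
        for r in cohort
        if traces[r.study_id].label != r.clinical_response
    )

    report["tests"] = {}
    if set(matches) == {"discovery", "validation"}:
        def rate_table(kind: str) -> ConcordanceTable:
            rows = []
            for key in ("discovery", "validation"):
                labels = resp_counts[key][kind]
                n_resp = sum(
                    label == Response.RESPONDER.value for label in labels
                )
                rows.append([n_resp, len(labels) - n_resp])
            return ConcordanceTable(
                np.array(rows),
                row_labels=("discovery", "validation"),
                col_labels=("responder", "non_responder"),
            )

        clin = chi_square(rate_table("clinical"), correction=False)
        pred = fisher_exact(rate_table("predicted"))
        match_table = ConcordanceTable(
            np.array([matches["discovery"], matches["validation"]]),
            row_labels=("discovery", "validation"),
            col_labels=("match", "mismatch"),
        )
        score_cmp = fisher_exact(match_table)
        report["tests"] = {
            "clinical_responder_rates": {
                "method": clin.method.value, "p_value": clin.p_value,
            },
            "predicted_responder_rates": {
                "method": pred.method.value, "p_value": pred.p_value,
            },
            "match_scores": {
                "method": score_cmp.method.value, "p_value": score_cmp.p_value,
            },
        }
    return report
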