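"""Three-step threshold decision tree for PD-1 responder status.

The tree sorts a patient by predicted PD-L1 percent change (step 1), by the
dendritic-cell infiltration index (steps 2a/2b), and by the excess of each
immunosuppressive molecule (ISM) over PD-L1 (steps 3a/3b):

* step 1  — PD-L1 below ``pdl1_cut`` (default 29.0%): non-responder.
* step 2a — DC index below ``dc_low`` (default 20.0%): non-responder.
* step 2b — DC index above ``dc_high`` (default 60.0%): responder.
* step 3a — any ISM above PD-L1 by more than ``ism_margin`` (default
  5.0 percentage points): non-responder, with the triggering molecules
  recorded.
* step 3b — otherwise: responder.

All four comparisons are strict, so a patient sitting exactly on a cutoff
proceeds to the next step (PD-L1 equal to the cutoff proceeds to step 2; a
DC index equal to either bound proceeds to step 3).  Step 3 treats "no ISM in
excess" as responder even when some ISM sits within the ±margin band of
PD-L1 — the only reading consistent with the published per-patient labels.

The classifier is exposed as a scikit-learn style estimator
(:class:`ResponseTreeClassifier`) operating on a feature table with columns
``PDL1``, ``DC_index`` and the 14 ISM names, plus thin functional wrappers
(:func:`classify_patient`, :func:`classify_cohort`) over cohort objects.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import ISM_NAMES, Cohort, PatientRecord, Response

__all__ = [
    "Thresholds",
    "Step",
    "DecisionTrace",
    "ResponseTreeClassifier",
    "classify_patient",
    "classify_cohort",
    "cohort_to_frame",
    "FEATURE_COLUMNS",
]

#: Feature columns consumed by the estimator, in canonical order.
FEATURE_COLUMNS: tuple[str, ...] = ("PDL1", "DC_index") + ISM_NAMES


class Step(str, enum.Enum):
    STEP1 = "step1"
    STEP2A = "step2a"
    STEP2B = "step2b"
    STEP3A = "step3a"
    STEP3B = "step3b"


#: Terminal steps that assign the non-responder label.
NON_RESPONDER_STEPS = frozenset({Step.STEP1, Step.STEP2A, Step.STEP3A})


@dataclass(frozen=True)
class Thresholds:
    """The four decision-tree cutoffs (all in percent)."""

    pdl1_cut: float = 29.0
    dc_low: float = 20.0
    dc_high: float = 60.0
    ism_margin: float = 5.0

    def __post_init__(self) -> None:
        values = (self.pdl1_cut, self.dc_low, self.dc_high, self.ism_margin)
        if not all(math.isfinite(v) for v in values):
            raise ValueError(f"thresholds must be finite, got {values}")
        if not self.dc_low < self.dc_high:
            raise ValueError(
                f"dc_low must be below dc_high "
                f"(got {self.dc_low} >= {self.dc_high})"
            )


@dataclass
class DecisionTrace:
    """Label, terminal step, and the threshold tests that produced it."""

    label: Response
    terminal_step: Step
    triggering_molecules: list[str] = field(default_factory=list)
    comparisons: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        is_nr = self.terminal_step in NON_RESPONDER_STEPS
        if is_nr != (self.label == Response.NON_RESPONDER):
            raise ValueError(
                f"terminal step {self.terminal_step.value} is inconsistent "
                f"with label {self.label.value}"
            )
        if bool(self.triggering_molecules) != (
            self.terminal_step == Step.STEP3A
        ):
            raise ValueError(
                "triggering_molecules must be non-empty exactly for step3a"
            )


def _classify_values(
    pdl1: float,
    dc_index: float,
    ism: dict[str, float],
    thresholds: Thresholds,
) -> DecisionTrace:
    comparisons: list[tuple[str, str, bool]] = []

    test = pdl1 < thresholds.pdl1_cut
    comparisons.append(("step1", f"PDL1 {pdl1} < {thresholds.pdl1_cut}", test))
    if test:
        return DecisionTrace(Response.NON_RESPONDER, Step.STEP1,
                             comparisons=comparisons)

    test = dc_index < thresholds.dc_low
    comparisons.append(
        ("step2a", f"DC_index {dc_index} < {thresholds.dc_low}", test))
    if test:
        return DecisionTrace(Response.NON_RESPONDER, Step.STEP2A,
                             comparisons=comparisons)

    test = dc_index > thresholds.dc_high
    comparisons.append(
        ("step2b", f"DC_index {dc_index} > {thresholds.dc_high}", test))
    if test:
        return DecisionTrace(Response.RESPONDER, Step.STEP2B,
                             comparisons=comparisons)

    triggering = [
        m for m in ISM_NAMES if ism[m] - pdl1 > thresholds.ism_margin
    ]
    comparisons.append(
        (
            "step3",
            f"ISM - PDL1 > {thresholds.ism_margin} for {triggering or 'none'}",
            bool(triggering),
        )
    )
    if triggering:
        return DecisionTrace(Response.NON_RESPONDER, Step.STEP3A,
                             triggering_molecules=triggering,
                             comparisons=comparisons)
    return DecisionTrace(Response.RESPONDER, Step.STEP3B,
                         comparisons=comparisons)


class ResponseTreeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based PD-1 response classifier with fixed published cutoffs.

    The estimator has no trainable state: :meth:`fit` only validates the
    feature table and records the fitted metadata scikit-learn expects, so
    the classifier composes with pipelines and model-selection utilities
    (e.g. for threshold sensitivity analyses via ``set_params``).

    Parameters
    ----------
    pdl1_cut : float, default=29.0
        Minimum PD-L1 percent change to avoid a step-1 non-responder call.
    dc_low, dc_high : float, default=20.0, 60.0
        DC infiltration index bounds for steps 2a (below: non-responder)
        and 2b (above: responder).
    ism_margin : float, default=5.0
        Margin (percentage points) by which an immunosuppressive molecule
        must exceed PD-L1 to trigger a step-3a non-responder call.
    """

    def __init__(
        self,
        pdl1_cut: float = 29.0,
        dc_low: float = 20.0,
        dc_high: float = 60.0,
        ism_margin: float = 5.0,
    ) -> None:
        self.pdl1_cut = pdl1_cut
        self.dc_low = dc_low
        self.dc_high = dc_high
        self.ism_margin = ism_margin

    # -- scikit-learn API -------------------------------------------------

    def fit(self, X, y=None) -> "ResponseTreeClassifier":
        X = self._validate_features(X)
        self.thresholds_ = Thresholds(
            self.pdl1_cut, self.dc_low, self.dc_high, self.ism_margin
        )
        self.classes_ = np.array(
            [Response.NON_RESPONDER.value, Response.RESPONDER.value]
        )
        self.feature_names_in_ = np.asarray(FEATURE_COLUMNS, dtype=object)
        self.n_features_in_ = len(FEATURE_COLUMNS)
        return self

    def predict(self, X) -> np.ndarray:
        traces = self.predict_trace(X)
        return np.array([t.label.value for t in traces], dtype=object)

    def predict_trace(self, X) -> list[DecisionTrace]:
        """Per-row decision traces (label, terminal step, triggering ISMs)."""
        if not hasattr(self, "thresholds_"):
            # stateless estimator: fitting is validation only, do it lazily
            self.fit(X)
        X = self._validate_features(X)
        traces = []
        for _, row in X.iterrows():
            traces.append(
                _classify_values(
                    float(row["PDL1"]),
                    float(row["DC_index"]),
                    {m: float(row[m]) for m in ISM_NAMES},
                    self.thresholds_,
                )
            )
        return traces

    def score(self, X, y) -> float:
        """Mean accuracy against labels ``y`` (fraction, not percent)."""
        return float(np.mean(self.predict(X) == np.asarray(y)))

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _validate_features(X) -> pd.DataFrame:
        if isinstance(X, Cohort):
            X = cohort_to_frame(X)
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=FEATURE_COLUMNS)
        missing = [c for c in FEATURE_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"feature table is missing columns {missing}")
        values = X[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature table contains non-finite values")
        return X


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Feature table (PDL1, DC_index, 14 ISMs) indexed by study_id."""
    rows = {}
    for rec in cohort:
        row = {"PDL1": rec.pdl1_pct, "DC_index": rec.dc_index_pct}
        row.update(rec.ism_pct)
        rows[rec.study_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "study_id"
    return frame[list(FEATURE_COLUMNS)]


def classify_patient(
    record: PatientRecord, thresholds: Thresholds | None = None
) -> DecisionTrace:
    """Classify one patient record through the three-step tree."""
    thresholds = thresholds or Thresholds()
    return _classify_values(
        record.pdl1_pct, record.dc_index_pct, record.ism_pct, thresholds
    )


def classify_cohort(
    cohort: Cohort, thresholds: Thresholds | None = None
) -> tuple[dict[str, DecisionTrace], Counter]:
    """Classify every patient; returns traces by study_id and step tallies."""
    if len(cohort) == 0:
        raise ValueError("cannot classify an empty cohort")
    thresholds = thresholds or Thresholds()
    traces = {
        rec.study_id: classify_patient(rec, thresholds) for rec in cohort
    }
    counts = Counter(t.terminal_step.value for t in traces.values())
    return traces, counts
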