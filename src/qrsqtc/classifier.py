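"""Threshold classification of cases by QRS/QTc and its evaluation.

A low QRS/QTc marks disproportionate repolarization delay relative to
depolarization; ratios strictly below the threshold (default 0.2, carried
over from the hypothermia work that introduced the marker) are classified
as high risk for VT/VF.  A ratio exactly at the threshold is *not* high
risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

__all__ = [
    "DEFAULT_THRESHOLD",
    "RiskAssessment",
    "ClassifierEvaluation",
    "classify",
    "evaluate_classifier",
    "threshold_sweep",
]

DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class RiskAssessment:
    ratio: float
    threshold: float
    predicted_high_risk: bool
    case_id: int | None = None


@dataclass(frozen=True)
class ClassifierEvaluation:
    """Confusion matrix of predicted high risk vs observed VT/VF."""

    threshold: float
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.fp + self.tn
        return self.tn / neg if neg else None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def classify(
    ratio: float, threshold: float = DEFAULT_THRESHOLD, case_id: int | None = None
) -> RiskAssessment:
    """High risk iff ratio < threshold (strict; boundary value is low risk)."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    return RiskAssessment(
        ratio=ratio,
        threshold=threshold,
        predicted_high_risk=ratio < threshold,
        case_id=case_id,
    )


def evaluate_classifier(
    cohort: "Cohort",
    threshold: float = DEFAULT_THRESHOLD,
    printed_precision: bool = True,
) -> ClassifierEvaluation:
    """Confusion counts of the threshold rule against observed VT/VF.

    ``printed_precision=True`` (reproduction mode) classifies the
    two-decimal printed ratios; False uses full-precision quotients.
    A single-outcome cohort still yields counts; the undefined rate is None.
    """
    if len(cohort) == 0:
        raise ValueError("cannot evaluate a classifier on an empty cohort")
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    tp = fn = fp = tn = 0
    ratios = cohort.values("ratio", printed_precision=printed_precision)
    for (case, _), ratio in zip(cohort, ratios):
        high = ratio < threshold
        if case.vt_vf:
            tp, fn = tp + high, fn + (not high)
        else:
            fp, tn = fp + high, tn + (not high)
    return ClassifierEvaluation(threshold=threshold, tp=tp, fn=fn, fp=fp, tn=tn)


def threshold_sweep(
    cohort: "Cohort",
    thresholds: Sequence[float],
    printed_precision: bool = True,
) -> list[ClassifierEvaluation]:
    """One evaluation per threshold (ROC points when plotted)."""
    return [
        evaluate_classifier(cohort, t, printed_precision=printed_precision)
        for t in thresholds
    ]
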