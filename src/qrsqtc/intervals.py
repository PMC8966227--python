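"""Heart-rate correction of the QT interval and the QRS/QTc ratio.

QTc normalises the measured QT interval to a heart rate of 60 bpm
(RR = 1 s).  Four standard corrections are provided:

====================  =========================================
bazett                QTc = QT / sqrt(RR)
fridericia            QTc = QT / RR^(1/3)
framingham            QTc = QT + 154 * (1 - RR)
hodges                QTc = QT + 1.75 * (HR - 60)
====================  =========================================

with QT and QTc in ms, RR in seconds and HR in bpm.  All four reduce to
the identity at RR = 1 s.  Bazett is the package default: recomputing
the fixture's printed QTc values from its printed QT/HR pairs matches
Bazett within ~1 ms for the cases whose QTc was derived from an attached
ECG recording (and exactly at HR 60).

``audit_qtc_consistency`` is a transcription quality-control step: it
recomputes QTc for every case and flags those whose reported value
disagrees beyond a tolerance.  Flags are expected where a case report
printed a QTc obtained with an unstated, different correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

__all__ = [
    "CORRECTION_FORMULAS",
    "DEFAULT_FORMULA",
    "ConsistencyFlag",
    "rr_from_hr",
    "correct_qt",
    "qrs_qtc_ratio",
    "round_half_up",
    "audit_qtc_consistency",
    "audit_to_frame",
    "write_audit_report",
]

CORRECTION_FORMULAS = ("bazett", "fridericia", "framingham", "hodges")
DEFAULT_FORMULA = "bazett"


def rr_from_hr(hr_bpm: float) -> float:
    """RR interval in seconds from heart rate in beats per minute."""
    if not hr_bpm > 0:
        raise ValueError(f"hr_bpm must be positive, got {hr_bpm}")
    return 60.0 / hr_bpm


def correct_qt(qt_ms: float, rr_s: float, formula: str = DEFAULT_FORMULA) -> float:
    """Rate-corrected QT interval (ms) for a given RR interval (s)."""
    if not qt_ms > 0:
        raise ValueError(f"qt_ms must be positive, got {qt_ms}")
    if not rr_s > 0:
        raise ValueError(f"rr_s must be positive, got {rr_s}")
    if formula == "bazett":
        return qt_ms / math.sqrt(rr_s)
    if formula == "fridericia":
        return qt_ms / rr_s ** (1.0 / 3.0)
    if formula == "framingham":
        return qt_ms + 154.0 * (1.0 - rr_s)
    if formula == "hodges":
        return qt_ms + 1.75 * (60.0 / rr_s - 60.0)
    raise ValueError(
        f"unknown correction formula {formula!r}; choose from {CORRECTION_FORMULAS}"
    )


def qrs_qtc_ratio(qrs_ms: float, qtc_ms: float) -> float:
    """Dimensionless QRS/QTc ratio (full precision; round separately)."""
    if not qrs_ms > 0:
        raise ValueError(f"qrs_ms must be positive, got {qrs_ms}")
    if not qtc_ms > 0:
        raise ValueError(f"qtc_ms must be positive, got {qtc_ms}")
    return qrs_ms / qtc_ms


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the source tables).

    Python's builtin ``round`` uses banker's rounding; printed clinical
    tables round 0.165 up to 0.17, so reproduction requires half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConsistencyFlag:
    """Agreement between a reported QTc and its recomputation from QT/HR."""

    case_id: int
    qt_ms: float
    hr_bpm: float
    reported_qtc_ms: float
    recomputed_qtc_ms: float
    formula: str
    tolerance_ms: float

    @property
    def discrepancy_ms(self) -> float:
        return self.recomputed_qtc_ms - self.reported_qtc_ms

    @property
    def flagged(self) -> bool:
        return abs(self.discrepancy_ms) > self.tolerance_ms


def audit_qtc_consistency(
    cohort: "Cohort",
    formula: str = DEFAULT_FORMULA,
    tolerance_ms: float = 6.0,
) -> list[ConsistencyFlag]:
    """Recompute QTc from each case's QT and HR and compare to the reported value.

    Returns one flag per case, in cohort order; ``flagged`` is True when the
    absolute discrepancy exceeds ``tolerance_ms``.
    """
    if not tolerance_ms > 0:
        raise ValueError(f"tolerance_ms must be positive, got {tolerance_ms}")
    flags = []
    for case, ecg in cohort:
        recomputed = correct_qt(ecg.qt_ms, rr_from_hr(ecg.hr_bpm), formula)
        flags.append(
            ConsistencyFlag(
                case_id=case.case_id,
                qt_ms=ecg.qt_ms,
                hr_bpm=ecg.hr_bpm,
                reported_qtc_ms=ecg.qtc_ms,
                recomputed_qtc_ms=recomputed,
                formula=formula,
                tolerance_ms=tolerance_ms,
            )
        )
    return flags


def audit_to_frame(flags: list[ConsistencyFlag]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "case_id": [f.case_id for f in flags],
            "qt_ms": [f.qt_ms for f in flags],
            "hr_bpm": [f.hr_bpm for f in flags],
            "qtc_reported": [f.reported_qtc_ms for f in flags],
            "qtc_recomputed": [f.recomputed_qtc_ms for f in flags],
            "formula": [f.formula for f in flags],
            "discrepancy_ms": [f.discrepancy_ms for f in flags],
            "flagged": [f.flagged for f in flags],
        }
    )


def write_audit_report(flags: list[ConsistencyFlag], path: str | Path) -> None:
    audit_to_frame(flags).to_csv(path, index=False)
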