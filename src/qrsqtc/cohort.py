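"""Case-level cohort data model and I/O.

The packaged fixture is a 16-patient case series of citalopram or
escitalopram exposure (intoxication or therapeutic use), each with an
admission ECG.  Every record pairs clinical data (demographics, dose,
serum concentration, co-ingestants, VT/VF outcome) with ECG interval
measurements (QRS, QT, QTc, heart rate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "CaseRecord",
    "EcgIntervals",
    "Cohort",
    "SchemaError",
    "ValidationError",
    "CSV_COLUMNS",
    "load_cohort",
    "write_cohort",
    "filter_cohort",
]

#: Exact column order of the on-disk CSV/JSON schema.
CSV_COLUMNS = [
    "case_id",
    "citation",
    "age_years",
    "sex",
    "exposure_type",
    "substance",
    "dose_g",
    "serum_ng_ml",
    "co_ingestants",
    "vt_vf",
    "qrs_ms",
    "qt_ms",
    "qtc_ms",
    "hr_bpm",
]

VALID_SEX = {"F", "M"}
VALID_EXPOSURE = {"intoxication", "therapeutic"}
VALID_SUBSTANCE = {"citalopram", "escitalopram"}


class SchemaError(ValueError):
    """The input file does not conform to the cohort schema."""


class ValidationError(ValueError):
    """A field value violates a range or consistency invariant."""


@dataclass(frozen=True)
class CaseRecord:
    """Clinical data for one patient from a published case report."""

    case_id: int
    citation: str
    age_years: float
    sex: str
    exposure_type: str
    substance: str
    dose_g: float | None = None
    serum_ng_ml: float | None = None
    co_ingestants: tuple[str, ...] = ()
    vt_vf: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.age_years <= 130:
            raise ValidationError(
                f"case {self.case_id}: age_years={self.age_years} outside [0, 130]"
            )
        if self.sex not in VALID_SEX:
            raise ValidationError(f"case {self.case_id}: sex={self.sex!r}")
        if self.exposure_type not in VALID_EXPOSURE:
            raise ValidationError(
                f"case {self.case_id}: exposure_type={self.exposure_type!r}"
            )
        if self.substance not in VALID_SUBSTANCE:
            raise ValidationError(f"case {self.case_id}: substance={self.substance!r}")
        if self.dose_g is not None and not self.dose_g > 0:
            raise ValidationError(f"case {self.case_id}: dose_g={self.dose_g} must be > 0")
        if self.serum_ng_ml is not None and not self.serum_ng_ml > 0:
            raise ValidationError(
                f"case {self.case_id}: serum_ng_ml={self.serum_ng_ml} must be > 0"
            )


@dataclass(frozen=True)
class EcgIntervals:
    """ECG interval durations for one admission ECG.

    ``ratio`` is the derived QRS/QTc quotient at full floating-point
    precision; use :meth:`ratio_2dp` for the value rounded the way the
    source tables print it (half-up at two decimals).
    """

    qrs_ms: float
    qt_ms: float
    qtc_ms: float
    hr_bpm: float
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if not 40 <= self.qrs_ms <= 300:
            raise ValidationError(f"qrs_ms={self.qrs_ms} outside [40, 300]")
        if not 200 <= self.qt_ms <= 800:
            raise ValidationError(f"qt_ms={self.qt_ms} outside [200, 800]")
        if not 200 <= self.qtc_ms <= 800:
            raise ValidationError(f"qtc_ms={self.qtc_ms} outside [200, 800]")
        if not 20 <= self.hr_bpm <= 250:
            raise ValidationError(f"hr_bpm={self.hr_bpm} outside [20, 250]")
        if not self.qrs_ms < self.qt_ms:
            raise ValidationError(
                f"qrs_ms={self.qrs_ms} must be < qt_ms={self.qt_ms}"
            )
        object.__setattr__(self, "ratio", self.qrs_ms / self.qtc_ms)
        if not 0 < self.ratio < 1:
            raise ValidationError(f"ratio={self.ratio} outside (0, 1)")

    def ratio_2dp(self) -> float:
        from .intervals import round_half_up

        return round_half_up(self.qrs_ms / self.qtc_ms, 2)


class Cohort:
    """An ordered collection of (CaseRecord, EcgIntervals) pairs."""

    def __init__(self, records: Iterable[tuple[CaseRecord, EcgIntervals]]):
        self.records: list[tuple[CaseRecord, EcgIntervals]] = list(records)
        ids = [c.case_id for c, _ in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate case_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[CaseRecord, EcgIntervals]]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.records == other.records

    def case(self, case_id: int) -> tuple[CaseRecord, EcgIntervals]:
        for rec in self.records:
            if rec[0].case_id == case_id:
                return rec
        raise KeyError(f"no case with case_id={case_id}")

    def values(self, variable: str, *, printed_precision: bool = False) -> list[float]:
        """Extract one ECG variable across the cohort, in record order.

        ``variable`` is one of ``ratio``, ``qrs_ms``, ``qtc_ms``, ``qt_ms``,
        ``hr_bpm``.  For ``ratio``, ``printed_precision=True`` returns the
        two-decimal half-up rounded values as printed in the source tables.
        """
        if variable == "ratio" and printed_precision:
            return [ecg.ratio_2dp() for _, ecg in self.records]
        if variable not in {"ratio", "qrs_ms", "qt_ms", "qtc_ms", "hr_bpm"}:
            raise ValueError(f"unknown variable {variable!r}")
        return [getattr(ecg, variable) for _, ecg in self.records]

    def split_by_outcome(self) -> tuple["Cohort", "Cohort"]:
        """Return (VT/VF = yes, VT/VF = no) sub-cohorts, order preserved."""
        yes = Cohort(r for r in self.records if r[0].vt_vf)
        no = Cohort(r for r in self.records if not r[0].vt_vf)
        return yes, no

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for case, ecg in self.records:
            rows.append(
                {
                    "case_id": case.case_id,
                    "citation": case.citation,
                    "age_years": case.age_years,
                    "sex": case.sex,
                    "exposure_type": case.exposure_type,
                    "substance": case.substance,
                    "dose_g": case.dose_g,
                    "serum_ng_ml": case.serum_ng_ml,
                    "co_ingestants": ";".join(case.co_ingestants),
                    "vt_vf": case.vt_vf,
                    "qrs_ms": ecg.qrs_ms,
                    "qt_ms": ecg.qt_ms,
                    "qtc_ms": ecg.qtc_ms,
                    "hr_bpm": ecg.hr_bpm,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _opt_float(value: object) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _record_from_row(row: dict) -> tuple[CaseRecord, EcgIntervals]:
    co = row.get("co_ingestants")
    if co is None or (isinstance(co, float) and math.isnan(co)):
        co_list: tuple[str, ...] = ()
    else:
        co_list = tuple(s for s in str(co).split(";") if s.strip())
    vt = row["vt_vf"]
    if isinstance(vt, str):
        low = vt.strip().lower()
        if low not in {"true", "false"}:
            raise SchemaError(f"vt_vf must be true/false, got {vt!r}")
        vt = low == "true"
    case = CaseRecord(
        case_id=int(row["case_id"]),
        citation=str(row["citation"]),
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        exposure_type=str(row["exposure_type"]),
        substance=str(row["substance"]),
        dose_g=_opt_float(row.get("dose_g")),
        serum_ng_ml=_opt_float(row.get("serum_ng_ml")),
        co_ingestants=co_list,
        vt_vf=bool(vt),
    )
    try:
        ecg = EcgIntervals(
            qrs_ms=float(row["qrs_ms"]),
            qt_ms=float(row["qt_ms"]),
            qtc_ms=float(row["qtc_ms"]),
            hr_bpm=float(row["hr_bpm"]),
        )
    except ValidationError as exc:
        raise ValidationError(f"case {case.case_id}: {exc}") from None
    return case, ecg


def _cohort_from_frame(df: pd.DataFrame) -> Cohort:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return Cohort(_record_from_row(row) for row in df.to_dict("records"))


def load_cohort(source: str | Path = "packaged") -> Cohort:
    """Load a cohort from CSV/JSON, or the packaged 16-case fixture.

    ``source="packaged"`` returns the case series transcribed from the
    published clinical and ECG tables (missing dose/serum values are kept
    missing, never coerced to zero).
    """
    if source == "packaged":
        ref = resources.files("qrsqtc.data") / "cohort_fixture.csv"
        with resources.as_file(ref) as path:
            return load_cohort(path)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        if not isinstance(raw, list) or not raw:
            raise SchemaError(f"{path}: expected a non-empty JSON array of case objects")
        return _cohort_from_frame(pd.DataFrame(raw))
    try:
        df = pd.read_csv(path, dtype={"co_ingestants": "string"})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return _cohort_from_frame(df)


def write_cohort(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort to disk; round-trips losslessly, including missingness.

    Missing dose/serum become empty CSV cells or JSON nulls.
    """
    path = Path(path)
    df = cohort.to_frame()
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        records = df.to_dict("records")
        for rec in records:
            for key in ("dose_g", "serum_ng_ml"):
                if rec[key] is not None and math.isnan(rec[key]):
                    rec[key] = None
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def filter_cohort(
    cohort: Cohort, predicate: Callable[[CaseRecord, EcgIntervals], bool]
) -> Cohort:
    """Sub-cohort of records satisfying ``predicate``, order preserved."""
    return Cohort((c, e) for c, e in cohort if predicate(c, e))
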