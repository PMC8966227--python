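"""Synthetic cohorts with the statistical structure of the case series.

Each group (VT/VF yes / no) draws QRS and QTc from independent truncated
Gaussians at the group means and SDs estimated from the case series; heart
rate is drawn from one shared Gaussian because the observed groups did not
differ in rate.  QT is then *back-computed* from QTc and HR by inverting
Bazett (QT = QTc * sqrt(60/HR)) so that every synthetic record is
internally consistent: a Bazett consistency audit of a synthetic cohort
flags nothing.

Outcome labels are assigned either by group membership (``by_group``) or
by a Bernoulli draw with P(VT/VF) = logistic(b0 + b1 * ratio)
(``logistic``).  The default logistic coefficients anchor P = 0.9 at
ratio 0.15 and P = 0.1 at ratio 0.24, the two observed group means.

QRS and QTc are drawn independently within group; the case series reports
no covariance, so independence is the minimal assumption (see the methods
note for what this leaves out).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._config import LOGISTIC_BETA0, LOGISTIC_BETA1
from .cohort import CaseRecord, Cohort, EcgIntervals
from .stats import Descriptives, descriptives, pooled_t_test

__all__ = ["SyntheticCohortSpec", "generate_cohort", "recover_parameters", "power_simulation"]

_MAX_REJECTIONS = 10_000

# Truncation bounds: interval invariants, HR narrowed to a plausible band.
_QRS_LO, _QRS_HI = 40.0, 300.0
_QTC_LO, _QTC_HI = 200.0, 800.0
_QT_LO, _QT_HI = 200.0, 800.0
_HR_LO, _HR_HI = 30.0, 200.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generating parameters; defaults are the case-series group estimates."""

    n_yes: int = 7
    n_no: int = 9
    qrs_mean_yes: float = 90.0
    qrs_sd_yes: float = 14.0
    qtc_mean_yes: float = 606.0
    qtc_sd_yes: float = 78.0
    qrs_mean_no: float = 122.0
    qrs_sd_no: float = 23.0
    qtc_mean_no: float = 508.0
    qtc_sd_no: float = 55.0
    hr_mean: float = 82.0
    hr_sd: float = 22.0
    label_model: str = "by_group"
    logistic_beta0: float = LOGISTIC_BETA0
    logistic_beta1: float = LOGISTIC_BETA1

    def __post_init__(self) -> None:
        if self.n_yes < 0 or self.n_no < 0:
            raise ValueError("group sizes must be non-negative")
        for name in ("qrs_sd_yes", "qtc_sd_yes", "qrs_sd_no", "qtc_sd_no", "hr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.label_model not in ("by_group", "logistic"):
            raise ValueError(f"label_model must be 'by_group' or 'logistic'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticCohortSpec":
        return cls(**json.loads(Path(path).read_text()))


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """Rejection-sample one truncated Gaussian value."""
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError(f"degenerate draw at {mean} outside [{lo}, {hi}]")
        return mean
    for _ in range(_MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError(
        f"truncated sampling failed after {_MAX_REJECTIONS} attempts "
        f"(mean={mean}, sd={sd}, bounds=[{lo}, {hi}])"
    )


def _draw_record(rng: np.random.Generator, spec: SyntheticCohortSpec,
                 group_yes: bool) -> EcgIntervals:
    if group_yes:
        qm, qs = spec.qrs_mean_yes, spec.qrs_sd_yes
        cm, cs = spec.qtc_mean_yes, spec.qtc_sd_yes
    else:
        qm, qs = spec.qrs_mean_no, spec.qrs_sd_no
        cm, cs = spec.qtc_mean_no, spec.qtc_sd_no
    for _ in range(_MAX_REJECTIONS):
        qrs = _draw_truncated(rng, qm, qs, _QRS_LO, _QRS_HI)
        qtc = _draw_truncated(rng, cm, cs, _QTC_LO, _QTC_HI)
        hr = _draw_truncated(rng, spec.hr_mean, spec.hr_sd, _HR_LO, _HR_HI)
        qt = qtc * math.sqrt(60.0 / hr)  # Bazett inversion
        if qt <= qrs or not _QT_LO <= qt <= _QT_HI:
            continue
        return EcgIntervals(qrs_ms=qrs, qt_ms=qt, qtc_ms=qtc, hr_bpm=hr)
    raise RuntimeError("record rejection limit exceeded; spec is pathological")


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> Cohort:
    """Generate a synthetic cohort; identical spec + seed gives identical output.

    Group-yes records come first, then group-no, mirroring a table sorted by
    outcome.  Demographics are placeholders (alternating sex, age 50).
    """
    rng = np.random.default_rng(seed)
    records = []
    group_flags = [True] * spec.n_yes + [False] * spec.n_no
    for i, in_yes_group in enumerate(group_flags, start=1):
        ecg = _draw_record(rng, spec, in_yes_group)
        if spec.label_model == "by_group":
            vt_vf = in_yes_group
        else:
            p = 1.0 / (1.0 + math.exp(-(spec.logistic_beta0
                                        + spec.logistic_beta1 * ecg.ratio)))
            vt_vf = bool(rng.random() < p)
        case = CaseRecord(
            case_id=i,
            citation="synthetic",
            age_years=50.0,
            sex="F" if i % 2 else "M",
            exposure_type="intoxication",
            substance="citalopram",
            vt_vf=vt_vf,
        )
        records.append((case, ecg))
    return Cohort(records)


def recover_parameters(
    cohort: Cohort, sd_mode: str = "population"
) -> dict[str, dict[str, Descriptives]]:
    """Per-group descriptives of QRS, QTc and HR — the generator's estimands."""
    yes, no = cohort.split_by_outcome()
    if len(yes) < 3 or len(no) < 3:
        raise ValueError("parameter recovery needs n >= 3 in both outcome groups")
    out: dict[str, dict[str, Descriptives]] = {}
    for name, grp in (("yes", yes), ("no", no)):
        out[name] = {
            var: descriptives(grp.values(var), sd_mode)
            for var in ("qrs_ms", "qtc_ms", "hr_bpm", "ratio")
        }
    return out


def power_simulation(
    spec: SyntheticCohortSpec,
    n_yes: int,
    n_no: int,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of synthetic cohorts where the ratio t-test rejects at alpha.

    Estimates the power of the two-group design at the spec's effect size.
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100 for a stable estimate, got {reps}")
    base = dict(asdict(spec), n_yes=n_yes, n_no=n_no, label_model="by_group")
    sim_spec = SyntheticCohortSpec(**base)
    seed_seq = np.random.SeedSequence(seed)
    rejections = 0
    for child in seed_seq.spawn(reps):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cohort = generate_cohort(sim_spec, sub_seed)
        yes, no = cohort.split_by_outcome()
        _, _, p = pooled_t_test(yes.values("ratio"), no.values("ratio"))
        if p < alpha:
            rejections += 1
    return rejections / reps
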