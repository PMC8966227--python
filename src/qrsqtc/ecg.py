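"""Synthetic single-lead ECG synthesis and interval delineation.

Case reports often attach an ECG strip rather than printed interval
values; turning such a recording into QRS/QT/QTc numbers is a manual
measurement step.  This module reconstructs that step at desk scale: a
minimal Gaussian-bump beat model (P, Q, R, S, T) generates waveforms with
known ground-truth intervals, and a delineator measures them back using
the standard manual conventions — derivative-threshold QRS bounds and the
tangent method for T-end.

The beat template is *calibrated*: the Q and S bump centres are placed so
that the points where the absolute slope of the clean template crosses
the detection fraction (5% of the per-beat maximum slope) fall exactly at
the nominal QRS onset and offset, and the T-wave Gaussian is positioned
so that the tangent at its steepest downslope crosses baseline exactly at
QRS onset + QT.  For a pure Gaussian bump centred at mu with width sigma
the steepest downslope is at mu + sigma and its tangent crosses baseline
at mu + 2*sigma; the T centre is therefore QT_end - 2*sigma_T.

The model makes no claim of physiological realism beyond interval
structure; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import brentq
from scipy.signal import find_peaks

from . import _config as cfg
from .cohort import EcgIntervals
from .intervals import correct_qt, qrs_qtc_ratio, rr_from_hr

__all__ = ["EcgWaveform", "DelineationResult", "synthesize_ecg", "delineate",
           "measure_case", "write_waveform_csv", "read_waveform_csv"]


@dataclass(frozen=True)
class EcgWaveform:
    """A sampled voltage trace with optional synthetic ground truth."""

    samples: np.ndarray
    fs: float
    true_intervals: EcgIntervals | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class DelineationResult:
    """Per-beat QRS onset/offset and T-end marks plus median intervals."""

    onsets_s: np.ndarray
    offsets_s: np.ndarray
    t_ends_s: np.ndarray
    r_peaks_s: np.ndarray
    qrs_ms: float
    qt_ms: float
    hr_bpm: float


def _slope_crossing_u(amplitude: float, sigma: float, threshold_slope: float) -> float:
    """Distance (in sigmas) from a Gaussian bump's centre at which the bump's
    absolute slope decays to ``threshold_slope``; calibrates onset/offset."""
    def excess(u: float) -> float:
        return abs(amplitude) * u / sigma * np.exp(-0.5 * u * u) - threshold_slope

    return brentq(excess, 1.0, 8.0)


def _beat_template(t_ms: np.ndarray, qrs_ms: float, qt_ms: float,
                   rr_ms: float) -> np.ndarray:
    """Voltage of one beat at times ``t_ms`` relative to QRS onset."""
    d = qrs_ms
    sigma_r = d * cfg.R_SIGMA_FRAC
    sigma_qs = d * cfg.QS_SIGMA_FRAC
    r_center = d / 2.0
    sigma_t = cfg.T_SIGMA_FRAC * (qt_ms - qrs_ms)
    t_center = qt_ms - 2.0 * sigma_t   # tangent crossing exactly at t = qt

    def qrst(t: np.ndarray, q_center: float, s_center: float) -> np.ndarray:
        return (
            cfg.Q_AMPLITUDE * np.exp(-0.5 * ((t - q_center) / sigma_qs) ** 2)
            + cfg.R_AMPLITUDE * np.exp(-0.5 * ((t - r_center) / sigma_r) ** 2)
            + cfg.S_AMPLITUDE * np.exp(-0.5 * ((t - s_center) / sigma_qs) ** 2)
            + cfg.T_AMPLITUDE * np.exp(-0.5 * ((t - t_center) / sigma_t) ** 2)
        )

    # Calibrate Q/S placement so the 5%-of-max-slope crossings of the
    # *composite* beat fall at t = 0 and t = d.  The maximum slope depends
    # weakly on the placement, so one refinement pass suffices.
    thr_slope = cfg.SLOPE_FRACTION * cfg.R_AMPLITUDE * np.exp(-0.5) / sigma_r
    fine = np.arange(-0.5 * d, qt_ms + 5 * sigma_t, 0.05)
    for _ in range(2):
        u_q = _slope_crossing_u(cfg.Q_AMPLITUDE, sigma_qs, thr_slope)
        u_s = _slope_crossing_u(cfg.S_AMPLITUDE, sigma_qs, thr_slope)
        q_center = u_q * sigma_qs
        s_center = d - u_s * sigma_qs
        max_slope = np.max(np.abs(np.gradient(qrst(fine, q_center, s_center), 0.05)))
        thr_slope = cfg.SLOPE_FRACTION * max_slope

    v = qrst(t_ms, q_center, s_center)
    # P wave only when it does not fuse with the preceding T wave.
    if qt_ms + cfg.P_CENTER_BEFORE_QRS_MS + 4 * cfg.P_SIGMA_MS <= rr_ms:
        p_center = -cfg.P_CENTER_BEFORE_QRS_MS
        v += cfg.P_AMPLITUDE * np.exp(-0.5 * ((t_ms - p_center) / cfg.P_SIGMA_MS) ** 2)
    return v


_LEAD_IN_MS = 300.0


def synthesize_ecg(
    hr_bpm: float,
    qrs_ms: float,
    qt_ms: float,
    fs: float = cfg.DEFAULT_FS,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_beats: int = cfg.DEFAULT_N_BEATS,
) -> EcgWaveform:
    """Generate a waveform of ``n_beats`` identical beats plus Gaussian noise.

    Amplitudes are in arbitrary units with the R peak at 1; ``noise_sd`` is
    on that scale.  Deterministic for a fixed seed.
    """
    if not qrs_ms < qt_ms:
        raise ValueError(f"qrs_ms={qrs_ms} must be < qt_ms={qt_ms}")
    if fs < 250:
        raise ValueError(f"fs must be >= 250 Hz, got {fs}")
    if n_beats < 5:
        raise ValueError(f"need >= 5 beats, got {n_beats}")
    rr_ms = 1000.0 * rr_from_hr(hr_bpm)
    total_ms = _LEAD_IN_MS + (n_beats - 1) * rr_ms + qt_ms + 200.0
    n = int(round(total_ms / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    v = np.zeros(n)
    for k in range(n_beats):
        onset = _LEAD_IN_MS + k * rr_ms
        v += _beat_template(t_ms - onset, qrs_ms, qt_ms, rr_ms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=n)
    truth = EcgIntervals(
        qrs_ms=qrs_ms,
        qt_ms=qt_ms,
        qtc_ms=correct_qt(qt_ms, rr_ms / 1000.0),
        hr_bpm=hr_bpm,
    )
    return EcgWaveform(samples=v, fs=fs, true_intervals=truth)


def delineate(waveform: EcgWaveform) -> DelineationResult:
    """Measure QRS and QT from a waveform.

    R peaks by relative-height peak picking; QRS onset/offset as the
    first/last sample within a +-110 ms window around R whose absolute
    slope exceeds 5% of the window's maximum absolute slope (raised above
    the noise floor when noise is present); T-end by the tangent method at
    the steepest T downslope.  Median across beats; needs >= 3 usable beats.
    All thresholds are relative, so the result is invariant to uniform
    amplitude scaling.
    """
    x = np.asarray(waveform.samples, dtype=float)
    fs = waveform.fs
    if x.size == 0 or np.max(np.abs(x)) == 0:
        raise ValueError("no beats detected: flat or empty signal")
    x = gaussian_filter1d(x, sigma=1.0)  # 1-sample smoothing against noise
    deriv = np.gradient(x) * fs  # units: amplitude per second

    peaks, _ = find_peaks(x, height=0.6 * np.max(x), distance=int(0.25 * fs))
    if peaks.size < 3:
        raise ValueError(f"no usable rhythm: {peaks.size} beat(s) detected, need >= 3")
    rr_samples = float(np.median(np.diff(peaks)))
    hr_bpm = 60.0 * fs / rr_samples

    # Noise floor of the slope signal, from the quiet lead-in.
    quiet = deriv[: int(0.1 * fs)]
    noise_slope = float(np.std(quiet)) if quiet.size else 0.0

    half_win = int(0.110 * fs)
    onsets, offsets, t_ends = [], [], []
    for pk in peaks:
        lo, hi = pk - half_win, pk + half_win
        t_hi = pk + int(min(0.8 * rr_samples, x.size))
        if lo < 0 or t_hi >= x.size:
            continue  # edge beat, window incomplete
        window = np.abs(deriv[lo:hi])
        thr = max(cfg.SLOPE_FRACTION * float(np.max(window)), 5.0 * noise_slope)
        above = window > thr
        if not above.any():
            continue
        i = int(np.argmax(above))
        j = int(len(above) - 1 - np.argmax(above[::-1]))
        # Sub-sample refinement: linear interpolation of the threshold crossing.
        onset = lo + float(i)
        if i > 0 and window[i] > window[i - 1]:
            onset -= (window[i] - thr) / (window[i] - window[i - 1])
        offset = lo + float(j)
        if j < len(above) - 1 and window[j] > window[j + 1]:
            offset += (window[j] - thr) / (window[j] - window[j + 1])
        # T-end: steepest downslope between QRS offset and 0.8 RR after R.
        t_lo = pk + int(0.120 * fs)
        seg = deriv[t_lo:t_hi]
        if seg.size == 0:
            continue
        t_star = t_lo + int(np.argmin(seg))
        slope = deriv[t_star]
        if slope >= 0 or x[t_star] <= 0:
            continue  # no discernible T downslope in this beat
        t_end = t_star + (-x[t_star] / slope) * fs
        onsets.append(onset)
        offsets.append(offset)
        t_ends.append(t_end)
    if len(onsets) < 3:
        raise ValueError(f"only {len(onsets)} beat(s) delineated, need >= 3")
    onsets_a = np.asarray(onsets, dtype=float)
    offsets_a = np.asarray(offsets, dtype=float)
    t_ends_a = np.asarray(t_ends, dtype=float)
    qrs_ms = float(np.median(offsets_a - onsets_a)) / fs * 1000.0
    qt_ms = float(np.median(t_ends_a - onsets_a)) / fs * 1000.0
    return DelineationResult(
        onsets_s=onsets_a / fs,
        offsets_s=offsets_a / fs,
        t_ends_s=t_ends_a / fs,
        r_peaks_s=peaks / fs,
        qrs_ms=qrs_ms,
        qt_ms=qt_ms,
        hr_bpm=hr_bpm,
    )


def measure_case(waveform: EcgWaveform, correction: str = "bazett") -> EcgIntervals:
    """Delineate a waveform and assemble rate-corrected interval metrics."""
    res = delineate(waveform)
    qtc = correct_qt(res.qt_ms, rr_from_hr(res.hr_bpm), correction)
    return EcgIntervals(
        qrs_ms=res.qrs_ms, qt_ms=res.qt_ms, qtc_ms=qtc, hr_bpm=res.hr_bpm
    )


def write_waveform_csv(waveform: EcgWaveform, path: str | Path) -> None:
    """Two-column CSV (time_s, voltage)."""
    arr = np.column_stack([waveform.times, waveform.samples])
    np.savetxt(path, arr, delimiter=",", header="time_s,voltage", comments="")


def read_waveform_csv(path: str | Path, fs: float | None = None) -> EcgWaveform:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    t, v = arr[:, 0], arr[:, 1]
    if fs is None:
        dt = np.median(np.diff(t))
        fs = 1.0 / float(dt)
    return EcgWaveform(samples=v, fs=fs)
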