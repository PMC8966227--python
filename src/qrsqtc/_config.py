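"""Package-wide tunable constants.

Kept in one place so that sensitivity analyses can override them without
touching algorithm code.
"""

import math

# --- synthetic cohort label model -------------------------------------------
# Logistic P(VT/VF) = 1 / (1 + exp(-(b0 + b1 * ratio))) anchored so that
# P = 0.9 at ratio 0.15 and P = 0.1 at ratio 0.24 (the two observed group
# means).  b1 = (logit(0.1) - logit(0.9)) / (0.24 - 0.15); b0 follows.
LOGISTIC_BETA1 = -2.0 * math.log(9.0) / 0.09
LOGISTIC_BETA0 = math.log(9.0) - LOGISTIC_BETA1 * 0.15

# --- ECG synthesis / delineation --------------------------------------------
#: Default sampling rate, Hz.
DEFAULT_FS = 500.0
#: QRS bounds: first/last point where |dV/dt| exceeds this fraction of the
#: per-beat maximum absolute slope.
SLOPE_FRACTION = 0.05
#: Default number of beats per synthesized waveform.
DEFAULT_N_BEATS = 10
#: Beat template geometry (fractions of the QRS duration D).
R_SIGMA_FRAC = 1.0 / 7.0   # R-wave Gaussian width
QS_SIGMA_FRAC = 1.0 / 12.0  # Q- and S-wave Gaussian widths
Q_AMPLITUDE = -0.15
R_AMPLITUDE = 1.0
S_AMPLITUDE = -0.25
T_AMPLITUDE = 0.35
P_AMPLITUDE = 0.04
P_SIGMA_MS = 25.0
P_CENTER_BEFORE_QRS_MS = 150.0
#: T-wave width as a fraction of (QT - QRS).
T_SIGMA_FRAC = 0.12
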