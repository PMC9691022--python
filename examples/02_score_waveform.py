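"""Score a skin-conductance waveform with the trough-to-peak method.

Builds a canonical SCR-like bump at 10 Hz and scores it: the trough is
searched 0.9-3.5 s after CS onset, the peak within 5 s of the trough, and
amplitudes below 0.01 uS are floored to zero responses.
"""

import numpy as np

from condrel import ScoringWindows, Waveform, score_trough_to_peak

rate = 10.0
t = np.arange(0, 10, 1 / rate)
baseline = 1.0
y = np.full(t.size, baseline)
rise = (t >= 1.5) & (t <= 3.0)
y[rise] = baseline + 0.8 * (t[rise] - 1.5) / 1.5   # linear rise to 1.8 uS
y[t > 3.0] = 1.8

w = Waveform(y, rate=rate)
res = score_trough_to_peak(w, onset=0.0, kind="CS", windows=ScoringWindows())
print(f"trough-to-peak amplitude: {res.amplitude:.3f} uS (peak 1.8 - trough 1.0)")

flat = Waveform(np.full(100, 2.0))
print(f"flat waveform scores: {score_trough_to_peak(flat, 0.0, 'CS').amplitude} "
      "(no deflection -> zero response)")

tiny = Waveform(y * 0.01 + 1.0)  # 0.008 uS bump, below the 0.01 uS floor
print(f"sub-floor bump scores: {score_trough_to_peak(tiny, 0.0, 'CS').amplitude} "
      "(floored to an exact zero response)")
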