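"""Canonical haemodynamic response function (double-gamma).

A single shared HRF definition is used both when synthesising task-evoked
BOLD and when building GLM design matrices, so that regression can remove
exactly what simulation injected. The shape is the conventional default:
response peak at 6 s, undershoot peak at 16 s, peak:undershoot amplitude
ratio 6, 32 s support, unit peak amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

PEAK_DELAY = 6.0        # seconds
UNDERSHOOT_DELAY = 16.0  # seconds
PEAK_DISP = 1.0
UNDERSHOOT_DISP = 1.0
RATIO = 6.0
DURATION = 32.0         # seconds of HRF support


def canonical_hrf(tr: float, duration: float = DURATION) -> np.ndarray:
    """Sample the canonical double-gamma HRF on the TR grid.

    Returns an array h with h[k] = HRF(k·tr), k = 0..floor(duration/tr),
    normalised so max(h) == 1.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    t = np.arange(0.0, duration + tr / 2, tr)
    # gamma pdf with shape a and scale b has its mode at (a-1)·b, so shape
    # delay/dispersion + 1 puts the response peak exactly at the delay
    peak = stats.gamma.pdf(t, PEAK_DELAY / PEAK_DISP + 1, scale=PEAK_DISP)
    under = stats.gamma.pdf(
        t, UNDERSHOOT_DELAY / UNDERSHOOT_DISP + 1, scale=UNDERSHOOT_DISP)
    h = peak - under / RATIO
    return h / h.max()


def hrf_convolve(boxcar: np.ndarray, tr: float) -> np.ndarray:
    """Convolve a TR-sampled indicator with the canonical HRF, same length."""
    h = canonical_hrf(tr)
    return np.convolve(np.asarray(boxcar, dtype=float), h)[: len(boxcar)]
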