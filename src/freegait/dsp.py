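"""Zero-phase filtering helpers shared by segmentation and analysis."""

from __future__ import annotations

import numpy as np
from scipy import signal

FILTER_ORDER = 4


def lowpass(x: np.ndarray, cutoff_hz: float, rate: float, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth lowpass (applied forward-backward)."""
    nyq = rate / 2.0
    wn = min(cutoff_hz / nyq, 0.99)
    sos = signal.butter(order, wn, btype="low", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def bandpass(
    x: np.ndarray, low_hz: float, high_hz: float, rate: float, order: int = FILTER_ORDER
) -> np.ndarray:
    """Zero-phase Butterworth bandpass."""
    nyq = rate / 2.0
    wn = (low_hz / nyq, min(high_hz / nyq, 0.99))
    sos = signal.butter(order, wn, btype="band", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)
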