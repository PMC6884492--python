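"""Cadence estimation, gait-event detection and stride segmentation.

Events are found on the cranial-caudal (CC) acceleration of one leg:

* stride/step frequencies from a Welch PSD of the raw CC signal,
* foot-off candidates at extrema of the CC signal lowpass-filtered at the
  stride frequency, confirmed by a matching extremum of the step-frequency
  filtered signal,
* foot contact at the first upward 1 g crossing of the 5 Hz-filtered CC
  signal after each foot-off (linearly interpolated between samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dsp import lowpass
from .errors import CadenceError

STRIDE_BAND_HZ = (0.5, 1.4)
STEP_REL_BAND = (1.5, 2.5)
EVENT_FILTER_HZ = 5.0
CONTACT_LEVEL_G = 1.0

ST_BOUNDS_S = (0.91, 1.57)
DF_BOUNDS = (0.44, 0.73)
MIN_STRIDES_PER_LEG = 2

#: Welch peak must exceed this multiple of the broadband median power.
PEAK_DOMINANCE_RATIO = 4.0


@dataclass
class CadenceEstimate:
    f_stride: float
    f_step: float

    def __post_init__(self) -> None:
        if self.f_stride <= 0 or self.f_step <= 0:
            raise CadenceError("cadence frequencies must be positive")
        ratio = self.f_step / self.f_stride
        if not (STEP_REL_BAND[0] <= ratio <= STEP_REL_BAND[1]):
            raise CadenceError(
                f"f_step/f_stride = {ratio:.2f} outside {STEP_REL_BAND}"
            )


def _band_peak(f: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> tuple[float, float] | None:
    """(frequency, power) of the tallest local maximum inside [lo, hi]."""
    band = (f >= lo) & (f <= hi)
    if band.sum() < 3:
        return None
    idx = np.flatnonzero(band)
    peaks, _ = signal.find_peaks(pxx[idx])
    if peaks.size == 0:
        return None
    best = idx[peaks[np.argmax(pxx[idx][peaks])]]
    return float(f[best]), float(pxx[best])


def estimate_cadence(
    cc: np.ndarray,
    rate: float,
    stride_band: tuple[float, float] = STRIDE_BAND_HZ,
    step_rel_band: tuple[float, float] = STEP_REL_BAND,
    dominance_ratio: float = PEAK_DOMINANCE_RATIO,
) -> CadenceEstimate:
    """Stride and step frequencies from a Welch PSD of the CC signal.

    The stride frequency is the tallest local PSD maximum inside
    ``stride_band`` and must dominate the broadband median power by
    ``dominance_ratio`` (otherwise :class:`CadenceError`: featureless
    spectra such as white noise carry no cadence). The step frequency is
    searched near the stride harmonic, inside ``step_rel_band * f_stride``.
    """
    x = np.asarray(cc, dtype=float)
    nperseg = int(min(round(4.0 * rate), max(16, x.size // 2)))
    nfft = max(4096, nperseg)
    f, pxx = signal.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft,
        detrend="constant",
    )
    stride_peak = _band_peak(f, pxx, *stride_band)
    broadband = pxx[(f >= 0.25) & (f <= min(5.0, rate / 2))]
    floor = float(np.median(broadband)) if broadband.size else 0.0
    if stride_peak is None or stride_peak[1] < dominance_ratio * max(floor, 1e-300):
        raise CadenceError("no dominant stride-frequency peak in the PSD")
    f_stride = stride_peak[0]
    step_peak = _band_peak(f, pxx, step_rel_band[0] * f_stride, step_rel_band[1] * f_stride)
    if step_peak is None:
        raise CadenceError("no step-frequency peak near the stride harmonic")
    return CadenceEstimate(f_stride=f_stride, f_step=step_peak[0])


@dataclass
class GaitEvents:
    """Alternating foot-contact / foot-off times (s) for one leg.

    ``foot_contacts[i]`` is the contact following ``foot_offs[i]``.
    """

    foot_contacts: np.ndarray
    foot_offs: np.ndarray

    def __post_init__(self) -> None:
        self.foot_contacts = np.asarray(self.foot_contacts, dtype=float)
        self.foot_offs = np.asarray(self.foot_offs, dtype=float)
        merged = np.empty(self.foot_contacts.size + self.foot_offs.size)
        merged[0::2] = self.foot_offs[: merged[0::2].size]
        merged[1::2] = self.foot_contacts[: merged[1::2].size]
        if merged.size > 1 and not np.all(np.diff(merged) > 0):
            raise ValueError("gait events must alternate and strictly increase")


def detect_gait_events(
    cc: np.ndarray,
    rate: float,
    cadence: CadenceEstimate,
    t0: float = 0.0,
    event_filter_hz: float = EVENT_FILTER_HZ,
    contact_level: float = CONTACT_LEVEL_G,
    foot_off_extremum: str = "min",
) -> GaitEvents:
    """Detect foot-off and foot-contact events on one leg's CC signal.

    Cycles whose foot-off is not followed by an upward ``contact_level``
    crossing before the next foot-off are discarded, which also enforces
    event alternation.
    """
    x = np.asarray(cc, dtype=float)
    filt5 = lowpass(x, event_filter_hz, rate)
    filt_step = lowpass(x, cadence.f_step, rate)
    filt_stride = lowpass(x, cadence.f_stride, rate)

    sign = -1.0 if foot_off_extremum == "min" else 1.0
    candidates, _ = signal.find_peaks(sign * filt_stride)
    confirm, _ = signal.find_peaks(sign * filt_step)
    tol = int(round(0.25 / cadence.f_step * rate))
    offs = [
        int(i)
        for i in candidates
        if confirm.size and np.min(np.abs(confirm - i)) <= tol
    ]

    foot_offs: list[float] = []
    foot_contacts: list[float] = []
    for j, off_idx in enumerate(offs):
        stop = offs[j + 1] if j + 1 < len(offs) else x.size
        below = filt5[off_idx:stop] < contact_level
        above = filt5[off_idx:stop] >= contact_level
        crossing = np.flatnonzero(below[:-1] & above[1:])
        if crossing.size == 0:
            continue  # no stance onset before the next foot-off
        i = off_idx + int(crossing[0])
        frac = (contact_level - filt5[i]) / (filt5[i + 1] - filt5[i])
        foot_offs.append(t0 + off_idx / rate)
        foot_contacts.append(t0 + (i + frac) / rate)
    return GaitEvents(foot_contacts=np.array(foot_contacts), foot_offs=np.array(foot_offs))


@dataclass
class Stride:
    """One stride of one leg: contact -> (off) -> next contact."""

    leg: str
    t_contact: float
    t_off: float
    t_next_contact: float

    def __post_init__(self) -> None:
        if not (self.t_contact < self.t_off < self.t_next_contact):
            raise ValueError("stride events out of order")

    @property
    def stride_time(self) -> float:
        return self.t_next_contact - self.t_contact

    @property
    def duty_factor(self) -> float:
        return (self.t_off - self.t_contact) / self.stride_time


@dataclass
class StrideRejection:
    leg: str
    t_contact: float
    stride_time: float
    duty_factor: float
    reason: str


def segment_strides(
    events: GaitEvents,
    leg: str = "right",
    st_bounds: tuple[float, float] = ST_BOUNDS_S,
    df_bounds: tuple[float, float] = DF_BOUNDS,
) -> tuple[list[Stride], list[StrideRejection]]:
    """Strides between consecutive foot contacts, filtered by ST/DF bounds.

    The foot-off inside each contact pair supplies the duty factor. Strides
    outside the stride-time or duty-factor bounds are logged and rejected.
    An empty result is allowed.
    """
    contacts = events.foot_contacts
    offs = events.foot_offs
    retained: list[Stride] = []
    rejected: list[StrideRejection] = []
    for i in range(contacts.size - 1):
        t_c, t_nc = float(contacts[i]), float(contacts[i + 1])
        inner = offs[(offs > t_c) & (offs < t_nc)]
        if inner.size != 1:
            rejected.append(StrideRejection(leg, t_c, t_nc - t_c, float("nan"), "no_unique_foot_off"))
            continue
        stride = Stride(leg=leg, t_contact=t_c, t_off=float(inner[0]), t_next_contact=t_nc)
        st, df = stride.stride_time, stride.duty_factor
        eps = 1e-9  # bounds are inclusive; guard float round-off at the edges
        if not (st_bounds[0] - eps <= st <= st_bounds[1] + eps):
            rejected.append(StrideRejection(leg, t_c, st, df, "stride_time_out_of_bounds"))
        elif not (df_bounds[0] - eps <= df <= df_bounds[1] + eps):
            rejected.append(StrideRejection(leg, t_c, st, df, "duty_factor_out_of_bounds"))
        else:
            retained.append(stride)
    return retained, rejected


def bout_has_min_strides(
    strides_by_leg: dict[str, list[Stride]], min_per_leg: int = MIN_STRIDES_PER_LEG
) -> bool:
    """Bout admission rule: at least ``min_per_leg`` retained strides per leg."""
    return all(len(strides_by_leg.get(leg, [])) >= min_per_leg for leg in ("right", "left"))
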