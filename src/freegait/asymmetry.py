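"""Per-bout stride waveforms and the seven asymmetry indices + composite.

Three discrete indices compare scalar variables between the injured (I)
and healthy (H) leg as ``|I - H| / |H|`` (duty factor, mean normalized
sEMG during stance, during swing). Four waveform indices compare the
ensemble-mean time-normalized waveforms of like channels (sEMG envelope,
CC, AP, ML) as ``(1 - r) / 2`` with ``r`` the Pearson correlation. The
composite score is the mean of the seven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsp import bandpass, lowpass
from .errors import AsymmetryUndefinedError, EnvelopeError
from .segmentation import Stride

GAIT_CYCLE_POINTS = 101
EMG_BAND_HZ = (20.0, 100.0)
ENVELOPE_LOWPASS_HZ = 6.0
KINEMATIC_LOWPASS_HZ = 6.0
#: Per-leg sEMG normalization constant: this quantile of the envelope over
#: all retained strides (no MVC trial exists in free living).
EMG_NORM_QUANTILE = 0.95

WAVEFORM_CHANNELS = ("emg", "cc", "ap", "ml")

OUTLIER_IQR_FACTOR = 1.5
OUTLIER_MIN_RECORDS = 4


def emg_envelope(
    semg: np.ndarray,
    rate: float,
    band: tuple[float, float] = EMG_BAND_HZ,
    lowpass_hz: float = ENVELOPE_LOWPASS_HZ,
) -> np.ndarray:
    """Linear envelope: zero-phase bandpass, full-wave rectify, 6 Hz lowpass.

    The output is clamped to be non-negative. Raises
    :class:`EnvelopeError` for segments shorter than the filter warm-up.
    """
    x = np.asarray(semg, dtype=float).ravel()
    if rate < 100.0:
        raise EnvelopeError(f"sEMG rate {rate} Hz too low for envelope band {band}")
    if x.size < int(rate * 0.25):
        raise EnvelopeError("sEMG segment shorter than the filter warm-up")
    env = lowpass(np.abs(bandpass(x, band[0], band[1], rate)), lowpass_hz, rate)
    return np.clip(env, 0.0, None)


def time_normalize(
    t: np.ndarray, x: np.ndarray, t_start: float, t_end: float, n: int = GAIT_CYCLE_POINTS
) -> np.ndarray:
    """Linearly interpolate ``x(t)`` onto ``n`` equispaced points of [t_start, t_end]."""
    grid = np.linspace(t_start, t_end, n)
    return np.interp(grid, np.asarray(t, dtype=float), np.asarray(x, dtype=float))


@dataclass
class StrideWaveforms:
    """Channels of one stride resampled to the 0-100% gait-cycle grid."""

    stride: Stride
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, w in self.channels.items():
            if len(w) != GAIT_CYCLE_POINTS:
                raise ValueError(f"channel {name!r} must have {GAIT_CYCLE_POINTS} samples")

    @property
    def stance_boundary(self) -> int:
        """Index of the last stance sample on the percent-cycle grid."""
        return int(round(self.stride.duty_factor * (GAIT_CYCLE_POINTS - 1)))


def normalize_stride_waveforms(
    stride: Stride,
    accel_channels: dict[str, tuple[np.ndarray, np.ndarray]],
    emg_channel: tuple[np.ndarray, np.ndarray] | None = None,
    accel_rate: float | None = None,
    lowpass_hz: float = KINEMATIC_LOWPASS_HZ,
    prefiltered: bool = False,
) -> StrideWaveforms:
    """Build the 101-point gait-cycle waveforms for one stride.

    ``accel_channels`` maps channel name -> ``(times, values)`` covering the
    stride; acceleration is lowpass filtered at ``lowpass_hz`` first unless
    ``prefiltered``. ``emg_channel`` is an already-enveloped
    ``(times, values)`` pair.
    """
    channels: dict[str, np.ndarray] = {}
    for name, (t, x) in accel_channels.items():
        if not prefiltered:
            if accel_rate is None:
                raise ValueError("accel_rate required when filtering")
            x = lowpass(x, lowpass_hz, accel_rate)
        channels[name] = time_normalize(t, x, stride.t_contact, stride.t_next_contact)
    if emg_channel is not None:
        t, x = emg_channel
        channels["emg"] = time_normalize(t, x, stride.t_contact, stride.t_next_contact)
    return StrideWaveforms(stride=stride, channels=channels)


def discrete_asymmetry(injured: float, healthy: float) -> float:
    """``|I - H| / |H|``; undefined for a zero healthy-leg value."""
    if healthy == 0.0:
        raise AsymmetryUndefinedError("healthy-leg value is zero")
    return abs((injured - healthy) / healthy)


def waveform_asymmetry(injured_mean: np.ndarray, healthy_mean: np.ndarray) -> float:
    """``(1 - r) / 2`` with r the Pearson correlation of the ensemble means."""
    a = np.asarray(injured_mean, dtype=float)
    b = np.asarray(healthy_mean, dtype=float)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise AsymmetryUndefinedError("zero-variance ensemble-mean waveform")
    r = float(np.clip(np.corrcoef(a, b)[0, 1], -1.0, 1.0))
    return 0.5 * (1.0 - r)


@dataclass
class AsymmetryRecord:
    """Seven asymmetry indices and their composite for one walking bout."""

    a_df: float
    a_emg_stance: float
    a_emg_swing: float
    a_emg_t: float
    a_cc_t: float
    a_ap_t: float
    a_ml_t: float
    bout_id: str = ""
    subject_id: str = "unknown"
    timestamp: float = 0.0
    n_strides: int = 0
    mean_stride_time: float = float("nan")
    composite: float = field(init=False)

    INDEX_NAMES = ("a_df", "a_emg_stance", "a_emg_swing", "a_emg_t", "a_cc_t", "a_ap_t", "a_ml_t")

    def __post_init__(self) -> None:
        vals = self.indices()
        if not np.all(np.isfinite(list(vals.values()))):
            raise AsymmetryUndefinedError(f"non-finite asymmetry index: {vals}")
        self.composite = float(np.mean(list(vals.values())))

    def indices(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.INDEX_NAMES}


def _mean_env_phase(waveforms: list[StrideWaveforms], norm: float, stance: bool) -> float:
    """Mean normalized envelope over stance (or swing) samples, across strides."""
    per_stride = []
    for w in waveforms:
        b = w.stance_boundary
        seg = w.channels["emg"][: b + 1] if stance else w.channels["emg"][b + 1 :]
        per_stride.append(np.mean(seg) / norm)
    return float(np.mean(per_stride))


def bout_asymmetry(
    strides_by_leg: dict[str, list[StrideWaveforms]],
    injured_leg: str = "left",
    bout_id: str = "",
    subject_id: str = "unknown",
    timestamp: float = 0.0,
) -> AsymmetryRecord:
    """Compute the seven indices + composite for one bout.

    Requires at least 2 stride waveform sets per leg, each carrying the
    ``emg``, ``cc``, ``ap`` and ``ml`` channels. sEMG envelopes are
    normalized per leg by the :data:`EMG_NORM_QUANTILE` quantile over all
    retained strides of that leg.
    """
    healthy_leg = "right" if injured_leg == "left" else "left"
    for leg in (injured_leg, healthy_leg):
        if len(strides_by_leg.get(leg, [])) < 2:
            raise AsymmetryUndefinedError(f"need >= 2 retained strides for leg {leg!r}")

    norms: dict[str, float] = {}
    for leg in (injured_leg, healthy_leg):
        pooled = np.concatenate([w.channels["emg"] for w in strides_by_leg[leg]])
        norms[leg] = float(np.quantile(pooled, EMG_NORM_QUANTILE))
        if norms[leg] <= 0.0:
            raise AsymmetryUndefinedError(f"zero sEMG envelope on leg {leg!r}")

    def mean_df(leg: str) -> float:
        return float(np.mean([w.stride.duty_factor for w in strides_by_leg[leg]]))

    def ensemble_mean(leg: str, channel: str) -> np.ndarray:
        stack = np.stack([w.channels[channel] for w in strides_by_leg[leg]])
        if channel == "emg":
            stack = stack / norms[leg]
        return stack.mean(axis=0)

    a_df = discrete_asymmetry(mean_df(injured_leg), mean_df(healthy_leg))
    a_emg_stance = discrete_asymmetry(
        _mean_env_phase(strides_by_leg[injured_leg], norms[injured_leg], stance=True),
        _mean_env_phase(strides_by_leg[healthy_leg], norms[healthy_leg], stance=True),
    )
    a_emg_swing = discrete_asymmetry(
        _mean_env_phase(strides_by_leg[injured_leg], norms[injured_leg], stance=False),
        _mean_env_phase(strides_by_leg[healthy_leg], norms[healthy_leg], stance=False),
    )
    waveform_indices = {
        ch: waveform_asymmetry(ensemble_mean(injured_leg, ch), ensemble_mean(healthy_leg, ch))
        for ch in WAVEFORM_CHANNELS
    }
    all_strides = strides_by_leg[injured_leg] + strides_by_leg[healthy_leg]
    return AsymmetryRecord(
        a_df=a_df,
        a_emg_stance=a_emg_stance,
        a_emg_swing=a_emg_swing,
        a_emg_t=waveform_indices["emg"],
        a_cc_t=waveform_indices["cc"],
        a_ap_t=waveform_indices["ap"],
        a_ml_t=waveform_indices["ml"],
        bout_id=bout_id,
        subject_id=subject_id,
        timestamp=timestamp,
        n_strides=len(all_strides),
        mean_stride_time=float(np.mean([w.stride.stride_time for w in all_strides])),
    )


def remove_outlier_asymmetries(
    records: list[AsymmetryRecord],
    iqr_factor: float = OUTLIER_IQR_FACTOR,
    min_records: int = OUTLIER_MIN_RECORDS,
) -> list[AsymmetryRecord]:
    """Drop records whose composite lies outside median +/- 1.5 IQR.

    Screening is per subject on the composite score; whole records are kept
    or dropped. Subjects with fewer than ``min_records`` records pass
    through unchanged.
    """
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "composite": [r.composite for r in records],
        }
    )
    keep: list[AsymmetryRecord] = []
    for subject, sub in df.groupby("subject", sort=False):
        rows = sub.index.to_numpy()
        if rows.size < min_records:
            keep.extend(records[i] for i in rows)
            continue
        values = sub["composite"].to_numpy()
        med = np.median(values)
        q1, q3 = np.quantile(values, [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = med - iqr_factor * iqr, med + iqr_factor * iqr
        keep.extend(records[i] for i, v in zip(rows, values) if lo <= v <= hi)
    keep.sort(key=lambda r: records.index(r))
    return keep
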