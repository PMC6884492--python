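"""Synthetic bilateral gait and activity signals with known ground truth.

The gait generator builds the cranial-caudal (CC) acceleration of each leg
from a periodic cycle shape designed so that the event-detection rules
apply exactly: the fundamental harmonic's minimum sits at the foot-off
phase, a step-harmonic minimum confirms it, and the only upward 1 g
crossing of the cycle is at foot contact. No biomechanical forward model
is attempted; the generators exist to provide controllable, reproducible
test signals with exact event/stride/asymmetry ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dsp import bandpass
from .features import FEATURE_REGISTRY
from .io import (
    ACCEL_RANGE_G,
    ACCEL_RATE,
    SEMG_RATE,
    BilateralRecording,
    SensorStream,
)
from .segmentation import GaitEvents, Stride

_FINE_GRID = 4096

DEFAULT_ACTIVITY_CLASSES = ("walk", "sit", "stand", "lie", "stairs", "crutch")


@dataclass
class GaitSimConfig:
    """Parameters of one simulated walking bout."""

    stride_time: float = 1.10
    duty_factor: float = 0.60
    n_strides: int = 30
    df_ratio: float = 1.0  # injured-leg DF multiplier
    emg_stance_ratio: float = 1.0  # injured-leg stance-burst amplitude multiplier
    waveform_decorrelation: float = 0.0  # target (1 - r)/2 of injured vs healthy
    noise_sd: float = 0.03  # accel sensor noise (g)
    clipping: bool = False
    seed: int = 0
    accel_rate: float = ACCEL_RATE
    semg_rate: float = SEMG_RATE
    injured_leg: str = "left"
    cc_amplitude: float = 0.35  # peak magnitude of the CC cycle shape (g)
    subject_id: str = "sim"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not (0.7 <= self.stride_time <= 2.2):
            raise ValueError("stride_time outside [0.7, 2.2] s")
        if not (0.3 < self.duty_factor < 0.8):
            raise ValueError("duty_factor outside (0.3, 0.8)")
        if not (0.0 <= self.waveform_decorrelation < 0.5):
            raise ValueError("waveform_decorrelation must be in [0, 0.5)")


@dataclass
class GaitGroundTruth:
    """Exact event times, strides and injected parameters of a simulation."""

    events: dict[str, GaitEvents]
    strides: dict[str, list[Stride]]
    axes: dict[str, np.ndarray]  # per-leg rows (cc, ap, ml) in sensor frame
    config: GaitSimConfig
    expected_a_df: float = 0.0
    expected_decorrelation: float = 0.0
    walking_interval: tuple[float, float] = (0.0, 0.0)


def _cycle_phase(t: np.ndarray, stride_time: float, phase_offset: float) -> np.ndarray:
    return (t / stride_time + phase_offset) % 1.0


def _sample_profile(profile: np.ndarray, phase: np.ndarray) -> np.ndarray:
    grid = np.arange(_FINE_GRID + 1) / _FINE_GRID
    closed = np.concatenate([profile, profile[:1]])
    return np.interp(phase, grid, closed)


def cc_cycle_profile(duty_factor: float, amplitude: float = 0.35) -> np.ndarray:
    """Zero-mean-crossing CC cycle shape on the fine phase grid.

    Built by Fourier-truncating a piecewise target (stance hump, descent to
    a trough, swing recovery) to 4 harmonics, pinning the fundamental's
    minimum at the duty-factor phase and forcing the value at phase 0 to
    zero so the 1 g crossing marks foot contact.
    """
    df = duty_factor
    phi = np.arange(_FINE_GRID) / _FINE_GRID
    d1 = 0.4 * df
    target = np.zeros(_FINE_GRID)
    m = phi < d1
    target[m] = np.sin(np.pi * phi[m] / d1)
    m = (phi >= d1) & (phi < df)
    target[m] = -np.sin(0.5 * np.pi * (phi[m] - d1) / (df - d1))
    m = phi >= df
    target[m] = -np.cos(0.5 * np.pi * (phi[m] - df) / (1.0 - df))

    coeff = np.fft.rfft(target) / _FINE_GRID
    a1 = 2.0 * np.abs(coeff[1])
    w = -a1 * np.cos(2.0 * np.pi * (phi - df))
    for k in range(2, 5):
        w += 2.0 * np.abs(coeff[k]) * np.cos(2.0 * np.pi * k * phi + np.angle(coeff[k]))
    w -= w[0]
    return w * (amplitude / np.max(np.abs(w)))


def ap_cycle_profile(amplitude: float = 0.25) -> np.ndarray:
    """Skewed AP cycle shape (positive skewness fixes the PCA sign)."""
    phi = np.arange(_FINE_GRID) / _FINE_GRID
    return amplitude * (np.cos(2 * np.pi * phi) + 0.5 * np.cos(4 * np.pi * phi))


def ml_cycle_profile(amplitude: float = 0.08) -> np.ndarray:
    phi = np.arange(_FINE_GRID) / _FINE_GRID
    return amplitude * np.sin(2 * np.pi * phi + 0.7)


def emg_modulation_profile(
    duty_factor: float, stance_amp: float = 1.0, swing_amp: float = 0.8
) -> np.ndarray:
    """Non-negative sEMG amplitude-modulation profile over the gait cycle.

    A loading-response burst early in stance and a terminal-swing burst,
    on a small baseline.
    """
    phi = np.arange(_FINE_GRID) / _FINE_GRID

    def burst(center: float, width: float) -> np.ndarray:
        d = np.abs(((phi - center + 0.5) % 1.0) - 0.5)
        out = np.zeros_like(phi)
        m = d < width / 2
        out[m] = 0.5 * (1 + np.cos(2 * np.pi * d[m] / width))
        return out

    profile = 0.08 + stance_amp * burst(0.12 * duty_factor + 0.03, 0.45 * duty_factor)
    profile += swing_amp * burst(1.0 - 0.1 * (1 - duty_factor), 0.5 * (1 - duty_factor))
    return profile


def decorrelate_profile(
    profile: np.ndarray, level: float, harmonic: int = 3, keep_positive: bool = False
) -> np.ndarray:
    """Mix an orthogonalized harmonic so corr(original, mixed) = 1 - 2*level.

    The perturbation is orthogonalized against the centered profile and
    scaled to its standard deviation, giving the requested Pearson
    correlation exactly on the fine grid. With ``keep_positive`` the mixed
    profile is shifted up (an offset changes no correlation) to stay
    positive.
    """
    if level <= 0.0:
        return profile.copy()
    r = 1.0 - 2.0 * level
    if r <= 0.0:
        raise ValueError("decorrelation level must be < 0.5")
    lam = np.sqrt(1.0 / (r * r) - 1.0)
    phi = np.arange(profile.size) / profile.size
    g = np.sin(2 * np.pi * harmonic * phi)
    centered = profile - profile.mean()
    g = g - g.mean()
    g = g - (g @ centered) / (centered @ centered) * centered
    g *= centered.std() / g.std()
    mixed = profile + lam * g
    if keep_positive:
        floor = mixed.min()
        if floor < 0.01:
            mixed += 0.01 - floor
    return mixed


def _leg_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random sensor-mounting rotation: rows are (cc, ap, ml) in sensor frame."""
    angle = rng.uniform(0.1, 0.5)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _generate_walking(
    cfg: GaitSimConfig, rng: np.random.Generator, axes: dict[str, np.ndarray]
) -> tuple[dict[tuple[str, str], np.ndarray], dict[str, GaitEvents], dict[str, list[Stride]], float]:
    """Raw sample arrays + exact ground truth for one continuous bout."""
    st = cfg.stride_time
    duration = (cfg.n_strides + 2) * st
    healthy = "right" if cfg.injured_leg == "left" else "left"

    df_by_leg = {healthy: cfg.duty_factor, cfg.injured_leg: cfg.duty_factor * cfg.df_ratio}
    if not (0.3 < df_by_leg[cfg.injured_leg] < 0.8):
        raise ValueError("injured-leg duty factor left the simulator's bounds")
    phase_by_leg = {"right": 0.0, "left": 0.5}

    profiles: dict[str, dict[str, np.ndarray]] = {}
    for leg in ("right", "left"):
        df = df_by_leg[leg]
        p = {
            "cc": cc_cycle_profile(df, cfg.cc_amplitude),
            "ap": ap_cycle_profile(),
            "ml": ml_cycle_profile(),
            "emg": emg_modulation_profile(
                df,
                stance_amp=cfg.emg_stance_ratio if leg == cfg.injured_leg else 1.0,
            ),
        }
        if leg == cfg.injured_leg and cfg.waveform_decorrelation > 0:
            for name in ("cc", "ap", "ml"):
                p[name] = decorrelate_profile(p[name], cfg.waveform_decorrelation)
            p["emg"] = decorrelate_profile(
                p["emg"], cfg.waveform_decorrelation, keep_positive=True
            )
        profiles[leg] = p

    arrays: dict[tuple[str, str], np.ndarray] = {}
    events: dict[str, GaitEvents] = {}
    strides: dict[str, list[Stride]] = {}

    n_acc = int(round(duration * cfg.accel_rate))
    t_acc = np.arange(n_acc) / cfg.accel_rate
    n_emg = int(round(duration * cfg.semg_rate))
    t_emg = np.arange(n_emg) / cfg.semg_rate

    for leg in ("right", "left"):
        df = df_by_leg[leg]
        phase = _cycle_phase(t_acc, st, phase_by_leg[leg])
        anat = np.column_stack(
            [
                1.0 + _sample_profile(profiles[leg]["cc"], phase),
                _sample_profile(profiles[leg]["ap"], phase),
                _sample_profile(profiles[leg]["ml"], phase),
            ]
        )
        raw = anat @ axes[leg] + rng.normal(0.0, cfg.noise_sd, size=(n_acc, 3))
        if cfg.clipping:
            mid = n_acc // 2
            raw[mid : mid + 8, 0] = ACCEL_RANGE_G
        arrays[("accel", leg)] = np.clip(raw, -ACCEL_RANGE_G, ACCEL_RANGE_G)

        phase_emg = _cycle_phase(t_emg, st, phase_by_leg[leg])
        carrier = bandpass(rng.normal(size=n_emg), 20.0, 100.0, cfg.semg_rate)
        carrier /= carrier.std()
        emg = 0.5 * _sample_profile(profiles[leg]["emg"], phase_emg) * carrier
        emg += rng.normal(0.0, 0.005, size=n_emg)
        arrays[("semg", leg)] = emg[:, None]

        # exact ground truth: contacts at integer cycle phases, offs at +DF
        offset = phase_by_leg[leg]
        k = np.arange(cfg.n_strides + 3)
        contacts = (k - offset) * st
        contacts = contacts[(contacts >= 0) & (contacts <= duration)]
        contacts = contacts[1:-1]  # drop edge cycles
        offs = contacts + df * st
        leg_strides = [
            Stride(leg=leg, t_contact=float(contacts[i]), t_off=float(offs[i]),
                   t_next_contact=float(contacts[i + 1]))
            for i in range(len(contacts) - 1)
            if offs[i] < contacts[i + 1]
        ]
        events[leg] = GaitEvents(
            foot_contacts=contacts[1:], foot_offs=offs[: len(contacts) - 1]
        )
        strides[leg] = leg_strides

    return arrays, events, strides, duration


def simulate_gait_recording(cfg: GaitSimConfig) -> tuple[BilateralRecording, GaitGroundTruth]:
    """Simulate one continuous walking bout on both legs.

    The recording spans ``n_strides + 2`` stride cycles; ground truth
    covers the interior ``n_strides`` cycles of each leg (the edge cycles
    absorb filter transients). Output is bit-reproducible for a fixed
    seed.
    """
    rng = np.random.default_rng(cfg.seed)
    axes = {leg: _leg_rotation(rng) for leg in ("right", "left")}
    arrays, events, strides, duration = _generate_walking(cfg, rng, axes)
    streams = {
        ("accel", leg): SensorStream(
            samples=arrays[("accel", leg)], rate=cfg.accel_rate, leg=leg, modality="accel"
        )
        for leg in ("right", "left")
    }
    streams.update(
        {
            ("semg", leg): SensorStream(
                samples=arrays[("semg", leg)], rate=cfg.semg_rate, leg=leg, modality="semg"
            )
            for leg in ("right", "left")
        }
    )
    rec = BilateralRecording(
        streams=streams,
        start_time=cfg.start_time,
        subject_id=cfg.subject_id,
    )
    truth = GaitGroundTruth(
        events=events,
        strides=strides,
        axes=axes,
        config=cfg,
        expected_a_df=abs(cfg.df_ratio - 1.0),
        expected_decorrelation=cfg.waveform_decorrelation,
        walking_interval=(cfg.stride_time, duration - cfg.stride_time),
    )
    return rec, truth


@dataclass
class DayGroundTruth:
    """Ground truth of a composite day: walking intervals and strides."""

    axes: dict[str, np.ndarray]
    walk_intervals: list[tuple[float, float]]
    strides: dict[str, list[Stride]]
    total_walk_s: float


def simulate_day(
    segments: list[tuple[str, float]],
    gait: GaitSimConfig | None = None,
    seed: int = 0,
    start_time: float = 0.0,
    subject_id: str = "sim-day",
) -> tuple[BilateralRecording, DayGroundTruth]:
    """Compose a subject-day from ``("walk"|"quiet", duration_s)`` segments.

    Walking segments are whole simulated bouts (duration rounded to a
    multiple of the stride time); quiet segments mimic standing. All
    segments share one sensor-mounting rotation per leg, so a single
    standing calibration applies to the whole day.
    """
    gait = gait or GaitSimConfig()
    rng = np.random.default_rng(seed)
    axes = {leg: _leg_rotation(rng) for leg in ("right", "left")}

    chunks: dict[tuple[str, str], list[np.ndarray]] = {
        ("accel", "right"): [], ("accel", "left"): [],
        ("semg", "right"): [], ("semg", "left"): [],
    }
    walk_intervals: list[tuple[float, float]] = []
    strides: dict[str, list[Stride]] = {"right": [], "left": []}
    t_cursor = 0.0
    for kind, dur in segments:
        if kind == "walk":
            n_strides = max(3, int(round(dur / gait.stride_time)) - 2)
            cfg = replace(gait, n_strides=n_strides, seed=int(rng.integers(2**31)))
            arrays, _events, piece_strides, piece_dur = _generate_walking(cfg, rng, axes)
            for key in chunks:
                chunks[key].append(arrays[key])
            walk_intervals.append((t_cursor, t_cursor + piece_dur))
            for leg in ("right", "left"):
                strides[leg].extend(
                    Stride(
                        leg=leg,
                        t_contact=s.t_contact + t_cursor,
                        t_off=s.t_off + t_cursor,
                        t_next_contact=s.t_next_contact + t_cursor,
                    )
                    for s in piece_strides[leg]
                )
            t_cursor += piece_dur
        elif kind == "quiet":
            n_acc = int(round(dur * gait.accel_rate))
            n_emg = int(round(dur * gait.semg_rate))
            t = np.arange(n_acc) / gait.accel_rate
            for leg in ("right", "left"):
                drift = 0.03 * np.sin(
                    2 * np.pi * rng.uniform(0.03, 0.08) * t + rng.uniform(0, 2 * np.pi)
                )
                anat = np.column_stack(
                    [0.98 + drift, 0.06 + 0.5 * drift, 0.02 * np.ones(n_acc)]
                )
                raw = anat @ axes[leg] + rng.normal(0.0, gait.noise_sd, size=(n_acc, 3))
                chunks[("accel", leg)].append(raw)
                chunks[("semg", leg)].append(
                    rng.normal(0.0, 0.01, size=(n_emg, 1))
                )
            t_cursor += n_acc / gait.accel_rate
        else:
            raise ValueError(f"unknown segment kind {kind!r}")

    streams = {}
    for (modality, leg), parts in chunks.items():
        rate = gait.accel_rate if modality == "accel" else gait.semg_rate
        streams[(modality, leg)] = SensorStream(
            samples=np.concatenate(parts, axis=0), rate=rate, leg=leg, modality=modality
        )
    rec = BilateralRecording(streams=streams, start_time=start_time, subject_id=subject_id)
    truth = DayGroundTruth(
        axes=axes,
        walk_intervals=walk_intervals,
        strides=strides,
        total_walk_s=float(sum(t1 - t0 for t0, t1 in walk_intervals)),
    )
    return rec, truth


def simulate_standing_calibration(
    tilt_deg: float,
    seed: int = 0,
    noise_sd: float = 0.01,
    duration_s: float = 3.0,
    rate: float = ACCEL_RATE,
    azimuth_deg: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Quiet-standing accelerometer segment and its true CC axis.

    The gravity reaction points along the CC axis tilted ``tilt_deg`` away
    from the sensor z axis (about an azimuth in the x-y plane).
    """
    if not (0.0 <= tilt_deg <= 30.0):
        raise ValueError("tilt must be within [0, 30] degrees")
    rng = np.random.default_rng(seed)
    tilt = np.deg2rad(tilt_deg)
    az = np.deg2rad(azimuth_deg)
    cc_true = np.array(
        [np.sin(tilt) * np.cos(az), np.sin(tilt) * np.sin(az), np.cos(tilt)]
    )
    n = int(round(duration_s * rate))
    segment = cc_true[None, :] + rng.normal(0.0, noise_sd, size=(n, 3))
    return segment, cc_true


# ---------------------------------------------------------------------------
# Labelled activity windows for classifier training/validation


def _activity_channels(
    activity: str, rng: np.random.Generator, subject: dict, rate: float, window_s: float
) -> dict[str, np.ndarray]:
    """Anatomical channels (both legs) for one 4-s window of one activity."""
    n = int(round(window_s * rate))
    t = np.arange(n) / rate
    ch: dict[str, np.ndarray] = {}

    def drift(amp: float) -> np.ndarray:
        return amp * np.sin(2 * np.pi * rng.uniform(0.03, 0.1) * t + rng.uniform(0, 2 * np.pi))

    if activity in ("walk", "stairs"):
        if activity == "walk":
            f0 = subject["walk_f0"] * rng.uniform(0.95, 1.05)
            cc_amp = subject["amp"] * rng.uniform(0.28, 0.38)
            ap_amp, noise = rng.uniform(0.2, 0.3), rng.uniform(0.03, 0.07)
            df = rng.uniform(0.55, 0.65)
        else:
            f0 = subject["stairs_f0"] * rng.uniform(0.9, 1.1)
            cc_amp, ap_amp, noise = 0.5 * subject["amp"], 0.38, 0.09
            df = 0.62
        cc_prof = cc_cycle_profile(df, cc_amp)
        ap_prof = ap_cycle_profile(ap_amp)
        start = rng.uniform(0, 1)
        for leg, short in (("right", "r"), ("left", "l")):
            phase = (t * f0 + start + (0.0 if leg == "right" else 0.5)) % 1.0
            ch[f"cc_{short}"] = 1.0 + _sample_profile(cc_prof, phase) + rng.normal(0, noise, n)
            ch[f"ap_{short}"] = _sample_profile(ap_prof, phase) + rng.normal(0, noise, n)
    elif activity in ("sit", "stand", "lie"):
        # static postures: orientation differs, variance is tiny
        cc_level = {"sit": 0.12, "stand": 0.98, "lie": 0.04}[activity]
        ap_level = {"sit": 0.9, "stand": 0.08, "lie": 0.3}[activity]
        for short in ("r", "l"):
            ch[f"cc_{short}"] = cc_level * subject["tilt"] + drift(0.04) + rng.normal(0, 0.02, n)
            ch[f"ap_{short}"] = ap_level + drift(0.05) + rng.normal(0, 0.02, n)
    elif activity == "crutch":
        # swing-through gait: slow, legs move together, irregular amplitude
        f0 = subject["crutch_f0"] * rng.uniform(0.85, 1.15)
        envelope = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.1, 0.25) * t)
        for short in ("r", "l"):
            base = 0.3 * envelope * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 0.3))
            ch[f"cc_{short}"] = 0.92 + base + rng.normal(0, 0.08, n)
            ch[f"ap_{short}"] = 0.25 * np.sin(2 * np.pi * f0 * t + 1.0) + drift(0.1) + rng.normal(0, 0.08, n)
    else:
        raise ValueError(f"unknown activity {activity!r}")
    return ch


def simulate_activity_windows(
    n_subjects: int = 16,
    classes: tuple[str, ...] = DEFAULT_ACTIVITY_CLASSES,
    windows_per_class: int = 8,
    seed: int = 0,
    rate: float = ACCEL_RATE,
    window_s: float = 4.0,
) -> pd.DataFrame:
    """Labelled per-window feature table for classifier development.

    Returns one row per window with columns ``subject``, ``activity``,
    ``is_walking`` and the registered features. Between-subject variation
    makes the canonical features informative but imperfect.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject = {
            "walk_f0": rng.uniform(0.75, 1.05),
            "stairs_f0": rng.uniform(0.42, 0.6),
            "crutch_f0": rng.uniform(0.4, 0.6),
            "amp": rng.uniform(0.75, 1.25),
            "tilt": rng.uniform(0.85, 1.15),
        }
        for activity in classes:
            for _ in range(windows_per_class):
                ch = _activity_channels(activity, rng, subject, rate, window_s)
                row = {
                    "subject": f"S{s:02d}",
                    "activity": activity,
                    "is_walking": activity == "walk",
                }
                for name, func in FEATURE_REGISTRY.items():
                    row[name] = func(ch, rate)
                rows.append(row)
    return pd.DataFrame(rows)
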