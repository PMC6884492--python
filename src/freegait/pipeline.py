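"""End-to-end subject-day pipeline: calibration -> classification ->
segmentation -> asymmetry analysis, with an audit trail of every dropped
window, bout and stride."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .asymmetry import (
    StrideWaveforms,
    bout_asymmetry,
    emg_envelope,
    normalize_stride_waveforms,
    AsymmetryRecord,
)
from .calibration import AnatomicalFrame, estimate_ap_ml_axes, estimate_cc_axis, to_anatomical
from .classify import WalkClassifier, build_walking_bouts
from .errors import AsymmetryUndefinedError, CadenceError, CalibrationError, FreegaitError
from .features import FEATURE_REGISTRY, window_channels
from .io import (
    AnalysisWindow,
    BilateralRecording,
    partition_windows,
    recording_is_clipped,
)
from .segmentation import (
    DF_BOUNDS,
    EVENT_FILTER_HZ,
    MIN_STRIDES_PER_LEG,
    ST_BOUNDS_S,
    bout_has_min_strides,
    detect_gait_events,
    estimate_cadence,
    segment_strides,
)

LEGS = ("right", "left")


@dataclass
class PipelineConfig:
    """All tunable thresholds; defaults are the deployment values."""

    prob_threshold: float = 0.8
    st_bounds: tuple[float, float] = ST_BOUNDS_S
    df_bounds: tuple[float, float] = DF_BOUNDS
    dbi_threshold: float = 2.0
    kinematic_lowpass_hz: float = 6.0
    event_filter_hz: float = EVENT_FILTER_HZ
    min_bout_windows: int = 2
    min_strides_per_leg: int = MIN_STRIDES_PER_LEG
    clip_run: int = 3
    clip_eps: float = 0.01
    injured_leg: str = "left"
    foot_off_extremum: str = "min"
    seed: int = 0
    bin_minutes: int = 15
    enable_binning: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["st_bounds"] = list(self.st_bounds)
        d["df_bounds"] = list(self.df_bounds)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("st_bounds", "df_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh))


@dataclass
class AuditEntry:
    kind: str  # window | bout | stride
    item_id: str
    status: str  # analyzed | dropped
    reason: str = ""


@dataclass
class SubjectDaySummary:
    subject_id: str
    total_walking_hours: float
    n_strides: int
    mean_stride_time: float
    index_means: dict[str, float]
    composite_mean: float
    n_bouts: int
    binned_composite: dict[int, float] | None = None


@dataclass
class PipelineResult:
    summary: SubjectDaySummary
    records: list[AsymmetryRecord]
    bouts: list
    audit: list[AuditEntry] = field(default_factory=list)
    windows: list[AnalysisWindow] = field(default_factory=list)
    posteriors: np.ndarray | None = None
    labels: np.ndarray | None = None


def _fallback_frame(cc: np.ndarray, leg: str) -> AnatomicalFrame:
    """Deterministic frame when transverse PCA is indeterminate at start."""
    seed_axis = np.array([1.0, 0.0, 0.0])
    if abs(float(seed_axis @ cc)) > 0.9:
        seed_axis = np.array([0.0, 1.0, 0.0])
    ap = seed_axis - (seed_axis @ cc) * cc
    ap /= np.linalg.norm(ap)
    ml = np.cross(cc, ap)
    return AnatomicalFrame(cc=cc, ap=ap, ml=ml, leg=leg, indeterminate=True)


def calibrate_windows(
    windows: list[AnalysisWindow], cc_axes: dict[str, np.ndarray]
) -> list[AnalysisWindow]:
    """Fill per-window anatomical channels (CC, AP, ML) for both legs."""
    previous: dict[str, AnatomicalFrame | None] = {leg: None for leg in LEGS}
    for window in windows:
        for leg in LEGS:
            cc = cc_axes[leg]
            try:
                frame = estimate_ap_ml_axes(
                    window.accel[leg], cc, previous=previous[leg], leg=leg
                )
            except CalibrationError:
                frame = _fallback_frame(cc / np.linalg.norm(cc), leg)
            if frame.indeterminate:
                window.flags.append(f"axis_indeterminate:{leg}")
            previous[leg] = frame
            window.anatomical[leg] = to_anatomical(window.accel[leg], frame)
    return windows


def window_feature_matrix(windows: list[AnalysisWindow], rate: float) -> pd.DataFrame:
    rows = []
    for window in windows:
        ch = window_channels(window)
        rows.append({name: func(ch, rate) for name, func in FEATURE_REGISTRY.items()})
    return pd.DataFrame(rows)


def _analyze_bout(
    rec: BilateralRecording,
    bout,
    cc_axes: dict[str, np.ndarray],
    cfg: PipelineConfig,
    bout_id: str,
) -> tuple[AsymmetryRecord | None, list, str]:
    """Segment and analyze one bout; returns (record, strides, drop reason)."""
    accel_rate = rec.accel("right").rate
    strides_by_leg: dict[str, list] = {}
    waveforms_by_leg: dict[str, list[StrideWaveforms]] = {}
    for leg in LEGS:
        raw = rec.accel(leg).slice(bout.start, bout.end)
        t = bout.start + np.arange(raw.shape[0]) / accel_rate
        cc_series = raw @ cc_axes[leg]
        try:
            cadence = estimate_cadence(cc_series, accel_rate)
        except CadenceError as exc:
            return None, [], f"cadence:{exc}"
        events = detect_gait_events(
            cc_series,
            accel_rate,
            cadence,
            t0=bout.start,
            event_filter_hz=cfg.event_filter_hz,
            foot_off_extremum=cfg.foot_off_extremum,
        )
        strides, _rejected = segment_strides(
            events, leg=leg, st_bounds=cfg.st_bounds, df_bounds=cfg.df_bounds
        )
        strides_by_leg[leg] = strides
        if len(strides) < cfg.min_strides_per_leg:
            continue

        # bout-level AP/ML axes for the analysis channels
        try:
            frame = estimate_ap_ml_axes(raw, cc_axes[leg], leg=leg)
        except CalibrationError:
            frame = _fallback_frame(cc_axes[leg] / np.linalg.norm(cc_axes[leg]), leg)
        anat = to_anatomical(raw, frame)

        semg = rec.semg(leg)
        emg_seg = semg.slice(bout.start, bout.end).ravel()
        t_emg = bout.start + np.arange(emg_seg.size) / semg.rate
        try:
            envelope = emg_envelope(emg_seg, semg.rate)
        except FreegaitError as exc:
            return None, [], f"envelope:{exc}"

        waveforms_by_leg[leg] = [
            normalize_stride_waveforms(
                stride,
                accel_channels={
                    "cc": (t, anat[:, 0]),
                    "ap": (t, anat[:, 1]),
                    "ml": (t, anat[:, 2]),
                },
                emg_channel=(t_emg, envelope),
                accel_rate=accel_rate,
                lowpass_hz=cfg.kinematic_lowpass_hz,
            )
            for stride in strides
        ]

    if not bout_has_min_strides(strides_by_leg, cfg.min_strides_per_leg):
        return None, strides_by_leg, "too_few_strides"
    try:
        record = bout_asymmetry(
            waveforms_by_leg,
            injured_leg=cfg.injured_leg,
            bout_id=bout_id,
            subject_id=rec.subject_id,
            timestamp=rec.start_time + bout.start,
        )
    except AsymmetryUndefinedError as exc:
        return None, strides_by_leg, f"asymmetry_undefined:{exc}"
    return record, strides_by_leg, ""


def run_pipeline(
    rec: BilateralRecording,
    model: WalkClassifier,
    cfg: PipelineConfig | None = None,
    cc_axes: dict[str, np.ndarray] | None = None,
    standing: dict[str, np.ndarray] | None = None,
) -> PipelineResult:
    """Run all stages over one recording and summarize the subject-day.

    Anatomical calibration comes either from precomputed ``cc_axes`` or
    from per-leg quiet-standing segments in ``standing``. A recording in
    which no bout survives every criterion yields a zero-stride summary,
    not an error.
    """
    cfg = cfg or PipelineConfig()
    if cc_axes is None:
        if standing is None:
            raise CalibrationError("provide cc_axes or standing segments")
        cc_axes = {leg: estimate_cc_axis(standing[leg]) for leg in LEGS}

    audit: list[AuditEntry] = []
    windows = partition_windows(rec)
    windows = calibrate_windows(windows, cc_axes)
    accel_rate = rec.accel("right").rate

    if windows:
        matrix = window_feature_matrix(windows, accel_rate)
        posteriors = model.predict_proba(matrix)
        labels = model.predict(matrix)
    else:
        posteriors = np.array([])
        labels = np.array([], dtype=bool)

    bouts, _ = build_walking_bouts(
        labels,
        posteriors,
        windows,
        prob_threshold=cfg.prob_threshold,
        min_windows=cfg.min_bout_windows,
    )
    kept_bouts = []
    for b, bout in enumerate(bouts):
        if recording_is_clipped(rec, bout.start, bout.end, k=cfg.clip_run, eps_frac=cfg.clip_eps):
            audit.append(AuditEntry("bout", f"bout{b}", "dropped", "clipped"))
        else:
            kept_bouts.append(bout)

    in_bout = {i for bout in kept_bouts for i in bout.window_indices}
    for w, window in enumerate(windows):
        if window.index in in_bout:
            audit.append(AuditEntry("window", f"w{w}", "analyzed", ""))
        elif not labels[w]:
            audit.append(AuditEntry("window", f"w{w}", "dropped", "not_walking"))
        elif posteriors[w] < cfg.prob_threshold:
            audit.append(AuditEntry("window", f"w{w}", "dropped", "low_posterior"))
        else:
            audit.append(AuditEntry("window", f"w{w}", "dropped", "isolated_or_clipped"))

    window_s = windows[0].end - windows[0].start if windows else 4.0
    walking_time_s = window_s * sum(b.n_windows for b in kept_bouts)

    records: list[AsymmetryRecord] = []
    stride_times: list[float] = []
    n_strides = 0
    for b, bout in enumerate(kept_bouts):
        bout_id = f"{rec.subject_id}-bout{b}"
        record, strides_by_leg, reason = _analyze_bout(rec, bout, cc_axes, cfg, bout_id)
        if record is None:
            audit.append(AuditEntry("bout", bout_id, "dropped", reason))
            continue
        audit.append(AuditEntry("bout", bout_id, "analyzed", ""))
        records.append(record)
        for leg in LEGS:
            for stride in strides_by_leg[leg]:
                stride_times.append(stride.stride_time)
                n_strides += 1

    index_means = {
        name: float(np.mean([getattr(r, name) for r in records])) if records else float("nan")
        for name in AsymmetryRecord.INDEX_NAMES
    }
    binned = None
    if cfg.enable_binning:
        binned = {}
        bin_s = cfg.bin_minutes * 60.0
        by_bin: dict[int, list[float]] = {}
        for record in records:
            key = int(record.timestamp // bin_s)
            by_bin.setdefault(key, []).append(record.composite)
        binned = {k: float(np.mean(v)) for k, v in sorted(by_bin.items())}

    summary = SubjectDaySummary(
        subject_id=rec.subject_id,
        total_walking_hours=walking_time_s / 3600.0,
        n_strides=n_strides,
        mean_stride_time=float(np.mean(stride_times)) if stride_times else float("nan"),
        index_means=index_means,
        composite_mean=float(np.mean([r.composite for r in records]))
        if records
        else float("nan"),
        n_bouts=len(records),
        binned_composite=binned,
    )
    return PipelineResult(
        summary=summary,
        records=records,
        bouts=kept_bouts,
        audit=audit,
        windows=windows,
        posteriors=posteriors,
        labels=labels,
    )


def records_to_frame(records: list[AsymmetryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "bout_id": r.bout_id,
            "subject_id": r.subject_id,
            "timestamp": r.timestamp,
            "n_strides": r.n_strides,
            "mean_stride_time": r.mean_stride_time,
            **r.indices(),
            "composite": r.composite,
        }
        rows.append(row)
    return pd.DataFrame(rows)
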