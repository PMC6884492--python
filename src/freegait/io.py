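"""Reading, validation, windowing and quality screening of bilateral sensor streams.

A recording couples four time-synchronized streams: tri-axial thigh
acceleration (g) and single-channel surface EMG (mV) for each leg. Two
on-disk dialects are supported:

* long-format CSV with columns ``stream, t, channel, value`` plus
  ``# key=value`` comment headers for recording metadata, and
* HDF5 with one group per stream (dataset ``samples``, scalar attrs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, SamplingError

ACCEL_RATE = 31.25
SEMG_RATE = 250.0
ACCEL_RANGE_G = 16.0
WINDOW_SECONDS = 4.0

LEGS = ("right", "left")
MODALITIES = ("accel", "semg")
ACCEL_CHANNELS = ("x", "y", "z")
SEMG_CHANNELS = ("emg",)

#: Relative tolerance on timestamp uniformity (fraction of the median step).
TIMESTAMP_TOLERANCE = 0.01

#: Default clipping rule: a run of >= CLIP_RUN samples within CLIP_EPS_FRAC
#: of the range limit marks the segment as clipped.
CLIP_RUN = 3
CLIP_EPS_FRAC = 0.01


@dataclass
class SensorStream:
    """Uniformly sampled sensor stream for one leg and one modality.

    ``samples`` has shape ``(n, 3)`` for acceleration (units of g) and
    ``(n, 1)`` for sEMG (mV). ``t0`` is the stream's offset from the
    recording start in seconds.
    """

    samples: np.ndarray
    rate: float
    leg: str
    modality: str
    range_limit: float | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.rate <= 0:
            raise SamplingError(f"rate must be positive, got {self.rate}")
        if self.leg not in LEGS:
            raise FormatError(f"unknown leg {self.leg!r}")
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        expected = 3 if self.modality == "accel" else 1
        if self.samples.shape[1] != expected:
            raise FormatError(
                f"{self.modality} stream must have {expected} channels, "
                f"got {self.samples.shape[1]}"
            )
        if self.modality == "accel" and self.range_limit is None:
            self.range_limit = ACCEL_RANGE_G

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def slice(self, t_start: float, t_end: float) -> np.ndarray:
        """Samples with time in ``[t_start, t_end)``."""
        i0 = max(0, math.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = min(self.n, math.ceil((t_end - self.t0) * self.rate - 1e-9))
        return self.samples[i0:i1]


@dataclass
class BilateralRecording:
    """Four synchronized streams (accel R/L, sEMG R/L) plus metadata."""

    streams: dict[tuple[str, str], SensorStream]
    start_time: float = 0.0
    subject_id: str = "unknown"
    group: str | None = None

    def __post_init__(self) -> None:
        for modality in MODALITIES:
            for leg in LEGS:
                if (modality, leg) not in self.streams:
                    raise FormatError(f"missing stream {modality}_{leg}")

    def accel(self, leg: str) -> SensorStream:
        return self.streams[("accel", leg)]

    def semg(self, leg: str) -> SensorStream:
        return self.streams[("semg", leg)]

    @property
    def duration(self) -> float:
        """Span of the time interval covered by all four streams."""
        start = max(s.t0 for s in self.streams.values())
        end = min(s.t0 + s.duration for s in self.streams.values())
        return max(0.0, end - start)


@dataclass
class AnalysisWindow:
    """One 4-s non-overlapping bilateral analysis window.

    ``accel`` maps leg -> raw (n, 3) sensor-frame acceleration.
    ``anatomical`` is filled by the calibration stage and maps leg -> (n, 3)
    with columns ordered (CC, AP, ML).
    """

    index: int
    start: float
    end: float
    accel: dict[str, np.ndarray]
    anatomical: dict[str, np.ndarray] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def partition_windows(
    rec: BilateralRecording, window_s: float = WINDOW_SECONDS
) -> list[AnalysisWindow]:
    """Partition a recording into non-overlapping ``window_s`` windows.

    The trailing remainder shorter than one window is discarded. A
    recording shorter than one window yields an empty list.
    """
    n_windows = int(math.floor(rec.duration / window_s + 1e-9))
    windows: list[AnalysisWindow] = []
    t_base = max(s.t0 for s in rec.streams.values())
    for i in range(n_windows):
        t0 = t_base + i * window_s
        t1 = t0 + window_s
        accel = {leg: rec.accel(leg).slice(t0, t1) for leg in LEGS}
        windows.append(AnalysisWindow(index=i, start=t0, end=t1, accel=accel))
    return windows


def detect_clipping(
    segment: np.ndarray,
    range_limit: float,
    k: int = CLIP_RUN,
    eps_frac: float = CLIP_EPS_FRAC,
) -> bool:
    """True iff any channel holds >= ``k`` consecutive samples at the rail.

    A sample is "at the rail" when ``|x| >= range_limit * (1 - eps_frac)``.
    The rule is symmetric in the sign of the rail.
    """
    x = np.atleast_2d(np.asarray(segment, dtype=float).T).T
    if x.size == 0:
        return False
    at_rail = np.abs(x) >= range_limit * (1.0 - eps_frac)
    for c in range(at_rail.shape[1]):
        col = at_rail[:, c]
        if not col.any():
            continue
        # run lengths of consecutive True values
        padded = np.concatenate(([False], col, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        run_lengths = edges[1::2] - edges[0::2]
        if run_lengths.size and run_lengths.max() >= k:
            return True
    return False


def recording_is_clipped(
    rec: BilateralRecording,
    t_start: float,
    t_end: float,
    k: int = CLIP_RUN,
    eps_frac: float = CLIP_EPS_FRAC,
) -> bool:
    """Check all four streams of ``rec`` for clipping over ``[t_start, t_end)``.

    Streams without a known ``range_limit`` (typically sEMG) are skipped.
    """
    for stream in rec.streams.values():
        if stream.range_limit is None:
            continue
        seg = stream.slice(t_start, t_end)
        if detect_clipping(seg, stream.range_limit, k=k, eps_frac=eps_frac):
            return True
    return False


# ---------------------------------------------------------------------------
# File I/O

_STREAM_NAMES = {
    ("accel", "right"): "accel_right",
    ("accel", "left"): "accel_left",
    ("semg", "right"): "semg_right",
    ("semg", "left"): "semg_left",
}
_NAME_TO_KEY = {v: k for k, v in _STREAM_NAMES.items()}

DEFAULT_LAYOUT: dict = {
    "stream_col": "stream",
    "time_col": "t",
    "channel_col": "channel",
    "value_col": "value",
    "rates": {"accel": None, "semg": None},  # None -> infer from timestamps
    "range_limit": {"accel": ACCEL_RANGE_G, "semg": None},
}


def _channels_for(modality: str) -> tuple[str, ...]:
    return ACCEL_CHANNELS if modality == "accel" else SEMG_CHANNELS


def save_recording(rec: BilateralRecording, path: str | Path) -> Path:
    """Write a recording in the dialect implied by the file suffix."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _save_hdf5(rec, path)
    return _save_csv(rec, path)


def load_recording(path: str | Path, layout: Mapping | None = None) -> BilateralRecording:
    """Read a recording written by :func:`save_recording` (or equivalent).

    No resampling is performed; rates come from the layout/metadata or are
    inferred from the median timestep. Non-uniform timestamps beyond
    tolerance raise :class:`SamplingError`; missing streams/columns raise
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _load_hdf5(path)
    return _load_csv(path, layout)


def _save_csv(rec: BilateralRecording, path: Path) -> Path:
    frames = []
    for key, stream in rec.streams.items():
        chans = _channels_for(stream.modality)
        t = stream.times
        for ci, ch in enumerate(chans):
            frames.append(
                pd.DataFrame(
                    {
                        "stream": _STREAM_NAMES[key],
                        "t": t,
                        "channel": ch,
                        "value": stream.samples[:, ci],
                    }
                )
            )
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# subject_id={rec.subject_id}\n")
        fh.write(f"# start_time={rec.start_time!r}\n")
        if rec.group is not None:
            fh.write(f"# group={rec.group}\n")
        for key, stream in rec.streams.items():
            name = _STREAM_NAMES[key]
            fh.write(f"# rate.{name}={stream.rate!r}\n")
            if stream.range_limit is not None:
                fh.write(f"# range_limit.{name}={stream.range_limit!r}\n")
        table.to_csv(fh, index=False, float_format="%.17g")
    return path


def _read_csv_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def _validate_uniform(t: np.ndarray, name: str) -> float:
    """Return the sampling rate implied by uniform timestamps."""
    if t.size < 2:
        raise SamplingError(f"stream {name} has fewer than 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError(f"stream {name}: non-increasing timestamps")
    if np.max(np.abs(dt - med)) > TIMESTAMP_TOLERANCE * med:
        raise SamplingError(f"stream {name}: non-uniform timestamps")
    return 1.0 / med


def _load_csv(path: Path, layout: Mapping | None) -> BilateralRecording:
    lay = dict(DEFAULT_LAYOUT)
    if layout:
        lay.update(layout)
    meta = _read_csv_meta(path)
    try:
        # round_trip parsing: written values must survive bit-exactly
        table = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    for col in (lay["stream_col"], lay["time_col"], lay["channel_col"], lay["value_col"]):
        if col not in table.columns:
            raise FormatError(f"missing column {col!r} in {path}")

    streams: dict[tuple[str, str], SensorStream] = {}
    for name, key in _NAME_TO_KEY.items():
        modality, leg = key
        sub = table[table[lay["stream_col"]] == name]
        if sub.empty:
            raise FormatError(f"missing stream {name!r} in {path}")
        chans = _channels_for(modality)
        cols = []
        t_ref = None
        for ch in chans:
            chan = sub[sub[lay["channel_col"]] == ch].sort_values(lay["time_col"])
            if chan.empty:
                raise FormatError(f"stream {name!r}: missing channel {ch!r}")
            if t_ref is None:
                t_ref = chan[lay["time_col"]].to_numpy(dtype=float)
            cols.append(chan[lay["value_col"]].to_numpy(dtype=float))
        assert t_ref is not None
        inferred = _validate_uniform(t_ref, name)
        rate = lay["rates"].get(modality) or float(meta.get(f"rate.{name}", inferred))
        limit_meta = meta.get(f"range_limit.{name}")
        range_limit = (
            float(limit_meta) if limit_meta is not None else lay["range_limit"].get(modality)
        )
        streams[key] = SensorStream(
            samples=np.column_stack(cols),
            rate=rate,
            leg=leg,
            modality=modality,
            range_limit=range_limit,
            t0=float(t_ref[0]),
        )
    return BilateralRecording(
        streams=streams,
        start_time=float(meta.get("start_time", 0.0)),
        subject_id=meta.get("subject_id", "unknown"),
        group=meta.get("group"),
    )


def _save_hdf5(rec: BilateralRecording, path: Path) -> Path:
    with h5py.File(path, "w") as fh:
        fh.attrs["subject_id"] = rec.subject_id
        fh.attrs["start_time"] = rec.start_time
        if rec.group is not None:
            fh.attrs["group"] = rec.group
        for key, stream in rec.streams.items():
            grp = fh.create_group(_STREAM_NAMES[key])
            grp.create_dataset("samples", data=stream.samples)
            grp.attrs["rate"] = stream.rate
            grp.attrs["t0"] = stream.t0
            grp.attrs["leg"] = stream.leg
            grp.attrs["modality"] = stream.modality
            if stream.range_limit is not None:
                grp.attrs["range_limit"] = stream.range_limit
    return path


def _load_hdf5(path: Path) -> BilateralRecording:
    streams: dict[tuple[str, str], SensorStream] = {}
    with h5py.File(path, "r") as fh:
        for name, key in _NAME_TO_KEY.items():
            if name not in fh:
                raise FormatError(f"missing stream group {name!r} in {path}")
            grp = fh[name]
            streams[key] = SensorStream(
                samples=np.asarray(grp["samples"], dtype=float),
                rate=float(grp.attrs["rate"]),
                leg=str(grp.attrs["leg"]),
                modality=str(grp.attrs["modality"]),
                range_limit=float(grp.attrs["range_limit"])
                if "range_limit" in grp.attrs
                else None,
                t0=float(grp.attrs.get("t0", 0.0)),
            )
        return BilateralRecording(
            streams=streams,
            start_time=float(fh.attrs.get("start_time", 0.0)),
            subject_id=str(fh.attrs.get("subject_id", "unknown")),
            group=str(fh.attrs["group"]) if "group" in fh.attrs else None,
        )
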