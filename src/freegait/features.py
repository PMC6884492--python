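"""Window feature extraction with an extensible feature registry.

Six canonical features drive the walking classifier; additional features
can be registered with :func:`register_feature` and are picked up by
:func:`extract_features` automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal, stats

#: Frequency bound for the low-frequency power-fraction feature (Hz).
LOWFREQ_CUTOFF_HZ = 0.25

Channels = dict[str, np.ndarray]
FeatureFunc = Callable[[Channels, float], float]

FEATURE_REGISTRY: dict[str, FeatureFunc] = {}

#: Names of the six canonical classifier inputs, in definition order.
CANONICAL_FEATURES = (
    "cc_q25_mean",
    "cc_ap_crosscorr_mean",
    "cc_bilateral_corr",
    "ap_skew_mean",
    "ap_lowfreq_power_mean",
    "ap_median_mean",
)


def register_feature(name: str) -> Callable[[FeatureFunc], FeatureFunc]:
    """Decorator adding a feature function to the registry."""

    def wrap(func: FeatureFunc) -> FeatureFunc:
        FEATURE_REGISTRY[name] = func
        return func

    return wrap


def _corr(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation; zero-variance inputs yield (0.0, flagged)."""
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0, True
    r = float(np.corrcoef(a, b)[0, 1])
    return r, False


def lowfreq_power_fraction(x: np.ndarray, rate: float, f_max: float = LOWFREQ_CUTOFF_HZ) -> float:
    """Fraction of total (DC-inclusive) periodogram power below ``f_max``."""
    f, pxx = signal.periodogram(x, fs=rate, detrend=False)
    total = float(pxx.sum())
    if total == 0.0:
        return 1.0
    return float(pxx[f < f_max].sum() / total)


@register_feature("cc_q25_mean")
def _cc_q25_mean(ch: Channels, rate: float) -> float:
    return float(np.mean([np.quantile(ch["cc_r"], 0.25), np.quantile(ch["cc_l"], 0.25)]))


@register_feature("cc_ap_crosscorr_mean")
def _cc_ap_crosscorr_mean(ch: Channels, rate: float) -> float:
    r1, _ = _corr(ch["cc_r"], ch["ap_l"])
    r2, _ = _corr(ch["cc_l"], ch["ap_r"])
    return 0.5 * (r1 + r2)


@register_feature("cc_bilateral_corr")
def _cc_bilateral_corr(ch: Channels, rate: float) -> float:
    r, _ = _corr(ch["cc_r"], ch["cc_l"])
    return r


@register_feature("ap_skew_mean")
def _ap_skew_mean(ch: Channels, rate: float) -> float:
    def safe_skew(x: np.ndarray) -> float:
        # skewness of an (effectively) constant channel is undefined; use 0
        if np.std(x) <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
            return 0.0
        return float(stats.skew(x))

    return float(np.mean([safe_skew(ch["ap_r"]), safe_skew(ch["ap_l"])]))


@register_feature("ap_lowfreq_power_mean")
def _ap_lowfreq_power_mean(ch: Channels, rate: float) -> float:
    return float(
        np.mean(
            [
                lowfreq_power_fraction(ch["ap_r"], rate),
                lowfreq_power_fraction(ch["ap_l"], rate),
            ]
        )
    )


@register_feature("ap_median_mean")
def _ap_median_mean(ch: Channels, rate: float) -> float:
    return float(np.mean([np.median(ch["ap_r"]), np.median(ch["ap_l"])]))


@dataclass
class FeatureVector:
    values: dict[str, float]
    window_index: int = -1
    subject_id: str = "unknown"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [f for f in CANONICAL_FEATURES if f not in self.values]
        if missing:
            raise ValueError(f"missing canonical features: {missing}")
        bad = {k: v for k, v in self.values.items() if not np.isfinite(v)}
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")


def window_channels(window) -> Channels:
    """Named anatomical channels of an :class:`~freegait.io.AnalysisWindow`."""
    ch: Channels = {}
    for leg, short in (("right", "r"), ("left", "l")):
        anat = window.anatomical[leg]
        ch[f"cc_{short}"] = anat[:, 0]
        ch[f"ap_{short}"] = anat[:, 1]
        ch[f"ml_{short}"] = anat[:, 2]
    return ch


def extract_features(
    window,
    rate: float,
    names: tuple[str, ...] | None = None,
) -> FeatureVector:
    """Evaluate registry features on a calibrated window.

    ``names`` restricts the computation (canonical features are always
    included). Zero-variance correlation inputs are reported as 0 and the
    window is flagged.
    """
    ch = window_channels(window)
    if names is None:
        wanted = tuple(FEATURE_REGISTRY)
    else:
        wanted = tuple(dict.fromkeys(tuple(names) + CANONICAL_FEATURES))
    flags = []
    for key in ("cc_r", "cc_l", "ap_r", "ap_l"):
        if np.std(ch[key]) == 0.0:
            flags.append(f"zero_variance:{key}")
    values = {name: FEATURE_REGISTRY[name](ch, rate) for name in wanted}
    return FeatureVector(
        values=values,
        window_index=window.index,
        flags=flags,
    )
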