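"""Sensor-to-thigh anatomical calibration.

The cranial-caudal (CC) axis is the gravity direction measured during a
quiet standing trial (directed proximally, i.e. along the measured reaction
for an upright thigh). Antero-posterior (AP) and medio-lateral (ML) axes
are re-estimated per analysis window as the first principal component of
acceleration in the transverse plane, completed to a right-handed frame
with ``ml = cc x ap``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError

#: Standing trial is rejected if any axis SD exceeds this (g).
STANDING_SD_MAX = 0.05
#: Acceptable mean-norm band for the standing trial (g).
STANDING_NORM_BOUNDS = (0.8, 1.2)
#: |skewness| below which the AP sign is inherited from the previous window.
AP_SKEW_MIN = 0.1
#: Transverse eigenvalue ratio above which the direction is indeterminate.
TRANSVERSE_ISOTROPY_MAX = 0.7
#: Total transverse variance (g^2) below which the direction is indeterminate.
TRANSVERSE_VAR_MIN = 1e-6

_ORTHO_TOL = 1e-6


@dataclass
class AnatomicalFrame:
    """Orthonormal right-handed thigh frame expressed in sensor coordinates."""

    cc: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    leg: str = "right"
    indeterminate: bool = False

    def __post_init__(self) -> None:
        for name in ("cc", "ap", "ml"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise CalibrationError(f"{name} axis is not unit norm")
        if (
            abs(float(self.cc @ self.ap)) > _ORTHO_TOL
            or abs(float(self.cc @ self.ml)) > _ORTHO_TOL
            or abs(float(self.ap @ self.ml)) > _ORTHO_TOL
        ):
            raise CalibrationError("anatomical axes are not mutually orthogonal")
        if np.linalg.norm(np.cross(self.cc, self.ap) - self.ml) > 1e-5:
            raise CalibrationError("frame is not right-handed (ml != cc x ap)")

    @property
    def matrix(self) -> np.ndarray:
        """Rows (cc, ap, ml); maps sensor vectors to anatomical components."""
        return np.vstack([self.cc, self.ap, self.ml])


def estimate_cc_axis(
    standing_accel: np.ndarray,
    sd_max: float = STANDING_SD_MAX,
    norm_bounds: tuple[float, float] = STANDING_NORM_BOUNDS,
) -> np.ndarray:
    """CC axis from a quiet standing trial: the unit mean acceleration.

    For an upright thigh the accelerometer measures the gravity reaction,
    so the mean acceleration points proximally already; no sign flip is
    applied. Raises :class:`CalibrationError` when the subject was moving
    (per-axis SD above ``sd_max``) or the mean norm falls outside
    ``norm_bounds``.
    """
    x = np.asarray(standing_accel, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise CalibrationError("standing trial must be an (n, 3) array, n >= 2")
    sds = x.std(axis=0, ddof=0)
    if np.any(sds > sd_max):
        raise CalibrationError(
            f"motion during standing trial (axis SD up to {sds.max():.3f} g)"
        )
    mean = x.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if not (norm_bounds[0] <= norm <= norm_bounds[1]):
        raise CalibrationError(f"standing mean norm {norm:.3f} g outside {norm_bounds}")
    return mean / norm


def estimate_ap_ml_axes(
    window_accel: np.ndarray,
    cc: np.ndarray,
    previous: AnatomicalFrame | None = None,
    leg: str = "right",
) -> AnatomicalFrame:
    """AP/ML axes for one window from transverse-plane PCA.

    Samples are projected onto the plane orthogonal to ``cc``; the first
    principal component of the projected cloud is the AP axis and
    ``ml = cc x ap``. PCA leaves the AP sign ambiguous: the sign making the
    AP-channel skewness non-negative is chosen, and when the skewness
    magnitude is below ``AP_SKEW_MIN`` the previous window's orientation is
    inherited (falling back to a fixed deterministic rule without one).

    When the transverse cloud is near-isotropic or near-degenerate the
    window is flagged ``indeterminate`` and the previous frame is returned
    if available.
    """
    x = np.asarray(window_accel, dtype=float)
    cc = np.asarray(cc, dtype=float)
    cc = cc / np.linalg.norm(cc)
    proj = x - np.outer(x @ cc, cc)
    proj = proj - proj.mean(axis=0)

    cov = proj.T @ proj / max(1, proj.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    total_var = float(evals[:2].sum())
    isotropy = float(evals[1] / evals[0]) if evals[0] > 0 else 1.0

    if total_var < TRANSVERSE_VAR_MIN or isotropy > TRANSVERSE_ISOTROPY_MAX:
        if previous is not None:
            return AnatomicalFrame(
                cc=previous.cc, ap=previous.ap, ml=previous.ml, leg=leg,
                indeterminate=True,
            )
        raise CalibrationError("transverse acceleration direction indeterminate")

    ap = evecs[:, 0]
    ap = ap - (ap @ cc) * cc  # exact orthogonality against cc
    ap = ap / np.linalg.norm(ap)

    skew = float(stats.skew(proj @ ap))
    if abs(skew) >= AP_SKEW_MIN:
        if skew < 0:
            ap = -ap
    elif previous is not None:
        if float(ap @ previous.ap) < 0:
            ap = -ap
    else:
        # deterministic fallback: make the largest-magnitude component positive
        if ap[np.argmax(np.abs(ap))] < 0:
            ap = -ap

    ml = np.cross(cc, ap)
    ml = ml / np.linalg.norm(ml)
    return AnatomicalFrame(cc=cc, ap=ap, ml=ml, leg=leg)


def to_anatomical(window_accel: np.ndarray, frame: AnatomicalFrame) -> np.ndarray:
    """Project raw samples onto (CC, AP, ML); returns an (n, 3) array.

    The frame is orthonormal, so the per-sample vector norm is preserved.
    """
    x = np.asarray(window_accel, dtype=float)
    return x @ frame.matrix.T
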