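"""Walking-bout identification: feature selection, SVM training, LOSO
validation, probability thresholding and bout aggregation.

Feature matrices are pandas DataFrames (one column per feature), labels are
boolean arrays with ``True`` meaning "walking".
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import SelectionError, TrainingError
from .io import BilateralRecording, recording_is_clipped

DEFAULT_DBI_THRESHOLD = 2.0
DEFAULT_PROB_THRESHOLD = 0.8
MIN_BOUT_WINDOWS = 2

MODEL_FORMAT_VERSION = 1


def davies_bouldin_index(values: np.ndarray, labels: np.ndarray) -> float:
    """Two-class, single-feature Davies-Bouldin index.

    ``(S_1 + S_2) / |m_1 - m_2|`` where ``S_c`` is the mean absolute
    deviation from the class centroid ``m_c``. Coincident centroids give
    ``+inf`` (the feature can never be selected).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise TrainingError("both classes must be non-empty")
    m1, m2 = x[y].mean(), x[~y].mean()
    sep = abs(m1 - m2)
    if sep == 0.0:
        return float("inf")
    s1 = np.abs(x[y] - m1).mean()
    s2 = np.abs(x[~y] - m2).mean()
    return float((s1 + s2) / sep)


def select_features(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    threshold: float = DEFAULT_DBI_THRESHOLD,
) -> list[str]:
    """Features with DBI below ``threshold``, sorted ascending by DBI."""
    y = np.asarray(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise TrainingError("need at least 2 observations per class")
    scores = {col: davies_bouldin_index(matrix[col].to_numpy(), y) for col in matrix.columns}
    kept = sorted((name for name, s in scores.items() if s < threshold), key=scores.__getitem__)
    if not kept:
        raise SelectionError(
            f"no feature has DBI < {threshold}; consider raising the threshold"
        )
    return kept


def median_distance_gamma(x: np.ndarray, max_rows: int = 500, seed: int = 0) -> float:
    """RBF kernel width heuristic: ``1 / (2 * median pairwise distance^2)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        x = x[rng.choice(x.shape[0], max_rows, replace=False)]
    d = pdist(x)
    d = d[d > 0]
    med = float(np.median(d)) if d.size else 1.0
    return 1.0 / (2.0 * med * med)


@dataclass
class WalkClassifier:
    """Gaussian-kernel SVM with Platt-calibrated posteriors."""

    scaler: StandardScaler
    svm: CalibratedClassifierCV
    selected_features: list[str]
    prob_threshold: float = DEFAULT_PROB_THRESHOLD
    format_version: int = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must be in (0, 1)")

    def _design(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in matrix.columns]
        if missing:
            raise TrainingError(f"feature matrix lacks columns {missing}")
        return self.scaler.transform(matrix[self.selected_features].to_numpy(dtype=float))

    def predict_proba(self, matrix: pd.DataFrame) -> np.ndarray:
        """Posterior probability of walking for each row."""
        z = self._design(matrix)
        walk_col = list(self.svm.classes_).index(1)
        return self.svm.predict_proba(z)[:, walk_col]

    def predict(self, matrix: pd.DataFrame) -> np.ndarray:
        return self.svm.predict(self._design(matrix)).astype(bool)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump({"format_version": self.format_version, "model": self}, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "WalkClassifier":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise TrainingError(
                f"unsupported model format {payload.get('format_version')!r}"
            )
        return payload["model"]


def train_classifier(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    feature_subset: list[str] | None = None,
    C: float = 1.0,
    gamma: float | str = "median",
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    seed: int = 0,
) -> WalkClassifier:
    """Fit the walking SVM on standardized selected features.

    Standardization and the kernel-width heuristic are fit on the training
    data only. Posteriors come from Platt-style sigmoid calibration
    (``SVC(probability=True)``); the fit is deterministic given ``seed``.
    """
    y = np.asarray(labels).astype(bool)
    if not y.any() or y.all():
        raise TrainingError("training data must contain both classes")
    features = list(feature_subset) if feature_subset else list(matrix.columns)
    x = matrix[features].to_numpy(dtype=float)
    scaler = StandardScaler().fit(x)
    z = scaler.transform(x)
    g = median_distance_gamma(z, seed=seed) if gamma == "median" else float(gamma)
    base = SVC(C=C, kernel="rbf", gamma=g, random_state=seed)
    cv = min(5, int(y.sum()), int((~y).sum()))
    svm = CalibratedClassifierCV(base, method="sigmoid", cv=max(2, cv), ensemble=False)
    svm.fit(z, y.astype(int))
    return WalkClassifier(
        scaler=scaler, svm=svm, selected_features=features, prob_threshold=prob_threshold
    )


@dataclass
class LosoResult:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_subject_confusion: dict[str, np.ndarray]
    roc: tuple[np.ndarray, np.ndarray, np.ndarray]  # fpr, tpr, thresholds
    posteriors: np.ndarray
    labels: np.ndarray
    predictions: np.ndarray
    subjects: np.ndarray
    fold_models: dict[str, "WalkClassifier"] = field(default_factory=dict)


def loso_cross_validate(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    subjects: np.ndarray,
    dbi_threshold: float = DEFAULT_DBI_THRESHOLD,
    C: float = 1.0,
    gamma: float | str = "median",
    seed: int = 0,
) -> LosoResult:
    """Leave-one-subject-out validation with in-fold feature selection.

    For every fold, feature selection (DBI < ``dbi_threshold``) and
    standardization are re-fit on the training subjects only; the held-out
    subject's predictions are pooled across folds before computing the
    confusion metrics and ROC.
    """
    y = np.asarray(labels).astype(bool)
    subj = np.asarray(subjects)
    unique_subjects = list(dict.fromkeys(subj.tolist()))
    if len(unique_subjects) < 2:
        raise TrainingError("LOSO needs at least 2 subjects")

    post = np.full(len(y), np.nan)
    pred = np.zeros(len(y), dtype=bool)
    fold_models: dict[str, WalkClassifier] = {}
    for held_out in unique_subjects:
        test = subj == held_out
        train = ~test
        try:
            kept = select_features(matrix.loc[train], y[train], threshold=dbi_threshold)
        except SelectionError:
            # nothing separates the classes in this fold (e.g. permuted
            # labels); fall back to the full feature set
            kept = list(matrix.columns)
        model = train_classifier(
            matrix.loc[train], y[train], feature_subset=kept, C=C, gamma=gamma, seed=seed
        )
        fold_models[str(held_out)] = model
        post[test] = model.predict_proba(matrix.loc[test])
        pred[test] = model.predict(matrix.loc[test])

    tp = int(np.sum(pred & y))
    tn = int(np.sum(~pred & ~y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = float(roc_auc_score(y, post)) if 0 < y.sum() < len(y) else float("nan")
    fpr, tpr, thr = roc_curve(y, post)

    per_subject = {}
    for s in unique_subjects:
        m = subj == s
        per_subject[str(s)] = np.array(
            [
                [int(np.sum(pred[m] & y[m])), int(np.sum(pred[m] & ~y[m]))],
                [int(np.sum(~pred[m] & y[m])), int(np.sum(~pred[m] & ~y[m]))],
            ]
        )
    return LosoResult(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=auc,
        per_subject_confusion=per_subject,
        roc=(fpr, tpr, thr),
        posteriors=post,
        labels=y,
        predictions=pred,
        subjects=subj,
        fold_models=fold_models,
    )


def select_probability_threshold(
    roc: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> float:
    """Threshold whose ROC point is closest (Euclidean) to (FPR, TPR) = (0, 1).

    Ties are broken toward the higher threshold.
    """
    fpr, tpr, thr = (np.asarray(a, dtype=float) for a in roc)
    if fpr.size == 0:
        raise ValueError("empty ROC")
    d2 = fpr**2 + (1.0 - tpr) ** 2
    best = d2 == d2.min()
    return float(thr[best].max())


@dataclass
class WalkingBout:
    """Maximal run of >= 2 consecutive accepted walking windows."""

    window_indices: list[int]
    start: float
    end: float
    posteriors: list[float] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.window_indices)

    @property
    def duration(self) -> float:
        return self.end - self.start


def build_walking_bouts(
    labels: np.ndarray,
    posteriors: np.ndarray,
    windows: list,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    min_windows: int = MIN_BOUT_WINDOWS,
    recording: BilateralRecording | None = None,
    clip_k: int = 3,
    clip_eps: float = 0.01,
) -> tuple[list[WalkingBout], float]:
    """Aggregate accepted windows into bouts; returns (bouts, walking time s).

    A window is accepted iff labelled walking AND its posterior is at least
    ``prob_threshold``. Maximal runs of at least ``min_windows`` accepted
    windows become bouts. When ``recording`` is given, bouts containing a
    clipped segment on any stream are dropped. Total walking time is the
    window length times the number of windows in the returned bouts.
    """
    labels = np.asarray(labels).astype(bool)
    posteriors = np.asarray(posteriors, dtype=float)
    accepted = labels & (posteriors >= prob_threshold)

    bouts: list[WalkingBout] = []
    run: list[int] = []
    for i, ok in enumerate(list(accepted) + [False]):
        if ok:
            run.append(i)
            continue
        if len(run) >= min_windows:
            start = windows[run[0]].start
            end = windows[run[-1]].end
            bout = WalkingBout(
                window_indices=[windows[j].index for j in run],
                start=start,
                end=end,
                posteriors=[float(posteriors[j]) for j in run],
            )
            if recording is None or not recording_is_clipped(
                recording, start, end, k=clip_k, eps_frac=clip_eps
            ):
                bouts.append(bout)
        run = []

    window_s = windows[0].end - windows[0].start if windows else 0.0
    walking_time = window_s * sum(b.n_windows for b in bouts)
    return bouts, walking_time
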