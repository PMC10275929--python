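"""Valence-arousal labels, classification problems, classifiers and evaluation.

IAPS ratings live on a 1-9 scale; subtracting 5 recentres them on [-4, 4] so
the origin is affective neutrality.  The plane is split into Russell's four
quadrants (HAHV, HALV, LALV, LAHV) plus a closed central neutral box of
half-width 1 on both axes (6.25% of the plane).  Four classification problems
are defined over these labels: high/low valence, high/low arousal (both
excluding neutral), the 4-quadrant problem, and the 5-class problem including
neutral.

Classifiers are scikit-learn pipelines behind a single estimator facade:
distance-weighted KNN, cubic and gaussian SVMs (one-vs-one for multi-class)
and LDA, each preceded by z-scoring fitted on the training split only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix, f1_score, precision_recall_fscore_support
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .io import Recording, SelfReport, StimulusEvent
from .features import FEATURE_NAMES

NEUTRAL_HALF_WIDTH = 1.0
QUADRANT_LABELS = ("HAHV", "HALV", "LALV", "LAHV", "N")
ALGORITHMS = ("KNN", "SVM_CUBIC", "SVM_GAUSSIAN", "LDA")


def rescale_rating(raw: float) -> float:
    """Map a 1-9 IAPS/SAM rating onto [-4, 4] (origin = neutral)."""
    if not 1.0 <= raw <= 9.0:
        raise ValueError(f"rating {raw} outside [1, 9]")
    return raw - 5.0


@dataclass(frozen=True)
class AffectPoint:
    """A rescaled (valence, arousal) coordinate in [-4, 4]^2."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        if not (-4 <= self.valence <= 4 and -4 <= self.arousal <= 4):
            raise ValueError(f"point ({self.valence}, {self.arousal}) outside [-4, 4]^2")


def assign_quadrant(point: AffectPoint) -> str:
    """The quadrant label of a rescaled affect point.

    The neutral box is closed (|v| <= 1 and |a| <= 1); outside it, the axis
    boundaries go with non-positive valence/arousal (v > 0 is high valence,
    a > 0 is high arousal).
    """
    v, a = point.valence, point.arousal
    if abs(v) <= NEUTRAL_HALF_WIDTH and abs(a) <= NEUTRAL_HALF_WIDTH:
        return "N"
    if a > 0:
        return "HAHV" if v > 0 else "HALV"
    return "LAHV" if v > 0 else "LALV"


def quadrant_of_raw(valence_raw: float, arousal_raw: float) -> str:
    return assign_quadrant(
        AffectPoint(rescale_rating(valence_raw), rescale_rating(arousal_raw))
    )


EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class Problem:
    """One of the four classification problems on the quadrant labels."""

    id: str
    class_map: dict[str, str]

    @property
    def classes(self) -> list[str]:
        return sorted({c for c in self.class_map.values() if c != EXCLUDED})

    def map_labels(self, quadrants: pd.Series) -> pd.Series:
        return quadrants.map(self.class_map)


PROBLEMS: dict[str, Problem] = {
    "HL_VALENCE": Problem("HL_VALENCE", {
        "HAHV": "high", "LAHV": "high", "HALV": "low", "LALV": "low", "N": EXCLUDED,
    }),
    "HL_AROUSAL": Problem("HL_AROUSAL", {
        "HAHV": "high", "HALV": "high", "LALV": "low", "LAHV": "low", "N": EXCLUDED,
    }),
    "FOUR_CLASS": Problem("FOUR_CLASS", {
        q: q for q in ("HAHV", "HALV", "LALV", "LAHV")
    } | {"N": EXCLUDED}),
    "FIVE_CLASS": Problem("FIVE_CLASS", {q: q for q in QUADRANT_LABELS}),
}


# ---------------------------------------------------------------------------
# self-assessment consistency


def consistency_filter(
    events: list[StimulusEvent], reports: list[SelfReport]
) -> tuple[list[str], list[dict]]:
    """Keep images whose self-assessment is not completely at odds with IAPS.

    An image is dropped only when the self-assessed quadrant is the diagonal
    opposite of the IAPS quadrant (both axes' signs flipped, neither point
    neutral) — single-axis disagreement and neutral self-reports are kept.
    A missing report keeps the image with a logged warning.

    Returns ``(kept_image_ids, exclusion_log)``.
    """
    opposite = {"HAHV": "LALV", "LALV": "HAHV", "HALV": "LAHV", "LAHV": "HALV"}
    by_image = {r.image_id: r for r in reports}
    kept, log = [], []
    for ev in events:
        iaps_q = quadrant_of_raw(ev.iaps_valence_raw, ev.iaps_arousal_raw)
        rep = by_image.get(ev.image_id)
        if rep is None:
            log.append({"image_id": ev.image_id, "action": "kept",
                        "reason": "missing self-report"})
            kept.append(ev.image_id)
            continue
        sam_q = quadrant_of_raw(rep.sam_valence, rep.sam_arousal)
        if opposite.get(iaps_q) == sam_q:
            log.append({"image_id": ev.image_id, "action": "excluded",
                        "iaps_quadrant": iaps_q, "sam_quadrant": sam_q})
        else:
            kept.append(ev.image_id)
    return kept, log


# ---------------------------------------------------------------------------
# leave-one-image-per-class-out split


def loio_split(
    windows: pd.DataFrame, problem: Problem, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hold out all windows of one image per class as the test set.

    ``windows`` must carry ``image_id`` and ``quadrant`` columns; rows whose
    quadrant is excluded by the problem are dropped from both splits.
    """
    labels = problem.map_labels(windows["quadrant"])
    data = windows[labels != EXCLUDED].copy()
    data["label"] = labels[labels != EXCLUDED]
    rng = np.random.default_rng(seed)
    test_images = []
    for cls in problem.classes:
        imgs = sorted(data.loc[data["label"] == cls, "image_id"].unique())
        if len(imgs) < 2:
            raise ValueError(
                f"class {cls!r} has {len(imgs)} image(s); need >= 2 for a LOIO split"
            )
        test_images.append(imgs[rng.integers(len(imgs))])
    is_test = data["image_id"].isin(test_images)
    return data[~is_test].reset_index(drop=True), data[is_test].reset_index(drop=True)


# ---------------------------------------------------------------------------
# classifiers


class WindowClassifier(ClassifierMixin, BaseEstimator):
    """One of the four study classifiers over a feature subset.

    Parameters
    ----------
    algorithm : {"KNN", "SVM_CUBIC", "SVM_GAUSSIAN", "LDA"}
    feature_subset : list of str or None
        Names of the features the model sees; ``None`` means all 23.
    n_neighbors : int, default=5
        K for the KNN vote (distance-weighted).
    C : float, default=1.0
        SVM box constraint.

    Features are z-scored with statistics fitted on the training data; the
    gaussian kernel width is ``1 / n_features`` after z-scoring.  Multi-class
    SVMs use one-vs-one decision.
    """

    def __init__(self, algorithm: str = "KNN", feature_subset: list[str] | None = None,
                 n_neighbors: int = 5, C: float = 1.0):
        self.algorithm = algorithm
        self.feature_subset = feature_subset
        self.n_neighbors = n_neighbors
        self.C = C

    def _make_estimator(self):
        if self.algorithm == "KNN":
            # exhaustive search: per-query cost scales with n x n_features,
            # so reducing the feature set reduces estimation time
            clf = KNeighborsClassifier(n_neighbors=self.n_neighbors, weights="distance",
                                       algorithm="brute")
        elif self.algorithm == "SVM_CUBIC":
            clf = SVC(kernel="poly", degree=3, C=self.C, gamma="auto",
                      decision_function_shape="ovo")
        elif self.algorithm == "SVM_GAUSSIAN":
            clf = SVC(kernel="rbf", C=self.C, gamma="auto",
                      decision_function_shape="ovo")
        elif self.algorithm == "LDA":
            clf = LinearDiscriminantAnalysis()
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    def _matrix(self, X) -> np.ndarray:
        names = list(self.feature_subset) if self.feature_subset else list(FEATURE_NAMES)
        if isinstance(X, pd.DataFrame):
            missing = [f for f in names if f not in X.columns]
            if missing:
                raise KeyError(f"feature(s) missing from input: {missing}")
            return X[names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X

    def fit(self, X, y):
        y = np.asarray(y)
        M = self._matrix(X)
        if len(M) == 0:
            raise ValueError("empty training set")
        if self.algorithm == "KNN":
            smallest = min(np.bincount(np.unique(y, return_inverse=True)[1]))
            if smallest < self.n_neighbors:
                raise ValueError(
                    f"smallest training class has {smallest} members; "
                    f"KNN needs at least K={self.n_neighbors}"
                )
        self.pipeline_ = self._make_estimator().fit(M, y)
        self.classes_ = self.pipeline_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.pipeline_.predict(self._matrix(X))


def fit(algorithm: str, train: pd.DataFrame, feature_subset=None, **kw) -> WindowClassifier:
    """Train one study classifier on a labeled window table."""
    return WindowClassifier(algorithm, feature_subset=feature_subset, **kw).fit(
        train, train["label"].to_numpy()
    )


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Per-window evaluation of one (problem, algorithm, feature-set) cell."""

    problem: str
    algorithm: str
    feature_set: str
    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    f_score: float
    per_class: pd.DataFrame
    estimation_times_ms: list[float] = field(default_factory=list)

    @property
    def mean_estimation_time_ms(self) -> float:
        return float(np.mean(self.estimation_times_ms)) if self.estimation_times_ms else float("nan")


def evaluate(
    model: WindowClassifier,
    test: pd.DataFrame,
    problem_id: str = "",
    feature_set: str = "all",
) -> EvalReport:
    """Confusion matrix, accuracy and macro F-score on per-window predictions."""
    if len(test) == 0:
        raise ValueError("empty test set")
    y_true = test["label"].to_numpy()
    y_pred = model.predict(test)
    classes = sorted(set(model.classes_) | set(y_true))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    accuracy = float(np.trace(cm) / cm.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    macro_f = float(f1_score(y_true, y_pred, labels=classes, average="macro",
                             zero_division=0))
    per_class = pd.DataFrame(
        {"class": classes, "precision": prec, "recall": rec, "f1": f1}
    )
    return EvalReport(
        problem=problem_id, algorithm=model.algorithm, feature_set=feature_set,
        classes=classes, confusion=cm, accuracy=accuracy, f_score=macro_f,
        per_class=per_class,
    )


def measure_estimation_time(model: WindowClassifier, process_window) -> float:
    """Wall-clock milliseconds for one raw window through the full chain.

    ``process_window`` is a zero-argument callable that filters the raw
    channel slices and returns the 23-feature row (a DataFrame of one row);
    the measured span covers filtering + feature extraction + subset
    selection + prediction, mirroring the latency a live estimator would pay.
    """
    t0 = time.perf_counter()
    row = process_window()
    model.predict(row)
    return (time.perf_counter() - t0) * 1000.0


# ---------------------------------------------------------------------------
# statistical comparison


BONFERRONI_P = 0.05
BONFERRONI_N_COMPARISONS = 6


def bonferroni_threshold(p: float = BONFERRONI_P, n_c: int = BONFERRONI_N_COMPARISONS) -> float:
    """Corrected pairwise significance threshold p_m = p / n_c."""
    return p / n_c


def compare_models(accuracies: dict[str, list[float]]) -> pd.DataFrame:
    """One-way ANOVA on per-participant accuracies for every algorithm pair.

    Returns a table with F, p and a Bonferroni-corrected significance flag
    (p <= 0.05/6, reported to 3 decimals as 0.008).
    """
    names = sorted(accuracies)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    p_m = bonferroni_threshold()
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ga, gb = np.asarray(accuracies[a]), np.asarray(accuracies[b])
            if len(ga) < 2 or len(gb) < 2:
                raise ValueError("each group needs at least 2 values")
            if np.ptp(ga) == 0 and np.ptp(gb) == 0 and ga.mean() == gb.mean():
                F, p = 0.0, 1.0
            else:
                F, p = sstats.f_oneway(ga, gb)
                if np.isnan(F):
                    F, p = 0.0, 1.0
            rows.append({"group_a": a, "group_b": b, "F": float(F), "p": float(p),
                         "significant": bool(p <= p_m)})
    out = pd.DataFrame(rows)
    out.attrs["p_threshold"] = p_m
    return out
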