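"""Incremental feature selection around a one-vs-rest SVM.

Growing prefixes of the MCFS feature ranking are scored by stratified
10-fold cross-validation of a one-vs-rest SVM (RBF kernel by default,
features z-scored on each training fold).  A two-stage scan — a coarse step
(default 10) over the whole list, then step 1 inside an interval around the
coarse optimum — finds the optimal feature set, the prefix with the highest
multi-class MCC (smallest prefix on ties).  A random-subset test puts the
optimal subset's MCC in the context of equally sized random gene subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .metrics import PerformanceReport, confusion_from_predictions

logger = logging.getLogger(__name__)

# fold-reduction pairs already warned about (avoids one line per CV call)
_warned_fold_reductions: set[tuple[int, int]] = set()

__all__ = [
    "ClassifierConfig",
    "CVConfig",
    "IFSCurve",
    "OptimalFeatureSet",
    "cv_evaluate",
    "ifs_stage",
    "two_stage_ifs",
    "random_subset_significance",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """One-vs-rest SVM settings.

    Defaults: RBF (Gaussian) kernel, C = 1, gamma = 1 / (d * Var(X))
    (scikit-learn's 'scale').  Class scores are Platt-style sigmoids of the
    per-class decision values; the class with the highest score wins, ties
    broken by class order.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"

    def validate(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be 'rbf' or 'linear', got {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass(frozen=True)
class CVConfig:
    """Stratified k-fold settings; repeats pool confusion counts."""

    folds: int = 10
    repeats: int = 1
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class IFSCurve:
    """Performance along increasing feature-prefix sizes."""

    points: tuple[tuple[int, PerformanceReport], ...]

    def __post_init__(self) -> None:
        sizes = [k for k, _ in self.points]
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("prefix sizes must be strictly increasing")

    def sizes(self) -> list[int]:
        return [k for k, _ in self.points]

    def mccs(self) -> list[float]:
        return [r.mcc for _, r in self.points]

    def best(self) -> tuple[int, PerformanceReport]:
        """Highest-MCC point; the smallest prefix wins ties."""
        return max(self.points, key=lambda kr: (kr[1].mcc, -kr[0]))


@dataclass(frozen=True)
class OptimalFeatureSet:
    """Best feature-list prefix found by the two-stage scan."""

    feature_indices: tuple[int, ...]
    report: PerformanceReport
    size: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "size", len(self.feature_indices))


def _ovr_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    clf: ClassifierConfig,
    n_classes: int,
) -> np.ndarray:
    """Fit one-vs-rest SVMs and return argmax-score class indices.

    The per-class probability score is a fixed sigmoid of the decision value;
    argmax over classes is therefore the argmax of the decision values, with
    ties resolved toward the lower class index.
    """
    model = OneVsRestClassifier(
        SVC(kernel=clf.kernel, C=clf.C, gamma=clf.gamma, random_state=0)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class folds inside OvR
        model.fit(X_train, y_train)
    scores = model.decision_function(X_test)
    if scores.ndim == 1:  # only two classes present in training data
        scores = np.column_stack([-scores, scores])
    probs = 1.0 / (1.0 + np.exp(-scores))
    present = np.asarray(model.classes_, dtype=int)
    pred_local = np.argmax(probs, axis=1)
    return present[pred_local]


def cv_evaluate(
    ds: LabeledDataset,
    feature_subset,
    clf: ClassifierConfig | None = None,
    cv: CVConfig | None = None,
) -> PerformanceReport:
    """Score a gene subset by pooled out-of-fold SVM predictions.

    Features are standardized with statistics of each training fold only.
    Confusion counts are summed over folds and over ``cv.repeats`` repeats
    (total count = repeats * n).  Folds are reduced with a warning when the
    smallest class has fewer samples than ``cv.folds``.
    """
    clf = clf or ClassifierConfig()
    cv = cv or CVConfig()
    clf.validate()
    cv.validate()
    feature_subset = np.asarray(feature_subset, dtype=int)
    if feature_subset.size == 0:
        raise ValueError("feature subset must be non-empty")
    y = ds.y
    C = ds.n_classes
    counts = np.bincount(y, minlength=C)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for CV")
    folds = min(cv.folds, int(counts.min()))
    if folds < cv.folds and (cv.folds, folds) not in _warned_fold_reductions:
        _warned_fold_reductions.add((cv.folds, folds))
        logger.warning("cv_evaluate: folds reduced from %d to %d", cv.folds, folds)
    X = ds.X[:, feature_subset]
    conf = np.zeros((C, C), dtype=int)
    for rep in range(cv.repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv.seed + rep)
        for train_idx, test_idx in skf.split(X, y):
            scaler = StandardScaler().fit(X[train_idx])
            X_train = scaler.transform(X[train_idx])
            X_test = scaler.transform(X[test_idx])
            pred = _ovr_predict(X_train, y[train_idx], X_test, clf, C)
            conf += confusion_from_predictions(y[test_idx], pred, C)
    return PerformanceReport(list(ds.classes), conf)


def ifs_stage(
    ds: LabeledDataset,
    feature_list: np.ndarray,
    start: int,
    stop: int,
    step: int,
    clf: ClassifierConfig | None = None,
    cv: CVConfig | None = None,
) -> IFSCurve:
    """Evaluate ranked-list prefixes of sizes start, start+step, ... <= stop."""
    feature_list = np.asarray(feature_list, dtype=int)
    N = feature_list.size
    if not (1 <= start <= stop <= N):
        raise ValueError(f"need 1 <= start <= stop <= {N}, got [{start}, {stop}]")
    if step < 1:
        raise ValueError("step must be >= 1")
    points = []
    for k in range(start, stop + 1, step):
        report = cv_evaluate(ds, feature_list[:k], clf, cv)
        points.append((k, report))
    return IFSCurve(tuple(points))


def two_stage_ifs(
    ds: LabeledDataset,
    feature_list: np.ndarray,
    clf: ClassifierConfig | None = None,
    cv: CVConfig | None = None,
    coarse_step: int = 10,
    interval_halfwidth_steps: int = 10,
) -> tuple[OptimalFeatureSet, IFSCurve, IFSCurve]:
    """Coarse scan of the whole ranking, then a step-1 scan around its best.

    Stage 1 walks prefixes ``coarse_step, 2*coarse_step, ... <= N``; stage 2
    walks every size in ``[b - h*coarse_step, b + h*coarse_step]`` (clipped
    to [1, N]) around the coarse optimum ``b``.  The optimal feature set is
    the stage-2 prefix with the highest MCC, smallest size on ties; because
    the stage-1 optimum lies inside the stage-2 scan, the final MCC is never
    below the stage-1 best.
    """
    feature_list = np.asarray(feature_list, dtype=int)
    N = feature_list.size
    if coarse_step < 1:
        raise ValueError("coarse_step must be >= 1")
    if N < coarse_step:
        stage1 = ifs_stage(ds, feature_list, N, N, 1, clf, cv)
    else:
        stage1 = ifs_stage(ds, feature_list, coarse_step, N, coarse_step, clf, cv)
    b, _ = stage1.best()
    half = interval_halfwidth_steps * coarse_step
    lo, hi = max(1, b - half), min(N, b + half)
    stage2 = ifs_stage(ds, feature_list, lo, hi, 1, clf, cv)
    size, report = stage2.best()
    optimal = OptimalFeatureSet(tuple(int(i) for i in feature_list[:size]), report)
    return optimal, stage1, stage2


def random_subset_significance(
    ds: LabeledDataset,
    subset_size: int,
    observed_mcc: float,
    clf: ClassifierConfig | None = None,
    cv: CVConfig | None = None,
    n_subsets: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Compare an observed MCC against equally sized random gene subsets.

    Draws ``n_subsets`` uniform random subsets of ``subset_size`` genes,
    scores each with :func:`cv_evaluate`, and returns the add-one empirical
    p-value ``(1 + #{random >= observed}) / (n_subsets + 1)``, the random MCC
    distribution, and its 95th percentile (the p < 0.05 significance line).
    """
    if subset_size < 1 or subset_size > ds.n_genes:
        raise ValueError("subset_size must be in [1, N]")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    rng = np.random.default_rng(seed)
    mccs = np.empty(n_subsets)
    for i in range(n_subsets):
        subset = rng.choice(ds.n_genes, size=subset_size, replace=False)
        mccs[i] = cv_evaluate(ds, subset, clf, cv).mcc
    p = (1 + int(np.count_nonzero(mccs >= observed_mcc))) / (n_subsets + 1)
    threshold = float(np.percentile(mccs, 95))
    return p, mccs, threshold
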