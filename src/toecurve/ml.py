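"""Classification of raw force-time curves by age group or sex.

The classifiers operate directly on the raw curve — the 500 force
samples of a trial, in newtons — rather than on the extracted
parameters. Three small-sample-friendly model families are supported:
k-nearest neighbors, a support-vector machine (RBF kernel), and a
random forest. Evaluation follows two designs: a single stratified
train/validation/test split, and stratified k-fold cross-validation
(k of 3 or 5). Accuracy is reported in percent; discrimination as the
rank-based AUC (the Mann-Whitney statistic normalized by n1*n0, with
midranks for ties), computed here and cross-checkable against any ROC
implementation.

The default split is 45/25/30 train/validation/test. With cohorts of
~31 subjects that yields a validation set of 8 and a test set of 9,
so split accuracies move in coarse steps (12.5 and ~11.1 percentage
points). Feature columns are standardized with statistics fit on the
training portion only (k-NN and SVM are scale-sensitive); this is
toggleable. A warning is emitted when the minority class falls below
35% of the sample — at 9 males vs 22 females, AUC estimates from a
9-to-10-subject test set are fragile, and reports should be read
accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import to_newtons
from .io import ForceTrial, SubjectRecord

__all__ = [
    "CurveDataset",
    "ModelSpec",
    "SplitConfig",
    "ClassifierReport",
    "build_dataset",
    "evaluate_split",
    "evaluate_cv",
    "auc_score",
]

TARGETS = {"age": "age_group", "sex": "sex"}

#: Positive class per target (the first-listed level of each factor).
POSITIVE_CLASS = {"age": "older", "sex": "male"}

IMBALANCE_WARN_FRACTION = 0.35


@dataclass(frozen=True)
class CurveDataset:
    """n trials x m force samples, with binary labels for one target."""

    X: np.ndarray
    y: np.ndarray  # 0/1, 1 = positive class
    subject_ids: tuple[str, ...]
    target: str
    positive_class: str
    negative_class: str

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label length does not match number of rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite values in the curve matrix")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class ModelSpec:
    """One of the three supported model families with its hyperparameters."""

    kind: str  # "knn" | "svm" | "rf"
    k: int = 5  # knn neighbors
    kernel: str = "rbf"  # svm kernel
    n_trees: int = 100  # rf size

    @property
    def name(self) -> str:
        if self.kind == "knn":
            return f"knn(k={self.k})"
        if self.kind == "svm":
            return f"svm({self.kernel})"
        return f"rf(n_trees={self.n_trees})"


@dataclass(frozen=True)
class SplitConfig:
    train: float = 0.45
    validation: float = 0.25
    test: float = 0.30

    def __post_init__(self) -> None:
        total = self.train + self.validation + self.test
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class ClassifierReport:
    """Validation/test accuracy (%) and AUC for one model and target."""

    model: str
    target: str
    validation_accuracy: float
    test_accuracy: float | None
    auc: float
    seed: int
    fold_count: int = 1
    fold_accuracies: tuple[float, ...] = field(default=())
    fold_accuracy_sd: float | None = None
    n_train: int | None = None
    n_validation: int | None = None
    n_test: int | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "target": self.target,
            "validation_accuracy_pct": self.validation_accuracy,
            "test_accuracy_pct": self.test_accuracy,
            "auc": self.auc,
            "seed": self.seed,
            "fold_count": self.fold_count,
        }
        if self.fold_accuracies:
            d["fold_accuracies_pct"] = list(self.fold_accuracies)
            d["fold_accuracy_sd"] = self.fold_accuracy_sd
        return d


def build_dataset(
    trials: Sequence[ForceTrial],
    subjects: Sequence[SubjectRecord],
    target: str,
) -> CurveDataset:
    """Assemble the raw-curve matrix with labels for ``target``.

    Trials are converted to newtons, ordered by subject id, and must
    all have the same (imputed) length. ``target`` is ``"age"`` or
    ``"sex"``.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {sorted(TARGETS)}")
    if not trials:
        raise ValueError("no trials")
    by_id = {s.subject_id: s for s in subjects}
    ordered = sorted(trials, key=lambda t: t.subject_id)
    lengths = {t.n_samples for t in ordered}
    if len(lengths) != 1:
        raise ValueError(f"trials have unequal lengths {sorted(lengths)}; "
                         "impute at ingestion first")
    attr = TARGETS[target]
    pos = POSITIVE_CLASS[target]
    labels, neg_classes = [], set()
    for t in ordered:
        if t.subject_id not in by_id:
            raise ValueError(f"unlabeled subject {t.subject_id!r}")
        value = getattr(by_id[t.subject_id], attr)
        labels.append(1 if value == pos else 0)
        if value != pos:
            neg_classes.add(value)
    if len(neg_classes) > 1:
        raise ValueError(f"non-binary label set for {target}: {neg_classes} + {pos}")
    X = np.vstack([to_newtons(t).force for t in ordered])
    y = np.asarray(labels)
    minority = min(y.mean(), 1 - y.mean())
    if 0 < minority < IMBALANCE_WARN_FRACTION:
        warnings.warn(
            f"class imbalance for target {target!r}: minority fraction "
            f"{minority:.2f} < {IMBALANCE_WARN_FRACTION}; accuracy and AUC "
            "estimates will be fragile",
            stacklevel=2,
        )
    return CurveDataset(
        X=X, y=y, subject_ids=tuple(t.subject_id for t in ordered),
        target=target, positive_class=pos,
        negative_class=neg_classes.pop() if neg_classes else "",
    )


def _make_estimator(spec: ModelSpec, standardize: bool, seed: int) -> Pipeline:
    if spec.kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=spec.k)
    elif spec.kind == "svm":
        clf = SVC(kernel=spec.kernel, random_state=seed)
    elif spec.kind == "rf":
        clf = RandomForestClassifier(n_estimators=spec.n_trees, random_state=seed)
    else:
        raise ValueError(f"unknown model kind {spec.kind!r}")
    steps = ([("scale", StandardScaler())] if standardize else []) + [("clf", clf)]
    return Pipeline(steps)


def _scores(est: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous positive-class score: neighbor/vote fraction for kNN
    and RF, decision-function value for the SVM."""
    clf = est.named_steps["clf"]
    if isinstance(clf, SVC):
        return est.decision_function(X)
    return est.predict_proba(X)[:, 1]


def auc_score(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC: P(score of a positive > score of a negative),
    counting ties as 1/2 (midranks); equals the normalized Mann-Whitney
    U statistic."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have the same length")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)  # midranks for ties
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate_split(
    dataset: CurveDataset,
    spec: ModelSpec,
    seed: int,
    split: SplitConfig = SplitConfig(),
    *,
    standardize: bool = True,
) -> ClassifierReport:
    """Fit on a stratified train split; report validation and test
    accuracy (%) and test AUC. Deterministic given ``seed``."""
    X, y = dataset.X, dataset.y
    try:
        X_rest, X_test, y_rest, y_test = train_test_split(
            X, y, test_size=split.test, stratify=y, random_state=seed,
        )
        val_frac = split.validation / (split.train + split.validation)
        X_train, X_val, y_train, y_val = train_test_split(
            X_rest, y_rest, test_size=val_frac, stratify=y_rest, random_state=seed,
        )
    except ValueError as err:
        raise ValueError(
            "a split stratum lost a class; try a different seed or larger "
            f"fractions ({err})"
        ) from err
    for part, name in ((y_train, "train"), (y_val, "validation"), (y_test, "test")):
        if len(np.unique(part)) < 2:
            raise ValueError(
                f"{name} stratum holds a single class; try a different seed "
                "or different split fractions"
            )
    est = _make_estimator(spec, standardize, seed)
    est.fit(X_train, y_train)
    val_acc = 100.0 * float(np.mean(est.predict(X_val) == y_val))
    test_acc = 100.0 * float(np.mean(est.predict(X_test) == y_test))
    auc = auc_score(y_test, _scores(est, X_test))
    return ClassifierReport(
        model=spec.name, target=dataset.target,
        validation_accuracy=val_acc, test_accuracy=test_acc, auc=auc,
        seed=seed, fold_count=1,
        n_train=len(y_train), n_validation=len(y_val), n_test=len(y_test),
    )


def evaluate_cv(
    dataset: CurveDataset,
    spec: ModelSpec,
    k_folds: int,
    seed: int,
    *,
    standardize: bool = True,
) -> ClassifierReport:
    """Stratified k-fold cross-validation (k in {3, 5}): per-fold
    accuracy (%), their mean and SD, and the AUC pooled over held-out
    scores."""
    if k_folds not in (3, 5):
        raise ValueError("k_folds must be 3 or 5")
    y = dataset.y
    if min(np.sum(y == 1), np.sum(y == 0)) < k_folds:
        raise ValueError(
            f"minority class too small for stratified {k_folds}-fold CV"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_accs: list[float] = []
    pooled_scores = np.empty(len(y))
    for train_idx, test_idx in skf.split(dataset.X, y):
        est = _make_estimator(spec, standardize, seed)
        est.fit(dataset.X[train_idx], y[train_idx])
        pred = est.predict(dataset.X[test_idx])
        fold_accs.append(100.0 * float(np.mean(pred == y[test_idx])))
        pooled_scores[test_idx] = _scores(est, dataset.X[test_idx])
    auc = auc_score(y, pooled_scores)
    return ClassifierReport(
        model=spec.name, target=dataset.target,
        validation_accuracy=float(np.mean(fold_accs)), test_accuracy=None,
        auc=auc, seed=seed, fold_count=k_folds,
        fold_accuracies=tuple(fold_accs),
        fold_accuracy_sd=float(np.std(fold_accs, ddof=1)),
    )


def reports_frame(reports: Sequence[ClassifierReport]) -> pd.DataFrame:
    """Stack reports into the summary-table layout (model, target,
    validation accuracy %, test accuracy %, AUC)."""
    return pd.DataFrame([r.to_dict() for r in reports])
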