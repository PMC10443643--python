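"""Subject-wise classification of condition from pulse-morphology features.

Reproduces the evaluation protocol of the source analysis: keep only the
810 nm distal-detector rows, binarize the condition labels (Trendelenburg vs
pooled supine for tilting; any Valsalva window vs baseline), randomly
undersample the majority class *per subject* to balance the classes, min-max
scale each feature to [0, 1] over the whole prepared dataset, and evaluate a
ridge-stabilized logistic regression (intercept + 9 coefficients, 0.5
threshold) under

* leave-one-subject-out validation (one fold per volunteer), and
* row-level 10-fold cross-validation with a seeded shuffle (subjects may span
  folds, so subject structure leaks across folds by design — reported, not
  hidden).

Scaling on the full dataset precedes splitting, matching the described
pre-processing order; ``strict_scaling=True`` refits the scaler on each
training fold instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .features import FEATURE_NAMES

POSITIVE_LABELS = {"tilting": ("trendelenburg",), "valsalva": ("valsalva1", "valsalva2", "valsalva3")}
NEGATIVE_LABELS = {"tilting": ("supine1", "supine2"), "valsalva": ("baseline",)}


@dataclass
class BalancedDataset:
    """Balanced, scaled feature matrix with per-row subject ids."""

    X: np.ndarray          # scaled to [0, 1] over the whole dataset
    X_raw: np.ndarray      # unscaled copy for strict per-fold scaling
    y: np.ndarray          # 0/1 labels
    subjects: np.ndarray
    intervention: str
    seed: int
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(set(self.subjects))


@dataclass(frozen=True)
class FoldMetrics:
    fold: str
    n_test: int
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class ClassificationReport:
    """Per-fold and averaged sensitivity/specificity/accuracy, in percent."""

    scheme: str
    folds: list[FoldMetrics] = field(default_factory=list)

    def _mean(self, attr: str) -> float:
        vals = np.array([getattr(f, attr) for f in self.folds])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(np.nanmean(vals))

    @property
    def mean_sensitivity(self) -> float:
        return self._mean("sensitivity")

    @property
    def mean_specificity(self) -> float:
        return self._mean("specificity")

    @property
    def mean_accuracy(self) -> float:
        return self._mean("accuracy")

    def n_excluded(self, metric: str) -> int:
        return int(sum(np.isnan(getattr(f, metric)) for f in self.folds))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "fold": [f.fold for f in self.folds],
                "n_test": [f.n_test for f in self.folds],
                "sensitivity_pct": [f.sensitivity for f in self.folds],
                "specificity_pct": [f.specificity for f in self.folds],
                "accuracy_pct": [f.accuracy for f in self.folds],
            }
        )
        df.insert(0, "scheme", self.scheme)
        return df

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scheme": [self.scheme],
                "n_folds": [len(self.folds)],
                "sensitivity_pct": [self.mean_sensitivity],
                "specificity_pct": [self.mean_specificity],
                "accuracy_pct": [self.mean_accuracy],
            }
        )


def prepare_dataset(
    table: pd.DataFrame,
    intervention: str,
    seed: int,
    detector: str = "distal",
    wavelength_nm: int = 810,
) -> BalancedDataset:
    """Filter, binarize, balance per subject and min-max scale the table."""
    df = table[
        (table["intervention"] == intervention)
        & (table["detector"] == detector)
        & (table["wavelength_nm"] == wavelength_nm)
    ].copy()
    pos, neg = POSITIVE_LABELS[intervention], NEGATIVE_LABELS[intervention]
    df = df[df["condition"].isin(pos + neg)]
    df["label"] = df["condition"].isin(pos).astype(int)

    rng = np.random.default_rng(seed)
    kept = []
    for subject in sorted(df["subject"].unique()):
        sub = df[df["subject"] == subject]
        n_pos = int((sub["label"] == 1).sum())
        n_neg = int((sub["label"] == 0).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                f"subject {subject!r} lacks a class for {intervention}; dropped",
                stacklevel=2,
            )
            continue
        n_keep = min(n_pos, n_neg)
        for label in (0, 1):
            idx = sub.index[sub["label"] == label].to_numpy()
            if len(idx) > n_keep:
                idx = np.sort(rng.choice(idx, size=n_keep, replace=False))
            kept.append(sub.loc[idx])
    if not kept:
        raise ValueError("no subjects with both classes present")
    balanced = pd.concat(kept)
    if balanced["subject"].nunique() < 2:
        raise ValueError("fewer than 2 subjects survive balancing")

    X_raw = balanced[list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = minmax_scale(X_raw)
    return BalancedDataset(
        X=X,
        X_raw=X_raw,
        y=balanced["label"].to_numpy(dtype=int),
        subjects=balanced["subject"].to_numpy(dtype=object),
        intervention=intervention,
        seed=seed,
    )


def minmax_scale(X: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Columnwise (x - min) / (max - min); constant columns map to 0."""
    ref = X if ref is None else ref
    lo = ref.min(axis=0)
    span = ref.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    return (X - lo) / span


def fit_predict_logistic(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-stabilized maximum-likelihood logistic regression, 0.5 threshold.

    Returns ``(predicted labels, positive-class probabilities)``.
    """
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000)  # l2 by default
    clf.fit(X_train, y_train)
    prob = clf.predict_proba(X_test)[:, 1]
    return (prob >= 0.5).astype(int), prob


def compute_metrics(predicted: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %); NaN when a class is absent."""
    predicted = np.asarray(predicted, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum((predicted == 1) & (truth == 1)))
    tn = int(np.sum((predicted == 0) & (truth == 0)))
    fp = int(np.sum((predicted == 1) & (truth == 0)))
    fn = int(np.sum((predicted == 0) & (truth == 1)))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else np.nan
    acc = 100.0 * (tp + tn) / len(truth) if len(truth) else np.nan
    return sens, spec, acc


def _evaluate_fold(ds: BalancedDataset, train_idx, test_idx, strict_scaling: bool):
    if strict_scaling:
        X_train = minmax_scale(ds.X_raw[train_idx])
        X_test = minmax_scale(ds.X_raw[test_idx], ref=ds.X_raw[train_idx])
    else:
        X_train, X_test = ds.X[train_idx], ds.X[test_idx]
    pred, _ = fit_predict_logistic(X_train, ds.y[train_idx], X_test)
    return compute_metrics(pred, ds.y[test_idx])


def loso_validate(ds: BalancedDataset, strict_scaling: bool = False) -> ClassificationReport:
    """Leave-one-subject-out: one fold per volunteer, train on all others.

    Folds whose held-out subject lacks a class report NaN for the affected
    metric; NaNs are excluded from the averages (see ``n_excluded``).
    """
    subjects = ds.subject_ids
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    report = ClassificationReport(scheme="leave-one-subject-out")
    idx = np.arange(ds.n)
    for subject in subjects:
        test_idx = idx[ds.subjects == subject]
        train_idx = idx[ds.subjects != subject]
        sens, spec, acc = _evaluate_fold(ds, train_idx, test_idx, strict_scaling)
        report.folds.append(FoldMetrics(str(subject), len(test_idx), sens, spec, acc))
    return report


def kfold_validate(
    ds: BalancedDataset, k: int = 10, seed: int = 0, strict_scaling: bool = False
) -> ClassificationReport:
    """Row-level k-fold CV over a seeded shuffle of the whole dataset."""
    if ds.n < k:
        raise ValueError(f"need at least k={k} rows, got {ds.n}")
    report = ClassificationReport(scheme=f"kfold{k}")
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for i, (train_idx, test_idx) in enumerate(splitter.split(np.arange(ds.n))):
        sens, spec, acc = _evaluate_fold(ds, train_idx, test_idx, strict_scaling)
        report.folds.append(FoldMetrics(f"fold{i}", len(test_idx), sens, spec, acc))
    return report
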