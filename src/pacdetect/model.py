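"""Random-forest training and patient-wise cross-validated evaluation.

Folds are assigned at the patient level, balanced on per-patient S-beat
counts by a greedy longest-processing-time heuristic.  Each fold's
feature transform and per-class training cap are fitted on the nine
training folds only; predictions are pooled for beat-wise metrics and
summarized per patient (median + IQR) for patient-wise metrics.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTransform

__all__ = [
    "RFConfig",
    "FoldPlan",
    "CVResult",
    "derive_seed",
    "make_folds",
    "cap_training",
    "train_rf",
    "confusion_counts",
    "metrics_from_confusion",
    "patientwise_metrics",
    "cross_validate",
    "feature_importance",
]

MULTICLASS_LABELS = ("N", "S", "V")
BINARY_LABELS = ("S", "O")
DEFAULT_SEED = 20210616
TRAIN_CAP_PER_CLASS = 10_000


def derive_seed(master: int, stage: str) -> int:
    """Stable per-stage seed from one master seed (documented fan-out)."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters (defaults are the tuned winners)."""

    n_estimators: int = 500
    min_samples_split: int = 10
    min_samples_leaf: int = 2
    max_depth: int = 20
    bootstrap_replacement: bool = False
    seed: int = DEFAULT_SEED


@dataclass(frozen=True)
class FoldPlan:
    """Patient-to-fold assignment with per-fold S totals."""

    k: int
    assignment: Dict[str, int]
    fold_s_counts: Tuple[int, ...]
    s_spread_tol: float = 0.20

    def patients_in_fold(self, fold: int) -> List[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)

    def relative_s_spread(self) -> float:
        counts = np.asarray(self.fold_s_counts, dtype=float)
        mean = counts.mean()
        if mean == 0:
            return 0.0
        return float((counts.max() - counts.min()) / mean)

    def validate(self) -> None:
        folds = set(self.assignment.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold ids out of range")
        spread = self.relative_s_spread()
        if spread > self.s_spread_tol:
            warnings.warn(
                f"fold S-proportion spread {spread:.2f} exceeds tolerance "
                f"{self.s_spread_tol:.2f}",
                stacklevel=2,
            )


def make_folds(
    s_counts: Mapping[str, int],
    k: int = 10,
    seed: int = DEFAULT_SEED,
    s_spread_tol: float = 0.20,
) -> FoldPlan:
    """Greedy S-balanced patient partition into ``k`` folds.

    Patients are shuffled (seeded, fixing tie order) then stably sorted
    by S count descending; each is assigned to the fold with the lowest
    running S total, ties broken by fewest patients then lowest fold id.
    """
    patients = list(s_counts)
    if len(patients) < k:
        raise ValueError(f"{len(patients)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = [patients[j] for j in rng.permutation(len(patients))]
    order.sort(key=lambda p: -s_counts[p])  # stable: shuffled tie order kept
    fold_s = [0] * k
    fold_n = [0] * k
    assignment: Dict[str, int] = {}
    for p in order:
        fold = min(range(k), key=lambda f: (fold_s[f], fold_n[f], f))
        assignment[p] = fold
        fold_s[fold] += int(s_counts[p])
        fold_n[fold] += 1
    plan = FoldPlan(k, assignment, tuple(fold_s), s_spread_tol)
    plan.validate()
    return plan


def cap_training(
    train: pd.DataFrame,
    cap: int = TRAIN_CAP_PER_CLASS,
    seed: int = DEFAULT_SEED,
    label_col: str = "label",
) -> pd.DataFrame:
    """Per-class uniform subsample (without replacement) above ``cap``."""
    rng = np.random.default_rng(seed)
    pieces = []
    for label, group in train.groupby(label_col, sort=True):
        if len(group) > cap:
            idx = rng.choice(len(group), size=cap, replace=False)
            group = group.iloc[np.sort(idx)]
        pieces.append(group)
    return pd.concat(pieces).sort_index()


def _as_mode_labels(labels: Sequence[str], mode: str) -> np.ndarray:
    y = np.asarray(labels, dtype=object)
    if mode == "binary":
        return np.where(y == "S", "S", "O")
    if mode == "multiclass":
        return y.astype(str)
    raise ValueError(f"unknown mode {mode!r}")


def train_rf(
    X: np.ndarray,
    labels: Sequence[str],
    cfg: RFConfig | None = None,
    mode: str = "multiclass",
) -> RandomForestClassifier:
    """Fit the random forest; binary mode relabels N/V as 'O'."""
    cfg = cfg or RFConfig()
    y = _as_mode_labels(labels, mode)
    if len(set(y)) < 2:
        raise ValueError("training labels are degenerate (single class)")
    clf = RandomForestClassifier(
        n_estimators=cfg.n_estimators,
        min_samples_split=cfg.min_samples_split,
        min_samples_leaf=cfg.min_samples_leaf,
        max_depth=cfg.max_depth,
        bootstrap=cfg.bootstrap_replacement,
        random_state=cfg.seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(X, dtype=float), y)
    return clf


def confusion_counts(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Sequence[str]
) -> np.ndarray:
    """Row = true class, column = predicted class, integer counts."""
    index = {c: j for j, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray, classes: Sequence[str]) -> Dict[str, Dict[str, float]]:
    """One-vs-rest accuracy/Se/Sp/PPV/NPV in percent, per class.

    Undefined ratios (zero denominators) are NaN.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    out: Dict[str, Dict[str, float]] = {}
    for j, c in enumerate(classes):
        tp = cm[j, j]
        fn = cm[j].sum() - tp
        fp = cm[:, j].sum() - tp
        tn = total - tp - fn - fp

        def ratio(num, den):
            return float(100.0 * num / den) if den > 0 else float("nan")

        out[c] = {
            "accuracy": ratio(tp + tn, total),
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn),
        }
    return out


def row_normalized_percent(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(sums > 0, 100.0 * cm / sums, 0.0)


def patientwise_metrics(
    predictions: pd.DataFrame, classes: Sequence[str]
) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Median + IQR of per-patient one-vs-rest metrics.

    Patients with no true beats of a class are excluded from that
    class's summary; per-patient NaN metrics (e.g. PPV with no positive
    predictions) are ignored by the quantiles.
    """
    per_patient: Dict[str, Dict[str, List[float]]] = {
        c: {m: [] for m in ("accuracy", "sensitivity", "specificity", "ppv", "npv")}
        for c in classes
    }
    n_patients: Dict[str, int] = {c: 0 for c in classes}
    for _, group in predictions.groupby("patient_id", sort=True):
        cm = confusion_counts(group["y_true"], group["y_pred"], classes)
        metrics = metrics_from_confusion(cm, classes)
        for j, c in enumerate(classes):
            if cm[j].sum() == 0:
                continue
            n_patients[c] += 1
            for m, v in metrics[c].items():
                if np.isfinite(v):
                    per_patient[c][m].append(v)
    summary: Dict[str, Dict[str, Dict[str, float]]] = {}
    for c in classes:
        summary[c] = {"n_patients": n_patients[c]}
        for m, values in per_patient[c].items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                summary[c][m] = {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
            else:
                summary[c][m] = {
                    "median": float(np.median(arr)),
                    "q1": float(np.percentile(arr, 25)),
                    "q3": float(np.percentile(arr, 75)),
                }
    return summary


@dataclass
class CVResult:
    mode: str
    classes: Tuple[str, ...]
    predictions: pd.DataFrame
    confusion: np.ndarray
    beatwise: Dict[str, Dict[str, float]]
    patientwise: Dict[str, Dict]
    importances: List[pd.Series]
    audit: List[Dict]
    per_fold_confusions: List[np.ndarray] = field(default_factory=list)


def cross_validate(
    dataset: pd.DataFrame,
    plan: FoldPlan,
    cfg: RFConfig | None = None,
    mode: str = "multiclass",
    cap: int = TRAIN_CAP_PER_CLASS,
    transform_factory=FeatureTransform,
) -> CVResult:
    """Patient-wise K-fold cross-validation over an assembled feature table.

    Per fold: cap the training beats per class, fit the feature
    transform on the (capped) training beats only, train, predict the
    held-out fold.  Predictions are pooled across folds.
    """
    cfg = cfg or RFConfig()
    classes = BINARY_LABELS if mode == "binary" else MULTICLASS_LABELS
    fold_of = dataset["patient_id"].map(plan.assignment)
    if fold_of.isna().any():
        missing = sorted(dataset.loc[fold_of.isna(), "patient_id"].unique())
        raise ValueError(f"patients missing from fold plan: {missing}")

    all_preds = []
    importances: List[pd.Series] = []
    audit: List[Dict] = []
    per_fold_cms: List[np.ndarray] = []
    for fold in range(plan.k):
        test_mask = fold_of == fold
        train = dataset.loc[~test_mask]
        test = dataset.loc[test_mask]
        if test.empty:
            continue
        train_patients = set(train["patient_id"])
        test_patients = set(test["patient_id"])
        if train_patients & test_patients:
            raise AssertionError("patient leaked across the train/test split")
        fold_seed = derive_seed(cfg.seed, f"fold{fold}")
        train = cap_training(train, cap=cap, seed=fold_seed)
        transform = transform_factory().fit(train)
        X_train = transform.transform(train)
        X_test = transform.transform(test)
        clf = train_rf(
            X_train.to_numpy(),
            train["label"],
            RFConfig(
                cfg.n_estimators,
                cfg.min_samples_split,
                cfg.min_samples_leaf,
                cfg.max_depth,
                cfg.bootstrap_replacement,
                fold_seed,
            ),
            mode=mode,
        )
        y_true = _as_mode_labels(test["label"], mode)
        y_pred = clf.predict(X_test.to_numpy())
        preds = pd.DataFrame(
            {
                "patient_id": test["patient_id"].to_numpy(),
                "beat_sample": test["beat_sample"].to_numpy(),
                "fold": fold,
                "y_true": y_true,
                "y_pred": y_pred,
            }
        )
        all_preds.append(preds)
        per_fold_cms.append(confusion_counts(y_true, y_pred, classes))
        importances.append(
            pd.Series(clf.feature_importances_, index=transform.kept, name=f"fold{fold}")
        )
        audit.append(
            {
                "fold": fold,
                "train_patients": sorted(train_patients),
                "test_patients": sorted(test_patients),
                "n_train_beats": int(len(train)),
                "n_test_beats": int(len(test)),
                "kept_features": list(transform.kept),
            }
        )

    predictions = pd.concat(all_preds, ignore_index=True)
    cm = confusion_counts(predictions["y_true"], predictions["y_pred"], classes)
    return CVResult(
        mode=mode,
        classes=tuple(classes),
        predictions=predictions,
        confusion=cm,
        beatwise=metrics_from_confusion(cm, classes),
        patientwise=patientwise_metrics(predictions, classes),
        importances=importances,
        audit=audit,
        per_fold_confusions=per_fold_cms,
    )


def feature_importance(importances: Sequence[pd.Series], top: int = 10) -> pd.DataFrame:
    """Top-``top`` impurity importances per fold, long format."""
    rows = []
    for series in importances:
        ranked = series.sort_values(ascending=False).head(top)
        for rank, (name, value) in enumerate(ranked.items(), start=1):
            rows.append(
                {"fold": series.name, "rank": rank, "feature": name, "importance": float(value)}
            )
    return pd.DataFrame(rows)
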