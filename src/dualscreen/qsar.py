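"""Three-class decision-tree QSAR with class weighting and cross-application.

Compounds binned into active / moderate / inactive are modelled with a
decision tree over ~200 interpretable RDKit descriptors (or Morgan
fingerprint / PLIF feature sets).  Hyperparameters (max depth, min leaf
size) are tuned by stratified 10-fold cross-validation; five misprediction
weight schemes are compared ("balanced", 1:1:1, 1:2:2, 1:2:5, 1:5:10,
ordered inactive:moderate:active so the heaviest penalty falls on
mispredicted actives).  Models trained on one target's dataset can be
cross-applied to the other's, with compounds outside the applicability
domain (nearest-neighbour Tanimoto to the training set below a threshold,
default 0.3) flagged as low-confidence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier, export_text

from .chemspace import FingerprintSet, cross_max_similarity

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CLASS_ORDER",
    "WEIGHT_SCHEMES",
    "ClassWeights",
    "ModelReport",
    "descriptor_table",
    "split_train_test",
    "tune_tree",
    "fit_tree",
    "fit_and_evaluate",
    "cross_apply",
]

CLASS_ORDER = ("active", "moderate", "inactive")

#: Named weight tuples, ordered (inactive, moderate, active).
WEIGHT_SCHEMES = {
    "w111": (1.0, 1.0, 1.0),
    "w122": (1.0, 2.0, 2.0),
    "w125": (1.0, 2.0, 5.0),
    "w1510": (1.0, 5.0, 10.0),
}


@dataclass
class ClassWeights:
    """Misprediction penalty weights per activity class."""

    scheme: str
    weights: dict

    @classmethod
    def from_scheme(cls, scheme: str, y: np.ndarray | None = None) -> "ClassWeights":
        """Build weights from a named scheme.

        ``balanced`` = inverse class frequency (n / (k * count)), computed
        from the training labels ``y``; the fixed schemes map their tuple
        onto (inactive, moderate, active).
        """
        if scheme == "balanced":
            if y is None:
                raise ValueError("balanced weights require training labels")
            y = np.asarray(y)
            n, k = len(y), len(CLASS_ORDER)
            weights = {
                c: n / (k * max(1, int((y == c).sum()))) for c in CLASS_ORDER
            }
        elif scheme in WEIGHT_SCHEMES:
            w_inactive, w_moderate, w_active = WEIGHT_SCHEMES[scheme]
            weights = {"inactive": w_inactive, "moderate": w_moderate, "active": w_active}
        else:
            raise ValueError(f"unknown weight scheme: {scheme!r}")
        return cls(scheme, weights)


@dataclass
class ModelReport:
    """Evaluation report: confusion matrix, per-class metrics, accuracy.

    Metrics are computed directly from the confusion matrix with the
    one-vs-rest definitions precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = harmonic mean, accuracy = trace/total. Precision of a class that
    was never predicted is NaN and listed in ``undefined_precision``.
    """

    confusion: np.ndarray  # 3x3, rows = true class, cols = predicted (CLASS_ORDER)
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    class_counts: dict
    max_depth: int | None
    min_leaf: int
    weight_scheme: str
    seed: int
    undefined_precision: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Human-readable table: Class, N, Precision, Recall, F1, Overall Accuracy."""
        rows = []
        for c in CLASS_ORDER:
            rows.append(
                {
                    "Class": c,
                    "N": self.class_counts[c],
                    "Precision": self.precision[c],
                    "Recall": self.recall[c],
                    "F1": self.f1[c],
                    "Overall Accuracy": self.accuracy,
                }
            )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "confusion": self.confusion.tolist(),
                "class_order": list(CLASS_ORDER),
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "accuracy": self.accuracy,
                "class_counts": self.class_counts,
                "max_depth": self.max_depth,
                "min_leaf": self.min_leaf,
                "weight_scheme": self.weight_scheme,
                "seed": self.seed,
                "undefined_precision": self.undefined_precision,
            },
            indent=2,
            default=float,
        )


def descriptor_table(structures: list[str], ids: list[str] | None = None) -> pd.DataFrame:
    """~200 interpretable 2-D RDKit descriptors per compound.

    NaN/inf descriptor values are imputed with the column median so the
    matrix is complete; compound ids form the index.
    """
    ids = ids if ids is not None else [f"cpd{i}" for i in range(len(structures))]
    rows = []
    for smi in structures:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        rows.append(Descriptors.CalcMolDescriptors(mol))
    df = pd.DataFrame(rows, index=ids).replace([np.inf, -np.inf], np.nan)
    return df.fillna(df.median(numeric_only=True)).fillna(0.0)


def split_train_test(
    X: pd.DataFrame,
    y: np.ndarray,
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
):
    """Deterministic 80:20 train/test split, stratified by class by default."""
    y = np.asarray(y)
    if stratified:
        counts = pd.Series(y).value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"stratified split needs >=2 members per class; got {counts.to_dict()}"
            )
    return train_test_split(
        X,
        y,
        train_size=fraction,
        random_state=seed,
        stratify=y if stratified else None,
    )


def tune_tree(
    X: pd.DataFrame,
    y: np.ndarray,
    max_depth_grid=(2, 3, 5, 8, None),
    min_leaf_grid=(1, 2, 5, 10),
    k: int = 10,
    seed: int = 0,
    weights: ClassWeights | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Grid search over (max_depth, min_leaf) by stratified k-fold CV.

    The objective is mean macro-F1 across folds. Ties are broken toward the
    simpler model: smaller depth first, then larger leaf. ``k`` is reduced
    (with a warning) when a class has fewer members than folds.
    """
    y = np.asarray(y)
    min_class = int(pd.Series(y).value_counts().min())
    if k > min_class:
        warnings.warn(f"k={k} exceeds smallest class size {min_class}; reduced")
        k = max(2, min_class)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(np.asarray(X), y))
    class_weight = weights.weights if weights is not None else None
    results = []
    for depth in max_depth_grid:
        for leaf in min_leaf_grid:
            scores = []
            for tr, va in folds:
                clf = DecisionTreeClassifier(
                    max_depth=depth,
                    min_samples_leaf=leaf,
                    class_weight=class_weight,
                    random_state=seed,
                )
                clf.fit(np.asarray(X)[tr], y[tr])
                pred = clf.predict(np.asarray(X)[va])
                scores.append(_macro_f1(y[va], pred))
            results.append(
                {"max_depth": depth, "min_leaf": leaf, "cv_macro_f1": float(np.mean(scores))}
            )
    table = pd.DataFrame(results)
    # simpler-model tie rule: smaller depth (None = unbounded = most complex),
    # then larger leaf
    def sort_key(row):
        depth = row["max_depth"]
        return (
            -row["cv_macro_f1"],
            np.inf if depth is None else depth,
            -row["min_leaf"],
        )

    best = min(results, key=sort_key)
    return {"max_depth": best["max_depth"], "min_leaf": best["min_leaf"]}, table


def _macro_f1(y_true, y_pred) -> float:
    cm = confusion_matrix(y_true, y_pred, labels=list(CLASS_ORDER))
    f1s = []
    for i in range(len(CLASS_ORDER)):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom else 0.0)
    return float(np.mean(f1s))


def fit_tree(
    X: pd.DataFrame,
    y: np.ndarray,
    params: dict,
    weights: ClassWeights | None = None,
    seed: int = 0,
) -> DecisionTreeClassifier:
    clf = DecisionTreeClassifier(
        max_depth=params.get("max_depth"),
        min_samples_leaf=params.get("min_leaf", 1),
        class_weight=weights.weights if weights is not None else None,
        random_state=seed,
    )
    clf.fit(np.asarray(X), np.asarray(y))
    return clf


def report_from_confusion(
    cm: np.ndarray, params: dict, weights: ClassWeights | None, seed: int
) -> ModelReport:
    """Compute all metrics exactly from a 3×3 confusion matrix."""
    cm = np.asarray(cm, dtype=int)
    precision, recall, f1 = {}, {}, {}
    undefined = []
    for i, c in enumerate(CLASS_ORDER):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        if tp + fp == 0:
            precision[c] = float("nan")
            undefined.append(c)
        else:
            precision[c] = tp / (tp + fp)
        recall[c] = tp / (tp + fn) if (tp + fn) else float("nan")
        p, r = precision[c], recall[c]
        f1[c] = (2 * p * r / (p + r)) if (p == p and r == r and p + r > 0) else (
            0.0 if (p == p and r == r) else float("nan")
        )
    total = cm.sum()
    return ModelReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(np.trace(cm) / total) if total else float("nan"),
        class_counts={c: int(cm[i, :].sum()) for i, c in enumerate(CLASS_ORDER)},
        max_depth=params.get("max_depth"),
        min_leaf=params.get("min_leaf", 1),
        weight_scheme=weights.scheme if weights is not None else "none",
        seed=seed,
        undefined_precision=undefined,
    )


def fit_and_evaluate(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    params: dict,
    weights: ClassWeights | None = None,
    seed: int = 0,
) -> tuple[ModelReport, DecisionTreeClassifier]:
    """Fit a weighted tree on the training set and report test-set metrics."""
    if list(getattr(X_train, "columns", [])) != list(getattr(X_test, "columns", [])):
        raise ValueError("train and test feature columns differ")
    clf = fit_tree(X_train, y_train, params, weights, seed)
    pred = clf.predict(np.asarray(X_test))
    cm = confusion_matrix(y_test, pred, labels=list(CLASS_ORDER))
    return report_from_confusion(cm, params, weights, seed), clf


def export_rules(clf: DecisionTreeClassifier, feature_names: list[str]) -> str:
    """Serialise the fitted tree as a portable text rule list."""
    return export_text(clf, feature_names=list(feature_names))


def cross_apply(
    model: DecisionTreeClassifier,
    X_other: pd.DataFrame,
    fps_train: FingerprintSet,
    fps_other: FingerprintSet,
    ad_threshold: float = 0.3,
) -> pd.DataFrame:
    """Apply a model trained on dataset A to dataset B with an
    applicability-domain flag.

    A compound is out-of-domain when its maximum Tanimoto similarity to any
    of A's training compounds falls below ``ad_threshold`` — predictions for
    such compounds extrapolate beyond the training chemical space.
    """
    if model.n_features_in_ != X_other.shape[1]:
        raise ValueError(
            f"descriptor schema mismatch: model expects {model.n_features_in_} "
            f"features, got {X_other.shape[1]}"
        )
    pred = model.predict(np.asarray(X_other))
    max_sim = cross_max_similarity(fps_other, fps_train)
    return pd.DataFrame(
        {
            "compound_id": fps_other.compound_ids,
            "predicted_class": pred,
            "max_train_similarity": max_sim,
            "in_domain": max_sim >= ad_threshold,
        }
    )
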