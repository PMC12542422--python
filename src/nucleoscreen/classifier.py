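"""Supervised per-cell phenotype classification.

A seeded random-forest ensemble over the fixed feature table stands in for
the interactive annotate-and-train step of high-content screening: training
labels come from the simulator's ground truth (the stand-in for manual
annotation), and the contract is behavioral — held-out accuracy on labeled
synthetic cells — rather than fidelity to any particular learner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .phenotypes import N_CLASSES, PHENOTYPE_CLASSES, validate_classes
from .segmentation import FEATURE_COLUMNS


class ClassifierError(ValueError):
    pass


@dataclass
class ClassifierModel:
    """Trained decision function plus its schema and provenance."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    training_counts: dict[str, int]

    def save(self, path) -> None:
        path = Path(path)
        joblib.dump(self.estimator, path)
        meta = {
            "feature_names": list(self.feature_names),
            "classes": list(self.classes),
            "seed": self.seed,
            "training_counts": self.training_counts,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        path = Path(path)
        est = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            estimator=est,
            feature_names=tuple(meta["feature_names"]),
            classes=tuple(meta["classes"]),
            seed=int(meta["seed"]),
            training_counts={k: int(v) for k, v in meta["training_counts"].items()},
        )


def _feature_matrix(features: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    missing = [c for c in names if c not in features.columns]
    if missing:
        raise ClassifierError(f"feature table is missing columns: {missing}")
    return features[list(names)].to_numpy(dtype=float)


def train_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_estimators: int = 300,
    feature_names: tuple[str, ...] = FEATURE_COLUMNS,
) -> ClassifierModel:
    """Fit the phenotype classifier on a labeled feature table.

    Labels must be drawn from the eight canonical classes and cover at least
    two of them.  Reproducible for a fixed seed.
    """
    labels = np.asarray(labels, dtype=object)
    validate_classes(labels)
    counts = pd.Series(labels).value_counts().to_dict()
    if len(counts) < 2:
        raise ClassifierError("training data must contain at least two classes")
    X = _feature_matrix(features, feature_names)
    if len(X) != len(labels):
        raise ClassifierError("features and labels lengths differ")
    est = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    est.fit(X, labels.astype(str))
    return ClassifierModel(
        estimator=est,
        feature_names=tuple(feature_names),
        classes=PHENOTYPE_CLASSES,
        seed=seed,
        training_counts={k: int(v) for k, v in counts.items()},
    )


def classify_cells(model: ClassifierModel, features: pd.DataFrame) -> pd.DataFrame:
    """Assign a class and posterior to every cell in the feature table.

    Returns the input's index with a ``predicted_class`` column plus one
    posterior column ``p_<class>`` per canonical class (summing to 1).  Ties
    in the posterior break toward the earlier canonical class.
    """
    if len(features) == 0:
        cols = ["predicted_class"] + [f"p_{c}" for c in PHENOTYPE_CLASSES]
        return pd.DataFrame(columns=cols)
    X = _feature_matrix(features, model.feature_names)
    raw = model.estimator.predict_proba(X)
    post = np.zeros((len(X), N_CLASSES))
    for j, cls in enumerate(model.estimator.classes_):
        post[:, PHENOTYPE_CLASSES.index(cls)] = raw[:, j]
    pred = [PHENOTYPE_CLASSES[i] for i in np.argmax(post, axis=1)]  # first max wins
    out = pd.DataFrame({"predicted_class": pred}, index=features.index)
    for i, cls in enumerate(PHENOTYPE_CLASSES):
        out[f"p_{cls}"] = post[:, i]
    return out


def evaluate_classifier(
    model: ClassifierModel, features: pd.DataFrame, labels
) -> dict:
    """Confusion matrix (rows = truth, canonical order) and summary metrics."""
    labels = np.asarray(labels, dtype=object)
    validate_classes(labels)
    pred = classify_cells(model, features)["predicted_class"].to_numpy()
    conf = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(labels, pred):
        conf[PHENOTYPE_CLASSES.index(t), PHENOTYPE_CLASSES.index(p)] += 1
    support = conf.sum(axis=1)
    predicted = conf.sum(axis=0)
    diag = np.diag(conf)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, diag / np.maximum(support, 1), np.nan)
        precision = np.where(predicted > 0, diag / np.maximum(predicted, 1), np.nan)
    accuracy = float(diag.sum() / max(conf.sum(), 1))
    per_class = pd.DataFrame(
        {
            "class": PHENOTYPE_CLASSES,
            "support": support,
            "precision": precision,
            "recall": recall,
        }
    )
    return {"confusion": conf, "accuracy": accuracy, "per_class": per_class}


def confusion_to_rates(conf: np.ndarray) -> np.ndarray:
    """Row-normalize a count confusion matrix into transition probabilities.

    Rows with no support become identity rows, so the result is always a
    valid input for table-mode simulation.
    """
    conf = np.asarray(conf, dtype=float)
    out = np.eye(N_CLASSES)
    sums = conf.sum(axis=1)
    for i in range(N_CLASSES):
        if sums[i] > 0:
            out[i] = conf[i] / sums[i]
    return out
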