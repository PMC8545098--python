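"""Random-forest classification of per-contig ¹³C enrichment.

Assigns each contig one of five categories — strongly enriched, weakly
enriched, unenriched, bimodal (local maxima in both the heavy and light
portions of the gradient) or undetermined — from the 24 gradient-profile
features, using a classification forest trained on labelled example
contigs with a stratified holdout for validation.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .features import FEATURE_NAMES
from .synthetic import CLASSES


@dataclass
class TrainedModel:
    """A fitted enrichment forest plus the metadata needed to reuse it."""

    forest: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    seed: int
    n_trees: int
    max_features: str
    max_depth: int | None
    split_fraction: float | None = None

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


@dataclass
class MetricsReport:
    """Holdout metrics: overall accuracy plus one-vs-rest sensitivity and
    specificity per class, with the full confusion matrix (rows = truth,
    columns = prediction)."""

    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": dict(self.sensitivity),
            "specificity": dict(self.specificity),
            "confusion": self.confusion.to_dict(),
        }


def split_train_validation(
    features: pd.DataFrame,
    labels: pd.Series,
    holdout_fraction: float = 0.20,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Stratified train/validation split; returns (X_tr, y_tr, X_val, y_val)."""
    if not 0 < holdout_fraction < 1:
        raise ValueError("holdout_fraction must be in (0, 1)")
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 examples: {bad}")
    x_tr, x_val, y_tr, y_val = train_test_split(
        features, labels, test_size=holdout_fraction, stratify=labels, random_state=seed
    )
    return x_tr, y_tr, x_val, y_val


def train(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    max_features: str = "sqrt",
    max_depth: int | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the enrichment forest (majority vote over ``n_trees`` trees,
    √p features per split, unlimited depth by default)."""
    if labels.nunique() < 2:
        raise ValueError("training data must contain at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        max_depth=max_depth,
        random_state=seed,
    )
    forest.fit(features.to_numpy(), labels.to_numpy())
    return TrainedModel(
        forest=forest,
        feature_names=tuple(features.columns),
        classes=tuple(forest.classes_),
        seed=seed,
        n_trees=n_trees,
        max_features=max_features,
        max_depth=max_depth,
    )


def predict(model: TrainedModel, features: pd.DataFrame) -> pd.DataFrame:
    """Per-contig enrichment calls with class probabilities.

    The call is the argmax class, with ties broken in the fixed order
    strong > weak > unenriched > bimodal > undetermined.  Contigs with no
    observed depth anywhere in the window (log_total_depth == 0) are
    routed directly to "undetermined".
    """
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"feature matrix is missing feature '{missing[0]}'")
    x = features[list(model.feature_names)]
    proba = model.forest.predict_proba(x.to_numpy())
    proba_df = pd.DataFrame(proba, columns=model.forest.classes_, index=features.index)
    for c in CLASSES:
        if c not in proba_df.columns:
            proba_df[c] = 0.0
    proba_df = proba_df[list(CLASSES)]
    # argmax with fixed-order tie break: first max in CLASSES order
    calls = proba_df.to_numpy().argmax(axis=1)
    call_labels = np.array(CLASSES, dtype=object)[calls]
    if "log_total_depth" in features.columns:
        zero_depth = features["log_total_depth"].to_numpy() == 0.0
        call_labels[zero_depth] = "undetermined"
        proba_df.loc[zero_depth, :] = 0.0
        proba_df.loc[zero_depth, "undetermined"] = 1.0
    out = proba_df.copy()
    out.insert(0, "call", call_labels)
    return out


def evaluate(predictions: pd.Series, truth: pd.Series) -> MetricsReport:
    """One-vs-rest sensitivity/specificity and overall accuracy.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) per class;
    confusion rows are truth, columns predictions.
    """
    predictions = pd.Series(predictions).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    unknown = set(predictions) | set(truth)
    if unknown - set(CLASSES):
        raise ValueError(f"labels outside the class set: {sorted(unknown - set(CLASSES))}")
    conf = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    for t, p in zip(truth, predictions):
        conf.loc[t, p] += 1
    total = conf.to_numpy().sum()
    accuracy = float(np.trace(conf.to_numpy())) / total
    sens, spec = {}, {}
    for c in CLASSES:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = float(tp / (tp + fn)) if (tp + fn) > 0 else float("nan")
        spec[c] = float(tn / (tn + fp)) if (tn + fp) > 0 else float("nan")
    return MetricsReport(accuracy=accuracy, sensitivity=sens, specificity=spec, confusion=conf)
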