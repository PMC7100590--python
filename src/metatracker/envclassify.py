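"""Random-forest classification of samples into source environments.

Complements the Bayesian mixing estimates: a forest of 500 trees is fit on
the same rarefied feature tables (samples x taxa), either one-vs-other for
a chosen target environment or multiclass over all environments.  Reports
held-out accuracy from a ~3:1 stratified train/test split, out-of-bag
error, the confusion matrix, and the ten most important taxa by mean
impurity decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from .errors import MetatrackerError
from .tables_io import FeatureTable

DEFAULT_N_TREES = 500
OTHER_LABEL = "other"
TOP_N_FEATURES = 10


@dataclass(frozen=True)
class ClassificationReport:
    """Outcome of one random-forest fit."""

    target: str                    # environment name, or "multiclass"
    classes: tuple[str, ...]
    accuracy: float                # held-out accuracy on the test split
    oob_error: float               # 1 - out-of-bag score on the train split
    confusion: pd.DataFrame        # true (rows) x predicted (cols) counts
    top_features: tuple[tuple[str, float], ...]  # (taxon, importance), desc

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": [self.target],
                "accuracy": [self.accuracy],
                "oob_error": [self.oob_error],
                "n_test": [int(self.confusion.to_numpy().sum())],
            }
        )


def make_labels(metadata: pd.DataFrame, target_env: str) -> pd.Series:
    """One-vs-other labels: ``target_env`` against ``"other"``."""
    envs = metadata["env"]
    if target_env not in set(envs):
        raise MetatrackerError(f"target environment {target_env!r} not in metadata")
    labels = envs.where(envs == target_env, OTHER_LABEL)
    labels.name = "label"
    return labels


def split_train_test(
    sample_ids: list[str],
    labels: pd.Series,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/test partition at ~3:1.

    The test set holds round(n * test_fraction) samples, stratified by
    label whenever every class has at least two members.
    """
    labels = labels.loc[sample_ids]
    n_test = int(round(len(sample_ids) * test_fraction))
    n_test = min(max(n_test, 1), len(sample_ids) - 1)
    counts = labels.value_counts()
    stratify = labels if (counts.min() >= 2 and n_test >= len(counts)) else None
    train, test = train_test_split(
        sample_ids, test_size=n_test, random_state=seed, stratify=stratify
    )
    return list(train), list(test)


def classify(
    table: FeatureTable,
    labels: pd.Series,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    test_fraction: float = 0.25,
    importance: str = "impurity",
) -> ClassificationReport:
    """Fit a random forest and report accuracy, OOB error and top taxa.

    ``labels`` indexes the samples to use (a subset of the table's
    columns).  ``importance`` selects mean-impurity-decrease (default) or
    ``"permutation"`` importance on the test split.  A class with fewer
    than two samples cannot be split or bagged meaningfully and is an
    error — merge it or add samples.
    """
    sample_ids = [s for s in labels.index if s in table.data.columns]
    if len(sample_ids) < 4:
        raise MetatrackerError("need at least 4 labelled samples to classify")
    labels = labels.loc[sample_ids]
    counts = labels.value_counts()
    if counts.min() < 2:
        tiny = counts[counts < 2].index.tolist()
        raise MetatrackerError(
            f"class(es) {tiny} have < 2 samples; merge environments or add samples"
        )
    X = table.data[sample_ids].T  # samples x taxa
    y = labels.to_numpy()
    train_ids, test_ids = split_train_test(sample_ids, labels,
                                           test_fraction=test_fraction, seed=seed)
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    clf.fit(X.loc[train_ids], labels.loc[train_ids])
    y_pred = clf.predict(X.loc[test_ids])
    y_true = labels.loc[test_ids].to_numpy()
    accuracy = float((y_pred == y_true).mean())
    classes = sorted(np.unique(y))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    confusion.index.name = "true"
    confusion.columns.name = "predicted"
    if importance == "permutation":
        perm = permutation_importance(
            clf, X.loc[test_ids], y_true, random_state=seed, n_repeats=5
        )
        imp = perm.importances_mean
    else:
        imp = clf.feature_importances_
    order = np.argsort(imp)[::-1][:TOP_N_FEATURES]
    top = tuple((str(X.columns[i]), float(imp[i])) for i in order)
    target = "multiclass" if len(classes) > 2 else next(
        c for c in classes if c != OTHER_LABEL
    )
    return ClassificationReport(
        target=target,
        classes=tuple(classes),
        accuracy=accuracy,
        oob_error=float(1.0 - clf.oob_score_),
        confusion=confusion,
        top_features=top,
    )
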