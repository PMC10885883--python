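"""Per-record labor/non-labor classification and the evaluation metric suite.

A decision tree on the (x, z) count pair is the production model; a
support-vector machine is kept as the comparison baseline. Metrics follow
the standard confusion-matrix definitions: per-class precision TP/(TP+FP),
recall TP/(TP+FN), F1 = 2PR/(P+R), plus accuracy and macro / support-
weighted averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (KidwatchError, MisalignedLabelsError, SingleClassError)

__all__ = [
    "SplitSpec",
    "ClassMetrics",
    "MetricsReport",
    "LaborClassifier",
    "split_dataset",
    "metrics",
    "train",
    "predict_stream",
    "save_model",
    "load_model",
]

DEFAULT_FEATURES = ("x", "z")


@dataclass(frozen=True)
class SplitSpec:
    """Seeded shuffle + contiguous 80/20 partition."""

    train_fraction: float = 0.8
    shuffle_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise KidwatchError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    """Per-class and aggregate scores, Table-style."""

    per_class: dict[int, ClassMetrics]
    accuracy: float
    macro: ClassMetrics
    weighted: ClassMetrics
    zero_division: bool = False  # any metric defined as 0 on a 0 denominator

    def to_frame(self) -> pd.DataFrame:
        rows = {f"class {c}": m for c, m in sorted(self.per_class.items())}
        rows["macro average"] = self.macro
        rows["weighted average"] = self.weighted
        df = pd.DataFrame(
            {name: {"Precision": m.precision, "Recall": m.recall,
                    "F-1 Score": m.f1, "Support": m.support}
             for name, m in rows.items()}).T
        df.loc["accuracy"] = [np.nan, np.nan, self.accuracy,
                              self.weighted.support]
        return df

    def __str__(self) -> str:
        return self.to_frame().round(2).to_string()


def split_dataset(samples: pd.DataFrame, spec: SplitSpec = SplitSpec()
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle with the spec's seed, then cut at floor(train_fraction * n)."""
    n = len(samples)
    if n < 10:
        raise KidwatchError("need at least 10 samples to split")
    if samples["label"].nunique() < 2:
        raise SingleClassError("both classes required before splitting")
    rng = np.random.default_rng(spec.shuffle_seed)
    perm = rng.permutation(n)
    cut = int(np.floor(spec.train_fraction * n))
    train_df = samples.iloc[perm[:cut]].reset_index(drop=True)
    test_df = samples.iloc[perm[cut:]].reset_index(drop=True)
    for name, part in (("train", train_df), ("test", test_df)):
        if part["label"].nunique() < 2:
            warnings.warn(f"{name} partition lost a class; consider "
                          "stratifying or a different seed", stacklevel=2)
    return train_df, test_df


def _div(num: float, den: float, flags: list) -> float:
    if den == 0:
        flags.append(True)
        return 0.0
    return num / den


def metrics(y_true, y_pred) -> MetricsReport:
    """Confusion-matrix metric suite over binary labels {0, 1}.

    Zero-denominator metrics are defined as 0 and flagged on the report.
    """
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.size == 0:
        raise KidwatchError("metrics on empty input")
    if yt.shape != yp.shape:
        raise MisalignedLabelsError("y_true and y_pred lengths differ")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise KidwatchError("labels must be in {0, 1}")
    flags: list = []
    per_class = {}
    for c in (0, 1):
        tp = int(((yp == c) & (yt == c)).sum())
        fp = int(((yp == c) & (yt != c)).sum())
        fn = int(((yp != c) & (yt == c)).sum())
        p = _div(tp, tp + fp, flags)
        r = _div(tp, tp + fn, flags)
        f1 = _div(2 * p * r, p + r, flags)
        per_class[c] = ClassMetrics(p, r, f1, int((yt == c).sum()))
    n = yt.size
    acc = float((yt == yp).mean())
    macro = ClassMetrics(
        float(np.mean([m.precision for m in per_class.values()])),
        float(np.mean([m.recall for m in per_class.values()])),
        float(np.mean([m.f1 for m in per_class.values()])),
        n)
    w = {c: m.support / n for c, m in per_class.items()}
    weighted = ClassMetrics(
        sum(w[c] * per_class[c].precision for c in per_class),
        sum(w[c] * per_class[c].recall for c in per_class),
        sum(w[c] * per_class[c].f1 for c in per_class),
        n)
    return MetricsReport(per_class, acc, macro, weighted, bool(flags))


@dataclass
class LaborClassifier:
    """A fitted labor/non-labor model plus its held-out evaluation."""

    kind: str  # 'tree' | 'svm'
    features: tuple[str, ...] = DEFAULT_FEATURES
    estimator: object | None = None
    report: MetricsReport | None = None

    def predict(self, samples: pd.DataFrame) -> np.ndarray:
        if self.estimator is None:
            raise KidwatchError("classifier is not fitted")
        if len(samples) == 0:
            return np.empty(0, dtype=int)
        X = samples.loc[:, list(self.features)].to_numpy()
        return self.estimator.predict(X).astype(int)


def train(samples: pd.DataFrame, kind: str = "tree",
          spec: SplitSpec = SplitSpec(),
          features: tuple[str, ...] = DEFAULT_FEATURES,
          svm_kernel: str = "rbf",
          max_depth: int = 10, min_samples_leaf: int = 5) -> LaborClassifier:
    """Fit a tree or SVM on an 80/20 split; evaluate on the held-out 20%."""
    train_df, test_df = split_dataset(samples, spec)
    if train_df["label"].nunique() < 2:
        raise SingleClassError("degenerate training partition")
    if kind == "tree":
        est = DecisionTreeClassifier(
            criterion="gini", max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=spec.shuffle_seed)
    elif kind == "svm":
        est = SVC(kernel=svm_kernel, random_state=spec.shuffle_seed)
    else:
        raise KidwatchError(f"unknown model kind {kind!r}")
    X = train_df.loc[:, list(features)].to_numpy()
    est.fit(X, train_df["label"].to_numpy())
    clf = LaborClassifier(kind, tuple(features), est)
    y_pred = clf.predict(test_df)
    clf.report = metrics(test_df["label"].to_numpy(), y_pred)
    return clf


def predict_stream(model: LaborClassifier, records: pd.DataFrame
                   ) -> np.ndarray:
    """One label per record, order preserved; uses the model's feature pair."""
    return model.predict(records)


def save_model(model: LaborClassifier, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> LaborClassifier:
    model = joblib.load(path)
    if not isinstance(model, LaborClassifier):
        raise KidwatchError(f"{path} does not contain a LaborClassifier")
    return model
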