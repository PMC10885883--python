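"""Outlier removal (range rule + Tukey quartile fences) and feature ranking.

Acceleration counts live on 0-255; transmissions occasionally arrive with
values outside that range and are dropped first. The remaining values are
then fenced per axis at Quartile1 - 1.5*IQR and Quartile3 + 1.5*IQR.
Feature relevance is scored with information gain and gain ratio over the
integer count categories, and the top two axes become the model features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SingleClassError

__all__ = [
    "OutlierBounds",
    "FeatureScore",
    "range_filter",
    "iqr_bounds",
    "iqr_filter",
    "clean_dataset",
    "rank_features",
    "write_feature_report",
]


@dataclass(frozen=True)
class OutlierBounds:
    """Tukey fences: CLO = Q1 - 1.5*IQR, CUO = Q3 + 1.5*IQR."""

    quartile1: float
    quartile3: float

    @property
    def iqr(self) -> float:
        return self.quartile3 - self.quartile1

    @property
    def cuo(self) -> float:
        return self.quartile3 + 1.5 * self.iqr

    @property
    def clo(self) -> float:
        return self.quartile1 - 1.5 * self.iqr


@dataclass(frozen=True)
class FeatureScore:
    feature_name: str
    info_gain: float  # bits
    gain_ratio: float


def range_filter(values, low: int = 0, high: int = 255
                 ) -> tuple[np.ndarray, int]:
    """Retain values in [low, high]; return (retained, n_removed)."""
    v = np.asarray(values)
    keep = (v >= low) & (v <= high)
    return v[keep], int((~keep).sum())


def iqr_bounds(values) -> OutlierBounds:
    """Quartiles by linear interpolation between order statistics (type 7)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InsufficientDataError(
            f"need at least 4 values for quartiles, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75])
    return OutlierBounds(float(q1), float(q3))


def iqr_filter(values, bounds: OutlierBounds | None = None) -> np.ndarray:
    """Retain values v with CLO <= v <= CUO."""
    v = np.asarray(values)
    if bounds is None:
        bounds = iqr_bounds(v)
    return v[(v >= bounds.clo) & (v <= bounds.cuo)]


def clean_dataset(samples: pd.DataFrame, axes=("x", "y", "z"),
                  per_goat: bool = True) -> tuple[pd.DataFrame, dict]:
    """Apply range filtering then quartile fencing row-wise to a dataset.

    A row survives if every axis value is within [0, 255] and inside the
    axis's Tukey fences (fences computed per goat by default, on the
    range-retained values). Returns the cleaned frame and a removal audit
    ``{'range': n, 'iqr': n}``.
    """
    removed = {"range": 0, "iqr": 0}
    groups = samples.groupby("goat_id") if per_goat and "goat_id" in samples \
        else [(None, samples)]
    kept = []
    for _, g in groups:
        in_range = np.ones(len(g), dtype=bool)
        for ax in axes:
            in_range &= (g[ax] >= 0) & (g[ax] <= 255)
        removed["range"] += int((~in_range).sum())
        g = g.loc[in_range]
        in_fence = np.ones(len(g), dtype=bool)
        for ax in axes:
            if len(g) >= 4:
                b = iqr_bounds(g[ax].to_numpy())
                in_fence &= (g[ax] >= b.clo) & (g[ax] <= b.cuo)
        removed["iqr"] += int((~in_fence).sum())
        kept.append(g.loc[in_fence])
    out = pd.concat(kept, ignore_index=True) if kept else samples.iloc[:0]
    return out, removed


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a vector of category counts."""
    counts = counts[counts > 0]
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def rank_features(samples: pd.DataFrame, features=("x", "y", "z"),
                  label_col: str = "label") -> list[FeatureScore]:
    """Score each feature by information gain and gain ratio.

    ``info_gain = H(label) - sum_v p(v) H(label | feature = v)`` with each
    integer count treated as its own category;
    ``gain_ratio = info_gain / split_information`` (0 when the split
    information is 0, i.e. a constant feature). Features are returned sorted
    by descending gain ratio.
    """
    y = samples[label_col].to_numpy()
    labels, y_idx = np.unique(y, return_inverse=True)
    if labels.size < 2:
        raise SingleClassError(
            "feature ranking needs both classes present")
    h_label = _entropy(np.bincount(y_idx))
    n = y_idx.size
    scores = []
    for feat in features:
        v = samples[feat].to_numpy()
        vals, v_idx = np.unique(v, return_inverse=True)
        joint = np.zeros((vals.size, labels.size))
        np.add.at(joint, (v_idx, y_idx), 1.0)
        nv = joint.sum(axis=1)
        cond = 0.0
        for row, cnt in zip(joint, nv):
            cond += (cnt / n) * _entropy(row)
        ig = max(h_label - cond, 0.0)
        split_info = _entropy(nv)
        gr = ig / split_info if split_info > 0 else 0.0
        scores.append(FeatureScore(str(feat), ig, gr))
    return sorted(scores, key=lambda s: s.gain_ratio, reverse=True)


def write_feature_report(scores: list[FeatureScore], path) -> None:
    pd.DataFrame([{"feature": s.feature_name, "info_gain": s.info_gain,
                   "gain_ratio": s.gain_ratio} for s in scores]
                 ).to_csv(path, index=False)
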