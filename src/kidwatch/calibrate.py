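"""Window-length selection, the three-sigma alarm threshold, and lead time.

Per candidate window length, the labor group is each goat's maximum LPI on
its parturition day and the non-labor group is the k highest LPIs (k = 110
by default) from pre-parturition, labor-free windows. The central range
value CRV = MSL - MSNL, where MSL = labor mean - SD and MSNL = non-labor
mean + SD, measures the separation between the groups; the window with the
largest CRV wins. The alarm threshold is the three-sigma bound of the
non-labor group, TCKG = mean + 3 * SD, and the mean detection-to-birth
offset MDV converts a detection time into a predicted first-birth time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import warnings

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (ContextMismatchError, InsufficientDataError,
                     KidwatchError)
from . import lpi as lpi_mod

__all__ = [
    "GroupStats",
    "WindowSelection",
    "CalibrationResult",
    "GroupComparison",
    "group_stats",
    "central_range_value",
    "select_window",
    "threshold",
    "threshold_from_moments",
    "mean_offset",
    "validate_groups",
    "calibrate_herd",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean/SD of a group of LPIs plus its inner boundary.

    For the labor group the boundary is MSL = mean - sd; for the non-labor
    group it is MSNL = mean + sd (the two one-sigma edges that face each
    other).
    """

    context: str  # 'labor' | 'non_labor'
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.context not in ("labor", "non_labor"):
            raise ContextMismatchError(
                f"context must be 'labor' or 'non_labor', got {self.context!r}")
        if self.sd < 0:
            raise KidwatchError("sd must be >= 0")

    @property
    def boundary(self) -> float:
        if self.context == "labor":
            return self.mean - self.sd
        return self.mean + self.sd


def group_stats(lpis, context: str) -> GroupStats:
    """Mean and sample (n-1) standard deviation of a group of LPIs."""
    v = np.asarray(lpis, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("group statistics need >= 2 values")
    return GroupStats(context, float(v.mean()), float(v.std(ddof=1)))


def central_range_value(labor: GroupStats, nonlabor: GroupStats) -> float:
    """CRV = MSL - MSNL; positive when the groups' 1-sigma edges separate."""
    if labor.context != "labor" or nonlabor.context != "non_labor":
        raise ContextMismatchError(
            "central_range_value(labor_stats, nonlabor_stats): "
            f"got contexts {labor.context!r}, {nonlabor.context!r}")
    return labor.boundary - nonlabor.boundary


@dataclass
class WindowSelection:
    """CRV table over the candidate windows and the argmax choice."""

    table: pd.DataFrame  # window_min, labor mean/sd/msl, nonlabor mean/sd/msnl, crv
    chosen_window_min: float

    def __str__(self) -> str:
        return (self.table.round(2).to_string(index=False)
                + f"\nchosen window: {self.chosen_window_min:g} min")


def select_window(per_window: dict[float, tuple[GroupStats, GroupStats]]
                  ) -> WindowSelection:
    """Pick the window length maximizing CRV; ties go to the shorter window
    (earlier detection)."""
    if not per_window:
        raise KidwatchError("no candidate windows")
    rows = []
    for w in sorted(per_window):
        lab, non = per_window[w]
        rows.append({
            "window_min": w,
            "labor_mean": lab.mean, "labor_sd": lab.sd, "msl": lab.boundary,
            "nonlabor_mean": non.mean, "nonlabor_sd": non.sd,
            "msnl": non.boundary,
            "crv": central_range_value(lab, non),
        })
    table = pd.DataFrame(rows)
    best = table.loc[table["crv"].idxmax(), "window_min"]  # first max: shortest
    return WindowSelection(table, float(best))


def threshold(nonlabor_lpis) -> float:
    """Three-sigma alarm threshold: TCKG = mean + 3 * sample SD."""
    v = np.asarray(nonlabor_lpis, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("threshold needs >= 2 values")
    return float(v.mean() + 3.0 * v.std(ddof=1))


def threshold_from_moments(mean: float, sd: float) -> float:
    """TCKG from already-computed group moments."""
    if sd < 0:
        raise KidwatchError("sd must be >= 0")
    return mean + 3.0 * sd


def mean_offset(detection_times, birth_times) -> tuple[float, float]:
    """Mean and sample SD (minutes) of birth - detection over paired goats.

    Positive offsets mean detection preceded the birth. A negative pair
    (detection after birth) triggers a warning but still enters the mean.
    """
    det = list(detection_times)
    bir = list(birth_times)
    if len(det) != len(bir):
        raise KidwatchError("detection and birth time lists must pair up")
    if len(det) == 0:
        raise InsufficientDataError("mean_offset on empty pairs")
    offs = []
    for d, b in zip(det, bir):
        if isinstance(d, (int, float, np.floating)):
            off = float(b) - float(d)
        else:
            off = (pd.Timestamp(b) - pd.Timestamp(d)).total_seconds() / 60.0
        offs.append(off)
    offs = np.asarray(offs)
    if (offs < 0).any():
        warnings.warn("some detections occurred after the recorded birth",
                      stacklevel=2)
    sd = float(offs.std(ddof=1)) if offs.size > 1 else 0.0
    return float(offs.mean()), sd


@dataclass
class GroupComparison:
    """KS normality per group and the independent two-sample t-test."""

    ks_stat_labor: float
    ks_p_labor: float
    ks_stat_nonlabor: float
    ks_p_nonlabor: float
    t_stat: float
    t_p: float
    normal_labor: bool
    normal_nonlabor: bool
    means_differ: bool  # at p < 0.001, the study's reported significance


def validate_groups(parturition_max_lpis, prior_day_max_lpis,
                    equal_var: bool = True) -> GroupComparison:
    """Normality (KS against the fitted normal) and mean-difference t-test."""
    a = np.asarray(parturition_max_lpis, dtype=float)
    b = np.asarray(prior_day_max_lpis, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("validate_groups needs >= 3 per group")

    def ks(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise InsufficientDataError("degenerate (constant) group")
        return stats.kstest(v, "norm", args=(v.mean(), sd))

    ka, kb = ks(a), ks(b)
    t = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        float(ka.statistic), float(ka.pvalue),
        float(kb.statistic), float(kb.pvalue),
        float(t.statistic), float(t.pvalue),
        ka.pvalue > 0.05, kb.pvalue > 0.05, t.pvalue < 0.001)


@dataclass
class CalibrationResult:
    """Everything the detector needs, plus provenance."""

    window_min: float
    tckg: float
    mdv_min: float
    sd_min: float
    n_goats: int = 0
    n_nonlabor: int = 0
    pool: str = "pooled_topk"

    def to_yaml(self, path) -> None:
        d = {k: (float(v) if isinstance(v, (float, np.floating))
                 else int(v) if isinstance(v, (int, np.integer)) else v)
             for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _nonlabor_pool(values_per_goat: dict[str, np.ndarray], k: int,
                   pool: str) -> np.ndarray:
    if pool == "pooled_topk":
        allv = np.sort(np.concatenate(list(values_per_goat.values())))[::-1]
        return allv[:k]
    if pool == "per_goat_topk":
        per = max(1, k // max(len(values_per_goat), 1))
        tops = [np.sort(v)[::-1][:per] for v in values_per_goat.values()]
        return np.concatenate(tops)
    raise KidwatchError(f"unknown pool strategy {pool!r}")


def calibrate_herd(streams, ground_truths, model,
                   window_minutes=(8.0, 10.0, 12.0, 14.0),
                   stride_sec: float = 60.0,
                   k: int = 110,
                   pool: str = "pooled_topk",
                   day_hours: float = 24.0
                   ) -> tuple[CalibrationResult, WindowSelection,
                              GroupComparison]:
    """End-to-end calibration on a labeled herd.

    For each goat the parturition day is the ``day_hours`` ending at the
    birth time; labor-group values are the day's maximum LPI. Non-labor
    values pool every window of the goat's pre-parturition stream that ends
    before labor onset (all monitored non-parturition behavior, not just
    the parturition day); the pool is built from the same sliding window
    grid the detector scans, so the threshold bounds the statistic it is
    later compared against. After choosing
    the window by CRV, TCKG is the three-sigma bound of that window's
    non-labor pool and MDV/SD are the mean/SD of birth minus first-crossing
    detection time across detected goats. Also returns the
    parturition-vs-prior-day group comparison on the chosen window.
    """
    from .classify import predict_stream
    from .detect import detect_day  # local import to avoid a cycle

    preds = {gt.goat_id: predict_stream(model, records)
             for records, gt in zip(streams, ground_truths)}

    per_window: dict[float, tuple[GroupStats, GroupStats]] = {}
    pools: dict[float, np.ndarray] = {}
    day_series: dict[float, dict[str, pd.DataFrame]] = {}
    for w in window_minutes:
        labor_vals = []
        nonlabor_per_goat: dict[str, np.ndarray] = {}
        day_series[w] = {}
        for records, gt in zip(streams, ground_truths):
            day_start = gt.birth_time - pd.Timedelta(hours=day_hours)
            full = lpi_mod.lpi_series(
                records, preds[gt.goat_id], w, stride_sec,
                start=gt.start_time, end=gt.birth_time, goat_id=gt.goat_id)
            series = full.loc[
                full["window_start"] >= max(day_start, gt.start_time)]
            day_series[w][gt.goat_id] = series
            labor_vals.append(
                float(lpi_mod.daily_max_lpi(series)["lpi"]))
            cutoff = gt.labor_onset if gt.labor_onset is not None \
                else gt.birth_time
            nl = full.loc[full["window_end"] <= cutoff, "lpi"]
            nonlabor_per_goat[gt.goat_id] = nl.to_numpy(dtype=float)
        pool_vals = _nonlabor_pool(nonlabor_per_goat, k, pool)
        pools[w] = pool_vals
        per_window[w] = (group_stats(labor_vals, "labor"),
                         group_stats(pool_vals, "non_labor"))

    selection = select_window(per_window)
    w = selection.chosen_window_min
    tckg = threshold(pools[w])

    det_times, birth_times = [], []
    for records, gt in zip(streams, ground_truths):
        event = detect_day(day_series[w][gt.goat_id], tckg)
        if event is not None:
            det_times.append(event.dpt)
            birth_times.append(gt.birth_time)
    if det_times:
        mdv, sd = mean_offset(det_times, birth_times)
    else:
        warnings.warn("no goat crossed the threshold; MDV undefined, "
                      "reported as 0", stacklevel=2)
        mdv, sd = 0.0, 0.0

    # secondary validation: parturition-day maxima vs the same goats' windows
    # ending before labor onset (prior, labor-free maxima)
    labor_max = [float(lpi_mod.daily_max_lpi(day_series[w][gt.goat_id])["lpi"])
                 for _, gt in zip(streams, ground_truths)]
    prior_max = []
    for records, gt in zip(streams, ground_truths):
        s = day_series[w][gt.goat_id]
        cutoff = gt.labor_onset if gt.labor_onset is not None else gt.birth_time
        nl = s.loc[s["window_end"] <= cutoff, "lpi"]
        if len(nl):
            prior_max.append(float(nl.max()))
    try:
        comparison = validate_groups(labor_max, prior_max)
    except InsufficientDataError:
        comparison = None

    result = CalibrationResult(
        window_min=w, tckg=tckg, mdv_min=mdv, sd_min=sd,
        n_goats=len(ground_truths), n_nonlabor=int(len(pools[w])), pool=pool)
    return result, selection, comparison
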