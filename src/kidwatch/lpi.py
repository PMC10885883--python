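"""The Labor Pain Index over time windows of a record stream.

For a window, TA is the number of activity-flagged records, TLP the number
of records the classifier labels as labor pain, and LPI = TA * TLP. The
product is large only when a doe is simultaneously very active and
persistently in the labor posture, which is exactly the pre-parturient
pattern of lateral recumbency with constantly moving legs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import LaborClassifier, predict_stream
from .errors import EmptyClassError, KidwatchError, MisalignedLabelsError

__all__ = [
    "labor_pain_index",
    "window_counts",
    "lpi_series",
    "daily_max_lpi",
    "write_series",
    "read_series",
]

SERIES_COLUMNS = ["goat_id", "window_start", "window_end", "ta", "tlp", "lpi"]


def labor_pain_index(ta: int, tlp: int) -> int:
    """LPI = TA * TLP, an exact integer product."""
    if ta < 0 or tlp < 0:
        raise KidwatchError("TA and TLP must be non-negative")
    return int(ta) * int(tlp)


def window_counts(records: pd.DataFrame, labels, window_start,
                  window_len: pd.Timedelta) -> tuple[int, int]:
    """Count (TA, TLP) in the half-open window [start, start + len)."""
    labels = np.asarray(labels)
    if labels.shape[0] != len(records):
        raise MisalignedLabelsError(
            f"{labels.shape[0]} labels for {len(records)} records")
    ts = records["timestamp"]
    start = pd.Timestamp(window_start)
    inside = (ts >= start) & (ts < start + window_len)
    ta = int((inside & records["activity"]).sum())
    tlp = int((inside.to_numpy() & (labels == 1)).sum())
    return ta, tlp


def _second_index(ts: pd.Series) -> np.ndarray:
    return ts.astype("datetime64[s]").astype("int64").to_numpy()


def lpi_series(records: pd.DataFrame,
               labels_or_model,
               window_min: float,
               stride_sec: float = 60.0,
               start: pd.Timestamp | None = None,
               end: pd.Timestamp | None = None,
               goat_id: str | None = None) -> pd.DataFrame:
    """Windowed (TA, TLP, LPI) over a time-ordered stream.

    Windows are anchored at ``start`` (default: the first record's
    timestamp) and advance by ``stride_sec`` while they fit entirely before
    ``end`` (default: one second past the last record). ``labels_or_model``
    is either a per-record 0/1 label array or a fitted
    :class:`~kidwatch.classify.LaborClassifier` applied to the stream.
    """
    if window_min <= 0 or stride_sec <= 0:
        raise KidwatchError("window_min and stride_sec must be positive")
    if isinstance(labels_or_model, LaborClassifier):
        labels = predict_stream(labels_or_model, records)
    else:
        labels = np.asarray(labels_or_model)
    if labels.shape[0] != len(records):
        raise MisalignedLabelsError(
            f"{labels.shape[0]} labels for {len(records)} records")
    if goat_id is None:
        goat_id = (str(records["gateway_id"].iloc[0])
                   if len(records) else "unknown")
    if len(records) == 0:
        return pd.DataFrame(columns=SERIES_COLUMNS)

    sec = _second_index(records["timestamp"])
    if np.any(np.diff(sec) < 0):
        raise KidwatchError("records must be time-ordered")
    t0 = int(_second_index(pd.Series([pd.Timestamp(start)]))[0]) \
        if start is not None else int(sec[0])
    t_end = int(_second_index(pd.Series([pd.Timestamp(end)]))[0]) \
        if end is not None else int(sec[-1]) + 1
    win = int(round(window_min * 60))
    stride = int(round(stride_sec))
    if t_end - t0 < win:
        return pd.DataFrame(columns=SERIES_COLUMNS)
    starts = np.arange(t0, t_end - win + 1, stride, dtype=np.int64)

    act_sec = sec[records["activity"].to_numpy()]
    lab_sec = sec[labels == 1]
    ta = (np.searchsorted(act_sec, starts + win, side="left")
          - np.searchsorted(act_sec, starts, side="left"))
    tlp = (np.searchsorted(lab_sec, starts + win, side="left")
           - np.searchsorted(lab_sec, starts, side="left"))
    epoch = pd.Timestamp(0)
    return pd.DataFrame({
        "goat_id": goat_id,
        "window_start": epoch + pd.to_timedelta(starts, unit="s"),
        "window_end": epoch + pd.to_timedelta(starts + win, unit="s"),
        "ta": ta.astype(np.int64),
        "tlp": tlp.astype(np.int64),
        "lpi": (ta * tlp).astype(np.int64),
    })


def daily_max_lpi(series: pd.DataFrame, day=None,
                  start=None, end=None) -> pd.Series:
    """The window with maximal LPI on a day (or inside [start, end)).

    Ties break toward the earliest window start. ``day`` is any date-like;
    alternatively pass an explicit half-open interval.
    """
    sel = series
    if day is not None:
        d0 = pd.Timestamp(day).normalize()
        start, end = d0, d0 + pd.Timedelta(days=1)
    if start is not None:
        sel = sel[sel["window_start"] >= pd.Timestamp(start)]
    if end is not None:
        sel = sel[sel["window_start"] < pd.Timestamp(end)]
    if len(sel) == 0:
        raise EmptyClassError("no windows in the requested day/interval")
    sel = sel.sort_values("window_start", kind="stable")
    return sel.loc[sel["lpi"].idxmax()]


def write_series(series: pd.DataFrame, path) -> None:
    out = series.loc[:, SERIES_COLUMNS].copy()
    for col in ("window_start", "window_end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["window_start", "window_end"])
    return df.loc[:, SERIES_COLUMNS]
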