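"""Read/write sensor record streams and behavior-label intervals.

The sensor CSV dialect mirrors the cloud-server fields: one row per
transmission with ``data_number, gateway_id, timestamp, rssi, battery,
activity, x, y, z``. The gateway id doubles as the goat/stream identifier.
Label intervals are half-open ``[start, end)`` at 1 s resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyClassError, KidwatchError, SchemaError

RECORD_COLUMNS = ["data_number", "gateway_id", "timestamp", "rssi",
                  "battery", "activity", "x", "y", "z"]
INTERVAL_COLUMNS = ["goat_id", "label", "start", "end"]

__all__ = [
    "RECORD_COLUMNS",
    "INTERVAL_COLUMNS",
    "ReadReport",
    "write_records",
    "read_records",
    "write_intervals",
    "read_intervals",
    "intervals_from_ground_truth",
    "build_dataset",
]


@dataclass
class ReadReport:
    """Parse outcome: per-goat streams plus an audit of rejected rows."""

    streams: dict[str, pd.DataFrame]
    n_rows: int = 0
    n_malformed: int = 0
    malformed_lines: list[int] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return sum(len(df) for df in self.streams.values())


def write_records(records: pd.DataFrame, path) -> None:
    """Write a record frame (one or many goats) to the sensor CSV dialect."""
    out = records.loc[:, RECORD_COLUMNS].copy()
    out["activity"] = out["activity"].astype(int)
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_records(path) -> ReadReport:
    """Parse a sensor CSV into per-goat, time-ordered streams.

    Malformed rows (unparseable numbers or timestamps, activity outside
    {0, 1}) are counted and reported with their 1-based line numbers, never
    silently dropped without trace.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    raw = raw.loc[:, RECORD_COLUMNS]
    n_rows = len(raw)
    if n_rows == 0:
        return ReadReport({}, 0, 0, [])

    conv = pd.DataFrame(index=raw.index)
    bad = pd.Series(False, index=raw.index)
    for col in ("data_number", "rssi", "battery", "activity", "x", "y", "z"):
        num = pd.to_numeric(raw[col], errors="coerce")
        frac = num - np.floor(num)
        col_bad = num.isna() | (frac != 0)
        bad |= col_bad
        conv[col] = num
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    bad |= ts.isna()
    bad |= ~conv["activity"].isin([0, 1])

    malformed_lines = [int(i) + 2 for i in raw.index[bad]]  # +2: header + 1-base
    good = ~bad
    df = pd.DataFrame({
        "data_number": conv.loc[good, "data_number"].astype(np.int64),
        "gateway_id": raw.loc[good, "gateway_id"],
        "timestamp": ts[good],
        "rssi": conv.loc[good, "rssi"].astype(np.int64),
        "battery": conv.loc[good, "battery"].astype(np.int64),
        "activity": conv.loc[good, "activity"].astype(bool),
        "x": conv.loc[good, "x"].astype(np.int64),
        "y": conv.loc[good, "y"].astype(np.int64),
        "z": conv.loc[good, "z"].astype(np.int64),
    })
    streams = {
        gid: g.sort_values("timestamp", kind="stable").reset_index(drop=True)
        for gid, g in df.groupby("gateway_id", sort=True)
    }
    return ReadReport(streams, n_rows, int(bad.sum()), malformed_lines)


def write_intervals(intervals: pd.DataFrame, path) -> None:
    out = intervals.loc[:, INTERVAL_COLUMNS].copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    df["label"] = df["label"].astype(int)
    _check_intervals(df)
    return df


def _check_intervals(intervals: pd.DataFrame) -> None:
    if (intervals["start"] >= intervals["end"]).any():
        raise KidwatchError("label intervals must satisfy start < end")
    for gid, g in intervals.groupby("goat_id"):
        g = g.sort_values("start")
        if (g["end"].values[:-1] > g["start"].values[1:]).any():
            raise KidwatchError(
                f"label intervals for goat {gid!r} overlap")


def intervals_from_ground_truth(ground_truths, nonlabor_hours: float = 12.0
                                ) -> pd.DataFrame:
    """Derive labeled intervals from simulated ground truth.

    Labor (label 1) covers each goat's labor episode; non-labor (label 0)
    covers the ``nonlabor_hours`` preceding the first kid's birth with the
    labor episode excised.
    """
    rows = []
    for gt in ground_truths:
        if gt.labor_interval is None:
            continue
        lab_start, lab_end = gt.labor_interval
        rows.append((gt.goat_id, 1, lab_start, lab_end))
        nl_start = max(gt.start_time,
                       gt.birth_time - pd.Timedelta(hours=nonlabor_hours))
        if nl_start < lab_start:
            rows.append((gt.goat_id, 0, nl_start, lab_start))
        if lab_end < gt.birth_time:
            rows.append((gt.goat_id, 0, lab_end, gt.birth_time))
    out = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    _check_intervals(out)
    return out


def build_dataset(streams: dict[str, pd.DataFrame],
                  intervals: pd.DataFrame,
                  balance: bool = False,
                  max_per_class: int | None = None,
                  seed: int | None = None) -> pd.DataFrame:
    """Assemble a labeled (x, y, z) training set from streams and intervals.

    Every record whose timestamp falls inside a half-open labeled interval
    contributes one sample; records outside any interval are excluded. With
    ``balance=True`` the majority class is downsampled to the minority size
    (seeded); ``max_per_class`` further caps each class.

    Raises
    ------
    EmptyClassError
        If a label present in ``intervals`` yields zero samples.
    KeyError
        If an interval references a goat absent from ``streams``.
    """
    if len(intervals) == 0:
        raise EmptyClassError("no label intervals provided")
    _check_intervals(intervals)
    parts = []
    for _, iv in intervals.iterrows():
        gid = iv["goat_id"]
        if gid not in streams:
            raise KeyError(f"interval references unknown goat {gid!r}")
        rec = streams[gid]
        ts = rec["timestamp"]
        sel = rec.loc[(ts >= iv["start"]) & (ts < iv["end"]),
                      ["timestamp", "x", "y", "z"]].copy()
        sel["goat_id"] = gid
        sel["label"] = int(iv["label"])
        parts.append(sel)
    cols = ["goat_id", "timestamp", "x", "y", "z", "label"]
    if not parts:
        ds = pd.DataFrame(columns=cols)
    else:
        ds = pd.concat(parts, ignore_index=True).loc[:, cols]
    for lab in sorted(intervals["label"].unique()):
        if (ds["label"] == int(lab)).sum() == 0:
            raise EmptyClassError(f"label {int(lab)} produced zero samples")
    if balance or max_per_class is not None:
        rng = np.random.default_rng(seed)
        counts = ds["label"].value_counts()
        cap = int(counts.min()) if balance else len(ds)
        if max_per_class is not None:
            cap = min(cap, max_per_class)
        kept = []
        for lab, g in ds.groupby("label"):
            if len(g) > cap:
                kept.append(g.iloc[rng.permutation(len(g))[:cap]])
            else:
                kept.append(g)
        ds = (pd.concat(kept)
              .sort_values(["goat_id", "timestamp"])
              .reset_index(drop=True))
    return ds
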