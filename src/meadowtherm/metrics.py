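"""The thermal-metric hierarchy.

Per probe: daily minimum / mean / maximum (DminT, DavgT, DmaxT), their 7-day
moving medians (WminT, WavgT, WmaxT -- the "weekly" metrics; the median keeps
single aberrant days from leaking into the weekly value), and the season
maxima MWavgT / MWmaxT, the standard proxies for chronic and acute thermal
exposure of cold-water fishes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import StudyDataset, TemperatureSeries

__all__ = [
    "daily_summaries",
    "weekly_moving_median",
    "season_maxima",
    "site_summary",
    "study_metrics",
]

DAILY_COLS = ["probe_id", "date", "DminT", "DavgT", "DmaxT", "n_records", "complete"]
WEEKLY_COLS = ["probe_id", "date", "WminT", "WavgT", "WmaxT", "n_days"]


def _infer_interval_minutes(ts: pd.Series) -> float:
    diffs = ts.diff().dropna().dt.total_seconds() / 60.0
    diffs = diffs[diffs > 0]
    return float(diffs.mode().iloc[0]) if len(diffs) else 30.0


def daily_summaries(
    series: TemperatureSeries,
    completeness_frac: float = 0.75,
    sampling_interval: float | None = None,
) -> pd.DataFrame:
    """One row per calendar day: DminT / DavgT / DmaxT over the day's records.

    Days with fewer than ``completeness_frac`` of the expected record count
    (1440 / sampling interval) are marked ``complete=False`` and excluded
    from the weekly metrics.  Pass ``completeness_frac=0`` to disable.
    """
    rec = series.records
    if rec.empty:
        return pd.DataFrame(columns=DAILY_COLS)
    interval = sampling_interval or _infer_interval_minutes(rec["timestamp"])
    expected = 1440.0 / interval
    g = rec.groupby(rec["timestamp"].dt.date)["temp_c"]
    df = g.agg(DminT="min", DavgT="mean", DmaxT="max", n_records="size").reset_index(
        names="date"
    )
    df.insert(0, "probe_id", series.probe_id)
    df["complete"] = df["n_records"] >= completeness_frac * expected
    return df[DAILY_COLS]


def weekly_moving_median(
    daily: pd.DataFrame,
    window_days: int = 7,
    min_days: int = 4,
    align: str = "center",
) -> pd.DataFrame:
    """Moving median of the daily metrics over ``window_days`` windows.

    Windows are centred on each date by default (``align="trailing"`` ends
    them there instead); a window must contain at least ``min_days`` complete
    days.  Calendar gaps count as missing days, so windows never silently
    bridge seasons.
    """
    if align not in ("center", "trailing"):
        raise ValueError("align must be 'center' or 'trailing'")
    if daily.empty:
        return pd.DataFrame(columns=WEEKLY_COLS)
    out = []
    for pid, grp in daily.groupby("probe_id", sort=True):
        grp = grp[grp["complete"]].sort_values("date")
        if grp.empty:
            continue
        idx = pd.DatetimeIndex(pd.to_datetime(grp["date"]))
        full = pd.date_range(idx.min(), idx.max(), freq="D")
        vals = grp.set_index(idx)[["DminT", "DavgT", "DmaxT"]].reindex(full)
        roll = vals.rolling(window_days, min_periods=min_days, center=(align == "center"))
        med = roll.median()
        n_days = vals["DavgT"].notna().rolling(
            window_days, min_periods=1, center=(align == "center")
        ).sum()
        res = pd.DataFrame(
            {
                "probe_id": pid,
                "date": full.date,
                "WminT": med["DminT"].to_numpy(),
                "WavgT": med["DavgT"].to_numpy(),
                "WmaxT": med["DmaxT"].to_numpy(),
                "n_days": n_days.to_numpy(),
            }
        )
        out.append(res.dropna(subset=["WminT", "WavgT", "WmaxT"]))
    if not out:
        return pd.DataFrame(columns=WEEKLY_COLS)
    res = pd.concat(out, ignore_index=True)
    res["n_days"] = res["n_days"].astype(int)
    return res


def season_maxima(weekly: pd.DataFrame, mode: str = "overall") -> pd.DataFrame:
    """Season maxima of the weekly metrics per probe.

    MWavgT = max WavgT, MWmaxT = max WmaxT, each with the centre date at
    which it occurs.  ``mode="per_year"`` returns one row per probe-year
    (their across-year maximum equals the overall value).
    """
    if weekly.empty:
        raise ValueError("season_maxima: empty weekly table")
    if mode not in ("overall", "per_year"):
        raise ValueError("mode must be 'overall' or 'per_year'")
    df = weekly.copy()
    keys = ["probe_id"]
    if mode == "per_year":
        df["year"] = pd.to_datetime(df["date"]).dt.year
        keys.append("year")
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        i_avg = grp["WavgT"].idxmax()
        i_max = grp["WmaxT"].idxmax()
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            MWavgT=float(grp.loc[i_avg, "WavgT"]),
            MWmaxT=float(grp.loc[i_max, "WmaxT"]),
            date_of_MWavgT=grp.loc[i_avg, "date"],
            date_of_MWmaxT=grp.loc[i_max, "date"],
        )
        rows.append(row)
    return pd.DataFrame(rows)


def site_summary(weekly: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Mean +- sd of the weekly metrics per group, over all probe-days."""
    df = weekly.copy()
    mapping = groups if isinstance(groups, dict) else groups.to_dict()
    df["group"] = df["probe_id"].map(mapping)
    agg = df.groupby("group", sort=True)[["WminT", "WavgT", "WmaxT"]].agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{'sd' if s == 'std' else s}" for m, s in agg.columns]
    return agg.reset_index()


def study_metrics(
    dataset: StudyDataset,
    completeness_frac: float = 0.75,
    min_days: int = 4,
    align: str = "center",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Daily, weekly, and season-maxima tables for every probe of a study."""
    daily = pd.concat(
        [daily_summaries(dataset.series[pid], completeness_frac) for pid in sorted(dataset.series)],
        ignore_index=True,
    )
    weekly = weekly_moving_median(daily, min_days=min_days, align=align)
    season = season_maxima(weekly)
    return daily, weekly, season
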