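"""Reading logger/metadata files and quality control.

QC follows the field protocol: whole calendar days flagged as out-of-water
are discarded atomically, and analyses are restricted to the eight warmest
weeks of the year (ISO weeks 24-31 by default).
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import ProbeMetadata, StudyDataset, TemperatureSeries

__all__ = [
    "read_logger",
    "read_probes",
    "read_willows",
    "drop_out_of_water_days",
    "select_summer_window",
    "flag_suspect_days",
    "load_study",
    "apply_qc",
    "qc_report",
]


def read_logger(path) -> TemperatureSeries | list[TemperatureSeries]:
    """Read a delimited logger file (``probe_id,timestamp,temp_c``).

    Returns one series, or a list when the file holds several probes.
    Duplicate timestamps keep the first record (with a warning); non-monotone
    timestamps are sorted with a warning; an unparseable row raises an error
    naming its line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"probe_id", "timestamp", "temp_c"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected header columns {sorted(required)}")

    temps = pd.to_numeric(df["temp_c"], errors="coerce")
    bad = temps.isna() | ~np.isfinite(temps)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: malformed temperature on line {line}")
    stamps = pd.to_datetime(df["timestamp"], errors="coerce")
    if stamps.isna().any():
        line = int(stamps.isna().idxmax()) + 2
        raise ValueError(f"{path}: malformed timestamp on line {line}")
    df = pd.DataFrame({"probe_id": df["probe_id"], "timestamp": stamps, "temp_c": temps})

    out = []
    for pid, grp in df.groupby("probe_id", sort=True):
        grp = grp.reset_index(drop=True)
        if not grp["timestamp"].is_monotonic_increasing:
            warnings.warn(f"{path}: {pid}: timestamps not sorted; sorting")
            grp = grp.sort_values("timestamp", kind="stable").reset_index(drop=True)
        dup = grp["timestamp"].duplicated()
        if dup.any():
            warnings.warn(f"{path}: {pid}: {int(dup.sum())} duplicate timestamps dropped")
            grp = grp[~dup].reset_index(drop=True)
        out.append(TemperatureSeries(str(pid), grp[["timestamp", "temp_c"]]))
    return out[0] if len(out) == 1 else out


def read_probes(path) -> list[ProbeMetadata]:
    df = pd.read_csv(path)
    fields = [
        "probe_id", "meadow", "treatment", "lat", "lon", "distance_m",
        "depth_cm", "velocity_ms", "vegetation", "habitat", "solar_pct",
    ]
    return [ProbeMetadata(**{f: row[f] for f in fields}) for _, row in df.iterrows()]


def read_willows(path, reach_lengths: dict[str, float]):
    from .types import WillowSurvey

    return WillowSurvey(records=pd.read_csv(path), reach_lengths=reach_lengths)


def drop_out_of_water_days(series: TemperatureSeries, flags=None) -> TemperatureSeries:
    """Remove every record of each flagged calendar day (whole-day atomic).

    ``flags`` is an iterable of dates; by default the series' own
    ``out_of_water`` flags are used.  Idempotent.
    """
    days = set(flags) if flags is not None else series.flagged_days("out_of_water")
    if not days:
        return series
    rec_days = series.records["timestamp"].dt.date
    span = set(rec_days)
    stale = days - span - set(series.flags)
    if stale:
        raise ValueError(f"flags reference days not in series: {sorted(stale)}")
    keep = ~rec_days.isin(days)
    kept_flags = {
        d: fl | {"out_of_water"} if d in days else fl for d, fl in series.flags.items()
    }
    for d in days:
        kept_flags.setdefault(d, frozenset({"out_of_water"}))
    return TemperatureSeries(
        series.probe_id, series.records[keep].reset_index(drop=True), kept_flags
    )


def _week_of(ts: pd.Series, convention: str) -> tuple[pd.Series, pd.Series]:
    if convention == "iso":
        iso = ts.dt.isocalendar()
        return iso.week.astype(int), iso.year.astype(int)
    if convention == "ordinal":
        week = ((ts.dt.dayofyear - 1) // 7 + 1).astype(int)
        return week, ts.dt.year.astype(int)
    raise ValueError(f"unknown week convention {convention!r}")


def select_summer_window(
    series: TemperatureSeries,
    window: tuple[int, int] = (24, 31),
    years=None,
    convention: str = "iso",
) -> TemperatureSeries:
    """Keep records within the summer week window (and years, if given)."""
    lo, hi = window
    if not (1 <= lo <= hi <= 53):
        raise ValueError(f"invalid window {window}")
    week, year = _week_of(series.records["timestamp"], convention)
    keep = (week >= lo) & (week <= hi)
    if years is not None:
        keep &= year.isin(list(years))
    out = series.records[keep.to_numpy()].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"{series.probe_id}: no records left in window {window}")
    return TemperatureSeries(series.probe_id, out, dict(series.flags))


def flag_suspect_days(series: TemperatureSeries, max_daily_range: float = 15.0) -> TemperatureSeries:
    """Optional heuristic: flag days whose diel range exceeds a threshold.

    OFF by default in the pipeline -- out-of-water days are normally known
    from field notes (or synthetic injection) rather than inferred.
    """
    by_day = series.records.groupby(series.records["timestamp"].dt.date)["temp_c"]
    ranges = by_day.max() - by_day.min()
    flags = dict(series.flags)
    for d, r in ranges.items():
        if r > max_daily_range:
            flags[d] = flags.get(d, frozenset()) | {"out_of_water"}
    return TemperatureSeries(series.probe_id, series.records, flags)


def load_study(
    data_dir,
    window: tuple[int, int] = (24, 31),
    years=None,
) -> StudyDataset:
    """Read probes.csv plus logger files from a directory.

    An optional ``out_of_water.csv`` (columns ``probe_id, date``) plays the
    role of the field notes: listed probe-days are flagged for removal.
    """
    data_dir = Path(data_dir)
    probes = read_probes(data_dir / "probes.csv")
    series: dict[str, TemperatureSeries] = {}
    long_file = data_dir / "loggers.csv"
    paths = [long_file] if long_file.exists() else sorted(data_dir.glob("logger_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no logger files under {data_dir}")
    for path in paths:
        got = read_logger(path)
        for s in got if isinstance(got, list) else [got]:
            series[s.probe_id] = s
    notes = data_dir / "out_of_water.csv"
    if notes.exists():
        flagged = pd.read_csv(notes)
        for _, row in flagged.iterrows():
            s = series.get(str(row["probe_id"]))
            if s is None:
                continue
            day = pd.Timestamp(row["date"]).date()
            s.flags[day] = s.flags.get(day, frozenset()) | {"out_of_water"}
    yrs = sorted(years) if years else sorted(
        {y for s in series.values() for y in s.records["timestamp"].dt.year.unique()}
    )
    return StudyDataset(probes=probes, series=series, window=window, years=yrs)


def apply_qc(
    dataset: StudyDataset,
    *,
    convention: str = "iso",
    range_heuristic: float | None = None,
) -> tuple[StudyDataset, pd.DataFrame]:
    """Drop out-of-water days and clip to the summer window; report removals.

    Returns the cleaned dataset and a per-probe QC table with columns
    ``probe_id, days_removed, days_kept, n_records``.
    """
    cleaned: dict[str, TemperatureSeries] = {}
    rows = []
    for pid in sorted(dataset.series):
        s = dataset.series[pid]
        if range_heuristic is not None:
            s = flag_suspect_days(s, range_heuristic)
        n_flagged = len(s.flagged_days("out_of_water"))
        s = drop_out_of_water_days(s)
        s = select_summer_window(s, dataset.window, dataset.years, convention)
        cleaned[pid] = s
        n_days = s.records["timestamp"].dt.date.nunique()
        rows.append((pid, n_flagged, n_days, len(s)))
    report = pd.DataFrame(rows, columns=["probe_id", "days_removed", "days_kept", "n_records"])
    out = StudyDataset(dataset.probes, cleaned, dataset.window, dataset.years)
    return out, report


def qc_report(report: pd.DataFrame) -> str:
    total = int(report["days_removed"].sum())
    lines = [
        f"probe-days removed (out of water): {total}",
        f"probes: {len(report)}, records retained: {int(report['n_records'].sum())}",
        "",
        report.to_string(index=False),
    ]
    return "\n".join(lines)
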