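import numpy as np
import pandas as pd
import pytest

from meadowtherm.synthetic import build_study
from meadowtherm.types import ProbeMetadata, SimulationParams, StudyDataset, TemperatureSeries


def make_meta(
    probe_id="P01",
    meadow="Mulkey",
    treatment="grazed",
    distance_m=0.0,
    solar_pct=99.0,
    lat=36.4,
    lon=-118.2,
    **kw,
):
    defaults = dict(depth_cm=25.0, velocity_ms=0.15, vegetation="sedge", habitat="riffle")
    defaults.update(kw)
    return ProbeMetadata(
        probe_id=probe_id,
        meadow=meadow,
        treatment=treatment,
        lat=lat,
        lon=lon,
        distance_m=distance_m,
        solar_pct=solar_pct,
        **defaults,
    )


def make_series(temps, probe_id="P01", start="2010-06-14", freq="30min"):
    """Series from a flat temperature list at a fixed sampling interval."""
    ts = pd.date_range(start, periods=len(temps), freq=freq)
    return TemperatureSeries(probe_id, pd.DataFrame({"timestamp": ts, "temp_c": list(temps)}))


@pytest.fixture
def quiet_params():
    """All stochastic components off: the series is the deterministic curve."""
    return SimulationParams(
        noise_sd=0.0, ar1_phi=0.0, weekly_anomaly_sd=0.0, probe_offset_sd=0.0, seed=11
    )


@pytest.fixture
def tiny_study():
    params = SimulationParams(seed=3)
    layout = {"Mulkey:grazed": (5, 400.0), "Ramshaw:ungrazed": (4, 300.0)}
    probes, series = build_study(params, layout, years=[2010], weeks=range(24, 28))
    return StudyDataset(probes, {s.probe_id: s for s in series}, years=[2010])


def naive_weekly_median(daily: pd.DataFrame, min_days: int = 4) -> pd.DataFrame:
    """Brute-force oracle: per-window sort-and-pick medians over calendar days."""
    rows = []
    for pid, grp in daily.groupby("probe_id"):
        grp = grp[grp["complete"]]
        by_date = {pd.Timestamp(d): r for d, r in zip(grp["date"], grp.to_dict("records"))}
        if not by_date:
            continue
        lo, hi = min(by_date), max(by_date)
        for centre in pd.date_range(lo, hi, freq="D"):
            window = [
                by_date[centre + pd.Timedelta(days=k)]
                for k in range(-3, 4)
                if centre + pd.Timedelta(days=k) in by_date
            ]
            if len(window) < min_days:
                continue
            rows.append(
                {
                    "probe_id": pid,
                    "date": centre.date(),
                    "WminT": float(np.median([w["DminT"] for w in window])),
                    "WavgT": float(np.median([w["DavgT"] for w in window])),
                    "WmaxT": float(np.median([w["DmaxT"] for w in window])),
                    "n_days": len(window),
                }
            )
    return pd.DataFrame(rows)


def naive_moran(values, weights):
    """Explicit O(n^2) double-sum Moran's I."""
    x = np.asarray(values, float)
    w = np.asarray(weights, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / float(z @ z)


def random_daily_table(rng, n_days=30, probe_id="P01", missing_frac=0.15):
    """Random daily-metric table with gaps, for oracle comparisons."""
    dates = pd.date_range("2011-06-13", periods=n_days, freq="D")
    keep = rng.random(n_days) > missing_frac
    lo = rng.normal(8, 2, n_days)
    hi = lo + rng.gamma(2.0, 2.0, n_days)
    mid = lo + (hi - lo) * rng.random(n_days)
    df = pd.DataFrame(
        {
            "probe_id": probe_id,
            "date": dates.date,
            "DminT": lo,
            "DavgT": mid,
            "DmaxT": hi,
            "n_records": 48,
            "complete": True,
        }
    )
    return df[keep].reset_index(drop=True)
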