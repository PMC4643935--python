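"""Synthetic probe network and logger time-series generator.

The generator emulates the statistical structure of the field study: three
meadow streams carrying 13-30 loggers each, sampled every 20-30 minutes over
the eight warmest weeks (ISO weeks 24-31) of several summers.  The daily mean
at a probe is

    reach baseline + (gradient / slope) * distance/100 m
    + zero-mean seasonal half-sine + meadow-wide weekly AR(1) anomaly
    + persistent probe-level microhabitat offset,

on which a diel sinusoid rides (amplitude set by solar exposure, sunny vs
shaded at the 98% threshold) plus AR(1) logger noise whose cross-probe
correlation decays as exp(-d / spatial_range) along the stream.

The diel amplitude is additionally modulated by the 7-day-median-smoothed
daily-mean anomaly so that the daily maximum responds to the weekly average
temperature with the prescribed ``max_vs_avg_slope`` -- the relationship the
climate projection model fits -- which also makes the configured
``gradient_per_100m`` the downstream trend of the daily maximum itself, the
observable the gradient analysis reports.

Randomness is keyed hierarchically off one root seed: meadow-level streams
(weekly weather) by meadow and year, probe-level innovation streams by a
stable hash of the probe id, so different meadows never share randomness.
"""

from __future__ import annotations

import zlib
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .types import (
    HABITAT_CLASSES,
    SOLAR_SUNNY_THRESHOLD,
    VEGETATION_CLASSES,
    ProbeMetadata,
    SimulationParams,
    TemperatureSeries,
    WillowSurvey,
    per_group,
)

__all__ = [
    "default_layout",
    "build_study",
    "simulate_series",
    "simulate_willows",
    "inject_out_of_water",
    "write_study",
    "write_willows",
    "reach_mean_wavgt",
]

#: (probe count, reach length m) per reach; the study deployment:
#: 17 + 13 probes in partially grazed Mulkey, 30 in Ramshaw, 21 in Big Whitney.
DEFAULT_LAYOUT = {
    "Mulkey:grazed": (17, 900.0),
    "Mulkey:ungrazed": (13, 1200.0),
    "Ramshaw:ungrazed": (30, 1500.0),
    "BigWhitney:ungrazed": (21, 1200.0),
}

DEFAULT_YEARS = (2010, 2011, 2012)
DEFAULT_WEEKS = range(24, 32)

_MEADOW_CENTER = {  # (lat, lon) anchors, decimal degrees
    "Mulkey": (36.4053, -118.1950),
    "Ramshaw": (36.3481, -118.2479),
    "BigWhitney": (36.4397, -118.2699),
}
_ABBREV = {"Mulkey": "Mu", "Ramshaw": "Ra", "BigWhitney": "BW"}
_DEG_PER_M = 1.0 / 111_320.0

#: Gap (m) assumed between the grazed reach outlet and the exclosure inlet
#: when reaches of one meadow are placed on a common stream coordinate.
_REACH_GAP_M = 100.0


def default_layout() -> dict[str, tuple[int, float]]:
    return dict(DEFAULT_LAYOUT)


def _rng(seed: int, *keys) -> np.random.Generator:
    """Generator keyed by the root seed plus stable hashes of string keys."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _split_reach(reach: str) -> tuple[str, str]:
    meadow, _, treatment = reach.partition(":")
    return meadow, treatment or "ungrazed"


def _meadow_base(params: SimulationParams, meadow: str) -> float:
    """Meadow-level reference mean: average of the reach baselines."""
    mm = params.meadow_means
    if isinstance(mm, (int, float)):
        return float(mm)
    vals = [v for k, v in mm.items() if k == meadow or k.startswith(meadow + ":")]
    if not vals:
        return per_group(mm, meadow)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# calendar helpers

def _week_dates(year: int, weeks) -> tuple[list[date], np.ndarray]:
    """Calendar days of the given ISO weeks and each day's ISO week number."""
    weeks = sorted(set(int(w) for w in weeks))
    if not weeks:
        raise ValueError("empty week range")
    if weeks[0] < 1 or weeks[-1] > 53:
        raise ValueError("weeks must lie in 1..53")
    days: list[date] = []
    wk: list[int] = []
    for w in weeks:
        monday = date.fromisocalendar(year, w, 1)
        days.extend(monday + timedelta(days=i) for i in range(7))
        wk.extend([w] * 7)
    return days, np.asarray(wk)


def _seasonal(params: SimulationParams, year: int, days: list[date]) -> np.ndarray:
    """Half-sine summer anomaly peaking near the configured peak week.

    Centred to zero mean over the simulated days so that ``meadow_means``
    keep their interpretation as summer-mean temperatures.
    """
    peak = date.fromisocalendar(year, params.seasonal_peak_week, 4).toordinal()
    span = 56.0
    t = np.array([d.toordinal() for d in days], dtype=float)
    phase = np.pi * (t - (peak - span / 2)) / span
    pulse = np.sin(np.clip(phase, 0.0, np.pi))
    return params.seasonal_amplitude * (pulse - pulse.mean())


def _weekly_anomaly(params: SimulationParams, meadow: str, year: int, weeks: np.ndarray) -> np.ndarray:
    """Weekly AR(1) 'weather' anomaly, one value per ISO week.

    Shared across meadows: the study meadows lie within ~10 km on the same
    plateau, so summer weather is regional -- which is also why the
    comparison model's month random intercept is common to all meadows.
    """
    uw = np.unique(weeks)
    if params.weekly_anomaly_sd == 0:
        return np.zeros(len(weeks))
    rng = _rng(params.seed, "weekly", "region", year)
    phi = params.weekly_anomaly_phi
    z = rng.standard_normal(len(uw))
    zeta = np.empty(len(uw))
    zeta[0] = z[0]
    for i in range(1, len(uw)):
        zeta[i] = phi * zeta[i - 1] + np.sqrt(1 - phi**2) * z[i]
    zeta *= params.weekly_anomaly_sd
    lookup = dict(zip(uw.tolist(), zeta))
    return np.array([lookup[w] for w in weeks])


def _centered_median7(x: np.ndarray) -> np.ndarray:
    """Centered 7-day running median along the last axis (shrinking edges)."""
    n = x.shape[-1]
    out = np.empty_like(x, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - 3), min(n, i + 4)
        out[..., i] = np.median(x[..., lo:hi], axis=-1)
    return out


# ---------------------------------------------------------------------------
# deterministic skeleton

def _daily_structure(
    metas: list[ProbeMetadata], params: SimulationParams, weeks, year: int
) -> tuple[list[date], np.ndarray, np.ndarray, np.ndarray, float]:
    """Daily means and amplitude ingredients for probes of ONE meadow.

    Returns (days, m, a_base, slope, ref) with m and a_base of shape
    (n_probes, n_days) and (n_probes,).
    """
    days, wk = _week_dates(year, weeks)
    meadow = metas[0].meadow
    seasonal = _seasonal(params, year, days)
    zeta = _weekly_anomaly(params, meadow, year, wk)

    slope = np.array([per_group(params.max_vs_avg_slope, p.meadow, p.treatment) for p in metas])
    # the configured gradient is the observable (daily-maximum) trend; the
    # daily-mean trend is gradient / slope so that max responds at `gradient`
    base = np.array(
        [
            per_group(params.meadow_means, p.meadow, p.treatment)
            + per_group(params.gradient_per_100m, p.meadow, p.treatment)
            / s
            * p.distance_m
            / 100.0
            + (
                _rng(params.seed, "probe_offset", p.probe_id).normal(0.0, params.probe_offset_sd)
                if params.probe_offset_sd > 0
                else 0.0
            )
            for p, s in zip(metas, slope)
        ]
    )
    m = base[:, None] + (seasonal + zeta)[None, :]

    sunny = np.array([p.solar_pct >= SOLAR_SUNNY_THRESHOLD for p in metas])
    a_sunny = np.array([per_group(params.diel_amplitude_sunny, p.meadow, p.treatment) for p in metas])
    a_shaded = np.array([per_group(params.diel_amplitude_shaded, p.meadow, p.treatment) for p in metas])
    a_base = np.where(sunny, a_sunny, a_shaded)

    ref = _meadow_base(params, meadow)
    return days, m, a_base, slope, ref


def _stream_positions(metas: list[ProbeMetadata]) -> np.ndarray:
    """Along-stream coordinate for probes of one meadow (grazed upstream)."""
    pos = np.empty(len(metas))
    grazed_len = max(
        (p.distance_m for p in metas if p.treatment == "grazed"), default=0.0
    )
    for i, p in enumerate(metas):
        if p.treatment == "grazed" or grazed_len == 0.0:
            pos[i] = p.distance_m
        else:
            pos[i] = grazed_len + _REACH_GAP_M + p.distance_m
    return pos


def _noise(
    metas: list[ProbeMetadata],
    params: SimulationParams,
    year: int,
    n_steps: int,
    correlate: bool,
) -> np.ndarray:
    """Stationary AR(1) logger noise, optionally spatially correlated."""
    if params.noise_sd == 0:
        return np.zeros((len(metas), n_steps))
    z = np.vstack(
        [_rng(params.seed, "noise", p.probe_id, year).standard_normal(n_steps) for p in metas]
    )
    if correlate and len(metas) > 1 and params.spatial_range > 0:
        pos = _stream_positions(metas)
        dist = np.abs(pos[:, None] - pos[None, :])
        cov = np.exp(-dist / params.spatial_range)
        z = np.linalg.cholesky(cov + 1e-10 * np.eye(len(metas))) @ z
    phi = params.ar1_phi
    w = z * np.sqrt(1 - phi**2)
    w[:, 0] = z[:, 0]  # exact stationary start: var = 1 at every step
    eps = lfilter([1.0], [1.0, -phi], w, axis=1)
    return params.noise_sd * eps


def _assemble_series(
    metas: list[ProbeMetadata],
    params: SimulationParams,
    weeks,
    year: int,
    correlate: bool,
) -> list[TemperatureSeries]:
    days, m, a_base, slope, ref = _daily_structure(metas, params, weeks, year)
    per_day = 1440 // params.sampling_interval
    minutes = np.arange(per_day) * params.sampling_interval
    # diel sinusoid peaking at 16:00, trough at 04:00, zero daily mean
    diel = np.cos(2 * np.pi * (minutes / 60.0 - 16.0) / 24.0)

    eps = _noise(metas, params, year, len(days) * per_day, correlate)
    # the diel amplitude tracks the realized 7-day-median smoothed daily
    # mean (the weekly thermal state of the stream), so the daily maximum
    # responds to the measured weekly average with slope `max_vs_avg_slope`
    day_mean_noise = eps.reshape(len(metas), len(days), per_day).mean(axis=2)
    smoothed = _centered_median7(m + day_mean_noise)
    amp = np.maximum(a_base[:, None] + (slope[:, None] - 1.0) * (smoothed - ref), 0.1)

    det = m[:, :, None] + amp[:, :, None] * diel[None, None, :]
    det = det.reshape(len(metas), -1)
    det += eps

    base_ts = np.array(
        [np.datetime64(d) + np.timedelta64(int(mm), "m") for d in days for mm in minutes]
    )
    out = []
    for i, p in enumerate(metas):
        rec = pd.DataFrame({"timestamp": pd.to_datetime(base_ts), "temp_c": det[i]})
        out.append(TemperatureSeries(probe_id=p.probe_id, records=rec))
    return out


def simulate_series(
    meta: ProbeMetadata,
    params: SimulationParams,
    weeks=DEFAULT_WEEKS,
    year: int = DEFAULT_YEARS[0],
) -> TemperatureSeries:
    """Simulate one probe's logger record for the given ISO weeks of a year.

    Cross-probe noise correlation only applies when probes are simulated
    jointly via :func:`build_study`; a standalone probe gets its own
    (hash-seeded) independent noise stream.
    """
    return _assemble_series([meta], params, weeks, year, correlate=False)[0]


# ---------------------------------------------------------------------------
# probe metadata

_VEG_PROBS = {
    "grazed": (0.10, 0.50, 0.25, 0.15),
    "ungrazed": (0.50, 0.25, 0.15, 0.10),
}
_VELOCITY = {
    "Mulkey:grazed": 0.13,
    "Mulkey:ungrazed": 0.10,
    "Ramshaw": 0.21,
    "BigWhitney": 0.35,
}


def _make_probes(params: SimulationParams, layout: dict[str, tuple[int, float]]) -> list[ProbeMetadata]:
    probes: list[ProbeMetadata] = []
    upstream_offset: dict[str, float] = {}
    for reach in sorted(layout):
        n, length = layout[reach]
        if n < 2:
            raise ValueError(f"{reach}: need at least 2 probes per reach")
        if length <= 0:
            raise ValueError(f"{reach}: reach length must be > 0")
        meadow, treatment = _split_reach(reach)
        rng = _rng(params.seed, "meta", reach)
        dists = np.linspace(0.0, length, n)
        lat0, lon0 = _MEADOW_CENTER.get(meadow, (36.4, -118.2))
        # grazed section sits upstream of the exclosure on the same stream
        off = upstream_offset.get(meadow, 0.0)
        upstream_offset[meadow] = off + length + _REACH_GAP_M
        p_sunny = per_group(params.sunny_fraction, meadow, treatment)
        veg_p = _VEG_PROBS.get(treatment, _VEG_PROBS["ungrazed"])
        prefix = _ABBREV.get(meadow, meadow[:2]) + treatment[0].upper()
        for i, d in enumerate(dists):
            sunny = rng.random() < p_sunny
            solar = rng.uniform(98.0, 100.0) if sunny else rng.uniform(60.0, 97.9)
            probes.append(
                ProbeMetadata(
                    probe_id=f"{prefix}{i + 1:02d}",
                    meadow=meadow,
                    treatment=treatment,
                    lat=lat0 - (off + d) * _DEG_PER_M,
                    lon=lon0 + 3e-4 * np.sin((off + d) / 150.0),
                    distance_m=float(d),
                    depth_cm=float(np.round(rng.lognormal(3.3, 0.35), 1)),
                    velocity_ms=float(
                        np.round(max(0.01, rng.normal(per_group(_VELOCITY, meadow, treatment), 0.08)), 2)
                    ),
                    vegetation=str(rng.choice(VEGETATION_CLASSES, p=veg_p)),
                    habitat=str(rng.choice(HABITAT_CLASSES, p=(0.45, 0.45, 0.10))),
                    solar_pct=float(np.round(solar, 1)),
                )
            )
    ids = [p.probe_id for p in probes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate probe ids in layout")
    return probes


def build_study(
    params: SimulationParams,
    layout: dict[str, tuple[int, float]] | None = None,
    years=DEFAULT_YEARS,
    weeks=DEFAULT_WEEKS,
) -> tuple[list[ProbeMetadata], list[TemperatureSeries]]:
    """Simulate the full probe network: metadata plus one series per probe.

    Series cover all requested ISO weeks of all requested years; noise is
    spatially correlated within each meadow.  Deterministic given
    ``params.seed``.
    """
    if not list(weeks):
        raise ValueError("empty week range")
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("empty year list")
    probes = _make_probes(params, layout or default_layout())

    by_meadow: dict[str, list[ProbeMetadata]] = {}
    for p in probes:
        by_meadow.setdefault(p.meadow, []).append(p)

    chunks: dict[str, list[pd.DataFrame]] = {p.probe_id: [] for p in probes}
    for meadow in sorted(by_meadow):
        metas = by_meadow[meadow]
        for year in years:
            for s in _assemble_series(metas, params, weeks, year, correlate=True):
                chunks[s.probe_id].append(s.records)
    series = [
        TemperatureSeries(pid, pd.concat(parts, ignore_index=True))
        for pid, parts in chunks.items()
    ]
    return probes, series


def reach_mean_wavgt(params: SimulationParams, layout: dict[str, tuple[int, float]] | None = None) -> dict[str, float]:
    """Closed-form expected summer-mean temperature per reach.

    Average of the deterministic daily mean over evenly spaced probes:
    baseline + (gradient / slope) * (mean distance)/100; the seasonal
    anomaly, weekly anomaly and probe offsets average to zero.
    """
    layout = layout or default_layout()
    out = {}
    for reach, (_, length) in layout.items():
        meadow, treatment = _split_reach(reach)
        base = per_group(params.meadow_means, meadow, treatment)
        grad = per_group(params.gradient_per_100m, meadow, treatment)
        slope = per_group(params.max_vs_avg_slope, meadow, treatment)
        out[reach] = base + grad / slope * (length / 2.0) / 100.0
    return out


# ---------------------------------------------------------------------------
# willows

DEFAULT_WILLOW_LENGTHS = {"Mulkey:ungrazed": 1200.0, "Mulkey:grazed": 900.0}
#: stem counts observed along the bank transects (exclosure vs grazed)
DEFAULT_WILLOW_COUNTS = {"Mulkey:ungrazed": 980, "Mulkey:grazed": 75}
#: stem height mean/sd in cm per reach
DEFAULT_WILLOW_HEIGHTS = {"Mulkey:ungrazed": (92.0, 56.0), "Mulkey:grazed": (43.0, 29.0)}


def simulate_willows(
    reach_lengths: dict[str, float] | None = None,
    *,
    counts: dict[str, int] | None = None,
    density: dict[str, float] | float | None = None,
    height_mean_sd: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> WillowSurvey:
    """Simulate a bank-willow census along one transect per reach.

    By default the exact observed stem counts (980 inside the exclosure over
    1200 m, 75 outside over 900 m) are drawn at uniform positions with
    truncated-normal heights (floor 1 cm).  Pass ``density`` (stems/m) for
    Poisson counts instead.
    """
    reach_lengths = dict(reach_lengths or DEFAULT_WILLOW_LENGTHS)
    for reach, length in reach_lengths.items():
        if length <= 0:
            raise ValueError(f"{reach}: reach length must be > 0")
    if density is None and counts is None:
        counts = dict(DEFAULT_WILLOW_COUNTS)
    height_mean_sd = height_mean_sd or DEFAULT_WILLOW_HEIGHTS

    rows = []
    for reach in sorted(reach_lengths):
        length = reach_lengths[reach]
        rng = _rng(seed, "willows", reach)
        if counts is not None:
            n = int(counts[reach])
        else:
            dens = density[reach] if isinstance(density, dict) else float(density)
            if dens <= 0:
                raise ValueError(f"{reach}: density must be > 0")
            n = int(rng.poisson(dens * length))
        mean, sd = height_mean_sd[reach]
        heights = np.maximum(rng.normal(mean, sd, size=n), 1.0)
        positions = np.sort(rng.uniform(0.0, length, size=n))
        _, treatment = _split_reach(reach)
        for pos, h in zip(positions, heights):
            rows.append((reach, treatment, float(pos), float(h)))
    records = pd.DataFrame(rows, columns=["reach", "treatment", "position_m", "height_cm"])
    return WillowSurvey(records=records, reach_lengths=reach_lengths)


# ---------------------------------------------------------------------------
# out-of-water artifacts

def inject_out_of_water(
    series: TemperatureSeries, day_list, seed: int = 0
) -> TemperatureSeries:
    """Replace the listed days' records with air-like readings and flag them.

    Air readings swing much harder than water: the injected diel range is
    at least 2.5x the largest clean daily range, plus high-frequency noise,
    mimicking a logger stranded on the bank.
    """
    day_list = [d.date() if hasattr(d, "date") else d for d in day_list]
    if not day_list:
        return series
    rec = series.records
    rec_days = rec["timestamp"].dt.date
    span = set(rec_days)
    missing = [d for d in day_list if d not in span]
    if missing:
        raise ValueError(f"days not in series span: {missing}")

    by_day = rec.groupby(rec_days)["temp_c"]
    ranges = by_day.max() - by_day.min()
    means = by_day.mean()
    air_amp = 1.25 * float(ranges.max()) + 1.0

    out = rec.copy()
    rng = _rng(seed, "oow", series.probe_id)
    for d in day_list:
        mask = (rec_days == d).to_numpy()
        hours = rec.loc[mask, "timestamp"].dt.hour + rec.loc[mask, "timestamp"].dt.minute / 60.0
        air = (
            means[d]
            + 3.0
            + air_amp * np.cos(2 * np.pi * (hours - 15.0) / 24.0)
            + rng.normal(0.0, 1.5, size=int(mask.sum()))
        )
        out.loc[mask, "temp_c"] = air.to_numpy()
    flags = dict(series.flags)
    for d in day_list:
        flags[d] = flags.get(d, frozenset()) | {"out_of_water"}
    return TemperatureSeries(series.probe_id, out, flags)


# ---------------------------------------------------------------------------
# writers (delimited text; the ingest module reads these back)

def write_study(out_dir, probes, series, *, long_format: bool = False) -> None:
    """Write probes.csv plus logger files (one per probe, or one long file)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .types import probes_frame

    probes_frame(probes).to_csv(out / "probes.csv", index=False)
    frames = []
    for s in sorted(series, key=lambda s: s.probe_id):
        df = s.records.assign(probe_id=s.probe_id)[["probe_id", "timestamp", "temp_c"]]
        if long_format:
            frames.append(df)
        else:
            df.to_csv(out / f"logger_{s.probe_id}.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    if long_format:
        pd.concat(frames, ignore_index=True).to_csv(
            out / "loggers.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S"
        )


def write_willows(path, survey: WillowSurvey) -> None:
    survey.records.to_csv(path, index=False)
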