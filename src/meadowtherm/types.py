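"""Core domain types shared across the pipeline.

Tabular data (metric tables, aggregated summaries, reports) travels as pandas
DataFrames with documented column names; the dataclasses below carry the
structured objects: probe metadata, logger series, simulation parameters, and
fitted-model results.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Union

import pandas as pd

#: Canonical meadow labels of the study system (two rested meadows and one
#: partially grazed meadow split by a livestock exclosure).
MEADOWS = ("Mulkey", "Ramshaw", "BigWhitney")

VEGETATION_CLASSES = ("willow", "sedge", "grass", "none")
HABITAT_CLASSES = ("pool", "riffle", "underbank")

#: Solar exposure (in percent) at or above this value counts as "sunny";
#: below it the channel is considered shaded.
SOLAR_SUNNY_THRESHOLD = 98.0

PerGroup = Union[float, Mapping[str, float]]


def per_group(value: PerGroup, meadow: str, treatment: str | None = None) -> float:
    """Resolve a scalar-or-mapping parameter for one reach.

    Mappings are keyed by ``"Meadow:treatment"`` (most specific), ``"Meadow"``,
    or ``"default"``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    if treatment is not None and f"{meadow}:{treatment}" in value:
        return float(value[f"{meadow}:{treatment}"])
    if meadow in value:
        return float(value[meadow])
    if "default" in value:
        return float(value["default"])
    raise KeyError(f"no value for meadow {meadow!r} (treatment {treatment!r})")


@dataclass(frozen=True)
class ProbeMetadata:
    """Identity and environmental covariates of one temperature logger."""

    probe_id: str
    meadow: str
    treatment: str  # "grazed" | "ungrazed"
    lat: float
    lon: float
    distance_m: float  # from the most-upstream probe of its reach
    depth_cm: float
    velocity_ms: float
    vegetation: str
    habitat: str
    solar_pct: float

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValueError("distance_m must be >= 0")
        if not 0.0 <= self.solar_pct <= 100.0:
            raise ValueError("solar_pct must be in [0, 100]")

    @property
    def reach(self) -> str:
        return f"{self.meadow}:{self.treatment}"


def probes_frame(probes: list[ProbeMetadata]) -> pd.DataFrame:
    """Metadata list as a DataFrame (one row per probe)."""
    df = pd.DataFrame([dataclasses.asdict(p) for p in probes])
    df["reach"] = [p.reach for p in probes]
    return df


@dataclass
class TemperatureSeries:
    """Timestamped water-temperature records for one probe.

    ``records`` has columns ``timestamp`` (datetime64) and ``temp_c`` (float),
    strictly increasing in time.  ``flags`` maps calendar dates to QC flag
    sets (e.g. ``{"out_of_water"}``).
    """

    probe_id: str
    records: pd.DataFrame
    flags: dict[date, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ts = self.records["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"{self.probe_id}: timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.records)

    def flagged_days(self, flag: str) -> set[date]:
        return {d for d, fl in self.flags.items() if flag in fl}


@dataclass
class SimulationParams:
    """Generative settings for the synthetic probe network.

    Defaults encode the study conditions.  ``meadow_means`` are summer-mean
    water temperatures at the upstream probe of each reach, chosen so reach
    averages land on the observed summaries (13.2/13.0 C in the grazed and
    ungrazed areas of Mulkey, 11.8 C Ramshaw, 10.7 C Big Whitney).
    ``gradient_per_100m`` is the downstream trend of the *daily maximum*
    (the observable the gradient analysis reports): +0.41 C/100 m in the
    grazed reach, -0.25 C/100 m inside the exclosure; the underlying
    daily-mean trend is gradient / max_vs_avg_slope.  Max-vs-avg slopes
    default to 1.74 (Mulkey), 1.62 (Ramshaw), 1.48 (Big Whitney).

    Scalar-or-mapping fields accept a single float or a per-reach mapping
    (see :func:`per_group`).
    """

    meadow_means: PerGroup = field(
        default_factory=lambda: {
            "Mulkey:grazed": 12.1,
            "Mulkey:ungrazed": 13.9,
            "Ramshaw": 11.8,
            "BigWhitney": 10.7,
        }
    )
    diel_amplitude_sunny: PerGroup = field(
        default_factory=lambda: {"Mulkey": 5.4, "Ramshaw": 4.3, "BigWhitney": 5.8}
    )
    diel_amplitude_shaded: PerGroup = field(
        default_factory=lambda: {"Mulkey": 3.4, "Ramshaw": 2.3, "BigWhitney": 3.8}
    )
    seasonal_amplitude: float = 2.5
    seasonal_peak_week: int = 28
    gradient_per_100m: PerGroup = field(
        default_factory=lambda: {
            "Mulkey:grazed": 0.41,
            "Mulkey:ungrazed": -0.25,
            "default": 0.0,
        }
    )
    ar1_phi: float = 0.9  # per sampling step (water has strong thermal inertia)
    noise_sd: float = 0.8  # marginal sd of the fast logger noise, C
    weekly_anomaly_sd: float = 0.8  # meadow-wide "weather" sd, C
    weekly_anomaly_phi: float = 0.6  # AR(1) of the weekly anomaly
    probe_offset_sd: float = 0.8  # persistent microhabitat offset sd, C
    spatial_range: float = 25.0  # e-folding distance of noise correlation, m
    sampling_interval: int = 30  # minutes
    max_vs_avg_slope: PerGroup = field(
        default_factory=lambda: {"Mulkey": 1.74, "Ramshaw": 1.62, "BigWhitney": 1.48}
    )
    sunny_fraction: PerGroup = field(
        default_factory=lambda: {
            "Mulkey:grazed": 0.954,
            "Mulkey:ungrazed": 0.841,
            "default": 0.90,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.noise_sd < 0 or self.weekly_anomaly_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if self.sampling_interval not in (20, 30):
            raise ValueError("sampling_interval must be 20 or 30 minutes")
        if self.spatial_range < 0:
            raise ValueError("spatial_range must be >= 0")


@dataclass
class StudyDataset:
    """All probes and series of one (real or synthetic) study."""

    probes: list[ProbeMetadata]
    series: dict[str, TemperatureSeries]
    window: tuple[int, int] = (24, 31)
    years: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {p.probe_id for p in self.probes}
        missing = set(self.series) - ids
        if missing:
            raise ValueError(f"series without metadata: {sorted(missing)}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= 53):
            raise ValueError(f"invalid week window {self.window}")

    @property
    def probes_df(self) -> pd.DataFrame:
        return probes_frame(self.probes)


@dataclass
class WillowSurvey:
    """Bank-willow census: one row per stem, plus surveyed reach lengths.

    ``records`` columns: ``reach``, ``treatment``, ``position_m``,
    ``height_cm``.
    """

    records: pd.DataFrame
    reach_lengths: dict[str, float]

    def __post_init__(self) -> None:
        if (self.records["height_cm"] <= 0).any():
            raise ValueError("willow heights must be > 0")
        for reach, grp in self.records.groupby("reach"):
            length = self.reach_lengths[reach]
            pos = grp["position_m"]
            if (pos < 0).any() or (pos > length).any():
                raise ValueError(f"{reach}: positions outside [0, {length}]")


@dataclass(frozen=True)
class MoranResult:
    """Moran's I with its randomization null moments and two-sided p."""

    I: float
    expected_I: float
    sd_I: float
    p_value: float

    @property
    def z(self) -> float:
        return (self.I - self.expected_I) / self.sd_I


@dataclass(frozen=True)
class GradientFit:
    """Per-reach OLS of season-maximum temperature on downstream distance."""

    reach: str
    slope_per_100m: float
    se_per_100m: float
    t: float
    df: int
    p_value: float
    n_probes: int
    intercept: float
    residual_moran: MoranResult | None = None


@dataclass(frozen=True)
class GroupContrast:
    """Pairwise group difference from the mixed-model comparison."""

    metric: str
    scale: str  # week | month | year
    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b), C
    se: float
    t: float
    df: float  # Satterthwaite-approximated
    p_value: float
    moran_i: float | None = None
    moran_p: float | None = None


@dataclass(frozen=True)
class ScenarioSpec:
    """One climate scenario: air warming scaled to water by a fixed ratio."""

    label: str
    delta_air: float
    ratio: float = 0.5
    delta_water: float | None = None

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.delta_water is None:
            object.__setattr__(self, "delta_water", self.delta_air * self.ratio)
        elif abs(self.delta_water - self.delta_air * self.ratio) > 0.06:
            raise ValueError(
                f"delta_water {self.delta_water} inconsistent with "
                f"delta_air * ratio = {self.delta_air * self.ratio}"
            )


@dataclass
class MeadowResponse:
    """Per-meadow fitted max-vs-avg response."""

    meadow: str
    slope: float
    slope_se: float
    intercept: float
    date_re_sd: float
    residual_sd: float
    n_obs: int
    singular: bool = False

    def sd_total(self, mode: str = "total") -> float:
        if mode == "residual_only":
            return self.residual_sd
        return float((self.residual_sd**2 + self.date_re_sd**2) ** 0.5)


@dataclass
class ProjectionModel:
    """Fitted daily-maximum vs weekly-average temperature response.

    ``responses`` holds the per-meadow fits used for projection;
    ``slope_differences`` the interaction-model contrasts of each meadow's
    slope against the reference meadow (estimate, se, t, df, p).
    """

    responses: dict[str, MeadowResponse]
    reference: str
    slope_differences: dict[str, tuple[float, float, float, float, float]]

    def __post_init__(self) -> None:
        if self.reference not in self.responses:
            raise ValueError("reference meadow not among fitted meadows")
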